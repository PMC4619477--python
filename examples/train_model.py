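"""Retrain the SNP scoring network from scratch.

Generates the fuzzy-scored synthetic feature samples (443 training, 147
validation), trains the 3-10-1 network with Levenberg-Marquardt, and prints
the optimisation trajectory. With a fixed seed the resulting model file is
bit-identical across runs.
"""

from sangerhet import snpnet

train_set, valid_set = snpnet.generate_training_set(443, 147, seed=20151024)
model, history = snpnet.train(
    train_set, valid_set, snpnet.LMConfig(seed=20151024)
)

print(f"iterations run: {len(history.records)}")
print(f"final training SSE (targets on [0,1]): {history.v_train[-1]:.4f}")
best = min(history.mse_valid)
print(f"best validation MSE: {best:.6f} at iteration {history.best_iteration}")
# The accepted-step SSE sequence never increases — the mu/beta schedule only
# commits steps that lower the error. The returned model is the snapshot
# with the best validation MSE (early stopping), not the last iterate.

snpnet.save_model(model, "model.json")
print("model written to model.json")
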