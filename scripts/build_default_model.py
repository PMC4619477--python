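"""Regenerate the packaged default SNP scoring model.

Run from the repository root:

    python scripts/build_default_model.py

Writes src/sangerhet/data/default_model.json deterministically; the same
file is reproduced bit-exactly by `sangerhet train --seed 20151024`.
"""

from pathlib import Path

from sangerhet import snpnet

model, history = snpnet.train_default_model()
dest = Path(__file__).resolve().parent.parent / "src" / "sangerhet" / "data" / "default_model.json"
dest.parent.mkdir(parents=True, exist_ok=True)
snpnet.save_model(model, dest)
print(f"wrote {dest}")
print(
    f"iterations={len(history.records)} converged={history.converged} "
    f"best validation MSE={min(history.mse_valid):.6f} "
    f"at iteration {history.best_iteration}"
)
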