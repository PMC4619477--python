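"""Neural SNP scoring: fuzzy-scored training data, Levenberg-Marquardt
training of a 3-10-1 back-propagation network, and six-grade classification.

The three double-peak features, normalized to [0, 1] (0 = ideal heterozygous
double peak), are scored in [1, 100] by a small feed-forward network with ten
logistic hidden units and a linear output. Because no hand-labelled corpus of
double-peak features exists, training targets come from a Mamdani fuzzy
system: each feature is graded good/fair/poor by triangular memberships and
a 27-rule base maps the combined quality to one of four score classes —
true (centroid 87.5), vague (67.5), false (40) and strongly-false (10) —
whose supports coincide with the reporting score bands. Centroid
defuzzification of the aggregated output membership gives the target score.

Training minimises the summed squared residual V(w) = sum_k (d_k - y_k)^2
with the Levenberg-Marquardt update

    delta_w = -(J^T J + mu I)^{-1} J^T e

adapting mu by a factor beta: divide on an accepted step (V decreased),
multiply and retry on a rejected one. Targets are trained on the [0, 1]
scale (score / 100); the stopping error epsilon applies to V on that scale.

Grades: score >= 75 -> 1 (true SNP); 60 <= score < 75 -> vague, split by the
noisy-wave count into 2 (<= 1), 3 (== 2) and 4 (> 2); 20 <= score < 60 -> 5
(false); score < 20 -> 6 (strongly false).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import peaks as _peaks
from .types import BasePositionFeatures, ChromatogramTrace, DegenerateFeatureError, NoisyWaveRule, SnpCall
from .wavelet import denoise_trace

FUZZY_RULE_VERSION = "tri3-sumquality-v1"

#: centroids and symmetric triangular supports of the four output classes;
#: supports sit exactly on the reporting score bands.
_OUTPUT_CLASSES = (
    ("true", 87.5, 75.0, 100.0),
    ("vague", 67.5, 60.0, 75.0),
    ("false", 40.0, 20.0, 60.0),
    ("strongly_false", 10.0, 1.0, 19.0),
)

_SCORE_GRID = np.linspace(1.0, 100.0, 9901)


def _tri(x, a, b, c):
    """Triangular membership with feet a, c and peak b (edge-saturating)."""
    x = np.asarray(x, dtype=float)
    left = np.ones_like(x) if b == a else np.clip((x - a) / (b - a), 0.0, 1.0)
    right = np.ones_like(x) if c == b else np.clip((c - x) / (c - b), 0.0, 1.0)
    return np.minimum(left, right)


def _feature_memberships(x: float) -> np.ndarray:
    """Membership of one normalized feature in (good, fair, poor)."""
    return np.array(
        [
            _tri(x, 0.0, 0.0, 0.5),
            _tri(x, 0.0, 0.5, 1.0),
            _tri(x, 0.5, 1.0, 1.0),
        ],
        dtype=float,
    )


def _class_of(q1: int, q2: int, q3: int) -> int:
    """Rule consequent: quality indices (0 good .. 2 poor) to output class."""
    s = q1 + q2 + q3
    if s == 0:
        return 0
    if s <= 2:
        return 1
    if s <= 4:
        return 2
    return 3


def fuzzy_score(features: Sequence[float]) -> float:
    """Mamdani fuzzy score in [1, 100] for a normalized feature triple.

    Features must lie in [0, 1]; 0 is ideal (coincident equal peaks).
    """
    f = np.asarray(features, dtype=float)
    if f.shape != (3,):
        raise ValueError("expected exactly three features")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("normalized features must lie in [0, 1]")
    mus = [_feature_memberships(x) for x in f]
    activation = np.zeros(4)
    for q1 in range(3):
        for q2 in range(3):
            for q3 in range(3):
                fire = min(mus[0][q1], mus[1][q2], mus[2][q3])
                c = _class_of(q1, q2, q3)
                if fire > activation[c]:
                    activation[c] = fire
    agg = np.zeros_like(_SCORE_GRID)
    for (name, centroid, a, c), act in zip(_OUTPUT_CLASSES, activation):
        if act > 0:
            np.maximum(agg, np.minimum(act, _tri(_SCORE_GRID, a, centroid, c)), out=agg)
    total = agg.sum()
    if total == 0:  # unreachable: memberships cover [0,1]
        return 1.0
    return float(np.clip((_SCORE_GRID * agg).sum() / total, 1.0, 100.0))


@dataclass(frozen=True)
class TrainingSample:
    features: np.ndarray  # normalized triple in [0,1]^3
    target_score: float  # de-fuzzified score in [1,100]

    def __post_init__(self) -> None:
        if not 1.0 <= self.target_score <= 100.0:
            raise ValueError("target_score out of [1, 100]")


def generate_training_set(
    n_train: int = 443, n_valid: int = 147, seed: int = 0
) -> tuple[list[TrainingSample], list[TrainingSample]]:
    """Space-filling synthetic samples over the normalized feature cube.

    Features are drawn by Latin-hypercube stratification of [0, 1]^3 so the
    network sees the whole feature space; targets come from the fuzzy system.
    """
    if n_train < 1 or n_valid < 1:
        raise ValueError("sample counts must be >= 1")
    rng = np.random.default_rng(seed)

    def lhs(n: int) -> np.ndarray:
        cols = []
        for _ in range(3):
            strata = (rng.permutation(n) + rng.uniform(size=n)) / n
            cols.append(strata)
        return np.column_stack(cols)

    def build(n: int) -> list[TrainingSample]:
        X = lhs(n)
        return [TrainingSample(x, fuzzy_score(x)) for x in X]

    return build(n_train), build(n_valid)


@dataclass
class NetworkModel:
    """3-10-1 network weights plus the feature scaler used at call time."""

    w1: np.ndarray  # (3, 10) input -> hidden
    b1: np.ndarray  # (10,) hidden thresholds
    w2: np.ndarray  # (10,) hidden -> output
    b2: float
    feature_min: np.ndarray = field(default_factory=lambda: np.zeros(3))
    feature_max: np.ndarray = field(default_factory=lambda: np.ones(3))
    fuzzy_rule_version: str = FUZZY_RULE_VERSION
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float).reshape(3, 10)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(10)
        self.w2 = np.asarray(self.w2, dtype=float).reshape(10)
        self.b2 = float(self.b2)
        self.feature_min = np.asarray(self.feature_min, dtype=float).reshape(3)
        self.feature_max = np.asarray(self.feature_max, dtype=float).reshape(3)
        for a in (self.w1, self.b1, self.w2):
            if not np.all(np.isfinite(a)):
                raise ValueError("weights must be finite")
        if np.any(self.feature_min >= self.feature_max):
            raise ValueError("scaler mins must be < maxes")

    # --- parameter vector layout: w1 (30), b1 (10), w2 (10), b2 (1) ---
    def pack(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2, [self.b2]])

    @classmethod
    def unpack(cls, params: np.ndarray, **kw) -> "NetworkModel":
        params = np.asarray(params, dtype=float)
        if params.shape != (51,):
            raise ValueError("expected 51 parameters")
        return cls(
            w1=params[:30].reshape(3, 10),
            b1=params[30:40],
            w2=params[40:50],
            b2=params[50],
            **kw,
        )


@dataclass(frozen=True)
class LMConfig:
    epsilon: float = 0.1
    mu0: float = 0.01
    beta: float = 10.0
    max_iterations: int = 110
    seed: int = 0
    mu_max: float = 1e12  # overflow guard on repeated rejections

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.mu0 <= 0 or self.beta <= 1:
            raise ValueError("require epsilon > 0, mu0 > 0, beta > 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_raw(model: NetworkModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw network output on the [0, 1] target scale. X is (n, 3)."""
    Z = X @ model.w1 + model.b1
    H = _sigmoid(Z)
    y = H @ model.w2 + model.b2
    return y, H


def forward(model: NetworkModel, features: Sequence[float]) -> tuple[float, np.ndarray]:
    """Score one normalized feature triple; returns (score, hidden vector).

    The raw linear output lives on the [0, 1] training-target scale; the
    score rescales it by 100 and clamps to [1, 100].
    """
    x = np.asarray(features, dtype=float).reshape(1, 3)
    y, H = _forward_raw(model, x)
    return float(np.clip(100.0 * y[0], 1.0, 100.0)), H[0]


def _residuals_jacobian(
    model: NetworkModel, X: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals e = d - y and their analytic Jacobian J (n, 51)."""
    Z = X @ model.w1 + model.b1
    H = _sigmoid(Z)
    y = H @ model.w2 + model.b2
    e = d - y
    n = len(d)
    dydh = model.w2  # (10,)
    s = H * (1.0 - H)  # sigmoid'
    g = s * dydh  # (n, 10) dy/dz_j
    J = np.empty((n, 51))
    # dy/dw1[i, j] = g_j * x_i
    J[:, :30] = (X[:, :, None] * g[:, None, :]).reshape(n, 30)
    J[:, 30:40] = g  # dy/db1_j
    J[:, 40:50] = H  # dy/dw2_j
    J[:, 50] = 1.0  # dy/db2
    np.negative(J, out=J)  # residual jacobian = -dy/dw
    return e, J


def lm_update(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations for the LM weight step."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    e = np.asarray(e, dtype=float).ravel()
    A = J.T @ J + mu * np.eye(J.shape[1])
    try:
        return np.linalg.solve(A, -(J.T @ e))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations singular; raise mu and retry"
        ) from exc


def _stack(samples: Sequence[TrainingSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.features for s in samples], dtype=float)
    d = np.array([s.target_score for s in samples], dtype=float) / 100.0
    return X, d


def lm_step(
    model: NetworkModel, samples: Sequence[TrainingSample], mu: float
) -> tuple[np.ndarray, float]:
    """One Levenberg-Marquardt step: returns (delta_w, V) for the 51 weights."""
    if not samples:
        raise ValueError("need at least one sample")
    X, d = _stack(samples)
    e, J = _residuals_jacobian(model, X, d)
    return lm_update(J, e, mu), float(e @ e)


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)
    converged: bool = False
    best_iteration: int = -1

    @property
    def v_train(self) -> list[float]:
        return [r["V_train"] for r in self.records]

    @property
    def mse_valid(self) -> list[float]:
        return [r["mse_valid"] for r in self.records]


def train(
    train_samples: Sequence[TrainingSample],
    valid_samples: Sequence[TrainingSample],
    config: LMConfig = LMConfig(),
) -> tuple[NetworkModel, TrainHistory]:
    """Train by Levenberg-Marquardt with mu adaptation and early stopping.

    Weights initialise uniform (0, 1) from ``config.seed``. Each iteration
    computes the residual Jacobian once; a trial step is accepted when it
    lowers V(w) (then mu /= beta), otherwise mu *= beta and the step is
    recomputed from the same Jacobian. Training stops when V < epsilon, the
    iteration budget is spent, or mu overflows its guard (converged=False).
    Returns the snapshot with the best validation MSE and the full history.
    """
    if not train_samples or not valid_samples:
        raise ValueError("need nonempty training and validation sets")
    rng = np.random.default_rng(config.seed)
    params = rng.uniform(0.0, 1.0, size=51)
    Xt, dt = _stack(train_samples)
    Xv, dv = _stack(valid_samples)

    def sse(p: np.ndarray) -> float:
        m = NetworkModel.unpack(p)
        y, _ = _forward_raw(m, Xt)
        return float(np.sum((dt - y) ** 2))

    def vmse(p: np.ndarray) -> float:
        m = NetworkModel.unpack(p)
        y, _ = _forward_raw(m, Xv)
        return float(np.mean((dv - y) ** 2))

    history = TrainHistory()
    mu = config.mu0
    V = sse(params)
    best = (vmse(params), params.copy(), -1)
    aborted = False
    for it in range(config.max_iterations):
        if V < config.epsilon:
            break
        e, J = _residuals_jacobian(NetworkModel.unpack(params), Xt, dt)
        accepted = False
        while True:
            try:
                delta = lm_update(J, e, mu)
            except np.linalg.LinAlgError:
                mu = max(mu * config.beta, config.mu0)
                continue
            trial = params + delta
            V_trial = sse(trial)
            if V_trial < V:
                params, V = trial, V_trial
                mu /= config.beta
                accepted = True
                break
            mu *= config.beta
            if mu > config.mu_max:
                break
        mv = vmse(params)
        history.records.append(
            {"iteration": it, "V_train": V, "mse_valid": mv, "mu": mu,
             "accepted": accepted}
        )
        if mv < best[0]:
            best = (mv, params.copy(), it)
        if not accepted:
            aborted = True
            break
    history.converged = (V < config.epsilon) and not aborted
    history.best_iteration = best[2]
    model = NetworkModel.unpack(best[1], seed=config.seed)
    return model, history


def assign_grade(score: float, noisy_count: int) -> int:
    """Six-grade classification from score bands and the noisy-wave count."""
    if not 1.0 <= score <= 100.0:
        raise ValueError("score out of [1, 100]")
    if noisy_count < 0:
        raise ValueError("noisy_count must be >= 0")
    if score >= 75.0:
        return 1
    if score >= 60.0:
        if noisy_count <= 1:
            return 2
        if noisy_count == 2:
            return 3
        return 4
    if score >= 20.0:
        return 5
    return 6


def normalize_features(
    feat: BasePositionFeatures,
    median_spacing: float,
    feature_min: np.ndarray,
    feature_max: np.ndarray,
    r_max: float = 5.0,
) -> np.ndarray:
    """Map raw features into [0, 1]^3 (0 = ideal double peak).

    Distance is divided by the trace's median inter-peak spacing; each ratio
    r is folded to max(r, 1/r) and mapped by (r - 1) / (r_max - 1); all
    clamped to [0, 1], then passed through the model's stored scaler.
    """
    d = feat.horizontal_distance / max(median_spacing, 1.0)
    h = feat.height_ratio
    w = feat.halfwave_width_ratio
    w = max(w, 1.0 / w) if w > 0 else r_max
    raw = np.array(
        [d, (h - 1.0) / (r_max - 1.0), (w - 1.0) / (r_max - 1.0)], dtype=float
    )
    raw = np.clip(raw, 0.0, 1.0)
    scaled = (raw - feature_min) / (feature_max - feature_min)
    return np.clip(scaled, 0.0, 1.0)


def call_snps(
    trace: ChromatogramTrace,
    model: NetworkModel,
    max_grade: int = 4,
    *,
    levels: int = 3,
    search_halfwidth: Optional[int] = None,
    floor_fraction: float = 0.10,
    noisy_rule: NoisyWaveRule = NoisyWaveRule(),
) -> list[SnpCall]:
    """Score every base position of a trace and return SNP calls.

    The trace is denoised first; positions without a resolvable secondary
    peak, or with degenerate features, are skipped. Calls with grade <=
    ``max_grade`` are returned sorted by base position.
    """
    if not 1 <= max_grade <= 6:
        raise ValueError("max_grade must lie in 1..6")
    dn = denoise_trace(trace, levels)
    spacing = _peaks.median_peak_spacing(dn)
    if search_halfwidth is None:
        search_halfwidth = _peaks.default_search_halfwidth(dn)
    calls: list[SnpCall] = []
    for i in range(dn.n_bases):
        try:
            primary, secondary = _peaks.primary_secondary(
                dn, i, search_halfwidth, floor_fraction
            )
        except _peaks.MalformedPositionError:
            continue
        if secondary is None:
            continue
        feat = _peaks.features_with_fallback(primary, secondary, i)
        if feat is None:
            continue
        x = normalize_features(feat, spacing, model.feature_min, model.feature_max)
        score, _ = forward(model, x)
        noisy = _peaks.count_noisy_waves(dn, i, secondary, noisy_rule, search_halfwidth)
        grade = assign_grade(score, noisy)
        if grade <= max_grade:
            calls.append(
                SnpCall(
                    base_index=i,
                    primary_base=primary.channel,
                    secondary_base=secondary.channel,
                    score=score,
                    grade=grade,
                    noisy_count=noisy,
                )
            )
    return sorted(calls, key=lambda c: c.base_index)


# --- persistence ---------------------------------------------------------


def save_model(model: NetworkModel, path) -> None:
    """Write a model as deterministic JSON (sorted keys, shortest floats)."""
    doc = {
        "architecture": "3-10-1",
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "feature_min": model.feature_min.tolist(),
        "feature_max": model.feature_max.tolist(),
        "fuzzy_rule_version": model.fuzzy_rule_version,
        "seed": model.seed,
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _model_from_doc(doc: dict) -> NetworkModel:
    return NetworkModel(
        w1=doc["w1"],
        b1=doc["b1"],
        w2=doc["w2"],
        b2=doc["b2"],
        feature_min=doc["feature_min"],
        feature_max=doc["feature_max"],
        fuzzy_rule_version=doc.get("fuzzy_rule_version", "unknown"),
        seed=doc.get("seed"),
    )


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return _model_from_doc(json.load(fh))


DEFAULT_MODEL_SEED = 20151024


def train_default_model(seed: int = DEFAULT_MODEL_SEED) -> tuple[NetworkModel, TrainHistory]:
    """Regenerate the shipped default model (443/147 samples, 110 iterations)."""
    tr, va = generate_training_set(443, 147, seed=seed)
    return train(tr, va, LMConfig(seed=seed))


def default_model() -> NetworkModel:
    """The pre-trained model shipped with the package."""
    with resources.files("sangerhet.data").joinpath("default_model.json").open() as fh:
        return _model_from_doc(json.load(fh))
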