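"""Per-residue nonsense predictor: ensembles of small neural networks.

Each member is a fully connected network with 23 inputs, one hidden layer
of 20 logistic units and a single logistic output, trained by full-batch
Adam on squared error against soft targets (0.1 for true-protein residues,
0.9 for nonsense residues) with patience-based early stopping on an
independent balanced validation sample.  The ensemble prediction is the
arithmetic mean of the 10 members' outputs; residues and whole sequences
are classified at the 0.5 threshold.

The network is implemented directly in numpy: the model is a logistic-output
least-squares regressor, a combination the mainstream MLP implementations do
not expose, and the training loop doubles as the reproducibility contract
(bitwise-identical weights under a fixed seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit as _sigmoid

from .dataset_builder import BalancedSample, ResidueDataset, balance_sample
from .sequence_features import FEATURE_NAMES, FeatureMatrix

N_FEATURES = len(FEATURE_NAMES)


@dataclass
class NetworkWeights:
    """Weights of one 23 -> hidden -> 1 logistic network."""

    w1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    train_epochs: int = 0
    val_mse: float = float("nan")

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = _sigmoid(X @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)


@dataclass
class TrainConfig:
    hidden: int = 20
    max_epochs: int = 300
    patience: int = 15
    learning_rate: float = 0.05

    def to_dict(self) -> dict:
        return {
            "hidden": self.hidden, "max_epochs": self.max_epochs,
            "patience": self.patience, "learning_rate": self.learning_rate,
        }


def train_network(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> NetworkWeights:
    """Train one network; deterministic for a fixed seed.

    Inputs are expected already standardized.  Early stopping keeps the
    weights of the epoch with the lowest validation squared error and gives
    up after ``patience`` epochs without improvement.
    """
    cfg = config or TrainConfig()
    if not (np.isfinite(X_train).all() and np.isfinite(X_val).all()):
        raise ValueError("non-finite feature values")
    if X_train.size == 0:
        raise ValueError("empty training sample")

    rng = np.random.default_rng(seed)
    n_in, nh = X_train.shape[1], cfg.hidden
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, nh))
    b1 = np.zeros(nh)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(nh), size=nh)
    b2 = 0.0

    # Adam state
    params = [w1, b1, w2, np.array([b2])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = cfg.learning_rate

    best = None
    best_val = np.inf
    best_epoch = 0
    stall = 0
    n = len(X_train)
    for epoch in range(1, cfg.max_epochs + 1):
        h = _sigmoid(X_train @ params[0] + params[1])
        out = _sigmoid(h @ params[2] + params[3][0])
        err = out - y_train
        # d(mse)/d(out_logit) for logistic output with squared error
        delta_out = (2.0 / n) * err * out * (1.0 - out)
        g_w2 = h.T @ delta_out
        g_b2 = np.array([delta_out.sum()])
        delta_h = np.outer(delta_out, params[2]) * h * (1.0 - h)
        g_w1 = X_train.T @ delta_h
        g_b1 = delta_h.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]
        for i, g in enumerate(grads):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mhat = m[i] / (1 - beta1 ** epoch)
            vhat = v[i] / (1 - beta2 ** epoch)
            params[i] -= lr * mhat / (np.sqrt(vhat) + eps)

        hv = _sigmoid(X_val @ params[0] + params[1])
        val_mse = float(np.mean((_sigmoid(hv @ params[2] + params[3][0]) - y_val) ** 2))
        if val_mse < best_val - 1e-9:
            best_val = val_mse
            best = [p.copy() for p in params]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    assert best is not None
    return NetworkWeights(
        w1=best[0], b1=best[1], w2=best[2], b2=float(best[3][0]),
        train_epochs=best_epoch, val_mse=best_val,
    )


@dataclass
class Ensemble:
    """Mean-of-members nonsense predictor with its feature scaling."""

    members: list[NetworkWeights]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    metadata: dict = field(default_factory=dict)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale

    def predict_standardized(self, Z: np.ndarray) -> np.ndarray:
        return np.mean([net.forward(Z) for net in self.members], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 2 or X.shape[1] != len(self.feature_mean):
            raise ValueError(
                f"expected {len(self.feature_mean)} feature columns, got {X.shape}"
            )
        return self.predict_standardized(self.standardize(X))


def train_ensemble(
    dataset: ResidueDataset,
    n_members: int = 10,
    base_seed: int = 0,
    indices: np.ndarray | None = None,
    train_frac: float = 0.08,
    val_frac: float = 0.02,
    config: TrainConfig | None = None,
) -> Ensemble:
    """Train ``n_members`` networks, each on its own independently drawn
    balanced train/validation sample (seeded ``base_seed + member``).

    Feature location/scale are estimated once from the full available pool
    and shared by all members.
    """
    cfg = config or TrainConfig()
    pool = np.arange(len(dataset)) if indices is None else np.asarray(indices)
    X_pool = dataset.features[pool]
    mean = X_pool.mean(axis=0)
    scale = X_pool.std(axis=0)
    scale[scale == 0] = 1.0

    members: list[NetworkWeights] = []
    samples: list[BalancedSample] = []
    y_all = dataset.targets
    for k in range(n_members):
        sample = balance_sample(
            dataset, train_frac=train_frac, val_frac=val_frac,
            seed=base_seed + k, indices=pool,
        )
        Xt = (dataset.features[sample.train_idx] - mean) / scale
        Xv = (dataset.features[sample.val_idx] - mean) / scale
        members.append(
            train_network(
                Xt, y_all[sample.train_idx], Xv, y_all[sample.val_idx],
                config=cfg, seed=base_seed + k,
            )
        )
        samples.append(sample)
    return Ensemble(
        members=members,
        feature_mean=mean,
        feature_scale=scale,
        metadata={
            "base_seed": base_seed, "n_members": n_members,
            "train_frac": train_frac, "val_frac": val_frac,
            "config": cfg.to_dict(),
        },
    )


def predict_residues(model: Ensemble, fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-residue nonsense scores in (0, 1)."""
    X = fm.rows if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    return model.predict(X)


def predict_protein(scores: np.ndarray, threshold: float = 0.5) -> tuple[float, bool]:
    """Aggregate per-residue scores into one per-sequence prediction."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no residue scores")
    mean = float(scores.mean())
    return mean, mean > threshold


def nonsense_content(scores: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of residues predicted nonsense (score above threshold)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no residue scores")
    return float(np.count_nonzero(scores > threshold)) / scores.size


# ---------------------------------------------------------------------------
# model persistence (versioned JSON)

_MODEL_FORMAT = "nonsenseq-ensemble-1"


def save_ensemble(model: Ensemble, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "feature_names": FEATURE_NAMES,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "metadata": model.metadata,
        "members": [
            {
                "w1": net.w1.tolist(), "b1": net.b1.tolist(),
                "w2": net.w2.tolist(), "b2": net.b2,
                "train_epochs": net.train_epochs, "val_mse": net.val_mse,
            }
            for net in model.members
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path: str | Path) -> Ensemble:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"unrecognized model format: {doc.get('format')!r}")
    members = [
        NetworkWeights(
            w1=np.array(mdoc["w1"]), b1=np.array(mdoc["b1"]),
            w2=np.array(mdoc["w2"]), b2=float(mdoc["b2"]),
            train_epochs=int(mdoc["train_epochs"]), val_mse=float(mdoc["val_mse"]),
        )
        for mdoc in doc["members"]
    ]
    return Ensemble(
        members=members,
        feature_mean=np.array(doc["feature_mean"]),
        feature_scale=np.array(doc["feature_scale"]),
        metadata=doc["metadata"],
    )
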