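"""Feature impact via finite-difference partial derivatives.

The contribution of each input feature to the prediction function is
estimated as the forward difference (pred(x + eps_i) - pred(x)) / eps at
every point of a dataset, averaged per feature.  The sign gives the
direction of the contribution, the magnitude its impact.  Derivatives are
taken on the standardized feature scale the networks actually see, with a
two-epsilon stability check available because the step size is a numerical
choice, not part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .sequence_features import FEATURE_NAMES

PredFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class ImpactEstimate:
    per_feature_mean_derivative: np.ndarray
    epsilon: float
    n_points: int

    def to_frame(self, pooled_freqs: np.ndarray | None = None) -> pd.DataFrame:
        d = self.per_feature_mean_derivative
        df = pd.DataFrame({
            "feature": FEATURE_NAMES[: len(d)],
            "mean_derivative": d,
            "abs_mean_derivative": np.abs(d),
        })
        df["rank"] = df["abs_mean_derivative"].rank(ascending=False).astype(int)
        if pooled_freqs is not None:
            freq = np.full(len(d), np.nan)
            freq[: len(pooled_freqs)] = pooled_freqs
            df["pooled_frequency"] = freq
        return df


def partial_derivative(
    pred_fn: PredFn, x: np.ndarray, i: int, eps: float = 0.01
) -> float:
    """Forward-difference estimate of d pred / d feature_i at point ``x``."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=float)
    if not 0 <= i < x.size:
        raise IndexError(f"feature index {i} out of range")
    xp = x.copy()
    xp[i] += eps
    f0, f1 = pred_fn(x[None, :]), pred_fn(xp[None, :])
    out = (float(f1[0]) - float(f0[0])) / eps
    if not np.isfinite(out):
        raise ValueError("prediction function returned a non-finite value")
    return out


def mean_feature_impacts(
    pred_fn: PredFn, points: np.ndarray, eps: float = 0.01
) -> ImpactEstimate:
    """Per-feature mean of forward-difference derivatives over ``points``.

    Vectorized: one batched prediction per feature plus the baseline.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("points must be a non-empty 2-D array")
    base = np.asarray(pred_fn(X), dtype=float)
    if not np.isfinite(base).all():
        raise ValueError("prediction function returned non-finite values")
    n, d = X.shape
    means = np.empty(d)
    for i in range(d):
        Xp = X.copy()
        Xp[:, i] += eps
        means[i] = float(np.mean((np.asarray(pred_fn(Xp)) - base) / eps))
    return ImpactEstimate(means, eps, n)


def impact_stability(
    pred_fn: PredFn, points: np.ndarray, eps_pair: tuple[float, float] = (0.01, 0.005)
) -> pd.DataFrame:
    """Impacts at two step sizes side by side, with their relative change."""
    a = mean_feature_impacts(pred_fn, points, eps_pair[0])
    b = mean_feature_impacts(pred_fn, points, eps_pair[1])
    da, db = a.per_feature_mean_derivative, b.per_feature_mean_derivative
    denom = np.maximum(np.abs(da), np.abs(db))
    rel = np.where(denom > 0, np.abs(da - db) / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame({
        "feature": FEATURE_NAMES[: len(da)],
        f"mean_derivative_eps_{eps_pair[0]}": da,
        f"mean_derivative_eps_{eps_pair[1]}": db,
        "relative_change": rel,
    })
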