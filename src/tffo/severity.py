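"""Disease-severity analysis from the distance-to-healthy feature.

Each patient's feature vector is summarized by its Euclidean distance to
the element-wise mean feature vector of the healthy group; a monotone
transform (natural log by default, since the distance is strictly positive)
linearizes the heavily right-skewed raw distances.  Hospitalization counts
are mapped onto an exponential 6-rank scale — bins (1), (2), (3–4), (5–7),
(8–15), (16+) — and ridge regression of rank on transformed distance
quantifies how much severity variance the EEG feature explains.  The
"severe half" checks count how many of the top-k patients by a clinical
covariate fall in the upper half of the distance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hospitalization_rank",
    "distance_to_healthy",
    "RidgeFit",
    "fit_severity",
    "severe_half_check",
]

#: (inclusive lower bound, rank); upper bounds implied by the next bin.
_HOSP_BINS = [(1, 1), (2, 2), (3, 3), (5, 4), (8, 5), (16, 6)]


class DataError(ValueError):
    pass


def hospitalization_rank(n: int) -> int:
    """Rank 1..6 of a hospitalization count on the exponential scale.

    Bins: 1→1, 2→2, 3–4→3, 5–7→4, 8–15→5, 16+→6.  Counts below 1 are
    rejected (patients have at least one documented hospitalization).
    """
    if n < 1:
        raise DataError(f"hospitalization count must be >= 1, got {n}")
    rank = 0
    for lo, r in _HOSP_BINS:
        if n >= lo:
            rank = r
    return rank


def distance_to_healthy(features, transform: str = "log") -> pd.DataFrame:
    """Per-subject Euclidean distance to the healthy-group mean feature.

    For a healthy subject the group mean excludes that subject.  Returns a
    DataFrame indexed by subject with columns ``group``, ``distance`` and
    ``transformed_distance`` (natural log by default; ``transform="identity"``
    keeps the raw distance).
    """
    if transform not in ("log", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    values = np.asarray(features.values, dtype=float)
    subjects = list(features.values.index)
    labels = pd.Series(features.labels).reindex(subjects)
    healthy_mask = (labels == "healthy").to_numpy()
    if healthy_mask.sum() < 2:
        raise DataError("need >= 2 healthy subjects for a leave-one-out centroid")
    healthy_sum = values[healthy_mask].sum(axis=0)
    n_healthy = int(healthy_mask.sum())
    rows = []
    for i, subj in enumerate(subjects):
        if healthy_mask[i]:
            centroid = (healthy_sum - values[i]) / (n_healthy - 1)
        else:
            centroid = healthy_sum / n_healthy
        d = float(np.linalg.norm(values[i] - centroid))
        rows.append(
            {
                "group": labels.iloc[i],
                "distance": d,
                "transformed_distance": float(np.log(d)) if transform == "log" else d,
            }
        )
    return pd.DataFrame(rows, index=subjects)


@dataclass
class RidgeFit:
    """Closed-form one-predictor ridge fit of severity rank on distance."""

    slope: float
    intercept: float
    penalty: float
    r2_in_sample: float
    r2_loo: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _ridge_1d(x, y, penalty):
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / (sxx + penalty)
    return slope, ym - slope * xm


def _loo_r2(x, y, penalty):
    n = len(x)
    resid = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        slope, intercept = _ridge_1d(x[mask], y[mask], penalty)
        resid[i] = y[i] - (intercept + slope * x[i])
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - float(np.sum(resid**2) / ss_tot)


def fit_severity(distances, ranks, penalty="auto") -> RidgeFit:
    """Ridge regression of severity rank on the transformed distance.

    ``penalty`` is the ridge strength λ in the closed-form solution
    slope = Sxy / (Sxx + λ); ``"auto"`` picks λ from a log grid (including
    0) by leave-one-out squared error.  Reports both the in-sample R² and
    the leave-one-out R² to expose fitting optimism.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(ranks, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise DataError("need >= 5 paired (distance, rank) observations")
    if np.allclose(x, x[0]):
        raise DataError("zero-variance distance predictor")
    if penalty == "auto":
        grid = np.concatenate([[0.0], np.logspace(-4, 3, 15)])
        penalty = float(grid[int(np.argmax([_loo_r2(x, y, lam) for lam in grid]))])
    elif penalty < 0:
        raise DataError("penalty must be >= 0")
    slope, intercept = _ridge_1d(x, y, penalty)
    pred = intercept + slope * x
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2_in = 1.0 - float(np.sum((y - pred) ** 2) / ss_tot) if ss_tot > 0 else float("nan")
    return RidgeFit(
        slope=float(slope),
        intercept=float(intercept),
        penalty=float(penalty),
        r2_in_sample=r2_in,
        r2_loo=_loo_r2(x, y, penalty),
    )


def severe_half_check(distance: pd.Series, covariate: pd.Series, top_k: int = 5) -> int:
    """How many of the top-k covariate patients sit in the severe half.

    The severe half is the ⌈n/2⌉ patients with the largest distance.  Ties
    — in the covariate and in the distance — are broken by stable subject
    order (the Series index order), making the count deterministic.
    """
    distance = pd.Series(distance)
    covariate = pd.Series(covariate).reindex(distance.index)
    n = len(distance)
    if n < 2 * top_k:
        raise DataError(f"need >= {2 * top_k} patients, got {n}")
    # negate before the stable argsort so ties keep subject order
    order_cov = (-covariate.to_numpy(dtype=float)).argsort(kind="stable")[:top_k]
    top_subjects = set(distance.index[order_cov])
    half = -(-n // 2)  # ceil
    order_dist = (-distance.to_numpy(dtype=float)).argsort(kind="stable")[:half]
    severe = set(distance.index[order_dist])
    return len(top_subjects & severe)
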