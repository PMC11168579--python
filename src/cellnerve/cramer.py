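"""Baringhaus–Franz multivariate two-sample (Cramér) test with bootstrap p.

Given samples X1..Xm and Y1..Yn in R^d with distributions F and G, the test
statistic weighs between-sample distances positively and within-sample
distances negatively:

    T = mn/(m+n) * [ 1/(mn) Σij φ(‖Xi−Yj‖²)
                     − 1/(2m²) Σij φ(‖Xi−Xj‖²)
                     − 1/(2n²) Σij φ(‖Yi−Yj‖²) ]

With the default kernel φ(z) = √z / 2 the bracket is half the energy
distance between the empirical laws, so T ≥ 0 with equality iff they
coincide, and the null F = G is rejected for large T.  P-values are
estimated by resampling: the ordinary bootstrap draws m+n points with
replacement from the pooled sample and splits them into pseudo-samples of
sizes m and n.  The p-value is the plain fraction of replicates with
T* ≥ T_observed (no +1 correction), so it is exactly zero when the observed
statistic exceeds every bootstrap value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

__all__ = [
    "TwoSampleResult",
    "cramer_statistic",
    "bootstrap_p",
    "compare_feature_cohorts",
    "kernel_half_euclidean",
]

RESAMPLING_MODES = ("ordinary_bootstrap", "permutation")


def kernel_half_euclidean(z: np.ndarray) -> np.ndarray:
    """Default kernel φ(z) = √z / 2 applied to squared distances."""
    return np.sqrt(z) / 2.0


@dataclass(frozen=True)
class TwoSampleResult:
    """Outcome of the two-sample comparison."""

    statistic: float
    p_value: float
    m: int
    n: int
    replicates: int
    seed: int | None
    kernel: str
    resampling: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _as_sample(X, name: str) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, np.newaxis]
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError(f"sample {name} must be a non-empty 2D array of vectors")
    return arr


def _statistic_from_kernel(K: np.ndarray, ix: np.ndarray, iy: np.ndarray) -> float:
    m, n = len(ix), len(iy)
    cross = K[np.ix_(ix, iy)].mean()
    within_x = K[np.ix_(ix, ix)].mean()
    within_y = K[np.ix_(iy, iy)].mean()
    return m * n / (m + n) * (cross - 0.5 * within_x - 0.5 * within_y)


def cramer_statistic(
    X, Y, kernel: Callable[[np.ndarray], np.ndarray] = kernel_half_euclidean
) -> float:
    """The Cramér statistic T between two samples of d-vectors.

    ``kernel`` maps squared Euclidean distances to contributions; the
    default half-Euclidean kernel yields the energy-distance form.
    """
    X, Y = _as_sample(X, "X"), _as_sample(Y, "Y")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    pool = np.vstack([X, Y])
    K = kernel(cdist(pool, pool, "sqeuclidean"))
    m = X.shape[0]
    return float(_statistic_from_kernel(K, np.arange(m), np.arange(m, len(pool))))


def bootstrap_p(
    X,
    Y,
    B: int = 1000,
    seed: int | None = None,
    resampling: str = "ordinary_bootstrap",
    kernel: Callable[[np.ndarray], np.ndarray] = kernel_half_euclidean,
) -> TwoSampleResult:
    """Two-sample test with resampled null distribution.

    ``resampling="ordinary_bootstrap"`` (default) draws m+n pooled points
    with replacement per replicate; ``"permutation"`` reshuffles the pooled
    sample without replacement.  Fully reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError(f"need at least one replicate, got B={B}")
    if resampling not in RESAMPLING_MODES:
        raise ValueError(f"resampling must be one of {RESAMPLING_MODES}, got {resampling!r}")
    X, Y = _as_sample(X, "X"), _as_sample(Y, "Y")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    m, n = X.shape[0], Y.shape[0]
    pool = np.vstack([X, Y])
    K = kernel(cdist(pool, pool, "sqeuclidean"))
    t_obs = _statistic_from_kernel(K, np.arange(m), np.arange(m + n)[m:])

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        if resampling == "ordinary_bootstrap":
            idx = rng.integers(0, m + n, size=m + n)
        else:
            idx = rng.permutation(m + n)
        t_b = _statistic_from_kernel(K, idx[:m], idx[m:])
        if t_b >= t_obs:
            exceed += 1
    kernel_name = getattr(kernel, "__name__", "custom")
    return TwoSampleResult(
        statistic=float(t_obs),
        p_value=exceed / B,
        m=m,
        n=n,
        replicates=B,
        seed=seed,
        kernel=kernel_name,
        resampling=resampling,
    )


def compare_feature_cohorts(
    matrix: FeatureMatrix,
    B: int = 1000,
    seed: int | None = None,
    resampling: str = "ordinary_bootstrap",
    kernel: Callable[[np.ndarray], np.ndarray] = kernel_half_euclidean,
) -> TwoSampleResult:
    """Run the Cramér test between the two cohorts of a feature matrix."""
    cohorts = matrix.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly two cohorts, found {cohorts}")
    X = matrix.cohort_values(cohorts[0])
    Y = matrix.cohort_values(cohorts[1])
    return bootstrap_p(X, Y, B=B, seed=seed, resampling=resampling, kernel=kernel)
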