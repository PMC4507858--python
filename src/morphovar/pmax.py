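"""Direction of maximal within-group variance (Pmax) and its bootstrap.

For a group of specimens, Pmax is the first eigenvector of the group's
phenotypic covariance matrix — the direction of most abundant phenotypic
variation, often interpreted as a line of least resistance to evolution.
Because a first eigenvector is a noisy quantity, its stability is gauged by
bootstrap: resample the group, re-estimate Pmax, and record the correlation
R between the original and each bootstrap estimate.  The lower 5th
percentile of that distribution (r95) serves as a one-sided 95% bound:
two groups whose between-group Pmax correlation falls above the looser of
their bounds cannot be told apart.

The correlation between two unit loading vectors is, by default, the
absolute Pearson correlation across the p loadings; the absolute cosine
similarity is available via ``method="cosine"``.  Both are symmetric and
invariant to negating either vector (an eigenvector's sign is arbitrary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._warnings import SmallSampleWarning, UnstableIntervalWarning

#: Recommended minimum group size for a stable first-eigenvector estimate.
WELL_SAMPLED_N = 30


@dataclass(frozen=True)
class PmaxEstimate:
    group_id: str
    loading_vector: np.ndarray
    percent_first_eigenvalue: float
    n_specimens: int
    bootstrap_r: np.ndarray | None = field(default=None, repr=False)
    r95: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.loading_vector, dtype=float)
        if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
            raise ValueError("loading vector must have unit norm")
        object.__setattr__(self, "loading_vector", v)


@dataclass(frozen=True)
class PmaxComparison:
    group_a: str
    group_b: str
    r_between: float
    threshold: float
    distinguishable: bool


def vector_correlation(u: np.ndarray, v: np.ndarray, method: str = "pearson") -> float:
    """Sign-invariant correlation between two loading vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("vectors must be 1-D, equal length >= 2")
    if method == "pearson":
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            raise ValueError("constant vector: Pearson correlation undefined")
        r = np.corrcoef(u, v)[0, 1]
    elif method == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("zero vector: cosine similarity undefined")
        r = float(u @ v) / (nu * nv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(abs(r), 1.0))


def _first_eigenvector(values: np.ndarray) -> tuple[np.ndarray, float]:
    cov = np.cov(values, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals[::-1], 0.0, None)
    v = vecs[:, ::-1][:, 0]
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v, float(100.0 * vals[0] / vals.sum())


def estimate_pmax(group_values: np.ndarray, group_id: str = "group") -> PmaxEstimate:
    """First eigenvector of the group covariance matrix (unit norm) and the
    share of variance it carries.

    Requires at least 3 specimens; below ``WELL_SAMPLED_N`` a small-sample
    warning is emitted (the estimate is noisy).
    """
    values = np.atleast_2d(np.asarray(group_values, dtype=float))
    n = values.shape[0]
    if n < 3:
        raise ValueError("Pmax estimation needs at least 3 specimens")
    if n < WELL_SAMPLED_N:
        warnings.warn(
            f"group {group_id!r}: n = {n} < {WELL_SAMPLED_N}; Pmax estimate unstable",
            SmallSampleWarning,
        )
    v, pct = _first_eigenvector(values)
    return PmaxEstimate(group_id, v, pct, n)


def bootstrap_pmax(
    group_values: np.ndarray,
    n_boot: int = 100,
    seed: int | None = None,
    group_id: str = "group",
    method: str = "pearson",
) -> PmaxEstimate:
    """Bootstrap the Pmax estimate.

    The group is resampled with replacement ``n_boot`` times at its
    original size; each replicate's Pmax is correlated with the original
    estimate, and ``r95`` is the 5th percentile of that distribution (a
    one-sided lower 95% bound: only low correlations signal disagreement).
    """
    values = np.atleast_2d(np.asarray(group_values, dtype=float))
    if n_boot < 20:
        warnings.warn(
            f"n_boot = {n_boot} < 20: percentile bound unstable", UnstableIntervalWarning
        )
    base = estimate_pmax(values, group_id)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    rs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vb, _ = _first_eigenvector(values[idx])
        rs[i] = vector_correlation(base.loading_vector, vb, method=method)
    return PmaxEstimate(
        group_id=base.group_id,
        loading_vector=base.loading_vector,
        percent_first_eigenvalue=base.percent_first_eigenvalue,
        n_specimens=n,
        bootstrap_r=rs,
        r95=float(np.percentile(rs, 5.0)),
        seed=seed,
    )


def compare_pmax(
    est_a: PmaxEstimate, est_b: PmaxEstimate, method: str = "pearson"
) -> PmaxComparison:
    """Decide whether two groups' Pmax directions can be told apart.

    The decision threshold is the looser (smaller) of the two bootstrap
    bounds — the less robustly estimated Pmax governs; the directions are
    distinguishable only when their correlation falls below it.
    """
    if est_a.r95 is None or est_b.r95 is None:
        raise ValueError("both estimates need bootstrap information (r95)")
    r = vector_correlation(est_a.loading_vector, est_b.loading_vector, method=method)
    threshold = min(est_a.r95, est_b.r95)
    return PmaxComparison(
        group_a=est_a.group_id,
        group_b=est_b.group_id,
        r_between=r,
        threshold=threshold,
        distinguishable=r < threshold,
    )
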