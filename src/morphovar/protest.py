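"""Procrustes comparison of two ordination configurations (Protest).

A configuration is the set of group means on the first k axes of an
ordination.  Two configurations over the same groups are superimposed
symmetrically — both centered and scaled to unit total sum of squares,
then optimally rotated (reflections allowed) — and compared through

* ``d``: the residual sum of squares after superimposition, in [0, 1];
* ``r = sqrt(1 - d)``: the Procrustes correlation.

Significance is assessed by permuting the rows of one configuration and
counting permuted statistics at least as close as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes

from ._warnings import ZeroPaddedConfigurationWarning


@dataclass(frozen=True)
class Configuration:
    """g labeled points in a k-dimensional ordination space."""

    labels: list[str]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        labels = [str(x) for x in self.labels]
        if len(labels) != len(set(labels)):
            raise ValueError("labels must be unique")
        if len(labels) < 3:
            raise ValueError("a configuration needs at least 3 points")
        if coords.shape[0] != len(labels) or coords.shape[1] < 1:
            raise ValueError("coords must be (g, k) with one row per label")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ProtestResult:
    d: float
    r: float
    p_value: float
    n_perm: int
    seed: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Protest: d = {self.d:.4f}, r = {self.r:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_perm} permutations)"
        )


def _aligned_matrices(x: Configuration, y: Configuration) -> tuple[np.ndarray, np.ndarray]:
    """Match y's rows to x's labels and equalize dimensionality."""
    if set(x.labels) != set(y.labels):
        raise ValueError("configurations must share the same label set")
    order = [y.labels.index(lab) for lab in x.labels]
    xm, ym = x.coords, y.coords[order]
    if xm.shape[1] != ym.shape[1]:
        warnings.warn(
            "configurations differ in axis count; padding the narrower with zeros",
            ZeroPaddedConfigurationWarning,
        )
        k = max(xm.shape[1], ym.shape[1])
        xm = np.hstack([xm, np.zeros((xm.shape[0], k - xm.shape[1]))])
        ym = np.hstack([ym, np.zeros((ym.shape[0], k - ym.shape[1]))])
    return xm, ym


def _statistic(xm: np.ndarray, ym: np.ndarray) -> float:
    """Residual sum of squares after symmetric Procrustes superimposition."""
    _, _, disparity = _scipy_procrustes(xm, ym)
    return float(disparity)


def procrustes_statistic(x: Configuration, y: Configuration) -> tuple[float, float]:
    """Procrustes distance ``d`` and correlation ``r = sqrt(1 - d)``.

    Invariant to translation, uniform scaling and any orthogonal transform
    (rotations and reflections) of either configuration, and to the row
    order of the inputs (rows are matched by label).
    """
    xm, ym = _aligned_matrices(x, y)
    d = _statistic(xm, ym)
    d = min(max(d, 0.0), 1.0)
    return d, float(np.sqrt(1.0 - d))


def protest(
    x: Configuration,
    y: Configuration,
    n_perm: int = 999,
    seed: int | None = None,
) -> ProtestResult:
    """Procrustes test of configuration concordance.

    The null distribution is built by permuting the rows of ``y``;
    ``p = (#{d_perm <= d_obs} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    xm, ym = _aligned_matrices(x, y)
    d_obs = min(max(_statistic(xm, ym), 0.0), 1.0)
    rng = np.random.default_rng(seed)
    hits = 0
    g = ym.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(g)
        if _statistic(xm, ym[perm]) <= d_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProtestResult(d=d_obs, r=float(np.sqrt(1.0 - d_obs)), p_value=p, n_perm=n_perm, seed=seed)
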