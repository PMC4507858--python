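"""Variance decomposition and ordination of grouped shape data.

The total variance-covariance matrix ``T`` of a grouped dataset splits into
a between-group part ``B`` (covariance of group means, weighted by sample
size) and a within-group part ``W = T - B``.  Three eigenanalyses of this
decomposition give the classic pictures of among-group differentiation:

* **PCA** — eigenanalysis of ``T``: axes of maximal total variance.
* **bgPCA** — eigenanalysis of ``B``: axes of maximal variance among group
  means, with no within-group standardization; at most ``g - 1`` non-null
  axes for ``g`` groups.
* **CVA** — eigenanalysis of ``B W⁻¹`` (with ``W`` the pooled within-group
  covariance): axes maximizing the between- to within-group variance
  ratio; canonical scores have unit pooled within-group variance.

CVA is solved by whitening: eigendecompose the pooled within-group
covariance, map the data so it becomes the identity, and eigenanalyze the
mapped ``B``.  The eigenvalues equal those of the literal product
``B W⁻¹``, but the whitened route is symmetric and numerically stable.

**PCoA** embeds an arbitrary distance matrix into orthogonal axes by Gower
double-centering; axes with non-positive eigenvalues are dropped with a
warning reporting the negative-eigenvalue mass (no Cailliez/Lingoes
correction is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._warnings import AxesClippedWarning, NegativeEigenvalueWarning
from .dataset import GroupedDataset
from .protest import Configuration

#: Relative eigenvalue below which a matrix is treated as rank deficient.
RANK_TOL = 1e-10


@dataclass(frozen=True)
class VarianceDecomposition:
    """Total / between-group / within-group covariance, divisor n."""

    T: np.ndarray
    B: np.ndarray
    W: np.ndarray
    divisor: str = "n"

    def __post_init__(self) -> None:
        scale = max(1.0, float(np.abs(self.T).max()))
        if not np.allclose(self.T, self.B + self.W, atol=1e-10 * scale):
            raise ValueError("T = B + W identity violated")


@dataclass(frozen=True)
class OrdinationResult:
    """Axes, variance shares, and the group-mean configuration of one
    ordination.

    ``percent_variance`` covers every non-null axis of the analysis (so it
    sums to 100) even when fewer axes are retained in the scores.
    """

    method: str
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray | None
    specimen_scores: np.ndarray | None
    group_labels: list[str]
    group_mean_config: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.group_mean_config.shape[1]

    def configuration(self, n_axes: int | None = None) -> Configuration:
        """Group-mean configuration on the first ``n_axes`` axes (zero
        padded when the analysis has fewer non-null axes)."""
        coords = self.group_mean_config
        if n_axes is not None:
            if n_axes > coords.shape[1]:
                coords = np.hstack(
                    [coords, np.zeros((coords.shape[0], n_axes - coords.shape[1]))]
                )
            else:
                coords = coords[:, :n_axes]
        return Configuration(list(self.group_labels), coords)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "percent_variance": self.percent_variance}
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled square symmetric distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        g = len(self.labels)
        if d.shape != (g, g):
            raise ValueError("distance matrix must be square and match labels")
        if np.any(d < 0):
            raise ValueError("negative distances")
        if not np.allclose(d, d.T, atol=1e-12 * max(1.0, d.max())):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(d)) > 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a labeled square distance matrix from delimited text (first
    column and header row carry the labels)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------

def variance_decomposition(data: GroupedDataset) -> VarianceDecomposition:
    """Split the total covariance into between- and within-group parts.

    All three matrices use divisor ``n`` so that ``T = B + W`` holds to
    floating point exactly; the grand mean is the specimen-weighted mean,
    which equals the sample-size-weighted mean of group means.
    """
    X = data.values
    n = data.n_specimens
    m = X.mean(axis=0)
    Xc = X - m
    T = Xc.T @ Xc / n
    B = np.zeros_like(T)
    for g in data.groups:
        xg = data.group_values(g)
        dg = xg.mean(axis=0) - m
        B += xg.shape[0] * np.outer(dg, dg)
    B /= n
    W = T - B
    return VarianceDecomposition(T, B, W)


def pooled_within_covariance(data: GroupedDataset) -> np.ndarray:
    """Pooled within-group covariance with divisor ``n - g`` (the unbiased
    convention used for canonical variates)."""
    n, g = data.n_specimens, data.n_groups
    if n - g < 1:
        raise ValueError("need n - g >= 1 for a pooled within-group covariance")
    S = np.zeros((data.n_variables, data.n_variables))
    for name in data.groups:
        xg = data.group_values(name)
        xc = xg - xg.mean(axis=0)
        S += xc.T @ xc
    return S / (n - g)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Per column, make the largest-magnitude coefficient positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _descending_eigh(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def _clip_axes(n_axes: int, available: int, method: str) -> int:
    if n_axes > available:
        warnings.warn(
            f"{method}: requested {n_axes} axes but only {available} available",
            AxesClippedWarning,
        )
        return available
    return n_axes


def _group_mean_scores(data: GroupedDataset, scores: np.ndarray) -> np.ndarray:
    return np.vstack(
        [scores[data.group_labels == g].mean(axis=0) for g in data.groups]
    )


def pca(data: GroupedDataset, n_axes: int = 4) -> OrdinationResult:
    """Principal component analysis: eigenanalysis of the total covariance."""
    decomp = variance_decomposition(data)
    vals, vecs = _descending_eigh(decomp.T)
    vals = np.clip(vals, 0.0, None)
    k = _clip_axes(n_axes, data.n_variables, "PCA")
    vecs = _fix_signs(vecs)
    scores = (data.values - data.values.mean(axis=0)) @ vecs[:, :k]
    return OrdinationResult(
        method="PCA",
        eigenvalues=vals,
        percent_variance=100.0 * vals / vals.sum(),
        loadings=vecs[:, :k],
        specimen_scores=scores,
        group_labels=data.groups,
        group_mean_config=_group_mean_scores(data, scores),
    )


def bgpca(data: GroupedDataset, n_axes: int = 4) -> OrdinationResult:
    """Between-group PCA: eigenanalysis of the weighted group-mean
    covariance ``B``; individuals are projected onto its eigenvectors."""
    if data.n_groups < 2:
        raise ValueError("between-group PCA needs at least 2 groups")
    decomp = variance_decomposition(data)
    vals, vecs = _descending_eigh(decomp.B)
    nonnull = max(1, int(np.sum(vals > RANK_TOL * max(vals.max(), 1e-300))))
    nonnull = min(nonnull, data.n_groups - 1)
    vals = np.clip(vals[:nonnull], 0.0, None)
    k = _clip_axes(n_axes, nonnull, "bgPCA")
    vecs = _fix_signs(vecs[:, :nonnull])
    scores = (data.values - data.values.mean(axis=0)) @ vecs[:, :k]
    return OrdinationResult(
        method="bgPCA",
        eigenvalues=vals,
        percent_variance=100.0 * vals / vals.sum(),
        loadings=vecs[:, :k],
        specimen_scores=scores,
        group_labels=data.groups,
        group_mean_config=_group_mean_scores(data, scores),
    )


def cva(data: GroupedDataset, n_axes: int = 4) -> OrdinationResult:
    """Canonical variate analysis via whitening of the pooled within-group
    covariance.

    Equivalent to the eigenanalysis of ``B W⁻¹``; canonical scores have
    unit pooled within-group variance on every axis and are invariant (up
    to per-axis sign) under any invertible linear map of the variables.
    """
    n, g, p = data.n_specimens, data.n_groups, data.n_variables
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    if n - g < p:
        raise ValueError(
            f"CVA needs n - g >= p (got n={n}, g={g}, p={p}); "
            "reduce dimensionality first"
        )
    Wp = pooled_within_covariance(data)
    wvals, wvecs = _descending_eigh(Wp)
    if wvals[-1] <= RANK_TOL * wvals[0]:
        raise ValueError(
            "pooled within-group covariance is rank deficient; "
            "reduce dimensionality first"
        )
    whiten = wvecs @ np.diag(1.0 / np.sqrt(wvals))  # p x p, maps W_pooled -> I
    decomp = variance_decomposition(data)
    Bw = whiten.T @ decomp.B @ whiten
    vals, q = _descending_eigh((Bw + Bw.T) / 2.0)
    nonnull = min(g - 1, p)
    vals = np.clip(vals[:nonnull], 0.0, None)
    k = _clip_axes(n_axes, nonnull, "CVA")
    load = _fix_signs(whiten @ q[:, :k])
    scores = (data.values - data.values.mean(axis=0)) @ load
    return OrdinationResult(
        method="CVA",
        eigenvalues=vals,
        percent_variance=100.0 * vals / vals.sum(),
        loadings=load,
        specimen_scores=scores,
        group_labels=data.groups,
        group_mean_config=_group_mean_scores(data, scores),
    )


def pcoa(dist: DistanceMatrix, n_axes: int = 4) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering of ``-d²/2`` followed by eigendecomposition;
    coordinates are eigenvectors scaled by the square roots of positive
    eigenvalues.  Non-positive eigenvalues are dropped with a warning
    stating the negative mass.
    """
    d2 = dist.d**2
    g = d2.shape[0]
    J = np.eye(g) - np.ones((g, g)) / g
    G = -0.5 * J @ d2 @ J
    vals, vecs = _descending_eigh((G + G.T) / 2.0)
    pos = vals > RANK_TOL * max(abs(vals[0]), 1e-300)
    neg_mass = float(-vals[vals < 0].sum())
    if np.any(vals < -RANK_TOL * max(abs(vals[0]), 1e-300)):
        warnings.warn(
            f"non-Euclidean distances: dropped negative eigenvalue mass {neg_mass:.6g}",
            NegativeEigenvalueWarning,
        )
    vals_pos = vals[pos]
    coords = _fix_signs(vecs[:, pos]) * np.sqrt(vals_pos)
    k = _clip_axes(n_axes, coords.shape[1], "PCoA")
    return OrdinationResult(
        method="PCoA",
        eigenvalues=vals_pos,
        percent_variance=100.0 * vals_pos / vals_pos.sum(),
        loadings=None,
        specimen_scores=None,
        group_labels=list(dist.labels),
        group_mean_config=coords[:, :k],
    )
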