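# Methods

This note documents the statistical procedures implemented in
`morphovar`, the conventions chosen where several are defensible, and
what the synthetic data generator does and does not emulate.

## Outline descriptors

An outline is an ordered ring of 2-D points treated as a closed polygon.
All analyses force counterclockwise orientation (reversing the ring if
the signed area is negative) so sine coefficients have a consistent sign,
and parametrize the contour by cumulative chord length with linear
interpolation between vertices.

**Resampling.** `resample_equal_arclength` places n points at equal
arc-length steps, keeping the input's first point as the starting point.
The canonical pipeline uses n = 64.

**Elliptic Fourier analysis** (Kuhl–Giardina form) expands x(t) and y(t)
against arc length; the coefficients are exact integrals over the polygon
edges, so the inverse expansion converges to the vertices as harmonics
accumulate. EFA is used here only for orientation: the first harmonic
defines a best-fitting ellipse; the outline is rotated so its major axis
lies along +x and resampled so the starting point sits at the outline's
intersection with that axis. Conventions:

* H = 7 harmonics are used for orientation, matching the radial step.
* Of the two major-axis intersections, the one whose EFA-reconstructed
  point has the larger rotated x-coordinate is chosen (the end of major
  elongation); ties go to the intersection nearer the input starting
  point. This makes the normalization deterministic.
* If the first-harmonic ellipse has minor/major axis ratio above 0.99 the
  orientation is undefined; the outline is returned unchanged with a
  warning.
* When the computed rotation and starting-point shift are both below
  1e-9 (outline already oriented), the input is returned as is, so
  repeated orientation is a strict no-op rather than accumulating
  interpolation error. Without this shortcut each pass would drift by
  the chord-sagitta discretization error (~(step)² × curvature).

**Radial Fourier analysis** decomposes the centroid-to-point distance
r_j of the N equally spaced points: a₀ = mean(r), A_h = (2/N) Σ r_j
cos(2πhj/N), B_h likewise with sine. Coefficients are divided by a₀,
making them dimensionless and exactly invariant under uniform scaling;
a₀ itself is the size estimator. The default H = 7 gives the 14 shape
variables used downstream. The inverse transform evaluates the radius
series at equal *angular* steps — an approximation of the arc-length
parameter that is adequate for mean-shape display, which is its only
intended use; a non-positive reconstructed radius signals that the
descriptor left the method's domain of validity.

## Variance decomposition and ordinations

With grand mean m (specimen-weighted, which equals the sample-size-
weighted mean of group means) the decomposition uses divisor n
throughout: T = (1/n) Σ (x−m)(x−m)ᵀ, B = (1/n) Σ_i n_i (m_i−m)(m_i−m)ᵀ,
W = T − B. Divisor n makes T = B + W hold to floating point exactly;
percent-variance outputs are divisor-invariant. The pooled within-group
covariance used by CVA follows the unbiased convention, divisor n − g.

* **PCA** eigendecomposes T; **bgPCA** eigendecomposes B (at most g − 1
  non-null axes). Specimen scores are centered data projected on the
  eigenvectors; group-mean configurations are per-group means of scores.
* **CVA** is solved by whitening: W_pooled = UΛUᵀ, data mapped by
  Λ^(−1/2)Uᵀ, then the mapped B is eigendecomposed. The eigenvalues
  equal those of the (non-symmetric) product BW⁻¹ but the route is
  symmetric and stable; canonical scores have unit pooled within-group
  variance per axis and are invariant (up to per-axis sign) under any
  invertible linear transform of the variables. Preconditions are
  enforced, not patched: n − g < p or a pooled within-group covariance
  with relative eigenvalue below 1e-10 raises an error advising
  dimension reduction rather than silently pseudo-inverting.
* Percent variance per axis is the eigenvalue share over all non-null
  eigenvalues of the respective analysis (for CVA, over the discriminant
  roots), so it always sums to 100.
* Eigenvector signs follow one convention everywhere: the largest-
  magnitude coefficient of each axis is positive. Protest is invariant to
  sign and rotation, so this is cosmetic but makes runs reproducible.
* **PCoA** Gower-centers −d²/2 and eigendecomposes; coordinates are
  eigenvectors scaled by √eigenvalue. Axes with non-positive eigenvalues
  are dropped with a warning reporting the negative mass; no
  Cailliez/Lingoes correction is applied — non-Euclidean input is
  reported, not repaired.

## Pmax and its bootstrap

Pmax of a group is the first eigenvector of the group covariance
(divisor n_i − 1; the eigenvector is divisor-invariant). Estimation
requires ≥ 3 specimens and warns below 30, the conventional minimum for
a stable first eigenvector. The correlation between two loading vectors
is the absolute Pearson correlation across the p loadings (the
convention of the ecology/morphometrics toolchain this mirrors);
absolute cosine similarity is available via `method="cosine"`. The two
differ unless loadings are centered; Pearson is the default.

The bootstrap resamples the group with replacement at its original size
(default 100 replicates), correlates each replicate's Pmax with the
original, and takes the 5th percentile as r95 — a one-sided bound, since
only low correlations indicate disagreement. Two groups are declared
distinguishable when their between-group correlation falls below the
*smaller* (looser) of their r95 bounds: the less robustly estimated Pmax
governs the decision.

## Protest

Configurations (group means on the first k axes) are matched by label,
centered, scaled to unit total sum of squares, and superimposed by the
optimal orthogonal map (reflections allowed; computed via SVD — the
implementation delegates to `scipy.spatial.procrustes`). The statistic
d is the residual sum of squares, equal to 1 − (Σ singular values)²;
r = √(1 − d) by construction. The permutation test permutes the rows of
one configuration; p = (#{d_perm ≤ d_obs} + 1)/(n_perm + 1), counting
ties as hits. When two configurations differ in axis count the narrower
is zero-padded with a warning (needed when an analysis has fewer
non-null axes than the requested four).

A note on labels: the correlation reported alongside d in the original
literature is printed as "R²", but numerically equals √(1 − d). This
package calls it r and defines it as √(1 − d) exactly; the identity is
asserted in the tests against the printed value pairs.

## Homogenized-variance simulation

The common variance of the surrogates is σ² = arithmetic mean over
groups of the geometric mean of the p per-variable within-group sample
variances (divisor n_i − 1). Any zero variance makes the geometric mean
degenerate and raises an error naming group and variable. Each surrogate
dataset draws every group from a multinormal with its observed mean and
covariance exactly σ²I — the covariance is not resampled, reading the
"same variance" condition strictly. Randomness is organised in derived
substreams: replicate r, group i uses `SeedSequence([seed, r, i])`, so
any replicate (or group) is reproducible in isolation. Observed
distances are computed on the same (sub)dataset the surrogates are built
from; by default all groups of the input participate, and a subset can
be requested.

The study records, per ordination pair, the 999 simulated Protest
distances, the observed distance, and the fraction of simulated
distances at or below it.

## Synthetic data generator

The generator emulates the statistical structure the analysis is
designed to detect: g groups of multinormal p-vectors (defaults g = 7,
p = 14, sizes 68/13/15/7/18/14/14 mirroring the study's continental
samples) sharing one within-group covariance V diag(λ) Vᵀ whose first
eigenvector is the shared Pmax. Defaults and their reasons:

* λ₁/λ₂ = anisotropy (default 10), λ₂ = 1 in dimensionless shape units,
  remaining spectrum geometric with ratio 0.7 — a steadily decaying
  spectrum typical of shape data.
* The default Pmax loading pattern is a smooth cosine ramp across the
  p coefficients — non-constant, because a constant loading vector would
  make Pearson vector correlations with it undefined.
* Group means are displaced along Pmax with standard deviation √λ₁ and
  orthogonally with relative standard deviations 0.911/0.435/0.404/
  0.302/0.302 on successive directions — the profile of the study's
  printed between-group variance shares, with the residual share spread
  over the remaining axes so the means span a full-rank scatter (real
  group means always do; a low-rank between structure makes the
  PCA-vs-bgPCA Procrustes comparison degenerate once the retained axes
  cover it).
* The orthogonal displacement directions are a fixed generic rotation of
  Pmax's complement (internal constant seed), deliberately *not* the
  covariance's minor eigenvectors: aligning the two makes B and W
  commute, a knife-edge structure under which PCA and bgPCA coincide in
  population — an artifact real data cannot exhibit.
* `SyntheticConfig.island()` and `SyntheticConfig.clade()` build the two
  schematic geometries (divergence purely along, or purely orthogonal
  to, Pmax). The clade displacement defaults to half the within-group
  sd on Pmax, large enough for CVA to pick up and small enough that the
  total-variance picture stays Pmax-dominated.

What the generator does **not** emulate: non-Gaussian within-group
variation, group-specific covariance differences beyond the shared
model, measurement error in outline digitization, and raw outlines
themselves (generation happens at the descriptor level). Tests passing
on synthetic data therefore validate the estimators and the logic of the
simulation study, not the biological claims about real molars.

## Problem sizes and determinism

The test suite and the acceptance script use the study-scale defaults
where they are cheap (100 bootstrap replicates, 999 permutations, 999
simulation replicates — the full study runs in seconds at p = 14) and
smaller replicate counts inside unit tests where only the mechanism is
being checked. Every stochastic routine takes an explicit seed and is
reproducible bit-for-bit under it; the end-to-end pipeline writes a
manifest from which a run can be replayed identically.

## Known limitations

* The EFA phase/starting-point convention and the harmonic count used
  for orientation are package choices; other software may normalize
  differently, changing individual coefficients (not the downstream
  variance structure) for the same outlines.
* The observed-vs-null quantile of the PCA–bgPCA comparison in the
  simulation study is an intrinsically noisy quantity when the two
  configurations are nearly identical; small absolute distances near
  zero make its position in the null sensitive to the fixture
  realization.
* CVA percent variance is reported on the discriminant roots; other
  conventions (e.g. canonical correlations) rescale but do not reorder
  axes.
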