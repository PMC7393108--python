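# Methods

This note documents the models, algorithms and numerical choices behind
`tlsmorph`, what the synthetic-forest generator does and does not emulate,
and the known limitations of each estimator.

## Scope and assumptions

The package operates on *segmented, ground-normalized single-tree point
clouds* in meters, z-up.  Scan registration, denoising beyond statistical
outlier removal, and tree segmentation from plot scans are upstream steps;
`tlsmorph.io` provides only the last-mile preprocessing (grid-minimum
ground detrending, k-NN statistical outlier removal) that such clouds
typically still need.  Branch-order tables and stem-diameter inventories
are taken as measured inputs — in practice these come from
human-assisted digitization, since branch topology under foliage is not
reliably machine-extractable.

## Stem morphometrics

**Height** is the z-extent of the cloud, max z − min z.  Exact for
normalized clouds; sensitive to any unremoved high/low outlier, which is
why SOR runs first in the pipeline.

**DBH** slices the cloud at 1.3 m ± 0.05 m, projects to XY, splits the
slice into stems by single-linkage connected components at 0.1 m, and
fits each stem with the Taubin algebraic circle fit (the gradient-norm
normalized algebraic fit, solved via the characteristic cubic and a
Newton step from zero — the standard numerically stable formulation).
The Taubin fit is exact on noiseless circles and nearly unbiased on
partial arcs, which matters for occluded stems.  Reported DBH is the
largest stem's diameter; the full per-stem list feeds the trunk
dominance ratio.  The 0.05 m half-width balances point count against
taper/curvature bias at typical TLS densities.

**Trunk dominance ratio.**  TDR = num · (Σ dᵢ / d_max) over the stem
diameters at 1 m aboveground.  TDR = 1 for a single trunk, n² for n
equal stems; it separates arborescent from shrub-like multi-stem forms.
The diameters are measured at 1 m, deliberately distinct from the 1.3 m
DBH slice.

**Crown base** uses the vertical profile of per-layer (0.25 m) convex
hull areas A(z).  Detection: the lowest layer with
A ≥ α·max A (α = 0.15) followed by at least 2 further qualifying layers
(persistence suppresses isolated branch clusters).  Localization: the
reported base sits half a layer *below* that layer's lower edge.  The
offset is deliberate: the area threshold is only crossed after the crown
has accumulated roughly 0.1·rz of depth (threshold plus the
finite-sample hull deficit of sparsely populated bottom-cap layers), so
the lower-edge convention is biased upward by up to slightly more than
one layer for deep crowns, while the half-layer-down convention centers
the error well inside ±1 layer.  A flat profile (bare trunk,
ground-hugging shrub) yields 0 with a warning.  CLR = crown base /
height.

**Canopy area** partitions canopy points (above the crown base) into
0.5 m layers and takes the maximum convex-hull area over layers with ≥ 3
points.  The hull is a from-scratch Graham scan (pivot at lowest point,
polar-angle sort with distance tie-break, strict left turns so collinear
boundary points drop out); areas use the shoelace formula.  The layer
maximum converges to the crown's true maximum cross-section from below:
hulls of finite samples are inscribed, and the best layer is only
near the widest cross-section.  At ~20k crown points the combined
deficit stays under ~3% for ellipsoidal crowns; the 5% recovery
tolerance used in the tests reflects that density.

**LAI** casts a regular angular grid of rays from a scanner position
(default 4 zenith sub-angles × 48 azimuths per zenith bin, bins
0–10–20–30°).  A ray is intercepted when it passes within the beam
radius (0.02 m) of any canopy point.  Per zenith bin the gap fraction
P(θ) is the non-intercepted fraction, inverted through Beer–Lambert:
L_e(θ) = −cos θ · ln P(θ) / G with a spherical leaf-angle distribution
(G = 0.5).  Non-random leaf dispersion is corrected by the Lang–Xiang
clumping index Ω = ln(mean P) / mean(ln P) over azimuth sectors (4
sectors), and LAI = mean L_e / Ω.  Saturated bins (P = 0) are excluded
with a warning; an empty crown gives P ≡ 1 and LAI = 0.  The ray grid is
deliberately dense: with few rays per sector, binomial noise in sector
gap fractions masquerades as clumping (Jensen's inequality pushes
Ω below 1 even for a homogeneous medium), inflating LAI by ~10–20%.
With the default grid the inversion recovers the analytic LAI of a
homogeneous Poisson slab to within a few percent; the 15% test tolerance
covers chord-length variation through non-slab crowns.

**Percentage cover** grids the plot (25 m side, 0.5 m cells) and reports
the share of cells containing any return at or above 2 m.

## Leaf traits

SLA = LA / dry weight (cm²/g) and LTD = dry weight / (LA · thickness)
(g/cm³); thickness is stored in cm (converted from caliper mm at
ingestion) so the identity SLA · LTD · thickness = 1 holds in
consistent units.  Leaf area from a binary scan mask is hole-filled
foreground area (pixel count × resolution²).  The main-vein length LV is
approximated by the longest geodesic through the skeletonized mask
(8-connected, diagonal steps √2 pixels, repeated farthest-point
Dijkstra sweeps — exact on tree-shaped skeletons).  This is a surrogate
for midrib tracing, accurate for elongated leaves; it is *not*
meaningful for near-circular masks, whose medial axis collapses toward
the center (the skeleton of a disc is a point, giving LV → 0).

## Power-law quantile envelopes

The conditional τ-quantile of y given x is modeled as y = a·xᵇ and
fitted by minimizing the pinball loss Σ ρ_τ(yᵢ − a·xᵢᵇ).  For fixed b
the inner problem is solved *exactly*: with zᵢ = xᵢᵇ > 0,
ρ_τ(y − a z) = z·ρ_τ(y/z − a), so the optimal a is the τ-quantile of the
ratios yᵢ/zᵢ weighted by zᵢ, found by sorting and cumulative weights.
The exponent is then a 1-D search: an 80-point coarse grid on
b ∈ [0.05, 8] (covering all published stem-allometry exponents with
margin) followed by bounded golden-section refinement between the grid
neighbors of the best point.  The exact inner solve avoids the
instability of iteratively reweighted schemes at extreme quantiles
(τ = 0.05/0.95 with n ≈ 10²–10³), and the grid guards the refinement
against the loss surface's local minima.  Fits carry their empirical
coverage (share of points below the curve), which should match τ to
binomial accuracy.

The through-origin proportional fit y = b₀x uses b₀ = Σxy/Σx² with a
t-test on n − 1 degrees of freedom.

**Theory curves.**  The LPJ allometric module Height = k_h·DBH^{p_h},
CA = k_ca·DBH^{p_ca} (k_h = 40, p_h = 0.5, k_ca = 100, p_ca = 1.6; DBH
in meters) composes exactly into CA = k_c·Height^{p_c} with
p_c = p_ca/p_h and k_c = k_ca·k_h^{−p_c} — numerically
(7.47·10⁻⁴, 3.2).  `compare_envelopes` evaluates a fitted envelope
against a theory curve on a grid and locates their crossing by bisection
on the log-difference (which is linear in log x, so the crossing is
unique when the exponents differ).

## Plot-level statistics

Pearson correlations are two-tailed with p from
t = r·√((n−2)/(1−r²)); partial correlations regress both variables on
the controls (OLS with intercept) and correlate residuals, testing on
n − 2 − k degrees of freedom; with no controls this reduces exactly to
the plain test.  Significance stars use the 0.1 / 0.05 / 0.01 levels,
uncorrected for multiple testing — the trait–environment matrix reports
raw per-cell stars by design.

PCA standardizes each trait column (mean 0, SD 1, n − 1 denominator) and
eigendecomposes the correlation matrix — the traits have incommensurate
units, so covariance PCA would be dominated by whichever trait has the
largest numeric range.  LTD and TDR are multiplied by −1 beforehand so
all loadings read along a common "taller, single-trunk, thinner-leaf"
direction; sign flips cannot change the spectrum, only the loadings'
signs.  Each axis's largest-magnitude loading is made positive for
reproducible orientation.

Trait clustering represents each of the 12 traits by its standardized
vector of plot values and merges agglomeratively with Euclidean
centroid linkage (scipy's implementation, verified in the tests against
a cubic-time re-computation of all centroid distances at every step).
Centroid linkage can produce dendrogram inversions (a merge lower than
its predecessor); these are reported in the merge table and flagged with
a warning rather than suppressed.

## Synthetic forest: what it emulates, and what it does not

`make_tree` builds a trunk as a *surface* sampling of one vertical
cylinder per stem (full 360° coverage, emulating a multi-station scan)
from the ground to the crown base, with the tallest stem continuing to
the tree top, plus leaf points uniform inside an ellipsoidal crown.
Multi-stem bases place stems on the smallest circle that keeps adjacent
stem surfaces 0.15 m apart, so breast-height slices are cleanly
separable.  Ground truth is analytic: CA = π·rx·ry, TDR from the stem
list, CLR from the declared crown base.

The bundled random-tree sampler (`random_tree_params`) draws the
semi-arid oak growth form: crown base 1.6–3 m (above breast height, so
the DBH slice contains no foliage), crown depth 2–5 m with crowns at
least as wide as deep, DBH 0.08–0.35 m, a 30% chance of 2–4 basal stems
— multi-stem (shrub-form) trees carry wide crowns (half-width ≥ 1.8 m),
which is both the morphotype such forms represent and what keeps the
basal cluster's footprint well below the crown's cross-section in the
area profile.  The default 20 000 crown points and 0.02 m trunk point
spacing correspond to a dense multi-station scan of a single tree.

Not emulated: ranging noise is off by default (a Gaussian jitter option
exists), there is no occlusion, no intensity, no wind deformation, no
within-crown leaf clumping, and leaves are points rather than surfaces.
Passing the recovery suite therefore demonstrates correctness of the
geometry pipeline under ideal sampling, not robustness to real scan
artifacts — the SOR and normalization tests cover only the simplest of
those.

`make_envelope_table` draws x uniform on a range and y = a(U)·x^{b(U)}
with U ~ Uniform(0,1), where (log a, b) interpolate linearly in U
between the lower curve at U = 0.05 and the upper curve at U = 0.95.
Because y is monotone in U at every x (guaranteed by the no-crossing
validation), the conditional 5% and 95% quantiles of y|x are *exactly*
the two prescribed power laws — recovery tests compare fitted parameters
against genuinely known truth, not against another estimator.

`make_plot_table` draws the 12 trait and 13 environment columns from a
multivariate Gaussian with a user-supplied correlation matrix (validated
symmetric, unit-diagonal, PSD).  Marginals are standard normal; all the
downstream statistics are location/scale invariant, so only the
correlation structure matters.

## Numerical choices and degenerate inputs

* Circle fits require ≥ 3 non-collinear points; collinearity is detected
  on the covariance determinant with a relative 10⁻¹² guard.
* The Graham scan works on de-duplicated points and rejects fully
  collinear inputs; hull tests cover idempotence and oracle equality.
* SOR never removes more than 20% of points (worst offenders first), a
  guard against eating sparse crowns when the distance distribution is
  bimodal.
* Quantile-fit golden-section tolerance is 10⁻⁸ on b; the coarse-grid
  best is kept if refinement fails to improve it.
* Partial correlations treat a residual with relative range below 10⁻¹⁰
  as fully explained by the controls (r = 0, p = 1).
* PCA refuses constant columns by name; the plot-table generator refuses
  non-PSD effect matrices with the offending eigenvalue.

## Problem sizes

The test suite and the acceptance script use 50 random trees at 20k
crown points for trait recovery, n = 2000 × 20 seeds for envelope
recovery, a ~36k-point Poisson medium for LAI, and 36-plot tables for
the statistics — sizes at which every stochastic tolerance in the tests
has comfortable margin while the full suite stays fast on a single CPU.

## Known limitations

* The crown-base detector assumes a single trunk/canopy transition; it
  has no notion of lianas, epicormic shoots or two-layer canopies.
* LAI inversion assumes the scanner sees the whole crown through the
  configured zenith range; rays that miss the crown dilute P toward 1
  and bias LAI low.  It reports *effective* plant area — wood in the
  crown volume is intercepted like foliage.
* The envelope fitter returns a point estimate; no confidence intervals
  are attached to (a, b).
* Vein length is undefined for near-circular leaves (see above).
* The deposited plot-average dataset associated with this analysis is
  not bundled; the PCA variance-accounting checks run on synthetic
  tables with known correlation structure instead.
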