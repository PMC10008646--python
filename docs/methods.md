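# Methods

This note documents the statistical machinery in `cytoflmm`: the models,
the estimators, the synthetic-data generator, the numerical choices, and
what the test suite does and does not establish.

## The curve model

A panel is a set of curves on a common hourly grid t = 1..72 (hours after
chemical treatment; the pre-treatment anchor point of the normalized cell
index, NCI = CI[k]/CI[0], is consumed by the normalization and not
stored).  The working model per curve is

    Y_τco(t) = μ_τ(t) + B_τc(t) + E_co(t) + ε_τco(t)

* τ ∈ {high, medium, low} — binned concentration level; control curves
  carry level "none" and have no chemical effect,
* B_τc — a concentration-specific functional random intercept for chemical
  c, mean zero, covariance surface K_{B,τ}(s,t),
* E_co — a smooth error process, one independent copy per observed curve,
  covariance K_E(s,t), shared across levels,
* ε — iid Gaussian white noise with variance σ² at each grid point.

B and E blocks are mutually uncorrelated; copies across chemicals and
curves are independent.  Whether the smooth error should be shared by a
replicate index across concentration levels is ambiguous in this design;
this package treats each observed curve as carrying its own copy (the
replicate indices of different levels come from different physical wells
once concentrations are binned), and the alternative is deliberately not
implemented.

## Concentration binning

The 11 dilution steps are reduced to three levels before mixed-model
fitting so that each (level, chemical) cell has 3–4 replicates.  Per
concentration index, each chemical's curve is summarized by the level-4
discrete-wavelet-transform approximation (scaling) coefficients and the
chemicals are split in two by Euclidean k-means on those coefficients
(k-means on scaling coefficients approximates functional k-means because
the orthonormal DWT preserves the discrete L2 geometry).  The 11 binary
labelings are compared pairwise with the Adjusted Rand Index; complete-
linkage hierarchical clustering of the dissimilarity 1 − ARI is cut into
three clusters, which are named high/medium/low by mean concentration
index (index 1 = strongest dose).  Defaults: Daubechies-4 wavelet,
periodization extension (keeps coefficient counts at ceil(n/2) per
cascade for the non-power-of-two lengths 72 and 792), 100 k-means
restarts.  The wavelet family and extension mode are configuration, not
science: coefficient values are never used as an acceptance surface.
Degenerate case: if all labelings coincide the ARI matrix is all ones and
any cut is equally valid; the implementation then falls back to a
contiguous index split and flags it.

ARI degenerate convention: the pair-counting formula is 0/0 when both
labelings are trivial (all one cluster, or all singletons); the package
defines the value as 1 if the two labelings induce the same partition and
0 otherwise.

## fPCA route

* **Means**: pointwise average per level (optional spline smoothing, off
  by default — the grid is dense and averages over hundreds of curves).
* **Covariance separation** (moments): with residuals r = Y − μ̂_τ,
  K̂_{B,τ} averages cross-replicate products r_o(s) r_{o′}(t), o ≠ o′,
  within (τ, chemical) cells — replicates share B but have independent E
  and ε, so these products are unbiased for K_{B,τ}.  The pooled
  within-curve moment M(s,t) estimates K_B + K_E + σ²·1{s=t}; subtracting
  the per-curve K̂_B and averaging gives K̂_E off the diagonal.  The K_E
  diagonal is filled by linear extrapolation along the ridge from the
  first two off-diagonals (the white-noise nugget lives only on the exact
  diagonal), and σ̂² is the remaining average diagonal excess, clipped at
  zero.  No bivariate smoothing is applied (the 1 h grid is dense); this
  is a documented switch point if sparser designs are ever needed.
* **Eigenpairs**: the covariance operator eigenproblem is discretized with
  trapezoid quadrature weights W: eigh(W^{1/2} K W^{1/2}), negative
  eigenvalues dropped (PSD projection), eigenfunctions returned
  quadrature-orthonormal.  Sign gauge: each eigenfunction integrates to a
  nonnegative value; if its integral is below 1e-8 in magnitude, its first
  non-negligible grid value is made positive.  Three components per B
  block are retained by default (they carry nearly all chemical-induced
  variability in both the motivating data and the generator); the E block
  keeps enough components for 95% of its variance.
* **Scores**: per chemical, all residual curves are stacked and the
  posterior mean (BLUP) of each B score is computed under the working
  Gaussian model with the truncated covariances plus σ²I.  Columns are
  ordered V1–V3 (high), V4–V6 (medium), V7–V9 (low).  A chemical missing
  a level gets NaN scores there rather than imputed values.

## B-spline route

The same model is projected on 4 cubic B-splines on [0, 72] with an open
uniform knot vector.  A 4-function cubic space has no interior knots under
the standard count n_interior = n_basis − degree − 1, i.e. the
Bernstein-type basis; this is the default.  (A four-subinterval cubic
spline space would have dimension 7; a 7-function basis is available via
`n_basis=7` for users who want interval-based local features.)  The model

    y_ck = μ + X β_k + Z1 u_c + Z2 w_c + ε

has per-level fixed spline coefficients crossed with MOA group (24 fixed
effects for two groups), chemical random effects u with one unstructured
4×4 covariance per level, curve random effects w with one shared
unstructured 4×4 covariance, and scalar noise.  The global mean μ is
handled by pointwise grand-mean pre-centering rather than 72 free
parameters, keeping X full rank.

**REML.**  Because all systematic structure lies in the spline span, the
Gaussian likelihood factorizes exactly through the per-curve least-squares
spline coefficients θ̂ = (ΦᵀΦ)⁻¹Φᵀy (noise covariance σ²(ΦᵀΦ)⁻¹): the
projected 4-vectors carry β, u, w, while the orthogonal residual sum of
squares identifies σ² with (72−4) degrees of freedom per curve.  The REML
criterion optimized is the full-data criterion in this factorized form —
an algebraic identity, not an approximation — which makes a fit on dozens
of chemicals take about a second and enables the 200-replicate power
study.  Covariance blocks use a log-Cholesky parameterization (PSD by
construction), initialization is a deterministic method-of-moments
estimate, and L-BFGS-B minimizes −2·REML to a criterion tolerance of
1e-8.  Fits are deterministic; non-convergence raises an error carrying
the best iterate.

**Contrasts.**  For two groups, the 12 contrasts β_{τ,g2,i} − β_{τ,g1,i}
(g2/g1 in sorted label order) are Wald tests with the GLS fixed-effect
covariance, two-sided p-values on residual degrees of freedom
(n_obs − rank X; Satterthwaite/Kenward–Roger corrections are out of
scope), and Benjamini–Yekutieli adjustment — chosen over
Benjamini–Hochberg because the 12 tests share one fitted covariance and
are dependent.  The number of rejections is reported, never assumed.

**Prediction.**  Chemical-level curves are μ̂ + Φ(β̂_τ + û_τc), excluding
replicate effects and noise.

## MANOVA

One-way MANOVA on score vectors computes between/within scatter H and E,
the eigenvalues of E⁻¹H, and the four classical statistics with their
standard approximate-F forms (Rao's F for Wilks; R's `summary.manova`
conventions for Pillai, Hotelling–Lawley and Roy — note statsmodels uses
McKeon's denominator df for Hotelling–Lawley, a deliberate difference
that the test suite pins against an R oracle).  With two groups all four
reduce to Hotelling's T² and the F distributions are exact; the output
flags exact cases.  Scores are assumed roughly multivariate Gaussian;
normality screening is the user's responsibility and is not implemented.

## Clustering and evaluation

k-means is restarted Lloyd (100 random initializations by default, best
within-cluster sum of squares wins).  The SOM is an online Kohonen
network: per step the nearest node and its grid neighbours (bubble or
gaussian kernel of grid distance; wrapped distances when toroidal; axial
offset distance when hexagonal) move toward the sample.  Defaults: 50
epochs, learning rate linear 0.05 → 0.01, radius linear from half the
grid diameter to 0, node initialization by sampling data rows.  With
radius 0 and a bubble kernel the update rule is exactly online k-means,
which the tests exploit as a cross-check.  Evaluation: pair-counting ARI;
permutation-matched accuracy (Hungarian assignment on the confusion
matrix — exact permutation maximization for the ≤ 6 classes supported);
BSS/TSS computed from the final partition, with BSS + WSS = TSS holding
by construction.

## Synthetic data generator

The generator draws panels from the fPCA form of the model with known
ground truth.  Defaults define the study conditions:

* layout: 20 + 13 + 30 chemicals in groups MOA1 / MOA10 / remainder, 11
  concentrations each (1:3 dilution, index 1 strongest), 12 controls —
  705 curves; indices {1–4}→high, {5–8}→medium, {9–11}→low, with the
  index's position inside its bin serving as the replicate index (binned
  indices are treated as replicates, matching the downstream models);
* means: growth-phase-like shapes anchored at NCI = 1 at t = 1 — strong
  doses decline toward zero, medium doses rise then decline, weak doses
  and controls rise to a plateau with a late decline;
* chemical-effect eigenfunctions: sinusoidal shapes orthonormalized under
  trapezoid quadrature, with a level-specific phase; eigenvalues
  (4, 1, 0.25) scaled by level (high 1.0, medium 0.8, low 0.5 — stronger
  doses induce more between-chemical variability); smooth-error
  eigenvalues (0.5, 0.1); σ² = 0.01.  These produce visually TCRC-like
  curves and are all configurable;
* group structure: groups differ only through fixed offsets δ on the
  first two score dimensions per level, pairwise separated by a
  configurable margin (default 3.0 against a leading score SD of 2).  The
  magnitude of real MOA separation is unknown; the margin is a free
  parameter of the generator, not an estimate.  Consequently the
  *chemical-effect covariance seen by the estimators includes the
  between-group score spread*; parameter-recovery tests therefore run at
  margin 0, where the planted eigenstructure is the whole covariance.

A second, "unbinned" mode gives every concentration index its own mean (a
dose ramp between the strong-dose and control shapes) and plants a binary
chemical partition per concentration regime — by MOA group in the high
regime, by two seeded balanced splits in the other two (offset
amplitude 2.0, small smooth + white noise).  Distinct partitions per
regime are essential: the ARI-based binning can only discover bins if
per-concentration labelings agree within a bin and are unrelated across
bins.  This mode exists solely to give the binning stage structure to
recover.

What the generator does **not** emulate: impedance-level measurement,
heteroscedastic or non-Gaussian noise, plate/batch effects, failed
experiments (e.g. doses chosen too low to kill), or more than three MOA
groups.  Passing recovery tests therefore demonstrates correctness of the
estimators under the model's assumptions, not performance on real panels.

## Reproducibility and problem sizes

Every stochastic stage receives a seed derived from the master seed by a
CRC32 hash of the stage name, so partial reruns reuse identical streams
and full reruns are byte-identical.  Test and acceptance problem sizes
are chosen to make Monte-Carlo tolerances comfortable at interactive run
times: 1,000 chemicals for covariance/eigen recovery (relative errors a
few percent against 20% tolerances), 10,000 score draws for sampler
variance (5% tolerance), 200 replicates at 6+6 chemicals for the
contrast power study, 2,000 replicates for the MANOVA null-uniformity
check.

## Known limitations

* The covariance separation is moment-based; it is consistent but not
  efficient, and can produce indefinite raw surfaces (handled by the PSD
  projection at the eigen step).
* Wald p-values use residual df; with few chemicals they are mildly
  anti-conservative compared to Satterthwaite-type corrections.
* The SOM uses a k×1 node grid as "k clusters" by default; larger grids
  report the winning node per sample and may leave nodes empty (flagged,
  not an error).
* `match_accuracy` supports at most 6 classes (explicit assignment
  matching); collapse rare groups first for finer label sets.
* No extrapolation is ever performed when regridding; curves that do not
  span the full 72 h are rejected rather than padded, because late-time
  behaviour drives both the B-spline contrasts and the clustering.
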