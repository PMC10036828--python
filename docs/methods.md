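# Methods

This note documents the model, the conventions fixed where the underlying
protocol leaves room, and what the synthetic-data generator does and does
not emulate.

## Preprocessing

Inputs are volumetric uptake images already registered to the atlas
template; spatial normalization is out of scope (a warning is raised if
image and atlas affines disagree beyond 1e-4). The single-subject chain is:

1. **Smoothing** with a separable Gaussian, FWHM in mm converted per axis
   to voxel-unit sigma via σ = FWHM / (2√(2 ln 2)). Default FWHM 6 mm.
   Boundary handling is constant-zero padding (configurable to any
   scipy.ndimage mode); edge behavior of the original SPM-based smoothing
   is unspecified, so this is a documented package choice.
2. **Global-mean normalization**: every voxel is divided by the mean over
   the brain mask, taken as all voxels with a nonzero atlas label
   (an explicit mask can be supplied). After this the in-mask mean is 1,
   and the operation is idempotent.
3. **ROI extraction** collects each region's voxel values in ascending
   linear (C storage) order — a fixed order so density estimation, and
   hence every downstream KLS value, is bit-reproducible.

Smoothing precedes normalization by default (the usual pipeline
convention); the order is switchable for sensitivity analysis.

## KLS network construction

Per region pair, a shared grid of 512 equally spaced points spans the
pooled sample range padded by 3 bandwidths on each side (padding prevents
truncating the Gaussian tails). Both densities are evaluated on the grid,
multiplied by the grid spacing to give probabilities, floored at 1e-10
(the divergence is undefined at zero probability; the floor only matters
where a density is effectively zero), and renormalized to sum to 1. The
edge weight is exp(−KL_sym) with natural logarithms, so weights live in
(0, 1]. Doubling the grid to 1024 points moves edge values by < 0.01 on
smooth samples (tested).

**Bandwidth.** Default is Silverman's rule of thumb
h = 0.9·min(sd, IQR/1.34)·n^(−1/5), which is well-defined, reproducible
and accurate for the unimodal regional distributions this pipeline sees.
An improved Sheather–Jones ("diffusion") plug-in selector is available as
`bandwidth="isj"`; it solves the fixed-point equation for the squared
bandwidth on a DCT grid and falls back to the rule of thumb when no root
is bracketed. Neither rule is claimed to be numerically identical to any
particular historical implementation. A zero-variance sample gets
h = max(1e-6, 1e-3·|v|) so a degenerate region cannot crash construction.

The diagonal is fixed at 0: self-connections carry no information and are
excluded from all graph analyses.

## Graph metrics

Thresholding retains the round(S·R(R−1)/2) largest off-diagonal weights by
absolute value, keeping their weights (no binarization). Ties at the
cutoff are broken by (|weight| desc, row asc, column asc), making retained
edge sets deterministic.

Weighted conventions (the toolbox this mirrors does not restate formulas,
so each convention is fixed and unit-tested against brute-force
references; exact equivalence with any toolbox is not claimed):

- **Cp** — Onnela geometric-mean clustering on weights rescaled by the
  maximum weight, averaged with degree-<2 nodes counted as 0.
- **Lp** — mean shortest-path length with edge length 1/w over pairs with
  finite distance. At S = 0.02 a 90-node graph is necessarily fragmented;
  restricting to finite pairs keeps Lp defined (logged when it happens).
- **Eglobal** — mean of 1/d over all pairs (0 for disconnected pairs);
  **Elocal** — mean over nodes of the global efficiency of the subgraph
  induced by the node's neighbours.
- **Q** — modularity of the greedy-modularity partition (deterministic).
- **Ar** — weighted degree-assortativity coefficient.
- **Hr** — exponent β from the least-squares fit log Cp(i) = a − β log k(i)
  over nodes with binary degree k > 1 and Cp > 0; NaN when fewer than two
  such nodes exist.
- **Sr** — λ₂/λ_max of the combinatorial Laplacian of the binarized graph.
- **Dc** — nodal strength; **Bc** — betweenness with edge length 1/w,
  unnormalized pair counts.

**Null model.** Degree-preserving double-edge swaps (≥ 10× the edge count
attempted) on the binarized topology, followed by a random permutation of
the original weights onto the surviving edges. Graphs with no feasible
swap are used unchanged and logged. λ = Lp/⟨Lp_null⟩, γ = Cp/⟨Cp_null⟩,
σ = γ/λ over n_rand nulls (default 100). Any raw metric can additionally
be summarized as a z-score (metric − null mean)/null sd; both raw and
z-scored modes are exposed because summary scales differ between
conventions and no single AUC scale can be matched to previously printed
tables.

**AUC.** Metric curves over the sweep are summarized by the trapezoidal
integral divided by the sweep range (a mean-height AUC), so a constant
metric has AUC equal to that constant regardless of sweep width.

**Seeds.** One master seed per analysis; per-null and per-threshold seeds
are derived by fixed offsets and recorded in output metadata.

## Group statistics

Features are residualized on [intercept, age, sex] across the pooled
sample by OLS; the fitted coefficients are exposed so training-fold
weights can deconfound held-out subjects. Covariate columns with zero
variance are dropped (a constant covariate carries no confounding and
would otherwise make the design singular). Groups are compared with
pooled-variance t-tests whose degrees of freedom are reduced by the number
of covariates actually regressed (ANCOVA-equivalent up to df); Welch's
test is available by configuration. Edge, nodal, and global families are
FDR-corrected separately — the conservative reading of per-analysis
reporting — and uncorrected p-values are always emitted alongside, since
nodal findings are sometimes reported at uncorrected thresholds.

## Survival model

The regression is the LIBLINEAR-style primal problem
min_w ½‖w‖² + C·Σ max(0, |yᵢ − w·xᵢ| − ε)², with C = 1, ε = 0.1 (the
standard defaults of that family of solvers; no tuning is performed) and
no intercept — features and outcome are centered by the per-fold
deconfounding and scaling, so none is needed.

Per LOOCV fold: (1) age/sex regression coefficients for every feature and
for survival are fit on the training patients and applied to the held-out
patient; (2) the feature set is the connections significant in the
training-patients-vs-all-controls edgewise comparison at level α (FDR by
default, uncorrected optional); (3) features are z-scored with
training-fold statistics; (4) the model is trained and the held-out
patient predicted. A fold that selects nothing predicts the training-fold
mean (logged). The reported correlation pairs each held-out prediction
with that patient's deconfounded observed survival — prediction happens in
the residual space where the model was trained; raw months are kept
alongside. Per-fold selection is the default because selecting features on
all patients before cross-validation leaks group information; the literal
"select once" protocol is available as `selection="fixed"` for comparison.

**Permutation inference.** p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)
(add-one, so p is never 0). Two modes: *full* re-runs the entire LOOCV —
selection, deconfounding, training — on each permuted outcome vector, and
is the default because the fast mode is measurably anticonservative under
the null (LOOCV fold coupling breaks exchangeability of deconfounded
observed values against fixed predictions; we measured ~10% of null runs
at p ≤ 0.05 versus ~4% for the full mode). The *fast* mode re-pairs the
fixed predictions with shuffled outcomes and supports the classic
10,000-permutation scale when the full mode is too costly; its p-values
should be read as slightly liberal.

**Weight aggregation.** Per-connection weights are averaged across folds
(a connection unselected in a fold contributes 0 there), and each
connection's |mean weight| is added to the total of both endpoint regions'
anatomical groups (once per group for within-group connections). The
90-region lookup bundled in `klsnet.atlas` assigns each region to one of
frontal, temporal, parietal, occipital, central structures, or
insula-and-cingulate; custom lookups override it.

## Synthetic cohorts

The generator emulates the study conditions: 78 patients vs 60 controls,
patient ages ≈ 64 ± 10 vs 61 ± 10 years, ~83% male, survival intercept 16
months truncated below at 1 month (matching the observed floor of such
cohorts without modeling censoring).

- **Voxel mode** draws each region's voxels from Normal(μ_r, σ_r) with
  μ_r ~ U(0.8, 1.2) and σ_r ~ U(0.05, 0.15) — a realistic spread of
  relative uptake after global-mean normalization — 200 voxels per region
  by default (a desk-scale stand-in for the thousands of 2-mm voxels in
  real parcels). A planted edge (i, j, d) shifts region j's patient mean
  by d·σ_j, which perturbs the KLS of every pair touching j — planted
  pairs most strongly.
- **Direct mode** skips voxels: edges are logit-normal in (0, 1) with
  per-edge base means U(0.25, 0.75) and logit-scale sd 0.5. Planted
  effects are calibrated numerically (Gauss–Hermite quadrature plus root
  finding) so the raw-scale patient-vs-control mean difference equals the
  requested shift, or d times the edge's raw sd for Cohen's-d effects.
- **Outcome**: survival = intercept + Σβ_e·(edge value, centered) +
  age/sex terms + Gaussian noise, truncated at 1. In direct mode the noise
  sd can instead be derived analytically from a target population
  correlation (`outcome_target_r`), which is how signal-to-noise is pinned
  in calibration tests.

What the generator does **not** emulate: spatially correlated noise,
partial-volume effects, non-Gaussian regional intensity distributions,
inter-regional correlation structure beyond the planted effects, or
censoring. Passing tests therefore demonstrate that the machinery is
correct and calibrated under a known data-generating process — not that
real PET cohorts satisfy these assumptions.

## Problem sizes in the test suite

Tests and the acceptance script run reduced configurations chosen as the
package's own desk-scale defaults: cohorts keep the 78/60 sample sizes but
use 6–20 regions where edge-level behavior is under test, brute-force
oracle comparisons use ≤ 10-node graphs (exhaustive enumeration is
exponential), null-calibration studies use 100–200 replicate cohorts, and
sparsity sweeps in end-to-end runs use 2 rewired nulls per threshold
rather than 100. None of these reductions changes any default the library
ships.

## Known limitations

- Weighted metric conventions are one reasonable fixing among several in
  circulation; summary magnitudes are not comparable across conventions.
- Lp on fragmented graphs (finite-pairs-only) changes meaning as the pair
  set changes with S; the harmonic alternative (Eglobal) is reported
  alongside and is often preferable at sparse thresholds.
- The fast permutation mode is anticonservative (see above).
- KLS depends on the KDE bandwidth rule; edge values are comparable only
  within a fixed rule.
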