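# Methods

This note records the statistical model behind `ssmnet`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
benchmark does and does not establish about behaviour on real data.

## Scaled subprofile model

All derivation inputs are positive scans on a common grid, reduced to a
subjects × in-mask-voxels matrix with a persisted voxel ordering (0-based
row-major flatten of the mask).  The model is multiplicative:

    ln Y(s,v) = ln g_s + GMP(v) + SRP(s,v)

Row centering of the log matrix removes `ln g_s` exactly (tested to
1e-12); the group mean profile is the column mean of the row-centered
matrix over *all* derivation subjects, patients and controls combined —
the standard convention, and the one that makes prospective single-case
scoring possible, because the stored GMP substitutes for any test-cohort
mean.  Row-then-column centering and the reverse compose to the same
double-centering projector, so the order is a non-choice.

PCA is computed as an economy SVD of the subjects × voxels residual
(never the voxel × voxel covariance); components are exact right singular
vectors, scores are computed as `SRP @ GIS` so the score/weight identity
holds to machine precision, and the variance fraction of component *k* is
`σ_k²/Σσ²`.  Sign convention: each component (and the final combined
pattern) is oriented so the patient mean score is ≥ the control mean; on
exact ties the first nonzero weight is made positive.  This makes
bootstrap sign alignment deterministic.

## Pattern definition by exhaustive AIC selection

The first six components (fewer if the rank is lower; logged) enter all
`2^K − 1` logistic regressions of group on their scores, fit by Newton
iterations capped at 200.  Under complete separation the deviance
converges toward zero and the fit stops when it no longer improves, so
model ranking then rests on the AIC parameter penalty, with ties broken
by fewer predictors and then lexicographically.

Scores are standardized to unit sample sd before entering the logistic
models.  The AIC ranking is provably unchanged — the binomial likelihood
is invariant to affine predictor rescaling — but the coefficients then
measure discriminative contribution *per sd of expression*, and the
combined pattern `w ∝ Σ β_k·GIS_k` weights each component accordingly.
With raw-scale coefficients, a low-variance component needs a huge β to
matter in the logit and that β would then dominate the voxel map; under
quasi-separation (common at n = 40 with six candidate predictors) the
raw-scale solution is ill-posed and the resulting map essentially
arbitrary.  The standardized form is the stable one and is what the
package uses.

Interactions are not enumerated.  The structural (MRI) variant of the
derivation is identical but drops a configurable list of components (e.g.
a leading artifact component) before enumeration.

Calibration: `hc_ref_mean`/`hc_ref_sd` are the mean and sample (n−1) sd
of the derivation controls' raw scores; z-scored derivation controls are
0 ± 1 exactly.

## Bootstrap stability

Subjects are resampled with replacement, stratified by group; each
iteration re-runs the *entire* derivation including PC selection (the CI
should reflect selection uncertainty; a frozen-subset mode is available),
aligns the resampled pattern's sign to the original, and contributes one
weight per voxel.  A voxel with positive original weight is stable when
the 5th percentile of its bootstrap weights exceeds zero (mirrored for
negative weights) — the one-sided 95% CI convention.  Degenerate
resamples with a single unique subject in a group are redrawn and
counted.

Two calibration facts, established on synthetic cohorts and worth knowing
before interpreting stability maps on real data:

* at a complete-separation effect size (the regime reported for real
  derivation cohorts) all planted-support voxels are flagged stable;
* the per-voxel test is *not* a calibrated 5% test on null voxels.  On a
  cohort with no pattern at all, resampled PCA directions decorrelate
  from the original and the flagged fraction falls to ~0 (conservative);
  at null voxels of a strong-signal cohort, shared-noise under-dispersion
  of the bootstrap makes the flagged fraction ~10% (anticonservative).
  This is a property of percentile bootstraps of PCA-derived weights, not
  of this implementation; treat the stable mask as a robustness
  descriptor, not as voxelwise inference.

## Prospective scoring and clinical statistics

TPR scoring is strictly per scan: `raw = (ln y − mean(ln y) − GMP)·w`.
It reproduces derivation scores exactly and is invariant to global
rescaling.  Longitudinal change is a random-intercept mixed model
`z ~ duration + (1|subject)` by REML; the fixed slope's CI and p-value
use t quantiles with containment degrees of freedom
(`n_obs − n_subjects − 1`), which brings CI coverage in the 6-subject,
two-scan design from ~84% (normal quantiles) to ~92–93%, inside the
nominal band.  Singular fits fall back to the two-stage per-subject-slope
estimator with a one-sample t (logged).  Group comparisons are one-way
ANOVA with classic pooled-variance pairwise t contrasts, Bonferroni
multiplied by the number of performed comparisons and capped at 1; the
covariate-adjusted variant runs the same ANOVA on residuals of a simple
`z ~ MMSE` regression.

## Metabolic network analysis

Nodes are atlas ROIs whose ROI-mean pattern weight, z-scored across ROIs
(sample sd, reference region excluded), exceeds |z| > 1; polarity follows
the sign.  Node activity is the subject's ROI mean divided by the
reference-region (pons-role) mean — global factors cancel in the ratio.
Group graphs are elementwise medians of 100 subject-bootstrap Pearson
matrices (NaN entries from constant resampled columns are excluded, with
counts logged).

* **Eigenvector centrality** is computed on the |r| > 0.6 thresholded
  absolute-weight graph (threshold configurable; weighted by default,
  binarized optional — the published convention is ambiguous), per
  connected component, scaled by component size fraction so an isolated
  module cannot dominate, and reported as the median over bootstrap
  iterations.
* **Edge gain/loss**: a pair is a candidate when |r| > .6 in either group
  and |Δr| > .4; the permutation p-value is the (b+1)/(m+1)-smoothed
  fraction of 1000 random group relabelings with |Δr| at least as large;
  candidates are confirmed when the joint criterion recurs in > 50% of
  100 paired bootstrap resamples (the confirmation quorum is a package
  choice — the published rule names the resampling but not the cutoff).
  Direction is "loss" when the control correlation dominates.  Under null
  (identical generative groups) the permutation gate rejects at 4.7–5.4%
  across seeds; a planted between-module decorrelation (r .8 → 0,
  n = 40/group) is detected as a loss in 100% of runs.
* **Global metrics** per bootstrap iteration and threshold
  (|r| = .30….60, step .05, binarized): mean degree, average clustering,
  characteristic path length over *reachable* pairs (the disconnected
  fraction is recorded so network splits remain visible), assortativity
  (degree correlation over edge endpoints), clustering and path length
  normalized by means over degree-preserving Maslov–Sneppen rewired
  nulls (10·|E| swap attempts, 100 nulls by default), and small-worldness
  as their ratio.  Swaps are restricted to edge pairs within a connected
  component: with free rewiring, the null graph of a disconnected
  (patient-like) network is connected, which under the reachable-pairs
  convention *deflates* the normalized path length of exactly the graphs
  whose paths are degenerating — the component-preserving null (the
  connectedness-preserving variant customary in brain-connectivity
  toolboxes) keeps observed and null comparable.  Degree sequences are
  preserved exactly (property-tested).
* **Group comparison** of metrics is a split-plot ANOVA (group between
  bootstrap-iteration units, threshold within), hand-assembled from sums
  of squares and verified against an independent mixed-ANOVA
  implementation to 1e-8.  Thresholds undefined for most units, and units
  with remaining NaNs, are dropped with counts.
* **Cross-site concordance** is ICC(A,1) — two-way, absolute agreement,
  single measure — over upper-triangle correlation pairs as objects and
  sites as raters, with the F-test of MSR/MSE; arbitrary pair blocks
  (e.g. subnetwork restrictions) are supported.

## Pattern comparison

Two maps are compared by Pearson correlation over in-mask voxels; only
the degrees of freedom are corrected for spatial autocorrelation.  Each
map's Gaussian-ACF scale `s` (voxels) is estimated from the variance of
differences between adjacent in-mask voxels of the standardized map
(`rho1 = 1 − var(diff)/2`, `s² = −1/(2 ln rho1)`, geometric mean across
axes); the product of two Gaussian ACFs has scale
`s_AB² = s_A²s_B²/(s_A²+s_B²)`, and the effective sample size is the
voxel count divided by the correlation-resel volume,
`n_eff = V/(2π s_AB²)^{3/2}`, floored at 12 and capped at V.  This
constant is the one that makes the null variance of r between two smooth
maps come out right: on independent smoothed null maps the corrected test
rejects at 5.3% (naive df: ~86%).  Unsmoothed maps recover the naive df
exactly.  A spatial-permutation null would be a drop-in alternative.

Overlap decomposition z-scores both maps within the shared mask
(commensurability) and partitions the union of their |z| > 1 supports
into intersection and exclusives, recording polarity concordance.  When a
resting-state-network map is compared as "loss", its additive inverse is
taken *before* any of this, fixing the sign convention once.  Paired
expression dominance is a two-sided paired t-test on z differences (both
patterns calibrated against the same controls); a zero-variance nonzero
difference is reported as t = ±inf, p = 0 and flagged.

## Synthetic cohort generator

The generator draws

    ln Y(s,v) = ln g_s + gmp0(v) + Σ_p α_{s,p}·P_p(v) + ε(s,v)

with parcel-constant planted patterns (hypometabolic "frontotemporal"
and relatively hypermetabolic "parieto-occipital" modules, a quarter of
the parcels each, deterministic magnitudes 0.8–1.2, zero mean, unit
norm), a reference parcel excluded from pattern support, and per-parcel
loadings `α_{s,p} = α_{s,m(p)} + τ_p·ζ` (module loading plus node
jitter).  Defaults, with reasoning:

| parameter | default | why |
| --- | --- | --- |
| cohort | 20 patients + 20 controls, 24³ grid, 20 parcels + reference | derivation-cohort scale of the motivating studies |
| loading mean/sd | patients 2.0/1.0, controls 0.0/1.0 | a per-module standardized effect of 2; realized expression effect d ≈ 2.1 |
| inter-module corr | controls 0.8, patients 0.5 | controls form one integrated network; patients partially decouple, so graphs stay connected at low thresholds but split near the 0.6 cutoff — the qualitative disease phenomenology the network tests reproduce |
| node jitter scale | controls 0.5, patients 0.7 (× per-parcel profile 0.7–1.8) | within-module node correlations ~0.55–0.89 (controls), lower and more heterogeneous in patients; avoids degenerate complete graphs at low thresholds |
| global scale sd | 0.2 (log) | realistic dose/sensitivity variation; exercises the scaling-invariance guarantee |
| voxel log-noise sd | 0.02 | chosen so the planted pattern's expected leading-PC variance fraction lands near one third of the total — the share a dominant disease pattern typically carries in real cohorts |
| annual increase | 0.95/yr on the total loading | the progression rate the longitudinal model must recover |
| MMSE | 28.5 − 2.0·(total loading) + N(0, 2), clipped to [0, 30] | controls ≈ 28.5, patients ≈ 20, inverse correlation with expression |
| structural attenuation | 0.4 | structural loading = `0.4·α + √(1−0.4²)·ξ`: same loading scale, standardized effect (and z-scored expression effect) shrunk to 0.4× the metabolic one, positive cross-modality score correlation |

The generator is seed-deterministic end to end; fixed loadings can be
injected for degenerate exact tests; per-(group, site) inter-module
correlations support multi-site concordance designs; longitudinal scans
add the annual increase (split equally across modules) before noise; the
structural cohort adds one structural-only parcel to emulate partial
topographic overlap.

**What the benchmark does not show.**  Parcel-constant patterns, i.i.d.
log-noise and block atlases are far cleaner than real anatomy: no
partial-volume effects, no scanner-specific smoothness, no registration
error, no age/site mean shifts.  Passing tests establish that the
*procedures* are implemented correctly and calibrated under their own
assumptions — not that real FDG-PET cohorts satisfy those assumptions.

## Benchmark problem sizes

The test suite and acceptance script run: 50 derivation seeds for
recovery; 200 bootstrap iterations for the stability checks; 200 null
replicates (500 permutations each) plus 20 planted-loss seeds for edge
inference; 200 mixed-model simulations; 1000 smooth-map null pairs; one
40+40 cohort with 100 bootstrap graphs, 7 thresholds and 20 rewired
nulls per graph for the connectivity contrasts; and a 3-site, 25+25-per-
site cohort for concordance.  These sizes put Monte-Carlo error well
inside each assertion's tolerance while keeping the full run in minutes
on one CPU.

## Known limitations

* The bootstrap stability map is a robustness descriptor; its per-voxel
  type-I behaviour is regime-dependent (see above).
* The AIC search can admit near-noise components at moderate effect
  sizes; the standardized combination bounds their influence on the map,
  but selected-subset membership itself is unstable there (the reported
  selection should be read together with the bootstrap).
* The effective-df estimator assumes roughly stationary Gaussian-like
  autocorrelation; heavy anisotropy or nonstationary smoothness calls
  for the permutation alternative.
* Eigenvector centrality on near-disconnected graphs depends on the
  component convention; the size-fraction scaling is one documented
  choice, not the only defensible one.
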