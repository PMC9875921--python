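# ssmnet

Covariance-pattern analysis of brain-image cohorts: scaled-subprofile-model
pattern derivation, prospective expression scoring, and metabolic network
graph analysis.

## The problem

In neurodegenerative disease, focal pathology perturbs the activity of
remote, functionally connected regions, so resting metabolic images (e.g.
FDG-PET) carry disease information as a *spatial covariance pattern* rather
than as independent voxel effects.  `ssmnet` is for researchers who want to

* derive a disease-specific covariance pattern from a patient/control cohort
  of spatially normalized scans,
* quantify its expression in *new, individual* scans (prospective
  validation, differential-diagnosis cohorts, longitudinal follow-up),
* analyse the pattern's internal connectivity structure as a graph over
  atlas regions, and compare patients with controls on global graph
  measures, and
* compare two pattern topographies (e.g. a metabolic vs. a structural
  atrophy pattern, or a disease pattern vs. a resting-state-network
  pattern) with inference that respects spatial autocorrelation.

Because suitable patient data cannot be shipped, the package includes a
fully seed-deterministic synthetic-cohort generator with planted ground
truth (pattern topography, subject loadings, inter-module connectivity,
longitudinal slopes, clinical covariates, paired structural volumes), which
the test suite and the acceptance script use to validate every stage.

## The model

For subject *s* and in-mask voxel *v* the scaled subprofile model writes
the log signal as

```
ln Y(s, v) = ln g_s  +  GMP(v)  +  SRP(s, v)
```

* `g_s` — subject global scaling factor, removed exactly by the log
  transform plus row centering;
* `GMP` — group mean profile, the column mean of the row-centered log data
  over the derivation cohort;
* `SRP` — subject residual profile, the doubly centered residual.

PCA of the SRP yields orthonormal voxel-weight patterns (GIS) with subject
scores `score_k(s) = SRP(s,·)·GIS_k`.  The first six components enter an
exhaustive series of logistic regressions of group on (standardized)
scores; the subset with the lowest `AIC = 2(k+1) − 2 lnL` defines the
disease pattern as the coefficient-weighted, unit-norm, patient-positive
combination of its components.  Expression is z-scored against the
derivation healthy controls.

A new scan is scored without reference to any cohort (topographic profile
rating): `raw = (ln y − mean(ln y) − GMP)·w`, then z-scored — exactly
reproducing derivation scores on the derivation scans, and exactly
invariant to global rescaling of the scan.

Downstream analyses: voxel-wise bootstrap stability (one-sided 95% CI of
each weight), pattern-space graphs (ROI nodes with |z| > 1 regional
weights, pons-normalized activities, bootstrap-median correlation
matrices), eigenvector centrality, permutation-tested edge gain/loss,
global graph metrics normalized by degree-preserving rewired nulls,
ICC(A,1) cross-site concordance, autocorrelation-corrected map
correlations, and a random-intercept mixed model for longitudinal
expression change.  See `docs/methods.md` for assumptions, parameter
defaults and numerical conventions.

## Worked example

```bash
ssmnet simulate --out cohort --seed 11
ssmnet derive  --scans cohort --meta cohort/metadata.csv \
               --mask cohort/mask.nii.gz --out pattern
ssmnet score   --model pattern.json --scans cohort \
               --meta cohort/metadata.csv --mask cohort/mask.nii.gz \
               --out scores.tsv
ssmnet compare --pattern-a pattern.weights.nii.gz \
               --pattern-b cohort/planted_pattern.nii.gz \
               --mask cohort/mask.nii.gz --out cmp
```

prints

```
wrote 40 scans to cohort
selected PCs (1-based): [1, 3]
variance accounted for — PC1: 25.3%, PC2: 3.8%, PC3: 3.4%, PC4: 3.2%, PC5: 2.6%, PC6: 2.4%
scored 40 scans -> scores.tsv
r = 0.91, corrected p = 1.07e-103 (effective df 265 of 10750)
```

The simulated cohort is 20 patients + 20 controls on a 24³ grid with a
planted two-module pattern.  The leading component carries 25.3% of the
subject × voxel variance and (with a second, near-noise component picked up
by the AIC search) defines the derived pattern; its voxel weights correlate
r = 0.91 with the planted topography, tested against an effective sample of
~267 independent resolution elements rather than the raw 10 752 voxels.
Group summaries of the scored expression (`scores.tsv`):

```
         mean   std
control -0.00  1.00
patient  1.92  0.75
```

Controls sit at 0 ± 1 by construction of the z-scale; patients express the
pattern about two control standard deviations more strongly — the planted
group contrast.

`ssmnet network` builds the per-group connectivity graphs and
`ssmnet simulate`'s `truth.json` exposes everything needed to check any
stage against ground truth.

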