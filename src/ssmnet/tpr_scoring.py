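"""Prospective pattern-expression scoring and its clinical statistics.

Topographic profile rating (TPR): a new scan is log-transformed, centered
on its own in-mask mean, the derivation group mean profile is subtracted,
and the residual profile is projected onto the fixed pattern weights.
Scoring is strictly per-scan — no quantity depends on the other scans in a
batch — which is what makes single-case prospective use possible, and it
is exactly invariant to global rescaling of the input scan.

Also here: the longitudinal random-intercept mixed model of expression on
disease duration, Pearson correlations of expression with clinical
covariates, and one-way ANOVA group comparisons with Bonferroni post-hocs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pattern_derivation import PatternModel, zscore_expression
from .volume_io import AnalysisMask, VolumeGrid, grids_compatible

logger = logging.getLogger(__name__)


def tpr_score_vector(values: np.ndarray, model: PatternModel) -> tuple[float, float]:
    """Score one scan given as its in-mask voxel vector.

    raw = (ln y - mean(ln y) - gmp) . weights; z via the model's
    healthy-control calibration.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != model.weights.shape:
        raise ValueError(f"expected {model.weights.shape[0]} in-mask values, "
                         f"got {values.shape}")
    if not (values > 0).all():
        j = int(np.flatnonzero(~(values > 0))[0])
        raise ValueError(f"non-positive in-mask value at voxel index {j}")
    ln = np.log(values)
    srp = ln - ln.mean() - model.gmp
    raw = float(srp @ model.weights)
    return raw, float(zscore_expression(raw, model))


def tpr_score(volume: VolumeGrid, model: PatternModel, mask: AnalysisMask) -> tuple[float, float]:
    """Score one scan volume; returns ``(raw, z)``."""
    if not grids_compatible(volume, mask):
        raise ValueError("scan grid incompatible with model mask")
    return tpr_score_vector(mask.flatten(volume.values), model)


def score_matrix(raw_matrix: np.ndarray, model: PatternModel) -> pd.DataFrame:
    """Score each row of a subjects × in-mask-voxels matrix independently."""
    rows = [tpr_score_vector(row, model) for row in np.asarray(raw_matrix, dtype=float)]
    return pd.DataFrame(rows, columns=["raw_score", "z_score"])


def score_cohort(raw_matrix: np.ndarray, model: PatternModel,
                 metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expression records: per-scan raw/z scores joined with subject metadata."""
    scores = score_matrix(raw_matrix, model)
    if metadata is None:
        return scores
    if len(metadata) != len(scores):
        raise ValueError("metadata length does not match number of scans")
    return pd.concat([metadata.reset_index(drop=True), scores], axis=1)


# ---------------------------------------------------------------------------
# longitudinal mixed model

@dataclass
class LongitudinalResult:
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "mixed" or "two-stage"
    n_subjects: int


def longitudinal_slope(records: pd.DataFrame, z_col: str = "z_score",
                       time_col: str = "duration_years",
                       subject_col: str = "subject_id") -> LongitudinalResult:
    """Annual change in expression from paired scans.

    Random-intercept linear mixed model ``z ~ duration + (1 | subject)``
    fit by restricted maximum likelihood.  The fixed slope's 95% CI and
    p-value use Wald statistics with containment-df t quantiles
    (df = n_obs - n_subjects - 1), which keep near-nominal coverage in the
    small paired designs this is meant for.  Singular or non-converged
    fits fall back to the two-stage estimator (per-subject OLS slopes,
    one-sample t), logged.
    """
    df = records[[subject_col, time_col, z_col]].dropna()
    counts = df.groupby(subject_col)[time_col].count()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >=2 timepoints for >=2 subjects")
    try:
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(f"{z_col} ~ {time_col}", df, groups=df[subject_col]).fit(reml=True)
        slope = float(fit.params[time_col])
        se = float(fit.bse[time_col])
        if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
            raise ValueError("singular mixed-model fit")
        dof = max(1, len(df) - counts.size - 1)
        tcrit = stats.t.ppf(0.975, dof)
        p = float(2.0 * stats.t.sf(abs(slope / se), dof))
        return LongitudinalResult(slope=slope, ci_low=slope - tcrit * se,
                                  ci_high=slope + tcrit * se,
                                  p_value=p, method="mixed", n_subjects=int(counts.size))
    except Exception as exc:  # singular fit -> two-stage fallback
        logger.warning("mixed model failed (%s); using two-stage estimator", exc)
        slopes = []
        for _, g in df.groupby(subject_col):
            if g[time_col].nunique() >= 2:
                slopes.append(np.polyfit(g[time_col], g[z_col], 1)[0])
        slopes = np.asarray(slopes)
        t, p = stats.ttest_1samp(slopes, 0.0)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        tcrit = stats.t.ppf(0.975, slopes.size - 1)
        m = float(slopes.mean())
        return LongitudinalResult(slope=m, ci_low=m - tcrit * se, ci_high=m + tcrit * se,
                                  p_value=float(p), method="two-stage",
                                  n_subjects=int(slopes.size))


# ---------------------------------------------------------------------------
# clinical correlations and group comparisons

def correlate_clinical(records: pd.DataFrame, covariate: str,
                       z_col: str = "z_score") -> tuple[float, float, int]:
    """Pearson correlation of expression with a clinical covariate.

    Missing covariates are dropped pairwise; returns ``(r, p, n)``.
    """
    df = records[[z_col, covariate]].dropna()
    n = len(df)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    x, y = df[z_col].to_numpy(float), df[covariate].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in expression or covariate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


@dataclass
class GroupComparison:
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, t, p_bonferroni
    group_means: dict[str, float]


def compare_expression_groups(records: pd.DataFrame, value_col: str = "z_score",
                              group_col: str = "group") -> GroupComparison:
    """One-way ANOVA across diagnosis groups with Bonferroni post-hoc t-tests.

    Post-hoc contrasts are classic pooled-variance two-sample t-tests; their
    p-values are multiplied by the number of performed comparisons (capped
    at 1).
    """
    df = records[[group_col, value_col]].dropna()
    groups = {g: sub[value_col].to_numpy(float) for g, sub in df.groupby(group_col)}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >=2 groups with n>=2 each")
    for g, v in groups.items():
        if v.size == 2 and v.std() == 0:
            logger.warning("group %r has n=2 and zero variance", g)
    names = sorted(groups)
    arrays = [groups[g] for g in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, p = 0.0, 1.0  # all observations identical
    else:
        f_stat, p = stats.f_oneway(*arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, pt = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        rows.append({"group_a": a, "group_b": b, "t": float(t),
                     "p_bonferroni": min(1.0, float(pt) * len(pairs))})
    return GroupComparison(f_stat=float(f_stat), p_value=float(p),
                           pairwise=pd.DataFrame(rows),
                           group_means={g: float(v.mean()) for g, v in groups.items()})


def mmse_adjusted_group_comparison(records: pd.DataFrame, value_col: str = "z_score",
                                   group_col: str = "group",
                                   mmse_col: str = "mmse") -> GroupComparison:
    """Group comparison of expression after regressing out the MMSE effect.

    One-way ANOVA on the residuals of ``z ~ mmse`` (simple OLS over all
    complete records).
    """
    df = records[[group_col, value_col, mmse_col]].dropna().copy()
    slope, intercept = np.polyfit(df[mmse_col], df[value_col], 1)
    df["residual"] = df[value_col] - (intercept + slope * df[mmse_col])
    return compare_expression_groups(df, value_col="residual", group_col=group_col)
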