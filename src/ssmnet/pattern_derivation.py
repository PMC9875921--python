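"""Disease-pattern derivation: AIC model selection, combination, bootstrap.

From the retained principal components, every non-empty subset (up to
``2^K - 1`` models, K <= 6 by default) is fit as a logistic regression of
group on the subset's subject scores.  The subset with the lowest Akaike
Information Criterion, ``AIC = 2(k + 1) - 2 lnL``, defines the disease
pattern as the coefficient-weighted combination of its components,
renormalized to unit norm and oriented patient-positive.  Expression is
standardized against the derivation healthy controls (z-scores).

Pattern stability is assessed by a stratified subject bootstrap that
re-runs the whole derivation (centering, PCA, selection, combination) on
each resample, aligns the resampled pattern's sign to the original, and
flags a voxel as stable when the one-sided 95% CI of its weight excludes
zero on the side toward zero.

The structural (MRI) variant is the same procedure with an explicit list
of components excluded before enumeration (e.g. a leading component that
captures preprocessing artifacts).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ssm_pca
from .ssm_pca import SSMDecomposition, DEFAULT_N_RETAIN
from .volume_io import AnalysisMask, save_volume, VolumeGrid, load_volume

logger = logging.getLogger(__name__)

_AIC_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# logistic regression (Newton/IRLS)

@dataclass
class LogisticFit:
    coef: np.ndarray          # slope per predictor
    intercept: float
    loglik: float
    deviance: float
    aic: float
    n_iter: int
    converged: bool


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression with an intercept.

    Newton iterations capped at ``max_iter``; under complete separation the
    deviance converges toward zero and the fit stops once it no longer
    improves, so AIC selection then rests on the parameter-count penalty.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = Xd.T @ (y - p)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-10 * np.eye(k + 1), grad)
        beta = beta + step
        dev = _binomial_deviance(y, Xd @ beta)
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    dev = dev_old if np.isfinite(dev_old) else _binomial_deviance(y, Xd @ beta)
    loglik = -dev / 2.0
    aic = 2.0 * (k + 1) - 2.0 * loglik
    return LogisticFit(coef=beta[1:], intercept=float(beta[0]), loglik=float(loglik),
                       deviance=float(dev), aic=float(aic), n_iter=it, converged=converged)


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    p = np.clip(p, 1e-16, 1.0 - 1e-16)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# model selection

@dataclass
class SelectionResult:
    selected: tuple[int, ...]
    fit: LogisticFit            # fit on standardized scores of the selected subset
    table: pd.DataFrame         # one row per candidate subset with its AIC
    score_scale: np.ndarray | None = None  # per-PC score sd used to standardize


def select_pc_combination(scores: np.ndarray, is_patient: np.ndarray,
                          retained: list[int] | None = None,
                          excluded_pcs: tuple[int, ...] = ()) -> SelectionResult:
    """Exhaustive lowest-AIC logistic subset selection over retained PCs.

    Scores are standardized (unit sample sd) before entering the logistic
    models; the AIC ranking is unaffected (the likelihood is invariant to
    predictor scaling) but the coefficients then measure contribution per
    sd of expression, which is how the components are later combined.
    Ties (within 1e-9 AIC) are broken by fewer predictors, then
    lexicographically by index set, so selection is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    if is_patient.all() or (~is_patient).all():
        raise ValueError("need subjects of both groups for selection")
    if retained is None:
        retained = list(range(scores.shape[1]))
    pcs = [k for k in retained if k not in set(excluded_pcs)]
    if not pcs:
        raise ValueError("no components left after exclusion")
    scale = scores.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    std_scores = scores / scale
    y = is_patient.astype(float)
    rows = []
    fits: dict[tuple[int, ...], LogisticFit] = {}
    for r in range(1, len(pcs) + 1):
        for subset in itertools.combinations(pcs, r):
            f = fit_logistic(std_scores[:, subset], y)
            fits[subset] = f
            rows.append({"subset": subset, "n_predictors": r, "loglik": f.loglik,
                         "deviance": f.deviance, "aic": f.aic, "converged": f.converged})
    table = pd.DataFrame(rows)
    best_aic = table["aic"].min()
    tied = [tuple(s) for s in table.loc[table["aic"] <= best_aic + _AIC_TIE_TOL, "subset"]]
    selected = min(tied, key=lambda s: (len(s), s))
    return SelectionResult(selected=selected, fit=fits[selected],
                           table=table.sort_values("aic", ignore_index=True),
                           score_scale=scale)


# ---------------------------------------------------------------------------
# pattern model

@dataclass
class PatternModel:
    """Everything needed to score a new scan prospectively.

    ``weights`` is the unit-norm voxel-weight map over the analysis-mask
    voxels; ``gmp`` the derivation group mean profile; ``hc_ref_mean`` and
    ``hc_ref_sd`` calibrate raw scores to healthy-control z-scores.
    """

    weights: np.ndarray
    gmp: np.ndarray
    selected_pcs: tuple[int, ...]
    logit_coefs: dict[int, float]
    logit_intercept: float
    hc_ref_mean: float
    hc_ref_sd: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hc_ref_sd > 0:
            raise ValueError("hc_ref_sd must be positive")

    def zscore(self, raw: np.ndarray | float) -> np.ndarray | float:
        return zscore_expression(raw, self)

    # -- persistence: NIfTI weight/gmp maps with a JSON sidecar -------------
    def save(self, stem: str | Path, mask: AnalysisMask) -> None:
        stem = Path(stem)
        save_volume(VolumeGrid(mask.unflatten(self.weights), mask.affine),
                    stem.with_suffix(".weights.nii.gz"))
        save_volume(VolumeGrid(mask.unflatten(self.gmp), mask.affine),
                    stem.with_suffix(".gmp.nii.gz"))
        meta = {
            "selected_pcs": list(self.selected_pcs),
            "logit_coefs": {str(k): v for k, v in self.logit_coefs.items()},
            "logit_intercept": self.logit_intercept,
            "hc_ref_mean": self.hc_ref_mean,
            "hc_ref_sd": self.hc_ref_sd,
            "provenance": self.provenance,
            "weights_map": stem.with_suffix(".weights.nii.gz").name,
            "gmp_map": stem.with_suffix(".gmp.nii.gz").name,
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, json_path: str | Path, mask: AnalysisMask) -> "PatternModel":
        json_path = Path(json_path)
        meta = json.loads(json_path.read_text())
        w = mask.flatten(load_volume(json_path.parent / meta["weights_map"]).values)
        g = mask.flatten(load_volume(json_path.parent / meta["gmp_map"]).values)
        return cls(weights=w, gmp=g,
                   selected_pcs=tuple(meta["selected_pcs"]),
                   logit_coefs={int(k): v for k, v in meta["logit_coefs"].items()},
                   logit_intercept=meta["logit_intercept"],
                   hc_ref_mean=meta["hc_ref_mean"], hc_ref_sd=meta["hc_ref_sd"],
                   provenance=meta.get("provenance", {}))


def combine_pcs(decomposition: SSMDecomposition, selection: SelectionResult,
                provenance: dict | None = None) -> PatternModel:
    """Coefficient-weighted combination of the selected components.

    Coefficients come from the logistic fit on standardized scores, so
    each component enters in proportion to its discriminative effect per
    sd of expression.  The combined map is renormalized to unit norm and
    sign-fixed so the
    patient mean raw score is >= the control mean; healthy-control mean/sd
    of the raw scores calibrate prospective z-scoring (sample sd, n-1).
    """
    sel = selection.selected
    betas = np.asarray([selection.fit.coef[i] for i in range(len(sel))])
    w = betas @ decomposition.components[list(sel)]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("zero combined pattern vector (all coefficients zero)")
    w = w / norm
    raw = decomposition.srp @ w
    is_pat = decomposition.is_patient
    if is_pat is None:
        raise ValueError("decomposition lacks group labels")
    diff = raw[is_pat].mean() - raw[~is_pat].mean()
    if diff < 0 or (diff == 0 and ssm_pca._first_nonzero_sign(w) < 0):
        w = -w
        raw = -raw
    hc = raw[~is_pat]
    sd = float(hc.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in derivation control scores")
    return PatternModel(
        weights=w, gmp=decomposition.gmp, selected_pcs=sel,
        logit_coefs={int(k): float(b) for k, b in zip(sel, betas)},
        logit_intercept=selection.fit.intercept,
        hc_ref_mean=float(hc.mean()), hc_ref_sd=sd,
        provenance=provenance or {},
    )


def zscore_expression(raw: np.ndarray | float, model: PatternModel) -> np.ndarray | float:
    """z = (raw - hc_ref_mean) / hc_ref_sd."""
    return (np.asarray(raw, dtype=float) - model.hc_ref_mean) / model.hc_ref_sd


@dataclass
class DerivationResult:
    model: PatternModel
    decomposition: SSMDecomposition
    selection: SelectionResult


def derive_pattern(raw: np.ndarray, is_patient: np.ndarray,
                   n_retain: int = DEFAULT_N_RETAIN,
                   exclude_pcs: tuple[int, ...] = (),
                   provenance: dict | None = None) -> DerivationResult:
    """Full derivation: log -> double center -> PCA -> AIC selection -> combine."""
    is_patient = np.asarray(is_patient, dtype=bool)
    if is_patient.sum() < 2 or (~is_patient).sum() < 2:
        raise ValueError("need at least 2 subjects per group for derivation")
    dec = ssm_pca.decompose(raw, is_patient=is_patient, n_retain=n_retain)
    sel = select_pc_combination(dec.scores, is_patient, retained=dec.retained,
                                excluded_pcs=exclude_pcs)
    model = combine_pcs(dec, sel, provenance=provenance)
    return DerivationResult(model=model, decomposition=dec, selection=sel)


# ---------------------------------------------------------------------------
# bootstrap stability

@dataclass
class StabilityMap:
    """Per-voxel one-sided bootstrap CI bound and stability flags.

    ``ci_bound`` is the bootstrap quantile on the side toward zero (the
    ``alpha`` quantile for positively weighted voxels, ``1 - alpha`` for
    negative); a voxel is stable when that bound excludes zero.
    """

    ci_bound: np.ndarray
    stable_mask: np.ndarray
    original_weights: np.ndarray
    n_iter: int
    alpha: float
    n_redraws: int = 0


def bootstrap_stability(raw: np.ndarray, is_patient: np.ndarray,
                        n_iter: int = 1000, alpha: float = 0.05,
                        seed: int | None = None,
                        n_retain: int = DEFAULT_N_RETAIN,
                        exclude_pcs: tuple[int, ...] = (),
                        freeze_selection: bool = False) -> StabilityMap:
    """Stratified full-procedure subject bootstrap of the pattern weights.

    Each iteration resamples subjects with replacement within group and
    re-runs the complete derivation (by default including the AIC selection
    step, so the CI reflects selection uncertainty; ``freeze_selection``
    reuses the original subset and only refits its coefficients).
    Resamples that collapse a group onto a single unique subject are
    redrawn (counted).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    raw = np.asarray(raw, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    original = derive_pattern(raw, is_patient, n_retain=n_retain, exclude_pcs=exclude_pcs)
    w0 = original.model.weights
    rng = np.random.default_rng(seed)
    pat_idx = np.flatnonzero(is_patient)
    hc_idx = np.flatnonzero(~is_patient)
    stack = np.empty((n_iter, raw.shape[1]))
    n_redraws = 0
    for b in range(n_iter):
        while True:
            take_p = rng.choice(pat_idx, size=pat_idx.size, replace=True)
            take_h = rng.choice(hc_idx, size=hc_idx.size, replace=True)
            if np.unique(take_p).size >= 2 and np.unique(take_h).size >= 2:
                break
            n_redraws += 1
        take = np.concatenate([take_p, take_h])
        grp = np.concatenate([np.ones(take_p.size, bool), np.zeros(take_h.size, bool)])
        dec = ssm_pca.decompose(raw[take], is_patient=grp, n_retain=n_retain)
        if freeze_selection:
            subset = tuple(k for k in original.selection.selected if k < dec.n_retained)
            if not subset:
                subset = (0,)
            scale = dec.scores.std(axis=0, ddof=1)
            scale[scale == 0] = 1.0
            fit = fit_logistic((dec.scores / scale)[:, subset], grp.astype(float))
            sel = SelectionResult(selected=subset, fit=fit, table=pd.DataFrame(),
                                  score_scale=scale)
        else:
            sel = select_pc_combination(dec.scores, grp, retained=dec.retained,
                                        excluded_pcs=exclude_pcs)
        wb = combine_pcs(dec, sel).weights
        if wb @ w0 < 0:  # align resampled pattern to the original
            wb = -wb
        stack[b] = wb
    if n_redraws:
        logger.info("redrew %d degenerate bootstrap resamples", n_redraws)
    q_low = np.quantile(stack, alpha, axis=0)
    q_high = np.quantile(stack, 1.0 - alpha, axis=0)
    stable = np.where(w0 > 0, q_low > 0, np.where(w0 < 0, q_high < 0, False))
    ci_bound = np.where(w0 > 0, q_low, q_high)
    return StabilityMap(ci_bound=ci_bound, stable_mask=stable.astype(bool),
                        original_weights=w0, n_iter=n_iter, alpha=alpha,
                        n_redraws=n_redraws)
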