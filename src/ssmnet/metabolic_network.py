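"""Pattern-space graph analysis of regional metabolic connectivity.

The voxel pattern is reduced to atlas nodes (ROI-mean weights, z-scored
across ROIs, |z| > 1 kept, reference region excluded).  Per-subject node
activity is the ROI mean normalized to the reference (pons-role) region.
Group connectivity is the node-to-node Pearson matrix, stabilized by a
subject bootstrap whose elementwise median defines each group's graph.

On thresholded graphs (|r| > threshold, binarized) the module computes
mean degree, clustering coefficient and characteristic path length
(normalized by degree-preserving Maslov–Sneppen rewired nulls),
small-worldness (their ratio), assortativity, and eigenvector centrality;
edge gain/loss between groups is tested with a label-permutation test on
the correlation difference plus paired bootstrap confirmation, and
cross-site concordance of matrices with a two-way mixed, absolute
agreement, single-measure intraclass correlation, ICC(A,1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components, shortest_path

from .pattern_derivation import PatternModel
from .volume_io import AnalysisMask, AtlasParcellation, VolumeGrid, roi_means

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.30, 0.601, 0.05), 2))
DISPLAY_THRESHOLD = 0.6  # |r| cutoff used for centrality and edge display


# ---------------------------------------------------------------------------
# nodes

@dataclass
class NodeSet:
    """Pattern nodes: ROI labels with z-scored regional weights and polarity."""

    table: pd.DataFrame  # columns: label, name, mean_weight, z_weight, polarity

    @property
    def labels(self) -> list[int]:
        return [int(v) for v in self.table["label"]]

    def __len__(self) -> int:
        return len(self.table)


def extract_nodes(pattern: PatternModel, atlas: AtlasParcellation, mask: AnalysisMask,
                  z_threshold: float = 1.0) -> NodeSet:
    """ROI-mean pattern weights -> z-scores across ROIs -> keep |z| > 1.

    The reference region never enters the z-transform or the node set.
    """
    vol = VolumeGrid(mask.unflatten(pattern.weights), mask.affine)
    means = roi_means(vol, atlas, mask)
    means.pop(atlas.reference_label, None)
    if len(means) < 2:
        raise ValueError("need at least 2 ROIs to extract nodes")
    labels = sorted(means)
    w = np.asarray([means[l] for l in labels])
    sd = w.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate weights: all ROI means equal")
    z = (w - w.mean()) / sd
    keep = np.abs(z) > z_threshold
    if keep.sum() < 2:
        raise ValueError("fewer than 2 nodes survive |z| threshold; graph undefined")
    table = pd.DataFrame({
        "label": np.asarray(labels)[keep],
        "name": [atlas.roi_table.get(int(l), str(int(l))) for l in np.asarray(labels)[keep]],
        "mean_weight": w[keep],
        "z_weight": z[keep],
        "polarity": np.where(z[keep] > 0, "hyper", "hypo"),
    })
    return NodeSet(table=table.reset_index(drop=True))


def node_activity(raw_matrix: np.ndarray, atlas: AtlasParcellation, mask: AnalysisMask,
                  labels: list[int], reference_label: int | None = None) -> np.ndarray:
    """Subject × node matrix of reference-normalized regional activity.

    Entry (s, j) = mean raw activity of subject s over label j's in-mask
    voxels divided by the subject's reference-region mean.
    """
    if reference_label is None:
        reference_label = atlas.reference_label
    lab = mask.flatten(atlas.labels).astype(np.int64)
    raw_matrix = np.asarray(raw_matrix, dtype=float)
    wanted = list(labels) + [reference_label]
    cols = {}
    for label in wanted:
        sel = lab == label
        if not sel.any():
            raise ValueError(f"label {label} has no in-mask voxels")
        cols[label] = raw_matrix[:, sel].mean(axis=1)
    ref = cols[reference_label]
    if not (ref > 0).all():
        raise ValueError("non-positive reference-region mean")
    return np.column_stack([cols[l] / ref for l in labels])


# ---------------------------------------------------------------------------
# bootstrap correlation graphs

@dataclass
class ConnectivityGraph:
    """Group correlation matrix with its bootstrap stack and median matrix."""

    r: np.ndarray
    bootstrap_stack: np.ndarray  # (n_boot, n, n); NaN rows for constant resamples
    median_matrix: np.ndarray
    group: str = ""
    n_excluded: int = 0


def _corr(X: np.ndarray) -> np.ndarray:
    """Pearson matrix; columns with zero variance yield NaN rows/cols."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Xc / sd
        R = (Z.T @ Z) / X.shape[0]
    R[np.isclose(sd, 0.0), :] = np.nan
    R[:, np.isclose(sd, 0.0)] = np.nan
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def bootstrap_graphs(activity: np.ndarray, n_boot: int = 100,
                     seed: int | None = None, group: str = "") -> ConnectivityGraph:
    """Subject bootstrap of the node correlation matrix.

    Each iteration resamples subjects with replacement and recomputes the
    full Pearson matrix; the reliable group matrix is the elementwise
    median over iterations (NaN entries from constant resampled columns
    are excluded from the median, with the count logged).
    """
    activity = np.asarray(activity, dtype=float)
    n, p = activity.shape
    if n < 5:
        raise ValueError("need at least 5 subjects per group")
    rng = np.random.default_rng(seed)
    stack = np.empty((n_boot, p, p))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        stack[b] = _corr(activity[take])
    n_nan = int(np.isnan(stack).any(axis=(1, 2)).sum())
    if n_nan:
        logger.info("%d bootstrap matrices contain NaN entries (constant columns)", n_nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(stack, axis=0)
    return ConnectivityGraph(r=_corr(activity), bootstrap_stack=stack,
                             median_matrix=median, group=group, n_excluded=n_nan)


# ---------------------------------------------------------------------------
# eigenvector centrality

def eigenvector_centrality(matrix: np.ndarray, threshold: float = DISPLAY_THRESHOLD,
                           weighted: bool = True) -> np.ndarray:
    """Leading-eigenvector node importance on the thresholded |r| graph.

    Computed per connected component (non-negative, unit 2-norm within the
    component) and scaled by the component's size fraction, so an isolated
    module cannot silently dominate.  Edgeless graphs give all zeros.
    """
    R = np.asarray(matrix, dtype=float)
    n = R.shape[0]
    A = np.abs(R).copy()
    np.fill_diagonal(A, 0.0)
    A[A <= threshold] = 0.0
    if not weighted:
        A = (A > 0).astype(float)
    if not A.any():
        logger.warning("empty graph at threshold %.2f; centralities all zero", threshold)
        return np.zeros(n)
    n_comp, comp = connected_components(A > 0, directed=False)
    cent = np.zeros(n)
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if idx.size < 2:
            continue
        sub = A[np.ix_(idx, idx)]
        vals, vecs = np.linalg.eigh(sub)
        v = np.abs(vecs[:, -1])
        v = v / np.linalg.norm(v)
        cent[idx] = v * (idx.size / n)
    return cent


def bootstrap_centrality(stack: np.ndarray, threshold: float = DISPLAY_THRESHOLD,
                         weighted: bool = True) -> np.ndarray:
    """Median eigenvector centrality per node over bootstrap matrices."""
    vals = np.asarray([
        eigenvector_centrality(np.nan_to_num(m, nan=0.0), threshold, weighted)
        for m in stack
    ])
    return np.median(vals, axis=0)


# ---------------------------------------------------------------------------
# edge gain / loss

@dataclass
class EdgeChangeSet:
    """Edges gained or lost between groups, with supporting statistics.

    ``changes`` rows satisfy all three criteria (|r| gate, |dr| gate with
    permutation p < alpha, bootstrap confirmation); ``candidates`` holds
    every pair passing the two magnitude gates, before inference.
    """

    changes: pd.DataFrame
    candidates: pd.DataFrame
    n_perm: int
    n_boot: int


def _perm_abs_delta(X: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """|corr(A) - corr(B)| for random relabelings, vectorized over permutations.

    Returns an (n_perm, p, p) array.  Uses raw-moment accumulation per
    permutation: for each relabeling only group-A sums are accumulated;
    group B follows from the fixed totals.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    M = np.zeros((n_perm, n))
    for k in range(n_perm):
        M[k, rng.permutation(n)[:n_a]] = 1.0
    tot1 = X.sum(axis=0)
    tot2 = np.einsum("ij,il->jl", X, X)
    s1a = M @ X                                     # (n_perm, p)
    s2a = np.einsum("ki,ij,il->kjl", M, X, X)       # (n_perm, p, p)
    out = np.empty((n_perm, p, p))
    n_b = n - n_a
    for k in range(n_perm):
        ra = _corr_from_moments(s1a[k], s2a[k], n_a)
        rb = _corr_from_moments(tot1 - s1a[k], tot2 - s2a[k], n_b)
        out[k] = np.abs(ra - rb)
    return out


def _corr_from_moments(s1: np.ndarray, s2: np.ndarray, n: int) -> np.ndarray:
    mean = s1 / n
    cov = s2 / n - np.outer(mean, mean)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov / np.outer(sd, sd)
    return np.clip(np.nan_to_num(R, nan=0.0), -1.0, 1.0)


def permutation_edge_pvalues(activity_a: np.ndarray, activity_b: np.ndarray,
                             n_perm: int = 1000, seed: int | None = None) -> np.ndarray:
    """Permutation p-value of |Δr| for every node pair, (b+1)/(m+1) smoothed."""
    A = np.asarray(activity_a, float)
    B = np.asarray(activity_b, float)
    obs = np.abs(_corr(A) - _corr(B))
    rng = np.random.default_rng(seed)
    perm = _perm_abs_delta(np.vstack([A, B]), A.shape[0], n_perm, rng)
    exceed = (perm >= obs[None]).sum(axis=0)
    return (exceed + 1.0) / (n_perm + 1.0)


def edge_changes(activity_hc: np.ndarray, activity_patients: np.ndarray,
                 r_threshold: float = 0.6, dr_threshold: float = 0.4,
                 n_perm: int = 1000, n_boot: int = 100, alpha: float = 0.05,
                 confirm_fraction: float = 0.5, seed: int | None = None,
                 node_labels: list[int] | None = None) -> EdgeChangeSet:
    """Gained/lost connections between the control and patient graphs.

    A pair is a candidate when |r| exceeds ``r_threshold`` in either group
    and |Δr| exceeds ``dr_threshold``; candidates get a label-permutation
    p-value on |Δr| and are confirmed when the joint criterion holds in
    more than ``confirm_fraction`` of paired bootstrap resamples.
    Direction is a loss when the control correlation dominates.
    """
    A = np.asarray(activity_hc, float)
    B = np.asarray(activity_patients, float)
    if A.shape[0] < 5 or B.shape[0] < 5:
        raise ValueError("need at least 5 subjects per group")
    p = A.shape[1]
    r_hc = _corr(A)
    r_pat = _corr(B)
    delta = r_pat - r_hc
    iu, ju = np.triu_indices(p, k=1)
    gate = ((np.abs(r_hc) > r_threshold) | (np.abs(r_pat) > r_threshold)) \
        & (np.abs(delta) > dr_threshold)
    pvals = permutation_edge_pvalues(A, B, n_perm=n_perm, seed=seed)

    rng = np.random.default_rng(None if seed is None else seed + 1)
    confirm_counts = np.zeros((p, p))
    if gate[iu, ju].any():
        for _ in range(n_boot):
            ra = _corr(A[rng.integers(0, A.shape[0], A.shape[0])])
            rb = _corr(B[rng.integers(0, B.shape[0], B.shape[0])])
            ok = ((np.abs(ra) > r_threshold) | (np.abs(rb) > r_threshold)) \
                & (np.abs(rb - ra) > dr_threshold)
            confirm_counts += ok
    confirmed = confirm_counts / max(n_boot, 1) > confirm_fraction

    rows = []
    for i, j in zip(iu, ju):
        if not gate[i, j]:
            continue
        rows.append({
            "i": int(i), "j": int(j),
            "label_i": node_labels[i] if node_labels else int(i),
            "label_j": node_labels[j] if node_labels else int(j),
            "r_hc": float(r_hc[i, j]), "r_patient": float(r_pat[i, j]),
            "delta_r": float(delta[i, j]), "p_perm": float(pvals[i, j]),
            "direction": "loss" if abs(r_hc[i, j]) > abs(r_pat[i, j]) else "gain",
            "bootstrap_confirmed": bool(confirmed[i, j]),
        })
    candidates = pd.DataFrame(rows, columns=[
        "i", "j", "label_i", "label_j", "r_hc", "r_patient", "delta_r",
        "p_perm", "direction", "bootstrap_confirmed"])
    changes = candidates[(candidates["p_perm"] < alpha)
                         & candidates["bootstrap_confirmed"]].reset_index(drop=True)
    return EdgeChangeSet(changes=changes, candidates=candidates,
                         n_perm=n_perm, n_boot=n_boot)


# ---------------------------------------------------------------------------
# binarized graph metrics

def binarize(matrix: np.ndarray, threshold: float) -> np.ndarray:
    A = (np.abs(np.nan_to_num(matrix, nan=0.0)) > threshold)
    np.fill_diagonal(A, False)
    return A


def mean_degree(A: np.ndarray) -> float:
    return float(A.sum(axis=1).mean())


def clustering_coefficient(A: np.ndarray) -> float:
    """Average local clustering; nodes with degree < 2 contribute 0."""
    Af = A.astype(float)
    deg = Af.sum(axis=1)
    tri = np.diag(Af @ Af @ Af) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.where(denom > 0, tri / denom, 0.0)
    return float(local.mean())


def characteristic_path_length(A: np.ndarray) -> tuple[float, float]:
    """Mean shortest path over reachable pairs and the disconnected fraction.

    Disconnected pairs are excluded from the average (the exclusion
    convention); their fraction is returned so disconnection stays visible
    as a reachability drop.
    """
    n = A.shape[0]
    if n < 2 or not A.any():
        return np.nan, 1.0
    D = shortest_path(A.astype(float), method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    frac_disconnected = 1.0 - finite.sum() / off.sum()
    if not finite.any():
        return np.nan, 1.0
    return float(D[finite].mean()), float(frac_disconnected)


def assortativity(A: np.ndarray) -> float:
    """Degree Pearson correlation over edge endpoints (both orientations)."""
    deg = A.sum(axis=1).astype(float)
    i, j = np.nonzero(np.triu(A, k=1))
    if i.size < 2:
        return np.nan
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def rewire_degree_preserving(A: np.ndarray, rng: np.random.Generator,
                             swaps_per_edge: int = 10,
                             within_components: bool = True) -> np.ndarray:
    """Maslov–Sneppen double-edge swaps; exactly preserves the degree sequence.

    With ``within_components`` (default) swaps are restricted to edge
    pairs inside the same connected component of the source graph, so
    null graphs keep (approximately) its component partition — the
    connectedness-preserving null customary for these metrics.  Without
    it, rewiring freely merges components, which makes path lengths of
    disconnected graphs incomparable to their nulls under the
    reachable-pairs convention.
    """
    A = A.copy()
    edges = np.argwhere(np.triu(A, k=1))
    m = len(edges)
    if m < 2:
        return A
    if within_components:
        _, comp = connected_components(A, directed=False)
    else:
        comp = np.zeros(A.shape[0], dtype=int)
    edges = [tuple(e) for e in edges]
    n_attempts = swaps_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if comp[a] != comp[c]:
            continue
        if flip[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = False
        A[c, d] = A[d, c] = False
        A[a, d] = A[d, a] = True
        A[c, b] = A[b, c] = True
        edges[e1] = (a, d) if a < d else (d, a)
        edges[e2] = (c, b) if c < b else (b, c)
    return A


@dataclass
class GraphMetricsTable:
    """Per (group, threshold, bootstrap iteration) global graph metrics."""

    table: pd.DataFrame
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_null: int = 100


METRIC_COLUMNS = ("degree", "clustering_norm", "path_norm", "small_worldness",
                  "assortativity")


def global_metrics(stack: np.ndarray, group: str = "",
                   thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                   n_null: int = 100, seed: int | None = None,
                   swaps_per_edge: int = 10) -> GraphMetricsTable:
    """Global metrics for every bootstrap matrix at every |r| threshold.

    Clustering and path length are normalized by means over ``n_null``
    degree-preserving rewired graphs; small-worldness is their ratio.
    Edgeless (or otherwise degenerate) graphs yield NaN metrics, which the
    group comparison later excludes with a count.
    """
    if not all(0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for b, matrix in enumerate(np.asarray(stack, dtype=float)):
        for thr in thresholds:
            A = binarize(matrix, thr)
            row = {"group": group, "iteration": b, "threshold": float(thr)}
            if not A.any():
                row.update({c: np.nan for c in METRIC_COLUMNS})
                row.update({"clustering": np.nan, "path_length": np.nan,
                            "frac_disconnected": 1.0})
                rows.append(row)
                continue
            C = clustering_coefficient(A)
            L, frac_disc = characteristic_path_length(A)
            c_null, l_null = [], []
            for _ in range(n_null):
                An = rewire_degree_preserving(A, rng, swaps_per_edge)
                c_null.append(clustering_coefficient(An))
                l_null.append(characteristic_path_length(An)[0])
            c_rand = float(np.mean(c_null))
            l_rand = float(np.nanmean(l_null))
            c_norm = C / c_rand if c_rand > 0 else np.nan
            l_norm = L / l_rand if (np.isfinite(L) and l_rand > 0) else np.nan
            row.update({
                "degree": mean_degree(A),
                "clustering": C, "path_length": L,
                "frac_disconnected": frac_disc,
                "clustering_norm": c_norm, "path_norm": l_norm,
                "small_worldness": (c_norm / l_norm
                                    if (np.isfinite(c_norm) and np.isfinite(l_norm)
                                        and l_norm != 0) else np.nan),
                "assortativity": assortativity(A),
            })
            rows.append(row)
    return GraphMetricsTable(table=pd.DataFrame(rows), thresholds=tuple(thresholds),
                             n_null=n_null)


# ---------------------------------------------------------------------------
# two-way mixed repeated-measures ANOVA on graph metrics

@dataclass
class MixedAnovaResult:
    f_group: float
    p_group: float
    df_group: tuple[int, int]
    f_threshold: float
    p_threshold: float
    f_interaction: float
    p_interaction: float
    n_units: dict[str, int]
    n_dropped: int


def compare_global_metrics(table_a: GraphMetricsTable, table_b: GraphMetricsTable,
                           metric: str) -> MixedAnovaResult:
    """Split-plot ANOVA: group between bootstrap-iteration units, threshold within.

    Thresholds where fewer than half the units of either group are defined
    are dropped, then units with any remaining NaN are dropped (counted).
    The group main effect is tested against the between-unit error.
    """
    df = pd.concat([table_a.table, table_b.table], ignore_index=True)
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    wide = df.pivot_table(index=["group", "iteration"], columns="threshold",
                          values=metric, dropna=False)
    # drop thresholds that are mostly undefined in either group
    ok_cols = []
    for col in wide.columns:
        fracs = wide[col].notna().groupby(level="group").mean()
        if (fracs >= 0.5).all():
            ok_cols.append(col)
    if not ok_cols:
        raise ValueError(f"metric {metric!r} undefined at every threshold")
    wide = wide[ok_cols]
    n_before = len(wide)
    wide = wide.dropna()
    n_dropped = n_before - len(wide)
    if n_dropped:
        logger.info("dropped %d units with undefined %s", n_dropped, metric)
    counts = wide.groupby(level="group").size()
    if (counts < 2).any():
        raise ValueError("fewer than 2 complete units in a group")

    Y = wide.to_numpy(float)
    t = Y.shape[1]
    grp = wide.index.get_level_values("group").to_numpy()
    grand = Y.mean()
    unit_means = Y.mean(axis=1)
    ss_between_units = t * np.sum((unit_means - grand) ** 2)
    ss_group = sum(t * np.sum(grp == g) * (unit_means[grp == g].mean() - grand) ** 2
                   for g in groups)
    ss_subj = ss_between_units - ss_group
    n_units = len(wide)
    df_group, df_subj = len(groups) - 1, n_units - len(groups)
    ms_group = ss_group / df_group
    ms_subj = ss_subj / df_subj
    f_group = ms_group / ms_subj
    p_group = float(stats.f.sf(f_group, df_group, df_subj))

    col_means = Y.mean(axis=0)
    ss_thr = n_units * np.sum((col_means - grand) ** 2)
    ss_cells = 0.0
    for g in groups:
        sel = grp == g
        cell = Y[sel].mean(axis=0)
        ss_cells += sel.sum() * np.sum((cell - grand) ** 2)
    ss_inter = ss_cells - ss_thr - ss_group
    ss_total = np.sum((Y - grand) ** 2)
    ss_err_within = ss_total - ss_between_units - ss_thr - ss_inter
    df_thr = t - 1
    df_inter = df_thr * df_group
    df_err = df_thr * df_subj
    f_thr = (ss_thr / df_thr) / (ss_err_within / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err_within / df_err)
    return MixedAnovaResult(
        f_group=float(f_group), p_group=p_group, df_group=(df_group, df_subj),
        f_threshold=float(f_thr), p_threshold=float(stats.f.sf(f_thr, df_thr, df_err)),
        f_interaction=float(f_inter),
        p_interaction=float(stats.f.sf(f_inter, df_inter, df_err)),
        n_units={str(g): int(counts[g]) for g in groups}, n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# intraclass correlation

@dataclass
class ICCResult:
    icc: float
    f_stat: float
    p_value: float
    df1: int
    df2: int
    n_objects: int
    n_raters: int


def icc_absolute_single(data: np.ndarray) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measure.

    ``data`` is objects × raters.  From the two-way ANOVA mean squares
    (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The p-value tests ICC = 0 via F = MSR/MSE with (n-1, (n-1)(k-1)) df.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need >=3 objects and >=2 raters")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse == 0:
        f, p = np.inf, 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=float(icc), f_stat=float(f), p_value=p,
                     df1=n - 1, df2=(n - 1) * (k - 1), n_objects=n, n_raters=k)


def matrix_concordance(matrices: list[np.ndarray],
                       pairs: list[tuple[int, int]] | None = None) -> ICCResult:
    """Cross-site concordance of correlation matrices.

    Upper-triangle correlation pairs are the objects, sites the raters;
    ``pairs`` restricts the analysis to a block of node pairs.
    """
    if len(matrices) < 2:
        raise ValueError("need matrices from at least 2 sites")
    p = matrices[0].shape[0]
    if pairs is None:
        iu, ju = np.triu_indices(p, k=1)
        pairs = list(zip(iu.tolist(), ju.tolist()))
    if len(pairs) < 3:
        raise ValueError("need at least 3 correlation pairs")
    data = np.column_stack([[m[i, j] for i, j in pairs] for m in matrices])
    return icc_absolute_single(data)


# ---------------------------------------------------------------------------
# export

def edge_list(matrix: np.ndarray, threshold: float = DISPLAY_THRESHOLD,
              node_labels: list[int] | None = None) -> pd.DataFrame:
    """Edge-list TSV-ready table (node_i, node_j, weight) above a threshold."""
    p = matrix.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    keep = np.abs(matrix[iu, ju]) > threshold
    lab = node_labels if node_labels is not None else list(range(p))
    return pd.DataFrame({
        "node_i": [lab[i] for i in iu[keep]],
        "node_j": [lab[j] for j in ju[keep]],
        "weight": matrix[iu, ju][keep],
    })
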