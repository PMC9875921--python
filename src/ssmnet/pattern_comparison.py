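"""Comparison of two pattern topographies and their subject expressions.

Voxelwise Pearson correlation between two maps is tested against an
effective number of independent observations instead of the raw voxel
count: neighbouring voxels of smoothed maps are strongly autocorrelated,
so the naive degrees of freedom wildly overstate significance.  Each
map's spatial autocorrelation scale is estimated from the variance of
neighbour differences of the standardized map (for a Gaussian
autocorrelation ``rho(d) = exp(-d^2 / 2 s^2)``, the lag-1 correlation
gives ``s``); the product of the two maps' autocorrelation functions is
again Gaussian with ``s_AB^2 = s_A^2 s_B^2 / (s_A^2 + s_B^2)``, and the
effective sample size is ``n_eff = V / (2 pi s_AB^2)^{3/2}`` — the voxel
count divided by the correlation-resel volume.  The correlation itself is
untouched; only the degrees of freedom and p-value change.

Also here: |z| > 1 overlap decomposition of two maps into intersection
and exclusive supports (voxel level and node level), subnetwork ICC
blocks, paired expression dominance tests, and expression correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metabolic_network import NodeSet, icc_absolute_single, matrix_concordance, ICCResult
from .volume_io import AnalysisMask

logger = logging.getLogger(__name__)

MIN_EFFECTIVE_N = 12  # floor on the effective sample size (df >= 10)


@dataclass
class MapCorrelation:
    r: float
    n_voxels: int
    effective_df: float
    p_corrected: float
    p_naive: float
    acf_sd_a: float  # per-map autocorrelation scale, voxel units
    acf_sd_b: float


def estimate_acf_sd(volume: np.ndarray, mask3d: np.ndarray) -> float:
    """Gaussian-ACF scale (voxels) of a map from neighbour differences.

    The map is standardized within the mask; along each axis the variance
    of differences between adjacent in-mask voxels gives the lag-1
    autocorrelation ``rho1 = 1 - var(diff)/2`` and hence
    ``s = sqrt(-1 / (2 ln rho1))``.  Axes with no measurable smoothness
    (rho1 <= 0) contribute scale 0.  Returns the geometric mean across
    axes with at least one valid neighbour pair.
    """
    vol = np.asarray(volume, dtype=float)
    mask3d = np.asarray(mask3d, dtype=bool)
    vals = vol[mask3d]
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero-variance map")
    z = np.where(mask3d, (vol - vals.mean()) / sd, np.nan)
    scales = []
    for axis in range(3):
        d = np.diff(z, axis=axis)
        valid = np.isfinite(d)
        if valid.sum() < 2:
            continue
        var_d = float(np.mean(d[valid] ** 2))
        rho1 = 1.0 - var_d / 2.0
        if rho1 <= 0:
            scales.append(0.0)
        else:
            scales.append(np.sqrt(-1.0 / (2.0 * np.log(rho1))))
    if not scales:
        return 0.0
    scales = np.asarray(scales)
    if (scales == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(scales))))


def effective_sample_size(s_a: float, s_b: float, n_voxels: int) -> float:
    """Effective independent-sample count for correlating two smooth maps."""
    if s_a == 0 or s_b == 0:
        return float(n_voxels)
    s_ab2 = (s_a**2 * s_b**2) / (s_a**2 + s_b**2)
    n_eff = n_voxels / (2.0 * np.pi * s_ab2) ** 1.5
    return float(np.clip(n_eff, MIN_EFFECTIVE_N, n_voxels))


def voxelwise_correlation_corrected(map_a: np.ndarray, map_b: np.ndarray,
                                    mask: AnalysisMask) -> MapCorrelation:
    """Pearson correlation over in-mask voxels with autocorrelation-corrected p.

    ``map_a``/``map_b`` may be masked vectors or full 3D volumes.
    """
    a3, a = _as_volume_and_vector(map_a, mask)
    b3, b = _as_volume_and_vector(map_b, mask)
    n = mask.n_voxels
    if n < 10:
        raise ValueError("need at least 10 in-mask voxels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map")
    r, p_naive = stats.pearsonr(a, b)
    s_a = estimate_acf_sd(a3, mask.data)
    s_b = estimate_acf_sd(b3, mask.data)
    n_eff = effective_sample_size(s_a, s_b, n)
    df = n_eff - 2.0
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p_corr = float(2.0 * stats.t.sf(abs(t), df))
    return MapCorrelation(r=float(r), n_voxels=n, effective_df=float(df),
                          p_corrected=p_corr, p_naive=float(p_naive),
                          acf_sd_a=s_a, acf_sd_b=s_b)


def _as_volume_and_vector(m: np.ndarray, mask: AnalysisMask) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        return mask.unflatten(m, fill=np.nan), m
    return m, mask.flatten(m)


# ---------------------------------------------------------------------------
# overlap decomposition

@dataclass
class SubnetworkSpaces:
    """Disjoint voxel sets from thresholded supports of two z-scored maps."""

    intersection: np.ndarray   # boolean over in-mask voxels: |zA|>thr & |zB|>thr
    a_only: np.ndarray
    b_only: np.ndarray
    concordant: np.ndarray     # intersection voxels with matching polarity
    z_a: np.ndarray
    z_b: np.ndarray
    threshold: float


def overlap_decomposition(weights_a: np.ndarray, weights_b: np.ndarray,
                          threshold: float = 1.0) -> SubnetworkSpaces:
    """Partition the union of two pattern supports at |z| > threshold.

    Both maps are z-scored over the shared in-mask voxels first, making
    differently scaled inputs commensurable; polarity concordance
    (hypo-with-hypo, hyper-with-hyper) is recorded for the intersection.
    """
    za = _zscore_map(weights_a)
    zb = _zscore_map(weights_b)
    sup_a = np.abs(za) > threshold
    sup_b = np.abs(zb) > threshold
    inter = sup_a & sup_b
    return SubnetworkSpaces(
        intersection=inter, a_only=sup_a & ~sup_b, b_only=sup_b & ~sup_a,
        concordant=inter & (np.sign(za) == np.sign(zb)),
        z_a=za, z_b=zb, threshold=threshold,
    )


def _zscore_map(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    sd = w.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance map")
    return (w - w.mean()) / sd


# ---------------------------------------------------------------------------
# node-level subnetworks

@dataclass
class NodeSubnetworks:
    """Node-label partition of two node sets and the ICC pair blocks."""

    common: list[int]       # A ∩ B
    a_only: list[int]       # A \ B
    b_only: list[int]       # B \ A
    pair_blocks: dict[str, list[tuple[int, int]]]


def subnetwork_node_spaces(nodes_a: NodeSet | list[int],
                           nodes_b: NodeSet | list[int]) -> NodeSubnetworks:
    """Partition the node union and enumerate within/between pair blocks.

    Blocks (node-label pairs): within the common nodes, within each
    exclusive set, and between the common and B-only sets — the four
    blocks on which subnetwork concordance is evaluated.
    """
    la = set(nodes_a.labels if isinstance(nodes_a, NodeSet) else nodes_a)
    lb = set(nodes_b.labels if isinstance(nodes_b, NodeSet) else nodes_b)
    common = sorted(la & lb)
    a_only = sorted(la - lb)
    b_only = sorted(lb - la)

    def within(labels: list[int]) -> list[tuple[int, int]]:
        return [(x, y) for k, x in enumerate(labels) for y in labels[k + 1:]]

    blocks = {
        "within_common": within(common),
        "within_b_only": within(b_only),
        "within_a_only": within(a_only),
        "common_vs_b_only": [(x, y) for x in common for y in b_only],
    }
    for name, pairs in blocks.items():
        if not pairs:
            logger.info("subnetwork block %r is empty; ICC will be skipped", name)
    return NodeSubnetworks(common=common, a_only=a_only, b_only=b_only,
                           pair_blocks=blocks)


def block_concordance(matrices: list[np.ndarray], node_labels: list[int],
                      block_pairs: list[tuple[int, int]]) -> ICCResult | None:
    """ICC(A,1) of a label-pair block across site matrices (None if empty/small)."""
    index = {lab: k for k, lab in enumerate(node_labels)}
    pairs = [(index[i], index[j]) for i, j in block_pairs if i in index and j in index]
    if len(pairs) < 3:
        return None
    return matrix_concordance(matrices, pairs=pairs)


# ---------------------------------------------------------------------------
# paired expression tests

def paired_pattern_dominance(z_a: np.ndarray, z_b: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sided t-test on z_a - z_b; returns (mean difference, t, p).

    Both score vectors must come from the same subjects and be calibrated
    against the same healthy-control reference.  A zero-variance nonzero
    difference is reported as t = ±inf, p = 0 (degenerate, logged).
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError("score vectors must be paired")
    d = z_a - z_b
    mean = float(d.mean())
    if d.std(ddof=1) == 0:
        if mean == 0:
            return 0.0, 0.0, 1.0
        logger.warning("zero-variance nonzero paired difference; degenerate t")
        return mean, float(np.sign(mean) * np.inf), 0.0
    t, p = stats.ttest_rel(z_a, z_b)
    return mean, float(t), float(p)


def expression_correlation(z_a: np.ndarray, z_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of paired subject scores with two-sided p."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.size < 4:
        raise ValueError("need at least 4 paired scores")
    if z_a.std() == 0 or z_b.std() == 0:
        raise ValueError("zero variance in scores")
    r, p = stats.pearsonr(z_a, z_b)
    return float(r), float(p)
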