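"""Scaled subprofile model decomposition (log transform, double centering, PCA).

The scaled subprofile model treats each scan as a multiplicative combination
of a subject global factor, a shared regional mean profile, and zero-mean
covariance patterns.  Taking natural logs and double-centering the
subjects × voxels matrix removes the global factor (rows) and the group mean
profile (columns); PCA of the residual (the subject residual profile, SRP)
yields covariance patterns (voxel-weight maps) and per-subject expression
scores.

Conventions
-----------
* The group mean profile (GMP) is the column mean of the row-centered log
  data over *all* derivation subjects, patients and controls combined.
* Components are the right singular vectors of the SRP, unit norm, ordered
  by singular value.  Scores are computed as ``srp @ component`` so the
  score/weight identity holds exactly.
* Sign convention: when group labels are supplied, each component is
  oriented so the patient mean score is >= the control mean score; on ties
  the first nonzero weight is made positive.  This makes bootstrap
  alignment deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_RETAIN = 6  # first six components enter model selection by default


def log_transform(raw: np.ndarray) -> np.ndarray:
    """Elementwise natural log; every entry must be strictly positive."""
    raw = np.asarray(raw, dtype=float)
    bad = ~(raw > 0)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive entry at subject {int(idx[0])}, voxel {int(idx[1])}: "
            f"{raw[tuple(idx)]!r}"
        )
    return np.log(raw)


def double_center(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract row means, then the column mean profile.

    Returns ``(gmp, srp)`` where ``gmp`` is the group mean profile (column
    mean of the row-centered matrix) and ``srp`` the doubly centered
    residual whose row and column means both vanish.
    """
    L = np.asarray(L, dtype=float)
    if not np.isfinite(L).all():
        raise ValueError("non-finite values in log matrix")
    row_centered = L - L.mean(axis=1, keepdims=True)
    gmp = row_centered.mean(axis=0)
    srp = row_centered - gmp
    return gmp, srp


@dataclass
class SSMDecomposition:
    """PCA of the subject residual profile.

    Attributes
    ----------
    gmp : (V,) group mean profile of the derivation cohort (log units).
    srp : (S, V) doubly centered log data.
    components : (K, V) unit-norm voxel-weight maps (GIS), ordered by
        singular value.
    vaf : (K,) fraction of SRP variance accounted for by each component.
    scores : (S, K) subject expression scores, ``srp @ components.T``.
    singular_values : (K,) singular values of the SRP.
    n_retained : number of leading components that enter model selection.
    is_patient : (S,) boolean group labels used for sign orientation, if any.
    """

    gmp: np.ndarray
    srp: np.ndarray
    components: np.ndarray
    vaf: np.ndarray
    scores: np.ndarray
    singular_values: np.ndarray
    n_retained: int
    is_patient: np.ndarray | None = None

    @property
    def retained(self) -> list[int]:
        return list(range(self.n_retained))


def fit_pca(srp: np.ndarray, is_patient: np.ndarray | None = None,
            n_retain: int = DEFAULT_N_RETAIN, gmp: np.ndarray | None = None) -> SSMDecomposition:
    """PCA of the SRP via economy SVD on the subjects × voxels matrix.

    At most ``min(S - 1, V)`` components carry variance for a doubly
    centered matrix; if the rank falls short of ``n_retain`` the retained
    set shrinks (logged).
    """
    srp = np.asarray(srp, dtype=float)
    S, V = srp.shape
    if S < 3:
        raise ValueError("need at least 3 subjects for PCA")
    if not np.any(srp):
        raise ValueError("all-zero residual matrix")
    U, s, Vt = np.linalg.svd(srp, full_matrices=False)
    # drop numerically null directions beyond the centering-limited rank
    rank = int(np.sum(s > max(S, V) * np.finfo(float).eps * s[0]))
    rank = min(rank, S - 1, V)
    s = s[:rank]
    components = Vt[:rank]

    if is_patient is not None:
        is_patient = np.asarray(is_patient, dtype=bool)
    for k in range(rank):
        flip = False
        if is_patient is not None and is_patient.any() and (~is_patient).any():
            sc = srp @ components[k]
            diff = sc[is_patient].mean() - sc[~is_patient].mean()
            if diff < 0:
                flip = True
            elif diff == 0:
                flip = _first_nonzero_sign(components[k]) < 0
        else:
            flip = _first_nonzero_sign(components[k]) < 0
        if flip:
            components[k] = -components[k]

    scores = srp @ components.T  # exact score/weight identity by construction
    vaf = s**2 / np.sum(s**2)
    n_retained = min(n_retain, rank)
    if n_retained < n_retain:
        logger.info("rank %d < requested %d components; retaining %d",
                    rank, n_retain, n_retained)
    return SSMDecomposition(
        gmp=gmp if gmp is not None else np.zeros(V),
        srp=srp, components=components, vaf=vaf, scores=scores,
        singular_values=s, n_retained=n_retained, is_patient=is_patient,
    )


def _first_nonzero_sign(v: np.ndarray) -> float:
    nz = np.flatnonzero(v)
    return float(np.sign(v[nz[0]])) if nz.size else 1.0


def decompose(raw: np.ndarray, is_patient: np.ndarray | None = None,
              n_retain: int = DEFAULT_N_RETAIN) -> SSMDecomposition:
    """Full SSM pipeline on a raw subjects × voxels matrix."""
    L = log_transform(raw)
    gmp, srp = double_center(L)
    return fit_pca(srp, is_patient=is_patient, n_retain=n_retain, gmp=gmp)
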