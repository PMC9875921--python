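"""Synthetic multi-site image cohorts with planted ground truth.

The generator emulates the statistical structure that covariance-pattern
analysis assumes in FDG-PET-like data, with every latent quantity exposed:

    ln Y(s, v) = ln g_s + gmp0(v) + sum_p alpha_{s,p} * P_p(v) + eps(s, v)

* ``g_s`` — lognormal per-subject global scale (removed by log +
  row-centering; planted so tests can assert scaling invariance).
* ``gmp0`` — shared baseline log-activity profile (patients and controls
  share it: disease enters only through loadings, matching the model's
  premise that the pattern is a covariance direction, not a mean shift).
* ``P_p`` — planted pattern, constant within parcels so node-extraction
  ground truth is unambiguous; parcels belong to a hypometabolic
  "frontotemporal" module and a relatively hypermetabolic
  "parieto-occipital" module; zero mean and unit norm over the mask.
* ``alpha_{s,p}`` — per-parcel loading: the subject's per-module loading
  (group-dependent mean and inter-module correlation — decorrelation in
  patients emulates connectivity loss) plus per-node jitter (stronger in
  patients: within-module coherence degrades too).
* ``eps`` — i.i.d. Gaussian voxel log-noise.

MMSE is anticorrelated with the total loading; longitudinal scans add a
fixed annual loading increase; a paired "structural" cohort shares the
topography at an attenuated effect size plus one structural-only parcel.
All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import (AnalysisMask, AtlasParcellation, VolumeGrid,
                        save_volume, write_metadata)

MODULE_NAMES = ("frontotemporal", "parieto-occipital")


@dataclass
class CohortSpec:
    """Cohort dimensions: counts are per site."""

    n_patients: int = 20
    n_controls: int = 20
    sites: tuple[str, ...] = ("SLO",)
    shape: tuple[int, int, int] = (24, 24, 24)
    n_parcels: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 4:
            raise ValueError("need at least 4 parcels")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the generator's full latent state."""

    pattern: np.ndarray                    # (V,) zero mean, unit norm
    module_patterns: dict[str, np.ndarray]
    parcel_basis: np.ndarray               # (n_pattern_parcels, V) per-parcel maps
    pattern_parcels: list[int]             # labels carrying pattern weight
    module_of_parcel: dict[int, str | None]
    gmp0: np.ndarray
    loading_mean: dict[str, float] = field(default_factory=lambda: {"patient": 2.0, "control": 0.0})
    loading_sd: float = 1.0
    inter_module_corr: dict = field(default_factory=lambda: {"control": 0.8, "patient": 0.5})
    node_jitter_scale: dict[str, float] = field(default_factory=lambda: {"control": 0.5, "patient": 0.7})
    parcel_jitter_profile: np.ndarray | None = None  # per pattern parcel
    global_scale_sd: float = 0.2
    noise_sd: float = 0.02
    annual_increase: float = 0.95
    mmse_intercept: float = 28.5
    mmse_slope: float = 2.0
    mmse_noise_sd: float = 2.0
    structural_attenuation: float = 0.4
    structural_extra_parcels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern, float)
        if abs(p.sum()) > 1e-8 * np.abs(p).sum():
            raise ValueError("planted pattern must have zero mean")
        if not np.isclose(np.linalg.norm(p), 1.0):
            raise ValueError("planted pattern must have unit norm")
        for rho in _corr_values(self.inter_module_corr):
            if abs(rho) > 1.0:
                raise ValueError("|inter_module_corr| must be <= 1")
        if self.loading_sd < 0 or self.noise_sd < 0 or self.global_scale_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def corr_for(self, group: str, site: str) -> float:
        v = self.inter_module_corr
        if isinstance(v, dict):
            if (group, site) in v:
                return float(v[(group, site)])
            return float(v[group])
        return float(v)

    def replace(self, **kw) -> "SyntheticTruth":
        return dataclasses.replace(self, **kw)


def _corr_values(v) -> list[float]:
    return [float(x) for x in v.values()] if isinstance(v, dict) else [float(v)]


# ---------------------------------------------------------------------------
# atlas

def make_atlas(spec: CohortSpec) -> tuple[AnalysisMask, AtlasParcellation, dict[int, str | None]]:
    """Contiguous-block parcellation with one reference (pons-role) parcel.

    The grid is cut into axis-aligned blocks; the first ``n_parcels``
    blocks are parcels 1..n_parcels, the next is the reference region, and
    leftover blocks stay outside the mask.  A quarter of the parcels go
    to each module; the remainder carries no pattern weight.
    """
    K = spec.n_parcels + 1
    na = int(np.ceil(K ** (1 / 3)))
    nb = int(np.ceil(np.sqrt(K / na)))
    nc = int(np.ceil(K / (na * nb)))
    sx, sy, sz = spec.shape
    if na > sx or nb > sy or nc > sz:
        raise ValueError(f"grid {spec.shape} too small for {K} blocks")
    labels = np.zeros(spec.shape, dtype=np.int32)
    xb = np.array_split(np.arange(sx), na)
    yb = np.array_split(np.arange(sy), nb)
    zb = np.array_split(np.arange(sz), nc)
    block = 0
    for xs in xb:
        for ys in yb:
            for zs in zb:
                block += 1
                if block > K:
                    continue
                labels[np.ix_(xs, ys, zs)] = block
    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic toy grid
    mask = AnalysisMask(data=labels > 0, affine=affine)
    reference = spec.n_parcels + 1
    n_mod = max(2, spec.n_parcels // 4)  # pattern support ~half the parcels,
    # mirroring node counts a real pattern yields from a whole-brain atlas
    modules: dict[int, str | None] = {}
    roi_table = {}
    for lab in range(1, spec.n_parcels + 1):
        if lab <= n_mod:
            modules[lab] = MODULE_NAMES[0]
        elif lab <= 2 * n_mod:
            modules[lab] = MODULE_NAMES[1]
        else:
            modules[lab] = None
        roi_table[lab] = f"parcel_{lab:02d}"
    roi_table[reference] = "reference_pons"
    atlas = AtlasParcellation(labels=labels, affine=affine, roi_table=roi_table,
                              reference_label=reference)
    return mask, atlas, modules


# ---------------------------------------------------------------------------
# truth construction

def default_truth(mask: AnalysisMask, atlas: AtlasParcellation,
                  modules: dict[int, str | None], **overrides) -> SyntheticTruth:
    """Build the default planted truth on a given atlas.

    The hypometabolic module gets negative parcel weights, the
    hypermetabolic module positive ones (deterministic magnitudes in
    0.8–1.2), balanced to zero mean and normalized to unit norm; the
    voxel log-noise default (0.02) puts the planted pattern's expected
    share of residual variance near one third of the total, the share a
    dominant disease pattern typically carries in real cohorts.
    """
    lab = mask.flatten(atlas.labels).astype(int)
    ft = [l for l, m in modules.items() if m == MODULE_NAMES[0]]
    po = [l for l, m in modules.items() if m == MODULE_NAMES[1]]
    if not ft or not po:
        raise ValueError("need parcels in both modules")
    raw = np.zeros(mask.n_voxels)
    mags_ft = np.linspace(0.8, 1.2, len(ft))
    mags_po = np.linspace(0.8, 1.2, len(po))
    for l, m in zip(ft, mags_ft):
        raw[lab == l] = -m
    for l, m in zip(po, mags_po):
        raw[lab == l] = +m
    # balance the positive module so the map has exactly zero mean
    pos = raw > 0
    raw[pos] *= -raw[raw < 0].sum() / raw[pos].sum()
    norm = np.linalg.norm(raw)
    pattern = raw / norm
    pattern_parcels = ft + po
    parcel_basis = np.zeros((len(pattern_parcels), mask.n_voxels))
    for k, l in enumerate(pattern_parcels):
        parcel_basis[k, lab == l] = pattern[lab == l]
    module_patterns = {
        MODULE_NAMES[0]: parcel_basis[:len(ft)].sum(axis=0),
        MODULE_NAMES[1]: parcel_basis[len(ft):].sum(axis=0),
    }
    parcels_all = atlas.parcel_labels
    offsets = np.linspace(-0.3, 0.3, len(parcels_all) + 1)
    gmp0 = np.full(mask.n_voxels, np.log(100.0))
    for off, l in zip(offsets, parcels_all + [atlas.reference_label]):
        gmp0[lab == l] += off
    jitter_profile = np.linspace(0.7, 1.8, len(pattern_parcels))
    null_parcels = [l for l, m in modules.items() if m is None]
    extra = (null_parcels[0],) if null_parcels else ()
    defaults = dict(
        pattern=pattern, module_patterns=module_patterns, parcel_basis=parcel_basis,
        pattern_parcels=pattern_parcels, module_of_parcel=dict(modules), gmp0=gmp0,
        parcel_jitter_profile=jitter_profile, structural_extra_parcels=extra,
    )
    defaults.update(overrides)
    return SyntheticTruth(**defaults)


def make_default_cohort_inputs(spec: CohortSpec, **truth_overrides):
    """Convenience: atlas + truth for a spec in one call."""
    mask, atlas, modules = make_atlas(spec)
    truth = default_truth(mask, atlas, modules, **truth_overrides)
    return mask, atlas, modules, truth


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class SimulatedCohort:
    raw: np.ndarray                 # (S, V) positive raw activity
    metadata: pd.DataFrame
    module_loadings: np.ndarray     # (S, M) planted module loadings
    parcel_loadings: np.ndarray     # (S, n_pattern_parcels)
    truth: SyntheticTruth
    mask: AnalysisMask
    atlas: AtlasParcellation

    @property
    def is_patient(self) -> np.ndarray:
        return (self.metadata["group"] == "patient").to_numpy()

    def volumes(self) -> list[VolumeGrid]:
        return [VolumeGrid(self.mask.unflatten(row, fill=0.0), self.mask.affine)
                for row in self.raw]

    def write(self, out_dir: str | Path) -> None:
        """Persist the cohort: NIfTI volumes, mask, atlas, metadata, truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mask.save(out / "mask.nii.gz")
        self.atlas.save(out / "atlas.nii.gz")
        save_volume(VolumeGrid(self.mask.unflatten(self.truth.pattern), self.mask.affine),
                    out / "planted_pattern.nii.gz")
        for sid, row in zip(self.metadata["subject_id"], self.raw):
            save_volume(VolumeGrid(self.mask.unflatten(row, fill=0.0), self.mask.affine),
                        out / f"{sid}.nii.gz")
        write_metadata(self.metadata, out / "metadata.csv")
        scalars = {
            "loading_mean": self.truth.loading_mean,
            "loading_sd": self.truth.loading_sd,
            "inter_module_corr": {str(k): v for k, v in self.truth.inter_module_corr.items()}
            if isinstance(self.truth.inter_module_corr, dict) else self.truth.inter_module_corr,
            "node_jitter_scale": self.truth.node_jitter_scale,
            "global_scale_sd": self.truth.global_scale_sd,
            "noise_sd": self.truth.noise_sd,
            "annual_increase": self.truth.annual_increase,
            "structural_attenuation": self.truth.structural_attenuation,
            "reference_label": self.atlas.reference_label,
            "pattern_parcels": self.truth.pattern_parcels,
            "module_of_parcel": {str(k): v for k, v in self.truth.module_of_parcel.items()},
        }
        (out / "truth.json").write_text(json.dumps(scalars, indent=2))


def _draw_module_loadings(n: int, group: str, site: str, truth: SyntheticTruth,
                          rng: np.random.Generator, n_modules: int) -> np.ndarray:
    rho = truth.corr_for(group, site)
    cov = np.full((n_modules, n_modules), rho * truth.loading_sd**2)
    np.fill_diagonal(cov, truth.loading_sd**2)
    mean = np.full(n_modules, truth.loading_mean[group])
    if truth.loading_sd == 0:
        return np.tile(mean, (n, 1))
    # eigh handles singular covariances (|rho| = 1) as well as the generic case
    return rng.multivariate_normal(mean, cov, size=n, method="eigh")


def _parcel_loadings(module_loadings: np.ndarray, group: str, truth: SyntheticTruth,
                     rng: np.random.Generator, n_ft: int, n_parcels: int) -> np.ndarray:
    """Per-parcel loading = module loading + heterogeneous per-node jitter."""
    n = module_loadings.shape[0]
    module_index = np.array([0] * n_ft + [1] * (n_parcels - n_ft))
    base = module_loadings[:, module_index]
    profile = truth.parcel_jitter_profile
    if profile is None:
        profile = np.ones(n_parcels)
    tau = truth.node_jitter_scale.get(group, 0.0) * np.asarray(profile)
    return base + rng.standard_normal((n, n_parcels)) * tau


def _synthesize(parcel_loadings: np.ndarray, truth: SyntheticTruth,
                rng: np.random.Generator, basis: np.ndarray | None = None,
                gmp0: np.ndarray | None = None,
                amplitude: float = 1.0) -> np.ndarray:
    basis = truth.parcel_basis if basis is None else basis
    gmp0 = truth.gmp0 if gmp0 is None else gmp0
    n = parcel_loadings.shape[0]
    V = basis.shape[1]
    ln_g = rng.normal(0.0, truth.global_scale_sd, size=n) if truth.global_scale_sd else np.zeros(n)
    eps = rng.normal(0.0, truth.noise_sd, size=(n, V)) if truth.noise_sd else 0.0
    ln_y = ln_g[:, None] + gmp0[None, :] + amplitude * (parcel_loadings @ basis) + eps
    return np.exp(ln_y)


def simulate_cohort(spec: CohortSpec, truth: SyntheticTruth,
                    seed: int | None = None,
                    module_loadings: np.ndarray | None = None) -> SimulatedCohort:
    """Draw a multi-site cohort from the generative model.

    ``module_loadings`` (ordered patients-then-controls per site) overrides
    the random loading draw, for degenerate/fixed-loading tests.
    """
    mask, atlas, modules = make_atlas(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_modules = len(truth.module_patterns)
    n_ft = sum(1 for l in truth.pattern_parcels
               if truth.module_of_parcel[l] == MODULE_NAMES[0])
    rows, mats, mod_list, parcel_list = [], [], [], []
    offset = 0
    for site in spec.sites:
        for group, n in (("patient", spec.n_patients), ("control", spec.n_controls)):
            if n == 0:
                continue
            if module_loadings is not None:
                alpha_mod = np.asarray(module_loadings[offset:offset + n], float)
            else:
                alpha_mod = _draw_module_loadings(n, group, site, truth, rng, n_modules)
            offset += n
            alpha_parcel = _parcel_loadings(alpha_mod, group, truth, rng, n_ft,
                                            len(truth.pattern_parcels))
            mats.append(_synthesize(alpha_parcel, truth, rng))
            total = alpha_mod.sum(axis=1)
            mmse = truth.mmse_intercept - truth.mmse_slope * total
            if truth.mmse_noise_sd:
                mmse = mmse + rng.normal(0.0, truth.mmse_noise_sd, size=n)
            mmse = np.clip(np.round(mmse), 0, 30)
            if group == "patient":
                duration = np.maximum(0.3, rng.normal(3.0, 2.0, size=n))
            else:
                duration = np.full(n, np.nan)
            for i in range(n):
                rows.append({
                    "subject_id": f"{site}-{group[:3]}-{i:03d}",
                    "group": group, "site": site, "scan_date": "2020-01-01",
                    "mmse": mmse[i], "duration_years": duration[i],
                })
            mod_list.append(alpha_mod)
            parcel_list.append(alpha_parcel)
    return SimulatedCohort(
        raw=np.vstack(mats), metadata=pd.DataFrame(rows),
        module_loadings=np.vstack(mod_list), parcel_loadings=np.vstack(parcel_list),
        truth=truth, mask=mask, atlas=atlas,
    )


# ---------------------------------------------------------------------------
# longitudinal

@dataclass
class SimulatedLongitudinal:
    raw: np.ndarray                 # (2S, V): baseline scans then follow-ups
    metadata: pd.DataFrame          # subject_id, timepoint, duration_years, ...
    baseline_loadings: np.ndarray   # (S, M)
    followup_loadings: np.ndarray
    truth: SyntheticTruth
    mask: AnalysisMask
    atlas: AtlasParcellation


def simulate_longitudinal(spec: CohortSpec, truth: SyntheticTruth,
                          years: np.ndarray | None = None,
                          seed: int | None = None) -> SimulatedLongitudinal:
    """Paired patient scans with a fixed annual increase in total loading.

    The planted annual increase is split equally across modules, so the
    noiseless follow-up total loading is baseline + annual_increase * t.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    site = spec.sites[0]
    if years is None:
        years = np.maximum(0.5, rng.normal(3.0, 2.0, size=n))
    years = np.asarray(years, float)
    if (years < 0).any():
        raise ValueError("negative scan interval")
    if years.size != n:
        raise ValueError("one interval per patient required")
    mask, atlas, modules = make_atlas(spec)
    n_modules = len(truth.module_patterns)
    n_ft = sum(1 for l in truth.pattern_parcels
               if truth.module_of_parcel[l] == MODULE_NAMES[0])
    alpha0 = _draw_module_loadings(n, "patient", site, truth, rng, n_modules)
    alpha1 = alpha0 + (truth.annual_increase / n_modules) * years[:, None]
    base_dur = np.maximum(0.3, rng.normal(2.2, 1.5, size=n))
    mats, rows = [], []
    for tp, alpha, dur in (("TP1", alpha0, base_dur), ("TP2", alpha1, base_dur + years)):
        pl = _parcel_loadings(alpha, "patient", truth, rng, n_ft, len(truth.pattern_parcels))
        mats.append(_synthesize(pl, truth, rng))
        for i in range(n):
            rows.append({
                "subject_id": f"{site}-long-{i:03d}", "group": "patient",
                "site": site, "scan_date": "2020-01-01", "timepoint": tp,
                "mmse": np.nan, "duration_years": dur[i],
            })
    return SimulatedLongitudinal(
        raw=np.vstack(mats), metadata=pd.DataFrame(rows),
        baseline_loadings=alpha0, followup_loadings=alpha1,
        truth=truth, mask=mask, atlas=atlas,
    )


def simulate_expression_records(n_subjects: int = 6, slope: float = 0.95,
                                noise_sd: float = 0.3, intercept_mean: float = 5.0,
                                intercept_sd: float = 1.0,
                                interval_mean: float = 3.0, interval_sd: float = 2.0,
                                seed: int | None = None) -> pd.DataFrame:
    """Score-level paired longitudinal records (two scans per subject).

    z(t) = subject intercept + slope * duration + noise; intervals are
    drawn N(interval_mean, interval_sd) truncated at 0.5 years.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(intercept_mean, intercept_sd, size=n_subjects)
    t0 = np.maximum(0.3, rng.normal(2.2, 1.5, size=n_subjects))
    dt = np.maximum(0.5, rng.normal(interval_mean, interval_sd, size=n_subjects))
    rows = []
    for i in range(n_subjects):
        for tp, t in (("TP1", t0[i]), ("TP2", t0[i] + dt[i])):
            rows.append({"subject_id": f"long-{i:03d}", "timepoint": tp,
                         "duration_years": t,
                         "z_score": a[i] + slope * t + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structural (atrophy-like) cohort

def structural_basis(truth: SyntheticTruth, mask: AnalysisMask,
                     atlas: AtlasParcellation) -> tuple[np.ndarray, list[int]]:
    """Parcel basis of the structural pattern: shared core + extra parcel(s)."""
    lab = mask.flatten(atlas.labels).astype(int)
    extra_rows = []
    mag = np.abs(truth.pattern[truth.pattern != 0]).mean()
    for l in truth.structural_extra_parcels:
        row = np.zeros(mask.n_voxels)
        row[lab == l] = -mag  # structural-only atrophy lobule
        extra_rows.append(row)
    basis = np.vstack([truth.parcel_basis] + extra_rows) if extra_rows else truth.parcel_basis
    parcels = truth.pattern_parcels + list(truth.structural_extra_parcels)
    return basis, parcels


def simulate_structural_cohort(spec: CohortSpec, truth: SyntheticTruth,
                               seed: int | None = None,
                               module_loadings: np.ndarray | None = None) -> SimulatedCohort:
    """Paired gray-matter-density-like cohort sharing the metabolic topography.

    ``structural_attenuation`` is the ratio of the structural to the
    metabolic *standardized* effect: the structural module loading is
    ``att * alpha + sqrt(1 - att^2) * xi`` with ``xi`` a modality-specific
    latent of the same scale, so the loading sd is unchanged while the
    patient-control contrast (and hence the standardized voxel effect and
    the z-scored expression effect) shrinks by ``att``, and paired
    expression scores correlate positively across modalities.  Pass the
    metabolic cohort's ``module_loadings`` to obtain modality-paired
    subjects.
    """
    att = truth.structural_attenuation
    if not (0.0 < att <= 1.0):
        raise ValueError("structural_attenuation must be in (0, 1]")
    mask, atlas, modules = make_atlas(spec)
    basis, parcels = structural_basis(truth, mask, atlas)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 7)
    n_modules = len(truth.module_patterns)
    n_ft = sum(1 for l in truth.pattern_parcels
               if truth.module_of_parcel[l] == MODULE_NAMES[0])
    gmp0_struct = np.full(mask.n_voxels, np.log(0.6))
    rows, mats, mod_list, parcel_list = [], [], [], []
    offset = 0
    for site in spec.sites:
        for group, n in (("patient", spec.n_patients), ("control", spec.n_controls)):
            if n == 0:
                continue
            if module_loadings is not None:
                alpha_mod = np.asarray(module_loadings[offset:offset + n], float)
            else:
                alpha_mod = _draw_module_loadings(n, group, site, truth, rng, n_modules)
            offset += n
            xi = _draw_module_loadings(n, group, site,
                                       truth.replace(loading_mean={group: 0.0}),
                                       rng, n_modules)
            beta_mod = att * alpha_mod + np.sqrt(1.0 - att**2) * xi
            beta_parcel = _parcel_loadings(beta_mod, group, truth, rng, n_ft,
                                           len(truth.pattern_parcels))
            # extra structural-only parcels load on the frontotemporal module
            n_extra = len(parcels) - beta_parcel.shape[1]
            if n_extra:
                beta_parcel = np.column_stack(
                    [beta_parcel] + [beta_mod[:, 0]] * n_extra)
            mats.append(_synthesize(beta_parcel, truth, rng, basis=basis,
                                    gmp0=gmp0_struct))
            for i in range(n):
                rows.append({
                    "subject_id": f"{site}-{group[:3]}-{i:03d}",
                    "group": group, "site": site, "scan_date": "2020-06-01",
                    "mmse": np.nan, "duration_years": np.nan,
                })
            mod_list.append(beta_mod)
            parcel_list.append(beta_parcel)
    return SimulatedCohort(
        raw=np.vstack(mats), metadata=pd.DataFrame(rows),
        module_loadings=np.vstack(mod_list), parcel_loadings=np.vstack(parcel_list),
        truth=truth, mask=mask, atlas=atlas,
    )


# ---------------------------------------------------------------------------
# overlapping reference pattern (DMN-like input for comparisons)

def overlapping_pattern(truth: SyntheticTruth, mask: AnalysisMask,
                        atlas: AtlasParcellation, shared_fraction: float = 0.5,
                        n_exclusive: int = 3) -> tuple[np.ndarray, list[int]]:
    """A second zero-mean unit-norm map overlapping the planted pattern.

    Takes the first ``shared_fraction`` of each module's parcels with the
    planted polarity, plus ``n_exclusive`` otherwise-unused parcels, so
    overlap-decomposition ground truth is exact.  Returns the map and its
    support labels.
    """
    lab = mask.flatten(atlas.labels).astype(int)
    ft = [l for l in truth.pattern_parcels
          if truth.module_of_parcel[l] == MODULE_NAMES[0]]
    po = [l for l in truth.pattern_parcels
          if truth.module_of_parcel[l] == MODULE_NAMES[1]]
    n_ft = max(1, int(round(shared_fraction * len(ft))))
    n_po = max(1, int(round(shared_fraction * len(po))))
    shared = ft[:n_ft] + po[:n_po]
    null_parcels = [l for l, m in truth.module_of_parcel.items()
                    if m is None and l not in truth.structural_extra_parcels]
    exclusive = null_parcels[:n_exclusive]
    raw = np.zeros(mask.n_voxels)
    for l in ft[:n_ft]:
        raw[lab == l] = -1.0
    for l in po[:n_po]:
        raw[lab == l] = +1.0
    for k, l in enumerate(exclusive):
        raw[lab == l] = -1.0 if k % 2 == 0 else 1.0
    raw -= raw.mean()
    raw /= np.linalg.norm(raw)
    return raw, sorted(shared + exclusive)
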