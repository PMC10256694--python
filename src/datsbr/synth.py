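"""Synthetic cohorts and imaging phantoms for the DAT-PET pipeline.

Two generators live here:

``simulate_cohort``
    Draws a subject table (diagnostic group, demographics, core clinical
    features, motor/cognitive scores, medication flags) together with
    age-dependent regional specific binding ratios (SBR). Regional SBRs
    follow the normative linear-in-age model used downstream,

        SBR_r = intercept_r + slope_r * age + sd_r * (eps_r + deficit_{r,g})

    where ``eps_r`` is a unit-variance Gaussian sharing a single latent
    severity factor across regions and ``deficit_{r,g}`` is the group-mean
    shift expressed in normative z units (0 for healthy controls by
    construction). Clinical flags are Bernoulli draws from logistic links
    on the true regional z-scores; continuous scores are linear in the
    z-scores, age and education plus Gaussian noise.

``simulate_phantom``
    Builds a small 3D PET uptake phantom with integer label masks (left and
    right caudate/putamen, left and right substantia nigra, an occipital
    white-matter reference block), plus per-subject modulated gray-matter
    density maps carrying an optional atrophy effect proportional to each
    subject's nigral z-score inside a designated cluster.

The default cohort calibration (:func:`reference_cohort_config`) reproduces
the group structure of a representative single-centre DLB-spectrum cohort:
40 healthy controls, 36 patients with mild cognitive impairment with Lewy
bodies (MCI-LB) and 51 with dementia with Lewy bodies (DLB), with the
substantia nigra the most affected region in z units.

All randomness flows from the single ``seed`` carried by the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import VolumeImage, LabelVolume
from .regions import REGIONS, STRIATAL_REGIONS, GROUPS, validate_regions

__all__ = [
    "NormativeParams",
    "FlagLink",
    "ScoreLink",
    "CohortConfig",
    "reference_cohort_config",
    "null_cohort_config",
    "simulate_cohort",
    "RoiBox",
    "PhantomConfig",
    "reference_phantom_config",
    "simulate_phantom",
]


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormativeParams:
    """True normative line for one region: SBR = intercept + slope*age + sd*eps."""

    intercept: float  # SBR units at age 0
    slope: float      # SBR units per year
    resid_sd: float   # SBR units

    def __post_init__(self):
        if not self.resid_sd > 0:
            raise ValueError("residual SD must be > 0")


@dataclass(frozen=True)
class FlagLink:
    """Logistic link from true regional z-scores to a binary feature.

    ``P(flag) = expit(intercept_g + sum_r coef_r * z_r)`` with a per-group
    intercept. Group intercepts are needed because the core clinical
    features are essentially absent in healthy controls while only weakly
    graded by zSBR within patients; slopes carry the zSBR dependence.
    """

    name: str
    intercepts: Mapping[str, float]
    z_coefs: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreLink:
    """Linear link from z-scores, age and education to a continuous score."""

    name: str
    base: Mapping[str, float]           # per-group level at age 70, 10 y education
    z_coefs: Mapping[str, float] = field(default_factory=dict)
    age_coef: float = 0.0               # per year, centred at 70
    edu_coef: float = 0.0               # per year of education, centred at 10
    noise_sd: float = 1.0
    lo: float | None = None
    hi: float | None = None


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a simulated DLB-spectrum cohort."""

    n_hc: int
    n_mci: int
    n_dlb: int
    age_range: Mapping[str, tuple[float, float]]
    normative_params: Mapping[str, NormativeParams]
    group_deficit: Mapping[str, Mapping[str, float]]
    clinical_link: Sequence[FlagLink] = ()
    score_link: Sequence[ScoreLink] = ()
    latent_share: float = 0.5   # fraction of eps variance from the shared factor
    asym_sd: float = 0.3        # hemispheric asymmetry SD, z units
    education_mean: float = 11.0
    education_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_hc, self.n_mci, self.n_dlb)
        if any(c < 0 for c in counts):
            raise ValueError("group counts must be >= 0")
        if all(c <= 0 for c in counts):
            raise ValueError("at least one group must have positive count")
        validate_regions(self.normative_params)
        for g in GROUPS:
            if g not in self.age_range:
                raise ValueError(f"missing age range for group {g}")
            lo, hi = self.age_range[g]
            if not lo <= hi:
                raise ValueError(f"invalid age range for group {g}")
        for g, deficits in self.group_deficit.items():
            missing = set(REGIONS) - set(deficits)
            if missing:
                raise ValueError(f"group {g} missing deficit for {missing}")
        hc = self.group_deficit.get("HC", {})
        if any(v != 0 for v in hc.values()):
            raise ValueError("HC deficits must all be 0")
        if not 0 <= self.latent_share <= 1:
            raise ValueError("latent_share must lie in [0, 1]")


def reference_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Calibrated default cohort: 40 HC / 36 MCI-LB / 51 DLB.

    Normative lines are chosen so that at the HC mean age (~65 y) the group
    mean SBRs are AP 3.5, PP 3.0, AC 3.1, PC 2.0, SN 1.1 and the HC SBR
    standard deviations (age spread plus residual) match the published
    summaries (0.6/0.5/0.6/0.5/0.2). Group deficits are the patient-group
    mean zSBRs of the same cohort, with the substantia nigra the most
    affected region (MCI-LB -1.5 z, DLB -2.2 z).
    """
    # Slopes and residual SDs are solved jointly so that (a) the HC group
    # SD (age spread + residual) matches the published SD and (b) the DLB
    # group mean SBR equals the HC-predicted mean at the DLB mean age plus
    # deficit * residual SD. Intercepts anchor the HC mean at age 65.2.
    norm = {
        "AP": NormativeParams(3.5 + 0.0205 * 65.2, -0.0205, 0.569),
        "PP": NormativeParams(3.0 + 0.0290 * 65.2, -0.0290, 0.424),
        "AC": NormativeParams(3.1 + 0.0258 * 65.2, -0.0258, 0.550),
        "PC": NormativeParams(2.0 + 0.0314 * 65.2, -0.0314, 0.410),
        "SN": NormativeParams(1.1 + 0.0120 * 65.2, -0.0120, 0.205),
    }
    deficits = {
        "HC": {r: 0.0 for r in REGIONS},
        "MCI-LB": {"AP": -0.9, "PP": -0.8, "AC": -1.1, "PC": -0.8, "SN": -1.5},
        "DLB": {"AP": -1.5, "PP": -1.5, "AC": -1.6, "PC": -1.0, "SN": -2.2},
    }
    # Uniform age ranges with the published group means and SDs
    # (range = mean +- sqrt(3)*SD).
    ages = {
        "HC": (49.1, 81.3),
        "MCI-LB": (63.4, 89.4),
        "DLB": (67.0, 88.2),
    }
    flags = (
        FlagLink("RBD", {"HC": -6.0, "MCI-LB": 1.25, "DLB": 0.28}),
        FlagLink("CF", {"HC": -6.0, "MCI-LB": -0.69, "DLB": 0.12}),
        FlagLink("VH", {"HC": -6.0, "MCI-LB": -2.1, "DLB": -1.0},
                 {"SN": -0.45}),
        FlagLink("parkinsonism", {"HC": -6.0, "MCI-LB": 4.0, "DLB": 3.0},
                 {"SN": -0.3}),
        FlagLink("SSRI", {"HC": -6.0, "MCI-LB": -1.43, "DLB": -0.97}),
        FlagLink("antipsychotics", {"HC": -6.0, "MCI-LB": -2.08, "DLB": -1.68}),
        FlagLink("levodopa", {"HC": -6.0, "MCI-LB": -2.4, "DLB": -1.84}),
    )
    scores = (
        ScoreLink("UPDRS_III", {"HC": 1.4, "MCI-LB": 25.5, "DLB": 26.0},
                  {"SN": -3.0}, noise_sd=6.0, lo=0.0, hi=108.0),
        ScoreLink("K_MMSE", {"HC": 29.0, "MCI-LB": 25.5, "DLB": 22.0},
                  {"SN": 1.0}, age_coef=-0.05, edu_coef=0.15,
                  noise_sd=2.0, lo=0.0, hi=30.0),
        ScoreLink("CDR_SOB", {"HC": 0.1, "MCI-LB": 0.6, "DLB": 4.5},
                  {"SN": -0.7}, noise_sd=1.0, lo=0.0, hi=18.0),
        ScoreLink("K_BNT", {"HC": 0.5, "MCI-LB": -0.6, "DLB": -1.4},
                  {"AP": 0.15, "AC": 0.2, "SN": 0.1},
                  edu_coef=0.05, noise_sd=0.8),
        ScoreLink("RCFT_copy", {"HC": 0.4, "MCI-LB": -0.5, "DLB": -1.5},
                  {"AP": 0.15, "AC": 0.15, "SN": 0.15},
                  noise_sd=0.9),
        ScoreLink("SVLT_delayed", {"HC": 0.5, "MCI-LB": -1.0, "DLB": -1.8},
                  {"AC": 0.15, "SN": 0.2}, noise_sd=0.9),
        ScoreLink("COWAT_semantic", {"HC": 0.3, "MCI-LB": -0.8, "DLB": -1.5},
                  {"AP": 0.15, "AC": 0.15, "SN": 0.18},
                  edu_coef=0.03, noise_sd=0.9),
        ScoreLink("Stroop_color", {"HC": 0.3, "MCI-LB": -0.9, "DLB": -1.7},
                  {"AP": 0.18, "SN": 0.18}, noise_sd=0.9),
        ScoreLink("digit_span_backward", {"HC": 0.2, "MCI-LB": -0.4, "DLB": -0.9},
                  {}, edu_coef=0.05, noise_sd=1.0),
    )
    base = dict(
        n_hc=40, n_mci=36, n_dlb=51,
        age_range=ages, normative_params=norm, group_deficit=deficits,
        clinical_link=flags, score_link=scores, seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def null_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Global-null cohort: no deficits, no zSBR links (calibration checks)."""
    cfg = reference_cohort_config(seed=seed)
    deficits = {g: {r: 0.0 for r in REGIONS} for g in GROUPS}
    flags = tuple(FlagLink(f.name, dict(f.intercepts), {})
                  for f in cfg.clinical_link)
    scores = tuple(
        ScoreLink(s.name, dict(s.base), {}, s.age_coef, s.edu_coef,
                  s.noise_sd, s.lo, s.hi)
        for s in cfg.score_link
    )
    base = dict(
        n_hc=cfg.n_hc, n_mci=cfg.n_mci, n_dlb=cfg.n_dlb,
        age_range=cfg.age_range, normative_params=cfg.normative_params,
        group_deficit=deficits, clinical_link=flags, score_link=scores,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a subject table and a regional SBR table.

    Returns
    -------
    subjects : DataFrame
        One row per subject: ``subject_id, group, age, sex, education``,
        one 0/1 column per clinical/medication flag and one column per
        continuous score.
    sbr : DataFrame
        One row per subject: ``subject_id, group, age`` plus bilateral SBR
        columns (one per region) and per-hemisphere columns ``{region}_L``
        and ``{region}_R``.

    Deterministic for a fixed config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = (["HC"] * config.n_hc + ["MCI-LB"] * config.n_mci
              + ["DLB"] * config.n_dlb)
    n = len(groups)
    group_arr = np.asarray(groups)

    age = np.empty(n)
    for g in GROUPS:
        sel = group_arr == g
        lo, hi = config.age_range[g]
        age[sel] = rng.uniform(lo, hi, sel.sum())
    sex = rng.integers(0, 2, n)  # 0 = male, 1 = female
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, n), 0, None)

    # shared latent severity factor + independent per-region noise
    rho = config.latent_share
    latent = rng.normal(size=n)
    z_true = {}
    sbr_cols = {}
    for r in REGIONS:
        p = config.normative_params[r]
        eps = np.sqrt(rho) * latent + np.sqrt(1 - rho) * rng.normal(size=n)
        deficit = np.array([config.group_deficit[g][r] for g in group_arr])
        z = eps + deficit
        z_true[r] = z
        sbr = p.intercept + p.slope * age + p.resid_sd * z
        sbr_cols[r] = sbr
        # hemispheric split around the bilateral value
        delta = rng.normal(0.0, config.asym_sd, n) * p.resid_sd
        sbr_cols[f"{r}_L"] = sbr + delta
        sbr_cols[f"{r}_R"] = sbr - delta

    subjects = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "group": group_arr,
        "age": age,
        "sex": sex,
        "education": education,
    })

    for link in config.clinical_link:
        eta = np.array([link.intercepts[g] for g in group_arr], dtype=float)
        for r, c in link.z_coefs.items():
            eta += c * z_true[r]
        subjects[link.name] = (rng.uniform(size=n) < _sigmoid(eta)).astype(int)

    for link in config.score_link:
        val = np.array([link.base[g] for g in group_arr], dtype=float)
        val += link.age_coef * (age - 70.0)
        val += link.edu_coef * (education - 10.0)
        for r, c in link.z_coefs.items():
            val += c * z_true[r]
        val += rng.normal(0.0, link.noise_sd, n)
        if link.lo is not None or link.hi is not None:
            val = np.clip(val, link.lo, link.hi)
        subjects[link.name] = val

    sbr = pd.DataFrame({"subject_id": subjects["subject_id"],
                        "group": group_arr, "age": age})
    for r in REGIONS:
        sbr[r] = sbr_cols[r]
    for r in REGIONS:
        sbr[f"{r}_L"] = sbr_cols[f"{r}_L"]
        sbr[f"{r}_R"] = sbr_cols[f"{r}_R"]
    return subjects, sbr


# ---------------------------------------------------------------------------
# phantom configuration and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box ROI in voxel coordinates (inclusive start, exclusive stop)."""

    label: int
    region: str
    side: str  # "L", "R" or "NA"
    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def slices(self):
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and signal model for the PET/GM phantom."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0  # mm, isotropic
    rois: Sequence[RoiBox] = ()
    true_ratio: Mapping[int, float] = field(default_factory=dict)
    reference_label: int = 99
    reference_level: float = 10.0   # arbitrary uptake units
    noise_sd: float = 0.0           # uptake units
    gm_baseline: float = 0.5        # GM probability/density
    gm_noise_sd: float = 0.02
    gm_effect: float = 0.0          # GM density decrease per unit SN z-score
    gm_cluster: tuple[tuple[int, int], ...] | None = None  # box per axis
    smooth_fwhm: float = 0.0        # mm, applied to GM maps
    seed: int = 0

    def validate(self) -> None:
        occupancy = np.zeros(self.shape, dtype=int)
        ref_found = False
        for roi in self.rois:
            for a, b, s in zip(roi.start, roi.stop, self.shape):
                if not (0 <= a < b <= s):
                    raise ValueError(f"ROI {roi.region} does not fit in grid")
            occupancy[roi.slices()] += 1
            if roi.label == self.reference_label:
                ref_found = True
        if (occupancy > 1).any():
            raise ValueError("overlapping ROI definitions")
        if not ref_found:
            raise ValueError("reference ROI missing from geometry")
        for lbl, ratio in self.true_ratio.items():
            if not ratio > 0:
                raise ValueError(f"true ratio for label {lbl} must be > 0")


def reference_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Default phantom: bilateral caudate/putamen/SN boxes + occipital WM block.

    Uptake ratios decrease from anterior putamen to substantia nigra in
    rough proportion to healthy-control SBR levels; the reference block has
    ratio 1 by construction.
    """
    rois = (
        # caudate: anterior-posterior elongated boxes (y axis), one per side
        RoiBox(1, "caudate", "L", (3, 8, 9), (7, 18, 13)),
        RoiBox(2, "caudate", "R", (17, 8, 9), (21, 18, 13)),
        # putamen
        RoiBox(3, "putamen", "L", (3, 6, 3), (7, 16, 7)),
        RoiBox(4, "putamen", "R", (17, 6, 3), (21, 16, 7)),
        # substantia nigra: small boxes, no erosion downstream
        RoiBox(5, "SN", "L", (8, 9, 15), (11, 12, 18)),
        RoiBox(6, "SN", "R", (13, 9, 15), (16, 12, 18)),
        # occipital white matter reference
        RoiBox(99, "occipital_wm", "NA", (9, 0, 3), (15, 4, 9)),
    )
    ratios = {1: 3.1, 2: 3.1, 3: 3.2, 4: 3.2, 5: 1.1, 6: 1.1, 99: 1.0}
    base = dict(rois=rois, true_ratio=ratios, seed=seed)
    base.update(overrides)
    return PhantomConfig(**base)


def small_phantom_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Compact 16^3 variant of the reference phantom (calibration runs)."""
    rois = (
        RoiBox(1, "caudate", "L", (2, 5, 6), (5, 12, 9)),
        RoiBox(2, "caudate", "R", (11, 5, 6), (14, 12, 9)),
        RoiBox(3, "putamen", "L", (2, 4, 2), (5, 11, 5)),
        RoiBox(4, "putamen", "R", (11, 4, 2), (14, 11, 5)),
        RoiBox(5, "SN", "L", (5, 6, 10), (8, 9, 13)),
        RoiBox(6, "SN", "R", (9, 6, 10), (12, 9, 13)),
        RoiBox(99, "occipital_wm", "NA", (6, 0, 2), (10, 3, 6)),
    )
    ratios = {1: 3.1, 2: 3.1, 3: 3.2, 4: 3.2, 5: 1.1, 6: 1.1, 99: 1.0}
    base = dict(shape=(16, 16, 16), rois=rois, true_ratio=ratios, seed=seed)
    base.update(overrides)
    return PhantomConfig(**base)


def simulate_phantom(
    config: PhantomConfig,
    sn_z: Sequence[float] | None = None,
) -> tuple[VolumeImage, LabelVolume, list[VolumeImage], np.ndarray]:
    """Build the PET phantom, its label volume, GM maps and ICVs.

    Parameters
    ----------
    config : PhantomConfig
    sn_z : sequence of float, optional
        Per-subject nigral z-scores driving the planted GM atrophy effect.
        Defaults to a single subject with z = 0.

    Returns
    -------
    pet : VolumeImage
    labels : LabelVolume
    gm_maps : list of VolumeImage, one per subject
    icv : ndarray, mm^3 per subject
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if sn_z is None:
        sn_z = np.zeros(1)
    sn_z = np.asarray(sn_z, dtype=float)

    affine = np.diag([config.voxel_size] * 3 + [1.0])
    label_arr = np.zeros(config.shape, dtype=np.int16)
    label_dict = {}
    for roi in config.rois:
        label_arr[roi.slices()] = roi.label
        label_dict[roi.label] = {"region": roi.region, "side": roi.side}

    pet_arr = np.full(config.shape, config.reference_level, dtype=float)
    for roi in config.rois:
        ratio = config.true_ratio.get(roi.label, 1.0)
        pet_arr[roi.slices()] = config.reference_level * ratio
    if config.noise_sd > 0:
        pet_arr = pet_arr + rng.normal(0.0, config.noise_sd, config.shape)

    pet = VolumeImage(pet_arr, affine)
    labels = LabelVolume(label_arr, affine, label_dict)

    cluster = np.zeros(config.shape, dtype=bool)
    if config.gm_cluster is not None:
        sl = tuple(slice(a, b) for a, b in config.gm_cluster)
        cluster[sl] = True

    from scipy import ndimage  # local import keeps module load light
    sigma_vox = (config.smooth_fwhm / 2.3548) / config.voxel_size
    vox_vol = config.voxel_size ** 3

    gm_maps = []
    icv = np.empty(len(sn_z))
    for i, z in enumerate(sn_z):
        gm = np.full(config.shape, config.gm_baseline, dtype=float)
        gm[cluster] -= config.gm_effect * z
        if config.gm_noise_sd > 0:
            gm = gm + rng.normal(0.0, config.gm_noise_sd, config.shape)
        if sigma_vox > 0:
            gm = ndimage.gaussian_filter(gm, sigma_vox, mode="nearest")
        gm = np.clip(gm, 0.0, 1.0)
        gm_maps.append(VolumeImage(gm, affine))
        # ICV = simulated GM + (WM + CSF filling the rest of the grid)
        gm_vol = gm.sum() * vox_vol
        other = (1.0 - config.gm_baseline) * gm.size * vox_vol
        icv[i] = gm_vol + other * (1.0 + 0.02 * rng.normal())
    return pet, labels, gm_maps, icv


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def cohort_config_to_json(config: CohortConfig, path) -> None:
    """Persist a cohort config (seed included) as JSON."""
    d = asdict(config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, default=list)


def write_cohort_csv(subjects: pd.DataFrame, sbr: pd.DataFrame,
                     subjects_path, sbr_path) -> None:
    subjects.to_csv(subjects_path, index=False)
    sbr.to_csv(sbr_path, index=False)
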