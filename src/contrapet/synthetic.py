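"""Synthetic study generator.

Emulates the statistical structure of a contralateral TSPO-PET study so the
full pipeline can be exercised with known ground truth:

* a mirrored Voronoi parcellation of a brain-shaped mask (default 123
  regions per hemisphere, 246 total) with 15 anatomo-functional groups;
* per-subject static SUV volumes in which the glioblastoma group carries a
  graded contralateral signal elevation (global default +9%, strongest in
  the mesio-temporal group at about +14%), a unilateral tumor ellipsoid
  with elevated uptake, and matched MRI abnormality maps for threshold
  segmentation;
* a positive latent coupling between tumor uptake/volume and contralateral
  elevation;
* proportional-hazards survival linked to the contralateral signal
  (default hazard ratio 2.18 per SD, 20% non-informative censoring);
* CD11b-sorted pellet activities with myeloid-specific per-cell uptake
  fold changes (defaults 2.8 tumor vs sham, 4.2 tumor vs healthy) and a
  null myeloid-depleted fraction.

All randomness flows from a single mandatory master seed, expanded by a
counter-based scheme (``SeedSequence(seed, spawn_key=...)``) so every
subject is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .kinetics import KineticParams, feng_input, simulate_1tc
from .regional import GROUP15_NAMES, AtlasParcellation, SubjectRecord
from .scradiotracing import F18_HALF_LIFE_MIN, CellPellet
from .volumes import DynamicPETVolume, SphericalVOI

__all__ = [
    "CohortConfig",
    "SimulatedSubject",
    "Cohort",
    "make_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_survival",
    "simulate_pellets",
    "simulate_dynamic_subject",
]

# relative contralateral effect profile across the 15 groups (percent);
# rescaled per atlas so the voxel-weighted hemisphere mean equals the
# configured global effect while keeping the mesio-temporal predominance
DEFAULT_REGIONAL_PROFILE = {
    "mesio-temporal": 14.0,
    "orbitofrontal": 12.0,
    "superior-temporal": 12.0,
    "mid-temporal": 12.0,
    "inferior-temporal": 10.0,
    "limbic": 9.0,
    "insula": 9.0,
    "superior-frontal": 8.0,
    "mid-frontal": 8.0,
    "inferior-frontal": 8.0,
    "motor area": 8.0,
    "parietal": 7.0,
    "occipital": 7.0,
    "basal ganglia": 7.0,
    "thalamus": 7.0,
}

# default small-animal emission frame scheme over 0-60 min
DEFAULT_FRAME_SCHEME = (
    [(i * 10 / 60, (i + 1) * 10 / 60) for i in range(6)]
    + [(1 + i * 0.5, 1 + (i + 1) * 0.5) for i in range(6)]
    + [(4 + i * 1.0, 4 + (i + 1) * 1.0) for i in range(6)]
    + [(10 + i * 5.0, 10 + (i + 1) * 5.0) for i in range(10)]
)


@dataclass
class CohortConfig:
    """All generator knobs; the seed is mandatory."""

    seed: int
    grid_size: int = 64
    voxel_mm: float = 3.0
    n_gbm: int = 41
    n_idh: int = 7
    n_hc: int = 20
    regions_per_hemisphere: int = 123
    global_contralateral_effect: float = 0.09  # GBM vs HC, fractional
    regional_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_REGIONAL_PROFILE)
    )
    region_baseline_sd: float = 0.05
    between_subject_sd: float = 0.10  # lognormal sigma of the global factor
    region_noise_sd: float = 0.05  # per-subject regional biological variability
    voxel_noise_sd: float = 0.05  # multiplicative Gaussian per voxel
    coupling: float = 0.5  # contralateral effect <- tumor latent severity
    # tumor geometry / uptake
    tumor_axes_mm: tuple = (12.0, 10.0, 10.0)
    tumor_uptake_multiplier: float = 3.0
    # survival model
    survival_baseline_rate: float = float(np.log(2) / 12.0)  # per month
    survival_hr_per_sd: float = 2.18
    censoring_fraction: float = 0.20
    # pellet model
    pellet_fold_tumor_vs_sham: float = 2.8
    pellet_fold_tumor_vs_healthy: float = 4.2
    pellet_cv: float = 0.15
    pellet_n: dict = field(
        default_factory=lambda: {"tumor": 13, "sham": 14, "healthy": 8}
    )
    pellet_base_per_cell_Bq: float = 0.002  # sham myeloid per-cell activity
    pellet_depleted_per_cell_Bq: float = 0.0004
    pellet_sort_loss_fraction: float = 0.10
    pellet_purity_mean: float = 0.90
    pellet_measurement_time_min: float = 75.0
    mouse_dose_Bq: float = 13.8e6
    mouse_weight_g: float = 20.0
    # dynamic (mouse) phantom
    frame_scheme: list = field(default_factory=lambda: list(DEFAULT_FRAME_SCHEME))
    k2_reference: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for name in ("n_gbm", "n_idh", "n_hc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.global_contralateral_effect <= -1:
            raise ValueError("effects must exceed -100%")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring fraction must lie in [0, 1)")
        if self.pellet_cv < 0:
            raise ValueError("pellet CV must be non-negative")
        if self.grid_size % 2:
            raise ValueError("grid size must be even (declared symmetric grid)")

    @classmethod
    def fast(cls, seed: int, **overrides) -> "CohortConfig":
        """Reduced profile: 32^3 grid, same statistical structure."""
        kw = dict(grid_size=32)
        kw.update(overrides)
        return cls(seed=seed, **kw)

    def rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=spawn_key)
        )


def _affine(voxel_mm: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = voxel_mm
    return a


def _brain_mask(n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    ax = 0.46 * n
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    return ((ii - c) / ax) ** 2 + ((jj - c) / (0.40 * n)) ** 2 + (
        (kk - c) / (0.40 * n)
    ) ** 2 <= 1.0


def make_atlas(config: CohortConfig) -> AtlasParcellation:
    """Mirrored Voronoi parcellation of an ellipsoidal brain mask.

    Seeds are drawn in the left half and mirrored; each left voxel joins its
    nearest seed, the right half is the exact mirror image, so flipping the
    label volume equals relabeling by mirror_id. The first 15 seeds anchor
    the 15 anatomo-functional groups; every region joins its nearest anchor.
    """
    R = config.regions_per_hemisphere
    if R < 15:
        raise ValueError("need at least 15 regions per hemisphere")
    n = config.grid_size
    rng = config.rng(0)
    mask = _brain_mask(n)
    left = np.array(np.nonzero(mask & (np.arange(n)[:, None, None] < n // 2))).T
    if len(left) < R:
        raise ValueError(f"region count {R} exceeds left-hemisphere voxel budget")
    sel = rng.choice(len(left), size=R, replace=False)
    seeds = left[sel].astype(float)
    tree = cKDTree(seeds)
    _, nearest = tree.query(left)
    labels = np.zeros((n, n, n), dtype=np.int32)
    labels[tuple(left.T)] = nearest + 1
    # mirror to the right hemisphere: x -> n-1-x, label -> label + R
    flipped = labels[::-1].copy()
    right_half = np.arange(n)[:, None, None] >= n // 2
    labels[right_half & (flipped > 0)] = (flipped + R)[right_half & (flipped > 0)]
    # 15-group membership via anchor seeds
    anchors = seeds[:15]
    _, grp = cKDTree(anchors).query(seeds)
    rows = []
    for i in range(R):
        g = GROUP15_NAMES[int(grp[i])]
        rows.append(dict(id=i + 1, name=f"L{i + 1}", hemisphere="left",
                         mirror_id=i + 1 + R, group15=g))
        rows.append(dict(id=i + 1 + R, name=f"R{i + 1}", hemisphere="right",
                         mirror_id=i + 1, group15=g))
    return AtlasParcellation(labels, pd.DataFrame(rows))


def _scaled_effects(config: CohortConfig, atlas: AtlasParcellation) -> dict:
    """Per-group15 fractional effects, rescaled so the voxel-weighted mean
    over the contralateral (right) hemisphere equals the global effect."""
    prof = config.regional_profile
    right = atlas.regions[atlas.regions["hemisphere"] == "right"]
    w = np.array([atlas.voxel_counts.get(int(i), 0) for i in right["id"]], float)
    p = np.array([prof[g] for g in right["group15"]], float)
    mean_p = float(np.average(p, weights=w))
    if mean_p == 0:
        return {g: 0.0 for g in prof}
    scale = config.global_contralateral_effect / (mean_p / 100.0)
    return {g: scale * v / 100.0 for g, v in prof.items()}


def _pons_voi(config: CohortConfig) -> SphericalVOI:
    n, vx = config.grid_size, config.voxel_mm
    c = (n - 1) / 2.0
    # low central position, inside the brain mask, straddling the midline
    center = (c * vx, c * vx, (c - 0.25 * n) * vx)
    return SphericalVOI(center, diameter_mm=max(3 * vx, 10.0), label="pons")


@dataclass
class SimulatedSubject:
    record: SubjectRecord
    suv: DynamicPETVolume | None
    mri: dict
    truth: dict


def _tumor_mask(config: CohortConfig, center_idx, axes_scale: float) -> np.ndarray:
    n, vx = config.grid_size, config.voxel_mm
    ax = np.array(config.tumor_axes_mm) * axes_scale / vx
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    d = (
        ((ii - center_idx[0]) / ax[0]) ** 2
        + ((jj - center_idx[1]) / ax[1]) ** 2
        + ((kk - center_idx[2]) / ax[2]) ** 2
    )
    return d <= 1.0


def simulate_subject(
    config: CohortConfig,
    atlas: AtlasParcellation,
    baselines: np.ndarray,
    group: str,
    subject_index: int,
    keep_volume: bool = True,
) -> SimulatedSubject:
    """One subject: static SUV volume (canonical space, flipped if the drawn
    lesion side is right), MRI abnormality maps for glioma subjects, the
    metadata record, and a truth record of every latent draw."""
    rng = config.rng(1, subject_index)
    n, vx = config.grid_size, config.voxel_mm
    R = config.regions_per_hemisphere
    effects = _scaled_effects(config, atlas)
    sid = f"sub-{group.lower().replace('-', '')}{subject_index:03d}"

    factor = float(np.exp(rng.normal(0.0, config.between_subject_sd)))
    global_scale = float(np.exp(rng.normal(0.0, 0.15)))  # dose/scanner factor
    zeta = float(rng.normal())  # tumor uptake severity latent
    eta = float(rng.normal())  # tumor volume latent

    grp_of = dict(zip(atlas.regions["id"], atlas.regions["group15"]))
    targets = np.zeros(2 * R + 1)
    effect_applied = np.zeros(2 * R + 1)
    region_noise = np.exp(rng.normal(0.0, config.region_noise_sd, 2 * R + 1))
    for rid in range(1, 2 * R + 1):
        t = baselines[rid] * region_noise[rid]
        if group == "GBM" and rid > R:  # right hemisphere = contralateral
            e = effects[grp_of[rid]]
            m = 1.0 + e * (1.0 + config.coupling * zeta + 0.5 * config.coupling * eta)
            t *= max(m, 0.01)
            effect_applied[rid] = m - 1.0
        targets[rid] = t

    lesion_side = None
    if group != "HC":
        lesion_side = "left" if rng.random() < 0.5 else "right"

    vol = None
    mri: dict = {}
    tumor_truth: dict = {}
    data = targets[atlas.labels] * factor
    pons = _pons_voi(config)
    if group != "HC":
        # the study excluded bi-hemispheric lesions: emulate that selection
        # by redrawing the tumor geometry until it stays unilateral
        for attempt in range(50):
            axes_scale = float(np.exp(0.15 * eta))
            center = np.array([0.27 * n, 0.5 * n, 0.5 * n]) + rng.normal(
                0, 0.015 * n, 3
            )
            tmask = _tumor_mask(config, center, axes_scale)
            if not tmask[n // 2:].any():
                break
            eta = float(rng.normal())
        else:
            raise ValueError(
                "tumor crosses the midline; bi-hemispheric lesions are "
                "excluded from the study design"
            )
        uptake = config.tumor_uptake_multiplier * (1.0 + 0.2 * zeta)
        uptake = max(uptake, 1.2)
        data[tmask] = float(np.mean(baselines[1:])) * factor * uptake
        tumor_truth = {
            "center_idx": center.tolist(),
            "axes_scale": axes_scale,
            "uptake_multiplier": uptake,
            "n_voxels": int(tmask.sum()),
            "volume_mL": float(tmask.sum()) * (vx**3) / 1000.0,
            "seed_idx": [int(round(c)) for c in center],
        }
        # MRI-derived abnormality maps (already background-normalized scale)
        noise = lambda sd: 1.0 + rng.normal(0.0, sd, size=data.shape)
        ce = noise(0.04)
        ce[tmask] = 2.2
        nat = noise(0.02)
        t2 = noise(0.05)
        t2mask = _tumor_mask(config, center, axes_scale * 1.3)
        t2[t2mask] = 1.8
        mri = {"CE-T1": ce, "native-T1": nat, "T2": t2}
    # pons keeps the baseline level: the biological factor applies to brain
    # tissue but the reference region stays stable across subjects
    tmp = DynamicPETVolume(data, _affine(vx), units="arb")
    pons_mask = pons.rasterize(tmp)
    data[pons_mask] = 1.0
    data = data * (1.0 + rng.normal(0.0, config.voxel_noise_sd, size=data.shape))
    data *= global_scale  # cancelled by SUVr normalization
    if lesion_side == "right":
        data = data[::-1].copy()
        mri = {k: v[::-1].copy() for k, v in mri.items()}

    ages = {"GBM": (62, 10), "IDHmut-A2": (40, 8), "HC": (60, 8)}
    mu, sd = ages[group]
    seizure_dx = bool(rng.random() < 0.5) if group == "GBM" else None
    record = SubjectRecord(
        id=sid,
        group=group,
        age=float(np.clip(rng.normal(mu, sd), 18, 90)),
        sex="F" if rng.random() < 0.5 else "M",
        snp_binding=str(rng.choice(["HAB", "MAB", "LAB"], p=[0.5, 0.4, 0.1])),
        lesion_side=lesion_side,
        seizure_at_dx=seizure_dx,
        seizure_persisting=(bool(rng.random() < 0.4) if seizure_dx else
                            (False if seizure_dx is not None else None)),
        radiotherapy=bool(rng.random() < 0.8) if group == "GBM" else False,
        chemotherapy=bool(rng.random() < 0.8) if group == "GBM" else False,
        resection=bool(rng.random() < 0.5) if group != "HC" else False,
        glucocorticoid_at_pet=bool(rng.random() < 0.3) if group == "GBM" else False,
        mgmt_methylated=bool(rng.random() < 0.4) if group == "GBM" else None,
        injected_dose_Bq=float(rng.normal(180e6, 15e6)),
        body_weight_g=float(np.clip(rng.normal(75e3, 12e3), 45e3, 120e3)),
    )
    # truth contralateral level: voxel-weighted mean of right-hemisphere
    # region targets relative to pons (=1)
    right_ids = np.arange(R + 1, 2 * R + 1)
    w = np.array([atlas.voxel_counts.get(int(i), 0) for i in right_ids], float)
    contra_truth = float(np.average(targets[right_ids], weights=w)) * factor
    truth = {
        "subject": sid,
        "group": group,
        "factor": factor,
        "global_scale": global_scale,
        "zeta": zeta,
        "eta": eta,
        "lesion_side": lesion_side,
        "region_targets": (targets * factor).tolist(),
        "contralateral_truth": contra_truth,
        "tumor": tumor_truth,
        "effects": effects,
    }
    if keep_volume:
        vol = DynamicPETVolume(
            data, _affine(vx), units="SUV", symmetric_x=True,
            provenance={"synthetic": True, "subject": sid},
        )
        mri = {
            k: DynamicPETVolume(v, _affine(vx), units="TBR", symmetric_x=True)
            for k, v in mri.items()
        }
    else:
        mri = {}
    return SimulatedSubject(record=record, suv=vol, mri=mri, truth=truth)


def simulate_survival(
    contralateral_z: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential proportional-hazards survival: hazard
    lambda0 * HR^z with non-informative uniform censoring C ~ U(0, c_max),
    c_max solved so the expected censored fraction matches the config."""
    z = np.asarray(contralateral_z, dtype=float)
    lam = config.survival_baseline_rate * np.power(config.survival_hr_per_sd, z)
    T = rng.exponential(1.0 / lam)
    frac = config.censoring_fraction
    if frac == 0:
        return pd.DataFrame({"time": T, "event": np.ones(len(T), dtype=bool)})

    def expected_censored(cmax: float) -> float:
        x = lam * cmax
        return float(np.mean((1.0 - np.exp(-x)) / x))

    cmax = brentq(lambda c: expected_censored(c) - frac, 1e-9, 1e9)
    C = rng.uniform(0.0, cmax, size=len(T))
    event = T <= C
    return pd.DataFrame({"time": np.minimum(T, C), "event": event})


@dataclass
class Cohort:
    config: CohortConfig
    atlas: AtlasParcellation
    subjects: list
    baselines: np.ndarray
    pellets: list
    pellet_truth: dict
    pons_voi: SphericalVOI

    def records(self) -> pd.DataFrame:
        import dataclasses

        return pd.DataFrame([dataclasses.asdict(s.record) for s in self.subjects])

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: s.truth[k] for k in
                 ("subject", "group", "contralateral_truth", "zeta", "eta")}
                for s in self.subjects
            ]
        )


def simulate_cohort(config: CohortConfig, keep_volumes: bool = True) -> Cohort:
    """Generate the full synthetic study: atlas, subjects with volumes and
    truth records, survival outcomes for the glioblastoma group, and sorted
    cell pellets."""
    atlas = make_atlas(config)
    rng0 = config.rng(2)
    R = config.regions_per_hemisphere
    base_left = 1.0 + rng0.normal(0.0, config.region_baseline_sd, size=R)
    base_left = np.clip(base_left, 0.2, None)
    baselines = np.zeros(2 * R + 1)
    baselines[1 : R + 1] = base_left
    baselines[R + 1 :] = base_left  # mirror-symmetric baseline pattern
    groups = (
        [("GBM", i) for i in range(config.n_gbm)]
        + [("IDHmut-A2", i) for i in range(config.n_idh)]
        + [("HC", i) for i in range(config.n_hc)]
    )
    subjects = []
    for idx, (grp, _) in enumerate(groups):
        subjects.append(
            simulate_subject(config, atlas, baselines, grp, idx, keep_volumes)
        )
    # survival for the glioblastoma group, linked to the truth contralateral
    # level z-scored within the group
    gbm = [s for s in subjects if s.record.group == "GBM"]
    vals = np.array([s.truth["contralateral_truth"] for s in gbm])
    z = (vals - vals.mean()) / vals.std(ddof=1) if len(gbm) > 1 else vals * 0
    surv = simulate_survival(z, config, config.rng(3))
    for s, (_, row) in zip(gbm, surv.iterrows()):
        s.record.survival_months = float(row["time"])
        s.record.event_observed = bool(row["event"])
    pellets, pellet_truth = simulate_pellets(config)
    return Cohort(
        config=config,
        atlas=atlas,
        subjects=subjects,
        baselines=baselines,
        pellets=pellets,
        pellet_truth=pellet_truth,
        pons_voi=_pons_voi(config),
    )


def simulate_pellets(config: CohortConfig) -> tuple[list, dict]:
    """Sorted-cell pellets for tumor / sham / healthy animals.

    Myeloid per-cell uptake is lognormal with group means in the configured
    fold relations; the depleted fraction shares one mean across groups.
    Enriched + depleted activities sum to the pre-sort total up to the
    configured sorting loss.
    """
    rng = config.rng(4)
    sham_mean = config.pellet_base_per_cell_Bq
    means = {
        "tumor": sham_mean * config.pellet_fold_tumor_vs_sham,
        "sham": sham_mean,
        "healthy": sham_mean
        * config.pellet_fold_tumor_vs_sham
        / config.pellet_fold_tumor_vs_healthy,
    }
    cv = config.pellet_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    t_meas = config.pellet_measurement_time_min
    decay = 2.0 ** (-t_meas / F18_HALF_LIFE_MIN)
    pellets: list[CellPellet] = []
    truth: dict = {"per_cell_means_Bq": means, "doses": {}}
    for grp, n_animals in config.pellet_n.items():
        if n_animals < 2:
            raise ValueError("need >= 2 animals per pellet group")
        for a in range(n_animals):
            sid = f"mouse-{grp}{a:02d}"
            dose = float(np.clip(rng.normal(config.mouse_dose_Bq, 3.1e6), 4e6, None))
            bw = float(np.clip(rng.normal(config.mouse_weight_g, 2.0), 14.0, None))
            truth["doses"][sid] = {"injected_dose_Bq": dose, "body_weight_g": bw}
            # tracer delivery scales with injected dose per body weight, so
            # the %ID x BW normalization removes it; biological variability
            # enters through the configured CV only
            delivery = (dose / config.mouse_dose_Bq) * (config.mouse_weight_g / bw)
            per_cell_my = means[grp] * delivery * float(
                np.exp(rng.normal(-(sigma**2) / 2, sigma))
            )
            per_cell_dep = config.pellet_depleted_per_cell_Bq * delivery * float(
                np.exp(rng.normal(-(sigma**2) / 2, sigma))
            )
            n_my = int(rng.lognormal(np.log(2e5), 0.2))
            n_dep = int(rng.lognormal(np.log(1.2e6), 0.2))
            a_my = per_cell_my * n_my  # at injection
            a_dep = per_cell_dep * n_dep
            purity = float(np.clip(rng.normal(config.pellet_purity_mean, 0.03), 0, 1))
            pellets.append(
                CellPellet(sid, "myeloid_enriched", a_my * decay, t_meas,
                           cell_count=n_my, purity_fraction=purity)
            )
            pellets.append(
                CellPellet(sid, "myeloid_depleted", a_dep * decay, t_meas,
                           cell_count=n_dep, purity_fraction=1.0 - purity)
            )
            total = (a_my + a_dep) / (1.0 - config.pellet_sort_loss_fraction)
            pellets.append(
                CellPellet(sid, "total", total * decay, t_meas, cell_count=None)
            )
    return pellets, truth


def simulate_dynamic_subject(
    config: CohortConfig,
    grid: int = 24,
    voxel_mm: float = 1.0,
    vt_background: float = 2.0,
    vt_tumor: float = 6.0,
    seed_offset: int = 0,
) -> dict:
    """A small dynamic (4D) phantom for kinetic modeling.

    Tissue voxels follow 1TC kinetics with a spatially varying VT (uniform
    background, a hot tumor sphere, a reference pons sphere at background
    VT); two carotid spheres carry the plasma input itself so the
    image-derived input recovers it. Returns the 4D volume, the input, the
    VOIs and the truth VT field.
    """
    rng = config.rng(5, seed_offset)
    fs = np.array([f[0] for f in config.frame_scheme])
    fe = np.array([f[1] for f in config.frame_scheme])
    inp = feng_input(t_end_min=float(fe.max()))
    n = grid
    aff = _affine(voxel_mm)
    c = (n - 1) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    brain = ((ii - c) / (0.42 * n)) ** 2 + ((jj - c) / (0.42 * n)) ** 2 + (
        (kk - c) / (0.42 * n)
    ) ** 2 <= 1.0
    vt_field = np.full((n, n, n), np.nan)
    vt_field[brain] = vt_background
    tumor = (ii - 0.30 * n) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= (0.10 * n) ** 2
    vt_field[tumor & brain] = vt_tumor
    pons = SphericalVOI(
        (c * voxel_mm, c * voxel_mm, (c - 0.2 * n) * voxel_mm),
        diameter_mm=3 * voxel_mm, label="pons",
    )
    carotids = [
        SphericalVOI(((c - 2) * voxel_mm, (c - 0.3 * n) * voxel_mm, 2 * voxel_mm),
                     diameter_mm=2 * voxel_mm, label="carotid_L"),
        SphericalVOI(((c + 2) * voxel_mm, (c - 0.3 * n) * voxel_mm, 2 * voxel_mm),
                     diameter_mm=2 * voxel_mm, label="carotid_R"),
    ]
    k2 = config.k2_reference
    data = np.zeros((n, n, n, len(fs)))
    # frame-average the input for blood voxels
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(inp.concentration, inp.times_min, initial=0.0)
    blood_means = (
        np.interp(fe, inp.times_min, cum) - np.interp(fs, inp.times_min, cum)
    ) / (fe - fs)
    for vt in np.unique(vt_field[np.isfinite(vt_field)]):
        tac = simulate_1tc(KineticParams(K1=vt * k2, k2=k2), inp, fs, fe)
        data[vt_field == vt, :] = tac.values
    tmp = DynamicPETVolume(data[..., 0], aff)
    for voi in carotids:
        data[voi.rasterize(tmp), :] = blood_means
    vol = DynamicPETVolume(
        data, aff, frame_starts=fs, frame_ends=fe, units="kBq/mL",
        provenance={"synthetic": True, "k2": k2},
    )
    return {
        "volume": vol,
        "input": inp,
        "pons_voi": pons,
        "carotid_vois": carotids,
        "vt_truth": vt_field,
        "k2": k2,
    }
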