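"""Atlas parcellation and regional group statistics.

The brain is parcellated into mirrored atlas regions (default 123 per
hemisphere, 246 total, emulating the Brainnetome layout), each assigned to
one of 15 anatomo-functional groups (superior-frontal, mid-frontal,
inferior-frontal, orbitofrontal, motor area, superior-temporal, mid-temporal,
inferior-temporal, mesio-temporal, parietal, insula, limbic, occipital,
basal ganglia, thalamus). Lesions are flipped to the canonical left side
before parcellation, so the contralateral hemisphere is always the right one.

Group statistics: per-region z-scores against the healthy-control cohort,
two-sided equal-variance t-tests with Benjamini-Hochberg FDR correction
across regions, Cohen's d effect sizes, and a one-way ANOVA comparing effect
sizes across region groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volumes import DynamicPETVolume, flip_lateral

__all__ = [
    "GROUP15_NAMES",
    "AtlasParcellation",
    "SubjectRecord",
    "parcellate_subject",
    "hc_control_values",
    "aggregate_group15",
    "regional_zscores",
    "compare_groups_fdr",
    "effect_size_anova",
]

GROUP15_NAMES = [
    "superior-frontal", "mid-frontal", "inferior-frontal", "orbitofrontal",
    "motor area", "superior-temporal", "mid-temporal", "inferior-temporal",
    "mesio-temporal", "parietal", "insula", "limbic", "occipital",
    "basal ganglia", "thalamus",
]

CONTRA, IPSI = "contralateral", "ipsilateral"


@dataclass
class AtlasParcellation:
    """Symmetric label volume plus region table.

    The region table columns: ``id`` (integer label), ``name``,
    ``hemisphere`` (left/right), ``mirror_id`` (the partner region in the
    other hemisphere) and ``group15`` (anatomo-functional group name).
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        r = self.regions
        need = {"id", "name", "hemisphere", "mirror_id", "group15"}
        if not need.issubset(r.columns):
            raise ValueError(f"region table missing columns {need - set(r.columns)}")
        ids = set(r["id"])
        if len(ids) != len(r):
            raise ValueError("duplicate region ids")
        mirror = dict(zip(r["id"], r["mirror_id"]))
        for i, m in mirror.items():
            if m not in ids or mirror.get(m) != i or m == i:
                raise ValueError(f"region {i} lacks a proper mirror partner")
        left = r[r["hemisphere"] == "left"]
        right = r[r["hemisphere"] == "right"]
        if len(left) != len(right):
            raise ValueError("hemisphere region counts differ")
        present = set(np.unique(self.labels)) - {0}
        if not present.issubset(ids):
            raise ValueError("label volume contains ids absent from the table")
        missing_grp = r[~r["group15"].isin(GROUP15_NAMES)]
        if len(missing_grp):
            raise ValueError(
                f"regions with unknown group15: {missing_grp['id'].tolist()[:5]}"
            )
        if not self.voxel_counts:
            flat = self.labels.ravel()
            counts = np.bincount(flat[flat > 0])
            self.voxel_counts = {
                int(i): int(counts[i]) for i in np.nonzero(counts)[0]
            }

    @property
    def n_per_hemisphere(self) -> int:
        return int((self.regions["hemisphere"] == "left").sum())

    def mirror_map(self) -> dict:
        return dict(zip(self.regions["id"], self.regions["mirror_id"]))

    def hemisphere_ids(self, hemisphere: str) -> list:
        return self.regions.loc[
            self.regions["hemisphere"] == hemisphere, "id"
        ].tolist()

    def to_files(self, label_path, table_path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), np.eye(4)), str(label_path))
        self.regions.to_csv(table_path, sep="\t", index=False)


@dataclass
class SubjectRecord:
    """One subject's metadata row (cohort table)."""

    id: str
    group: str  # GBM, IDHmut-A2, HC
    age: float = np.nan
    sex: str = ""
    snp_binding: str = "NA"  # LAB/MAB/HAB/NA
    lesion_side: str | None = None
    seizure_at_dx: bool | None = None
    seizure_persisting: bool | None = None
    resection: bool = False
    radiotherapy: bool = False
    chemotherapy: bool = False
    glucocorticoid_at_pet: bool = False
    mgmt_methylated: bool | None = None
    survival_months: float | None = None
    event_observed: bool | None = None
    injected_dose_Bq: float = np.nan
    body_weight_g: float = np.nan

    def __post_init__(self) -> None:
        if (self.survival_months is None) != (self.event_observed is None):
            raise ValueError("survival time and event flag must be present together")
        if self.group == "HC" and self.lesion_side is not None:
            raise ValueError("healthy controls have no lesion side")


def parcellate_subject(
    suvr_volume: DynamicPETVolume,
    atlas: AtlasParcellation,
    lesion_side: str | None,
    subject: str = "",
) -> pd.DataFrame:
    """Per-region mean SUVr with contralateral/ipsilateral side tags.

    Right-sided lesions are flipped so the lesion sits on the canonical left
    side; the contralateral tag then always refers to the right hemisphere.
    Healthy controls (lesion_side None) are parcellated unflipped with the
    same canonical convention. Empty regions yield NaN with a note.
    """
    vol = suvr_volume
    if lesion_side == "right":
        vol = flip_lateral(vol)
    elif lesion_side not in (None, "left"):
        raise ValueError(f"unknown lesion side {lesion_side!r}")
    if vol.data.shape != atlas.labels.shape:
        raise ValueError("volume and atlas grids do not match")
    flat_labels = atlas.labels.ravel()
    flat_vals = vol.data.ravel()
    nmax = int(flat_labels.max()) + 1
    sums = np.bincount(flat_labels, weights=flat_vals, minlength=nmax)
    counts = np.bincount(flat_labels, minlength=nmax)
    rows = []
    for _, reg in atlas.regions.iterrows():
        rid = int(reg["id"])
        n = counts[rid] if rid < nmax else 0
        value = sums[rid] / n if n > 0 else np.nan
        side = CONTRA if reg["hemisphere"] == "right" else IPSI
        rows.append(
            dict(subject=subject, region_id=rid, side=side, value=value,
                 group15=reg["group15"], n_voxels=int(n))
        )
    return pd.DataFrame(rows)


def hc_control_values(table: pd.DataFrame, atlas: AtlasParcellation) -> pd.DataFrame:
    """Healthy-control value per contralateral region id: both hemispheres
    averaged per mirror pair (controls have no lesion side, so each mirrored
    pair contributes its mean)."""
    mirror = atlas.mirror_map()
    right_ids = atlas.hemisphere_ids("right")
    out = []
    for subj, sub in table.groupby("subject"):
        vals = dict(zip(sub["region_id"], sub["value"]))
        for rid in right_ids:
            pair = [vals.get(rid, np.nan), vals.get(mirror[rid], np.nan)]
            out.append(
                dict(subject=subj, region_id=rid, side=CONTRA,
                     value=float(np.nanmean(pair)))
            )
    return pd.DataFrame(out)


def aggregate_group15(table: pd.DataFrame, atlas: AtlasParcellation) -> pd.DataFrame:
    """Aggregate region values into the 15 anatomo-functional groups by
    voxel-count-weighted mean, per subject and side."""
    grp_of = dict(zip(atlas.regions["id"], atlas.regions["group15"]))
    missing = set(table["region_id"]) - set(grp_of)
    if missing:
        raise ValueError(f"regions without group15 mapping: {sorted(missing)[:5]}")
    t = table.copy()
    t["group15"] = t["region_id"].map(grp_of)
    t["w"] = t["region_id"].map(atlas.voxel_counts).astype(float)
    t = t[np.isfinite(t["value"])]

    def wmean(sub: pd.DataFrame) -> float:
        return float(np.average(sub["value"], weights=sub["w"]))

    rows = []
    for (subj, side, g15), sub in t.groupby(["subject", "side", "group15"]):
        rows.append(dict(subject=subj, side=side, group15=g15, value=wmean(sub)))
    return pd.DataFrame(rows)


def regional_zscores(
    subject_rows: pd.DataFrame, control_rows: pd.DataFrame, key: str = "region_id"
) -> pd.DataFrame:
    """z = (x - mean_HC) / sd_HC per region, HC sd with ddof=1.

    Regions with zero control variance yield NaN and are flagged.
    """
    ctrl = control_rows.groupby(key)["value"]
    n = ctrl.count()
    if (n < 3).any():
        raise ValueError("control cohort must have n >= 3 per region")
    mu = ctrl.mean()
    sd = ctrl.std(ddof=1)
    out = subject_rows.copy()
    out["z"] = (out["value"] - out[key].map(mu)) / out[key].map(sd)
    out["z_undefined"] = out[key].map(sd) == 0
    out.loc[out["z_undefined"], "z"] = np.nan
    return out


def compare_groups_fdr(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    value: str = "value",
    key: str = "region_id",
) -> pd.DataFrame:
    """Per-region two-sided equal-variance t-test (group A vs B) with
    Benjamini-Hochberg FDR across regions and pooled-sd Cohen's d.

    Regions with zero variance in both groups get p = 1 and a flag. The
    returned frame carries attrs['n_significant'].
    """
    keys = sorted(set(table_a[key]) & set(table_b[key]))
    rows = []
    for k in keys:
        a = np.asarray(table_a.loc[table_a[key] == k, value].dropna(), float)
        b = np.asarray(table_b.loc[table_b[key] == k, value].dropna(), float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 subjects per group for region {k}")
        flagged = False
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t_val, p = 0.0, 1.0
            flagged = True
        else:
            t_val, p = stats.ttest_ind(a, b, equal_var=True)
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        rows.append(
            dict(**{key: k}, t=float(t_val), p=float(p), cohens_d=float(d),
                 mean_a=a.mean(), mean_b=b.mean(), zero_variance=flagged)
        )
    out = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = reject
    out.attrs["n_significant"] = int(reject.sum())
    out.attrs["alpha"] = alpha
    return out


def effect_size_anova(groups: dict[str, Sequence[float]]) -> dict:
    """One-way fixed-effects ANOVA across groupings of per-region effect
    sizes. All-constant input yields F = 0, p = 1 with a flag."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        return {"F": 0.0, "p": 1.0, "degenerate": True}
    F, p = stats.f_oneway(*arrays.values())
    return {"F": float(F), "p": float(p), "degenerate": False}
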