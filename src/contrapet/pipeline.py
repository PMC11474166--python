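"""End-to-end pipeline orchestration with provenance and caching.

Stages run in dependency order; each writes its outputs (TSV/JSON/NIfTI)
under ``out_dir/<stage>/`` and records parameters plus SHA-256 checksums of
its inputs and outputs in ``manifest.json``. A re-run skips a stage as
"cached" when its parameters and input/output checksums are unchanged; when
a stage does recompute, every downstream stage recomputes too. All
randomness is seeded from the run configuration, so two runs from the same
config produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    matched_region_correlation,
    synchronicity_matrix,
    tumor_seed_correlation,
)
from .kinetics import image_derived_input, vt_map, vtr_map
from .outcome import cox_fit, logrank_median_split, seizure_comparison
from .regional import (
    AtlasParcellation,
    CONTRA,
    aggregate_group15,
    compare_groups_fdr,
    hc_control_values,
    parcellate_subject,
    regional_zscores,
)
from .scradiotracing import fraction_fold_change, pellet_table, per_cell_uptake
from .segmentation import rce_map, region_grow, tbr_map
from .synthetic import CohortConfig, simulate_cohort, simulate_dynamic_subject
from .volumes import Dosimetry, DynamicPETVolume, SphericalVOI, normalize_suvr, voi_stats

log = logging.getLogger("contrapet")

STAGE_ORDER = [
    "simulate",
    "suvr",
    "parcellate",
    "segment",
    "kinetics",
    "regional_stats",
    "connectivity",
    "outcome",
    "scrt",
]

STAGE_DEPS = {
    "simulate": [],
    "suvr": ["simulate"],
    "parcellate": ["suvr", "simulate"],
    "segment": ["suvr", "simulate"],
    "kinetics": ["simulate"],
    "regional_stats": ["parcellate", "simulate"],
    "connectivity": ["parcellate", "segment"],
    "outcome": ["parcellate", "simulate"],
    "scrt": ["simulate"],
}


@dataclass
class RunConfig:
    """Run configuration (YAML/JSON loadable)."""

    out_dir: str
    seed: int
    profile: str = "fast"  # fast (32^3) or full (64^3)
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.profile not in ("fast", "full"):
            raise ValueError("profile must be 'fast' or 'full'")

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.params.get("cohort", {}))
        if self.profile == "fast":
            return CohortConfig.fast(self.seed, **overrides)
        return CohortConfig(seed=self.seed, **overrides)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        obj = yaml.safe_load(Path(path).read_text())
        return cls(**obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


class PipelineRun:
    """Executes stages against one output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )
        self.manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "stages": {},
        }
        self._forced_stale: set[str] = set()

    # ---- helpers ---------------------------------------------------------

    def _stage_dir(self, name: str) -> Path:
        d = self.out / name
        d.mkdir(exist_ok=True)
        return d

    def _hash_files(self, paths: list[Path]) -> dict:
        return {str(p.relative_to(self.out)): _sha256(p) for p in sorted(paths)}

    def _stage_outputs(self, name: str) -> list[Path]:
        d = self.out / name
        return sorted(p for p in d.rglob("*") if p.is_file()) if d.exists() else []

    def _is_cached(self, name: str, params: dict) -> bool:
        if name in self._forced_stale:
            return False
        prev = self.previous.get("stages", {}).get(name)
        if prev is None or prev.get("params") != json.loads(
            json.dumps(params, sort_keys=True, default=_jsonable)
        ):
            return False
        # inputs: recorded dependency-output hashes must match current files
        for rel, sha in {**prev.get("inputs", {}), **prev.get("outputs", {})}.items():
            p = self.out / rel
            if not p.exists() or _sha256(p) != sha:
                return False
        return True

    def _record(self, name, params, deps, status) -> None:
        inputs: dict = {}
        for d in deps:
            inputs.update(self._hash_files(self._stage_outputs(d)))
        self.manifest["stages"][name] = {
            "params": json.loads(json.dumps(params, sort_keys=True, default=_jsonable)),
            "inputs": inputs,
            "outputs": self._hash_files(self._stage_outputs(name)),
            "status": status,
        }

    # ---- stage implementations ------------------------------------------

    def run(self) -> dict:
        requested = [s for s in STAGE_ORDER if s in self.config.stages]
        for name in requested:
            deps = STAGE_DEPS[name]
            params = self._params_for(name)
            if self._is_cached(name, params):
                log.info("stage %s: cached", name)
                self._record(name, params, deps, "cached")
                continue
            log.info("stage %s: computing", name)
            try:
                getattr(self, f"stage_{name}")()
            except Exception as exc:
                self.manifest["stages"][name] = {"status": "incomplete",
                                                 "error": str(exc)}
                _write_json(self.manifest_path, self.manifest)
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            self._record(name, params, deps, "computed")
            # a recomputed stage invalidates everything downstream
            for later in STAGE_ORDER:
                if name in _transitive_deps(later):
                    self._forced_stale.add(later)
        _write_json(self.manifest_path, self.manifest)
        return self.manifest

    def _params_for(self, name: str) -> dict:
        base = {"seed": self.config.seed, "profile": self.config.profile}
        base.update(self.config.params.get(name, {}))
        if name == "simulate":
            base["cohort"] = self.config.params.get("cohort", {})
        return base

    # Cohort generation is deterministic in (seed, profile); stages that
    # need in-memory objects regenerate them instead of pickling volumes.
    def _cohort(self):
        if not hasattr(self, "_cohort_cache"):
            self._cohort_cache = simulate_cohort(self.config.cohort_config())
        return self._cohort_cache

    def stage_simulate(self) -> None:
        d = self._stage_dir("simulate")
        co = self._cohort()
        co.atlas.to_files(d / "atlas.nii", d / "regions.tsv")
        (d / "subjects").mkdir(exist_ok=True)
        for s in co.subjects:
            s.suv.to_nifti(d / "subjects" / f"{s.record.id}_suv.nii")
            for mod, vol in s.mri.items():
                tag = mod.replace("-", "").lower()
                vol.to_nifti(d / "subjects" / f"{s.record.id}_{tag}.nii")
        co.records().to_csv(d / "records.tsv", sep="\t", index=False)
        _write_json(d / "truth.json", [s.truth for s in co.subjects])
        pellet_table(co.pellets).to_csv(d / "pellets.tsv", sep="\t", index=False)
        _write_json(d / "pellet_truth.json", co.pellet_truth)
        _write_json(d / "pons_voi.json", co.pons_voi.to_json())

    def stage_suvr(self) -> None:
        d = self._stage_dir("suvr")
        sim = self.out / "simulate"
        pons = SphericalVOI.from_json(json.loads((sim / "pons_voi.json").read_text()))
        for p in sorted((sim / "subjects").glob("*_suv.nii")):
            vol = DynamicPETVolume.from_nifti(p)
            suvr = normalize_suvr(vol, pons)
            suvr.to_nifti(d / p.name.replace("_suv", "_suvr"))

    def stage_parcellate(self) -> None:
        d = self._stage_dir("parcellate")
        sim = self.out / "simulate"
        atlas = _load_atlas(sim)
        records = pd.read_csv(sim / "records.tsv", sep="\t")
        side = dict(zip(records["id"], records["lesion_side"]))
        tables = []
        for p in sorted((self.out / "suvr").glob("*_suvr.nii")):
            sid = p.name.replace("_suvr.nii", "")
            vol = DynamicPETVolume.from_nifti(p)
            ls = side.get(sid)
            ls = None if pd.isna(ls) else ls
            tables.append(parcellate_subject(vol, atlas, ls, subject=sid))
        pd.concat(tables, ignore_index=True).to_csv(
            d / "regional_table.tsv", sep="\t", index=False
        )

    def stage_segment(self) -> None:
        d = self._stage_dir("segment")
        sim = self.out / "simulate"
        records = pd.read_csv(sim / "records.tsv", sep="\t")
        params = self.config.params.get("segment", {})
        tspo_thr = params.get("tspo_threshold", 1.8)
        n = None
        rows = []
        for _, rec in records[records["group"] != "HC"].iterrows():
            sid = rec["id"]
            suvr = DynamicPETVolume.from_nifti(self.out / "suvr" / f"{sid}_suvr.nii")
            if rec["lesion_side"] == "right":
                suvr = DynamicPETVolume(
                    suvr.data[::-1].copy(), suvr.affine, units=suvr.units
                )
            n = suvr.data.shape[0]
            maps = {"TSPO": suvr}
            for mod, tag in [("CE-T1", "cet1"), ("native-T1", "nativet1"), ("T2", "t2")]:
                p = sim / "subjects" / f"{sid}_{tag}.nii"
                if p.exists():
                    v = DynamicPETVolume.from_nifti(p)
                    if rec["lesion_side"] == "right":
                        v = DynamicPETVolume(v.data[::-1].copy(), v.affine)
                    maps[mod] = v
            # background VOI: contralateral (right-half) white-matter box
            bg = np.zeros(suvr.data.shape, dtype=bool)
            bg[int(0.65 * n):int(0.8 * n), int(0.4 * n):int(0.6 * n),
               int(0.4 * n):int(0.6 * n)] = True
            seg_maps: dict[str, DynamicPETVolume] = {"TSPO": suvr}
            thresholds = {"TSPO": tspo_thr}
            if "CE-T1" in maps:
                tb_ce = tbr_map(maps["CE-T1"], bg, "CE-T1")
                tb_nat = tbr_map(maps["native-T1"], bg, "native-T1")
                seg_maps["rCE"] = rce_map(tb_ce, tb_nat)
                thresholds["rCE"] = params.get("rce_threshold", 1.6)
            if "T2" in maps:
                seg_maps["T2"] = tbr_map(maps["T2"], bg, "T2").volume
                thresholds["T2"] = params.get("t2_threshold", 1.3)
            for mod, vol in seg_maps.items():
                # seed: hottest voxel in the lesion (left) half
                half = vol.data.copy()
                half[n // 2:] = -np.inf
                half[~np.isfinite(half)] = -np.inf
                seed = np.unravel_index(int(np.argmax(half)), half.shape)
                thr = thresholds[mod]
                if vol.data[seed] < thr:
                    rows.append(dict(subject=sid, modality=mod, threshold=thr,
                                     volume_mL=0.0, n_voxels=0,
                                     tumor_mean=np.nan, tumor_max=np.nan,
                                     note="no lesion"))
                    continue
                res = region_grow(vol, [seed], thr)
                stats_ = voi_stats(suvr, res.mask) if res.mask.any() else {}
                rows.append(dict(subject=sid, modality=mod, threshold=thr,
                                 volume_mL=res.volume_mL, n_voxels=res.n_voxels,
                                 tumor_mean=stats_.get("mean", np.nan),
                                 tumor_max=stats_.get("max", np.nan), note=""))
        pd.DataFrame(rows).to_csv(d / "tumor_volumes.tsv", sep="\t", index=False)

    def stage_kinetics(self) -> None:
        d = self._stage_dir("kinetics")
        cc = self.config.cohort_config()
        params = self.config.params.get("kinetics", {})
        grid = params.get("grid", 20)
        phantom = simulate_dynamic_subject(cc, grid=grid)
        vol = phantom["volume"]
        idif = image_derived_input(vol, phantom["carotid_vois"][0].rasterize(vol)
                                   | phantom["carotid_vois"][1].rasterize(vol))
        # fit a central slab to keep the voxel loop small
        mask = np.isfinite(phantom["vt_truth"])
        zc = vol.shape3d[2] // 2
        slab = np.zeros_like(mask)
        slab[:, :, zc - 1: zc + 2] = True
        slab |= phantom["pons_voi"].rasterize(vol)  # reference must be fitted
        vt = vt_map(vol, idif, mask & slab)
        vtr = vtr_map(vt, phantom["pons_voi"])
        vt.to_nifti(d / "vt.nii")
        vtr.to_nifti(d / "vtr.nii")
        truth = phantom["vt_truth"]
        fitted = vt.data[mask & slab]
        true = truth[mask & slab]
        rel_err = np.abs(fitted - true) / true
        _write_json(d / "summary.json", {
            "n_voxels_fit": int((mask & slab).sum()),
            "median_rel_error": float(np.nanmedian(rel_err)),
            "max_rel_error": float(np.nanmax(rel_err)),
            "vtr_tumor_over_background": float(
                np.nanmean(vtr.data[truth == truth[np.isfinite(truth)].max()])
            ),
        })

    def stage_regional_stats(self) -> None:
        d = self._stage_dir("regional_stats")
        sim = self.out / "simulate"
        atlas = _load_atlas(sim)
        table = pd.read_csv(self.out / "parcellate" / "regional_table.tsv", sep="\t")
        records = pd.read_csv(sim / "records.tsv", sep="\t")
        grp = dict(zip(records["id"], records["group"]))
        table["group"] = table["subject"].map(grp)
        alpha = self.config.params.get("regional_stats", {}).get("alpha", 0.05)

        hc = hc_control_values(table[table["group"] == "HC"], atlas)
        gbm = table[(table["group"] == "GBM") & (table["side"] == CONTRA)]
        comp = compare_groups_fdr(gbm, hc, alpha=alpha)
        comp.to_csv(d / "gbm_vs_hc_regions.tsv", sep="\t", index=False)
        zs = regional_zscores(gbm, hc)
        zs.to_csv(d / "gbm_contralateral_zscores.tsv", sep="\t", index=False)
        g15 = aggregate_group15(table, atlas)
        g15.to_csv(d / "group15_table.tsv", sep="\t", index=False)

        elev = contralateral_elevation(table, atlas, grp)
        _write_json(d / "summary.json", {
            "n_regions": len(comp),
            "n_significant": int(comp.attrs["n_significant"]),
            "alpha_fdr": alpha,
            "contralateral_elevation_pct": elev,
        })

    def stage_connectivity(self) -> None:
        d = self._stage_dir("connectivity")
        sim = self.out / "simulate"
        atlas = _load_atlas(sim)
        table = pd.read_csv(self.out / "parcellate" / "regional_table.tsv", sep="\t")
        records = pd.read_csv(sim / "records.tsv", sep="\t")
        grp = dict(zip(records["id"], records["group"]))
        table["group"] = table["subject"].map(grp)
        gbm = table[table["group"] == "GBM"]
        matched = matched_region_correlation(gbm, atlas)
        tum = pd.read_csv(self.out / "segment" / "tumor_volumes.tsv", sep="\t")
        seed = (
            tum[tum["modality"] == "TSPO"]
            .set_index("subject")["tumor_mean"]
            .reindex(sorted(gbm["subject"].unique()))
        )
        seed_corr = tumor_seed_correlation(gbm, seed)
        seed_corr.to_csv(d / "tumor_seed_correlation.tsv", sep="\t", index=False)
        g15 = aggregate_group15(gbm, atlas)
        g15 = g15[g15["side"] == CONTRA].rename(columns={"group15": "region_id"})
        sync = synchronicity_matrix(g15, key="region_id", cohort="GBM")
        sync.to_frame().to_csv(d / "synchronicity_gbm.tsv", sep="\t")
        _write_json(d / "summary.json", {
            "matched_region_R": matched["R"],
            "matched_region_n_pairs": matched["n_pairs"],
            "synchronicity_mean_offdiag": sync.mean_offdiagonal,
            "tumor_seed_mean_R": float(seed_corr["R"].mean()),
        })

    def stage_outcome(self) -> None:
        d = self._stage_dir("outcome")
        sim = self.out / "simulate"
        atlas = _load_atlas(sim)
        table = pd.read_csv(self.out / "parcellate" / "regional_table.tsv", sep="\t")
        records = pd.read_csv(sim / "records.tsv", sep="\t").set_index("id")
        contra = contralateral_subject_means(table, atlas)
        gbm = records[records["group"] == "GBM"].join(contra.rename("contra"))
        surv = gbm.dropna(subset=["survival_months"])
        out: dict = {}
        if len(surv) >= 5 and surv["event_observed"].sum() >= 5:
            uni = cox_fit(
                surv["survival_months"], surv["event_observed"],
                surv[["contra"]], z_transform_flags={"contra": True},
            )
            out["cox_univariate"] = uni.as_frame().to_dict("records")
            # scale the covariate battery to the number of events (roughly
            # three events per term) so small cohorts stay estimable
            battery = ["contra", "age", "radiotherapy", "chemotherapy",
                       "glucocorticoid_at_pet"]
            k = max(1, min(len(battery), int(surv["event_observed"].sum() // 3)))
            if k >= 2:
                try:
                    multi = cox_fit(
                        surv["survival_months"], surv["event_observed"],
                        surv[battery[:k]].astype(float),
                        z_transform_flags={"contra": True},
                    )
                    out["cox_multivariate"] = multi.as_frame().to_dict("records")
                except RuntimeError as exc:
                    out["cox_multivariate_skipped"] = str(exc)
            lr = logrank_median_split(
                surv["contra"], surv["survival_months"], surv["event_observed"]
            )
            out["logrank_median_split"] = lr
        dx = gbm.dropna(subset=["seizure_at_dx"])
        if len(dx) >= 4 and dx["seizure_at_dx"].astype(bool).nunique() == 2:
            out["seizure_at_dx"] = seizure_comparison(
                dx["contra"], dx["seizure_at_dx"].astype(bool),
                dx[["glucocorticoid_at_pet"]].astype(float),
            )
        _write_json(d / "outcome.json", out)

    def stage_scrt(self) -> None:
        d = self._stage_dir("scrt")
        sim = self.out / "simulate"
        pellets = pd.read_csv(sim / "pellets.tsv", sep="\t")
        doses = json.loads((sim / "pellet_truth.json").read_text())["doses"]
        from .scradiotracing import CellPellet

        rows = []
        for _, r in pellets.iterrows():
            if r["fraction"] == "total":
                continue
            dd = doses[r["subject"]]
            p = CellPellet(r["subject"], r["fraction"], r["activity_Bq"],
                           r["time_min"], cell_count=int(r["cells"]),
                           purity_fraction=r["purity"])
            dose = Dosimetry(dd["injected_dose_Bq"], dd["body_weight_g"])
            u = per_cell_uptake(p, dose)
            grp = r["subject"].split("-")[1].rstrip("0123456789")
            rows.append(dict(subject=r["subject"], group=grp,
                             fraction=r["fraction"], **u))
        df = pd.DataFrame(rows)
        df.to_csv(d / "per_cell_uptake.tsv", sep="\t", index=False)
        res = {}
        for frac in ("myeloid_enriched", "myeloid_depleted"):
            sub = df[df["fraction"] == frac]
            groups = {
                g: sub.loc[sub["group"] == g, "pct_ID_x_BW_per_cell"].to_numpy()
                for g in ("tumor", "sham", "healthy")
            }
            fc = fraction_fold_change(groups)
            res[frac] = fc
        _write_json(d / "scrt.json", res)


def _transitive_deps(stage: str) -> set:
    seen: set[str] = set()
    stack = list(STAGE_DEPS[stage])
    while stack:
        s = stack.pop()
        if s not in seen:
            seen.add(s)
            stack.extend(STAGE_DEPS[s])
    return seen


def _load_atlas(sim_dir: Path) -> AtlasParcellation:
    import nibabel as nib

    labels = np.asanyarray(nib.load(str(sim_dir / "atlas.nii")).dataobj).astype(int)
    regions = pd.read_csv(sim_dir / "regions.tsv", sep="\t")
    return AtlasParcellation(labels, regions)


def contralateral_subject_means(
    table: pd.DataFrame, atlas: AtlasParcellation
) -> pd.Series:
    """Voxel-weighted contralateral hemisphere mean per subject (for
    controls this is the right-hemisphere canonical tag)."""
    contra = table[table["side"] == CONTRA].copy()
    contra["w"] = contra["region_id"].map(atlas.voxel_counts).astype(float)
    contra = contra[np.isfinite(contra["value"])]
    return contra.groupby("subject").apply(
        lambda s: float(np.average(s["value"], weights=s["w"])),
        include_groups=False,
    )


def contralateral_elevation(
    table: pd.DataFrame, atlas: AtlasParcellation, group_of: dict
) -> dict:
    """Percent elevation of group-mean contralateral hemisphere SUVr vs
    healthy controls (controls: both hemispheres mirror-averaged)."""
    means = contralateral_subject_means(table, atlas)
    hc_tab = table[table["subject"].map(group_of) == "HC"]
    hc_vals = hc_control_values(hc_tab, atlas)
    hc_vals["w"] = hc_vals["region_id"].map(atlas.voxel_counts).astype(float)
    hc_means = hc_vals.groupby("subject").apply(
        lambda s: float(np.average(s["value"], weights=s["w"])),
        include_groups=False,
    )
    ref = float(hc_means.mean())
    out = {}
    for g in ("GBM", "IDHmut-A2"):
        subs = [s for s, gg in group_of.items() if gg == g and s in means.index]
        if subs:
            out[g] = 100.0 * (float(means.loc[subs].mean()) / ref - 1.0)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    return PipelineRun(config).run()


def analyze_cohort_regional(cohort_config: CohortConfig) -> dict:
    """In-memory regional analysis of one synthetic cohort.

    Generates the cohort, normalizes each subject to the pons reference,
    parcellates (flipping right-sided lesions), and returns the estimated
    contralateral elevation per patient group plus the FDR-corrected count
    of significant contralateral regions (glioblastoma vs controls). Used
    for parameter-recovery studies without touching disk.
    """
    from .volumes import normalize_suvr

    co = simulate_cohort(cohort_config)
    tables = []
    for s in co.subjects:
        suvr = normalize_suvr(s.suv, co.pons_voi)
        tables.append(
            parcellate_subject(suvr, co.atlas, s.record.lesion_side,
                               subject=s.record.id)
        )
    table = pd.concat(tables, ignore_index=True)
    group_of = {s.record.id: s.record.group for s in co.subjects}
    table["group"] = table["subject"].map(group_of)
    hc = hc_control_values(table[table["group"] == "HC"], co.atlas)
    gbm = table[(table["group"] == "GBM") & (table["side"] == CONTRA)]
    comp = compare_groups_fdr(gbm, hc)
    elev = contralateral_elevation(table, co.atlas, group_of)
    # per-group15 elevation (GBM contralateral vs HC mirror-averaged)
    g15_of = dict(zip(co.atlas.regions["id"], co.atlas.regions["group15"]))
    w_of = co.atlas.voxel_counts
    def _g15_mean(frame):
        f = frame.copy()
        f["g15"] = f["region_id"].map(g15_of)
        f["w"] = f["region_id"].map(w_of).astype(float)
        f = f[np.isfinite(f["value"])]
        per_subj = f.groupby(["subject", "g15"]).apply(
            lambda s: float(np.average(s["value"], weights=s["w"])),
            include_groups=False,
        )
        return per_subj.groupby("g15").mean()
    g15_elev = (
        100.0 * (_g15_mean(gbm) / _g15_mean(hc) - 1.0)
    ).to_dict()
    return {
        "elevation_pct": elev,
        "n_regions": len(comp),
        "n_significant": int(comp.attrs["n_significant"]),
        "group15_elevation_pct": g15_elev,
        "comparison": comp,
        "cohort": co,
        "regional_table": table,
    }
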