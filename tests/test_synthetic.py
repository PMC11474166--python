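import numpy as np
import pandas as pd
import pytest

from contrapet.regional import parcellate_subject
from contrapet.scradiotracing import per_cell_uptake, CellPellet
from contrapet.synthetic import (
    CohortConfig,
    make_atlas,
    simulate_cohort,
    simulate_dynamic_subject,
    simulate_pellets,
    simulate_survival,
)
from contrapet.volumes import Dosimetry, normalize_suvr


class TestAtlas:
    def test_region_counts(self, tiny_config, tiny_cohort):
        atlas = tiny_cohort.atlas
        R = tiny_config.regions_per_hemisphere
        assert len(atlas.regions) == 2 * R
        assert atlas.n_per_hemisphere == R

    def test_default_has_123_per_hemisphere(self):
        cfg = CohortConfig.fast(3)
        atlas = make_atlas(cfg)
        assert atlas.n_per_hemisphere == 123
        assert len(atlas.regions) == 246

    def test_flip_equals_mirror_relabel(self, tiny_cohort):
        atlas = tiny_cohort.atlas
        mirror = atlas.mirror_map()
        lut = np.zeros(max(mirror) + 1, dtype=int)
        for k, v in mirror.items():
            lut[k] = v
        flipped = atlas.labels[::-1]
        relabeled = np.where(atlas.labels > 0, lut[atlas.labels], 0)
        assert (flipped == relabeled).all()

    def test_brain_mask_partitioned(self, tiny_cohort):
        labels = tiny_cohort.atlas.labels
        brain = labels > 0
        assert brain.any()
        # every brain voxel has exactly one label (by construction of the
        # label volume) and labels vanish outside the brain
        assert set(np.unique(labels[brain])) == set(
            tiny_cohort.atlas.regions["id"]
        )


class TestDeterminism:
    def test_identical_seed_bit_identical_volumes(self, tiny_config):
        a = simulate_cohort(tiny_config)
        b = simulate_cohort(tiny_config)
        for sa, sb in zip(a.subjects, b.subjects):
            assert (sa.suv.data == sb.suv.data).all()
            assert sa.truth == sb.truth
        assert (a.atlas.labels == b.atlas.labels).all()

    def test_different_seed_differs(self, tiny_config, tiny_cohort):
        import dataclasses

        other = dataclasses.replace(tiny_config, seed=tiny_config.seed + 1)
        b = simulate_cohort(other)
        assert not (tiny_cohort.subjects[0].suv.data == b.subjects[0].suv.data).all()


class TestSubjectRoundTrip:
    def test_regional_means_recover_truth(self, tiny_cohort):
        co = tiny_cohort
        s = next(x for x in co.subjects if x.record.group == "HC")
        suvr = normalize_suvr(s.suv, co.pons_voi)
        table = parcellate_subject(suvr, co.atlas, s.record.lesion_side)
        targets = np.asarray(s.truth["region_targets"])
        got = table.set_index("region_id")["value"]
        rel = np.abs(
            got.loc[np.arange(1, len(targets))].to_numpy() - targets[1:]
        ) / targets[1:]
        # voxel noise (5%) averages out over region voxels; pons overlap and
        # the reference-mean estimate leave a small residual
        assert np.nanmedian(rel) < 0.05

    def test_tumor_only_in_lesion_hemisphere(self, tiny_cohort):
        n = tiny_cohort.config.grid_size
        for s in tiny_cohort.subjects:
            if s.record.group == "HC":
                assert s.truth["tumor"] == {}
                continue
            data = s.suv.data
            canonical = data[::-1] if s.record.lesion_side == "right" else data
            left_max = canonical[: n // 2].max()
            right_max = canonical[n // 2:].max()
            assert left_max > 1.5 * right_max

    def test_coupling_produces_positive_truth_correlation(self):
        # across cohorts, tumor severity and contralateral truth co-vary
        signs = []
        for seed in range(10):
            cfg = CohortConfig.fast(500 + seed, n_gbm=100, n_idh=1, n_hc=3,
                                    regions_per_hemisphere=20)
            co = simulate_cohort(cfg, keep_volumes=False)
            t = co.truth_frame()
            gbm = t[t["group"] == "GBM"]
            signs.append(np.corrcoef(gbm["zeta"], gbm["contralateral_truth"])[0, 1])
        assert all(s > 0 for s in signs)


class TestSurvival:
    def test_zero_censoring_all_events(self):
        cfg = CohortConfig.fast(9, censoring_fraction=0.0)
        out = simulate_survival(np.zeros(200), cfg, cfg.rng(3))
        assert out["event"].all()

    def test_censoring_fraction_calibrated(self):
        cfg = CohortConfig.fast(9, censoring_fraction=0.3)
        out = simulate_survival(np.zeros(20_000), cfg, cfg.rng(3))
        assert abs(1 - out["event"].mean() - 0.3) < 0.02

    def test_null_hr_centered_at_one(self):
        from contrapet.outcome import cox_fit

        cfg = CohortConfig.fast(9, survival_hr_per_sd=1.0)
        rng = cfg.rng(3)
        z = rng.normal(size=2000)
        out = simulate_survival(z, cfg, rng)
        res = cox_fit(out["time"], out["event"], pd.DataFrame({"z": z}))
        assert abs(res.coefficients[0]) < 0.1

    def test_invalid_censoring_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig.fast(9, censoring_fraction=1.0)


class TestPellets:
    def test_activity_conservation_within_loss(self):
        cfg = CohortConfig.fast(10)
        pellets, _ = simulate_pellets(cfg)
        by_subject = {}
        for p in pellets:
            by_subject.setdefault(p.subject, {})[p.fraction] = p.measured_activity_Bq
        for subj, d in by_subject.items():
            got = (d["myeloid_enriched"] + d["myeloid_depleted"]) / d["total"]
            assert np.isclose(got, 1 - cfg.pellet_sort_loss_fraction, rtol=1e-9)

    def test_unit_folds_when_configured_null(self):
        from contrapet.scradiotracing import fraction_fold_change

        cfg = CohortConfig.fast(
            11, pellet_fold_tumor_vs_sham=1.0, pellet_fold_tumor_vs_healthy=1.0,
            pellet_n={"tumor": 40, "sham": 40, "healthy": 40},
        )
        pellets, truth = simulate_pellets(cfg)
        groups = {}
        for p in pellets:
            if p.fraction != "myeloid_enriched":
                continue
            grp = p.subject.split("-")[1].rstrip("0123456789")
            d = truth["doses"][p.subject]
            u = per_cell_uptake(
                p, Dosimetry(d["injected_dose_Bq"], d["body_weight_g"])
            )
            groups.setdefault(grp, []).append(u["pct_ID_x_BW_per_cell"])
        out = fraction_fold_change(groups)
        for v in out["fold_changes"].values():
            assert abs(v - 1.0) < 0.25


class TestDynamicPhantom:
    def test_idif_recovers_painted_input(self, tiny_config):
        from contrapet.kinetics import image_derived_input

        ph = simulate_dynamic_subject(tiny_config, grid=16)
        vol = ph["volume"]
        voi = ph["carotid_vois"][0].rasterize(vol) | ph["carotid_vois"][1].rasterize(vol)
        idif = image_derived_input(vol, voi)
        mids = vol.frame_midpoints_min
        # blood voxels carry the frame-averaged input; agreement to ~ the
        # frame-averaging error
        assert np.allclose(idif.at(mids)[3:], ph["input"].at(mids)[3:], rtol=0.1)

    def test_vtr_contrast_matches_truth(self, tiny_config):
        from contrapet.kinetics import image_derived_input, vt_map, vtr_map

        ph = simulate_dynamic_subject(tiny_config, grid=16)
        vol = ph["volume"]
        voi = ph["carotid_vois"][0].rasterize(vol) | ph["carotid_vois"][1].rasterize(vol)
        idif = image_derived_input(vol, voi)
        truth = ph["vt_truth"]
        mask = np.isfinite(truth)
        sub = np.zeros_like(mask)
        sub[:, :, truth.shape[2] // 2] = True
        sub |= ph["pons_voi"].rasterize(vol)
        vt = vt_map(vol, idif, mask & sub)
        vtr = vtr_map(vt, ph["pons_voi"])
        hot = mask & sub & (truth == np.nanmax(truth))
        bg = mask & sub & (truth == 2.0)
        if hot.any():
            ratio = np.nanmean(vtr.data[hot]) / np.nanmean(vtr.data[bg])
            assert abs(ratio - 3.0) < 0.15
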