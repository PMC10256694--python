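"""Synthetic cohort and phantom generators: contracts and recovery."""

import numpy as np
import pandas as pd
import pytest

from datsbr import synth
from datsbr.imaging import extract_regional_sbr
from datsbr.normative import NormativeAgeModel
from datsbr.regions import REGIONS


class TestCohortConfig:
    def test_rejects_all_zero_counts(self):
        cfg = synth.reference_cohort_config(n_hc=0, n_mci=0, n_dlb=0)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_rejects_negative_counts(self):
        cfg = synth.reference_cohort_config(n_hc=-1)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_rejects_missing_region(self):
        cfg = synth.reference_cohort_config()
        bad = {r: p for r, p in cfg.normative_params.items() if r != "SN"}
        cfg2 = synth.reference_cohort_config(normative_params=bad)
        with pytest.raises(ValueError):
            cfg2.validate()

    def test_rejects_nonzero_hc_deficit(self):
        cfg = synth.reference_cohort_config()
        deficits = {g: dict(d) for g, d in cfg.group_deficit.items()}
        deficits["HC"]["SN"] = -0.5
        cfg2 = synth.reference_cohort_config(group_deficit=deficits)
        with pytest.raises(ValueError):
            cfg2.validate()


class TestSimulateCohort:
    def test_determinism_same_seed(self):
        cfg = synth.reference_cohort_config(seed=11)
        s1, b1 = synth.simulate_cohort(cfg)
        s2, b2 = synth.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_different_seeds_differ(self):
        _, b1 = synth.simulate_cohort(synth.reference_cohort_config(seed=1))
        _, b2 = synth.simulate_cohort(synth.reference_cohort_config(seed=2))
        assert not b1[list(REGIONS)].equals(b2[list(REGIONS)])

    def test_null_config_groups_identical_in_expectation(self):
        # no deficits, no link slopes: SBR distributions and flag
        # prevalences must not differ by group beyond sampling noise
        cfg = synth.null_cohort_config(
            seed=3, n_hc=3000, n_mci=3000, n_dlb=3000,
            age_range={g: (60.0, 80.0) for g in ("HC", "MCI-LB", "DLB")})
        subjects, sbr = synth.simulate_cohort(cfg)
        means = sbr.groupby("group")[list(REGIONS)].mean()
        for r in REGIONS:
            assert means[r].max() - means[r].min() < 0.08
        # null VH link has group intercepts only; slopes are all zero, so
        # within each group prevalence equals the intercept probability
        link = [f for f in cfg.clinical_link if f.name == "VH"][0]
        for g in ("MCI-LB", "DLB"):
            prev = subjects.loc[subjects.group == g, "VH"].mean()
            expect = 1 / (1 + np.exp(-link.intercepts[g]))
            assert abs(prev - expect) < 3 * np.sqrt(expect * (1 - expect) / 3000)

    def test_calibrated_dlb_nigral_sbr(self, reference_cohort):
        # DLB nigral deficit of -2.2 z on the calibrated normative line
        # puts the DLB group mean SN-SBR near 0.5
        _, _, sbr = reference_cohort
        dlb_sn = sbr.loc[sbr.group == "DLB", "SN"]
        se = dlb_sn.std(ddof=1) / np.sqrt(len(dlb_sn))
        assert abs(dlb_sn.mean() - 0.5) < 4 * se

    def test_deficit_ordering_sn_most_affected(self, reference_ztable):
        _, z = reference_ztable
        means = z[z.group == "DLB"][list(REGIONS)].mean()
        assert means.idxmin() == "SN"

    def test_normative_parameter_recovery(self):
        # fitting the normative model on a large HC arm recovers the
        # configured intercept/slope within 3 Monte-Carlo SEs
        cfg = synth.reference_cohort_config(seed=5, n_hc=400, n_mci=0,
                                            n_dlb=1)
        _, sbr = synth.simulate_cohort(cfg)
        hc = sbr[sbr.group == "HC"]
        res = NormativeAgeModel(hc).fit()
        age = hc["age"].to_numpy()
        sxx = np.sum((age - age.mean()) ** 2)
        for r in REGIONS:
            true = cfg.normative_params[r]
            p = res.params[r]
            se_slope = true.resid_sd / np.sqrt(sxx)
            se_int = true.resid_sd * np.sqrt(1 / len(age)
                                             + age.mean() ** 2 / sxx)
            assert abs(p.slope - true.slope) < 3 * se_slope
            assert abs(p.intercept - true.intercept) < 3 * se_int

    def test_deficit_recovery(self):
        # group-mean zSBR of a large patient arm recovers the configured
        # deficit within 3 SEs (scored against the true normative line)
        cfg = synth.reference_cohort_config(seed=9, n_hc=1, n_mci=0,
                                            n_dlb=2000)
        _, sbr = synth.simulate_cohort(cfg)
        dlb = sbr[sbr.group == "DLB"]
        for r in REGIONS:
            p = cfg.normative_params[r]
            z = (dlb[r] - (p.intercept + p.slope * dlb["age"])) / p.resid_sd
            se = z.std(ddof=1) / np.sqrt(len(z))
            assert abs(z.mean() - cfg.group_deficit["DLB"][r]) < 3 * se


class TestSimulatePhantom:
    def test_noiseless_pet_values_exact(self):
        cfg = synth.reference_phantom_config(noise_sd=0.0)
        pet, labels, _, _ = synth.simulate_phantom(cfg)
        for lbl, ratio in cfg.true_ratio.items():
            vals = pet.data[labels.data == lbl]
            assert np.allclose(vals, cfg.reference_level * ratio)

    def test_determinism(self):
        cfg = synth.reference_phantom_config(seed=4, noise_sd=0.1,
                                             gm_noise_sd=0.02)
        z = np.array([-1.0, 0.5])
        p1, l1, g1, i1 = synth.simulate_phantom(cfg, z)
        p2, l2, g2, i2 = synth.simulate_phantom(cfg, z)
        assert np.array_equal(p1.data, p2.data)
        assert np.array_equal(l1.data, l2.data)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(g1, g2))
        assert np.array_equal(i1, i2)

    def test_overlapping_rois_rejected(self):
        cfg = synth.reference_phantom_config()
        rois = list(cfg.rois)
        clash = synth.RoiBox(50, "clash", "NA", rois[0].start, rois[0].stop)
        cfg2 = synth.reference_phantom_config(rois=tuple(rois + [clash]),
                                              true_ratio={**cfg.true_ratio,
                                                          50: 1.0})
        with pytest.raises(ValueError, match="overlap"):
            cfg2.validate()

    def test_gm_effect_plants_atrophy(self):
        cfg = synth.small_phantom_config(
            gm_effect=0.05, gm_noise_sd=0.0,
            gm_cluster=((4, 10), (4, 10), (4, 10)))
        _, _, gm, _ = synth.simulate_phantom(cfg, sn_z=np.array([-2.0, 0.0]))
        inside = gm[0].data[5, 5, 5] - gm[1].data[5, 5, 5]
        outside = gm[0].data[1, 1, 1] - gm[1].data[1, 1, 1]
        assert inside == pytest.approx(0.05 * 2.0)
        assert outside == pytest.approx(0.0)

    def test_roundtrip_extraction_recovers_ratios(self):
        # noiseless phantom -> full extraction chain -> exact ratios
        cfg = synth.reference_phantom_config(noise_sd=0.0)
        pet, labels, _, _ = synth.simulate_phantom(cfg)
        row = extract_regional_sbr(pet, labels)
        assert row["SN"] == pytest.approx(1.1)
        assert row["AP"] == pytest.approx(3.2)
        assert row["PP"] == pytest.approx(3.2)
        assert row["AC"] == pytest.approx(3.1)
        assert row["PC"] == pytest.approx(3.1)
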