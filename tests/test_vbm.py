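"""Voxel-wise GLM, smoothing, cluster labeling and permutation FWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from datsbr import synth, vbm


def _covariates(rng, n):
    return pd.DataFrame({"age": rng.normal(75, 7, n),
                         "sex": rng.integers(0, 2, n),
                         "education": rng.normal(9, 4, n),
                         "icv": rng.normal(1400, 120, n)})


class TestGmMask:
    def test_uniform_half_probability_full_mask(self):
        maps = [np.full((4, 4, 4), 0.5)] * 3
        assert vbm.build_gm_mask(maps).all()

    def test_low_probability_errors(self):
        maps = [np.full((4, 4, 4), 0.2)] * 3
        with pytest.raises(ValueError, match="empty"):
            vbm.build_gm_mask(maps)

    def test_thresholding_by_hand(self):
        m = np.full((4, 4, 4), 0.1)
        m[:2] = 0.6
        mask = vbm.build_gm_mask([m, m])
        assert mask[:2].all() and not mask[2:].any()


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        v = rng.normal(size=(6, 6, 6))
        out = vbm.smooth_volume(v, 0.0)
        assert np.array_equal(out, v)
        assert out is not v

    def test_impulse_mass_preserved(self):
        v = np.zeros((21, 21, 21))
        v[10, 10, 10] = 1.0
        out = vbm.smooth_volume(v, fwhm=6.0, voxel_size=1.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        assert out[10, 10, 10] < 1.0
        # sigma in voxels = 6/2.3548 = 2.548
        assert out[10, 10, 10] == pytest.approx(
            (1 / (np.sqrt(2 * np.pi) * 2.548)) ** 3, rel=0.05)

    def test_constant_volume_unchanged(self):
        v = np.full((8, 8, 8), 3.3)
        assert np.allclose(vbm.smooth_volume(v, 6.0, 2.0), 3.3)

    def test_negative_fwhm_errors(self):
        with pytest.raises(ValueError):
            vbm.smooth_volume(np.zeros((3, 3, 3)), -1.0)


class TestVoxelwiseGlm:
    def test_null_t_follows_t_distribution(self):
        rng = np.random.default_rng(0)
        n = 30
        gm = [rng.normal(size=(8, 8, 8)) for _ in range(n)]
        pred = rng.normal(size=n)
        t_map, dof = vbm.voxelwise_glm(gm, pred, _covariates(rng, n))
        ks = stats.kstest(t_map.ravel(), stats.t(dof).cdf)
        assert ks.pvalue > 0.01

    def test_planted_block_raises_t(self):
        rng = np.random.default_rng(1)
        n = 40
        pred = rng.normal(size=n)
        gm = []
        for i in range(n):
            v = rng.normal(0, 0.1, (8, 8, 8))
            v[2:5, 2:5, 2:5] += 0.3 * pred[i]
            gm.append(v)
        t_map, _ = vbm.voxelwise_glm(gm, pred, _covariates(rng, n))
        block = np.zeros((8, 8, 8), bool)
        block[2:5, 2:5, 2:5] = True
        assert np.abs(t_map[block]).mean() > np.abs(t_map[~block]).mean()

    def test_single_voxel_matches_statsmodels_t(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 25
        pred = rng.normal(size=n)
        cov = _covariates(rng, n)
        y = 0.2 * pred + rng.normal(size=n)
        gm = [np.full((1, 1, 1), yi) for yi in y]
        t_map, dof = vbm.voxelwise_glm(gm, pred, cov)
        X = sm.add_constant(pd.concat([cov, pd.Series(pred, name="x")],
                                      axis=1))
        res = sm.OLS(y, X).fit()
        assert t_map[0, 0, 0] == pytest.approx(res.tvalues["x"], rel=1e-8)
        assert dof == int(res.df_resid)

    def test_rank_deficient_design_errors(self, rng):
        n = 20
        cov = _covariates(rng, n)
        cov["dup"] = cov["age"] * 2.0
        gm = [rng.normal(size=(3, 3, 3)) for _ in range(n)]
        with pytest.raises(ValueError, match="rank"):
            vbm.voxelwise_glm(gm, cov["age"].to_numpy(), cov)


class TestClusterCorrect:
    def test_cluster_labeling_matches_flood_fill(self, rng):
        # 26-connectivity labeling against a brute-force flood fill
        supra = rng.uniform(size=(10, 10, 10)) < 0.1

        def flood(mask):
            seen = np.zeros_like(mask)
            sizes = []
            idx = np.argwhere(mask)
            for start in map(tuple, idx):
                if seen[start]:
                    continue
                stack, size = [start], 0
                seen[start] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in np.ndindex(3, 3, 3):
                        q = tuple(np.array(p) + np.array(d) - 1)
                        if all(0 <= qi < 10 for qi in q) and mask[q] \
                                and not seen[q]:
                            seen[q] = True
                            stack.append(q)
                sizes.append(size)
            return sorted(sizes)

        lab, nlab = ndimage.label(supra, structure=np.ones((3, 3, 3)))
        ours = sorted(np.bincount(lab.ravel())[1:].tolist()) if nlab else []
        assert ours == flood(supra)

    def test_strong_planted_cluster_saturates(self):
        rng = np.random.default_rng(3)
        n, n_perm = 40, 200
        pred = rng.normal(size=n)
        gm = []
        for i in range(n):
            v = rng.normal(0, 0.05, (10, 10, 10))
            v[3:7, 3:7, 3:7] += 0.5 * pred[i]
            gm.append(v)
        rep = vbm.cluster_correct(gm, pred, _covariates(rng, n),
                                  n_perm=n_perm, seed=0)
        assert rep.clusters
        top = rep.clusters[0]
        assert top.p_fwe == pytest.approx(1 / (1 + n_perm))
        assert top.size >= 4 ** 3

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(4)
        n = 25
        pred = rng.normal(size=n)
        gm = [vbm.smooth_volume(np.random.default_rng(100 + i)
                                .normal(0, 0.05, (8, 8, 8)), 4.0, 2.0)
              for i in range(n)]
        cov = _covariates(rng, n)
        r1 = vbm.cluster_correct(gm, pred, cov, n_perm=120, seed=9)
        r2 = vbm.cluster_correct(gm, pred, cov, n_perm=120, seed=9)
        assert r1.clusters == r2.clusters
        assert np.array_equal(r1.perm_max_sizes, r2.perm_max_sizes)

    def test_low_n_perm_warns_and_empty_report_ok(self):
        rng = np.random.default_rng(5)
        n = 20
        gm = [np.full((4, 4, 4), 0.5) + rng.normal(0, 1e-6, (4, 4, 4))
              for _ in range(n)]
        with pytest.warns(UserWarning, match="n_perm"):
            rep = vbm.cluster_correct(gm, rng.normal(size=n), None,
                                      n_perm=99, seed=0)
        assert isinstance(rep.clusters, list)

    def test_null_fwe_not_inflated(self):
        # light version of the full calibration experiment: under the
        # global null the chance of any significant cluster stays near the
        # nominal 5% level (upper binomial bound at 20 repetitions)
        hits = 0
        reps = 20
        for rep in range(reps):
            ph = synth.small_phantom_config(seed=300 + rep, gm_noise_sd=0.05,
                                            smooth_fwhm=6.0)
            r2 = np.random.default_rng(400 + rep)
            _, _, gm_maps, icv = synth.simulate_phantom(ph, np.zeros(30))
            cov = _covariates(r2, 30)
            cov["icv"] = icv
            out = vbm.cluster_correct([m.data for m in gm_maps],
                                      r2.normal(size=30), cov,
                                      n_perm=200, seed=rep)
            hits += bool(out.significant())
        assert hits <= 5  # P(X > 5 | Bin(20, 0.05)) < 0.0003


class TestEffectSize:
    def test_zero_t_zero_r(self):
        assert vbm.effect_size_map(np.zeros((2, 2, 2)), 10).sum() == 0.0

    def test_hand_value(self):
        r = vbm.effect_size_map(np.array([[[2.0]]]), 4)
        assert r[0, 0, 0] == pytest.approx(2 / np.sqrt(8))

    def test_odd_symmetry_and_monotone(self, rng):
        t = rng.normal(size=(5, 5, 5))
        r = vbm.effect_size_map(t, 12)
        assert np.allclose(vbm.effect_size_map(-t, 12), -r)
        flat_t = np.sort(t.ravel())
        flat_r = np.sort(r.ravel())
        assert np.all(np.diff(vbm.effect_size_map(flat_t, 12)) >= 0)
        assert np.abs(r).max() < 1.0
        assert np.allclose(flat_r, vbm.effect_size_map(flat_t, 12))
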