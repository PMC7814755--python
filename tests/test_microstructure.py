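import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from paintract.density import ImageGrid
from paintract.gradients import GradientScheme, make_scheme
from paintract.microstructure import (Prior, _shell_features, batch_signal,
                                      estimate_map, mask_mean, train_estimator)
from paintract.phantom import synthesize_dwi


def single_voxel_params(vi, ve, vc, d_a=2.0, dirs=(0.0, 0.0, 1.0)):
    return {"v_intra": np.array([vi]), "v_extra": np.array([ve]),
            "v_csf": np.array([vc]), "d_a": np.array([d_a]),
            "d_e_par": np.array([2.0]), "d_e_perp": np.array([0.7]),
            "dirs": np.array([dirs], dtype=float)}


def noisy_features(params, scheme, snr, rng):
    sig = batch_signal(params, scheme)
    s = 1.0 / snr
    noisy = np.sqrt((sig + rng.normal(0, s, sig.shape)) ** 2
                    + rng.normal(0, s, sig.shape) ** 2)
    return _shell_features(noisy, scheme)


class TestTrainEstimator:
    def test_same_seed_identical_coefficients(self, scheme3):
        a = train_estimator(scheme3, n_samples=12_000, seed=4)
        b = train_estimator(scheme3, n_samples=12_000, seed=4)
        assert np.array_equal(a.coef, b.coef)

    def test_heldout_noise_free_correlation(self, scheme3, estimator3):
        prior = Prior()
        params = prior.sample(2000, np.random.default_rng(99))
        feats = _shell_features(batch_signal(params, scheme3), scheme3)
        pred = estimator3.predict(feats)
        r = np.corrcoef(pred["v_intra"], params["v_intra"])[0, 1]
        assert r >= 0.95

    def test_pure_csf_maps_to_low_v_intra(self, scheme3, estimator3):
        feats = _shell_features(
            batch_signal(single_voxel_params(0.0, 0.0, 1.0), scheme3), scheme3)
        pred = estimator3.predict(feats)
        assert pred["v_intra"][0] <= 0.1
        assert pred["v_csf"][0] >= 0.8

    def test_fraction_simplex_after_clipping(self, scheme3, estimator3):
        rng = np.random.default_rng(12)
        feats = rng.uniform(0, 1, (100, 3))  # arbitrary, even unphysical features
        pred = estimator3.predict(feats)
        total = pred["v_intra"] + pred["v_extra"] + pred["v_csf"]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        for n in ("v_intra", "v_extra", "v_csf"):
            assert np.all(pred[n] >= 0) and np.all(pred[n] <= 1)

    def test_single_shell_warns(self):
        sch = make_scheme(shell_bvalues=(1.0,), n_dirs=12)
        with pytest.warns(UserWarning, match="single-shell"):
            train_estimator(sch, n_samples=10_000, seed=0)

    def test_monotone_in_true_v_intra(self, scheme3, estimator3):
        rng = np.random.default_rng(5)
        grid_vi = np.linspace(0.05, 0.9, 8)
        means = []
        for vi in grid_vi:
            ve = (1 - vi) * 0.7
            vc = (1 - vi) * 0.3
            p = single_voxel_params(vi, ve, vc)
            p = {k: np.repeat(v, 50, axis=0) for k, v in p.items()}
            dirs = rng.standard_normal((50, 3))
            p["dirs"] = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
            feats = noisy_features(p, scheme3, snr=50, rng=rng)
            means.append(estimator3.predict(feats)["v_intra"].mean())
        assert np.all(np.diff(means) > 0)

    def test_noise_robustness_rmse_ordering(self, scheme3, estimator3):
        prior = Prior()
        params = prior.sample(2000, np.random.default_rng(21))
        rng = np.random.default_rng(22)
        rmse = {}
        for snr in (20, 100):
            feats = noisy_features(params, scheme3, snr=snr, rng=rng)
            err = estimator3.predict(feats)["v_intra"] - params["v_intra"]
            rmse[snr] = np.sqrt((err**2).mean())
        assert rmse[20] >= rmse[100]

    def test_rotation_invariance_of_estimates(self, scheme3, estimator3):
        prior = Prior()
        params = prior.sample(500, np.random.default_rng(31))
        rot = Rotation.random(random_state=3).as_matrix()
        feats1 = _shell_features(batch_signal(params, scheme3), scheme3)
        rot_scheme = GradientScheme(bvalues=scheme3.bvalues,
                                    directions=scheme3.directions @ rot.T,
                                    shell_ids=scheme3.shell_ids)
        feats2 = _shell_features(batch_signal(params, rot_scheme), scheme3)
        p1 = estimator3.predict(feats1)["v_intra"]
        p2 = estimator3.predict(feats2)["v_intra"]
        assert np.sqrt(((p1 - p2) ** 2).mean()) < 0.01


class TestEstimateMap:
    def test_phantom_tube_recovery(self, phantom_single, scheme3, estimator3):
        dwi = synthesize_dwi(phantom_single, scheme3)
        maps = estimate_map(dwi, scheme3, estimator3, mask=phantom_single.tube_mask)
        tube_vi = maps["v_intra"][phantom_single.tube_mask]
        assert abs(np.nanmean(tube_vi) - 0.60) <= 0.05

    def test_background_csf_recovery(self, phantom_single, scheme3, estimator3):
        dwi = synthesize_dwi(phantom_single, scheme3)
        bg = ~phantom_single.tube_mask
        sub = np.zeros_like(bg)
        sub[::4, ::4, ::4] = True
        sub &= bg
        maps = estimate_map(dwi, scheme3, estimator3, mask=sub)
        assert np.nanmean(maps["v_csf"][sub]) >= 0.85

    def test_invalid_b0_flagged(self, scheme3, estimator3):
        dwi = np.ones((2, 2, 2, scheme3.n_volumes))
        dwi[0, 0, 0] = 0.0
        maps = estimate_map(dwi, scheme3, estimator3)
        assert not maps["valid"][0, 0, 0]
        assert np.isnan(maps["v_intra"][0, 0, 0])
        assert maps["valid"][1, 1, 1]

    def test_volume_count_mismatch_raises(self, scheme3, estimator3):
        with pytest.raises(ValueError):
            estimate_map(np.ones((2, 2, 2, 5)), scheme3, estimator3)


class TestMaskMean:
    def test_uniform_volume(self):
        vol = np.full((5, 5, 5), 0.6)
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        m, n = mask_mean(vol, mask)
        assert m == pytest.approx(0.6) and n == 8

    def test_half_and_half(self):
        vol = np.zeros((2, 2, 2))
        vol[0] = 0.4
        vol[1] = 0.8
        m, n = mask_mean(vol, np.ones((2, 2, 2), dtype=bool))
        assert m == pytest.approx(0.6) and n == 8

    def test_matches_brute_force_on_random(self):
        rng = np.random.default_rng(8)
        vol = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        m, n = mask_mean(vol, mask)
        assert m == pytest.approx(vol[mask].mean())
        assert n == int(mask.sum())

    def test_nan_voxels_excluded_and_empty_mask(self):
        vol = np.full((3, 3, 3), np.nan)
        vol[0, 0, 0] = 0.5
        m, n = mask_mean(vol, np.ones((3, 3, 3), dtype=bool))
        assert m == pytest.approx(0.5) and n == 1
        m, n = mask_mean(vol, np.zeros((3, 3, 3), dtype=bool))
        assert np.isnan(m) and n == 0
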