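import numpy as np
import pytest
from scipy import stats

import skinfab as sf
from skinfab.calibration import (
    build_patch_set,
    compare_methods,
    fit_lut,
    fit_mlp,
    fit_regression,
    loocv,
    make_levels,
    measure_patch_set,
    pigment_color,
    plant_linear_targets,
    rgb_to_cmyk,
)


class TestLevels:
    @pytest.mark.parametrize(
        "n, lo, hi, expected",
        [
            (2, 0.0, 1.0, [0.0, 1.0]),
            (5, 0.0, 2.0, [0.0, 0.5, 1.0, 1.5, 2.0]),
        ],
    )
    def test_equally_spaced(self, n, lo, hi, expected):
        assert np.allclose(make_levels(n, lo, hi), expected)

    def test_thirty_levels_step(self):
        levels = make_levels(30)
        assert len(levels) == 30
        assert np.allclose(np.diff(levels), 1 / 29)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            make_levels(1)


class TestPigmentColor:
    def test_zero_concentration_is_white(self):
        assert np.allclose(pigment_color(0.0, np.ones(3), np.zeros(3)), 1.0)

    def test_single_channel_density(self):
        rgb = pigment_color(1.0, np.array([np.log(10), 0, 0]), np.zeros(3))
        assert np.allclose(rgb, [0.1, 1.0, 1.0])

    def test_monotone_in_concentration(self, basis):
        sweep = pigment_color(
            np.linspace(0, 2, 20), basis.melanin_vector, basis.bias
        )
        assert np.all(np.diff(sweep, axis=0) <= 1e-15)


class TestRgbToCmyk:
    @pytest.mark.parametrize(
        "rgb, cmyk",
        [
            ([1, 1, 1], [0, 0, 0, 0]),
            ([0, 0, 0], [0, 0, 0, 1]),
            ([1, 0, 0], [0, 1, 1, 0]),
        ],
    )
    def test_under_colour_removal(self, rgb, cmyk):
        assert np.allclose(rgb_to_cmyk(np.array(rgb, float)), cmyk)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_cmyk(np.array([1.2, 0.0, 0.0]))


class TestPatchSet:
    def test_grid_is_complete_and_unique(self, patch_set):
        assert len(patch_set) == 900
        pairs = set(zip(patch_set.mel_idx.tolist(), patch_set.hem_idx.tolist()))
        assert len(pairs) == 900

    def test_single_patch_grid(self, basis):
        assert len(build_patch_set(1, 1, basis)) == 1

    def test_small_grid_count(self, basis):
        assert len(build_patch_set(3, 5, basis)) == 15

    def test_csv_round_trip(self, patch_set, tmp_path):
        path = tmp_path / "patches.csv"
        patch_set.to_csv(path)
        back = sf.PatchSet.from_csv(path)
        assert len(back) == len(patch_set)
        assert np.allclose(back.features(), patch_set.features())
        assert np.allclose(back.targets(), patch_set.targets())


class TestLUT:
    def test_exact_hit_returns_stored_cmyk(self, measured_set):
        lut = fit_lut(measured_set)
        pred = lut.predict(measured_set.features()[:10])
        assert np.array_equal(pred, measured_set.targets()[:10])

    def test_matches_exhaustive_scan(self, measured_set):
        lut = fit_lut(measured_set)
        rng = np.random.default_rng(4)
        queries = rng.uniform(0.05, 1.0, (200, 6))
        pred = lut.predict(queries)
        feats = measured_set.features()
        for q, p in zip(queries, pred):
            idx = int(np.argmin(np.sqrt(((feats - q) ** 2).mean(axis=1))))
            assert np.array_equal(p, measured_set.targets()[idx])

    def test_tie_breaks_to_lower_index(self):
        ps = build_patch_set(2, 2, sf.default_basis())
        # symmetric features around the query guarantee an exact tie
        ps.mel_rgb = np.array([[0.2] * 3, [0.4] * 3, [0.2] * 3, [0.4] * 3])
        ps.hem_rgb = np.array([[0.5] * 3] * 4)
        lut = fit_lut(ps)
        query = np.array([[0.3] * 3 + [0.5] * 3])
        assert np.array_equal(lut.predict(query)[0], ps.targets()[0])


class TestRegression:
    def test_plant_and_recover_coefficients(self, planted_set):
        coef_mel_true = np.array(
            [
                [0.05, -0.10, 0.02, 0.30],
                [-0.08, 0.03, 0.06, 0.40],
                [0.02, 0.09, -0.07, 0.35],
                [-0.04, -0.05, 0.08, 0.25],
            ]
        )
        model = fit_regression(planted_set)
        assert np.abs(model.coef_mel - coef_mel_true).max() <= 1e-8
        pred = model.predict(planted_set.features())
        rmse = np.sqrt(((pred - planted_set.targets()) ** 2).mean())
        assert rmse <= 1e-8

    def test_constant_targets_give_zero_slopes(self, measured_set):
        from dataclasses import replace

        ps = replace(
            measured_set,
            mel_cmyk=np.full((len(measured_set), 4), 0.3),
            hem_cmyk=np.full((len(measured_set), 4), 0.6),
        )
        model = fit_regression(ps)
        assert np.abs(model.coef_mel[:, :3]).max() <= 1e-8
        assert np.allclose(model.coef_mel[:, 3], 0.3)
        assert np.allclose(model.coef_hem[:, 3], 0.6)

    def test_in_sample_rmse_tracks_target_noise(self, planted_set):
        from dataclasses import replace

        rng = np.random.default_rng(8)
        sigma = 0.02
        noisy = replace(
            planted_set,
            mel_cmyk=planted_set.mel_cmyk + rng.normal(0, sigma, (900, 4)),
            hem_cmyk=planted_set.hem_cmyk + rng.normal(0, sigma, (900, 4)),
        )
        model = fit_regression(noisy)
        model.clip = False
        pred = model.predict(noisy.features())
        rmse = np.sqrt(((pred - noisy.targets()) ** 2).mean())
        assert rmse == pytest.approx(sigma, rel=0.2)

    def test_collinear_nominal_grid_rejected(self, patch_set):
        # nominal encodings are exact 1-D sweeps per pigment: rank-deficient
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_regression(patch_set)


class TestMLP:
    def test_parameter_count_is_1414(self, planted_set):
        mlp = fit_mlp(planted_set, epochs=2, seed=0)
        assert mlp.n_parameters() == (1414, 1414)

    def test_seed_reproducible(self, planted_set):
        a = fit_mlp(planted_set, epochs=3, seed=5)
        b = fit_mlp(planted_set, epochs=3, seed=5)
        feats = planted_set.features()
        assert np.array_equal(a.predict(feats), b.predict(feats))

    def test_thirty_epochs_fit_linear_targets(self, planted_set):
        mlp = fit_mlp(planted_set, epochs=30, seed=0)
        pred = mlp.predict(planted_set.features())
        rmse = np.sqrt(((pred - planted_set.targets()) ** 2).mean())
        assert rmse <= 0.05

    def test_loss_curve_recorded(self, planted_set):
        mlp = fit_mlp(planted_set, epochs=4, seed=0)
        mel_curve, hem_curve = mlp.loss_curves()
        assert len(mel_curve) == 4 and len(hem_curve) == 4


class TestLOOCV:
    def test_regression_exact_on_model_class(self, planted_set):
        rmse, per_patch = loocv(planted_set, "regression")
        assert rmse <= 1e-6
        assert per_patch.shape == (900,)

    def test_lut_two_patch_folds_predict_the_other(self, basis):
        ps = measure_patch_set(build_patch_set(2, 2, basis), seed=0)
        from dataclasses import replace

        two = replace(
            ps,
            mel_idx=np.array([0, 1]), hem_idx=np.array([0, 0]),
            mel_conc=ps.mel_conc[:2], hem_conc=ps.hem_conc[:2],
            mel_rgb=ps.mel_rgb[:2], hem_rgb=ps.hem_rgb[:2],
            mel_cmyk=ps.mel_cmyk[:2], hem_cmyk=ps.hem_cmyk[:2],
            n_mel=2, n_hem=1,
        )
        rmse, per_patch = loocv(two, "lut")
        expected = np.sqrt(
            ((two.targets()[0] - two.targets()[1]) ** 2).mean()
        )
        assert np.allclose(per_patch, expected)

    def test_mlp_loocv_small_grid_completes(self, basis):
        ps = measure_patch_set(build_patch_set(3, 3, basis), seed=0)
        rmse, per_patch = loocv(ps, "mlp", seed=0, epochs=5)
        assert np.isfinite(rmse) and per_patch.shape == (9,)

    def test_unknown_method_rejected(self, measured_set):
        with pytest.raises(ValueError, match="unknown method"):
            loocv(measured_set, "kriging")


class TestCompareMethods:
    def test_identical_errors_flagged_degenerate(self):
        e = np.linspace(0.01, 0.05, 30)
        res = compare_methods(e, e)
        assert res.degenerate and not res.significant and res.p_value == 1.0

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.01, 0.05, 100)
        res = compare_methods(a, a + 0.02 + rng.normal(0, 1e-4, 100))
        assert res.significant and res.p_value < 1e-6

    def test_matches_textbook_paired_t(self):
        a = np.array([0.10, 0.12, 0.09, 0.11, 0.13])
        b = np.array([0.08, 0.11, 0.10, 0.09, 0.10])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        res = compare_methods(a, b)
        assert res.p_value == pytest.approx(p_manual, rel=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, 50)
        b = rng.uniform(0, 1, 50)
        assert compare_methods(a, b).p_value == pytest.approx(
            compare_methods(b, a).p_value
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(np.zeros(3), np.zeros(4))


class TestEstimatorRanges:
    @pytest.mark.parametrize("method", ["lut", "regression", "mlp"])
    def test_predictions_stay_in_unit_interval(self, method, planted_set):
        fitters = {
            "lut": lambda ps: fit_lut(ps),
            "regression": lambda ps: fit_regression(ps),
            "mlp": lambda ps: fit_mlp(ps, epochs=3, seed=0),
        }
        model = fitters[method](planted_set)
        rng = np.random.default_rng(6)
        queries = rng.uniform(0.05, 1.0, (50, 6))
        pred = model.predict(queries)
        assert np.all(pred >= 0.0) and np.all(pred <= 1.0)
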