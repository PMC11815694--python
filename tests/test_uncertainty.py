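import numpy as np
import pytest

import sctuq as sq
from sctuq.core import Volume
from sctuq.uncertainty import (McdConfig, McdEnsemble, UncertaintyCalibrator,
                               apply_calibration, combine_uncertainty,
                               fit_calibration, mcd_sample, model_variance,
                               normal_interval_coverage, uncertainty_maps)


def _vol(vals, semantics="normalized"):
    return Volume(np.asarray(vals, dtype=float), (1.0, 1.0, 1.0), semantics=semantics)


def _ensemble(arrays):
    samples = [_vol(a) for a in arrays]
    stack = np.stack([s.values.astype(float) for s in samples])
    return McdEnsemble(samples=samples, mean=_vol(stack.mean(axis=0)),
                       log_scale_samples=[_vol(np.zeros_like(arrays[0]), "scale")
                                          for _ in arrays])


class TestModelVariance:
    def test_three_sample_voxel(self):
        arrays = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)]
        var = model_variance(_ensemble(arrays))
        assert var.values == pytest.approx(2.0 / 3.0)  # divisor T, not T-1

    def test_identical_samples_give_zero(self):
        var = model_variance(_ensemble([np.ones((2, 2, 2))] * 5))
        assert np.all(var.values == 0.0)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(3)
        arrays = [rng.normal(size=(8, 8, 8)) for _ in range(7)]
        ens = _ensemble(arrays)
        var = model_variance(ens).values.astype(np.float64)
        stored = [s.values.astype(np.float64) for s in ens.samples]
        oracle = np.zeros((8, 8, 8))
        mean = sum(stored) / len(stored)
        for a in stored:
            oracle += (a - mean) ** 2
        oracle /= len(stored)
        assert np.abs(var - oracle).max() < 1e-10

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        arrays = [rng.normal(size=(4, 4, 4)) for _ in range(5)]
        a = model_variance(_ensemble(arrays)).values
        b = model_variance(_ensemble(arrays[::-1])).values
        assert np.allclose(a, b, atol=1e-12)


class TestCombine:
    def test_pythagorean_triple(self):
        out = combine_uncertainty(_vol(np.full((2, 2, 2), 3.0), "scale"),
                                  _vol(np.full((2, 2, 2), 4.0), "scale"))
        assert out.values == pytest.approx(5.0)

    def test_zero_component_is_identity(self):
        s = np.random.default_rng(0).uniform(0, 2, (4, 4, 4))
        out = combine_uncertainty(_vol(s, "scale"), _vol(np.zeros((4, 4, 4)), "scale"))
        assert out.values == pytest.approx(np.asarray(s, dtype=np.float32), abs=1e-6)
        zz = combine_uncertainty(_vol(np.zeros((2, 2, 2)), "scale"),
                                 _vol(np.zeros((2, 2, 2)), "scale"))
        assert np.all(zz.values == 0.0)

    def test_symmetric_and_monotone(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (2, 4, 4, 4))
        ab = combine_uncertainty(_vol(a, "scale"), _vol(b, "scale")).values
        ba = combine_uncertainty(_vol(b, "scale"), _vol(a, "scale")).values
        assert np.allclose(ab, ba)
        bigger = combine_uncertainty(_vol(a + 0.5, "scale"), _vol(b, "scale")).values
        assert np.all(bigger > ab)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            combine_uncertainty(_vol(np.full((2, 2, 2), -1.0), "scale"),
                                _vol(np.zeros((2, 2, 2)), "scale"))


class TestMcd:
    def test_config_contracts(self):
        with pytest.raises(ValueError):
            McdConfig(T=1)
        with pytest.raises(ValueError):
            McdConfig(dropout=0.0)

    def test_vanishing_dropout_reduces_to_deterministic(self, tiny_model, small_cohort):
        cbct = sq.clip_and_normalize(small_cohort[0].cbct)
        det = tiny_model.predict(cbct)
        ens = mcd_sample(tiny_model, cbct, McdConfig(T=3, dropout=1e-9, seed=0))
        for s in ens.samples:
            assert np.allclose(s.values, det.sct.values, atol=1e-6)

    def test_seeded_ensembles_are_bit_identical(self, tiny_model, small_cohort):
        cbct = sq.clip_and_normalize(small_cohort[0].cbct)
        a = mcd_sample(tiny_model, cbct, McdConfig(T=4, dropout=0.3, seed=9))
        b = mcd_sample(tiny_model, cbct, McdConfig(T=4, dropout=0.3, seed=9))
        for x, y in zip(a.samples, b.samples):
            assert np.array_equal(x.values, y.values)

    def test_samples_are_distinct_and_mean_recomputable(self, tiny_model, small_cohort):
        cbct = sq.clip_and_normalize(small_cohort[0].cbct)
        ens = mcd_sample(tiny_model, cbct, McdConfig(T=5, dropout=0.3, seed=1))
        assert not np.array_equal(ens.samples[0].values, ens.samples[1].values)
        stack = np.stack([s.values.astype(float) for s in ens.samples])
        assert np.allclose(ens.mean.values, stack.mean(axis=0), atol=1e-12)
        maps = uncertainty_maps(ens, units="HU")
        assert np.all(maps.sigma_total.values >= maps.sigma_model.values - 1e-6)


class TestCalibration:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        sigma = rng.uniform(0.1, 2.0, (8, 8, 8))
        cal = fit_calibration([_vol(sigma, "scale")], [_vol(2.0 * sigma, "scale")],
                              [_vol(np.ones_like(sigma), "mask")])
        assert cal.slope_ == pytest.approx(2.0, abs=1e-6)
        assert cal.intercept_ == pytest.approx(0.0, abs=1e-6)

    def test_exact_affine_relation(self):
        rng = np.random.default_rng(1)
        sigma = rng.uniform(0.1, 2.0, (8, 8, 8))
        cal = fit_calibration([_vol(sigma, "scale")], [_vol(sigma + 0.1, "scale")],
                              [_vol(np.ones_like(sigma), "mask")])
        assert cal.slope_ == pytest.approx(1.0, abs=1e-6)
        assert cal.intercept_ == pytest.approx(0.1, abs=1e-6)

    def test_independent_error_gives_flat_fit(self):
        rng = np.random.default_rng(2)
        n = 32
        sigma = rng.uniform(0.5, 1.5, (n, n, n))
        error = rng.uniform(0.0, 1.0, (n, n, n))  # independent of sigma
        cal = fit_calibration([_vol(sigma, "scale")], [_vol(error, "scale")],
                              [_vol(np.ones_like(sigma), "mask")])
        # OLS slope s.e. ~ sd(e)/(sd(sigma)*sqrt(n^3)); 5 s.e. tolerance
        se = np.std(error) / (np.std(sigma) * np.sqrt(n ** 3))
        assert abs(cal.slope_) < 5 * se
        assert cal.intercept_ == pytest.approx(error.mean(), abs=5 * se)

    def test_apply_identity_direct_and_floor(self):
        sigma = _vol(np.full((2, 2, 2), 0.5), "scale")
        ident = UncertaintyCalibrator()
        ident.slope_, ident.intercept_, ident.n_voxels_, ident.residual_var_ = 1.0, 0.0, 8, 0.0
        assert np.allclose(apply_calibration(ident, sigma).values, 0.5)
        double = UncertaintyCalibrator()
        double.slope_, double.intercept_, double.n_voxels_, double.residual_var_ = 2.0, 0.0, 8, 0.0
        assert np.allclose(double.transform(sigma).values, 1.0)
        neg = UncertaintyCalibrator(floor=0.01)
        neg.slope_, neg.intercept_, neg.n_voxels_, neg.residual_var_ = -1.0, 0.0, 8, 0.0
        assert np.allclose(neg.transform(sigma).values, 0.01)

    def test_too_few_voxels_and_unfitted_raise(self):
        tiny = np.ones((1, 2, 2))
        m = np.zeros((1, 2, 2)); m[0, 0, 0] = 1.0
        with pytest.raises(ValueError):
            fit_calibration([Volume(tiny, (1, 1, 1), semantics="scale")],
                            [Volume(tiny, (1, 1, 1), semantics="scale")],
                            [Volume(m, (1, 1, 1), semantics="mask")])
        with pytest.raises(RuntimeError):
            UncertaintyCalibrator().transform(_vol(tiny.repeat(2, 0), "scale"))

    def test_save_load_round_trip(self, tmp_path):
        cal = UncertaintyCalibrator()
        cal.slope_, cal.intercept_, cal.n_voxels_, cal.residual_var_ = 1.5, 0.2, 100, 0.01
        cal.save(tmp_path / "cal.json")
        back = UncertaintyCalibrator.load(tmp_path / "cal.json")
        assert back.slope_ == 1.5 and back.intercept_ == 0.2


def test_normal_coverage_is_three_sigma():
    cov = normal_interval_coverage(3.0, n=1_000_000, seed=4)
    assert cov == pytest.approx(99.73, abs=0.1)
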