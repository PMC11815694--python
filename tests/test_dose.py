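import numpy as np
import pytest

import sctuq as sq
from sctuq.core import StructureSet, Volume
from sctuq.dose import (BeamConfig, DoseEngine, compute_dose,
                        dose_ensemble_stats, dvh, dvh_band, gamma_index,
                        subset_variance_mae)


def _water_phantom(shape=(32, 16, 16), spacing=(2.0, 2.0, 2.0), hu=0.0):
    """Uniform body with a central PTV."""
    vals = np.full(shape, hu)
    image = Volume(vals, spacing, semantics="HU")
    ptv = np.zeros(shape)
    c = [s // 2 for s in shape]
    ptv[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2, c[2] - 2:c[2] + 2] = 1.0
    structures = StructureSet({
        "external": Volume(np.ones(shape), spacing, semantics="mask"),
        "ptv": Volume(ptv, spacing, semantics="mask"),
    })
    return image, structures


def _gy(vals, spacing=(2.0, 2.0, 2.0)):
    return Volume(np.asarray(vals, dtype=float), spacing, semantics="Gy")


class TestDoseEngine:
    def test_depth_dose_monotone_beyond_buildup(self):
        image, structures = _water_phantom()
        beams = BeamConfig(directions=((1.0, 0.0, 0.0),), aperture_radius_mm=50.0,
                           buildup_mm=10.0)
        dose = compute_dose(image, beams, structures)
        axis = dose.values[:, 8, 8].astype(float)
        start = int(np.ceil(10.0 / 2.0)) + 1  # past the build-up region
        assert np.all(np.diff(axis[start:]) <= 1e-6)

    def test_bone_slab_attenuates_downstream(self):
        image, structures = _water_phantom()
        beams = BeamConfig(directions=((1.0, 0.0, 0.0),), aperture_radius_mm=50.0)
        water = compute_dose(image, beams, structures).values[24, 8, 8]
        vals = image.values.copy()
        vals[10:14] += 700.0  # bone slab upstream
        engine = DoseEngine(beams)
        engine.plan(image, structures)  # plan on water, recompute on slab image
        with_bone = engine.compute(Volume(vals, image.spacing, semantics="HU"))
        assert with_bone.values[24, 8, 8] < water

    def test_opposed_beams_symmetric(self):
        image, structures = _water_phantom()
        dose = compute_dose(image, BeamConfig(), structures)
        v = dose.values.astype(np.float64)
        assert np.abs(v - v[::-1]).max() < 1e-6 * v.max()

    def test_linearity_in_beam_weights(self):
        image, structures = _water_phantom()
        base = BeamConfig()
        engine = DoseEngine(base)
        engine.plan(image, structures)
        engine.scale_ *= 1.0  # frozen scale
        d1 = engine.compute(image).values.astype(np.float64)
        engine2 = DoseEngine(BeamConfig(beam_weights=(2.0, 2.0)))
        engine2.plan(image, structures)
        engine2.scale_ = engine.scale_  # same output scale, doubled weights
        d2 = engine2.compute(image).values.astype(np.float64)
        assert np.allclose(d2, 2.0 * d1, rtol=1e-6)

    def test_ptv_median_equals_prescription(self):
        image, structures = _water_phantom()
        dose = compute_dose(image, BeamConfig(prescription_gy=60.0), structures)
        med = np.median(dose.values[structures["ptv"].values > 0])
        assert med == pytest.approx(60.0, rel=1e-5)

    def test_oblique_marching_agrees_with_axis_fast_path(self):
        image, structures = _water_phantom(shape=(24, 24, 16))
        rho = np.clip(1.0 + image.values.astype(float) / 1000.0, 0, 3)
        engine = DoseEngine(BeamConfig(step_mm=0.25))
        fast = engine._radiological_depth(rho, image, np.array([1.0, 0.0, 0.0]))
        tilt = np.array([1.0, 1e-6, 0.0])
        tilt /= np.linalg.norm(tilt)
        marched = engine._radiological_depth(rho, image, tilt)
        interior = np.s_[2:-2, 4:-4, 4:-4]
        # the two quadratures treat the half-voxel at ray entry differently,
        # so agreement is expected only to ~spacing/2 water-equivalent mm
        assert np.abs(fast[interior] - marched[interior]).max() < 1.5

    def test_compute_before_plan_raises(self):
        image, _ = _water_phantom()
        with pytest.raises(RuntimeError):
            DoseEngine().compute(image)

    def test_missing_ptv_raises(self):
        image, _ = _water_phantom()
        structures = StructureSet(
            {"external": Volume(np.ones(image.shape), image.spacing, semantics="mask")}
        )
        with pytest.raises(ValueError):
            compute_dose(image, BeamConfig(), structures)


class TestEnsembleStats:
    def test_identical_members_degenerate(self):
        d = _gy(np.full((4, 4, 4), 10.0))
        stats = dose_ensemble_stats([d, d, d], d)
        assert np.all(stats.sigma.values == 0.0)
        assert np.array_equal(stats.lower.values, d.values)
        assert np.array_equal(stats.upper.values, d.values)

    def test_three_sigma_bounds(self):
        rng = np.random.default_rng(0)
        members = [_gy(60.0 + rng.normal(0, 1, (4, 4, 4))) for _ in range(200)]
        nominal = _gy(np.full((4, 4, 4), 60.0))
        stats = dose_ensemble_stats(members, nominal)
        v = stats.sigma.values.mean()
        assert stats.lower.values.mean() == pytest.approx(60.0 - 3 * v, abs=1e-4)
        assert stats.upper.values.mean() == pytest.approx(60.0 + 3 * v, abs=1e-4)
        assert np.all(stats.lower.values >= 0.0)

    def test_sigma_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        members = [_gy(rng.uniform(0, 2, (8, 8, 8))) for _ in range(6)]
        stats = dose_ensemble_stats(members, members[0])
        stored = [m.values.astype(np.float64) for m in members]
        mean = sum(stored) / 6
        var = sum((a - mean) ** 2 for a in stored) / 6  # divisor = member count
        assert np.abs(stats.sigma.values.astype(np.float64) ** 2 - var).max() < 1e-10

    def test_too_few_members_raises(self):
        d = _gy(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            dose_ensemble_stats([d], d)


class TestDVH:
    def _mask(self, shape=(4, 4, 4)):
        return Volume(np.ones(shape), (2, 2, 2), semantics="mask")

    def test_uniform_dose_step_function(self):
        curve = dvh(_gy(np.full((4, 4, 4), 2.0)), self._mask(), bin_width=0.5)
        assert np.all(curve.fraction[curve.edges <= 2.0] == 1.0)
        assert np.all(curve.fraction[curve.edges > 2.0] == 0.0)

    def test_two_level_dose(self):
        vals = np.ones((4, 4, 4))
        vals[:2] = 3.0
        curve = dvh(_gy(vals), self._mask(), bin_width=0.5)
        at2 = curve.fraction[np.isclose(curve.edges, 2.0)]
        assert at2 == pytest.approx(0.5)

    def test_non_increasing_matches_sorting_oracle(self):
        rng = np.random.default_rng(2)
        dose = _gy(rng.uniform(0, 5, (6, 6, 6)))
        mask = Volume((rng.uniform(size=(6, 6, 6)) > 0.4).astype(float), (2, 2, 2),
                      semantics="mask")
        curve = dvh(dose, mask, bin_width=0.1)
        assert np.all(np.diff(curve.fraction) <= 1e-12)
        sel = dose.values[mask.values > 0]
        oracle = [(sel >= e).mean() for e in curve.edges]
        assert np.allclose(curve.fraction, oracle, atol=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            dvh(_gy(np.ones((2, 2, 2))),
                Volume(np.zeros((2, 2, 2)), (2, 2, 2), semantics="mask"))


class TestDVHBand:
    def test_zero_sigma_collapses(self):
        d = _gy(np.full((4, 4, 4), 2.0))
        lo, nom, up = dvh_band(d, d, d, Volume(np.ones((4, 4, 4)), (2, 2, 2),
                                               semantics="mask"))
        assert np.array_equal(lo.fraction, nom.fraction)
        assert np.array_equal(nom.fraction, up.fraction)

    def test_band_ordering_holds_everywhere(self):
        rng = np.random.default_rng(3)
        members = [_gy(2.0 + rng.normal(0, 0.2, (6, 6, 6))) for _ in range(10)]
        nominal = members[0]
        stats = dose_ensemble_stats(members, nominal)
        mask = Volume(np.ones((6, 6, 6)), (2, 2, 2), semantics="mask")
        lo, nom, up = dvh_band(stats.lower, nominal, stats.upper, mask)
        assert np.all(lo.fraction <= nom.fraction + 1e-12)
        assert np.all(nom.fraction <= up.fraction + 1e-12)

    def test_ordering_violation_raises(self):
        hi = _gy(np.full((2, 2, 2), 3.0))
        lo = _gy(np.full((2, 2, 2), 1.0))
        mask = Volume(np.ones((2, 2, 2)), (2, 2, 2), semantics="mask")
        with pytest.raises(ValueError):
            dvh_band(hi, lo, hi, mask)


class TestGamma:
    def test_identical_grids_pass_everywhere(self):
        rng = np.random.default_rng(4)
        d = _gy(rng.uniform(1, 10, (12, 12, 8)))
        res = gamma_index(d, d, 1.0, 1.0, local=True, threshold_percent=10.0)
        g = res.gamma.values[res.evaluated_mask.values > 0]
        assert np.all(g <= 1e-9)
        assert res.pass_rate == 100.0

    def test_single_voxel_dose_difference(self):
        ref = _gy(np.full((1, 1, 1), 100.0))
        ev = _gy(np.full((1, 1, 1), 100.5))
        res = gamma_index(ref, ev, 1.0, 1.0, local=True, threshold_percent=10.0)
        assert res.gamma.values[0, 0, 0] == pytest.approx(0.5, abs=1e-9)
        assert res.pass_rate == 100.0

    def test_one_voxel_spatial_shift_within_dta(self):
        # spacing 1 mm, dta 1 mm: a 1-voxel shifted smooth field must pass
        x = np.linspace(0, 1, 16)
        field = 10.0 + 5.0 * np.sin(2 * np.pi * x)[:, None, None] * np.ones((1, 8, 8))
        ref = Volume(field, (1.0, 1.0, 1.0), semantics="Gy")
        ev = Volume(np.roll(field, 1, axis=0), (1.0, 1.0, 1.0), semantics="Gy")
        res = gamma_index(ref, ev, dd_percent=2.0, dta_mm=1.5, local=True,
                          threshold_percent=10.0)
        inner = res.gamma.values[2:-2][res.evaluated_mask.values[2:-2] > 0]
        assert np.mean(inner <= 1.0) > 0.95

    def test_below_threshold_voxels_are_sentinel(self):
        vals = np.ones((4, 4, 4))
        vals[0, 0, 0] = 100.0
        res = gamma_index(_gy(vals), _gy(vals), 1.0, 1.0, True, 50.0)
        assert res.gamma.values[1, 1, 1] == -1.0
        assert res.evaluated_mask.values.sum() == 1.0

    def test_all_below_threshold_raises(self):
        z = _gy(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            gamma_index(z, z, 1.0, 1.0, True, 10.0)


class TestSubsetVariance:
    def test_contracts(self):
        members = [_gy(np.ones((2, 2, 2))) for _ in range(5)]
        with pytest.raises(ValueError):
            subset_variance_mae(members, 5)
        with pytest.raises(ValueError):
            subset_variance_mae(members, 1)

    def test_identical_members_give_zero(self):
        members = [_gy(np.ones((2, 2, 2)))] * 6
        assert subset_variance_mae(members, 3, repeats=5, seed=0) == 0.0

    def test_mae_shrinks_with_subset_size(self):
        rng = np.random.default_rng(5)
        members = [_gy(10.0 + rng.normal(0, 0.5, (8, 8, 8))) for _ in range(50)]
        maes = [subset_variance_mae(members, n, repeats=20, seed=1)
                for n in (5, 10, 25)]
        assert maes[0] > maes[1] > maes[2]
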