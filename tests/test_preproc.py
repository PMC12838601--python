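"""Preprocessing chain: rescale, decay/SUV closed forms, MIP projection,
resize/pad geometry, min-max normalization, and clinical encoding."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from petmip.preproc import (
    ActivityVolume,
    CONTINUOUS_VARS,
    ClinicalRecord,
    F18_HALF_LIFE_S,
    PetMeta,
    clinical_feature_names,
    decay_corrected_dose,
    encode_clinical,
    finalize_image,
    fit_train_stats,
    prepare_model_images,
    project_mip,
    rescale_raw,
    resize_pad,
    suv_bw,
)

T0 = datetime(2020, 1, 1, 9, 0, 0)


def _meta(weight=70.0, dose=370e6, dt_s=3600.0, slope=1.0, manufacturer=0):
    return PetMeta(
        rescale_slope=slope,
        rescale_intercept=0.0,
        weight_kg=weight,
        injected_dose_bq=dose,
        injection_time=T0,
        acquisition_start_time=T0 + timedelta(seconds=dt_s),
        manufacturer=manufacturer,
    )


class TestRescale:
    def test_direct_arithmetic(self):
        out = rescale_raw(np.full((2, 2, 2), 100), 1.5, 2.0)
        assert np.all(out.grid == 152.0)
        assert np.all(rescale_raw(np.zeros((2, 2, 2)), 2.0, 0.0).grid == 0)

    def test_matches_elementwise_loop_oracle(self, rng):
        raw = rng.integers(0, 1000, size=(4, 5, 6))
        out = rescale_raw(raw, 0.37, 1.2)
        for idx in np.ndindex(raw.shape):
            assert out.grid[idx] == raw[idx] * 0.37 + 1.2

    def test_zero_slope_rejected_and_negative_clamped(self):
        with pytest.raises(ValueError, match="slope"):
            rescale_raw(np.ones((2, 2, 2)), 0.0, 0.0)
        out = rescale_raw(np.zeros((2, 2, 2)), 1.0, -5.0)
        assert np.all(out.grid == 0.0)


class TestDecayAndSuv:
    def test_zero_interval_and_exact_half_life(self):
        assert decay_corrected_dose(370e6, T0, T0) == 370e6
        half = decay_corrected_dose(
            370e6, T0, T0 + timedelta(seconds=F18_HALF_LIFE_S)
        )
        assert half == pytest.approx(185e6, rel=1e-12)

    def test_worked_example_against_closed_form(self):
        """370 MBq decayed 60 min: independent evaluation via exp(-ln2 t/T)."""
        dose = decay_corrected_dose(370e6, T0, T0 + timedelta(seconds=3600))
        oracle = 370e6 * math.exp(-math.log(2.0) * 3600.0 / 6586.2)
        assert dose == pytest.approx(oracle, rel=1e-12)
        assert dose == pytest.approx(253.3e6, rel=5e-4)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            decay_corrected_dose(370e6, T0, T0 - timedelta(seconds=1))

    def test_suv_worked_example(self):
        """5000 Bq/mL, 70 kg, 370 MBq decayed 60 min -> SUV ~ 1.381."""
        vol = ActivityVolume(np.full((2, 2, 2), 5000.0), (1, 1, 1))
        suv = suv_bw(vol, _meta())
        dose = 370e6 * 2.0 ** (-3600.0 / 6586.2)
        assert np.all(suv == pytest.approx(5000.0 * 70.0 * 1000.0 / dose))
        assert suv[0, 0, 0] == pytest.approx(1.3817, abs=5e-4)

    def test_suv_linearity_in_weight_and_zero_activity(self, rng):
        grid = rng.uniform(0, 1e4, size=(3, 3, 3))
        vol = ActivityVolume(grid, (1, 1, 1))
        np.testing.assert_allclose(
            suv_bw(vol, _meta(weight=140.0)), 2.0 * suv_bw(vol, _meta(weight=70.0))
        )
        zero = ActivityVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        assert np.all(suv_bw(zero, _meta()) == 0.0)

    def test_suv_invariant_to_raw_encoding(self, rng):
        """encode -> decode -> SUV equals direct SUV within quantization."""
        grid = rng.uniform(0, 2e4, size=(4, 4, 4))
        vol = ActivityVolume(grid, (2, 2, 2))
        meta = _meta(slope=2e4 / 32767.0)
        raw = np.round(grid / meta.rescale_slope)
        back = rescale_raw(raw, meta.rescale_slope, 0.0, (2, 2, 2))
        direct = suv_bw(vol, meta)
        via_raw = suv_bw(back, meta)
        suv_per_bq = 70.0 * 1000.0 / (370e6 * 2 ** (-3600 / 6586.2))
        assert np.max(np.abs(direct - via_raw)) <= meta.rescale_slope * suv_per_bq


class TestMip:
    def test_constant_and_delta(self):
        const = project_mip(np.full((4, 5, 6), 3.0), "anterior")
        assert const.pixels.shape == (4, 6)
        assert np.all(const.pixels == 3.0)
        vol = np.zeros((4, 5, 6))
        vol[1, 2, 3] = 9.0
        ant = project_mip(vol, "anterior").pixels
        lat = project_mip(vol, "lateral").pixels
        # head-up: z index 1 -> row (4-1) - 1 = 2
        assert ant[2, 3] == 9.0 and ant.sum() == 9.0
        assert lat[2, 2] == 9.0 and lat.sum() == 9.0

    def test_matches_triple_loop_oracle(self, rng):
        vol = rng.uniform(0, 10, size=(12, 10, 8))
        ant = project_mip(vol, "anterior").pixels
        lat = project_mip(vol, "lateral").pixels
        nz, ny, nx = vol.shape
        for z in range(nz):
            for x in range(nx):
                m = max(vol[z, y, x] for y in range(ny))
                assert ant[nz - 1 - z, x] == m
            for y in range(ny):
                m = max(vol[z, y, x] for x in range(nx))
                assert lat[nz - 1 - z, y] == m

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            project_mip(np.zeros((4, 4)), "anterior")


class TestResizePad:
    def test_known_geometry_620x400(self):
        img = np.ones((620, 400))
        out = resize_pad(img, target=310)
        assert out.shape == (310, 310)
        # content scaled to 310x200, centered with 55 zero columns each side
        assert np.all(out[:, :55] == 0) and np.all(out[:, -55:] == 0)
        assert np.all(out[:, 55:255] > 0)

    def test_identity_for_square_target(self, rng):
        img = rng.uniform(0, 1, size=(310, 310))
        np.testing.assert_allclose(resize_pad(img, 310), img)

    def test_output_shape_for_random_inputs(self, rng):
        for _ in range(50):
            h, w = rng.integers(5, 200, size=2)
            assert resize_pad(rng.uniform(size=(h, w)), 64).shape == (64, 64)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resize_pad(np.zeros((0, 5)))


class TestFinalize:
    def test_formula_and_channels(self):
        img = np.array([[2.0, 10.0], [6.0, 2.0]])
        out = finalize_image(img)
        assert out.shape == (2, 2, 3)
        np.testing.assert_allclose(out[..., 0], (img - 2.0) / 8.0)
        assert np.all(out[..., 0] == out[..., 1]) and np.all(out[..., 1] == out[..., 2])

    def test_constant_maps_to_zero(self):
        assert np.all(finalize_image(np.full((4, 4), 7.0)) == 0.0)

    def test_range_property(self, rng):
        for _ in range(20):
            out = finalize_image(rng.uniform(-5, 20, size=(8, 9)))
            assert out.min() == 0.0 and out.max() == 1.0


class TestPipeline:
    def test_gain_invariance_of_normalized_mip(self, rng):
        """A pure multiplicative scanner gain is erased by per-image min-max
        normalization — the motivation for SCN targeting residual effects."""
        grid = rng.uniform(0, 1e4, size=(16, 12, 12))
        meta = _meta()
        a = prepare_model_images(ActivityVolume(grid, (4, 4, 4)), meta, target=32)
        b = prepare_model_images(ActivityVolume(3.7 * grid, (4, 4, 4)), meta, target=32)
        for view in ("anterior", "lateral"):
            np.testing.assert_allclose(a[view], b[view], atol=1e-12)

    def test_suv_cap_optional_and_off_by_default(self, rng):
        grid = rng.uniform(0, 5e4, size=(16, 12, 12))
        vol = ActivityVolume(grid, (4, 4, 4))
        capped = prepare_model_images(vol, _meta(), target=32, suv_cap=2.0)
        plain = prepare_model_images(vol, _meta(), target=32)
        assert not np.allclose(capped["anterior"], plain["anterior"])
        with pytest.raises(ValueError, match="cap"):
            prepare_model_images(vol, _meta(), target=32, suv_cap=-1.0)

    def test_bit_identical_determinism(self, rng):
        grid = rng.uniform(0, 1e4, size=(16, 12, 12))
        vol = ActivityVolume(grid, (4, 4, 4))
        meta = _meta()
        a = prepare_model_images(vol, meta, target=32)
        b = prepare_model_images(vol, meta, target=32)
        for view in a:
            assert a[view].tobytes() == b[view].tobytes()


def _record(**overrides):
    base = dict(
        age=60.0, wbc=7.0, anc=4.0, alc=1.5, plt=250.0, hb=13.0,
        nlr=2.7, plr=160.0, ldh=300.0, ann_arbor_stage=2, deauville=4,
        family_history=0, hypertension=1, abnormal_glucose=0, smoking=0,
    )
    base.update(overrides)
    return ClinicalRecord(**base)


class TestClinicalEncoding:
    def test_training_mean_maps_to_zero(self):
        records = [_record(ldh=200.0), _record(ldh=400.0)]
        stats = fit_train_stats(records)
        vec = encode_clinical(_record(ldh=300.0), stats)
        names = clinical_feature_names(stats)
        assert vec[names.index("ldh")] == pytest.approx(0.0)

    def test_leakage_guard_rejects_non_training_cohort(self):
        records = [_record(), _record(ldh=400.0)]
        with pytest.raises(ValueError, match="training split only"):
            fit_train_stats(records, cohorts=["train", "internal_test"])

    def test_external_encoding_uses_training_stats(self):
        train = [_record(ldh=100.0), _record(ldh=200.0)]
        external = [_record(ldh=500.0), _record(ldh=900.0)]
        train_stats = fit_train_stats(train)
        own_stats = fit_train_stats(external)
        with_train = encode_clinical(external[0], train_stats)
        with_own = encode_clinical(external[0], own_stats)
        names = clinical_feature_names(train_stats)
        assert with_train[names.index("ldh")] != pytest.approx(
            with_own[names.index("ldh")]
        )

    def test_one_hot_binarization_and_flags(self):
        stats = fit_train_stats([_record(), _record(ldh=400.0, age=70.0)])
        vec = encode_clinical(_record(ann_arbor_stage=3, deauville=5), stats)
        names = clinical_feature_names(stats)
        assert vec[names.index("ann_arbor_stage_3")] == 1.0
        assert vec[names.index("ann_arbor_stage_1")] == 0.0
        assert vec[names.index("deauville_5")] == 1.0
        assert vec[names.index("hypertension")] == 1.0

    def test_missing_imputed_with_indicator(self):
        records = [_record(ldh=100.0), _record(ldh=200.0), _record(ldh=300.0)]
        stats = fit_train_stats(records)
        vec = encode_clinical(_record(ldh=float("nan")), stats)
        names = clinical_feature_names(stats)
        assert vec[names.index("ldh_missing")] == 1.0
        # imputed at the training median (200) -> z-score of the median
        expected = (200.0 - stats.mean["ldh"]) / stats.sd["ldh"]
        assert vec[names.index("ldh")] == pytest.approx(expected)

    def test_degenerate_variable_dropped(self):
        records = [_record(), _record(ldh=400.0)]  # hb constant across records
        stats = fit_train_stats(records)
        assert "hb" in stats.dropped
        assert "hb" not in clinical_feature_names(stats)

    def test_monte_carlo_recovery_of_generator_truth(self):
        from petmip import PhantomConfig
        from petmip.phantom import CLINICAL_BASE, generate_clinical

        cfg = PhantomConfig(grid_shape=(16, 12, 12), clinical_effect_sizes={})
        gen = np.random.default_rng(5)
        records = [generate_clinical(0, cfg, gen) for _ in range(1000)]
        stats = fit_train_stats(records)
        mu, sd = CLINICAL_BASE["wbc"]
        se = sd / np.sqrt(1000)
        assert abs(stats.mean["wbc"] - mu) < 3 * se
        assert abs(stats.sd["wbc"] - sd) < 4 * se
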