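"""Phantom generator: lesion placement, scanner effects, metadata, clinical
covariates, cohort assembly, and the planted-signal/no-signal properties."""

import numpy as np
import pytest
from scipy import stats

from petmip import PhantomConfig, SplitSpec, generate_cohort
from petmip.phantom import (
    ManufacturerEffect,
    apply_scanner_effect,
    encode_raw,
    generate_activity_volume,
    generate_case,
    generate_clinical,
    generate_meta,
)
from petmip.preproc import CONTINUOUS_VARS, rescale_raw


def _flat_counts(config, lo, hi):
    return {s: (lo, hi) for s in (1, 2, 3, 4)}


class TestActivityVolume:
    def test_no_lesions_gives_pure_background(self, tiny_config, rng):
        import dataclasses

        cfg = dataclasses.replace(
            tiny_config, lesion_count_by_stage=_flat_counts(tiny_config, 0, 0)
        )
        vol, mask = generate_activity_volume(cfg, label=1, stage=2, rng=rng)
        background = cfg.background_suv * cfg.nominal_activity_per_suv
        assert vol.grid.max() == pytest.approx(background)
        assert not mask.any()

    def test_same_seed_bit_identical(self, tiny_config):
        a, ma = generate_activity_volume(
            tiny_config, 1, 3, np.random.default_rng(5)
        )
        b, mb = generate_activity_volume(
            tiny_config, 1, 3, np.random.default_rng(5)
        )
        assert a.grid.tobytes() == b.grid.tobytes()
        assert np.array_equal(ma, mb)

    def test_mask_matches_volume_shape_and_marks_lesions(self, tiny_config, rng):
        vol, mask = generate_activity_volume(tiny_config, 0, 4, rng)
        assert mask.shape == vol.shape
        assert mask.any()
        background = tiny_config.background_suv * tiny_config.nominal_activity_per_suv
        assert vol.grid[mask].min() > background

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            PhantomConfig(grid_shape=(4, 12, 12))

    def test_invalid_stage_rejected(self, tiny_config, rng):
        with pytest.raises(ValueError, match="stage"):
            generate_activity_volume(tiny_config, 0, 5, rng)

    def test_class_separation_detectable_by_excess_activity_oracle(self):
        """With a 2-SUV separation in class lesion means, the oracle feature
        'total activity above background' must discriminate (AUC > 0.8).
        AUC is computed by brute-force pair counting, independent of the
        package implementation."""
        cfg = PhantomConfig(
            grid_shape=(16, 12, 12),
            voxel_mm=(12.0, 12.0, 12.0),
            lesion_suv_mean_by_class={0: 5.0, 1: 7.0},
            lesion_suv_sd=0.5,
            lesion_sigma_mm=(10.0, 12.0),  # narrow size band and fixed count: the
            lesion_count_by_stage=_flat_counts(None, 3, 3),  # feature should reflect
            # contrast, not size/count variation
        )
        rng = np.random.default_rng(42)
        feats, labels = [], []
        bg = cfg.background_suv * cfg.nominal_activity_per_suv
        for i in range(200):
            label = i % 2
            vol, _ = generate_activity_volume(cfg, label, 2, rng)
            feats.append(np.clip(vol.grid - bg, 0, None).sum())
            labels.append(label)
        feats, labels = np.array(feats), np.array(labels)
        pos, neg = feats[labels == 1], feats[labels == 0]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        auc = wins / (len(pos) * len(neg))
        assert auc > 0.8


class TestScannerEffect:
    def test_identity_effect(self, rng):
        cfg = PhantomConfig(
            grid_shape=(12, 10, 10),
            manufacturer_effects=(
                ManufacturerEffect(1.0, 0.0, 0.0),
                ManufacturerEffect(2.0, 0.0, 0.0),
            ),
        )
        vol, _ = generate_activity_volume(cfg, 0, 2, rng)
        out = apply_scanner_effect(vol, 0, cfg, rng)
        np.testing.assert_array_equal(out.grid, vol.grid)

    def test_pure_gain_doubles(self, rng):
        cfg = PhantomConfig(
            grid_shape=(12, 10, 10),
            manufacturer_effects=(
                ManufacturerEffect(1.0, 0.0, 0.0),
                ManufacturerEffect(2.0, 0.0, 0.0),
            ),
        )
        vol, _ = generate_activity_volume(cfg, 0, 2, rng)
        out = apply_scanner_effect(vol, 1, cfg, rng)
        np.testing.assert_allclose(out.grid, 2.0 * vol.grid)

    def test_blur_preserves_sum_and_caps_max(self, rng):
        """Interior lesion: blurring must not raise the global maximum and
        must conserve total activity to within 1%."""
        cfg = PhantomConfig(
            grid_shape=(20, 20, 20),
            voxel_mm=(8.0, 8.0, 8.0),
            manufacturer_effects=(
                ManufacturerEffect(1.0, 0.0, 0.0),
                ManufacturerEffect(1.0, 10.0, 0.0),
            ),
            lesion_count_by_stage=_flat_counts(None, 1, 1),
        )
        vol, _ = generate_activity_volume(cfg, 0, 1, rng)
        out = apply_scanner_effect(vol, 1, cfg, rng)
        assert out.grid.max() <= vol.grid.max() + 1e-9
        assert out.grid.sum() == pytest.approx(vol.grid.sum(), rel=0.01)

    def test_unknown_manufacturer_rejected(self, tiny_config, rng):
        vol, _ = generate_activity_volume(tiny_config, 0, 1, rng)
        with pytest.raises(ValueError, match="manufacturer"):
            apply_scanner_effect(vol, 99, tiny_config, rng)

    def test_manufacturer_detectable_from_raw_intensity_stats(self):
        """A linear probe on raw image summary statistics must beat chance
        when vendor gains differ by >= 20% (batch effect is really there)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        cfg = PhantomConfig(
            grid_shape=(16, 12, 12),
            manufacturer_effects=(
                ManufacturerEffect(1.0, 0.0, 0.05),
                ManufacturerEffect(1.25, 0.0, 0.05),
            ),
        )
        rng = np.random.default_rng(3)
        X, y = [], []
        for i in range(120):
            m = i % 2
            vol, _ = generate_activity_volume(cfg, i % 2, 2, rng)
            out = apply_scanner_effect(vol, m, cfg, rng)
            g = out.grid[out.grid > 0]
            X.append([g.mean(), g.std(), g.max()])
            y.append(m)
        acc = cross_val_score(
            LogisticRegression(max_iter=1000), np.array(X), np.array(y), cv=5
        ).mean()
        assert acc > 0.65


class TestMeta:
    def test_raw_roundtrip_within_quantization(self, tiny_config, rng):
        meta = generate_meta(tiny_config, rng)
        vol, _ = generate_activity_volume(tiny_config, 1, 3, rng)
        raw = encode_raw(vol, meta)
        back = rescale_raw(raw, meta.rescale_slope, meta.rescale_intercept,
                           vol.spacing_mm)
        assert np.max(np.abs(back.grid - vol.grid)) <= meta.rescale_slope / 2 + 1e-9

    def test_uptake_interval_within_clip_bounds(self, tiny_config):
        rng = np.random.default_rng(0)
        for _ in range(200):
            meta = generate_meta(tiny_config, rng)
            dt = (meta.acquisition_start_time - meta.injection_time).total_seconds()
            assert 2700.0 <= dt <= 5400.0

    def test_mean_weight_near_population_mean(self, tiny_config):
        rng = np.random.default_rng(1)
        weights = np.array(
            [generate_meta(tiny_config, rng).weight_kg for _ in range(10_000)]
        )
        se = weights.std() / np.sqrt(weights.size)
        assert abs(weights.mean() - 70.0) < 3 * se + 0.2  # clipping shifts ~0


class TestClinical:
    def test_null_effects_give_identical_distributions(self):
        cfg = PhantomConfig(
            grid_shape=(16, 12, 12),
            clinical_effect_sizes={},
            deauville_probs_by_class={
                0: (0.1, 0.2, 0.3, 0.2, 0.2),
                1: (0.1, 0.2, 0.3, 0.2, 0.2),
            },
            binary_rates_by_class={
                k: (0.2, 0.2)
                for k in ("family_history", "hypertension", "abnormal_glucose", "smoking")
            },
        )
        rng = np.random.default_rng(11)
        ldh0 = [generate_clinical(0, cfg, rng).ldh for _ in range(2500)]
        ldh1 = [generate_clinical(1, cfg, rng).ldh for _ in range(2500)]
        _, p = stats.ks_2samp(ldh0, ldh1)
        assert p > 0.01

    def test_effect_size_recovered(self):
        cfg = PhantomConfig(
            grid_shape=(16, 12, 12), clinical_effect_sizes={"ldh": 1.0}
        )
        rng = np.random.default_rng(12)
        ldh0 = np.array([generate_clinical(0, cfg, rng).ldh for _ in range(2000)])
        ldh1 = np.array([generate_clinical(1, cfg, rng).ldh for _ in range(2000)])
        pooled = np.sqrt((ldh0.var() + ldh1.var()) / 2)
        smd = (ldh1.mean() - ldh0.mean()) / pooled
        assert abs(smd - 1.0) < 0.15

    def test_deauville_range_and_missingness(self, rng):
        cfg = PhantomConfig(grid_shape=(16, 12, 12), missing_rate=0.3)
        miss = 0
        for _ in range(300):
            rec = generate_clinical(1, cfg, rng)
            assert rec.deauville in (1, 2, 3, 4, 5)
            miss += sum(np.isnan(getattr(rec, v)) for v in CONTINUOUS_VARS)
        assert miss > 0


class TestCohort:
    def test_dev_split_partition(self, tiny_cohort):
        dev = [c for c in tiny_cohort if c.cohort in ("train", "internal_test")]
        n_train = sum(c.cohort == "train" for c in dev)
        assert abs(n_train - round(0.8 * len(dev))) <= 1
        ids_train = {c.case_id for c in dev if c.cohort == "train"}
        ids_test = {c.case_id for c in dev if c.cohort == "internal_test"}
        assert not ids_train & ids_test

    def test_external_cohort_only_heldout_manufacturer(self, tiny_cohort):
        for c in tiny_cohort:
            if c.cohort == "external_test":
                assert c.manufacturer == 2
            else:
                assert c.manufacturer in (0, 1)

    def test_imbalance_within_binomial_bounds(self):
        cfg = PhantomConfig(grid_shape=(16, 12, 12))
        cases = generate_cohort(cfg, 600, SplitSpec(), seed=21)
        n_minority = sum(c.label == 1 for c in cases)
        lo = stats.binom.ppf(0.005, 600, 1 / 6)
        hi = stats.binom.ppf(0.995, 600, 1 / 6)
        assert lo <= n_minority <= hi

    def test_cohort_determinism(self, tiny_config):
        spec = SplitSpec(dev_manufacturers=(0,), external_manufacturers=(1,))
        a = generate_cohort(tiny_config, 12, spec, seed=3)
        b = generate_cohort(tiny_config, 12, spec, seed=3)
        for ca, cb in zip(a, b):
            assert ca.volume.grid.tobytes() == cb.volume.grid.tobytes()
            assert ca.clinical == cb.clinical
            assert (ca.label, ca.stage, ca.cohort) == (cb.label, cb.stage, cb.cohort)

    def test_absent_manufacturer_rejected(self, tiny_config):
        spec = SplitSpec(dev_manufacturers=(0,), external_manufacturers=(5,))
        with pytest.raises(ValueError, match="absent manufacturer"):
            generate_cohort(tiny_config, 12, spec, seed=0)

    def test_too_few_cases_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="at least 10"):
            generate_cohort(tiny_config, 5, None, seed=0)


def test_zero_signal_cohort_yields_chance_auc():
    """With every class difference switched off, a trained classifier must
    sit at chance (AUC in [0.4, 0.6] on the held-out cases)."""
    from petmip import LymphomaMipModel, TrainConfig
    from petmip.evalstats import roc_auc

    cfg = PhantomConfig(
        grid_shape=(24, 18, 18),
        voxel_mm=(10.0, 10.0, 10.0),
        lesion_suv_mean_by_class={0: 6.0, 1: 6.0},
        clinical_effect_sizes={},
        class_spatial_priors=False,
        deauville_probs_by_class={
            0: (0.05, 0.1, 0.2, 0.3, 0.35),
            1: (0.05, 0.1, 0.2, 0.3, 0.35),
        },
        binary_rates_by_class={
            k: (0.25, 0.25)
            for k in ("family_history", "hypertension", "abnormal_glucose", "smoking")
        },
        minority_fraction=0.35,
    )
    cases = generate_cohort(cfg, 640, SplitSpec(external_fraction=0.35), seed=77)
    model = LymphomaMipModel(cases, image_size=32)
    res = model.fit(TrainConfig(seed=0, max_epochs=12, patience=4))
    held = res.predictions[res.predictions["cohort"] != "train"]
    assert len(held) >= 300
    auc = roc_auc(held["score"].to_numpy(), held["label"].to_numpy())
    assert 0.4 <= auc <= 0.6
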