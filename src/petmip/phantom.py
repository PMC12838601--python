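"""Synthetic multi-scanner PET phantom cohorts.

Generates labeled cases (activity volume + acquisition metadata + clinical
record) with a controllable class signal and manufacturer-specific batch
effects, so the whole classification pipeline is testable without any
patient data.  The lesion model is deliberately simple — isotropic Gaussian
blobs in an ellipsoidal body — because the phantom's job is to exercise
projection, harmonization and localization, not to simulate physiology.

Class signal has three planted components:

* lesion contrast — per-class mean lesion SUV (survives per-image min-max
  normalization as a background-to-lesion contrast difference);
* spatial prior — class 0 lesions form a contiguous supradiaphragmatic chain
  with a narrow anterior–posterior spread, class 1 lesions are dispersed
  through the body; the anterior–posterior component is only visible in the
  lateral view, which gives the dual-view model something the anterior-only
  model cannot see;
* clinical shifts — standardized mean differences on the continuous
  laboratory variables plus class-dependent Deauville probabilities.

Scanner batch effects are a per-manufacturer gain, point-spread blur
(Gaussian, sigma in mm) and multiplicative log-normal noise with a given
coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as pio
from .preproc import (
    ActivityVolume,
    BINARY_VARS,
    CONTINUOUS_VARS,
    ClinicalRecord,
    PetMeta,
)

# population means/SDs the clinical sampler draws around (adult lymphoma-like
# cohort; lab units: counts 10^3/uL, Hb g/dL, LDH IU/L)
CLINICAL_BASE: dict[str, tuple[float, float]] = {
    "age": (67.0, 16.0),
    "wbc": (7.5, 2.5),
    "anc": (4.8, 2.0),
    "alc": (1.6, 0.7),
    "plt": (250.0, 80.0),
    "hb": (13.0, 2.0),
    "nlr": (3.0, 1.5),
    "plr": (160.0, 70.0),
    "ldh": (380.0, 300.0),
}


@dataclass(frozen=True)
class ManufacturerEffect:
    """One scanner vendor's systematic signature."""

    gain: float = 1.0
    blur_sigma_mm: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.blur_sigma_mm < 0 or self.noise_cv < 0:
            raise ValueError("blur sigma and noise CV must be nonnegative")


DEFAULT_MANUFACTURER_EFFECTS = (
    ManufacturerEffect(gain=0.9, blur_sigma_mm=2.0, noise_cv=0.05),
    ManufacturerEffect(gain=1.0, blur_sigma_mm=3.0, noise_cv=0.08),
    ManufacturerEffect(gain=1.1, blur_sigma_mm=4.0, noise_cv=0.12),
    ManufacturerEffect(gain=1.3, blur_sigma_mm=6.0, noise_cv=0.18),
)

# class-1-minus-class-0 shift in units of the population SD
DEFAULT_CLINICAL_EFFECTS = {
    "ldh": 0.9,
    "nlr": 0.6,
    "age": 0.4,
    "alc": -0.4,
    "hb": -0.3,
}

DEFAULT_DEAUVILLE_PROBS = {
    0: (0.05, 0.10, 0.20, 0.30, 0.35),
    1: (0.02, 0.03, 0.10, 0.25, 0.60),
}

DEFAULT_BINARY_RATES = {
    "family_history": (0.10, 0.15),
    "hypertension": (0.30, 0.35),
    "abnormal_glucose": (0.20, 0.25),
    "smoking": (0.25, 0.30),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for a synthetic cohort.

    ``lesion_suv_mean_by_class`` sets the per-class mean peak lesion SUV;
    ``lesion_count_by_stage`` maps stage 1..4 to an inclusive (lo, hi) count
    range; ``clinical_effect_sizes`` are standardized class-1-minus-class-0
    mean shifts.
    """

    grid_shape: tuple[int, int, int] = (48, 36, 36)
    voxel_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    background_suv: float = 1.0
    lesion_suv_mean_by_class: dict[int, float] = field(
        default_factory=lambda: {0: 5.0, 1: 5.8}
    )
    lesion_suv_sd: float = 0.9
    chain_step_sd: float = 0.3
    class0_y_sd: float = 0.12
    class_spatial_priors: bool = True  # False: both classes use the dispersed prior
    lesion_sigma_mm: tuple[float, float] = (9.0, 14.0)
    lesion_sigma_mm_by_class: dict[int, tuple[float, float]] | None = None
    lesion_count_by_stage: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (1, 2), 2: (2, 4), 3: (3, 6), 4: (5, 9)}
    )
    stage_probs: tuple[float, ...] = (0.15, 0.25, 0.20, 0.40)
    manufacturer_effects: tuple[ManufacturerEffect, ...] = DEFAULT_MANUFACTURER_EFFECTS
    clinical_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    deauville_probs_by_class: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DEAUVILLE_PROBS)
    )
    binary_rates_by_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_RATES)
    )
    minority_fraction: float = 1.0 / 6.0  # P(label == 1); ~1:5 imbalance
    missing_rate: float = 0.0
    encoding_max_activity: float = 2.0e5  # Bq/mL ceiling for int16 raw encoding
    nominal_activity_per_suv: float = 3500.0  # Bq/mL per SUV unit (70 kg, 370 MBq-ish)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel size must be positive")
        if self.background_suv <= 0:
            raise ValueError("background SUV must be positive")
        for rng_ in self.lesion_count_by_stage.values():
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError("lesion count ranges must be nonnegative (lo <= hi)")
        if len(self.manufacturer_effects) < 2:
            raise ValueError("need at least 2 manufacturers")
        if not 0 < self.minority_fraction < 1:
            raise ValueError("minority_fraction must be in (0, 1)")

    @property
    def n_manufacturers(self) -> int:
        return len(self.manufacturer_effects)


@dataclass
class LabeledCase:
    """One synthetic patient: volume + metadata + clinical record + truth."""

    case_id: str
    volume: ActivityVolume
    meta: PetMeta
    clinical: ClinicalRecord
    label: int
    stage: int
    lesion_mask: np.ndarray
    cohort: str  # train | internal_test | external_test

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.lesion_mask.shape != self.volume.shape:
            raise ValueError("lesion mask shape must match volume shape")

    @property
    def manufacturer(self) -> int:
        return self.meta.manufacturer


def _body_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid occupying ~90% of each axis, centered in the grid."""
    zz, yy, xx = np.meshgrid(
        *(np.linspace(-1.0, 1.0, n) for n in shape), indexing="ij"
    )
    return (zz / 0.9) ** 2 + (yy / 0.9) ** 2 + (xx / 0.9) ** 2 <= 1.0


def _sample_lesion_centers(
    n: int,
    label: int,
    rng: np.random.Generator,
    chain_step_sd: float = 0.3,
    class0_y_sd: float = 0.12,
) -> np.ndarray:
    """Lesion centers in normalized body coordinates u in [-1, 1]^3 (z, y, x).

    Class 0: contiguous supradiaphragmatic-leaning chain with a narrow
    anterior-posterior (y) spread — the y signature is only visible in the
    lateral projection.  Class 1: dispersed uniformly through the body.
    ``chain_step_sd`` sets how tight the class-0 chain is (smaller = more
    contiguous, hence more separable in any view).
    """
    centers = np.zeros((n, 3))
    if label == 0:
        cur = np.array([
            rng.uniform(0.1, 0.65),            # supradiaphragmatic-leaning start
            rng.normal(0.0, class0_y_sd),      # near mid anterior-posterior plane
            rng.uniform(-0.45, 0.45),
        ])
        for i in range(n):
            centers[i] = cur
            cur = cur + rng.normal(0.0, chain_step_sd, size=3)
            cur[0] = np.clip(cur[0], -0.3, 0.8)
            cur[1] = np.clip(cur[1], -0.3, 0.3)
            cur[2] = np.clip(cur[2], -0.6, 0.6)
    else:
        centers[:, 0] = rng.uniform(-0.75, 0.75, size=n)
        centers[:, 1] = rng.uniform(-0.7, 0.7, size=n)
        centers[:, 2] = rng.uniform(-0.6, 0.6, size=n)
    # pull any center that left the ellipsoid back onto a 0.8-radius shell
    r = np.sqrt((centers**2).sum(axis=1))
    out = r > 0.8
    if np.any(out):
        centers[out] *= (0.8 / r[out])[:, None]
    return centers


def generate_activity_volume(
    config: PhantomConfig,
    label: int,
    stage: int,
    rng: np.random.Generator,
    activity_per_suv: float | None = None,
) -> tuple[ActivityVolume, np.ndarray]:
    """Noise- and scanner-free activity volume plus ground-truth lesion mask.

    Body ellipsoid at background activity; N lesions (N drawn from the stage's
    count range) as additive Gaussian blobs whose peak SUV is drawn around the
    class mean.  The mask marks voxels within each lesion's half maximum.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be in 1..4")
    if label not in config.lesion_suv_mean_by_class:
        raise ValueError(f"no lesion SUV mean configured for class {label}")
    aps = config.nominal_activity_per_suv if activity_per_suv is None else activity_per_suv

    shape = config.grid_shape
    body = _body_mask(shape)
    suv = np.where(body, config.background_suv, 0.0)
    mask = np.zeros(shape, dtype=bool)

    lo, hi = config.lesion_count_by_stage[stage]
    n_lesions = int(rng.integers(lo, hi + 1))
    if n_lesions > 0:
        prior_label = label if config.class_spatial_priors else 1
        centers = _sample_lesion_centers(
            n_lesions, prior_label, rng, config.chain_step_sd, config.class0_y_sd
        )
        grids = np.meshgrid(*(np.linspace(-1.0, 1.0, n) for n in shape), indexing="ij")
        half_extent_mm = np.array(
            [0.5 * (n - 1) * v for n, v in zip(shape, config.voxel_mm)]
        )
        sigma_range = config.lesion_sigma_mm
        if config.lesion_sigma_mm_by_class is not None:
            sigma_range = config.lesion_sigma_mm_by_class[label]
        for c in centers:
            peak = rng.normal(config.lesion_suv_mean_by_class[label], config.lesion_suv_sd)
            peak = max(peak, config.background_suv + 1.0)
            sigma_mm = rng.uniform(*sigma_range)
            # squared Mahalanobis distance in mm, isotropic sigma
            d2 = sum(
                ((g - ci) * he) ** 2
                for g, ci, he in zip(grids, c, half_extent_mm)
            )
            blob = peak * np.exp(-d2 / (2.0 * sigma_mm**2))
            suv = suv + np.where(body, blob, 0.0)
            mask |= body & (blob >= peak / 2.0)
    return ActivityVolume(suv * aps, config.voxel_mm), mask


def apply_scanner_effect(
    volume: ActivityVolume,
    manufacturer: int,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> ActivityVolume:
    """Vendor signature: Gaussian PSF blur, global gain, multiplicative noise.

    Noise is log-normal with unit mean and the configured coefficient of
    variation, so output stays strictly positive wherever the input is.
    """
    if not 0 <= manufacturer < config.n_manufacturers:
        raise ValueError(f"unknown manufacturer index {manufacturer}")
    eff = config.manufacturer_effects[manufacturer]
    out = volume.grid
    if eff.blur_sigma_mm > 0:
        sigma_vox = [eff.blur_sigma_mm / s for s in volume.spacing_mm]
        out = gaussian_filter(out, sigma=sigma_vox, mode="reflect")
    out = out * eff.gain
    if eff.noise_cv > 0:
        s = np.sqrt(np.log1p(eff.noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * s**2, sigma=s, size=out.shape)
        out = out * factors
    return ActivityVolume(np.clip(out, 0.0, None), volume.spacing_mm)


def generate_meta(
    config: PhantomConfig, rng: np.random.Generator, manufacturer: int = 0
) -> PetMeta:
    """Acquisition metadata with realistic injected-dose / weight / timing draws.

    Weight ~ N(70, 12) kg clipped to [40, 120]; dose ~ N(370, 40) MBq clipped
    to [180, 550]; uptake interval ~ N(60, 7) min clipped to [45, 90].  The
    rescale slope maps the configured activity ceiling onto int16, so the
    raw -> activity -> raw round trip is exact to one quantization step.
    """
    weight = float(np.clip(rng.normal(70.0, 12.0), 40.0, 120.0))
    dose = float(np.clip(rng.normal(370e6, 40e6), 180e6, 550e6))
    uptake_s = float(np.clip(rng.normal(3600.0, 420.0), 2700.0, 5400.0))
    injection = datetime(2020, 1, 1, 9, 0, 0)
    slope = config.encoding_max_activity / 32767.0
    return PetMeta(
        rescale_slope=slope,
        rescale_intercept=0.0,
        weight_kg=weight,
        injected_dose_bq=dose,
        injection_time=injection,
        acquisition_start_time=injection + timedelta(seconds=uptake_s),
        manufacturer=manufacturer,
    )


def encode_raw(volume: ActivityVolume, meta: PetMeta) -> np.ndarray:
    """Quantize activity to the int16 raw representation the metadata describes."""
    raw = np.round((volume.grid - meta.rescale_intercept) / meta.rescale_slope)
    return np.clip(raw, 0, 32767).astype(np.int16)


def generate_clinical(
    label: int,
    config: PhantomConfig,
    rng: np.random.Generator,
    stage: int | None = None,
) -> ClinicalRecord:
    """Class-correlated clinical record.

    Continuous variables are normal draws shifted by the configured
    standardized effect size for class 1; Deauville uses class-dependent
    category probabilities; binary flags are Bernoulli.  With a nonzero
    ``missing_rate`` continuous values are dropped to NaN at random.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    values: dict[str, float] = {}
    for name in CONTINUOUS_VARS:
        mu, sd = CLINICAL_BASE[name]
        shift = config.clinical_effect_sizes.get(name, 0.0) if label == 1 else 0.0
        x = rng.normal(mu + shift * sd, sd)
        values[name] = max(x, 0.05 * mu)  # labs cannot go nonpositive
    if config.missing_rate > 0:
        for name in CONTINUOUS_VARS:
            if rng.random() < config.missing_rate:
                values[name] = float("nan")
    if stage is None:
        stage = int(rng.choice([1, 2, 3, 4], p=np.asarray(config.stage_probs)))
    probs = np.asarray(config.deauville_probs_by_class[label], dtype=float)
    deauville = int(rng.choice([1, 2, 3, 4, 5], p=probs / probs.sum()))
    flags = {
        name: int(rng.random() < config.binary_rates_by_class[name][label])
        for name in BINARY_VARS
    }
    return ClinicalRecord(
        **values, ann_arbor_stage=stage, deauville=deauville, **flags
    )


def generate_case(
    config: PhantomConfig,
    label: int,
    manufacturer: int,
    cohort: str,
    case_id: str,
    rng: np.random.Generator,
) -> LabeledCase:
    """One complete case: metadata-consistent volume, scanner effect applied."""
    stage = int(rng.choice([1, 2, 3, 4], p=np.asarray(config.stage_probs)))
    meta = generate_meta(config, rng, manufacturer=manufacturer)
    from .preproc import decay_corrected_dose

    dose = decay_corrected_dose(
        meta.injected_dose_bq, meta.injection_time, meta.acquisition_start_time
    )
    activity_per_suv = dose / (meta.weight_kg * 1000.0)
    clean, mask = generate_activity_volume(
        config, label, stage, rng, activity_per_suv=activity_per_suv
    )
    volume = apply_scanner_effect(clean, manufacturer, config, rng)
    clinical = generate_clinical(label, config, rng, stage=stage)
    return LabeledCase(
        case_id=case_id,
        volume=volume,
        meta=meta,
        clinical=clinical,
        label=label,
        stage=stage,
        lesion_mask=mask,
        cohort=cohort,
    )


@dataclass(frozen=True)
class SplitSpec:
    """Which manufacturers feed the development pool vs the external cohort.

    The development pool (train + internal test) draws manufacturers uniformly
    from ``dev_manufacturers``; the external cohort uses only
    ``external_manufacturers`` and receives ``external_fraction`` of all cases.
    Inside the development pool an 80/20 patient-level split (stratified by
    label) separates train from internal test.
    """

    dev_manufacturers: tuple[int, ...] = (0, 1, 2)
    external_manufacturers: tuple[int, ...] = (3,)
    dev_fraction: float = 0.8
    external_fraction: float = 0.25


def generate_cohort(
    config: PhantomConfig,
    n_cases: int,
    split_spec: SplitSpec | None = None,
    seed: int | None = None,
) -> list[LabeledCase]:
    """Generate a full labeled cohort with train / internal_test / external_test tags.

    Deterministic: identical (config, seed) gives a byte-identical cohort
    (per-case streams come from ``SeedSequence(seed).spawn``).
    """
    if n_cases < 10:
        raise ValueError("need at least 10 cases")
    spec = split_spec or SplitSpec()
    for m in spec.dev_manufacturers + spec.external_manufacturers:
        if not 0 <= m < config.n_manufacturers:
            raise ValueError(f"split names absent manufacturer {m}")
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(np.random.SeedSequence(seed))
    child_seeds = np.random.SeedSequence(seed).spawn(n_cases + 1)
    assign_rng = np.random.default_rng(child_seeds[0])

    n_external = int(round(n_cases * spec.external_fraction))
    n_dev = n_cases - n_external
    labels = (assign_rng.random(n_cases) < config.minority_fraction).astype(int)

    # development 80/20 patient-level split, stratified by label
    dev_idx = np.arange(n_dev)
    cohorts = np.empty(n_cases, dtype=object)
    cohorts[n_dev:] = "external_test"
    for cls in (0, 1):
        cls_idx = dev_idx[labels[:n_dev] == cls]
        perm = assign_rng.permutation(cls_idx)
        n_train = int(round(spec.dev_fraction * len(cls_idx)))
        cohorts[perm[:n_train]] = "train"
        cohorts[perm[n_train:]] = "internal_test"

    manufacturers = np.empty(n_cases, dtype=int)
    manufacturers[:n_dev] = assign_rng.choice(
        np.asarray(spec.dev_manufacturers), size=n_dev
    )
    manufacturers[n_dev:] = assign_rng.choice(
        np.asarray(spec.external_manufacturers), size=n_external
    )

    cases = []
    for i in range(n_cases):
        rng = np.random.default_rng(child_seeds[i + 1])
        cases.append(
            generate_case(
                config,
                label=int(labels[i]),
                manufacturer=int(manufacturers[i]),
                cohort=str(cohorts[i]),
                case_id=f"case_{i:04d}",
                rng=rng,
            )
        )
    return cases


def write_cohort(cases: Sequence[LabeledCase], outdir: str | Path) -> pd.DataFrame:
    """Write volumes/masks as NIfTI, clinical table as CSV, metadata as JSON,
    and return (and save) the cohort manifest."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    rows, clin_rows = [], []
    for case in cases:
        vpath = outdir / "volumes" / f"{case.case_id}.nii.gz"
        mpath = outdir / "volumes" / f"{case.case_id}_mask.nii.gz"
        pio.save_volume_nifti(case.volume, vpath)
        pio.save_volume_nifti(
            ActivityVolume(case.lesion_mask.astype(np.float64), case.volume.spacing_mm),
            mpath,
        )
        pio.write_json(
            pio.meta_to_json_dict(case.meta), outdir / "volumes" / f"{case.case_id}_meta.json"
        )
        rows.append(
            {
                "case_id": case.case_id,
                "volume_path": str(vpath.relative_to(outdir)),
                "mask_path": str(mpath.relative_to(outdir)),
                "label": case.label,
                "stage": case.stage,
                "manufacturer": case.manufacturer,
                "cohort": case.cohort,
            }
        )
        clin_rows.append({"case_id": case.case_id, **case.clinical.to_dict()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(outdir / "clinical.csv", index=False)
    return manifest


def read_cohort(indir: str | Path) -> list[LabeledCase]:
    """Load a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    clinical = pd.read_csv(indir / "clinical.csv").set_index("case_id")
    cases = []
    for row in manifest.itertuples():
        volume = pio.load_volume_nifti(indir / row.volume_path)
        mask_vol = pio.load_volume_nifti(indir / row.mask_path)
        meta = pio.meta_from_json_dict(
            pio.read_json(indir / "volumes" / f"{row.case_id}_meta.json")
        )
        crow = clinical.loc[row.case_id].to_dict()
        for name in ("ann_arbor_stage", "deauville", *BINARY_VARS):
            crow[name] = int(crow[name])
        cases.append(
            LabeledCase(
                case_id=row.case_id,
                volume=volume,
                meta=meta,
                clinical=ClinicalRecord(**crow),
                label=int(row.label),
                stage=int(row.stage),
                lesion_mask=mask_vol.grid > 0.5,
                cohort=row.cohort,
            )
        )
    return cases
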