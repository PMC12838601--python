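"""PET preprocessing: raw counts -> activity -> SUV -> MIP -> model-ready images,
plus clinical-table encoding with train-only normalization statistics.

Axis convention for all volumes: (z, y, x) with z inferior->superior,
y anterior->posterior, x patient-left->patient-right.  MIP images are emitted
head-up (row 0 = most superior slice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from datetime import datetime
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("petmip.preproc")

#: F-18 physical half-life in seconds.
F18_HALF_LIFE_S = 6586.2

VIEWS = ("anterior", "lateral")


@dataclass
class ActivityVolume:
    """3D activity-concentration grid in Bq/mL on the (z, y, x) convention."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError(f"activity grid must be 3D, got ndim={self.grid.ndim}")
        if np.any(self.grid < 0):
            raise ValueError("activity values must be nonnegative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class PetMeta:
    """Acquisition metadata required for SUV computation and SCN conditioning."""

    rescale_slope: float
    rescale_intercept: float
    weight_kg: float
    injected_dose_bq: float
    injection_time: datetime
    acquisition_start_time: datetime
    half_life_s: float = F18_HALF_LIFE_S
    manufacturer: int = 0

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be positive")
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if self.acquisition_start_time < self.injection_time:
            raise ValueError("acquisition must not precede injection")


@dataclass
class MipImage:
    """2D maximum-intensity projection in SUV units."""

    pixels: np.ndarray
    view: str
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("MIP image must be 2D")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")


def rescale_raw(
    raw: np.ndarray,
    slope: float,
    intercept: float,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ActivityVolume:
    """Convert stored integer voxel values to activity via value*slope + intercept.

    Negative results (possible with a negative intercept) are clamped to zero and
    counted in the log, since activity concentration cannot be negative.
    """
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    values = np.asarray(raw, dtype=np.float64) * float(slope) + float(intercept)
    n_neg = int(np.count_nonzero(values < 0))
    if n_neg:
        logger.warning("rescale_raw: clamped %d negative voxels to 0", n_neg)
        values = np.clip(values, 0.0, None)
    return ActivityVolume(values, spacing_mm)


def _delta_seconds(t0: datetime | float, t1: datetime | float) -> float:
    if isinstance(t0, datetime) and isinstance(t1, datetime):
        return (t1 - t0).total_seconds()
    return float(t1) - float(t0)


def decay_corrected_dose(
    dose0_bq: float,
    injection_time: datetime | float,
    acquisition_start_time: datetime | float,
    half_life_s: float = F18_HALF_LIFE_S,
) -> float:
    """Injected dose decayed to the scan start: dose0 * 2**(-dt/half_life)."""
    dt = _delta_seconds(injection_time, acquisition_start_time)
    if dt < 0:
        raise ValueError("acquisition start precedes injection")
    if dose0_bq <= 0 or half_life_s <= 0:
        raise ValueError("dose and half-life must be positive")
    return float(dose0_bq) * 2.0 ** (-dt / half_life_s)


def suv_bw(volume: ActivityVolume, meta: PetMeta) -> np.ndarray:
    """Body-weight SUV: activity (Bq/mL) * weight (g) / decay-corrected dose (Bq).

    Unitless under the standard 1 g/mL tissue-density assumption.
    """
    dose = decay_corrected_dose(
        meta.injected_dose_bq,
        meta.injection_time,
        meta.acquisition_start_time,
        meta.half_life_s,
    )
    return volume.grid * (meta.weight_kg * 1000.0 / dose)


def project_mip(
    suv: np.ndarray,
    view: str,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MipImage:
    """Maximum-intensity projection of a (z, y, x) SUV volume.

    anterior: max over y -> (z, x) image; lateral: max over x -> (z, y) image.
    Rows are flipped so the most superior slice is row 0 (head-up display).
    """
    suv = np.asarray(suv)
    if suv.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={suv.ndim}")
    sz, sy, sx = spacing_mm
    if view == "anterior":
        img = suv.max(axis=1)
        spacing = (sz, sx)
    elif view == "lateral":
        img = suv.max(axis=2)
        spacing = (sz, sy)
    else:
        raise ValueError(f"view must be one of {VIEWS}")
    return MipImage(img[::-1].copy(), view, spacing)


def resize_pad(image: np.ndarray, target: int = 310) -> np.ndarray:
    """Scale the longest side to `target` (bilinear, aspect preserved), then
    zero-pad symmetrically to a target x target square."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    h, w = image.shape
    if h >= w:
        nh, nw = target, max(1, round(w * target / h))
    else:
        nh, nw = max(1, round(h * target / w)), target
    if (nh, nw) != (h, w):
        image = _sk_resize(
            image, (nh, nw), order=1, preserve_range=True, anti_aliasing=False
        )
        image = np.clip(image, 0.0, None)
    out = np.zeros((target, target), dtype=np.float64)
    top = (target - nh) // 2
    left = (target - nw) // 2
    out[top : top + nh, left : left + nw] = image
    return out


def finalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1], replicated to 3 channels.

    A constant image maps to all zeros (the 0/0 case is defined away).
    Returns (H, W, 3) with identical channels.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        norm = (image - lo) / (hi - lo)
    else:
        norm = np.zeros_like(image)
    return np.repeat(norm[:, :, None], 3, axis=2)


def prepare_model_images(
    volume: ActivityVolume,
    meta: PetMeta,
    target: int = 310,
    suv_cap: float | None = None,
) -> dict[str, np.ndarray]:
    """Full image chain: SUV -> anterior/lateral MIP -> resize/pad -> normalize.

    ``suv_cap`` optionally clips SUV before projection (off by default: the
    baseline pipeline min-max normalizes the raw SUV range).
    Returns {"anterior": (target, target, 3), "lateral": ...} arrays in [0, 1].
    """
    suv = suv_bw(volume, meta)
    if suv_cap is not None:
        if suv_cap <= 0:
            raise ValueError("SUV cap must be positive")
        suv = np.minimum(suv, suv_cap)
    out = {}
    for view in VIEWS:
        mip = project_mip(suv, view, volume.spacing_mm)
        out[view] = finalize_image(resize_pad(mip.pixels, target))
    return out


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = ("age", "wbc", "anc", "alc", "plt", "hb", "nlr", "plr", "ldh")
ORDINAL_VARS = {"ann_arbor_stage": (1, 2, 3, 4), "deauville": (1, 2, 3, 4, 5)}
BINARY_VARS = ("family_history", "hypertension", "abnormal_glucose", "smoking")


@dataclass
class ClinicalRecord:
    """One patient's raw clinical variables; NaN marks a missing continuous value."""

    age: float
    wbc: float
    anc: float
    alc: float
    plt: float
    hb: float
    nlr: float
    plr: float
    ldh: float
    ann_arbor_stage: int
    deauville: int
    family_history: int
    hypertension: int
    abnormal_glucose: int
    smoking: int

    def __post_init__(self) -> None:
        if self.ann_arbor_stage not in (1, 2, 3, 4):
            raise ValueError("Ann Arbor stage must be in 1..4")
        if self.deauville not in (1, 2, 3, 4, 5):
            raise ValueError("Deauville score must be in 1..5")
        for name in BINARY_VARS:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TrainStats:
    """Per-variable normalization statistics, fitted on the training split only.

    Continuous variables with zero spread are dropped (logged) so every retained
    SD is strictly positive; medians back the missing-value imputation.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    median: dict[str, float]
    dropped: tuple[str, ...] = ()
    ordinal_onehot: bool = True
    variables: tuple[str, ...] = field(default=CONTINUOUS_VARS)

    def to_json_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "dropped": list(self.dropped),
            "ordinal_onehot": self.ordinal_onehot,
            "variables": list(self.variables),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrainStats":
        return cls(
            mean=dict(d["mean"]),
            sd=dict(d["sd"]),
            median=dict(d["median"]),
            dropped=tuple(d.get("dropped", ())),
            ordinal_onehot=bool(d.get("ordinal_onehot", True)),
            variables=tuple(d.get("variables", CONTINUOUS_VARS)),
        )


def fit_train_stats(
    records: Sequence[ClinicalRecord],
    cohorts: Sequence[str] | None = None,
    ordinal_onehot: bool = True,
) -> TrainStats:
    """Fit mean/SD/median for every continuous variable on training records.

    If cohort tags are supplied, any non-``train`` tag is rejected — this is the
    leakage guard: test-set statistics must never enter the encoder.
    """
    if not records:
        raise ValueError("no records to fit statistics on")
    if cohorts is not None:
        bad = {c for c in cohorts if c != "train"}
        if bad:
            raise ValueError(
                f"normalization statistics must be fitted on the training split only; "
                f"got cohort tags {sorted(bad)}"
            )
    mean, sd, median, dropped, kept = {}, {}, {}, [], []
    for name in CONTINUOUS_VARS:
        col = np.array([getattr(r, name) for r in records], dtype=np.float64)
        obs = col[~np.isnan(col)]
        if obs.size == 0 or float(obs.std()) == 0.0:
            dropped.append(name)
            logger.warning("fit_train_stats: dropping degenerate variable %r", name)
            continue
        kept.append(name)
        mean[name] = float(obs.mean())
        sd[name] = float(obs.std())
        median[name] = float(np.median(obs))
    return TrainStats(
        mean, sd, median, tuple(dropped), ordinal_onehot, variables=tuple(kept)
    )


def clinical_feature_names(stats: TrainStats, missing_indicator: bool = True) -> list[str]:
    """Fixed, versioned encoding order for the clinical vector."""
    names: list[str] = []
    for name in stats.variables:
        names.append(name)
        if missing_indicator:
            names.append(f"{name}_missing")
    for name, levels in ORDINAL_VARS.items():
        if stats.ordinal_onehot:
            names.extend(f"{name}_{lv}" for lv in levels)
        else:
            names.append(name)
    names.extend(BINARY_VARS)
    return names


def encode_clinical(
    record: ClinicalRecord, stats: TrainStats, missing_indicator: bool = True
) -> np.ndarray:
    """Encode one record into the fixed-order numeric vector.

    Continuous: (x - train_mean)/train_SD, missing values imputed by the training
    median with an added 0/1 indicator.  Ordinal stage and Deauville score are
    one-hot binarized by default (numeric passthrough behind ``ordinal_onehot``).
    Binary flags pass through as {0, 1}.
    """
    parts: list[float] = []
    for name in stats.variables:
        x = float(getattr(record, name))
        missing = np.isnan(x)
        if missing:
            x = stats.median[name]
        parts.append((x - stats.mean[name]) / stats.sd[name])
        if missing_indicator:
            parts.append(1.0 if missing else 0.0)
    for name, levels in ORDINAL_VARS.items():
        val = int(getattr(record, name))
        if stats.ordinal_onehot:
            parts.extend(1.0 if val == lv else 0.0 for lv in levels)
        else:
            parts.append(float(val))
    for name in BINARY_VARS:
        parts.append(float(getattr(record, name)))
    return np.asarray(parts, dtype=np.float64)
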