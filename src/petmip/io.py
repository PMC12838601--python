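"""File IO: NIfTI volumes, DICOM PET series, and cohort manifests.

Internally volumes are (z, y, x); NIfTI stores (x, y, z), so arrays are
transposed on the way in and out and the voxel spacing goes into the affine.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .preproc import ActivityVolume, F18_HALF_LIFE_S, PetMeta

logger = logging.getLogger("petmip.io")


def save_volume_nifti(volume: ActivityVolume, path: str | Path) -> None:
    sz, sy, sx = volume.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(volume.grid.transpose(2, 1, 0).astype(np.float32), affine)
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path) -> ActivityVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    data = np.clip(data, 0.0, None)  # guard against float32 round-off
    return ActivityVolume(data, (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def _parse_dicom_time(date_str: str, time_str: str) -> datetime:
    time_str = time_str.split(".")[0].ljust(6, "0")
    return datetime.strptime(date_str + time_str, "%Y%m%d%H%M%S")


def read_dicom_series(
    directory: str | Path, manufacturer_vocab: dict[str, int] | None = None
) -> tuple[ActivityVolume, PetMeta]:
    """Read a single-frame PET DICOM series into an activity volume + metadata.

    Slices are ordered by ImagePositionPatient z (inferior -> superior).  Rescale
    slope/intercept, patient weight, injected dose and injection/acquisition
    times come from the standard PET tags; the Manufacturer string is mapped to
    an integer index through ``manufacturer_vocab`` (unknown vendors get a fresh
    index and a warning).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files if p.is_file()]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    raw = np.stack([ds.pixel_array for ds in slices]).astype(np.float64)
    grid = np.clip(raw * slope + intercept, 0.0, None)  # (z, rows=y, cols=x)

    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2])
            - float(first.ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    volume = ActivityVolume(grid, (dz, row_mm, col_mm))

    radio = first.RadiopharmaceuticalInformationSequence[0]
    dose = float(radio.RadionuclideTotalDose)
    half_life = float(getattr(radio, "RadionuclideHalfLife", F18_HALF_LIFE_S))
    study_date = str(first.StudyDate)
    injection = _parse_dicom_time(
        study_date, str(radio.RadiopharmaceuticalStartTime)
    )
    acquisition = _parse_dicom_time(
        str(getattr(first, "AcquisitionDate", study_date)),
        str(first.AcquisitionTime),
    )

    vendor = str(getattr(first, "Manufacturer", "UNKNOWN")).strip().upper()
    if manufacturer_vocab is None:
        manufacturer_vocab = {}
    if vendor not in manufacturer_vocab:
        manufacturer_vocab[vendor] = len(manufacturer_vocab)
        logger.warning("read_dicom_series: new manufacturer %r -> index %d",
                       vendor, manufacturer_vocab[vendor])

    meta = PetMeta(
        rescale_slope=slope,
        rescale_intercept=intercept,
        weight_kg=float(first.PatientWeight),
        injected_dose_bq=dose,
        injection_time=injection,
        acquisition_start_time=acquisition,
        half_life_s=half_life,
        manufacturer=manufacturer_vocab[vendor],
    )
    return volume, meta


def meta_to_json_dict(meta: PetMeta) -> dict:
    return {
        "rescale_slope": meta.rescale_slope,
        "rescale_intercept": meta.rescale_intercept,
        "weight_kg": meta.weight_kg,
        "injected_dose_bq": meta.injected_dose_bq,
        "injection_time": meta.injection_time.isoformat(),
        "acquisition_start_time": meta.acquisition_start_time.isoformat(),
        "half_life_s": meta.half_life_s,
        "manufacturer": meta.manufacturer,
    }


def meta_from_json_dict(d: dict) -> PetMeta:
    return PetMeta(
        rescale_slope=float(d["rescale_slope"]),
        rescale_intercept=float(d["rescale_intercept"]),
        weight_kg=float(d["weight_kg"]),
        injected_dose_bq=float(d["injected_dose_bq"]),
        injection_time=datetime.fromisoformat(d["injection_time"]),
        acquisition_start_time=datetime.fromisoformat(d["acquisition_start_time"]),
        half_life_s=float(d["half_life_s"]),
        manufacturer=int(d["manufacturer"]),
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
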