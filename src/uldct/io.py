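"""Reading and writing CT images (DICOM, NPZ) and run configuration (YAML)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .phantom import (
    AcquisitionProtocol,
    CTImage,
    InsertSpec,
    PhantomSpec,
)

CT_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.2"


def write_dicom(img: CTImage, path: str | Path, series_uid: str | None = None,
                instance_number: int = 1) -> None:
    """Write a single-frame CT DICOM file.

    Stored pixels are int16 with RescaleSlope 1 / RescaleIntercept -1024,
    so stored = HU + 1024 maps back to HU on read.
    """
    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(CT_STORAGE_UID)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Modality = "CT"
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = img.shape
    ds.PixelSpacing = [f"{img.spacing_mm[0]:.6f}", f"{img.spacing_mm[1]:.6f}"]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    if img.dose_mAs is not None:
        ds.ExposureInmAs = float(img.dose_mAs)
    stored = np.clip(np.rint(img.pixels) + 1024, -32768, 32767).astype(np.int16)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom(path: str | Path) -> CTImage:
    """Read a single-frame CT DICOM, honoring RescaleSlope/Intercept."""
    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(np.float64) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    dose = getattr(ds, "ExposureInmAs", None)
    return CTImage(hu, (float(spacing[0]), float(spacing[1])),
                   float(dose) if dose is not None else None)


def write_npz(img: CTImage, path: str | Path) -> None:
    np.savez(
        path,
        pixels=img.pixels,
        spacing_mm=np.asarray(img.spacing_mm),
        dose_mAs=np.asarray(-1.0 if img.dose_mAs is None else img.dose_mAs),
        seed=np.asarray(-1 if img.seed is None else img.seed),
    )


def read_npz(path: str | Path) -> CTImage:
    with np.load(path) as data:
        dose = float(data["dose_mAs"])
        seed = int(data["seed"])
        return CTImage(
            data["pixels"],
            tuple(float(s) for s in data["spacing_mm"]),
            None if dose < 0 else dose,
            None if seed < 0 else seed,
        )


def read_image(path: str | Path) -> CTImage:
    path = Path(path)
    if path.suffix == ".npz":
        return read_npz(path)
    return read_dicom(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def phantom_from_config(cfg: dict) -> PhantomSpec:
    inserts = tuple(
        InsertSpec(
            name=i["name"],
            hu=float(i["hu"]),
            diameter_mm=float(i.get("diameter_mm", 12.5)),
            center_xy_mm=tuple(i.get("center_xy_mm", (0.0, 0.0))),
        )
        for i in cfg.get("inserts", [])
    )
    return PhantomSpec(
        body_diameter_mm=float(cfg.get("body_diameter_mm", 200.0)),
        body_hu=float(cfg.get("body_hu", 0.0)),
        inserts=inserts,
        uniform_module=bool(cfg.get("uniform_module", False)),
    )


def protocol_from_config(cfg: dict) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        kVp=float(cfg.get("kVp", 120.0)),
        tube_current_mAs=float(cfg.get("tube_current_mAs", 200.0)),
        dlp_mGy_cm=float(cfg.get("dlp_mGy_cm", 466.67)),
        conversion_k=float(cfg.get("conversion_k", 0.015)),
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
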