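"""Reading and writing image stacks.

Two on-disk forms are supported: a DICOM series (one CT-type file per
slice, HU recovered through the standard rescale slope/intercept) and a
raster volume (``volume.npy``) with a JSON sidecar carrying the spacing
and acquisition labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .stack import ImageStack

__all__ = ["read_stack", "write_stack"]

_SIDECAR = "sidecar.json"
_VOLUME = "volume.npy"


def write_stack(stack: ImageStack, path, format: str = "raster") -> Path:
    """Write a stack to ``path`` (a directory) as raster+sidecar or DICOM."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "raster":
        np.save(path / _VOLUME, np.asarray(stack.pixels, dtype=np.float32))
        sidecar = {
            "pixel_mm": stack.pixel_mm,
            "slice_mm": stack.slice_mm,
            "dose_mgy": stack.dose_mgy,
            "preset": stack.preset,
        }
        (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    elif format == "dicom":
        _write_dicom_series(stack, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack` or a plain DICOM series."""
    path = Path(path)
    if (path / _VOLUME).exists():
        if not (path / _SIDECAR).exists():
            raise ValueError("raster volume without a sidecar")
        sidecar = json.loads((path / _SIDECAR).read_text())
        if "pixel_mm" not in sidecar:
            raise ValueError("sidecar lacks pixel_mm")
        pixels = np.load(path / _VOLUME)
        return ImageStack(
            pixels=pixels,
            pixel_mm=float(sidecar["pixel_mm"]),
            slice_mm=float(sidecar.get("slice_mm", 1.0)),
            dose_mgy=sidecar.get("dose_mgy"),
            preset=sidecar.get("preset"),
        )
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise ValueError(f"no raster volume or DICOM files under {path}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError("DICOM series lacks PixelSpacing")
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    spacing = float(first.PixelSpacing[0])
    slice_mm = (
        float(getattr(first, "SpacingBetweenSlices", 0.0))
        or float(getattr(first, "SliceThickness", 1.0))
    )
    comments = getattr(first, "ImageComments", "")
    meta = json.loads(comments) if comments else {}
    return ImageStack(
        pixels=np.stack(slices),
        pixel_mm=spacing,
        slice_mm=slice_mm,
        dose_mgy=meta.get("dose_mgy"),
        preset=meta.get("preset"),
    )


def _write_dicom_series(stack: ImageStack, path: Path) -> None:
    series_uid = generate_uid()
    study_uid = generate_uid()
    meta_json = json.dumps({"dose_mgy": stack.dose_mgy, "preset": stack.preset})
    for i in range(stack.n_slices):
        hu = np.asarray(stack.pixels[i], dtype=np.float64)
        stored = np.clip(np.rint(hu + 1024.0), 0, 65535).astype(np.uint16)

        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = CTImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid()
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = file_meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i * stack.slice_mm)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [stack.pixel_mm, stack.pixel_mm]
        ds.SliceThickness = stack.slice_mm
        ds.SpacingBetweenSlices = stack.slice_mm
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.ImageComments = meta_json
        ds.PixelData = stored.tobytes()
        ds.save_as(path / f"slice_{i:04d}.dcm", enforce_file_format=True)
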