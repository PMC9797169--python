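"""Reading and writing radiographs as 16-bit TIFF and secondary-capture DICOM.

Generated images are real-valued; on write they are linearly mapped to the
16-bit range and the scale/offset stored alongside (TIFF: a JSON image
description; DICOM: RescaleSlope/RescaleIntercept), so a read round-trip
recovers pixel values to within half a quantization step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .radiograph import InvalidArgumentError, Radiograph

_MAX16 = 65535


def _scale_to_uint16(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo = float(pixels.min())
    hi = float(pixels.max())
    slope = (hi - lo) / _MAX16 if hi > lo else 1.0
    raw = np.round((pixels - lo) / slope).astype(np.uint16)
    return raw, slope, lo


def write_tiff(img: Radiograph, path: str | Path) -> None:
    """Write a radiograph as 16-bit TIFF with metadata in the description."""
    raw, slope, intercept = _scale_to_uint16(img.pixels)
    meta = {
        "slope": slope,
        "intercept": intercept,
        "pixel_pitch_mm": img.pixel_pitch,
        "mas": img.mas,
        "kvp": img.kvp,
        "label": img.label,
    }
    tifffile.imwrite(
        str(path), raw, description=json.dumps(meta),
        resolution=(10.0 / img.pixel_pitch, 10.0 / img.pixel_pitch),
        resolutionunit="CENTIMETER",
    )


def read_tiff(path: str | Path, pixel_pitch: float | None = None) -> Radiograph:
    """Read a 16-bit TIFF back into a real-valued radiograph.

    Metadata written by :func:`write_tiff` is honored when present; for
    foreign TIFFs the pixel pitch must be supplied.
    """
    with tifffile.TiffFile(str(path)) as tf:
        raw = tf.pages[0].asarray().astype(np.float64)
        desc = tf.pages[0].tags.get("ImageDescription")
        meta: dict = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    slope = float(meta.get("slope", 1.0))
    intercept = float(meta.get("intercept", 0.0))
    pitch = pixel_pitch if pixel_pitch is not None else meta.get("pixel_pitch_mm")
    if pitch is None:
        raise InvalidArgumentError("pixel pitch not stored in file; pass pixel_pitch=")
    return Radiograph(
        raw * slope + intercept,
        pixel_pitch=float(pitch),
        mas=float(meta.get("mas", 1.0)),
        kvp=float(meta.get("kvp", 85.0)),
        label=str(meta.get("label", Path(path).stem)),
    )


def write_dicom(img: Radiograph, path: str | Path) -> None:
    """Write a minimal secondary-capture DICOM with pixel spacing and exposure."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    raw, slope, intercept = _scale_to_uint16(img.pixels)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = img.label
    ds.Rows, ds.Columns = raw.shape
    ds.PixelSpacing = [f"{img.pixel_pitch:.6f}", f"{img.pixel_pitch:.6f}"]
    ds.KVP = f"{img.kvp:g}"
    ds.ExposureInmAs = float(img.mas)
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = raw.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom(path: str | Path) -> Radiograph:
    """Read a DICOM file into a real-valued radiograph (rescale applied)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    raw = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise InvalidArgumentError("DICOM file has no PixelSpacing")
    mas = getattr(ds, "ExposureInmAs", None)
    if mas is None:
        mas = getattr(ds, "Exposure", 1.0)
    return Radiograph(
        raw * slope + intercept,
        pixel_pitch=float(spacing[0]),
        mas=float(mas),
        kvp=float(getattr(ds, "KVP", 85.0)),
        label=str(getattr(ds, "SeriesDescription", Path(path).stem)),
    )
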