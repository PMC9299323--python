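"""Reading and writing CT slices, organ masks and quality reports.

All downstream analysis consumes the neutral containers defined here:
:class:`CTImage` (a 2-D array of Hounsfield units with physical pixel
spacing) and :class:`OrganMask` (a congruent boolean mask of the reference
organ).  DICOM input is handled by :mod:`pydicom`; raster masks by
:mod:`imageio`.  Physical quantities (areas, distances) are always derived
through the pixel spacing, never counted in raw pixels.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = [
    "CTImage",
    "OrganMask",
    "SliceRecord",
    "QualityReport",
    "load_dicom_series",
    "write_dicom_slice",
    "load_mask",
    "write_mask",
    "mask_area_cm2",
    "write_report",
    "read_report",
]

#: Slices whose organ mask area is not strictly greater than this (cm^2)
#: are excluded from quality evaluation.
MIN_ORGAN_AREA_CM2 = 100.0


@dataclass
class CTImage:
    """A single CT slice in Hounsfield units.

    Parameters
    ----------
    pixels
        2-D float array of HU values (water = 0, air ~ -1000).
    spacing_row_mm, spacing_col_mm
        Physical size of one pixel along the row / column axis, in mm.
    identifier
        Opaque series/slice key used in reports.
    """

    pixels: np.ndarray
    spacing_row_mm: float
    spacing_col_mm: float
    identifier: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 16:
            raise ValueError(f"image too small: shape {self.pixels.shape}, need >= 16x16")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if not (self.spacing_row_mm > 0 and self.spacing_col_mm > 0):
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row_mm * self.spacing_col_mm


@dataclass
class OrganMask:
    """Boolean organ mask congruent with a :class:`CTImage`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) != 0

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def area_cm2(self, image: CTImage) -> float:
        return mask_area_cm2(self, image)


def mask_area_cm2(mask: OrganMask | np.ndarray, image: CTImage) -> float:
    """Physical area of the mask in cm^2 (true pixels x pixel area / 100)."""
    m = mask.mask if isinstance(mask, OrganMask) else np.asarray(mask) != 0
    if m.shape != image.pixels.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {image.pixels.shape}")
    return float(m.sum()) * image.pixel_area_mm2 / 100.0


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = ("PixelSpacing", "RescaleSlope", "RescaleIntercept")


def load_dicom_series(path: str | Path) -> list[tuple[CTImage, dict[str, Any]]]:
    """Read a directory of single-frame CT DICOM files as HU slices.

    Pixels are rescaled ``stored * RescaleSlope + RescaleIntercept``; slices
    are sorted by the patient-axis position (``ImagePositionPatient[2]``,
    falling back to ``InstanceNumber``).  Missing spacing/rescale tags and
    mixed in-plane shapes are hard errors.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in (".dcm", ""))
    entries = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        for tag in _REQUIRED_TAGS:
            if getattr(ds, tag, None) is None:
                raise ValueError(f"{f.name}: missing required DICOM tag {tag}")
        entries.append((f, ds))
    if not entries:
        raise ValueError(f"no readable CT slices found in {path}")

    def sort_key(item):
        ds = item[1]
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]))
        return (1, float(getattr(ds, "InstanceNumber", 0)))

    entries.sort(key=sort_key)

    shapes = {ds.pixel_array.shape for _, ds in entries}
    if len(shapes) > 1:
        raise ValueError(f"mixed slice shapes in series: {sorted(shapes)}")

    out: list[tuple[CTImage, dict[str, Any]]] = []
    for f, ds in entries:
        stored = ds.pixel_array.astype(np.float64)
        hu = stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        sp = [float(v) for v in ds.PixelSpacing]  # (row, col)
        ident = f.stem  # file stem keys masks and report rows
        meta = {
            "path": str(f),
            "sop_instance_uid": str(getattr(ds, "SOPInstanceUID", "")),
            "rescale_slope": float(ds.RescaleSlope),
            "rescale_intercept": float(ds.RescaleIntercept),
            "position": [float(v) for v in getattr(ds, "ImagePositionPatient", (0, 0, 0))],
        }
        out.append((CTImage(hu, sp[0], sp[1], identifier=ident), meta))
    return out


def write_dicom_slice(
    image: CTImage,
    path: str | Path,
    *,
    slice_position_mm: float = 0.0,
    instance_number: int = 1,
    series_uid: str | None = None,
    rescale_intercept: float = -1024.0,
    rescale_slope: float = 1.0,
    omit_tags: Sequence[str] = (),
) -> Path:
    """Write one CT slice as a minimal single-frame DICOM file.

    Intended for test fixtures and ``make-fixtures``; ``omit_tags`` lets
    tests exercise the missing-tag error contract of the reader.
    """
    path = Path(path)
    stored = np.rint((image.pixels - rescale_intercept) / rescale_slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise ValueError("HU values out of int16 stored range")
    stored = stored.astype(np.int16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.Modality = "CT"
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [0.0, 0.0, float(slice_position_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [image.spacing_row_mm, image.spacing_col_mm]
    ds.RescaleSlope = rescale_slope
    ds.RescaleIntercept = rescale_intercept
    ds.Rows, ds.Columns = stored.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    for tag in omit_tags:
        if hasattr(ds, tag):
            delattr(ds, tag)
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def load_mask(path: str | Path) -> OrganMask:
    """Load a mask from PNG (any nonzero = true) or a .npy boolean array."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
    return OrganMask(arr != 0)


def write_mask(mask: OrganMask | np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    m = mask.mask if isinstance(mask, OrganMask) else np.asarray(mask) != 0
    if path.suffix.lower() == ".npy":
        np.save(path, m)
    else:
        iio.imwrite(path, (m.astype(np.uint8) * 255))
    return path


# ---------------------------------------------------------------------------
# Quality report
# ---------------------------------------------------------------------------

@dataclass
class SliceRecord:
    """One report row: the per-slice metric set, or an exclusion reason."""

    identifier: str
    included: bool = True
    reason: str = ""
    noise_hu: float | None = None
    ssi_raw: float | None = None
    ssi_calibrated: float | None = None
    sai: float | None = None
    n_pixels_rh: int | None = None
    n_pixels_rs: int | None = None


@dataclass
class QualityReport:
    rows: list[SliceRecord] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def n_included(self) -> int:
        return sum(r.included for r in self.rows)

    @property
    def n_excluded(self) -> int:
        return len(self.rows) - self.n_included


_CSV_COLUMNS = [
    "identifier", "included", "reason", "noise_HU", "ssi_raw",
    "ssi_calibrated", "sai", "n_pixels_RH", "n_pixels_RS",
]


def _fmt(v: float | int | None) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{v:.6g}"


def write_report(report: QualityReport, path: str | Path) -> Path:
    """Write the report as CSV plus a JSON mirror (with the config echoed).

    Numeric fields are printed to 6 significant digits; the CSV body is a
    deterministic function of the report, so identical runs are
    byte-identical.
    """
    path = Path(path)
    lines = [",".join(_CSV_COLUMNS)]
    for r in report.rows:
        lines.append(",".join([
            r.identifier,
            "1" if r.included else "0",
            r.reason.replace(",", ";"),
            _fmt(r.noise_hu), _fmt(r.ssi_raw), _fmt(r.ssi_calibrated),
            _fmt(r.sai), _fmt(r.n_pixels_rh), _fmt(r.n_pixels_rs),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mirror = path.with_suffix(".json")
    payload = {
        "config": report.config,
        "rows": [dataclasses.asdict(r) for r in report.rows],
    }
    mirror.write_text(json.dumps(payload, indent=2, default=float) + "\n", encoding="utf-8")
    return path


def read_report(path: str | Path) -> QualityReport:
    """Read back a CSV written by :func:`write_report`."""
    df = pd.read_csv(path, dtype={"identifier": str, "reason": str}, keep_default_na=False)
    rows = []
    for _, row in df.iterrows():
        def num(key, cast=float):
            v = row[key]
            return None if v == "" else cast(v)
        rows.append(SliceRecord(
            identifier=str(row["identifier"]),
            included=bool(int(row["included"])),
            reason=str(row["reason"]),
            noise_hu=num("noise_HU"),
            ssi_raw=num("ssi_raw"),
            ssi_calibrated=num("ssi_calibrated"),
            sai=num("sai"),
            n_pixels_rh=num("n_pixels_RH", int),
            n_pixels_rs=num("n_pixels_RS", int),
        ))
    return QualityReport(rows=rows)
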