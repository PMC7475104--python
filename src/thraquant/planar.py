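"""Planar-image plumbing: I/O, ROI counts, background handling, scout
thickness.

The portable image format is a whitespace-delimited integer matrix plus a
JSON sidecar carrying ``duration_s``, ``view``, ``window_lo_keV``,
``window_hi_keV``, ``pixel_size_mm`` and ``timestamp``.  DICOM NM planar
read/write is supported through pydicom as an optional convenience.

ROI counts follow the oversized-ROI scheme: the main ROI (larger than the
source, to capture spill-out) minus an identically sized background ROI
placed over representative background, which removes counts from under-
and overlying activity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import EnergyWindow, STANDARD_WINDOWS

__all__ = [
    "PlanarImage",
    "ROI",
    "ScoutCalibration",
    "read_planar",
    "write_planar",
    "read_planar_dicom",
    "write_planar_dicom",
    "subtract_room_background",
    "roi_counts",
    "scout_thickness",
]

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_MM = 9.59


@dataclass
class PlanarImage:
    """A single planar acquisition in one energy window and view."""

    matrix: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM  # mm
    view: str = "anterior"
    window: EnergyWindow = STANDARD_WINDOWS[0]
    duration: float = 1200.0  # s
    timestamp: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if np.any(self.matrix < 0):
            raise ValueError("counts must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.view not in ("anterior", "posterior"):
            raise ValueError(f"view must be anterior or posterior, got {self.view!r}")

    @property
    def total_counts(self) -> float:
        return float(self.matrix.sum())


def _match_window(lo: float, hi: float, tol: float = 1.0) -> EnergyWindow:
    """Snap bounds to the nearest standard acquisition window (within 1 keV)."""
    for w in STANDARD_WINDOWS:
        if abs(w.lo - lo) <= tol and abs(w.hi - hi) <= tol:
            return w
    return EnergyWindow(lo, hi)


def write_planar(img: PlanarImage, path: Path | str) -> None:
    """Write the portable text format: ``<path>`` matrix + ``<path>.json``."""
    path = Path(path)
    mat = np.asarray(img.matrix)
    fmt = "%d" if np.issubdtype(mat.dtype, np.integer) else "%.10g"
    np.savetxt(path, mat, fmt=fmt)
    sidecar = {
        "duration_s": img.duration,
        "view": img.view,
        "window_lo_keV": img.window.lo,
        "window_hi_keV": img.window.hi,
        "pixel_size_mm": img.pixel_size,
        "timestamp": img.timestamp,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_planar(path: Path | str) -> PlanarImage:
    """Read the portable text format written by :func:`write_planar`."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for required in ("duration_s", "view", "window_lo_keV", "window_hi_keV"):
        if required not in meta:
            raise ValueError(f"sidecar missing required field {required!r}")
    matrix = np.loadtxt(path)
    if np.allclose(matrix, np.round(matrix)):
        matrix = matrix.astype(np.int64)
    return PlanarImage(
        matrix=np.atleast_2d(matrix),
        pixel_size=float(meta.get("pixel_size_mm", DEFAULT_PIXEL_SIZE_MM)),
        view=meta["view"],
        window=_match_window(float(meta["window_lo_keV"]), float(meta["window_hi_keV"])),
        duration=float(meta["duration_s"]),
        timestamp=meta.get("timestamp", ""),
    )


def write_planar_dicom(img: PlanarImage, path: Path | str) -> None:
    """Write a minimal DICOM NM planar file (uint32 counts)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.NuclearMedicineImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    mat = np.asarray(img.matrix)
    if np.any(mat < 0) or not np.allclose(mat, np.round(mat)):
        raise ValueError("DICOM export requires nonnegative integer counts")
    mat = mat.astype(np.uint32)
    ds.Rows, ds.Columns = mat.shape
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelSpacing = [img.pixel_size, img.pixel_size]
    ds.ActualFrameDuration = int(round(img.duration * 1000))  # ms
    ds.ViewPosition = "ANT" if img.view == "anterior" else "POST"
    # window bounds stored in an energy-window sequence analogue
    ds.add_new(0x00540014, "DS", f"{img.window.lo}")  # EnergyWindowLowerLimit
    ds.add_new(0x00540015, "DS", f"{img.window.hi}")  # EnergyWindowUpperLimit
    if img.timestamp:
        ds.AcquisitionDate = img.timestamp.replace("-", "")[:8]
    ds.PixelData = mat.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_planar_dicom(path: Path | str) -> PlanarImage:
    """Read a DICOM NM planar file written by :func:`write_planar_dicom`."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "ActualFrameDuration" not in ds:
        raise ValueError("DICOM file missing ActualFrameDuration")
    if 0x00540014 not in ds or 0x00540015 not in ds:
        raise ValueError("DICOM file missing energy window limits")
    mat = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(ds.Rows, ds.Columns)
    lo = float(ds[0x00540014].value)
    hi = float(ds[0x00540015].value)
    view = "anterior" if str(getattr(ds, "ViewPosition", "ANT")).startswith("ANT") else "posterior"
    pixel_size = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else DEFAULT_PIXEL_SIZE_MM
    return PlanarImage(
        matrix=mat.astype(np.int64),
        pixel_size=pixel_size,
        view=view,
        window=_match_window(lo, hi),
        duration=ds.ActualFrameDuration / 1000.0,
    )


def subtract_room_background(img: PlanarImage, bkg: PlanarImage) -> PlanarImage:
    """Subtract a room-background acquisition scaled to the image duration.

    The background image (typically a long acquisition, e.g. 9 h) is
    scaled by ``img.duration / bkg.duration`` and subtracted pixelwise;
    negative results are clipped to zero (clips are logged).  The result
    is real-valued.
    """
    if img.matrix.shape != bkg.matrix.shape:
        raise ValueError("image and background dimensions differ")
    if img.window != bkg.window:
        raise ValueError(f"window mismatch: {img.window} vs {bkg.window}")
    scale = img.duration / bkg.duration
    corrected = img.matrix.astype(float) - scale * bkg.matrix.astype(float)
    n_clip = int(np.count_nonzero(corrected < 0))
    if n_clip:
        logger.info("room-background subtraction clipped %d negative pixels", n_clip)
        corrected = np.clip(corrected, 0.0, None)
    return PlanarImage(
        matrix=corrected,
        pixel_size=img.pixel_size,
        view=img.view,
        window=img.window,
        duration=img.duration,
        timestamp=img.timestamp,
    )


@dataclass
class ROI:
    """A main ROI paired with an identically sized background ROI.

    ``shape`` is ``"circle"`` (center_px, radius_px), ``"rect"``
    (center_px, extent_px as (rows, cols)) or ``"mask"`` (explicit boolean
    array).  ``background_offset_px`` shifts the identical geometry to the
    background position (e.g. inferior to a source).
    """

    shape: str
    center_px: tuple[float, float] | None = None
    radius_px: float | None = None
    extent_px: tuple[int, int] | None = None
    mask: np.ndarray | None = None
    background_offset_px: tuple[int, int] | None = None

    def _mask_at(self, image_shape, center) -> np.ndarray:
        rows, cols = np.ogrid[: image_shape[0], : image_shape[1]]
        if self.shape == "circle":
            r0, c0 = center
            return (rows - r0) ** 2 + (cols - c0) ** 2 <= self.radius_px**2
        if self.shape == "rect":
            r0, c0 = center
            h, w = self.extent_px
            return (np.abs(rows - r0) <= h / 2) & (np.abs(cols - c0) <= w / 2)
        if self.shape == "mask":
            return np.asarray(self.mask, dtype=bool)
        raise ValueError(f"unknown ROI shape {self.shape!r}")

    def main_mask(self, image_shape) -> np.ndarray:
        m = self._mask_at(image_shape, self.center_px)
        self._check_bounds(m, image_shape, "main")
        return m

    def background_mask(self, image_shape) -> np.ndarray | None:
        if self.background_offset_px is None:
            return None
        if self.shape == "mask":
            dr, dc = self.background_offset_px
            m = np.roll(np.roll(self.mask, dr, axis=0), dc, axis=1)
        else:
            dr, dc = self.background_offset_px
            r0, c0 = self.center_px
            m = self._mask_at(image_shape, (r0 + dr, c0 + dc))
        self._check_bounds(m, image_shape, "background")
        main = self.main_mask(image_shape)
        if m.sum() != main.sum():
            raise ValueError("background ROI must match the main ROI pixel count")
        if np.any(m & main):
            raise ValueError("background ROI overlaps the main ROI")
        return m

    def _check_bounds(self, mask: np.ndarray, image_shape, which: str) -> None:
        if mask.shape != tuple(image_shape):
            raise ValueError(f"{which} ROI mask shape does not match image")
        if self.shape == "circle" and self.center_px is not None:
            r0, c0 = self.center_px
            if which == "background" and self.background_offset_px is not None:
                r0 += self.background_offset_px[0]
                c0 += self.background_offset_px[1]
            r = self.radius_px
            if (
                r0 - r < -0.5
                or c0 - r < -0.5
                or r0 + r > image_shape[0] - 0.5
                or c0 + r > image_shape[1] - 0.5
            ):
                raise ValueError(f"{which} ROI extends outside the image")


def roi_counts(img: PlanarImage, roi: ROI) -> float:
    """Main-ROI counts minus paired background-ROI counts, clipped at 0.

    The identically sized background ROI removes counts from under- and
    overlying activity; an oversized main ROI captures spill-out.
    """
    main = roi.main_mask(img.matrix.shape)
    total = float(img.matrix[main].sum())
    bkg_mask = roi.background_mask(img.matrix.shape)
    if bkg_mask is not None:
        total -= float(img.matrix[bkg_mask].sum())
    return max(total, 0.0)


@dataclass
class ScoutCalibration:
    """Empirical map from mean scout-image pixel value to water-equivalent
    thickness (cm), fitted to user-supplied (p, x) pairs.

    The default model is linear, x = a·p + b (couch contribution folded
    into the coefficients); the calibrated p-range is enforced.
    """

    slope: float
    intercept: float
    p_range: tuple[float, float]

    @classmethod
    def from_pairs(cls, pixel_values, thicknesses) -> "ScoutCalibration":
        p = np.asarray(pixel_values, dtype=float)
        x = np.asarray(thicknesses, dtype=float)
        if p.size < 2:
            raise ValueError("need at least two calibration pairs")
        if np.any(x < 0):
            raise ValueError("thicknesses must be nonnegative")
        slope, intercept = np.polyfit(p, x, 1)
        return cls(
            slope=float(slope),
            intercept=float(intercept),
            p_range=(float(p.min()), float(p.max())),
        )

    def __call__(self, p: float) -> float:
        return scout_thickness(p, self)


def scout_thickness(p: float, cal: ScoutCalibration) -> float:
    """Water-equivalent thickness (cm) from a mean scout pixel value."""
    lo, hi = cal.p_range
    if not (lo <= p <= hi):
        raise ValueError(
            f"scout pixel value {p:g} outside calibrated range [{lo:g}, {hi:g}]"
        )
    x = cal.slope * p + cal.intercept
    if x < 0:
        raise ValueError("calibration yields negative thickness; check pairs")
    return float(x)
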