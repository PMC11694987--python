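"""Domain types and I/O for CT volumes.

CT scanners store intensities in Hounsfield Units (HU), an affine scale with
water at 0 and air at -1000.  The filter itself operates on linear attenuation
coefficients, the physical quantity HU is derived from, so that no information
is lost and results can be converted back to HU.  This module holds the volume
container, the HU <-> attenuation conversion, and readers/writers for DICOM
series, raw little-endian binary volumes (with a YAML sidecar describing the
layout) and 8-bit PGM slice stacks.

Conventions: volumes are indexed (slice, row, col), 0-based; a "pixel" is one
(row, col) cell of one slice.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

#: Linear attenuation coefficient of water (mm^-1) used when no per-scan
#: calibration is available (e.g. phantom-derived volumes).
DEFAULT_MU_WATER = 0.0192

__all__ = [
    "DEFAULT_MU_WATER",
    "AttenuationVolume",
    "GrayImage",
    "InvalidCalibrationError",
    "VolumeFormatError",
    "hu_to_attenuation",
    "attenuation_to_hu",
    "read_volume",
    "write_volume",
]


class InvalidCalibrationError(ValueError):
    """Raised for a non-positive water attenuation coefficient."""


class VolumeFormatError(ValueError):
    """Raised when a file does not match its declared volume layout."""


def hu_to_attenuation(hu, mu_water: float):
    """Convert Hounsfield Units to linear attenuation coefficients.

    Uses the defining relation ``HU = 1000 * (mu - mu_water) / mu_water``,
    i.e. ``mu = mu_water * (1 + HU/1000)``.  HU below -1000 (below air) would
    give a negative attenuation, which is unphysical; those clamp to 0.

    Parameters
    ----------
    hu : array_like
        HU values (integer or float).
    mu_water : float
        Water linear attenuation coefficient for this scan, > 0.
    """
    if mu_water <= 0:
        raise InvalidCalibrationError(f"mu_water must be > 0, got {mu_water}")
    mu = mu_water * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)
    return np.maximum(mu, 0.0)[()]


def attenuation_to_hu(mu, mu_water: float):
    """Inverse of :func:`hu_to_attenuation` on its range (mu >= 0)."""
    if mu_water <= 0:
        raise InvalidCalibrationError(f"mu_water must be > 0, got {mu_water}")
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    return (1000.0 * (mu - mu_water) / mu_water)[()]


@dataclasses.dataclass
class AttenuationVolume:
    """A 3-D grid of non-negative attenuation coefficients.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Attenuation coefficients (or [0,1] intensities for phantom volumes).
    mu_water : float
        Per-scan water attenuation calibration used for HU conversion.
    source : str
        Provenance tag: ``dicom``, ``binary``, ``phantom`` or ``derived``.
    """

    voxels: np.ndarray
    mu_water: float = DEFAULT_MU_WATER
    source: str = "derived"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if self.mu_water <= 0:
            raise InvalidCalibrationError(f"mu_water must be > 0, got {self.mu_water}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("attenuation coefficients must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[2]

    def to_hu(self) -> np.ndarray:
        return attenuation_to_hu(self.voxels, self.mu_water)

    def with_voxels(self, voxels: np.ndarray, source: str = "derived") -> "AttenuationVolume":
        return AttenuationVolume(voxels, mu_water=self.mu_water, source=source)


@dataclasses.dataclass
class GrayImage:
    """A 2-D gray-scale image, either [0,1] floats or 8-bit integers."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("8-bit images must lie in {0..255}")
        else:
            if self.pixels.min() < 0 or self.pixels.max() > 1:
                raise ValueError("normalized images must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


# ---------------------------------------------------------------------------
# raw binary dialect: little-endian IEEE double, C row-major, no header;
# dimensions and calibration travel in a YAML sidecar next to the data file.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _write_raw(vol: AttenuationVolume, path: Path) -> None:
    data = np.ascontiguousarray(vol.voxels, dtype="<f8")
    path.write_bytes(data.tobytes())
    meta = {
        "shape": [int(vol.n_slices), int(vol.n_rows), int(vol.n_cols)],
        "dtype": "<f8",
        "order": "C",
        "mu_water": float(vol.mu_water),
        "source": vol.source,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def _read_raw(path: Path, layout: dict | None) -> AttenuationVolume:
    if layout is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise VolumeFormatError(f"no layout given and no sidecar at {sidecar}")
        layout = yaml.safe_load(sidecar.read_text())
    shape = tuple(int(s) for s in layout["shape"])
    dtype = np.dtype(layout.get("dtype", "<f8"))
    raw = path.read_bytes()
    expected = int(np.prod(shape)) * dtype.itemsize
    if len(raw) != expected:
        raise VolumeFormatError(
            f"{path}: file holds {len(raw)} bytes but layout {shape} ({dtype}) "
            f"needs {expected}"
        )
    voxels = np.frombuffer(raw, dtype=dtype).reshape(shape).astype(np.float64)
    return AttenuationVolume(
        voxels,
        mu_water=float(layout.get("mu_water", DEFAULT_MU_WATER)),
        source=str(layout.get("source", "binary")),
    )


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(path: Path, mu_water: float | None) -> AttenuationVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".yaml")
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:  # non-DICOM stray file
            continue
        datasets.append(ds)
    if not datasets:
        raise VolumeFormatError(f"no readable DICOM files under {path}")

    # Order along the slice normal (cross product of the in-plane axes of
    # ImageOrientationPatient); ties broken by InstanceNumber.
    def sort_key(ds):
        inst = int(getattr(ds, "InstanceNumber", 0))
        iop = getattr(ds, "ImageOrientationPatient", None)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if iop is not None and ipp is not None:
            row = np.array(iop[:3], dtype=float)
            col = np.array(iop[3:], dtype=float)
            normal = np.cross(row, col)
            return (float(np.dot(normal, np.array(ipp, dtype=float))), inst)
        return (0.0, inst)

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeFormatError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; cannot recover HU"
            )
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    hu_vol = np.stack(slices, axis=0)
    mw = DEFAULT_MU_WATER if mu_water is None else mu_water
    return AttenuationVolume(hu_to_attenuation(hu_vol, mw), mu_water=mw, source="dicom")


# ---------------------------------------------------------------------------
# PGM slices
# ---------------------------------------------------------------------------

def quantize_to_uint8(voxels: np.ndarray) -> np.ndarray:
    """Map the volume's [0, max] range onto {0..255}, rounding half away from zero."""
    vmax = float(voxels.max())
    if vmax <= 0:
        return np.zeros(voxels.shape, dtype=np.uint8)
    scaled = voxels / vmax * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # values are non-negative


def _write_pgm_slices(vol: AttenuationVolume, path: Path) -> None:
    import imageio.v3 as iio

    path.mkdir(parents=True, exist_ok=True)
    quant = quantize_to_uint8(vol.voxels)
    width = len(str(vol.n_slices - 1))
    for k in range(vol.n_slices):
        iio.imwrite(path / f"slice_{k:0{width}d}.pgm", quant[k])


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_volume(
    path, format: str = "raw-binary", layout: dict | None = None, mu_water: float | None = None
) -> AttenuationVolume:
    """Read a CT volume.

    Parameters
    ----------
    path : path-like
        File (raw-binary) or directory (dicom-series).
    format : {"raw-binary", "dicom-series"}
    layout : dict, optional
        Raw-binary layout descriptor (``shape``, ``dtype``, ``mu_water``); when
        omitted the YAML sidecar written by :func:`write_volume` is used.
    mu_water : float, optional
        Overrides the water attenuation coefficient for DICOM series (no
        standard public tag carries it).
    """
    path = Path(path)
    if format == "raw-binary":
        return _read_raw(path, layout)
    if format == "dicom-series":
        return _read_dicom_series(path, mu_water)
    raise ValueError(f"unknown volume format: {format!r}")


def write_volume(vol: AttenuationVolume, path, format: str = "raw-binary") -> None:
    """Write a volume as raw binary (+YAML sidecar) or as a stack of 8-bit PGM slices."""
    path = Path(path)
    if format == "raw-binary":
        _write_raw(vol, path)
    elif format == "pgm-slices":
        _write_pgm_slices(vol, path)
    else:
        raise ValueError(f"unknown volume format: {format!r}")
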