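"""Core data types, coordinate conventions and raw-volume file I/O.

Conventions used throughout the package:

* Volumes are indexed ``(x, y, z)`` with ``z`` the axial (depth) axis and
  fastest-varying in memory (one A-scan is contiguous).
* ``z = 0`` is the *top* of the scan volume, i.e. the side nearest the scan
  head; depth increases with ``z``.  "Closest to the topside" therefore
  always means *smallest* ``z``.
* Surfaces are 2D heightmaps of fractional axial positions.  Undefined
  positions ("holes") are represented by NaN, which is out-of-band for
  heights (defined heights are always finite).

On disk, volumes are stored as little-endian raw binary plus a JSON sidecar
describing dims, dtype, voxel pitch and axis order; surfaces as 16-bit
TIFF heightmaps with the affine height scale recorded in the image
description; masks and 2D fingerprints as 8-bit PNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "FormatError",
    "ProcessingError",
    "Volume",
    "Surface",
    "Mask",
    "Region",
    "cast_to_uint8",
    "read_raw_volume",
    "write_raw_volume",
    "read_surface",
    "write_surface",
    "read_mask",
    "write_mask",
    "write_image",
]

#: Default voxel pitch (lateral x, lateral y, axial) in micrometres.
DEFAULT_PITCH_UM = (20.0, 20.0, 5.5)


class FormatError(Exception):
    """Raised for malformed or inconsistent on-disk data."""


class ProcessingError(Exception):
    """Raised when a processing stage cannot produce a usable result."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


@dataclass
class Volume:
    """A volumetric intensity scan indexed ``(x, y, z)``, z = 0 at the top."""

    data: np.ndarray
    pitch_um: tuple[float, float, float] = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        # scan volumes must be >= 8 per axis (enforced where scans enter
        # the system); coarse pyramid levels may be smaller
        if min(self.data.shape) < 2:
            raise ValueError(f"all dims must be >= 2, got {self.data.shape}")
        if self.data.dtype == np.uint8:
            pass
        elif np.issubdtype(self.data.dtype, np.floating):
            pass
        else:
            raise ValueError(f"unsupported dtype {self.data.dtype}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def dtype_tag(self) -> str:
        return "uint8" if self.data.dtype == np.uint8 else "float32"


@dataclass
class Surface:
    """2D heightmap of fractional axial positions; NaN marks a hole."""

    heights: np.ndarray
    nz: int
    pitch_um: tuple[float, float, float] = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError("surface heights must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]

    def holes(self) -> np.ndarray:
        return ~np.isfinite(self.heights)

    @property
    def n_holes(self) -> int:
        return int(self.holes().sum())

    def validate(self) -> None:
        """Check that all defined heights lie inside [0, nz - 1]."""
        h = self.heights[np.isfinite(self.heights)]
        if h.size and (h.min() < 0 or h.max() > self.nz - 1):
            raise ValueError(
                f"heights outside [0, {self.nz - 1}]: "
                f"range [{h.min():.2f}, {h.max():.2f}]"
            )

    def copy(self) -> "Surface":
        return Surface(self.heights.copy(), self.nz, self.pitch_um)


@dataclass
class Mask:
    """Boolean lateral map; True = position covered by the fingertip."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape  # type: ignore[return-value]

    @property
    def n_true(self) -> int:
        return int(self.bits.sum())


@dataclass
class Region:
    """Per-lateral-position axial search band [lo, hi] in voxel units."""

    lo: np.ndarray
    hi: np.ndarray
    nz: int = field(default=0)

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.float64)
        self.hi = np.asarray(self.hi, dtype=np.float64)
        if self.lo.shape != self.hi.shape:
            raise ValueError("lo/hi shape mismatch")
        if np.any(self.lo > self.hi):
            raise ValueError("region requires lo <= hi everywhere")
        if np.any(self.lo < 0) or (self.nz and np.any(self.hi > self.nz - 1)):
            raise ValueError("region band outside volume bounds")

    @classmethod
    def full(cls, shape: tuple[int, int], nz: int, z_min: float = 0.0) -> "Region":
        lo = np.full(shape, float(min(z_min, nz - 1)))
        hi = np.full(shape, float(nz - 1))
        return cls(lo, hi, nz)


def cast_to_uint8(v: Volume) -> Volume:
    """Cast a float volume to 8-bit: clamp to [0, 255], truncate decimals.

    The 8-bit range covers the full dynamic range of the scan data, so the
    cast loses only the decimal places while quartering the memory
    footprint.  Idempotent on volumes that are already 8-bit.
    """
    if v.data.dtype == np.uint8:
        return Volume(v.data, v.pitch_um)
    if not np.all(np.isfinite(v.data)):
        raise ValueError("cannot cast non-finite values")
    clipped = np.clip(v.data, 0.0, 255.0)
    return Volume(np.trunc(clipped).astype(np.uint8), v.pitch_um)


# ---------------------------------------------------------------------------
# Raw volume files (.raw + .json sidecar)

_DTYPES = {"uint8": np.uint8, "float32": np.float32}


def write_raw_volume(v: Volume, path: str | Path, meta_path: str | Path) -> None:
    path, meta_path = Path(path), Path(meta_path)
    data = np.ascontiguousarray(v.data)
    if data.dtype == np.float32 or data.dtype == np.float64:
        data = data.astype("<f4")
        dtype = "float32"
    else:
        dtype = "uint8"
    meta = {
        "dims": list(v.dims),
        "dtype": dtype,
        "pitch_um": list(v.pitch_um),
        "axis_order": "xyz",
        "z_origin": "top",
    }
    data.tofile(path)
    meta_path.write_text(json.dumps(meta, indent=2))


def read_raw_volume(path: str | Path, meta_path: str | Path) -> Volume:
    """Read a raw binary volume described by a JSON sidecar.

    The sidecar declares ``dims``, ``dtype``, ``pitch_um``, ``axis_order``
    (a permutation of "xyz" giving the order of the axes in the file, the
    last named axis fastest-varying) and ``z_origin`` ("top" or "bottom").
    The returned volume is normalized to (x, y, z) order with z = 0 at the
    top.
    """
    path, meta_path = Path(path), Path(meta_path)
    try:
        meta = json.loads(meta_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read sidecar {meta_path}: {exc}") from exc
    try:
        dims = tuple(int(d) for d in meta["dims"])
        dtype_name = meta["dtype"]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed sidecar {meta_path}: {exc}") from exc
    if dtype_name not in _DTYPES:
        raise FormatError(f"unknown dtype {dtype_name!r}")
    if len(dims) != 3:
        raise FormatError(f"dims must have 3 entries, got {dims}")
    if min(dims) < 8:
        raise FormatError(f"scan volumes must be >= 8 per axis, got {dims}")
    dtype = np.dtype(_DTYPES[dtype_name]).newbyteorder("<")
    expected = int(np.prod(dims)) * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise FormatError(
            f"{path}: file is {actual} bytes but sidecar implies {expected}"
        )
    data = np.fromfile(path, dtype=dtype).reshape(dims)

    axis_order = meta.get("axis_order", "xyz")
    if sorted(axis_order) != ["x", "y", "z"]:
        raise FormatError(f"invalid axis_order {axis_order!r}")
    data = np.transpose(data, [axis_order.index(a) for a in "xyz"])
    if meta.get("z_origin", "top") == "bottom":
        data = data[:, :, ::-1]
    pitch = tuple(meta.get("pitch_um", DEFAULT_PITCH_UM))
    return Volume(np.ascontiguousarray(data.astype(dtype.newbyteorder("="))), pitch)


# ---------------------------------------------------------------------------
# Surfaces, masks, images

_HOLE_CODE = 0  # reserved 16-bit value for holes; defined heights use 1..65535


def write_surface(s: Surface, path: str | Path) -> None:
    """Write a surface as a 16-bit TIFF heightmap with scale metadata.

    Heights are affinely mapped to 1..65535; the reserved value 0 encodes a
    hole.  The affine scale is stored as JSON in the TIFF description so the
    mapping is invertible to within 1/65535 of the height range.
    """
    h = s.heights
    defined = np.isfinite(h)
    if defined.any():
        h_min = float(np.min(h[defined]))
        h_max = float(np.max(h[defined]))
    else:
        h_min = h_max = 0.0
    span = h_max - h_min
    scaled = np.zeros(h.shape, dtype=np.uint16)
    if defined.any():
        if span > 0:
            vals = 1 + np.round((h[defined] - h_min) / span * 65534)
        else:
            vals = np.ones(int(defined.sum()))
        scaled[defined] = vals.astype(np.uint16)
    meta = {
        "h_min": h_min,
        "h_max": h_max,
        "nz": s.nz,
        "pitch_um": list(s.pitch_um),
        "has_holes": bool((~defined).any()),
    }
    tifffile.imwrite(Path(path), scaled, description=json.dumps(meta))


def read_surface(path: str | Path) -> Surface:
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        scaled = page.asarray()
        try:
            meta = json.loads(page.tags["ImageDescription"].value)
        except (KeyError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: missing surface scale metadata") from exc
    h = np.full(scaled.shape, np.nan)
    defined = scaled != _HOLE_CODE
    span = meta["h_max"] - meta["h_min"]
    h[defined] = meta["h_min"] + (scaled[defined] - 1) / 65534 * span
    return Surface(h, int(meta["nz"]), tuple(meta.get("pitch_um", DEFAULT_PITCH_UM)))


def write_mask(m: Mask, path: str | Path) -> None:
    iio.imwrite(Path(path), np.where(m.bits, 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> Mask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return Mask(arr > 127)


def write_image(pixels: np.ndarray, path: str | Path, ppi: float | None = None) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG, optionally with ppi."""
    from PIL import Image

    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    img = Image.fromarray(np.round(arr * 255).astype(np.uint8))
    if ppi:
        img.save(Path(path), dpi=(ppi, ppi))
    else:
        img.save(Path(path))
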