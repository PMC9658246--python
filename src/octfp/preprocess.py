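"""Intensity roll-off compensation, the 3D volume pyramid, and contrast
enhancement.

OCT sensitivity decreases with depth, so on a curved fingertip the far
parts of the surface are dimmer than the near parts.  Compensation fits an
ordinary least-squares line to the per-depth mean intensity A(z) and
subtracts the fitted deviation from the global mean, amplifying deep
voxels without touching the overall brightness.

The volume pyramid halves all three dimensions per level (which preserves
the finger's aspect ratio), and contrast enhancement cascades coarse-level
structure down the pyramid by upsampling each level and multiplying it
voxelwise into the next finer level, rescaling the product into the dtype
range.  Up/downsampling is trilinear with voxel-center alignment (the fine
sample positions are offset half a voxel from the coarse centers), which
keeps constant fields exactly constant and so cannot create the block
artifacts that nearest-neighbour or value-doubling upsampling would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_types import Volume

__all__ = [
    "DepthProfile",
    "VolumePyramid",
    "depth_profile",
    "rolloff_compensate",
    "build_pyramid",
    "contrast_enhance",
    "downsample2",
    "upsample2",
]


@dataclass
class DepthProfile:
    """Per-depth mean intensity and its deviation from the fitted trend."""

    A: np.ndarray       # mean intensity of each en-face slice, length Nz
    delta: np.ndarray   # fitted linear trend minus the global mean of A
    slope: float
    intercept: float


@dataclass
class VolumePyramid:
    """Levels V0..VN; each level halves the previous in all dimensions."""

    levels: list[Volume]

    @property
    def depth(self) -> int:
        return len(self.levels) - 1


def depth_profile(v: Volume) -> DepthProfile:
    if v.nz < 2:
        raise ValueError("need at least 2 depth samples for a regression")
    A = v.data.astype(np.float64).mean(axis=(0, 1))
    z = np.arange(v.nz, dtype=np.float64)
    slope, intercept = np.polyfit(z, A, 1)
    fitted = slope * z + intercept
    delta = fitted - A.mean()
    return DepthProfile(A, delta, float(slope), float(intercept))


def _restore_dtype(data: np.ndarray, like: np.ndarray) -> np.ndarray:
    if like.dtype == np.uint8:
        return np.clip(np.rint(data), 0, 255).astype(np.uint8)
    return data.astype(like.dtype)


def rolloff_compensate(v: Volume) -> Volume:
    """Subtract the fitted per-depth intensity trend from every voxel.

    Values are clamped to the input's value range ([0, 255] for 8-bit
    data) but returned as float32: the subtracted trend is fractional,
    and requantizing would inject +/-1 LSB noise whose pattern depends on
    the (data-dependent) fit — downstream sub-voxel detection is more
    reproducible without it.
    """
    if v.nz < 8:
        raise ValueError("volume too shallow for roll-off compensation")
    prof = depth_profile(v)
    out = v.data.astype(np.float64) - prof.delta[np.newaxis, np.newaxis, :]
    if v.data.dtype == np.uint8:
        np.clip(out, 0.0, 255.0, out=out)
    return Volume(out.astype(np.float32), v.pitch_um)


def downsample2(data: np.ndarray) -> np.ndarray:
    """2x trilinear reduction with center alignment (= 2x2x2 block mean)."""
    if any(d % 2 for d in data.shape):
        raise ValueError(f"dims must be even to downsample, got {data.shape}")
    nx, ny, nz = data.shape
    out = data.astype(np.float64).reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2)
    return out.mean(axis=(1, 3, 5))


def _upsample2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling along one axis, centers aligned.

    Fine sample j sits at coarse coordinate j/2 - 1/4, so even outputs mix
    the left neighbour with weight 1/4 and odd outputs the right one.
    Edges clamp (nearest) outside the coarse grid.
    """
    a = np.moveaxis(a, axis, -1)
    prev = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    nxt = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=np.float64)
    out[..., 0::2] = 0.25 * prev + 0.75 * a
    out[..., 1::2] = 0.75 * a + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def upsample2(data: np.ndarray) -> np.ndarray:
    """Separable trilinear 2x upsampling in all three dimensions."""
    out = data.astype(np.float64)
    for axis in range(3):
        out = _upsample2_axis(out, axis)
    return out


def build_pyramid(v: Volume, N: int) -> VolumePyramid:
    """Build levels V0..VN, halving all three dims per level.

    Levels are stored as float32: block means are fractional, and keeping
    them unquantized makes the later edge detection exactly invariant to
    the affine renormalization applied by :func:`contrast_enhance` (the
    edge kernels sum to zero, and peak location and sub-voxel refinement
    are invariant to positive rescaling).
    """
    if N < 1:
        raise ValueError("pyramid depth must be >= 1")
    if any(d % (1 << N) for d in v.dims):
        raise ValueError(f"dims {v.dims} not divisible by 2^{N}")
    levels = [Volume(v.data.astype(np.float32), v.pitch_um)]
    pitch = v.pitch_um
    for _ in range(N):
        pitch = tuple(2 * p for p in pitch)
        down = downsample2(levels[-1].data)
        levels.append(Volume(down.astype(np.float32), pitch))
    return VolumePyramid(levels)


def contrast_enhance(p: VolumePyramid) -> VolumePyramid:
    """Cascade coarse structure into the finer levels by multiplication.

    For i = N..1 the (already enhanced) level i is trilinearly upsampled to
    the dims of level i-1 and multiplied voxelwise into it; the product is
    computed in float and affinely rescaled to the full working range
    [0, 255] so repeated products cannot overflow.  A degenerate
    (constant) product maps to the range maximum.  Levels stay float (see
    :func:`build_pyramid`); the coarsest level is returned unchanged.
    """
    if p.depth < 1:
        raise ValueError("pyramid must have at least one coarse level")
    levels = [lev.data.astype(np.float32, copy=True) for lev in p.levels]
    for i in range(p.depth, 0, -1):
        up = upsample2(levels[i].astype(np.float64))
        prod = levels[i - 1].astype(np.float64) * up
        lo, hi = float(prod.min()), float(prod.max())
        if hi > lo:
            scaled = (prod - lo) * (255.0 / (hi - lo))
        else:
            scaled = np.full_like(prod, 255.0)
        levels[i - 1] = scaled.astype(np.float32)
    return VolumePyramid(
        [Volume(d, lev.pitch_um) for d, lev in zip(levels, p.levels)]
    )
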