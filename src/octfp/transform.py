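"""Envelope-based volume flattening/unflattening and 3D-to-2D conversion.

Flattening shifts every A-scan toward the volume top by the outer upper
envelope plus the outer-layer thickness ``delta_s = max(S - E)`` over the
mask, which moves the dermal-epidermal junction close to the top and
truncates the outer skin layer entirely out of the volume.  Flattening is
deliberately performed against the *envelope*, never the raw surface: a
surface-based flattening would imprint the outer ridge pattern onto the
deeper layers and produce a hybrid fingerprint.  The applied integer
shifts are recorded so the inner surface detected in the flattened volume
can be shifted back to its true position.

The 2D grayscale fingerprint is a parallel projection of a surface: its
height above the upper envelope, normalized by the local upper-lower
envelope distance (compensating natural ridge-height variation) and
clamped to [0, 1].  Ridge tops map to 0 (dark), valleys to 1 (light).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_types import Mask, Surface, Volume

__all__ = [
    "FlattenRecord",
    "Fingerprint2D",
    "flatten_volume",
    "unflatten_surface",
    "project_2d",
]


@dataclass
class FlattenRecord:
    """Applied per-line integer axial shifts and the layer thickness."""

    shift: np.ndarray          # rounded shifts, voxels, >= 0
    delta_s: float             # max over mask of (S - E)
    extrapolated: np.ndarray   # lines whose envelope came from the nearest
                               # masked neighbour


@dataclass
class Fingerprint2D:
    """2D grayscale fingerprint in [0, 1]; 1.0 (valley-white) outside the
    mask.  ``ppi`` derives from the lateral voxel pitch."""

    pixels: np.ndarray
    ppi: float


def _extrapolate_nearest(values: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """Fill positions outside ``bits`` with the nearest masked value."""
    if bits.all():
        return values
    _, (ix, iy) = ndimage.distance_transform_edt(~bits, return_indices=True)
    return values[ix, iy]


def flatten_volume(
    v: Volume, s: Surface, e_s: Surface, m: Mask
) -> tuple[Volume, FlattenRecord]:
    """Shift every A-scan up by ``round(E(x,y) + delta_s)`` voxels.

    ``E`` is the outer upper envelope (nearest-masked extrapolated outside
    the mask) and ``delta_s = max over mask of (S - E)``, so for every
    masked line the flattened content at z = 0 lies at or below the
    original surface: the outer layer is completely removed.  Samples
    shifted past the top are discarded; vacated samples at the bottom are
    zero-filled.  Shifts are integer (no axial resampling) and recorded.
    """
    bits = m.bits
    if not bits.any():
        raise ValueError("empty mask")
    S, E = s.heights, e_s.heights
    if not (np.isfinite(S[bits]).all() and np.isfinite(E[bits]).all()):
        raise ValueError("surface and envelope must be hole-free inside the mask")
    E_ext = _extrapolate_nearest(np.where(bits, E, np.nan), bits)
    delta_s = float(np.max(S[bits] - E[bits]))
    shift = np.rint(E_ext + delta_s).astype(np.int32)
    np.clip(shift, 0, None, out=shift)

    nz = v.nz
    zsrc = shift[..., None] + np.arange(nz, dtype=np.int32)
    valid = zsrc < nz
    flat = np.take_along_axis(v.data, np.minimum(zsrc, nz - 1), axis=2)
    flat = np.where(valid, flat, 0)
    rec = FlattenRecord(shift=shift, delta_s=delta_s, extrapolated=~bits)
    return Volume(flat.astype(v.data.dtype), v.pitch_um), rec


def unflatten_surface(s_flat: Surface, rec: FlattenRecord) -> Surface:
    """Reverse the recorded shifts: exact inverse on the integer shifts."""
    if s_flat.heights.shape != rec.shift.shape:
        raise ValueError("surface and flatten record dims differ")
    return Surface(s_flat.heights + rec.shift, s_flat.nz, s_flat.pitch_um)


def project_2d(
    s: Surface,
    eup: Surface,
    elow: Surface,
    m: Mask,
    eps: float = 1e-6,
) -> Fingerprint2D:
    """(S - Eup) / (Elow - Eup), clamped to [0, 1].

    Degenerate pixels (envelope distance below ``eps``) carry no relief
    and map to 0.5; everything outside the mask is background white (1.0).
    """
    bits = m.bits
    denom = elow.heights - eup.heights
    with np.errstate(invalid="ignore", divide="ignore"):
        val = (s.heights - eup.heights) / denom
    val = np.clip(val, 0.0, 1.0)
    val = np.where(np.abs(denom) < eps, 0.5, val)
    pixels = np.where(bits, val, 1.0)
    ppi = 25400.0 / s.pitch_um[0]
    return Fingerprint2D(pixels, ppi)
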