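"""Fingertip-coverage mask from intensity contrast across the surface.

A detected surface covers the whole scan area even where there is no
finger, so the valid fingerprint area has to be recovered.  The detected
outer surface sits exactly at the air-skin boundary: below it there is
bright tissue, above it only air.  Comparing the maximum voxel value in a
band just below the surface with the one just above therefore classifies
fingertip lines correctly almost everywhere, while background lines (where
the "surface" is noise) come out right only about half the time.  Box
blurring at the friction-ridge scale followed by Otsu re-binarization
removes that salt noise, and connected-component cleanup (keep the largest
4-connected foreground component, fill enclosed background) yields a
single contiguous fingertip mask, independent of finger shape or
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io_types import Mask, ProcessingError, Surface, Volume

__all__ = ["MaskingConfig", "raw_mask", "refine_mask", "compute_mask"]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class MaskingConfig:
    """w_n: half-depth (voxels) of the above/below probe bands, roughly the
    outer skin-layer thickness; ridge_px: expected pixel distance between
    friction ridges (box-blur size, odd)."""

    w_n: int = 20
    ridge_px: int = 25

    def __post_init__(self) -> None:
        if self.w_n < 1:
            raise ValueError("w_n must be >= 1")
        if self.ridge_px < 3 or self.ridge_px % 2 == 0:
            raise ValueError("ridge_px must be odd and >= 3")


def raw_mask(v: Volume, s: Surface, w_n: int) -> Mask:
    """Per line: True iff max intensity below the surface exceeds the max
    above it (bands of depth w_n, clipped at the volume; ties -> False).

    ``v`` should be the *uncompensated* scan: roll-off compensation adds
    the fitted depth trend to every voxel including the air, which tilts
    the below/above comparison toward True everywhere and drowns the
    ~50/50 behaviour of background lines that the later refinement relies
    on.  The air/skin contrast this probe measures needs no compensation.
    """
    if w_n >= v.nz:
        raise ValueError(f"w_n={w_n} must be smaller than the scan depth {v.nz}")
    if s.holes().any():
        raise ProcessingError("surface must be hole-free for masking", stage="raw_mask")
    S = s.heights[..., None]
    zg = np.arange(v.nz)
    below = np.where((zg > S) & (zg <= S + w_n), v.data, 0).max(axis=-1)
    above = np.where((zg >= S - w_n) & (zg < S), v.data, 0).max(axis=-1)
    return Mask(below > above)


def _largest_component(bits: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(bits, structure=_CROSS)
    if n == 0:
        raise ProcessingError("no fingertip found", stage="refine_mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _fill_enclosed(bits: np.ndarray) -> np.ndarray:
    """Set background components that do not touch the image border."""
    labels, n = ndimage.label(~bits, structure=_CROSS)
    if n == 0:
        return bits
    border = np.zeros(bits.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    exterior = np.unique(labels[border & ~bits])
    out = bits.copy()
    interior = ~np.isin(labels, np.concatenate([[0], exterior]))
    out[interior] = True
    return out


def refine_mask(raw: Mask, ridge_px: int) -> Mask:
    """Clean the raw mask: ridge-scale box blur, Otsu re-binarization,
    connected-component cleanup, and one final blur+rebinarize smoothing
    pass.  The result is a single 4-connected component without holes."""
    f = ndimage.uniform_filter(raw.bits.astype(np.float64), ridge_px, mode="nearest")
    if np.ptp(f) == 0:
        raise ProcessingError("uniform blurred mask (no fingertip found)", stage="refine_mask")
    bits = f > threshold_otsu(f)
    if not bits.any():
        raise ProcessingError("Otsu removed everything", stage="refine_mask")
    bits = _fill_enclosed(_largest_component(bits))
    # edge smoothing: one more blur + rebinarize, then re-establish the
    # single-component/no-hole invariant
    g = ndimage.uniform_filter(bits.astype(np.float64), ridge_px, mode="nearest")
    bits = g > 0.5
    if not bits.any():
        raise ProcessingError("smoothing removed everything", stage="refine_mask")
    return Mask(_fill_enclosed(_largest_component(bits)))


def compute_mask(v: Volume, s: Surface, cfg: MaskingConfig | None = None) -> Mask:
    cfg = cfg or MaskingConfig()
    return refine_mask(raw_mask(v, s, cfg.w_n), cfg.ridge_px)
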