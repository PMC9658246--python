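"""Upper and lower ridge envelopes of a fingerprint surface.

Flattening a volume directly against the fingerprint surface would press
the ridge pattern into the deeper skin layers, so flattening uses an
*envelope*: a smooth surface that carries the overall finger shape but no
ridge information.  The upper envelope touches only the ridge tops (small
z; z = 0 is the scan top), the lower envelope only the valley bottoms.

Per scan row the envelope is found by a horizon search: starting at the
highest ridge top (the global minimum z of the profile), the next top in
each direction is the sample, within the expected ridge spacing ``l``,
that maximizes the elevation angle toward the scan top — i.e. the point
visible on the horizon of the downward-curved fingertip.  This is a
bounded-edge-length upper convex hull step: for a convex profile it
reproduces the convex hull, while the window bound keeps concave
fingertips from being bridged too far.  Adjacent tops are joined by
linear interpolation.  A single pass can dip into valleys where ridges
are crossed at a shallow angle, so the search runs along rows and along
columns and keeps, per pixel, whichever preliminary envelope is closer to
the scan top.  A final box filter removes the roughness left by diagonal
ridges.  The lower envelope reuses the same search on the surface
mirrored about the upper envelope, flipping the result back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_types import Mask, Surface

__all__ = [
    "EnvelopeConfig",
    "envelope_1d",
    "upper_envelope",
    "lower_envelope",
]


@dataclass
class EnvelopeConfig:
    """l: expected maximum pixel distance between adjacent papillary
    ridges (horizon visibility window); smooth_px: final box-filter size
    (odd; 1 disables smoothing).

    ``smooth_px`` targets the line-to-line roughness left by per-B-scan
    processing and detection noise — a few pixels — not the ridge period;
    smoothing at the ridge scale would drag the envelope far enough off
    the tops to defeat its purpose.  After smoothing the envelope is
    projected back onto the correct side of the surface, so the envelope
    property (upper at or above every sample, lower at or below) holds
    exactly even where the box filter would have crossed.
    """

    l: int = 50
    smooth_px: int = 9

    def __post_init__(self) -> None:
        if self.l < 2:
            raise ValueError("l must be >= 2")
        if self.smooth_px < 1 or self.smooth_px % 2 == 0:
            raise ValueError("smooth_px must be odd and >= 1")


def _march(profile: np.ndarray, start: int, l: int, direction: int) -> list[int]:
    """Collect ridge tops from ``start`` marching in ``direction``.

    The next top is the sample within the window of length ``l`` whose
    line of sight from the current top has the steepest rise toward the
    scan top, i.e. minimal (h[j] - h[c]) / |j - c|; ties go to the
    farthest sample, so flat stretches are crossed in single steps.
    """
    n = profile.size
    tops = []
    c = start
    while True:
        if direction > 0:
            if c >= n - 1:
                break
            j = np.arange(c + 1, min(c + l, n - 1) + 1)
        else:
            if c <= 0:
                break
            j = np.arange(max(c - l, 0), c)[::-1]
        slopes = (profile[j] - profile[c]) / np.abs(j - c)
        # last occurrence of the minimum = farthest candidate
        best = slopes.size - 1 - int(np.argmin(slopes[::-1]))
        c = int(j[best])
        tops.append(c)
    return tops


def envelope_1d(profile: np.ndarray, l: int) -> np.ndarray:
    """Upper envelope of one height profile (smaller value = higher).

    Seeds at the global minimum, marches the horizon search outward in
    both directions, and linearly interpolates between consecutive tops.
    Because each hop takes the minimal-slope line of sight, every
    interpolated segment lies at or above (in the scan-top sense, i.e. at
    smaller or equal z than) the profile samples it spans: the envelope
    bridges valleys and never undercuts a ridge top.
    """
    profile = np.asarray(profile, dtype=np.float64)
    n = profile.size
    if n < 2:
        return profile.copy()
    if l > n - 1:
        raise ValueError(f"window l={l} larger than profile length {n}")
    seed = int(np.argmin(profile))
    tops = (
        _march(profile, seed, l, -1)[::-1] + [seed] + _march(profile, seed, l, +1)
    )
    idx = np.asarray(tops)
    return np.interp(np.arange(n), idx, profile[idx])


def _runs(mask_row: np.ndarray):
    """Contiguous True runs of a 1D boolean array as (start, stop) pairs."""
    d = np.diff(mask_row.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return zip(starts, stops)


def _envelope_lines(h: np.ndarray, bits: np.ndarray, l: int) -> np.ndarray:
    out = np.full(h.shape, np.nan)
    for i in range(h.shape[0]):
        for a, b in _runs(bits[i]):
            seg = h[i, a:b]
            out[i, a:b] = (
                envelope_1d(seg, min(l, seg.size - 1)) if seg.size > 1 else seg
            )
    return out


def _masked_box(h: np.ndarray, bits: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return h
    num = ndimage.uniform_filter(np.where(bits, h, 0.0), size, mode="constant")
    den = ndimage.uniform_filter(bits.astype(np.float64), size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(bits, out, np.nan)


def upper_envelope(s: Surface, m: Mask, cfg: EnvelopeConfig | None = None) -> Surface:
    """Upper ridge envelope inside the mask (NaN outside).

    Horizon search along every row and every column of the mask, combined
    per pixel by the value closer to the scan top (smaller z), then
    box-smoothed within the mask.
    """
    cfg = cfg or EnvelopeConfig()
    bits = m.bits
    if not bits.any():
        raise ValueError("empty mask")
    h = s.heights
    if not np.isfinite(h[bits]).all():
        raise ValueError("surface must be hole-free inside the mask")
    rows = _envelope_lines(h, bits, cfg.l)
    cols = _envelope_lines(h.T, bits.T, cfg.l).T
    comb = np.fmin(rows, cols)
    comb = _masked_box(comb, bits, cfg.smooth_px)
    # order-restoring projection: smoothing must not push the envelope
    # below any ridge top it is supposed to touch
    comb = np.fmin(comb, h)
    return Surface(np.where(bits, comb, np.nan), s.nz, s.pitch_um)


def lower_envelope(
    s: Surface, eup: Surface, m: Mask, cfg: EnvelopeConfig | None = None
) -> Surface:
    """Lower (valley) envelope: upper envelope of the surface mirrored
    about the upper envelope, flipped back."""
    cfg = cfg or EnvelopeConfig()
    mirrored = Surface(2.0 * eup.heights - s.heights, s.nz, s.pitch_um)
    env = upper_envelope(mirrored, m, cfg)
    return Surface(2.0 * eup.heights - env.heights, s.nz, s.pitch_um)
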