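"""Coarse-to-fine surface segmentation over the volume pyramid.

Skin-layer thickness varies across a fingertip, and the edge filter only
works well when its kernel size roughly matches the layer it is probing.
Detection therefore runs a whole set of kernel sizes on every scan line
and keeps, per line and per kernel, the best valid candidate position and
its peak response (the *result set*).  The kernel actually used at a line
is the one whose candidate positions are most self-consistent in a small
lateral neighbourhood: for each kernel the standard deviation of its
candidates over a (2r+1)^2 window, weighted by peak response, is computed,
and the kernel with the smallest deviation wins (ties go to the smaller
kernel).  Lines where no kernel produced a valid candidate stay holes and
are later collapsed by repeated interpolation at their perimeter.

Because edge responses are only trustworthy near the true surface, each
pyramid level restricts the search to a band (the *region*) centered on
the previous (coarser) level's surface.  The band half-width is a multiple
of the weighted-median kernel size of the previous run — kernel size
tracks layer thickness, so the band is wide enough for the layer but does
not reach neighbouring layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import edge_filter
from .io_types import Mask, ProcessingError, Region, Surface, Volume
from .preprocess import build_pyramid, contrast_enhance

__all__ = [
    "ResultSet",
    "DetectionConfig",
    "KernelSelection",
    "detect_surface",
    "select_kernel_per_line",
    "weighted_median_kernel",
    "narrow_region",
    "fill_holes",
    "upscale_surface",
    "segment_fingerprint",
]


@dataclass
class ResultSet:
    """Per lateral position and kernel size: candidate position + weight.

    ``positions[x, y, k]`` is the sub-voxel axial position found by kernel
    ``kernel_sizes[k]`` (NaN if the line produced no valid candidate for
    that kernel); ``weights[x, y, k]`` is the peak filter response within
    the region (kept for diagnostics even when the candidate is invalid).
    """

    positions: np.ndarray
    weights: np.ndarray
    kernel_sizes: tuple[int, ...]


@dataclass
class KernelSelection:
    """Outcome of the per-line kernel choice."""

    kernel_index: np.ndarray  # index into kernel_sizes, -1 for holes
    weight: np.ndarray        # peak response of the chosen candidate
    kernel_sizes: tuple[int, ...]


@dataclass
class DetectionConfig:
    """Tunables of the coarse-to-fine segmentation.

    The defaults substitute the hardware-dependent constants of the
    original acquisition setup and are logged at every run:

    f_w            region scaling factor (region half-width = f_w x
                   weighted-median kernel size of the previous level).
    w_N            initial axial search extent at the coarsest level in
                   coarsest-level voxels (None = full depth).
    kernel_sizes   kernel-size set at full resolution; halved (kept even,
                   min 2) per pyramid level.
    r_var          neighbourhood radius of the weighted-std kernel vote.
    pyramid_depth  number of pyramid levels above full resolution
                   (None = 3, or 4 for gigavoxel scans).
    z_min          lower bound of the initial search region in full-
                   resolution voxels (used to skip the truncated outer
                   layer during the inner-fingerprint pass).
    contrast_enhancement
                   multiply coarse pyramid structure into the finer
                   levels before detection.  This rescues low-contrast
                   boundary detection against a noisy background (the
                   outer pass), but ties the detected sub-voxel positions
                   to the absolute pyramid alignment, so the inner pass —
                   which runs on a per-line-shifted (flattened) volume
                   whose alignment depends on the other run's envelope —
                   turns it off for reproducibility.
    max_hole_iters safety bound for hole interpolation sweeps.
    """

    f_w: float = 1.5
    w_N: int | None = None
    kernel_sizes: tuple[int, ...] = (4, 6, 8, 12, 16)
    r_var: int = 2
    pyramid_depth: int | None = None
    z_min: int = 0
    contrast_enhancement: bool = True
    max_hole_iters: int = 1024

    def __post_init__(self) -> None:
        if self.f_w <= 1.0:
            raise ValueError("f_w must be > 1")
        if not self.kernel_sizes:
            raise ValueError("kernel set must not be empty")
        if any(L < 2 or L % 2 for L in self.kernel_sizes):
            raise ValueError("kernel sizes must be even and >= 2")
        if self.r_var < 1:
            raise ValueError("r_var must be >= 1")
        self.kernel_sizes = tuple(sorted(self.kernel_sizes))


# A-scan chunk target (samples) for the vectorized response sweep; bounds
# the float64 working set to ~256 MB regardless of volume size.
_CHUNK_VOXELS = 1 << 25


def detect_surface(
    v: Volume,
    region: Region,
    kernel_sizes: tuple[int, ...] | list[int],
    mask: Mask | None = None,
) -> ResultSet:
    """Run the multi-kernel edge search on every (masked) scan line.

    For each line and kernel size the maximum response within the region
    is located; the candidate survives only if it is strictly positive and
    declines to zero within one kernel length on both sides (see
    :mod:`octfp.edge_filter`).  Surviving positions are parabolically
    refined to sub-voxel precision.
    """
    if not kernel_sizes:
        raise ValueError("empty kernel set")
    kernel_sizes = tuple(sorted(set(int(L) for L in kernel_sizes)))
    nx, ny, nz = v.dims
    if region.lo.shape != (nx, ny):
        raise ValueError("region shape does not match volume")
    nk = len(kernel_sizes)
    positions = np.full((nx, ny, nk), np.nan)
    weights = np.zeros((nx, ny, nk))
    line_ok = mask.bits if mask is not None else np.ones((nx, ny), bool)

    zg = np.arange(nz)
    x_step = max(1, _CHUNK_VOXELS // (ny * nz))
    for ki, L in enumerate(kernel_sizes):
        fam = edge_filter.normalize(edge_filter.make_kernels(L))
        if nz < L + 2:
            continue
        for x0 in range(0, nx, x_step):
            sl = slice(x0, min(nx, x0 + x_step))
            resp = edge_filter.response_full(v.data[sl], fam)
            lo = region.lo[sl][..., None]
            hi = region.hi[sl][..., None]
            in_band = (zg >= lo - 1e-9) & (zg <= hi + 1e-9)
            in_band &= line_ok[sl][..., None]
            banded = np.where(in_band, resp, -np.inf)
            iz = np.argmax(banded, axis=-1)
            peak = np.take_along_axis(banded, iz[..., None], axis=-1)[..., 0]
            has_band = in_band.any(axis=-1)
            peak = np.where(has_band, peak, 0.0)

            floor = 1e-9 * np.maximum(1.0, np.abs(resp).max(axis=-1))
            tol = np.maximum(edge_filter.GATE_REL * peak, floor)
            # windowed "any response <= tol" on each side of the peak via a
            # cumulative count; indices beyond the line count as <= 0
            # (zero-padded signal).
            nonpos = (resp <= tol[..., None]).astype(np.int32)
            cs = np.zeros(nonpos.shape[:-1] + (nz + 1,), np.int32)
            np.cumsum(nonpos, axis=-1, out=cs[..., 1:])
            total = cs[..., -1]

            def count_between(a, b):
                # nonpos count over integer z in [a, b], clipped to line
                a = np.clip(a, 0, nz)
                b = np.clip(b + 1, 0, nz)
                lo_c = np.take_along_axis(cs, a[..., None], axis=-1)[..., 0]
                hi_c = np.take_along_axis(cs, b[..., None], axis=-1)[..., 0]
                return hi_c - lo_c

            right_ok = (iz + L >= nz) | (count_between(iz + 1, iz + L) > 0)
            left_ok = (iz - L < 0) | (count_between(iz - L, iz - 1) > 0)
            # peaks at the line boundary are the zero-padding step artifact
            interior = (iz > 0) & (iz < nz - 1)
            valid = has_band & interior & (peak > floor) & right_ok & left_ok

            # sub-voxel parabolic refinement through the raw response
            izc = iz[..., None]
            r0 = np.take_along_axis(resp, izc, axis=-1)[..., 0]
            rm1 = np.take_along_axis(resp, np.maximum(izc - 1, 0), -1)[..., 0]
            rp1 = np.take_along_axis(resp, np.minimum(izc + 1, nz - 1), -1)[..., 0]
            denom = rm1 - 2.0 * r0 + rp1
            safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
            off = np.where(np.abs(denom) > 1e-12, 0.5 * (rm1 - rp1) / safe, 0.0)
            off = np.clip(off, -0.5, 0.5)
            off[(iz == 0) | (iz == nz - 1)] = 0.0
            pos = np.clip(iz + off, region.lo[sl], region.hi[sl])

            positions[sl, :, ki] = np.where(valid, pos, np.nan)
            weights[sl, :, ki] = np.maximum(np.where(has_band, peak, 0.0), 0.0)
    return ResultSet(positions, weights, kernel_sizes)


def select_kernel_per_line(
    rs: ResultSet, r_var: int = 2, line_offset: np.ndarray | None = None
) -> tuple[Surface, KernelSelection]:
    """Pick, per line, the kernel with the most laterally stable candidates.

    For each kernel the response-weighted standard deviation of its
    candidate positions over the (2*r_var+1)^2 neighbourhood is computed
    (holes excluded, windows truncated at the borders); the chosen kernel
    is the argmin, ties broken toward the smaller kernel size.  Lines with
    no valid candidate from any kernel remain holes.

    ``line_offset`` (per lateral position, same axial units as the
    positions) is added to the candidates *for the variance computation
    only*.  A volume that was flattened by per-line integer shifts is
    deliberately jagged; the lateral-smoothness assumption behind the
    variance vote holds for the physical surface, so the vote must be
    taken on unshifted positions.  The returned surface stays in the
    volume's own (shifted) coordinates.
    """
    pos, w = rs.positions, rs.weights
    pos_eff = pos
    if line_offset is not None:
        pos_eff = pos + np.asarray(line_offset, dtype=np.float64)[..., None]
    nx, ny, nk = pos.shape
    size = 2 * r_var + 1
    stds = np.full((nx, ny, nk), np.inf)
    for k in range(nk):
        valid = np.isfinite(pos[..., k])
        wk = np.where(valid, w[..., k], 0.0)
        pk = np.where(valid, pos_eff[..., k], 0.0)
        area = float(size * size)
        sw = ndimage.uniform_filter(wk, size, mode="constant") * area
        swx = ndimage.uniform_filter(wk * pk, size, mode="constant") * area
        swx2 = ndimage.uniform_filter(wk * pk * pk, size, mode="constant") * area
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = swx / sw
            var = np.maximum(swx2 / sw - mean * mean, 0.0)
        std = np.sqrt(var)
        std[~valid | (sw <= 0)] = np.inf
        stds[..., k] = std
    choice = np.argmin(stds, axis=-1)  # first minimum -> smaller L on ties
    any_valid = np.isfinite(stds).any(axis=-1)
    heights = np.take_along_axis(pos, choice[..., None], axis=-1)[..., 0]
    cw = np.take_along_axis(w, choice[..., None], axis=-1)[..., 0]
    heights = np.where(any_valid, heights, np.nan)
    sel = KernelSelection(
        kernel_index=np.where(any_valid, choice, -1),
        weight=np.where(any_valid, cw, 0.0),
        kernel_sizes=rs.kernel_sizes,
    )
    return Surface(heights, nz=0), sel


def weighted_median_kernel(sel: KernelSelection) -> int:
    """Weighted median of the chosen kernel sizes (weights = peak
    responses), deterministic tie-break toward the smaller size."""
    sizes = np.asarray(sel.kernel_sizes)
    totals = np.array(
        [
            sel.weight[sel.kernel_index == k].sum()
            for k in range(sizes.size)
        ]
    )
    total = totals.sum()
    if total <= 0:
        raise ProcessingError("no usable surface candidates", stage="narrow_region")
    cum = np.cumsum(totals)
    return int(sizes[int(np.searchsorted(cum, total / 2.0))])


def narrow_region(
    center: Surface,
    sel: KernelSelection,
    f_w: float,
    level_scale: int = 2,
) -> Region:
    """Axial search band for the next (finer) level.

    Centered on the upscaled, hole-free previous surface; the half-width is
    ``f_w`` times the weighted-median kernel size of the previous run,
    multiplied by ``level_scale`` to convert the coarser level's voxel
    units to the target level.
    """
    if not np.isfinite(center.heights).all():
        raise ProcessingError("region center surface has holes", stage="narrow_region")
    wm = weighted_median_kernel(sel)
    hw = f_w * wm * level_scale
    nz = center.nz
    lo = np.clip(center.heights - hw, 0.0, nz - 1)
    hi = np.clip(center.heights + hw, 0.0, nz - 1)
    return Region(lo, hi, nz)


def fill_holes(
    s: Surface, mask: Mask | None = None, max_iters: int = 1024
) -> Surface:
    """Collapse holes by repeated interpolation at their perimeter.

    Each sweep assigns every hole with at least one defined 8-neighbour the
    mean of those neighbours (double-buffered, so the sweep order cannot
    bias the result).  With a mask, only holes inside the mask are filled;
    defined values outside may still contribute as neighbours.
    """
    h = s.heights.copy()
    target = mask.bits if mask is not None else np.ones(h.shape, bool)
    if not np.isfinite(h[target]).any():
        raise ProcessingError("surface is entirely holes", stage="fill_holes")
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    for _ in range(max_iters):
        holes = ~np.isfinite(h) & target
        if not holes.any():
            break
        defined = np.isfinite(h)
        vals = np.where(defined, h, 0.0)
        ssum = ndimage.convolve(vals, kernel, mode="constant")
        cnt = ndimage.convolve(defined.astype(np.float64), kernel, mode="constant")
        fill = holes & (cnt > 0)
        h[fill] = ssum[fill] / cnt[fill]
    else:
        if (~np.isfinite(h) & target).any():
            raise ProcessingError(
                "hole interpolation did not converge", stage="fill_holes"
            )
    return Surface(h, s.nz, s.pitch_um)


def upscale_surface(s: Surface) -> Surface:
    """Bilinear 2x lateral upscaling with center alignment; heights double
    because the axial pitch halves at the finer level."""
    h = s.heights
    for axis in (0, 1):
        h = _up2_axis(h, axis)
    return Surface(2.0 * h, 2 * s.nz, tuple(p / 2 for p in s.pitch_um))


def _up2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, -1)
    prev = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    nxt = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],))
    out[..., 0::2] = 0.25 * prev + 0.75 * a
    out[..., 1::2] = 0.75 * a + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _level_kernels(kernel_sizes: tuple[int, ...], n: int) -> tuple[int, ...]:
    """Kernel set at pyramid level n: sizes halved n times, floored to the
    nearest even value, minimum 2, duplicates merged."""
    out = sorted({max(2, ((L >> n) // 2) * 2) for L in kernel_sizes})
    return tuple(out)


def _downscale_mask(bits: np.ndarray) -> np.ndarray:
    nx, ny = bits.shape
    blocks = bits.astype(np.float64).reshape(nx // 2, 2, ny // 2, 2)
    return blocks.mean(axis=(1, 3)) >= 0.5


def default_pyramid_depth(dims: tuple[int, int, int]) -> int:
    """3 levels above full resolution (4 for gigavoxel scans), reduced so
    that the coarsest level keeps at least 32 voxels per dimension — any
    coarser and the two skin-layer bands merge into single voxels."""
    n = 4 if min(dims) >= 1024 else 3
    while n > 1 and (any(d % (1 << n) for d in dims) or min(dims) >> n < 32):
        n -= 1
    return n


def _downscale_offset(off: np.ndarray) -> np.ndarray:
    nx, ny = off.shape
    return off.reshape(nx // 2, 2, ny // 2, 2).mean(axis=(1, 3)) / 2.0


def segment_fingerprint(
    v: Volume,
    cfg: DetectionConfig | None = None,
    mask: Mask | None = None,
    collect: dict | None = None,
    line_offset: np.ndarray | None = None,
) -> Surface:
    """Full coarse-to-fine fingerprint surface segmentation.

    Builds the contrast-enhanced pyramid, then walks it from coarsest to
    finest: multi-kernel detection in the current region, per-line kernel
    selection, hole collapse, then 2x surface upscaling and region
    narrowing for the next level.  Returns the full-resolution surface
    (hole-free inside the mask).

    ``collect``, if given, receives per-level diagnostics (surfaces, hole
    counts, regions, kernel sets, weighted-median kernel sizes).
    ``line_offset`` is the per-line axial shift previously applied to the
    volume (see :func:`select_kernel_per_line`); it is rescaled per
    pyramid level.
    """
    cfg = cfg or DetectionConfig()
    if min(v.dims) < 8:
        raise ValueError(f"scan volume too small: {v.dims}")
    N = cfg.pyramid_depth if cfg.pyramid_depth is not None else default_pyramid_depth(v.dims)
    if N < 1:
        raise ValueError("volume too small to build a pyramid")
    pyr = build_pyramid(v, N)
    if cfg.contrast_enhancement:
        pyr = contrast_enhance(pyr)

    masks: list[np.ndarray | None] = [mask.bits if mask is not None else None]
    offsets: list[np.ndarray | None] = [
        np.asarray(line_offset, dtype=np.float64) if line_offset is not None else None
    ]
    for _ in range(N):
        prev = masks[-1]
        masks.append(_downscale_mask(prev) if prev is not None else None)
        prev_off = offsets[-1]
        offsets.append(_downscale_offset(prev_off) if prev_off is not None else None)

    log: dict = {"levels": [], "pyramid_depth": N}
    nz_top = pyr.levels[N].nz
    z_min_top = cfg.z_min / (1 << N)
    hi_top = nz_top - 1
    if cfg.w_N is not None:
        hi_top = min(hi_top, z_min_top + cfg.w_N)
    lo = np.full(pyr.levels[N].data.shape[:2], float(z_min_top))
    hi = np.full_like(lo, float(hi_top))
    region = Region(np.minimum(lo, hi), hi, nz_top)

    surf: Surface | None = None
    for n in range(N, -1, -1):
        level = pyr.levels[n]
        Ls = _level_kernels(cfg.kernel_sizes, n)
        m_n = Mask(masks[n]) if masks[n] is not None else None
        rs = detect_surface(level, region, Ls, m_n)
        raw_surf, sel = select_kernel_per_line(rs, cfg.r_var, offsets[n])
        raw_surf.nz = level.nz
        raw_surf.pitch_um = level.pitch_um
        n_holes_raw = int(
            (~np.isfinite(raw_surf.heights) & (m_n.bits if m_n else np.True_)).sum()
        )
        surf = fill_holes(raw_surf, m_n, cfg.max_hole_iters)
        log["levels"].append(
            {
                "level": n,
                "dims": list(level.dims),
                "kernel_sizes": list(Ls),
                "holes_before_fill": n_holes_raw,
                "region_mean_width": float((region.hi - region.lo).mean()),
            }
        )
        if collect is not None:
            collect.setdefault("surfaces", []).append(surf.copy())
            collect.setdefault("regions", []).append(region)
        if n > 0:
            wm = weighted_median_kernel(sel)
            log["levels"][-1]["weighted_median_kernel"] = wm
            # extend the center surface beyond the mask so the next level
            # has a defined band everywhere it might look
            center = surf
            if center.holes().any():
                center = fill_holes(center, None, cfg.max_hole_iters)
            center = upscale_surface(center)
            hw = cfg.f_w * wm * 2
            nz_next = pyr.levels[n - 1].nz
            region = Region(
                np.clip(center.heights - hw, 0.0, nz_next - 1),
                np.clip(center.heights + hw, 0.0, nz_next - 1),
                nz_next,
            )
    if collect is not None:
        collect["log"] = log
    assert surf is not None
    return surf
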