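"""Adaptive 1D low-pass edge detection along A-scans.

The filter convolves each scan line with a size-``L`` antisymmetric ramp
kernel

    kernel0 = [1, 2, ..., L/2, -L/2, ..., -2, -1]

which responds with a positive peak both to a dark-to-bright step and to a
thin bright band (the air-skin boundary) at the feature position, while its
ramp shape suppresses speckle.  Convolving with the dense kernel directly
would cost O(L) per sample; instead the kernel is differentiated twice
under zero padding, leaving a sparse kernel with exactly four non-zero taps
{+1, -(L+1), +(L+1), -1}.  Convolution with the sparse kernel followed by
two cumulative sums (plus the two integration constants contributed by the
zero- and first-order kernels at the start index) reproduces the dense
result in a single O(n) pass, independent of L.

All kernels are used in normalized form, scaled by (2/L)/(L/2+1), which
makes the peak response to a unit step equal to 0.5 for every kernel size
so that responses of different kernel sizes are directly comparable.

Response alignment: ``response[z]`` is the full (zero-padded) convolution
evaluated at lag ``z + L/2 - 1``, which places the positive peak exactly at
a step transition or thin-band position ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KernelFamily",
    "make_kernels",
    "normalize",
    "sparse_convolve",
    "dense_convolve",
    "line_edge_response",
]


@dataclass(frozen=True)
class KernelFamily:
    """The three derivative levels of the edge kernel of size ``L``."""

    L: int
    taps0: np.ndarray  # dense ramp kernel, length L
    taps1: np.ndarray  # first zero-padded difference, length L+1
    taps2: np.ndarray  # second difference, length L+2, 4 non-zero taps
    norm: float  # normalization constant (2/L)/(L/2+1)
    normalized: bool = False


def make_kernels(L: int) -> KernelFamily:
    """Construct the (unnormalized) kernel family for even ``L >= 2``."""
    if L < 2 or L % 2:
        raise ValueError(f"kernel size must be even and >= 2, got {L}")
    half = L // 2
    taps0 = np.concatenate(
        [np.arange(1, half + 1), -np.arange(half, 0, -1)]
    ).astype(np.float64)
    taps1 = np.diff(taps0, prepend=0.0, append=0.0)
    taps2 = np.diff(taps1, prepend=0.0, append=0.0)
    norm = (2.0 / L) / (L / 2 + 1)
    return KernelFamily(L, taps0, taps1, taps2, norm)


def normalize(k: KernelFamily) -> KernelFamily:
    """Scale every tap by the family's normalization constant."""
    if k.normalized:
        return k
    return replace(
        k,
        taps0=k.taps0 * k.norm,
        taps1=k.taps1 * k.norm,
        taps2=k.taps2 * k.norm,
        normalized=True,
    )


def _family(L_or_family: int | KernelFamily) -> KernelFamily:
    if isinstance(L_or_family, KernelFamily):
        return L_or_family if L_or_family.normalized else normalize(L_or_family)
    return normalize(make_kernels(L_or_family))


def response_full(a: np.ndarray, k: KernelFamily) -> np.ndarray:
    """Edge response along the last axis for every sample, sparse path.

    Works on arrays of any leading shape; the last axis is the A-scan.
    Anchoring the two cumulative sums at the very start of the zero-padded
    full convolution makes both integration constants vanish, so this is
    the start-index-0 case of :func:`sparse_convolve`, vectorized.
    """
    a = np.asarray(a, dtype=np.float64)
    n = a.shape[-1]
    L = k.L
    if n < L + 2:
        raise ValueError(f"line length {n} shorter than kernel support {L + 2}")
    d2 = np.zeros(a.shape[:-1] + (n + L + 1,), dtype=np.float64)
    for p in np.flatnonzero(k.taps2):
        d2[..., p : p + n] += k.taps2[p] * a
    np.cumsum(d2, axis=-1, out=d2)
    np.cumsum(d2, axis=-1, out=d2)
    return d2[..., L // 2 - 1 : L // 2 - 1 + n]


def dense_convolve(line: np.ndarray, k: KernelFamily) -> np.ndarray:
    """Reference dense convolution with the ramp kernel, same alignment."""
    k = _family(k)
    line = np.asarray(line, dtype=np.float64)
    full = np.convolve(line, k.taps0)
    return full[k.L // 2 - 1 : k.L // 2 - 1 + line.size]


def _direct_at(line: np.ndarray, taps: np.ndarray, m0: int) -> float:
    """Full-convolution value sum_i taps[i] * line[m0 - i], zero padded."""
    i = np.arange(taps.size)
    j = m0 - i
    ok = (j >= 0) & (j < line.size)
    return float(np.dot(taps[ok], line[j[ok]]))


def sparse_convolve(
    line: np.ndarray, k: int | KernelFamily, z0: int = 0
) -> np.ndarray:
    """Ramp-kernel convolution of one scan line via the sparse kernel.

    Returns the response at every sample.  For ``z >= z0`` the result is
    built from the 4-tap second-difference kernel with two cumulative sums
    seeded by the directly-evaluated integration constants
    ``(kernel1 * s)(z0)`` and ``(kernel0 * s)(z0)``; for ``z < z0`` (empty
    when ``z0 = 0``) the start-anchored evaluation is used, which is
    mathematically identical.
    """
    k = _family(k)
    line = np.asarray(line, dtype=np.float64)
    n = line.size
    L = k.L
    if n < L + 2:
        raise ValueError(f"line length {n} shorter than kernel support {L + 2}")
    if not 0 <= z0 < n:
        raise ValueError(f"start index {z0} outside line")
    if z0 == 0:
        return response_full(line, k)

    out = np.empty(n, dtype=np.float64)
    out[:z0] = response_full(line, k)[:z0]
    m0 = z0 + L // 2 - 1
    c0 = _direct_at(line, k.taps0, m0)
    c1 = _direct_at(line, k.taps1, m0)
    # sparse second-difference values at full lags m0+1 .. n-1 + L/2 - 1
    m = np.arange(m0 + 1, n + L // 2 - 1)
    d2 = np.zeros(m.size, dtype=np.float64)
    for p in np.flatnonzero(k.taps2):
        j = m - p
        ok = (j >= 0) & (j < n)
        d2[ok] += k.taps2[p] * line[j[ok]]
    i1 = c1 + np.cumsum(d2)
    out[z0] = c0
    out[z0 + 1 :] = c0 + np.cumsum(i1)
    return out


#: relative gate threshold: "declines to zero" means dropping below this
#: fraction of the peak, so sub-quantum float residue (e.g. the smooth
#: background field left by contrast enhancement) does not block the gate.
GATE_REL = 0.01


def peak_is_valid(
    resp: np.ndarray, iz: int, L: int, tol: float = 0.0
) -> bool:
    """Gate: the response must decline to <= tol within L samples on both
    sides of the maximum.  Samples beyond the line count as zero response
    (consistent with zero padding)."""
    n = resp.size
    right = resp[iz + 1 : min(n, iz + L + 1)]
    left = resp[max(0, iz - L) : iz]
    ok_right = (iz + L >= n) or bool(np.any(right <= tol))
    ok_left = (iz - L < 0) or bool(np.any(left <= tol))
    return ok_right and ok_left


def _parabolic_offset(rm1: float, r0: float, rp1: float) -> float:
    denom = rm1 - 2.0 * r0 + rp1
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (rm1 - rp1) / denom, -0.5, 0.5))


def line_edge_response(
    line: np.ndarray,
    L: int | KernelFamily,
    region: tuple[float, float] | None = None,
) -> tuple[float | None, float]:
    """Locate the maximum filter response of one scan line within a region.

    Returns ``(position, peak_response)``.  The position is the sub-voxel
    (parabolically refined) index of the maximum, or None if the peak fails
    the validity gate: the response must be strictly positive and decline
    to zero within one kernel length on either side of the maximum, which
    discards false edges produced by mismatched kernel sizes.
    """
    k = _family(L)
    line = np.asarray(line, dtype=np.float64)
    n = line.size
    if region is None:
        lo, hi = 0, n - 1
    else:
        lo = int(np.ceil(region[0] - 1e-9))
        hi = int(np.floor(region[1] + 1e-9))
    if lo > hi or lo < 0 or hi >= n:
        raise ValueError(f"empty or out-of-bounds region [{lo}, {hi}]")
    resp = response_full(line, k)
    iz = lo + int(np.argmax(resp[lo : hi + 1]))
    peak = float(resp[iz])
    floor = 1e-9 * max(1.0, float(np.abs(resp).max()))
    tol = max(GATE_REL * peak, floor)
    # a maximum at the very first or last sample is the zero-padding step
    # artifact, not a located edge
    if iz in (0, n - 1) or peak <= floor or not peak_is_valid(resp, iz, k.L, tol):
        return None, peak
    pos = float(iz)
    if 0 < iz < n - 1:
        pos += _parabolic_offset(resp[iz - 1], resp[iz], resp[iz + 1])
    return float(np.clip(pos, lo, hi)), peak
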