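"""Shared fixtures: phantom study conditions and full pipeline runs.

The heavyweight end-to-end artifacts (256^3 phantoms and their pipeline
results) are computed once per session and shared across test modules.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from octfp import phantom, pipeline
from octfp.io_types import cast_to_uint8
from octfp.masking import compute_mask
from octfp.preprocess import rolloff_compensate
from octfp.surface_detection import fill_holes, segment_fingerprint

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# -- small, fast phantom for unit-scale end-to-end checks -------------------

SMALL_SPEC = replace(
    phantom.PhantomSpec(),
    dims=(96, 96, 96),
    apex_depth=24.0,
    epidermis_thickness=36.0,
    contact_radius=40.0,
    ridge_period=18.0,
    ridge_amplitude=5.0,
    junction_amplitude=4.0,
    seed=5,
)


@pytest.fixture(scope="session")
def small_phantom():
    return phantom.generate(SMALL_SPEC)


# -- reference study conditions ---------------------------------------------


@pytest.fixture(scope="session")
def clean_bundle():
    vol, truth = phantom.generate(phantom.preset("clean-finger-256"))
    result = pipeline.run(vol)
    return {"volume": vol, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def scar_bundle():
    vol, truth = phantom.generate(phantom.preset("scarred-finger"))
    result = pipeline.run(vol)
    return {"volume": vol, "truth": truth, "result": result}


def _mask_only(preset_name: str):
    vol, truth = phantom.generate(phantom.preset(preset_name))
    v8 = cast_to_uint8(vol)
    outer = fill_holes(segment_fingerprint(rolloff_compensate(v8)))
    mask = compute_mask(v8, outer)
    return {"truth": truth, "mask": mask, "outer": outer}


@pytest.fixture(scope="session")
def offcenter_mask_case():
    return _mask_only("off-center-tilted")


@pytest.fixture(scope="session")
def noisy_mask_case():
    return _mask_only("noisy-finger-256")


# -- analysis helpers --------------------------------------------------------


def rmse(a: np.ndarray, b: np.ndarray, where: np.ndarray) -> float:
    d = (a - b)[where]
    return float(np.sqrt(np.mean(d * d)))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return float(2.0 * (a & b).sum() / (a.sum() + b.sum()))


def _central_crop(field: np.ndarray, bits: np.ndarray, half: int = 64) -> np.ndarray:
    cx, cy = np.array(np.where(bits)).mean(axis=1).astype(int)
    return field[cx - half : cx + half, cy - half : cy + half]


def ridge_band_power(field: np.ndarray, bits: np.ndarray, period: float) -> float:
    """Spectral power near the friction-ridge frequency, central crop."""
    crop = _central_crop(field, bits).astype(np.float64)
    crop = np.nan_to_num(crop - np.nanmean(crop))
    n = crop.shape[0]
    crop = crop * np.outer(np.hanning(n), np.hanning(n))
    F = np.abs(np.fft.fft2(crop)) ** 2
    fx = np.fft.fftfreq(n)[:, None]
    fy = np.fft.fftfreq(n)[None, :]
    r = np.sqrt(fx * fx + fy * fy)
    band = (r > 0.85 / period) & (r < 1.15 / period)
    return float(F[band].sum())


def dominant_frequency(field: np.ndarray, bits: np.ndarray) -> float:
    """Dominant non-DC spatial frequency (cycles/pixel), central crop."""
    crop = _central_crop(field, bits).astype(np.float64)
    crop = np.nan_to_num(crop - np.nanmean(crop))
    n = crop.shape[0]
    crop = crop * np.outer(np.hanning(n), np.hanning(n))
    F = np.abs(np.fft.fft2(crop)) ** 2
    fx = np.fft.fftfreq(n)[:, None]
    fy = np.fft.fftfreq(n)[None, :]
    r = np.sqrt(fx * fx + fy * fy)
    F[r < 0.015] = 0.0  # suppress DC / finger-shape leakage
    i, j = np.unravel_index(np.argmax(F), F.shape)
    return float(r[i, j])


def scar_band(spec: phantom.PhantomSpec) -> np.ndarray:
    """Lateral region of the scar groove of a scarred phantom spec."""
    nx, ny, _ = spec.dims
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    theta = spec.ridge_orientation
    vperp = -x * np.sin(theta) + y * np.cos(theta)
    return np.abs(vperp - spec.scar_offset) <= spec.scar_width
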