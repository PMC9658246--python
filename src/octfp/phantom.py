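"""Synthetic OCT fingertip phantom with exact ground truth.

The phantom emulates the appearance of a non-contact fingertip scan: a
spherically curved fingertip suspended in air near the volume top, a
bright thin air-skin boundary band carrying a cosine friction-ridge
pattern, a dimmer band at the dermal-epidermal junction carrying the same
ridge pattern at reduced amplitude (the junction is the template of the
surface pattern), exponentially attenuated tissue in between,
multiplicative speckle, and a linear depth-dependent intensity roll-off.

Geometry (z = 0 at the scan top, depth in axial voxels):

    ridge(x, y)  = (1 - cos(2*pi*u / T)) / 2,  u = ridge-normal coordinate
    S*(x, y)     = apex + tilt + spherical sag + A * ridge   (outer surface)
    I*(x, y)     = apex + tilt + spherical sag + D + A_in * ridge  (junction)

so ridge *tops* (ridge = 0) are closest to the scan head, the outer
peak-to-peak ridge relief is ``A``, the inner one ``A_in``, and the
epidermis is ``D`` thick at the ridge tops.  An optional scar gouges a
Gaussian-profile groove across the ridges of the outer surface only; the
junction underneath is untouched, which is the anatomical reason the
inner fingerprint survives superficial skin damage.

Speckle is modelled as clipped multiplicative Gaussian noise
``I * max(0, 1 + sigma_s * N(0,1))`` — a deliberate simplification of
fully developed coherent speckle that is sufficient to stress the edge
filter.  The double-row microstructure of the junction is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .io_types import Mask, Surface, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "generate", "presets", "preset"]


@dataclass(frozen=True)
class PhantomSpec:
    """All phantom parameters.  Lateral quantities are in pixels, axial in
    voxels, physical pitches in micrometres."""

    dims: tuple[int, int, int] = (256, 256, 256)
    pitch_um: tuple[float, float, float] = (20.0, 20.0, 5.5)
    curvature_radius_um: float = 8000.0   # fingertip sphere radius; inf = flat
    center: tuple[float, float] | None = None  # lateral apex, None = middle
    tilt: tuple[float, float] = (0.0, 0.0)     # axial voxels per lateral pixel
    apex_depth: float = 40.0              # z of the highest ridge top
    ridge_period: float = 25.0            # T, pixels (~500 um at 20 um pitch)
    ridge_amplitude: float = 8.0          # A, peak-to-peak relief in voxels
    ridge_orientation: float = 0.3        # radians
    epidermis_thickness: float = 70.0     # D, voxels (~385 um at 5.5 um)
    junction_amplitude: float = 6.0       # A_in, voxels
    contact_radius: float = 110.0         # lateral extent of the fingertip, px
    surface_brightness: float = 240.0
    junction_brightness: float = 100.0
    tissue_brightness: float = 60.0
    background_level: float = 6.0
    band_sigma: float = 1.0               # axial sigma of the surface band
    junction_band_sigma: float = 1.5
    attenuation: float = 0.008            # per voxel of depth below surface
    speckle_sigma: float = 0.3            # sigma_s
    rolloff_slope: float = 0.001          # a in intensity * (1 - a * z)
    scar_depth: float = 0.0               # extra outer-surface depth, voxels
    scar_width: float = 12.0              # Gaussian FWHM-ish width, px
    scar_offset: float = 20.0             # scar position along the ridge
                                          # normal, px from center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_amplitude >= self.epidermis_thickness:
            raise ValueError("ridge amplitude must be below epidermis thickness")
        if not (
            self.surface_brightness
            > self.junction_brightness
            > self.tissue_brightness
            > self.background_level
        ):
            raise ValueError(
                "brightness ordering surface > junction > tissue > background required"
            )
        if self.epidermis_thickness <= self.ridge_amplitude - self.junction_amplitude:
            raise ValueError("junction would intersect the outer surface")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("dims", "pitch_um", "tilt"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Exact outer surface, inner (junction) surface, and contact mask.

    Surfaces are defined inside the contact mask and NaN outside (no skin
    exists there)."""

    outer: Surface
    inner: Surface
    mask: Mask
    ridge_period: float = field(default=25.0)


def _geometry(spec: PhantomSpec):
    nx, ny, nz = spec.dims
    cx, cy = spec.center if spec.center is not None else ((nx - 1) / 2, (ny - 1) / 2)
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    px, py, pz = spec.pitch_um
    rho_um2 = (x * px) ** 2 + (y * py) ** 2
    R = spec.curvature_radius_um
    if np.isfinite(R):
        sag_um = R - np.sqrt(np.maximum(R * R - rho_um2, 0.0))
        sag = sag_um / pz
    else:
        sag = np.zeros((nx, ny))
    theta = spec.ridge_orientation
    u = x * np.cos(theta) + y * np.sin(theta)
    vperp = -x * np.sin(theta) + y * np.cos(theta)
    ridge = 0.5 * (1.0 - np.cos(2.0 * np.pi * u / spec.ridge_period))
    base = spec.apex_depth + spec.tilt[0] * x + spec.tilt[1] * y + sag
    outer = base + spec.ridge_amplitude * ridge
    if spec.scar_depth > 0:
        sw = spec.scar_width / 2.0
        outer = outer + spec.scar_depth * np.exp(
            -0.5 * ((vperp - spec.scar_offset) / sw) ** 2
        )
    inner = base + spec.epidermis_thickness + spec.junction_amplitude * ridge
    rho_px = np.sqrt(x * x + y * y)
    mask = rho_px <= spec.contact_radius
    return outer, inner, mask


def generate(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[Volume, PhantomTruth]:
    """Render the phantom volume and its ground truth.

    Deterministic for a given seed (``spec.seed`` unless overridden).
    """
    nx, ny, nz = spec.dims
    outer, inner, mask = _geometry(spec)
    if np.nanmax(np.where(mask, inner, np.nan)) > nz - 4:
        raise ValueError("junction extends past the volume bottom")
    if np.nanmin(np.where(mask, outer, np.nan)) < 2:
        raise ValueError("outer surface extends past the volume top")

    zg = np.arange(nz, dtype=np.float32)
    intensity = np.full(spec.dims, np.float32(spec.background_level))

    depth_below = zg[None, None, :] - outer[..., None].astype(np.float32)
    tissue = np.where(
        depth_below > 0,
        np.float32(spec.tissue_brightness)
        * np.exp(np.float32(-spec.attenuation) * depth_below),
        np.float32(0.0),
    )
    tissue += np.float32(spec.surface_brightness) * np.exp(
        -0.5 * (depth_below / np.float32(spec.band_sigma)) ** 2
    )
    del depth_below
    depth_inner = zg[None, None, :] - inner[..., None].astype(np.float32)
    tissue += np.float32(spec.junction_brightness) * np.exp(
        -0.5 * (depth_inner / np.float32(spec.junction_band_sigma)) ** 2
    )
    del depth_inner
    intensity += np.where(mask[..., None], tissue, np.float32(0.0))
    del tissue

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.speckle_sigma > 0:
        noise = rng.standard_normal(spec.dims, dtype=np.float32)
        intensity *= np.maximum(
            np.float32(0.0), np.float32(1.0) + np.float32(spec.speckle_sigma) * noise
        )
        del noise
    if spec.rolloff_slope > 0:
        intensity *= np.float32(1.0) - np.float32(spec.rolloff_slope) * zg[None, None, :]

    data = np.trunc(np.clip(intensity, 0.0, 255.0)).astype(np.uint8)
    truth = PhantomTruth(
        outer=Surface(np.where(mask, outer, np.nan), nz, spec.pitch_um),
        inner=Surface(np.where(mask, inner, np.nan), nz, spec.pitch_um),
        mask=Mask(mask),
        ridge_period=spec.ridge_period,
    )
    return Volume(data, spec.pitch_um), truth


def presets() -> dict[str, PhantomSpec]:
    """Named study conditions.

    flat-slab          noiseless flat skin slab, for detection unit tests.
    clean-finger-256   curved ridged fingertip with realistic speckle and
                       roll-off; the end-to-end reference condition.
    noisy-finger-256   heavier speckle and roll-off.
    scarred-finger     clean finger plus a groove crossing the ridges of
                       the outer surface; junction untouched.
    off-center-tilted  displaced, tilted fingertip for masking robustness.
    """
    clean = PhantomSpec(seed=42)
    return {
        "flat-slab": PhantomSpec(
            dims=(64, 64, 64),
            curvature_radius_um=np.inf,
            apex_depth=20.0,
            ridge_amplitude=0.0,
            epidermis_thickness=24.0,
            junction_amplitude=0.0,
            contact_radius=1e9,
            speckle_sigma=0.0,
            rolloff_slope=0.0,
            seed=0,
        ),
        "clean-finger-256": clean,
        "noisy-finger-256": replace(
            clean, speckle_sigma=0.5, rolloff_slope=0.0015, seed=7
        ),
        "scarred-finger": replace(clean, scar_depth=15.0),
        "off-center-tilted": replace(
            clean,
            center=(96.0, 144.0),
            tilt=(0.05, -0.04),
            contact_radius=92.0,
            seed=11,
        ),
    }


def preset(name: str) -> PhantomSpec:
    try:
        return presets()[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets())}"
        ) from None
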