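"""End-to-end processing chain: scan volume in, two 2D fingerprints out.

Stage order: 8-bit cast -> intensity roll-off compensation -> outer
surface segmentation -> surface masking -> outer upper/lower envelopes ->
volume flattening against the outer upper envelope -> inner surface
segmentation in the flattened, mask-restricted volume -> unflattening ->
inner envelopes -> 3D-to-2D projection of both surfaces.  The inner pass
reuses the identical segmentation code; its only configuration difference
is a small initial axial margin that keeps the search out of the residual
top-of-volume tail of the truncated outer layer.  The outer mask is used
for both fingerprints.

Every stage's output is retained in the result for inspection, and the run
log records all configuration values (each default that substitutes a
hardware-dependent constant of the original setup is logged), per-stage
timings, hole counts and region sizes per pyramid level.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .envelope import EnvelopeConfig, lower_envelope, upper_envelope
from .io_types import Mask, ProcessingError, Surface, Volume, cast_to_uint8
from .masking import MaskingConfig, raw_mask, refine_mask
from .preprocess import rolloff_compensate
from .surface_detection import DetectionConfig, fill_holes, segment_fingerprint
from .transform import (
    Fingerprint2D,
    FlattenRecord,
    flatten_volume,
    project_2d,
    unflatten_surface,
)

__all__ = ["PipelineConfig", "PipelineResult", "run", "load_config"]


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    #: initial axial margin (full-resolution voxels) of the inner-pass
    #: search region, skipping the truncated outer-layer tail at the top
    inner_margin: int = 4


@dataclass
class PipelineResult:
    outer_surface: Surface
    inner_surface: Surface
    mask: Mask
    outer_upper: Surface
    outer_lower: Surface
    inner_upper: Surface
    inner_lower: Surface
    outer_fp: Fingerprint2D
    inner_fp: Fingerprint2D
    flatten_record: FlattenRecord
    run_log: dict


def _stage(log: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            log.setdefault("timings_s", {})[name] = round(
                time.perf_counter() - self.t0, 3
            )
            if isinstance(exc, ProcessingError) and exc.stage is None:
                exc.stage = name
            return False

    return _Timer()


def run(v: Volume, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the complete chain on one scan volume."""
    cfg = cfg or PipelineConfig()
    log: dict = {
        "config": {
            "detection": asdict(cfg.detection),
            "masking": asdict(cfg.masking),
            "envelope": asdict(cfg.envelope),
            "inner_margin": cfg.inner_margin,
        }
    }

    with _stage(log, "cast"):
        v8 = cast_to_uint8(v)
    with _stage(log, "rolloff_compensate"):
        vc = rolloff_compensate(v8)

    with _stage(log, "outer_segmentation"):
        outer_collect: dict = {}
        outer = segment_fingerprint(vc, cfg.detection, None, collect=outer_collect)
        outer = fill_holes(outer, max_iters=cfg.detection.max_hole_iters)
        log["outer_levels"] = outer_collect["log"]["levels"]

    with _stage(log, "masking"):
        # masking probes the raw air/skin contrast: use the cast volume,
        # not the compensated one (see masking.raw_mask)
        mask = refine_mask(raw_mask(v8, outer, cfg.masking.w_n), cfg.masking.ridge_px)
        log["mask_area_px"] = mask.n_true

    with _stage(log, "outer_envelopes"):
        eup_o = upper_envelope(outer, mask, cfg.envelope)
        elow_o = lower_envelope(outer, eup_o, mask, cfg.envelope)

    with _stage(log, "flatten"):
        flat_v, rec = flatten_volume(vc, outer, eup_o, mask)
        log["delta_s_vox"] = rec.delta_s

    with _stage(log, "inner_segmentation"):
        inner_cfg = replace(
            cfg.detection, z_min=cfg.inner_margin, contrast_enhancement=False
        )
        inner_collect: dict = {}
        inner_flat = segment_fingerprint(
            flat_v, inner_cfg, mask, collect=inner_collect,
            line_offset=rec.shift.astype(np.float64),
        )
        inner_flat = fill_holes(inner_flat, mask, cfg.detection.max_hole_iters)
        log["inner_levels"] = inner_collect["log"]["levels"]

    with _stage(log, "unflatten"):
        inner = unflatten_surface(inner_flat, rec)

    with _stage(log, "inner_envelopes"):
        eup_i = upper_envelope(inner, mask, cfg.envelope)
        elow_i = lower_envelope(inner, eup_i, mask, cfg.envelope)

    with _stage(log, "projection"):
        fp_out = project_2d(outer, eup_o, elow_o, mask)
        fp_in = project_2d(inner, eup_i, elow_i, mask)

    bits = mask.bits
    ordered = inner.heights[bits] > outer.heights[bits]
    log["inner_below_outer_frac"] = float(ordered.mean())
    return PipelineResult(
        outer_surface=outer,
        inner_surface=inner,
        mask=mask,
        outer_upper=eup_o,
        outer_lower=elow_o,
        inner_upper=eup_i,
        inner_lower=elow_i,
        outer_fp=fp_out,
        inner_fp=fp_in,
        flatten_record=rec,
        run_log=log,
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a TOML file.

    Recognized tables: [detection], [masking], [envelope]; top-level key
    ``inner_margin``.  Unknown keys raise, so typos do not silently fall
    back to defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    det = doc.pop("detection", {})
    if "kernel_sizes" in det:
        det["kernel_sizes"] = tuple(det["kernel_sizes"])
    msk = doc.pop("masking", {})
    env = doc.pop("envelope", {})
    inner_margin = doc.pop("inner_margin", 4)
    if doc:
        raise ValueError(f"unknown config keys: {sorted(doc)}")
    return PipelineConfig(
        detection=DetectionConfig(**det),
        masking=MaskingConfig(**msk),
        envelope=EnvelopeConfig(**env),
        inner_margin=inner_margin,
    )
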