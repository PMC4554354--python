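"""YAML configuration for analysis runs and synthetic-image specs.

One flat, documented key namespace grouped into sections::

    input:   mode, roi_channel, foci1_channel, foci2_channel, invert,
             channel_token
    seg:     threshold_mode, manual_threshold, auto_method, min_area,
             max_area, min_circularity, max_circularity, exclude_edge,
             fill_holes, watershed
    foci:    noise_level_1, noise_level_2, cutoff_1, cutoff_2
    measure: area_correction_factor, percentile, intensity_channel,
             pixel_size_um
    coloc:   enabled, tolerance, export_pairs
    output:  dir, formats, qc_overlays

All keys have defaults except the channel assignment and the noise
level(s), which depend on the experiment and must be stated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .colocalization import ColocParams
from .errors import ConfigurationError, InputError
from .foci import FociParams
from .image_io import ChannelAssignment
from .measurement import MeasureParams
from .pipeline import AnalysisParams
from .segmentation import SegmentationParams
from .synthetic import SyntheticSpec

_SECTIONS = {"input", "seg", "foci", "measure", "coloc", "output"}


def _section(cfg: dict, name: str) -> dict:
    sec = cfg.get(name, {}) or {}
    if not isinstance(sec, dict):
        raise ConfigurationError(f"config section {name!r} must be a mapping")
    return dict(sec)


def params_from_dict(cfg: dict) -> AnalysisParams:
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")

    inp = _section(cfg, "input")
    if "roi_channel" not in inp or "foci1_channel" not in inp:
        raise ConfigurationError(
            "input.roi_channel and input.foci1_channel are required")
    assignment = ChannelAssignment(
        mode=inp.get("mode", "multichannel_file"),
        roi_channel=int(inp["roi_channel"]),
        foci1_channel=int(inp["foci1_channel"]),
        foci2_channel=(int(inp["foci2_channel"])
                       if inp.get("foci2_channel") is not None else None),
        invert=bool(inp.get("invert", False)),
        channel_token=inp.get("channel_token", "_c{index}"),
    )

    seg = _section(cfg, "seg")
    seg_params = SegmentationParams(
        threshold_mode=seg.get("threshold_mode", "auto"),
        manual_threshold=seg.get("manual_threshold"),
        auto_method=seg.get("auto_method", "isodata"),
        min_area=float(seg.get("min_area", 50.0)),
        max_area=(float(seg["max_area"])
                  if seg.get("max_area") is not None else None),
        min_circularity=float(seg.get("min_circularity", 0.0)),
        max_circularity=float(seg.get("max_circularity", 1.0)),
        exclude_edge=bool(seg.get("exclude_edge", True)),
        fill_holes=bool(seg.get("fill_holes", True)),
        use_watershed=bool(seg.get("watershed", False)),
    )

    foc = _section(cfg, "foci")
    if "noise_level_1" not in foc:
        raise ConfigurationError("foci.noise_level_1 is required")
    foci_params = FociParams(
        noise_level_1=float(foc["noise_level_1"]),
        noise_level_2=(float(foc["noise_level_2"])
                       if foc.get("noise_level_2") is not None else None),
        cutoff_1=(float(foc["cutoff_1"])
                  if foc.get("cutoff_1") is not None else None),
        cutoff_2=(float(foc["cutoff_2"])
                  if foc.get("cutoff_2") is not None else None),
    )

    mea = _section(cfg, "measure")
    measure_params = MeasureParams(
        area_correction_factor=float(mea.get("area_correction_factor", 1000.0)),
        percentile=(float(mea["percentile"])
                    if mea.get("percentile") is not None else None),
        intensity_channel=mea.get("intensity_channel", "roi"),
        pixel_size_um=(float(mea["pixel_size_um"])
                       if mea.get("pixel_size_um") is not None else None),
    )

    col = _section(cfg, "coloc")
    coloc_params: Optional[ColocParams] = None
    if col.get("enabled", False):
        coloc_params = ColocParams(
            tolerance=float(col.get("tolerance", 2.0)),
            enabled=True,
            export_pairs=bool(col.get("export_pairs", False)),
        )

    out = _section(cfg, "output")
    formats = out.get("formats", ["csv"])
    if isinstance(formats, str):
        formats = [f.strip() for f in formats.split(",") if f.strip()]

    return AnalysisParams(
        assignment=assignment, seg=seg_params, foci=foci_params,
        measure=measure_params, coloc=coloc_params,
        output_dir=str(out.get("dir", "results")),
        output_formats=tuple(formats),
        qc_overlays=bool(out.get("qc_overlays", False)),
    )


def load_params(path) -> AnalysisParams:
    """Load and validate an analysis configuration from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such config file: {path}")
    cfg = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    return params_from_dict(cfg)


def spec_from_dict(cfg: dict) -> SyntheticSpec:
    known = {f for f in SyntheticSpec.__dataclass_fields__}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigurationError(
            f"unknown synthetic-spec key(s): {sorted(unknown)}")
    kwargs = dict(cfg)
    for tup_key in ("image_size", "nucleus_axes_range"):
        if tup_key in kwargs and kwargs[tup_key] is not None:
            kwargs[tup_key] = tuple(kwargs[tup_key])
    return SyntheticSpec(**kwargs)


def load_spec(path) -> SyntheticSpec:
    """Load a synthetic-image spec from a YAML file (same dialect as the
    analysis config: one mapping of SyntheticSpec field names)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such spec file: {path}")
    cfg = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: spec root must be a mapping")
    return spec_from_dict(cfg)
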