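"""Per-image analysis orchestration, batch driving, aggregation and export.

``analyze_image`` chains segmentation -> per-ROI foci detection -> cutoff ->
measurement -> percentile filter -> optional colocalization and returns the
per-focus / per-ROI / per-image rows for one image.  ``run_batch`` applies
it to every image in a folder tree; one failing image is logged and skipped
without disturbing the others.  ``export_results`` writes the four result
tables (CSV canonical, optional xlsx mirror), a failures manifest and a
metadata file echoing every parameter.

Aggregation contract: the per-image foci means are computed over the ROIs
not excluded by the percentile filter and are exactly recomputable from the
per-ROI table; the batch summary row holds the unweighted mean over images
(each image counts once), plus a second, pooled row weighting every ROI
equally — both are labeled in an ``aggregation`` column.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .colocalization import ColocParams, match_foci, summarize_coloc
from .errors import (ConfigurationError, DegenerateImageError, FociCountError,
                     InputError, OutputError)
from .foci import FociParams, detect_foci_per_roi
from .image_io import (ChannelAssignment, MultiChannelImage, invert_image,
                       list_batch_inputs, load_image)
from .measurement import MeasureParams, build_roi_records
from .segmentation import SegmentationParams, segment

logger = logging.getLogger("focicount")

FOCUS_COLUMNS = ["image", "roi_id", "channel", "x", "y", "peak_intensity"]


@dataclass(frozen=True)
class AnalysisParams:
    assignment: ChannelAssignment
    seg: SegmentationParams
    foci: FociParams
    measure: MeasureParams = MeasureParams()
    coloc: Optional[ColocParams] = None
    output_dir: str = "results"
    output_formats: tuple = ("csv",)
    qc_overlays: bool = False

    def __post_init__(self) -> None:
        has2 = self.assignment.foci2_channel is not None
        if (self.foci.noise_level_2 is not None
                or self.foci.cutoff_2 is not None) and not has2:
            raise ConfigurationError(
                "foci-channel-2 parameters set but no foci2 channel assigned")
        if has2 and self.foci.noise_level_2 is None:
            raise ConfigurationError(
                "foci2 channel assigned but noise_level_2 missing")
        if self.coloc is not None and self.coloc.enabled and not has2:
            raise ConfigurationError(
                "colocalization requires a foci2 channel assignment")
        bad = set(self.output_formats) - {"csv", "xlsx"}
        if bad:
            raise ConfigurationError(f"unknown output format(s): {sorted(bad)}")
        if self.measure.intensity_channel not in ("roi", "foci1", "foci2"):
            raise ConfigurationError(
                f"unknown intensity_channel {self.measure.intensity_channel!r}")


@dataclass
class ImageResult:
    image: str
    focus_rows: list = field(default_factory=list)
    roi_records: list = field(default_factory=list)
    coloc_rows: list = field(default_factory=list)
    pair_rows: list = field(default_factory=list)
    image_row: dict = field(default_factory=dict)
    threshold: float = 0.0
    dropped: dict = field(default_factory=dict)


def _image_row(name: str, records, coloc_summary, threshold, has2) -> dict:
    kept = [r for r in records if not r.excluded_by_percentile]
    row = {
        "image": name,
        "n_rois": len(records),
        "n_rois_excluded": sum(r.excluded_by_percentile for r in records),
        "threshold_roi": threshold,
        "n_foci_1": int(sum(r.foci_count_1 for r in kept)),
        "mean_foci_1": float(np.mean([r.foci_count_1 for r in kept])) if kept else 0.0,
        "mean_density_1": float(np.mean([r.foci_density_1 for r in kept])) if kept else 0.0,
    }
    if has2:
        row["n_foci_2"] = int(sum(r.foci_count_2 for r in kept))
        row["mean_foci_2"] = float(np.mean([r.foci_count_2 for r in kept])) if kept else 0.0
        row["mean_density_2"] = float(np.mean([r.foci_density_2 for r in kept])) if kept else 0.0
    if coloc_summary is not None:
        row["n_colocalized"] = coloc_summary.n_colocalized
        row["pct_colocalized_1"] = coloc_summary.pct_colocalized_1
        row["pct_colocalized_2"] = coloc_summary.pct_colocalized_2
    return row


def analyze_image(img: MultiChannelImage, params: AnalysisParams,
                  name: Optional[str] = None) -> ImageResult:
    """Run the full single-image pipeline; deterministic given img+params."""
    name = name if name is not None else img.source_path
    has2 = "foci2" in img.channel_roles

    seg_res = segment(img.channel("roi"), params.seg, source=name)
    rois = seg_res.rois
    if not rois:
        logger.warning("%s: no ROIs survived segmentation/filters", name)

    foci = detect_foci_per_roi(img, rois, params.foci)

    intensity_raster = img.channel(params.measure.intensity_channel)
    records = build_roi_records(name, rois, intensity_raster, foci,
                                params.measure, has2)

    res = ImageResult(image=name, threshold=seg_res.threshold,
                      dropped=seg_res.dropped)
    res.roi_records = records
    res.focus_rows = [
        {"image": name, "roi_id": f.roi_id, "channel": f.channel_role,
         "x": f.x, "y": f.y, "peak_intensity": f.peak_intensity}
        for f in foci
    ]

    coloc_summary = None
    if params.coloc is not None and params.coloc.enabled and has2:
        excluded = {r.roi_id for r in records if r.excluded_by_percentile}
        per_roi = []
        for roi in rois:
            f1 = [f for f in foci
                  if f.roi_id == roi.roi_id and f.channel_role == "foci1"]
            f2 = [f for f in foci
                  if f.roi_id == roi.roi_id and f.channel_role == "foci2"]
            cr = match_foci(f1, f2, params.coloc)
            cr.roi_id = roi.roi_id
            per_roi.append(cr)
            res.coloc_rows.append({
                "image": name, "roi_id": roi.roi_id,
                "n_foci_1": cr.n_foci_1, "n_foci_2": cr.n_foci_2,
                "n_colocalized": cr.n_colocalized,
                "pct_colocalized_1": cr.pct_colocalized_1,
                "pct_colocalized_2": cr.pct_colocalized_2,
            })
            if params.coloc.export_pairs:
                for (a, b, d) in cr.pairs:
                    res.pair_rows.append({
                        "image": name, "roi_id": roi.roi_id,
                        "x1": a.x, "y1": a.y, "x2": b.x, "y2": b.y,
                        "distance": d,
                    })
        coloc_summary = summarize_coloc(
            [c for c in per_roi if c.roi_id not in excluded])

    res.image_row = _image_row(name, records, coloc_summary,
                               seg_res.threshold, has2)
    logger.info(
        "%s: %d ROI(s) (dropped %s), %d focus/foci, threshold %.1f",
        name, len(rois), seg_res.dropped, len(foci), seg_res.threshold)
    return res


@dataclass
class ResultBundle:
    per_focus: pd.DataFrame
    per_roi: pd.DataFrame
    per_image: pd.DataFrame
    batch_summary: pd.DataFrame
    coloc: Optional[pd.DataFrame] = None
    pairs: Optional[pd.DataFrame] = None
    failures: list = field(default_factory=list)   # (image, reason)
    skipped: list = field(default_factory=list)    # (image, reason)
    run_metadata: dict = field(default_factory=dict)

    @property
    def status(self) -> int:
        """0 = clean, 2 = partial (some images failed)."""
        return 2 if self.failures else 0


_MEAN_COLUMNS = ["n_rois", "n_foci_1", "mean_foci_1", "mean_density_1",
                 "n_foci_2", "mean_foci_2", "mean_density_2",
                 "n_colocalized", "pct_colocalized_1", "pct_colocalized_2"]


def _summarize(per_image: pd.DataFrame, per_roi: pd.DataFrame) -> pd.DataFrame:
    rows = []
    cols = [c for c in _MEAN_COLUMNS if c in per_image.columns]
    mean_row = {"aggregation": "mean_of_images",
                "n_images": len(per_image)}
    for c in cols:
        mean_row[c] = float(per_image[c].mean()) if len(per_image) else 0.0
    rows.append(mean_row)

    kept = per_roi[~per_roi["excluded_by_percentile"]] if len(per_roi) else per_roi
    pooled = {"aggregation": "pooled_over_rois", "n_images": len(per_image)}
    for c in cols:
        if c in ("mean_foci_1", "mean_density_1"):
            src = {"mean_foci_1": "foci_count_1",
                   "mean_density_1": "foci_density_1"}[c]
            pooled[c] = float(kept[src].mean()) if len(kept) else 0.0
        elif c in ("mean_foci_2", "mean_density_2"):
            src = {"mean_foci_2": "foci_count_2",
                   "mean_density_2": "foci_density_2"}[c]
            pooled[c] = float(kept[src].mean()) if len(kept) else 0.0
        elif c in ("n_rois", "n_foci_1", "n_foci_2", "n_colocalized"):
            pooled[c] = float(per_image[c].sum()) if len(per_image) else 0.0
        elif c == "pct_colocalized_1":
            tot1 = per_image["n_foci_1"].sum()
            pooled[c] = float(100.0 * per_image["n_colocalized"].sum() / tot1) \
                if tot1 else 0.0
        elif c == "pct_colocalized_2":
            tot2 = per_image["n_foci_2"].sum()
            pooled[c] = float(100.0 * per_image["n_colocalized"].sum() / tot2) \
                if tot2 else 0.0
    rows.append(pooled)
    return pd.DataFrame(rows)


def bundle_results(results: List[ImageResult], params: AnalysisParams,
                   failures=None, skipped=None) -> ResultBundle:
    """Collect per-image results into the exportable table bundle."""
    focus_rows, roi_rows, image_rows, coloc_rows, pair_rows = [], [], [], [], []
    for r in results:
        focus_rows.extend(r.focus_rows)
        roi_rows.extend(asdict(rec) for rec in r.roi_records)
        image_rows.append(r.image_row)
        coloc_rows.extend(r.coloc_rows)
        pair_rows.extend(r.pair_rows)

    per_focus = pd.DataFrame(focus_rows, columns=FOCUS_COLUMNS)
    per_roi = pd.DataFrame(roi_rows)
    if per_roi.empty:
        per_roi = pd.DataFrame(columns=[
            "image", "roi_id", "area", "perimeter", "circularity",
            "centroid_x", "centroid_y", "touches_border", "mean_intensity",
            "min_intensity", "max_intensity", "foci_count_1", "foci_count_2",
            "foci_density_1", "foci_density_2", "excluded_by_percentile"])
    per_image = pd.DataFrame(image_rows)
    summary = _summarize(per_image, per_roi)

    meta = {
        "focicount_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "parameters": params_to_dict(params),
        "n_images_analyzed": len(results),
        "n_images_failed": len(failures or []),
        "n_inputs_skipped": len(skipped or []),
    }
    return ResultBundle(
        per_focus=per_focus, per_roi=per_roi, per_image=per_image,
        batch_summary=summary,
        coloc=pd.DataFrame(coloc_rows) if coloc_rows else None,
        pairs=pd.DataFrame(pair_rows) if pair_rows else None,
        failures=list(failures or []), skipped=list(skipped or []),
        run_metadata=meta)


def params_to_dict(params: AnalysisParams) -> dict:
    d = asdict(params)
    d["output_formats"] = list(params.output_formats)
    return d


def run_batch(root, params: AnalysisParams) -> ResultBundle:
    """Analyze every image under *root* (recursively).

    Per-image failures (corrupt files, degenerate histograms) are recorded
    in the failures manifest and never abort the run or disturb other
    images' rows.  Raises ``InputError`` when the tree holds no analyzable
    image at all.
    """
    listing = list_batch_inputs(root, params.assignment)
    if not listing.groups:
        raise InputError(f"no analyzable images under {root}")

    results, failures = [], []
    for group in listing.groups:
        try:
            img = load_image(group.path, params.assignment)
            if params.assignment.invert:
                img = invert_image(img)
            results.append(analyze_image(img, params, name=group.name))
        except FociCountError as exc:
            logger.error("%s: %s", group.name, exc)
            failures.append((group.name, f"{type(exc).__name__}: {exc}"))
    return bundle_results(results, params, failures=failures,
                          skipped=listing.skipped)


def export_results(bundle: ResultBundle, params: AnalysisParams) -> List[str]:
    """Write all tables under ``params.output_dir``; returns written paths.

    CSV is canonical (UTF-8, header row, '.' decimal separator) and
    byte-stable across reruns; the xlsx workbook mirrors the CSVs sheet per
    table.  Timestamps appear only in the metadata file.
    """
    out = Path(params.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OutputError(f"output directory {out} not writable: {exc}")

    written = []
    tables = {
        "per_focus": bundle.per_focus,
        "per_roi": bundle.per_roi,
        "per_image": bundle.per_image,
        "summary": bundle.batch_summary,
    }
    if bundle.coloc is not None:
        tables["coloc"] = bundle.coloc
    if bundle.pairs is not None:
        tables["coloc_pairs"] = bundle.pairs

    if "csv" in params.output_formats:
        for stem, df in tables.items():
            p = out / f"{stem}.csv"
            df.to_csv(p, index=False, encoding="utf-8", lineterminator="\n")
            written.append(str(p))
    if "xlsx" in params.output_formats:
        p = out / "results.xlsx"
        with pd.ExcelWriter(p, engine="openpyxl") as xl:
            for stem, df in tables.items():
                df.to_excel(xl, sheet_name=stem[:31], index=False)
        written.append(str(p))

    fail_df = pd.DataFrame(
        bundle.failures + bundle.skipped, columns=["image", "reason"])
    p = out / "failures.csv"
    fail_df.to_csv(p, index=False, encoding="utf-8", lineterminator="\n")
    written.append(str(p))

    p = out / "run_metadata.json"
    p.write_text(json.dumps(bundle.run_metadata, indent=2, default=str) + "\n",
                 encoding="utf-8")
    written.append(str(p))
    return written
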