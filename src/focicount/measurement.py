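"""Per-ROI measurement and the percentile outlier filter.

Each ROI is measured for area and mean/min/max intensity (on a configurable
channel, the nuclear stain by default), the foci counts per channel are
attached, and an area-corrected density ``count / area * factor`` is
computed — the correction factor rescales the per-pixel density to a
convenient magnitude (or to physical units when a pixel size is supplied).

The percentile option removes outlier nuclei — e.g. S-phase cells whose
replication-associated γ-H2AX signal mimics damage foci — by flagging, per
image, every ROI whose foci count lies strictly above the nearest-rank
p-th percentile of the counts.  Flagged ROIs stay in the per-ROI export
but are omitted from summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import ComputationError, ConfigurationError
from .segmentation import ROI


@dataclass(frozen=True)
class MeasureParams:
    area_correction_factor: float = 1000.0
    percentile: Optional[float] = None         # in (0, 100]; None = off
    intensity_channel: str = "roi"             # role measured for intensities
    pixel_size_um: Optional[float] = None      # optional physical calibration

    def __post_init__(self) -> None:
        if self.area_correction_factor <= 0:
            raise ConfigurationError("area_correction_factor must be > 0")
        if self.percentile is not None and not (0 < self.percentile <= 100):
            raise ConfigurationError(
                f"percentile must lie in (0, 100], got {self.percentile}")


@dataclass
class ROIRecord:
    image: str
    roi_id: int
    area: int
    perimeter: float
    circularity: float
    centroid_x: float
    centroid_y: float
    touches_border: bool
    mean_intensity: float
    min_intensity: float
    max_intensity: float
    foci_count_1: int
    foci_count_2: Optional[int] = None
    foci_density_1: float = 0.0
    foci_density_2: Optional[float] = None
    excluded_by_percentile: bool = False


def measure_roi(roi: ROI, raster: np.ndarray):
    """Area plus mean/min/max intensity over exactly the ROI's pixels."""
    if len(roi.ys) == 0:
        raise ComputationError("cannot measure an empty ROI")
    vals = np.asarray(raster)[roi.ys, roi.xs]
    return len(vals), float(vals.mean()), float(vals.min()), float(vals.max())


def area_corrected_count(foci_count: int, area: float, factor: float) -> float:
    """Foci per unit area times the correction factor."""
    if area <= 0:
        raise ComputationError(f"area must be positive, got {area}")
    return foci_count / area * factor


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    if not (0 < percentile <= 100):
        raise ConfigurationError(
            f"percentile must lie in (0, 100], got {percentile}")
    s = sorted(values)
    if not s:
        raise ComputationError("percentile of an empty sequence")
    rank = math.ceil(percentile / 100.0 * len(s))
    return s[rank - 1]


def percentile_filter(records: List[ROIRecord], percentile: Optional[float],
                      key: str = "foci_count_1") -> List[ROIRecord]:
    """Flag records whose *key* lies strictly above the nearest-rank
    percentile of that key over all records (one image's worth).

    Flagged records keep their data (``excluded_by_percentile = True``);
    nothing is deleted, only summary statistics skip them.
    """
    if percentile is None or not records:
        return records
    cut = nearest_rank_percentile([getattr(r, key) for r in records], percentile)
    for r in records:
        if getattr(r, key) > cut:
            r.excluded_by_percentile = True
    return records


def build_roi_records(image_name: str, rois: Sequence[ROI],
                      intensity_raster: np.ndarray, foci,
                      params: MeasureParams, has_foci2: bool) -> List[ROIRecord]:
    """Assemble per-ROI records from segmentation, measurement and the
    detected foci list, then apply the percentile filter."""
    factor = params.area_correction_factor
    if params.pixel_size_um is not None:
        # report densities per (factor) um^2 instead of per (factor) px^2
        factor = params.area_correction_factor / (params.pixel_size_um ** 2)
    counts1 = {r.roi_id: 0 for r in rois}
    counts2 = {r.roi_id: 0 for r in rois}
    for f in foci:
        if f.channel_role == "foci1":
            counts1[f.roi_id] += 1
        else:
            counts2[f.roi_id] += 1
    records = []
    for roi in rois:
        area, mean, mn, mx = measure_roi(roi, intensity_raster)
        n1 = counts1[roi.roi_id]
        rec = ROIRecord(
            image=image_name, roi_id=roi.roi_id,
            area=area, perimeter=roi.perimeter, circularity=roi.circularity,
            centroid_x=roi.centroid[0], centroid_y=roi.centroid[1],
            touches_border=roi.touches_border,
            mean_intensity=mean, min_intensity=mn, max_intensity=mx,
            foci_count_1=n1,
            foci_density_1=area_corrected_count(n1, area, factor),
        )
        if has_foci2:
            n2 = counts2[roi.roi_id]
            rec.foci_count_2 = n2
            rec.foci_density_2 = area_corrected_count(n2, area, factor)
        records.append(rec)
    return percentile_filter(records, params.percentile)
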