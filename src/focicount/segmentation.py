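"""Nucleus segmentation: thresholding, hole filling, watershed separation,
connected-component labeling and size/circularity/edge filtering.

The nuclear-stain channel is binarized (manual intensity threshold or an
automatic histogram method), holes inside nuclei are optionally filled,
touching nuclei are optionally separated by a distance-transform watershed,
and the resulting 8-connected objects become ROIs.  Each ROI carries area,
perimeter (Crofton estimate), circularity 4*pi*area/perimeter^2 capped at 1,
centroid and a border flag; ROIs failing the size, circularity or edge
filters are dropped and the survivors renumbered from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed as _watershed

from .errors import ComputationError, ConfigurationError, DegenerateImageError

_EIGHT = np.ones((3, 3), dtype=bool)

# Minimum Euclidean separation (px) between watershed seed points; touching
# nuclei closer than this are treated as one object.
WATERSHED_SEED_SEPARATION = 4


@dataclass(frozen=True)
class SegmentationParams:
    threshold_mode: str = "auto"          # "manual" | "auto"
    manual_threshold: Optional[float] = None
    auto_method: str = "isodata"          # "isodata" | "otsu"
    min_area: float = 50.0                # px^2
    max_area: Optional[float] = None      # px^2, None = unbounded
    min_circularity: float = 0.0
    max_circularity: float = 1.0
    exclude_edge: bool = True
    fill_holes: bool = True
    use_watershed: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("manual", "auto"):
            raise ConfigurationError(
                f"threshold_mode must be 'manual' or 'auto', got "
                f"{self.threshold_mode!r}")
        if self.threshold_mode == "manual" and self.manual_threshold is None:
            raise ConfigurationError("manual threshold_mode needs manual_threshold")
        if self.auto_method not in ("isodata", "otsu"):
            raise ConfigurationError(f"unknown auto_method {self.auto_method!r}")
        if not (0 <= self.min_circularity <= self.max_circularity <= 1):
            raise ConfigurationError(
                "need 0 <= min_circularity <= max_circularity <= 1")
        if self.min_area <= 0:
            raise ConfigurationError("min_area must be positive")
        if self.max_area is not None and self.max_area < self.min_area:
            raise ConfigurationError("max_area must be >= min_area")


@dataclass
class ROI:
    """One labeled nucleus.  Coordinates are 0-based, x = column, y = row."""

    roi_id: int
    ys: np.ndarray          # row coordinates of member pixels
    xs: np.ndarray          # column coordinates of member pixels
    area: int
    perimeter: float
    circularity: float
    centroid: tuple         # (x, y), continuous
    touches_border: bool
    bbox: tuple             # (min_row, min_col, max_row, max_col) half-open

    @property
    def pixel_set(self) -> set:
        return set(zip(self.xs.tolist(), self.ys.tolist()))

    def mask(self, shape: Optional[tuple] = None) -> np.ndarray:
        """Boolean mask of the ROI; full-frame if *shape* given, else the
        bounding box."""
        if shape is None:
            r0, c0, r1, c1 = self.bbox
            m = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            m[self.ys - r0, self.xs - c0] = True
        else:
            m = np.zeros(shape, dtype=bool)
            m[self.ys, self.xs] = True
        return m


def auto_threshold(raster: np.ndarray, method: str = "isodata",
                   source: str = "") -> float:
    """Histogram-based automatic threshold (isodata intermeans iteration or
    Otsu's between-class variance criterion)."""
    raster = np.asarray(raster)
    if raster.min() == raster.max():
        raise DegenerateImageError(
            f"{source or 'raster'}: constant image, automatic thresholding "
            "has no separable histogram")
    if method == "isodata":
        # the intermeans criterion can have several fixed points when one
        # class is small; the highest one separates the bright class from
        # everything darker, which is what nuclear-stain segmentation wants
        return float(np.max(threshold_isodata(raster, return_all=True)))
    if method == "otsu":
        return float(threshold_otsu(raster))
    raise ConfigurationError(f"unknown auto threshold method {method!r}")


def apply_threshold(raster: np.ndarray, params: SegmentationParams,
                    source: str = ""):
    """Binarize *raster*; foreground is pixel >= threshold.

    Returns ``(mask, threshold_used)`` so the chosen automatic value can be
    logged and echoed in result metadata.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ComputationError("empty raster")
    if params.threshold_mode == "manual":
        t = float(params.manual_threshold)
    else:
        t = auto_threshold(raster, params.auto_method, source)
    return raster >= t, t


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set every background region not connected to the image border to
    foreground.  Never removes foreground (output is a superset) and is
    idempotent."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def separate_touching(mask: np.ndarray) -> np.ndarray:
    """Split touching convex blobs with a Euclidean-distance-transform
    watershed.

    Seeds are local maxima of the distance transform at least
    ``WATERSHED_SEED_SEPARATION`` px apart; a component is split only when
    it holds >= 2 seeds.  Every true pixel keeps exactly one label, so
    pixel coverage is preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    comp_labels, n_comp = ndi.label(mask, structure=_EIGHT)
    out = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for sl, comp_id in zip(ndi.find_objects(comp_labels), range(1, n_comp + 1)):
        comp = comp_labels[sl] == comp_id
        dist = ndi.distance_transform_edt(comp)
        seeds = peak_local_max(
            dist, min_distance=WATERSHED_SEED_SEPARATION,
            exclude_border=False, labels=comp)
        if len(seeds) < 2:
            out[sl][comp] = next_label
            next_label += 1
            continue
        markers = np.zeros(comp.shape, dtype=np.int32)
        # deterministic marker numbering: sort seeds by (row, col)
        order = np.lexsort((seeds[:, 1], seeds[:, 0]))
        for k, (r, c) in enumerate(seeds[order], start=1):
            markers[r, c] = k
        ws = _watershed(-dist, markers=markers, mask=comp, connectivity=2)
        out[sl][comp] = ws[comp] + (next_label - 1)
        next_label += int(ws.max())
    return out


def label_components(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling (no separation)."""
    labels, _ = ndi.label(np.asarray(mask, dtype=bool), structure=_EIGHT)
    return labels.astype(np.int32)


def circularity(area: float, perimeter: float) -> float:
    """Shape descriptor 4*pi*area/perimeter^2, capped at 1.0.

    1 for a perfect circle, pi/4 for a square, approaching 0 for elongated
    objects.  The cap absorbs rasterization noise on tiny objects.
    """
    if perimeter <= 0:
        raise ComputationError(f"perimeter must be positive, got {perimeter}")
    return min(1.0, 4.0 * math.pi * area / perimeter ** 2)


def extract_rois(labels: np.ndarray, params: SegmentationParams):
    """Turn a label map into filtered, renumbered ROIs.

    Returns ``(rois, dropped)`` where *dropped* counts objects removed per
    filter (``size``, ``circularity``, ``edge``).  Survivors are renumbered
    1..n in ascending original-label order.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    rois = []
    dropped = {"size": 0, "circularity": 0, "edge": 0}
    for prop in regionprops(labels):
        area = int(prop.area)
        perim = float(prop.perimeter_crofton)
        if perim <= 0:  # single-pixel or degenerate object
            perim = float(prop.perimeter) or 4.0
        circ = circularity(area, perim)
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        touches = bool(
            (rr.min() == 0) or (cc.min() == 0)
            or (rr.max() == h - 1) or (cc.max() == w - 1))
        if not (params.min_area <= area
                and (params.max_area is None or area <= params.max_area)):
            dropped["size"] += 1
            continue
        if not (params.min_circularity <= circ <= params.max_circularity):
            dropped["circularity"] += 1
            continue
        if params.exclude_edge and touches:
            dropped["edge"] += 1
            continue
        cy, cx = prop.centroid
        r0, c0, r1, c1 = prop.bbox
        rois.append(ROI(
            roi_id=0,
            ys=rr.astype(np.int32), xs=cc.astype(np.int32),
            area=area, perimeter=perim, circularity=circ,
            centroid=(float(cx), float(cy)),
            touches_border=touches,
            bbox=(r0, c0, r1, c1),
        ))
    for i, roi in enumerate(rois, start=1):
        roi.roi_id = i
    return rois, dropped


@dataclass
class SegmentationResult:
    rois: list
    threshold: float
    dropped: dict = field(default_factory=dict)


def segment(raster: np.ndarray, params: SegmentationParams,
            source: str = "") -> SegmentationResult:
    """Full ROI-selection chain: threshold -> fill holes -> (watershed or
    plain labeling) -> filtered ROIs."""
    mask, t = apply_threshold(raster, params, source)
    if params.fill_holes:
        mask = fill_holes(mask)
    if params.use_watershed:
        labels = separate_touching(mask)
    else:
        labels = label_components(mask)
    rois, dropped = extract_rois(labels, params)
    return SegmentationResult(rois=rois, threshold=t, dropped=dropped)
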