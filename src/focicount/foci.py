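"""Foci detection: prominence-based local-maxima picking inside ROIs.

A focus is a local intensity maximum whose peak stands out from its
surroundings by more than the user's *noise level* (the maxima-finding
tolerance familiar from interactive image analysis).  Formally, for a local
maximum m with value v the *merged region* R(m) is the connected set of ROI
pixels reachable from m through pixels of value > v - noise_level; m is
accepted iff R(m) contains no pixel strictly brighter than v.  When several
equal-valued maxima share one merged region, only a single representative
survives.  Pixels outside the ROI are treated as -inf, so signal outside a
nucleus can neither create nor suppress a focus inside it.

Deterministic tie rules (pinned so repeated runs are bit-identical):

* a plateau of equal-valued maximal pixels yields one focus, at the plateau
  pixel nearest the plateau centroid (ties by smallest (y, x));
* among equal-valued maxima merged into one region, the representative with
  the smallest (y, x) position is kept;
* a plateau spanning an entire ROI (no strictly lower in-ROI neighbor, as
  on a constant ROI) is not a peak and yields no focus.

An optional absolute intensity *cutoff* then deletes accepted foci whose
peak value lies below it (>= keeps a focus exactly at the cutoff).  Foci
are never found by watershedding the intensity image: splitting merged
foci that way would require 8-bit reformatting and lose intensity
information, so overlapping foci closer than the merge scale count as one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima

from .errors import ConfigurationError
from .image_io import MultiChannelImage
from .segmentation import ROI

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FociParams:
    noise_level_1: float = 0.0
    noise_level_2: Optional[float] = None
    cutoff_1: Optional[float] = None
    cutoff_2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("noise_level_1", "noise_level_2", "cutoff_1", "cutoff_2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")

    def noise_level(self, role: str) -> float:
        return self.noise_level_1 if role == "foci1" else self.noise_level_2

    def cutoff(self, role: str) -> Optional[float]:
        return self.cutoff_1 if role == "foci1" else self.cutoff_2


@dataclass(frozen=True)
class Focus:
    x: int
    y: int
    peak_intensity: float
    channel_role: str = "foci1"
    roi_id: int = 0


def _plateau_representative(ys: np.ndarray, xs: np.ndarray) -> tuple:
    """Plateau pixel nearest the plateau centroid; ties by smallest (y, x)."""
    cy, cx = ys.mean(), xs.mean()
    d2 = (ys - cy) ** 2 + (xs - cx) ** 2
    order = np.lexsort((xs, ys, d2))
    k = order[0]
    return int(ys[k]), int(xs[k])


def find_maxima(raster: np.ndarray, roi: ROI, noise_level: float,
                *, min_peak: Optional[float] = None) -> List[Focus]:
    """Detect accepted maxima of *raster* inside *roi*.

    ``min_peak`` (optional) discards candidate maxima below that value
    before the prominence check; because acceptance of one maximum never
    depends on other candidates, this is a pure shortcut for a subsequent
    cutoff at the same value.  Results are sorted by (y, x).
    """
    raster = np.asarray(raster)
    r0, c0, r1, c1 = roi.bbox
    sub = raster[r0:r1, c0:c1].astype(np.int64)
    inroi = np.zeros(sub.shape, dtype=bool)
    inroi[roi.ys - r0, roi.xs - c0] = True

    lo = int(sub[inroi].min()) - 1
    vals = np.where(inroi, sub, lo)
    # float view with -inf outside the ROI for the flood traversal test
    fvals = np.where(inroi, sub.astype(np.float64), -np.inf)

    cand_mask = local_maxima(vals, connectivity=2) & inroi
    if not cand_mask.any():
        return []

    plats, n_plat = ndi.label(cand_mask, structure=_EIGHT)
    # value of each plateau (all member pixels share it)
    plat_slices = ndi.find_objects(plats)
    candidates = []  # (value, rep_y, rep_x, plateau_id)
    for pid in range(1, n_plat + 1):
        sl = plat_slices[pid - 1]
        # expand the tight bounding slice by 1 px so dilation sees neighbors
        y0 = max(sl[0].start - 1, 0)
        y1 = min(sl[0].stop + 1, sub.shape[0])
        x0 = max(sl[1].start - 1, 0)
        x1 = min(sl[1].stop + 1, sub.shape[1])
        m = plats[y0:y1, x0:x1] == pid
        pys, pxs = np.nonzero(m)
        pys = pys + y0
        pxs = pxs + x0
        v = int(vals[pys[0], pxs[0]])
        if min_peak is not None and v < min_peak:
            continue
        # a plateau must look down on at least one in-ROI neighbor;
        # otherwise (constant ROI) there is no peak at all
        dil = ndi.binary_dilation(m, structure=_EIGHT)
        ring = dil & ~m
        if not (ring & inroi[y0:y1, x0:x1]).any():
            continue
        ry, rx = _plateau_representative(pys, pxs)
        candidates.append((v, ry, rx))

    if not candidates:
        return []

    accepted = []  # (y, x, v)
    if noise_level <= 0:
        accepted = [(ry, rx, v) for v, ry, rx in candidates]
    else:
        by_value: dict = {}
        for v, ry, rx in candidates:
            by_value.setdefault(v, []).append((ry, rx))
        for v, pts in by_value.items():
            trav = fvals > (v - noise_level)
            comp, _ = ndi.label(trav, structure=_EIGHT)
            comp_max = ndi.maximum(fvals, labels=comp,
                                   index=np.arange(1, comp.max() + 1))
            groups: dict = {}
            for (ry, rx) in pts:
                cid = comp[ry, rx]
                if comp_max[cid - 1] > v:
                    continue  # a brighter pixel owns this region
                groups.setdefault(cid, []).append((ry, rx))
            for cid, members in groups.items():
                ry, rx = min(members)  # smallest (y, x) representative
                accepted.append((ry, rx, v))

    accepted.sort()
    return [
        Focus(x=c0 + rx, y=r0 + ry,
              peak_intensity=float(raster[r0 + ry, c0 + rx]),
              roi_id=roi.roi_id)
        for ry, rx, v in accepted
    ]


def apply_cutoff(foci: Sequence[Focus], cutoff: Optional[float]) -> List[Focus]:
    """Keep foci with peak_intensity >= cutoff, order preserved."""
    if cutoff is None:
        return list(foci)
    return [f for f in foci if f.peak_intensity >= cutoff]


def detect_foci_per_roi(img: MultiChannelImage, rois: Sequence[ROI],
                        params: FociParams) -> List[Focus]:
    """Run maxima detection plus cutoff over every ROI and every active
    foci channel.  Each focus is tagged with its owning ROI id and channel
    role; the input rasters are never modified."""
    active = ["foci1"]
    has2 = "foci2" in img.channel_roles
    if params.noise_level_2 is not None or params.cutoff_2 is not None:
        if not has2:
            raise ConfigurationError(
                "foci-channel-2 parameters set but no 'foci2' channel assigned")
    if has2:
        if params.noise_level_2 is None:
            raise ConfigurationError(
                "a 'foci2' channel is assigned but noise_level_2 is not set")
        active.append("foci2")

    out: List[Focus] = []
    for role in active:
        raster = img.channel(role)
        cut = params.cutoff(role)
        for roi in rois:
            found = find_maxima(raster, roi, params.noise_level(role),
                                min_peak=cut)
            found = apply_cutoff(found, cut)
            out.extend(Focus(x=f.x, y=f.y, peak_intensity=f.peak_intensity,
                             channel_role=role, roi_id=roi.roi_id)
                       for f in found)
    return out
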