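import numpy as np
import pytest

from focicount.segmentation import ROI


def roi_from_mask(mask, roi_id=1):
    """Build a bare ROI (geometry fields only) from a boolean mask, for
    feeding detection and measurement functions directly."""
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty mask")
    return ROI(
        roi_id=roi_id,
        ys=ys.astype(np.int32), xs=xs.astype(np.int32),
        area=int(len(ys)), perimeter=1.0, circularity=1.0,
        centroid=(float(xs.mean()), float(ys.mean())),
        touches_border=bool(ys.min() == 0 or xs.min() == 0),
        bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
    )


def full_frame_roi(shape, roi_id=1):
    return roi_from_mask(np.ones(shape, dtype=bool), roi_id=roi_id)


def disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
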