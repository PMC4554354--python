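"""QC overlay rendering: ROI outlines and focus markers burned into an RGB
copy of the image, the non-interactive stand-in for watching the selection
happen on screen."""

from __future__ import annotations

import numpy as np
from skimage.segmentation import find_boundaries

from .image_io import MultiChannelImage, save_raster


def render_overlay(img: MultiChannelImage, rois, foci) -> np.ndarray:
    """8-bit RGB: ROI channel in gray, ROI outlines green, foci crosses
    red (foci1) / cyan (foci2)."""
    base = img.channel("roi").astype(np.float64)
    top = 2 ** img.bit_depth - 1
    gray = (base / top * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)

    label_map = np.zeros(img.shape, dtype=np.int32)
    for roi in rois:
        label_map[roi.ys, roi.xs] = roi.roi_id
    edges = find_boundaries(label_map, mode="inner")
    rgb[edges] = (0, 255, 0)

    h, w = img.shape
    for f in foci:
        color = (255, 0, 0) if f.channel_role == "foci1" else (0, 255, 255)
        for dy, dx in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
            y, x = f.y + dy, f.x + dx
            if 0 <= y < h and 0 <= x < w:
                rgb[y, x] = color
    return rgb


def save_overlay(path, img: MultiChannelImage, rois, foci) -> None:
    save_raster(path, render_overlay(img, rois, foci))
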