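"""Recover a radiation dose-response curve.

Foci per nucleus scale roughly linearly with absorbed dose (order of
15-19 foci per Gy in the clinical range).  This script plants foci at
16 per Gy for doses 0.5/1.5/3.0 Gy, counts them blind, and fits the line.
"""

import numpy as np

from focicount import (AnalysisParams, ChannelAssignment, FociParams,
                       SegmentationParams, SyntheticSpec, analyze_image,
                       generate_dose_series)

doses = [0.5, 1.5, 3.0]
base = SyntheticSpec(image_size=(768, 768), n_nuclei=12,
                     nucleus_axes_range=(40, 48), min_focus_spacing=6,
                     seed=7)
params = AnalysisParams(
    assignment=ChannelAssignment(roi_channel=0, foci1_channel=1),
    seg=SegmentationParams(min_area=2000),
    foci=FociParams(noise_level_1=24, cutoff_1=140),
)

print(f"{'dose (Gy)':>10} {'planted/nucleus':>16} {'counted/nucleus':>16}")
means = []
for dose, (img, truth) in zip(doses, generate_dose_series(doses, 16.0, base)):
    res = analyze_image(img, params, name=f"{dose} Gy")
    counted = float(np.mean([r.foci_count_1 for r in res.roi_records]))
    planted = len(truth.foci_1) / len(truth.nuclei)
    means.append(counted)
    print(f"{dose:>10.1f} {planted:>16.2f} {counted:>16.2f}")

slope, intercept = np.polyfit(doses, means, 1)
fitted = np.polyval([slope, intercept], doses)
r2 = 1 - np.sum((np.array(means) - fitted) ** 2) / \
    np.sum((np.array(means) - np.mean(means)) ** 2)
print(f"\nlinear fit: {slope:.1f} foci per nucleus per Gy "
      f"(planted 16.0), R^2 = {r2:.4f}")
print("slope near the planted rate and R^2 near 1 mean the counter tracks "
      "the dose linearly, as damage foci do in this range")
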