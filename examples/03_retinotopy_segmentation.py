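"""ISOI retinotopy round trip: sweep stacks -> sign map -> visual areas.

Renders forward/reverse sweep stacks for a six-area cortical layout with a
1-s hemodynamic delay, recovers azimuth/elevation maps by Fourier phase
analysis with delay subtraction, computes the visual-field sign map, and
segments the areas with the three-step border detection.
"""

import numpy as np

from dsstream import isoi
from dsstream.protocols import make_stimulus_protocol
from dsstream.simulate_imaging import (
    default_six_area_layout,
    synthesize_retinotopy_stack,
)

layout = default_six_area_layout()
protocol = make_stimulus_protocol("retinotopy-bar")
stacks, truth = synthesize_retinotopy_stack(layout, protocol, seed=0, delay_s=1.0)

maps, mag = {}, None
for axis, st in stacks.items():
    pf, mf = isoi.fourier_component_map(st.forward, st.frame_rate, st.stim_freq_hz)
    pr, mr = isoi.fourier_component_map(st.reverse, st.frame_rate, st.stim_freq_hz)
    phase, delay = isoi.delay_corrected_retinotopy(pf, pr, weights=mf * mr)
    maps[axis] = isoi.phase_to_degrees(phase, st.extent_deg) + st.center_deg
    mag = mf * mr if mag is None else mag * mf * mr
    print(f"{axis}: sweep {st.stim_freq_hz:.3f} Hz, "
          f"recovered delay phase {delay:+.3f} rad")

for axis, gt in (("azimuth", truth.azimuth_deg), ("elevation", truth.elevation_deg)):
    mae = np.abs(maps[axis] - gt)[truth.mask].mean()
    print(f"{axis} map mean absolute error vs ground truth: {mae:.3f} deg")

sign = isoi.visual_field_sign(maps["azimuth"], maps["elevation"],
                              response_mask=mag > 0.05 * mag.max())
sm = isoi.threshold_and_clean(sign)
seg = isoi.detect_borders(isoi.neighbor_filter(sm.mask), sign=sm.sign)
print(f"segmented {seg.area_mm2.size} areas "
      f"(layout has {len(layout)}); field signs {seg.signs.astype(int)}")
print("per-area size (mm^2) and centroid offset from V1 (mm):")
for k in range(seg.area_mm2.size):
    print(f"  area {k + 1}: {seg.area_mm2[k]:.4f} mm^2, "
          f"offset {np.round(seg.centroids_rel_mm[k], 3)}")
print("the delay phase is identical in both sweep directions, so the")
print("half-sum isolates it and the maps match ground truth despite it.")
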