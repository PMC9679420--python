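"""Render a preprocessed segment into a 3D isopotential sequence map.

Every time sample of a 2-s segment becomes a grayscale image of the
anterior torso via inverse-distance-weighted interpolation of the 74
anterior electrode voltages; stacking the frames gives the H x W x T input
of the classifier.
"""

import numpy as np

from bspmaf.isopotential import InterpolationGrid, build_sequence, resize_sequence
from bspmaf.preprocess import (
    apply_wct_reference,
    bandpass_filter,
    normalize_amplitude,
    segment_recording,
)
from bspmaf.synthetic import generate_electrode_layout, simulate_recording

layout = generate_electrode_layout()
rec = simulate_recording(layout, duration_s=6.0, seed=11, rhythm="af")
rec = bandpass_filter(apply_wct_reference(rec, layout))

segment = normalize_amplitude(segment_recording(rec)[0])
grid = InterpolationGrid.from_layout(layout, size=64)
seq = build_sequence(segment, grid)
print(f"raster {grid.height}x{grid.width}, {int(grid.mask.sum())} pixels inside "
      f"the anterior hull")
print(f"sequence: {seq.frames.shape[0]}x{seq.frames.shape[1]}x"
      f"{seq.frames.shape[2]} frames at dt = {seq.dt_s * 1e3:.0f} ms")

small = resize_sequence(seq, 16, 16, 32)
print(f"network input after resize: {small.frames.shape}, "
      f"range [{small.frames.min():.3f}, {small.frames.max():.3f}]")

# the wavefront sweeps across the grid: during the QRS the bright lobe of
# the potential pattern drifts frame to frame (intensity-weighted centroid)
t_peak = int(np.argmax(seq.frames.max(axis=(0, 1))))
rr, cc = np.mgrid[0 : grid.height, 0 : grid.width]
for t in range(t_peak - 16, t_peak + 17, 8):
    w = seq.frames[:, :, t][grid.mask]
    r = (rr[grid.mask] * w).sum() / w.sum()
    c = (cc[grid.mask] * w).sum() / w.sum()
    print(f"frame {t}: intensity centroid (row {r:.1f}, col {c:.1f}), "
          f"peak {seq.frames[:, :, t].max():.3f}")
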