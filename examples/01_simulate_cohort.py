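"""Simulate a labeled BSPM cohort and store it on disk.

Builds the parametric torso and 128-electrode vest, simulates a small
cohort of AF patients (some destined to relapse after ablation, some not),
and writes everything to standard formats: OBJ for the mesh, JSON for the
electrode layout, HDF5 per recording.
"""

from pathlib import Path

import numpy as np

from bspmaf.io import save_layout_json, save_mesh_obj, save_recording_h5
from bspmaf.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_electrode_layout,
    generate_torso_mesh,
)

out = Path("scratch/cohort")
out.mkdir(parents=True, exist_ok=True)

mesh = generate_torso_mesh()
layout = generate_electrode_layout(mesh)
save_mesh_obj(mesh, out / "torso.obj")
save_layout_json(layout, out / "layout.json")
print(f"torso: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces")
print(f"vest: {(layout.side == 'A').sum()} anterior + {(layout.side == 'P').sum()} "
      f"posterior electrodes, refs {layout.ref_names}")

spec = CohortSpec(n_patients=6, recurrence_fraction=2 / 6, duration_s=10.0, seed=7)
for rec in generate_cohort(spec, layout):
    save_recording_h5(rec, out / f"{rec.patient_id}.h5")
    rms = np.sqrt(np.mean(rec.data**2))
    print(f"{rec.patient_id}: label={rec.label:<14s} "
          f"{rec.data.shape[0]} ch x {rec.data.shape[1]} samples, RMS {rms:.3f} mV")

# Each recording has 131 rows: the 128 vest channels plus the three Wilson
# reference traces that the preprocessing stage subtracts and drops.
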