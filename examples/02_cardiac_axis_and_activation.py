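"""Derive limb leads, compute the cardiac axis, and rank activation order.

A sinus-rhythm recording propagates along the configured 48-degree cardiac
axis.  Channels 29/93/37 approximate Einthoven leads I and III; their summed
signed QRS amplitudes give the frontal-plane mean electrical axis.  Six
reference channels laid out along the axis receive the QRS in a canonical
order; small delays show up as inversions.
"""

from bspmaf.leads import activation_sequence, cardiac_axis_angle, recording_axis
from bspmaf.preprocess import apply_wct_reference, bandpass_filter
from bspmaf.synthetic import generate_electrode_layout, simulate_recording

layout = generate_electrode_layout()
rec = simulate_recording(layout, duration_s=20.0, seed=3, rhythm="sinus",
                         axis_angle_deg=48.0)
rec = bandpass_filter(apply_wct_reference(rec, layout))

u_i, u_iii, angle = recording_axis(rec)
print(f"summed QRS amplitudes: U_I = {u_i:.4f}, U_III = {u_iii:.4f}")
print(f"mean electrical axis: {angle:.4f} deg (configured 48.0)")
print(f"reference worked example: axis({383.7130}, {176.5790}) = "
      f"{cardiac_axis_angle(383.7130, 176.5790):.4f} deg\n")

ao = activation_sequence(rec)
print(f"{len(ao.orders)} beats; QRS arrival order at channels "
      f"{ao.channel_labels}:")
for order, count in sorted(ao.order_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {' -> '.join(map(str, order))}: {count} beats")
print(f"delay bins (largest pairwise inversion per beat): {ao.delay_bins}")
# A beat counts as delay 0 when it follows the canonical order exactly;
# sensor noise occasionally swaps neighbouring channels by a millisecond.
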