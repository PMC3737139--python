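"""Z-score infant anthropometry against an LMS reference.

Builds the synthetic reference shipped with the package, scores one
infant's weight and length, and converts between z-scores and centiles.
"""

import growthrisk as gr

refs = gr.synthetic_reference(seed=0)

# a 6.5-month-old girl: 7.2 kg, 66 cm
m = gr.Measurement(subject_id="demo", sex="f", age_days=198,
                   weight_kg=7.2, length_cm=66.0)
z = gr.measurement_to_z(m, refs)

print(f"weight z = {z.weight_z:+.2f}  ({gr.z_to_centile(z.weight_z):.0f}th centile)")
print(f"length z = {z.length_z:+.2f}")
print(f"BMI    z = {z.bmi_z:+.2f}")
print()
print(f"the 91st centile corresponds to z = {gr.centile_to_z(91):.4f}")
# A z-score of 0 means the infant sits exactly on the reference median for
# their age and sex; each unit is one SD of the reference distribution.
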