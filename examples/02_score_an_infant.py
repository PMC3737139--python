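"""Score one infant's childhood-obesity risk, as the App would.

Inputs: sex, date of birth, birthweight, current weight (any supported
unit), and optionally maternal height/weight.  Output: a probability and a
low/medium/high band from the published equation for the infant's age.
"""

import datetime as dt

import growthrisk as gr

refs = gr.synthetic_reference(seed=0)
config = gr.default_model_config()

result = gr.assess(
    sex="f",
    dob=dt.date(2023, 1, 10),
    assessment_date=dt.date(2023, 7, 20),   # ~6.3 months old -> equation 1
    birth_weight="3.2kg",
    current_weight="7.9kg",
    maternal_height="165cm",
    maternal_weight="70kg",
    refs=refs,
    conditional_model=config.conditional_model,
)

print(f"equation used:    {result.equation_id} ({result.variant})")
print(f"birthweight z:    {result.bw_z:+.2f}")
print(f"current weight z: {result.current_weight_z:+.2f}")
print(f"conditional gain: {result.gain_z:+.2f}")
print(f"risk probability: {result.probability:.3f}")
print(f"risk band:        {result.band}")
# The band compares the probability with the thresholds that put 10%/20% of
# the development population above them: top decile = high, decile-to-
# quintile = medium, the rest = low.
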