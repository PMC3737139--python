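"""Draw synthetic cohorts matching the development and external samples.

Model mode draws covariates at the published summary moments and the
outcome from the published logistic model; growth mode emits raw weights
and lengths and recomputes everything through the z-scoring pipeline.
"""

import growthrisk as gr

# model mode, development-sample conditions for the 12-month equation
frame = gr.simulate_model_mode(gr.bib_preset("eq3", n=50_000, seed=7))
print(f"model mode: n={len(frame)}, outcome prevalence "
      f"{100 * frame['outcome'].mean():.1f}% (development sample: ~8%)")
print(f"  birthweight z mean {frame['bw_z'].mean():+.2f} "
      f"(configured {gr.bib_preset('eq3').bw_z_mean:+.2f})")

# external (ALSPAC-like) preset: leaner mothers, almost entirely White
ext = gr.simulate_model_mode(gr.external_preset("eq3", n=50_000, seed=7))
print(f"external preset: maternal BMI mean {ext['maternal_bmi'].mean():.1f} "
      f"(configured 23.4), prevalence {100 * ext['outcome'].mean():.1f}%")

# growth mode: raw measurements through the full pipeline
refs = gr.synthetic_reference(seed=0)
sim = gr.simulate_growth_mode(
    gr.SimulationConfig(n=3_000, seed=7, mode="growth"), refs)
print(f"growth mode: {len(sim.measurements)} raw measurements -> "
      f"{len(sim.cohort)} records, prevalence "
      f"{100 * sim.cohort['outcome'].mean():.1f}%")
print(f"  birth->2y conditioning slope {sim.conditional_2y.slope:.2f} "
      f"(latent correlation 0.5, scaled by the birth-z SD)")
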