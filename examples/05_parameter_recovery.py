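"""Simulate -> fit -> recover: can the hierarchy retrieve known parameters?

Generates a 30-subject cohort with known latents, refits it, and prints
per-parameter recovery correlations, bias, and 95%-interval coverage.
"""

from twostep.cohort import CohortSpec
from twostep.evaluate import parameter_recovery

spec = CohortSpec(n_per_arm={"placebo": 30}, n_trials=150, master_seed=5)
report = parameter_recovery(spec, chains=2, iterations=500, warmup=250,
                            seed=5)

print(report.latent_table.round(3).to_string(index=False))
print()
print(f"pooled 95%-interval coverage: {report.overall_coverage:.3f}")
print("r is the Pearson correlation between true and posterior-mean "
      "estimation-space latents; baselines (omega0, eta0) recover well, "
      "session differences are intrinsically harder because each is "
      "informed by the contrast of two noisy sessions.")
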