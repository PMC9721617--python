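"""Hierarchical Bayesian estimation of drug effects on a synthetic cohort.

Generates a small three-arm cohort in which amisulpride shifts the session
difference of the model-based weight by +0.8 in estimation space, fits the
joint two-session hierarchical model, and prints the recovered group-level
coefficients with effect sizes.  Runs in about half a minute.
"""

from twostep.cohort import CohortSpec, generate_cohort
from twostep.hbayes import fit_hierarchical

spec = CohortSpec(
    n_per_arm={"placebo": 12, "amisulpride": 12, "naltrexone": 12},
    drug_effects={("amisulpride", "d_omega"): 0.8},
    n_trials=150, master_seed=0,
)
trials, truth = generate_cohort(spec)
fit = fit_hierarchical(trials, "M1", chains=2, iterations=450, warmup=225,
                       seed=100)

print(fit.summary().round(3).to_string(index=False))
print()
print("beta_ami_d_omega is the amisulpride shift of the session difference "
      "of the model-based weight (probit space); its posterior mean should "
      "be positive here because the cohort was generated with a +0.8 shift "
      "(hierarchical shrinkage pulls the estimate toward zero at this "
      "cohort size).  d is the shift standardized by the pooled baseline + "
      "difference SD.  tail_prob is P(coefficient < 0).")
for w in fit.warnings:
    print("warning:", w)
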