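# Examples

Short narrative scripts, one per capability; each builds a small synthetic
input, runs the method, and prints what it computes.

| script | capability | approx. runtime |
| --- | --- | --- |
| `01_simulate_task.py` | task environment, agent simulation, stay coding | seconds |
| `02_fit_drug_effects.py` | hierarchical drug-effect estimation, effect sizes | ~30 s |
| `03_stay_regression.py` | hierarchical logistic stay regression | ~30 s |
| `04_model_comparison.py` | PSIS-LOO + pseudo-BMA across M1/M2/M3 | ~1 min |
| `05_parameter_recovery.py` | simulate -> fit -> recovery scoring | ~1 min |

Run from the repository root, e.g. `python examples/01_simulate_task.py`.
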