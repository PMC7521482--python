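"""Fit the progressive illness-death model to a synthetic panel and compare
the estimates with the generating truth.

The model has three transitions (CI-free to CI, CI-free to death, CI to
death), each with a Gompertz-type log-linear age effect, plus a hazard ratio
of a binary exposure on CI onset.
"""

import math

from healthspan import IllnessDeathSpec, default_config, fit, generate_cohort

config = default_config(n_subjects=3000, seed=7)
panel, _ = generate_cohort(config)

spec = IllnessDeathSpec(covariates={"12": ("exposure",)}, age_effect=True, ref_age=80.0)
result = fit(panel, spec)

truth = {
    "beta0_12": -3.0, "beta0_13": -3.2, "beta0_23": -2.0,
    "beta_age_12": 0.08, "beta_age_13": 0.09, "beta_age_23": 0.07,
    "beta_12_exposure": math.log(1.5),
}
se = result.standard_errors()
print(f"converged: {result.converged} (loglik {result.loglik:.1f}, "
      f"{result.n_iterations} iterations)")
print(f"observed transitions: {result.transition_counts}")
print(f"{'parameter':<18}{'estimate':>10}{'SE':>8}{'truth':>9}")
for i, name in enumerate(spec.parameter_names()):
    print(f"{name:<18}{result.theta[i]:>10.3f}{se[name]:>8.3f}{truth[name]:>9.3f}")

hr = math.exp(result.theta[-1])
print(f"\nfitted hazard ratio of the exposure on CI onset: {hr:.2f} (true 1.50)")
# Each estimate should sit within roughly two standard errors of the truth;
# the exposure's log-hazard-ratio recovers the simulated 1.5-fold risk.
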