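"""Estimate counterfactual survival curves and the A/B decomposition.

Simulates a confounded two-arm study, fits the embedding pipeline and
prints the four curves with the composition/treatment decomposition.
"""

import numpy as np

from cse import SimulationConfig, estimate_effect_curves, simulate_dataset

sim = simulate_dataset(SimulationConfig(n_control=1000, n_treated=800, seed=1))
obs = sim.observed
print(f"n={obs.n} subjects, {obs.events.mean():.0%} with observed events")

curves = estimate_effect_curves(obs)
print(f"{'t':>5} {'S00':>6} {'S11':>6} {'S01':>6} {'S10':>6} {'A':>7} {'B':>7} {'gain':>7}")
for i in range(4, 50, 9):
    print(f"{curves.grid[i]:5.2f} {curves.S00[i]:6.3f} {curves.S11[i]:6.3f} "
          f"{curves.S01[i]:6.3f} {curves.S10[i]:6.3f} {curves.A[i]:+7.3f} "
          f"{curves.B[i]:+7.3f} {curves.gain[i]:+7.3f}")

print(
    "\nA = S01 - S00 is the share of the observed gap S11 - S00 explained by\n"
    "the arms' differing covariates; B = S11 - S01 is the treatment effect on\n"
    "the treated; gain is the population counterfactual survival gain d(t).\n"
    f"Here A is negative (mean {curves.A.mean():+.3f}): the treated arm's\n"
    "covariate shift alone would have shortened survival, so the treatment\n"
    "effect exceeds the raw between-arm gap."
)
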