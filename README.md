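# cse — counterfactual survival curves under right-censoring

`cse` estimates **counterfactual survival functions** from right-censored
observational data with a binary treatment, using kernel mean embeddings of
counterfactual distributions combined with inverse-probability-of-censoring
weighting (IPCW). It is aimed at biostatisticians and epidemiologists who
want to decompose an observed survival difference between two arms into the
part explained by differing covariate distributions and the part explained
by the treatment itself.

## The problem and the estimator

Each subject carries a survival time `T`, a censoring time `C`, a treatment
arm `Z ∈ {0,1}` and covariates `X`; we observe `T* = min(T, C)`,
`Δ = 1{T ≤ C}`, `Z`, `X`. Writing `S⟨z|z'⟩` for the survival law of arm
`z`'s response structure integrated against arm `z'`'s covariate
distribution, the observed gap between arm curves decomposes as

    S11(t) − S00(t) = [S01(t) − S00(t)] + [S11(t) − S01(t)] = A(t) + B(t)

with `A` the **composition effect** (covariate shift) and `B` the
**distributional treatment effect on the treated**. Under conditional
exogeneity the counterfactual survival gain is

    d(t) = P(T̃1 > t) − P(T̃0 > t)
         = [S10(t) − S00(t)] P(Z=0) + [S11(t) − S01(t)] P(Z=1).

`S00`/`S11` are observational arm curves (Kaplan–Meier). The transported
curves `S01`/`S10` are the hard part: `cse` embeds the conditional law
`x ↦ E[l(T,·)|X=x]` into the RKHS of a Gaussian time kernel `l` by a
vector-valued kernel ridge regression whose empirical risk is reweighted by
IPCW weights `W_i = Δ_i / Ĝ(T*_i⁻)` (`Ĝ` = reverse Kaplan–Meier estimate of
the censoring survival), then averages the fitted embedding over the other
arm's covariates. The whole estimator is one closed-form linear solve:

    μ̂_{T⟨0|1⟩}(·) = H′ W (K W + n ε I)⁻¹ K̃ 1_m ,

an expansion `Σ_i a_i l(T*_i, ·)` whose coefficients vanish on censored
rows. A survival curve is recovered from `μ̂` either by transferring the
coefficients to indicator features (`plugin`) or by projecting onto the
set of probability measures supported on the uncensored atoms (`simplex`,
the default in the effect-curve pipeline).

Two comparators are built in: **Naive** (the identical pipeline with
`W_i = Δ_i`, i.e. uncensored observations only) and **AKME** (the
IPTW-adjusted Kaplan–Meier with linear-logistic propensity scores).
Causal survival forests, which estimate the same gain `d(t) = E[τ_t(X)]`,
are treated purely as an external comparator and are not implemented.

## Worked example

```python
import numpy as np
from cse import SimulationConfig, simulate_dataset, estimate_effect_curves

sim = simulate_dataset(SimulationConfig(n_control=1000, n_treated=800, seed=1))
curves = estimate_effect_curves(sim.observed)
for t, s00, s11, a, b, g in zip(curves.grid[10:31:10], curves.S00[10:31:10],
                                curves.S11[10:31:10], curves.A[10:31:10],
                                curves.B[10:31:10], curves.gain[10:31:10]):
    print(f"t={t:5.2f}  S00={s00:.3f}  S11={s11:.3f}  A={a:+.3f}  B={b:+.3f}  gain={g:+.3f}")
```

prints

```
t= 0.30  S00=0.811  S11=0.910  A=-0.170  B=+0.270  gain=+0.167
t= 0.59  S00=0.665  S11=0.849  A=-0.194  B=+0.378  gain=+0.181
t= 0.89  S00=0.538  S11=0.753  A=-0.149  B=+0.364  gain=+0.196
```

Read: at `t = 0.89` the treated arm's observed survival exceeds the
control arm's by 21.5 points. The composition effect is *negative*
(`A = −0.149`: the treated arm's shifted covariates would have *hurt*
survival under the control response structure), so the treatment effect on
the treated is even larger than the raw gap (`B = +0.364`). `gain` is the
estimated population-level counterfactual gain `d̂(t)`. The same pipeline runs on any CSV with time/event/treatment/
covariate columns via the CLI:

```bash
cse simulate --seed 1 --out study.csv
cse fit --data study.csv --out study        # writes study_curves.tsv + manifest
cse benchmark --methods cse,naive,akme --reps 100 --seed 1 --out table.tsv
```

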