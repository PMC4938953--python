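# fluxdrift

Forward-time evolutionary simulation of a five-enzyme metabolic pathway,
built to ask a population-genetics question about biochemistry: **is the
rate-limiting (flux-controlling) step of a pathway evolutionarily stable
when flux is under stabilizing selection?**

Under mutation-selection-drift balance, degrading mutational pressure on
kinetic parameters, purifying selection on pathway function, and random
drift jointly hold fitness at a plateau while the underlying parameters —
and with them the identity of the flux-controlling reaction — keep
wandering. `fluxdrift` simulates this process and measures the wandering.

It is intended for molecular-evolution and systems-biology researchers who
want a null model of compensatory pathway evolution, e.g. as a baseline for
detecting directional selection on pathway function.

## The model

A linear chain `A → B → C → D → E → F` of five reversible
Michaelis–Menten reactions, each catalysed by one enzyme with kinetic
parameters ([E], k_cat, K_M, k_catr, K_Mr):

    v = [E] (k_cat S/K_M − k_catr P/K_Mr) / (1 + S/K_M + P/K_Mr + [I]/K_I)

[A] is clamped, F is drained by first-order mass action (k_use), and the
end product F feedback-inhibits the first enzyme through K_I — a
glycolysis-like regulatory loop. Steady-state flux J satisfies
J = k_use·[F] and is found by an exact 1-D reduction of the chain (each
rate law is linear in its substrate), cross-checked against brute-force ODE
integration.

**Mutation** hits each of the 26 parameters with probability 3×10⁻³ per
individual per generation. Percent effects are Normal with an
activity-dependent mean — μ₁(p) = −0.01·e^(c·p) for concentrations and
catalytic constants, a clamped reciprocal form for binding constants — so
highly active enzymes predominantly receive degrading changes. A neutral
(mean-zero) control and a Haldane-constrained mode (Keq =
k_cat·K_Mr/(k_catr·K_M) preserved exactly) are also provided.

**Selection** uses five schemes: no selection; logistic selection on flux
F₁ = 1/(1+e^(−0.07(J−650))); F₁·F₂ with F₂ = e^(−9.4×10⁻⁴·[B]) against a
toxic intermediate; F₁·F₃ with an expression-cost penalty; and a positive
control (F₁·F₂ with neutral mutation).

**Population genetics** comes in two engines: explicit Wright–Fisher
sampling of N = 100 individuals, and an origin-fixation walk where one
mutation per generation fixes with the Kimura probability
ψ = (1−e^(−2cNₑsp))/(1−e^(−2cNₑs)) at p = ½ (so neutral mutations fix with
probability ½), for Nₑ up to 10⁶.

**Analysis**: the rate-limiting step is the reaction whose 10 % slowdown
causes the largest flux drop; its consecutive-generation run lengths are
summarised with a permutation test and nested bootstrap CIs; allele counts
are compared with the Kimura–Crow expectation n = 2Nₑμ+1; and parameter
co-evolution is clustered by complete linkage on absolute correlations of
detrended per-generation rates of change, with bootstrap cluster support.

## Worked example

```python
import dataclasses
import numpy as np
from fluxdrift import *
from fluxdrift.experiment_io import preset_config

cfg = preset_config("flux_only")            # selection on flux alone
cfg = dataclasses.replace(cfg, population_size=30, total_generations=3000,
                          equilibrium_generation=1000, replicates=2, seed=7)
res = run_experiment(cfg)
rep = summarize_experiment([r.frame() for r in res], cfg, n_perm=10_000,
                           n_boot=2_000, cluster=False,
                           rng=np.random.default_rng(7))
print(rep["proportions"])
print(rep["run_lengths"]["mean_run_length"], rep["run_lengths"]["permutation_p"])
print(rep["allele_segregation"]["mean"], rep["allele_segregation"]["expected_neutral"])
```

prints (at this reduced scale):

```
{1: 0.8545, 2: 0.0, 3: 0.0025, 4: 0.143, 5: 0.0}
45.98 0.594
1.745 1.18
```

Read: in the post-equilibrium window reaction 1 was rate limiting 85 % of
the time but in runs averaging only ~98 consecutive generations, with
reactions 3 and 4 taking over repeatedly; the permutation test does not
reject equal mean run lengths across reactions (p ≈ 0.59); and each
parameter segregates ~1.7 alleles on average, above the neutral 2Nₑμ+1 =
1.18 for this population size. The same machinery is available from the
shell:

```
fluxdrift run --preset flux_only --seed 7 --out traj/ --generations 3000 --pop-size 30
fluxdrift analyze --traj traj/ --out report/
fluxdrift export-sbml --out pathway.xml
```

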