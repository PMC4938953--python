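# Methods

This note documents the model, the numerical choices, and the open design
decisions behind `fluxdrift`, in the spirit of a simulator's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Kinetic model

The pathway is a fixed linear chain A → B → C → D → E → F. Reaction *i*
converts metabolite *i* to metabolite *i+1* under reversible
Michaelis–Menten kinetics,

    v_i = [E_i] (k_cat,i S/K_M,i − k_catr,i P/K_Mr,i)
          / (1 + S/K_M,i + P/K_Mr,i + [I]/K_I,i),

with the inhibition term present on exactly one enzyme per genotype. All
concentrations are in mmol/l and catalytic constants in mmol/l/s. The
boundary conditions are a clamped substrate concentration [A] and a
first-order sink on the end product, d[F]/dt ∋ −k_use·[F], so at steady
state the common chain flux is J = k_use·[F].

**Feedback wiring.** The end product F inhibits enzyme 1 through K_I, the
classic glycolysis-like end-product feedback. The inhibitor species and
the inhibited enzyme are both configurable (`KineticEnvironment.
inhibitor_species`; place `K_I` on any enzyme). The inhibition enters as
an additive [I]/K_I denominator term (competitive-style).

**Initial kinetic values (surrogate).** All five enzymes start identical:
[E] = 5, k_cat = 300, K_M = 2, k_catr = 3, K_Mr = 20 (so Keq = 1000), K_I
= 250 on enzyme 1; [A] = 5, k_use = 1/s. These are this package's own
choices, made once, with two constraints: (i) the initial steady flux
(619.27 mmol/l/s, computed by the solver) sits in the rising region just
below the fitness midpoint of 650, so selection pressure exists at
generation 0 (the test suite asserts flux ∈ [300, 640]); and (ii) every
parameter lies where the activity-dependent mutational means are modest
(fractions of a percent for the μ₁ classes), i.e. in the regime the
mutation model was designed for. They are config-overridable.

## Steady-state solver

Because each rate law is *linear in its substrate* at fixed product
concentration, the steady state reduces to one dimension. For a trial
value of [F], the flux is J = k_use·[F] and the substrate of each reaction
5, 4, …, 2 back-substitutes in closed form,

    S = K_M [J(1 + P/K_Mr + [I]/K_I) + [E] k_catr P/K_Mr] / ([E] k_cat − J),

leaving a single residual — the rate of reaction 1 at the implied [B]
minus J — that is bracketed on [0, F_cap) (F_cap from the smallest
downstream capacity [E]·k_cat/k_use) and solved with Brent's method
(xtol 1e−14). The 1-D solution is accepted when the absolute residual is
below 5× the solver tolerance (default 1e−9).

Two fallbacks handle the rest:

* **Ill-conditioned bottlenecks.** When reaction 1 is deeply limiting, the
  residual's slope in [F] can exceed 1/eps, so no float64 value of [F]
  makes the residual small even though the steady state is well defined.
  The 1-D solution then seeds a Newton polish of the full 5-D rate-balance
  system in concentration space, scaled by the seed concentrations so the
  Jacobian stays conditioned across many orders of magnitude.
* **Everything else** (bracket failures, overflow shadows) falls back to
  LSODA integration of the ODE system to quiescence.

Non-convergence is reported in-band (`converged=False`, never an
exception); the engines assign such genotypes the floor fitness 0. A chain
that cannot carry forward flux (e.g. a deleted enzyme, [E] = 0) reports
flux 0. Flux is reported as the net rate of reaction 5, which equals
k_use·[F] and, within tolerance, every other net rate; the brute-force ODE
integrator doubles as an independent oracle in the tests (agreement to
1e−6 relative on random genotypes, usually ~1e−15).

## Mutation model

Each of the 26 parameters mutates independently with probability 3×10⁻³
per individual per generation. Effects are *percent* changes δ ~
Normal(μ, 1) applied multiplicatively, with the multiplier floored at
1e−3 so no parameter can become non-positive. The percent scale is
anchored by the Haldane-constrained scheme, whose means are stated as
−1 %; the same scale is applied to all regimes.

* **Biological regime.** For enzyme concentration and the catalytic
  constants, μ₁(p) = −0.01·e^(c·p) percent with class-specific scaling
  index c (conc 2.5e−2, k_cat 1e−2, k_catr 3.33e−4). For the binding
  constants K_M (c = 1), K_Mr (3.33e−2) and K_I (2.5e−2), the reciprocal
  form μ₂(K) = 1/(−0.01·e^(c·K)), clamped to [−25, 0] percent: taken
  literally μ₂ → −100 % as K → 0, which destroys numerical stability and
  cannot be the intended behaviour, so only the direction and
  activity-dependence of the bias are treated as meaningful near that
  extreme. Note the bias makes K_M drift directionally downward under
  weak selection; the co-evolution analysis detrends group means for
  exactly this reason.
* **Neutral regime.** μ = 0 for every class, parameter-independent.
* **Haldane regime.** K_M, K_Mr and k_cat receive independent percent
  effects with mean −1; k_catr is then recomputed as
  k_cat·K_Mr/(Keq·K_M), preserving each reaction's equilibrium constant
  to machine precision over arbitrarily long mutation chains (tested over
  10³ mutations). The "modifier" coupling of k_cat to the mutated ratios
  is not specifiable unambiguously; the projection onto k_catr is the
  unique operation that satisfies every stated constraint, and is what we
  implement. Enzyme concentration and K_I are not constrained by the
  relationship; they keep mutating with the same −1 % mean (the simplest
  uniform reading of the modified scheme).

## Fitness

F₁ = 1/(1+e^(−0.07(J−650))). The printed form of this function elsewhere
(a 0.07 *exponent* on (flux−650)) is undefined for J < 650; the standard
logistic with midpoint 650 and slope 0.07 is the only form consistent with
the stated asymptote/slope and defined for all fluxes, and is what we use.
F₂ = e^(−9.4×10⁻⁴·[B]) penalises the toxic intermediate B (the
methylglyoxal analogue). F₃ = 1/(1 + 10⁻⁶(cost_protein + cost_mRNA)) with
cost_AA = 30.3 per residue, cost_nuc = 49.2 per nucleotide and per-enzyme
amino-acid lengths {A 450, B 390, C 350, D 510, E 330} — surrogate values
spanning a realistic glycolytic-enzyme range, chosen distinct so
length-dependent effects are testable; configurable. Schemes:
mutation_only (fitness ≡ 1), flux_only (F₁), flux_intermediate (F₁F₂),
flux_cost (F₁F₃), positive_control (F₁F₂ with the neutral mutation
regime). Non-converged steady states get fitness 0 under any selective
scheme.

## Engines

**Explicit Wright–Fisher.** N = 100 (configurable). Each generation:
mutate every individual, evaluate steady state and fitness, record the
median individual, then resample N offspring with replacement weighted by
fitness (uniformly under mutation_only). Mutating before selection lets a
mutation's fitness effect act in the generation it arises. The *median
individual* is the rank ⌊N/2⌋ member of the fitness ordering with ties
broken by stable population index — fitness rank is the only ordering the
model defines. Genotypes are immutable and copy-on-mutate, so steady-state
evaluations are cached per genotype object and the per-generation cost
scales with the ~N·26·3×10⁻³ ≈ 8 new genotypes rather than with N.

**Origin-fixation.** One mutation proposed per generation on a parameter
chosen uniformly (among the 26; among the free parameters in Haldane
mode), accepted with ψ = (1−e^(−2cNₑsp))/(1−e^(−2cNₑs)), c = 1 (haploid),
p = ½, s = f′/f₀ − 1. The s → 0 limit returns p analytically; deep tails
are computed in log space to avoid overflow. p = ½ means a neutral
proposal fixes with probability 0.5 (verified empirically in the tests).

**Determinism.** One master seed per experiment; replicate streams are
spawned with numpy's `SeedSequence`, recorded in the output sidecar.
Identical (config, seed) reproduce trajectories bit for bit.

## Analysis

* **Rate-limiting step**: scale one reaction's capacity by 0.9 and
  re-solve; sensitivity = flux drop; the argmax (ties → lowest index) is
  the rate-limiting reaction. Scaling enzyme concentration is the default
  because it multiplies the entire rate law by 0.9 — exactly a 10 % rate
  reduction at fixed metabolite concentrations; scaling (k_cat, k_catr)
  jointly is available as `method="catalytic"`.
* **Run lengths**: maximal constant runs per reaction; pooled proportions
  of generations spent rate limiting. The permutation test permutes
  reaction labels within each replicate (100,000 permutations at full
  scale) and compares the average absolute deviation of per-reaction mean
  run lengths from their overall mean; empirical p-values use the +1
  correction. CIs come from the nested bootstrap: resample replicates,
  then runs within each selected replicate; 2.5/97.5 percentiles.
* **Allele segregation**: distinct parameter values in the population
  (exact float identity — every mutation draws a continuous multiplier,
  so recurrent identical alleles have measure zero), sampled every 10
  generations over the post-equilibrium window, against n = 2Nₑμ+1.
* **Co-evolution**: per-generation first differences of the 15 retained
  parameters (concentrations, k_cat, K_M; reverse and inhibitory constants
  carry little signal and are excluded), detrended by subtracting each
  group's per-generation mean; complete-linkage clustering on 1 − |r|;
  cluster support = fraction of 10,000 bootstrap dendrograms (generation
  rows resampled within each replicate) containing the identical leaf
  set; maximal clusters with support ≥ 95 % are reported, everything else
  as unclustered. Dendrograms export as Newick text.

## Scales used in the shipped checks

The full published geometries (22,000 generations × 5 replicates explicit;
200,000 × 30 origin-fixation) are what the presets encode and take hours.
The shipped test suite and acceptance script run the same machinery at
reduced sizes chosen so mutation-selection-balance *properties*, not
absolute durations, are exercised: the positive control at N = 50 × 4,000
generations × 2 replicates; allele segregation on a 5,000-generation
flux-only run; the deleterious-intermediate ordering at N = 50 × 3,000 ×
2; and the Haldane origin-fixation run-length scale at 50,000 generations
× 5 replicates (the quantity `scripts/acceptance.py` reports). Statistical
calibration checks (permutation-p uniformity, bootstrap coverage, planted
cluster recovery) use synthetic data from `experiment_io`'s fixture
generators at reduced resampling counts.

## What the synthetic fixtures do and do not show

The fixture generators produce planted correlation blocks (latent-factor
construction with exact within-block correlation), geometric run-length
samples, and bottlenecked/broken genotypes. They validate the statistics
against known ground truth; they do not emulate the autocorrelation of
real evolutionary trajectories, so calibration results on them bound, but
do not guarantee, behaviour on trajectory data (the permutation test in
particular assumes exchangeability of reaction labels, which holds under
the null of no stability).

## Known limitations

* Linear chain only; no branches, cycles, duplication or network growth.
* Steady-state read-outs only; no transient dynamics enter fitness.
* The explicit engine's N = 100 reflects the computational budget of
  solving a kinetic system per individual per generation; scaling
  properties with N are only probed, not characterised.
* The μ₂ reciprocal mean is an interpretation stabilised by clamping;
  alternative readings of that functional form would change the
  directional drift of binding constants, though not the existence of
  mutation-selection balance.
* Mixed-effects slope comparisons across enzyme lengths (cost scheme) are
  out of scope; the per-replicate tidy tables those models need are what
  `ReplicateResult.frame()` emits.
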