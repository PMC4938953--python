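"""Generational loops: explicit Wright-Fisher sampling and origin-fixation.

Two population-genetic engines drive the same mutation and fitness
machinery:

* the **explicit** engine holds N individuals (default 100), mutates each
  parameter with the per-parameter rate, evaluates every individual's
  steady-state flux and fitness, and resamples the next generation with
  replacement, weighted by fitness (uniformly under ``mutation_only``);

* the **origin-fixation** engine removes the explicit population: one
  mutation is proposed per generation and fixed with the Kimura
  probability ``psi = (1 - exp(-2*c*Ne*s*p)) / (1 - exp(-2*c*Ne*s))``
  evaluated at initial frequency p = 1/2, so a neutral proposal fixes
  with probability one half.  The selection coefficient is
  ``s = f'/f0 - 1``.

Because populations are nearly clonal at the simulated mutation rate,
steady-state evaluations are cached on genotype objects (copy-on-mutate),
which keeps the per-generation cost proportional to the number of *new*
genotypes rather than to N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .fitness_models import FitnessConfig, fitness
from .mutation_models import HaldaneConfig, MutationConfig, apply_mutations, sample_effect
from .pathway_kinetics import Genotype, KineticEnvironment, SteadyState, solve_steady_state
from .pathway_analysis import identify_rate_limiting

__all__ = [
    "Population",
    "OriginFixationConfig",
    "GenerationRecord",
    "ExperimentConfig",
    "ReplicateResult",
    "DegeneratePopulationError",
    "evaluate",
    "wright_fisher_step",
    "median_individual",
    "kimura_fixation_prob",
    "origin_fixation_step",
    "run_experiment",
]


class DegeneratePopulationError(RuntimeError):
    """Raised when every individual has fitness 0 (nothing can reproduce)."""

    def __init__(self, generation: int, replicate: int | None = None):
        self.generation = generation
        self.replicate = replicate
        where = f"generation {generation}"
        if replicate is not None:
            where += f", replicate {replicate}"
        super().__init__(f"all individuals have zero fitness at {where}")


@dataclass
class Population:
    individuals: list  # list[Genotype]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass(frozen=True)
class OriginFixationConfig:
    """Settings of the Kimura origin-fixation approximation."""

    Ne: float = 1e6
    ploidy_c: float = 1.0
    p_init: float = 0.5
    generations: int = 200_000
    replicates: int = 30

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError(f"Ne must be >= 1, got {self.Ne}")
        if not (0 < self.p_init < 1):
            raise ValueError(f"p_init must lie in (0, 1), got {self.p_init}")


@dataclass
class GenerationRecord:
    """Per-generation snapshot of the evolving population (or lineage)."""

    generation: int
    median_genotype: Genotype
    median_flux: float
    median_fitness: float
    rate_limiting_reaction: int  # 1..5; 0 when the base state did not converge
    allele_counts: Optional[np.ndarray] = None  # per-parameter, explicit engine


@dataclass
class ExperimentConfig:
    """Full specification of one simulation experiment."""

    engine: str = "explicit"  # explicit | origin_fixation
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    mutation: MutationConfig = field(default_factory=MutationConfig)
    environment: KineticEnvironment = field(default_factory=KineticEnvironment)
    initial_genotype: Optional[Genotype] = None
    haldane: Optional[HaldaneConfig] = None
    population_size: int = 100
    origin_fixation: OriginFixationConfig = field(default_factory=OriginFixationConfig)
    total_generations: int = 22_000
    equilibrium_generation: int = 20_000
    replicates: int = 5
    seed: int = 0
    rls_perturbation: str = "enzyme_conc"  # see identify_rate_limiting

    def __post_init__(self) -> None:
        if self.engine not in ("explicit", "origin_fixation"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (0 <= self.equilibrium_generation < self.total_generations):
            raise ValueError("equilibrium_generation must precede total_generations")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ReplicateResult:
    """Trajectory of one replicate plus its resolved seed."""

    replicate: int
    seed_entropy: int
    records: list  # list[GenerationRecord]

    def frame(self) -> pd.DataFrame:
        """Tidy per-generation table (one row per generation)."""
        if not self.records:
            return pd.DataFrame()
        names = self.records[0].median_genotype.param_names()
        rows = []
        for r in self.records:
            row = {
                "generation": r.generation,
                "flux": r.median_flux,
                "fitness": r.median_fitness,
                "rate_limiting_reaction": r.rate_limiting_reaction,
            }
            row.update(zip(names, r.median_genotype.param_vector()))
            if r.allele_counts is not None:
                row.update({f"alleles_{n}": int(c)
                            for n, c in zip(names, r.allele_counts)})
            rows.append(row)
        return pd.DataFrame(rows)


# -- evaluation with per-genotype caching --------------------------------------


def evaluate(
    g: Genotype, env: KineticEnvironment, fcfg: FitnessConfig
) -> tuple[SteadyState, float]:
    """Steady state and fitness of a genotype, cached on the object."""
    hit = g._cache.get("eval")
    if hit is None:
        st = solve_steady_state(g, env)
        hit = (st, fitness(g, st, fcfg))
        g._cache["eval"] = hit
    return hit


def _rate_limiting(g: Genotype, env: KineticEnvironment, method: str) -> int:
    hit = g._cache.get("rls")
    if hit is None:
        hit = identify_rate_limiting(g, env, method=method)
        g._cache["rls"] = hit
    return hit


# -- explicit Wright-Fisher engine ---------------------------------------------


def median_individual(pop: Population, fitnesses: Sequence[float]) -> int:
    """Index of the median individual: rank floor(N/2) of the fitness
    ordering, ties broken by stable population index."""
    order = np.argsort(np.asarray(fitnesses), kind="stable")
    return int(order[len(order) // 2])


def wright_fisher_step(
    pop: Population,
    env: KineticEnvironment,
    fcfg: FitnessConfig,
    mcfg: MutationConfig,
    rng: np.random.Generator,
    haldane: HaldaneConfig | None = None,
    fitnesses: Sequence[float] | None = None,
) -> Population:
    """One generation: fitness-weighted resampling, then mutation.

    ``fitnesses`` may be supplied to avoid re-evaluating (they are cached on
    the genotypes anyway).  Under ``mutation_only`` sampling is uniform.
    """
    n = len(pop)
    if fitnesses is None:
        fitnesses = [evaluate(g, env, fcfg)[1] for g in pop.individuals]
    w = np.asarray(fitnesses, dtype=float)
    if fcfg.scheme == "mutation_only":
        idx = rng.integers(0, n, size=n)
    else:
        total = w.sum()
        if total <= 0:
            raise DegeneratePopulationError(pop.generation)
        idx = rng.choice(n, size=n, replace=True, p=w / total)
    offspring = [
        apply_mutations(pop.individuals[i], mcfg, rng, haldane=haldane) for i in idx
    ]
    return Population(offspring, pop.generation + 1)


def _allele_counts(pop: Population) -> np.ndarray:
    """Distinct-value count of each of the 26 parameters across the population.

    Allele identity is exact floating-point equality — every mutation draws
    a continuous multiplier, so identical values arising twice have measure
    zero.
    """
    vecs = np.vstack([g.param_vector() for g in pop.individuals])
    return np.array([len(set(vecs[:, j])) for j in range(vecs.shape[1])])


def _record_population(
    pop: Population,
    env: KineticEnvironment,
    fcfg: FitnessConfig,
    rls_method: str,
    track_alleles: bool = True,
) -> GenerationRecord:
    evals = [evaluate(g, env, fcfg) for g in pop.individuals]
    fits = [f for _, f in evals]
    mi = median_individual(pop, fits)
    g = pop.individuals[mi]
    st, f = evals[mi]
    rls = _rate_limiting(g, env, rls_method) if st.converged else 0
    return GenerationRecord(
        generation=pop.generation,
        median_genotype=g,
        median_flux=st.flux if st.converged else 0.0,
        median_fitness=f,
        rate_limiting_reaction=rls,
        allele_counts=_allele_counts(pop) if track_alleles else None,
    )


# -- origin-fixation engine ----------------------------------------------------


def kimura_fixation_prob(
    s: float, cfg: OriginFixationConfig = OriginFixationConfig()
) -> float:
    """Kimura fixation probability of an allele at frequency ``p_init``.

    Returns the analytic limit ``p_init`` as s -> 0 and handles the
    strongly selected tails without overflow.
    """
    if s <= -1:
        raise ValueError(f"selection coefficient must exceed -1, got {s}")
    a = 2.0 * cfg.ploidy_c * cfg.Ne * s
    p = cfg.p_init
    if abs(a) < 1e-9:
        return p
    if a < 0 and -a * p > 700.0:
        # deeply deleterious: psi ~ exp(a*(1-p)) underflows to 0 gracefully
        try:
            return math.exp(a * (1.0 - p))
        except OverflowError:
            return 0.0
    try:
        return math.expm1(-a * p) / math.expm1(-a)
    except OverflowError:
        return 1.0 if a > 0 else 0.0


def origin_fixation_step(
    g: Genotype,
    env: KineticEnvironment,
    fcfg: FitnessConfig,
    mcfg: MutationConfig,
    ofcfg: OriginFixationConfig,
    rng: np.random.Generator,
    haldane: HaldaneConfig | None = None,
) -> Genotype:
    """Propose one mutation, accept it with the Kimura fixation probability.

    The mutated parameter is chosen uniformly; in ``haldane`` mode k_catr is
    not a free parameter (it is recomputed from Haldane's relationship
    whenever k_cat, K_M or K_Mr of that enzyme changes).
    """
    items = g.param_items()
    if mcfg.mode == "haldane":
        items = [(i, f) for (i, f) in items if f != "k_catr"]
    enz_i, fname = items[rng.integers(0, len(items))]
    mult = sample_effect(mcfg, fname, getattr(g.enzymes[enz_i], fname), rng)
    mutant = g.with_param(enz_i, fname, getattr(g.enzymes[enz_i], fname) * mult)
    if mcfg.mode == "haldane" and fname in ("k_cat", "K_M", "K_Mr"):
        if haldane is None:
            raise ValueError("haldane mode requires a HaldaneConfig")
        e = mutant.enzymes[enz_i]
        keq = haldane.Keq_per_reaction[enz_i]
        mutant = mutant.with_enzyme(
            enz_i, e.evolve(k_catr=(e.k_cat * e.K_Mr) / (keq * e.K_M))
        )
    _, f0 = evaluate(g, env, fcfg)
    if f0 <= 0:
        raise DegeneratePopulationError(-1)
    _, f1 = evaluate(mutant, env, fcfg)
    s = f1 / f0 - 1.0
    if s <= -1:
        psi = 0.0
    else:
        psi = kimura_fixation_prob(s, ofcfg)
    return mutant if rng.random() < psi else g


# -- experiment driver ---------------------------------------------------------


def _replicate_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_experiment(
    cfg: ExperimentConfig,
    progress: Callable[[int, int, GenerationRecord], None] | None = None,
) -> list[ReplicateResult]:
    """Run all replicates of an experiment; deterministic given (cfg, seed).

    Every generation of every replicate is recorded.  Replicate seeds are
    spawned from the master seed with numpy's SeedSequence, so replicates
    are mutually independent and individually reproducible.
    """
    if cfg.initial_genotype is None:
        raise ValueError("ExperimentConfig.initial_genotype must be set")
    mcfg = cfg.mutation
    haldane = cfg.haldane
    if mcfg.mode == "haldane" and haldane is None:
        haldane = HaldaneConfig.from_genotype(cfg.initial_genotype)
    results = []
    for rep, ss in enumerate(_replicate_seeds(cfg.seed, cfg.replicates)):
        rng = np.random.default_rng(ss)
        records: list[GenerationRecord] = []
        try:
            if cfg.engine == "explicit":
                pop = Population([cfg.initial_genotype] * cfg.population_size, 0)
                for gen in range(cfg.total_generations + 1):
                    rec = _record_population(
                        pop, cfg.environment, cfg.fitness, cfg.rls_perturbation
                    )
                    records.append(rec)
                    if progress is not None:
                        progress(rep, gen, rec)
                    if gen == cfg.total_generations:
                        break
                    fits = [
                        evaluate(g, cfg.environment, cfg.fitness)[1]
                        for g in pop.individuals
                    ]
                    pop = wright_fisher_step(
                        pop, cfg.environment, cfg.fitness, mcfg, rng,
                        haldane=haldane, fitnesses=fits,
                    )
            else:
                g = cfg.initial_genotype
                total = cfg.origin_fixation.generations
                for gen in range(total + 1):
                    st, f = evaluate(g, cfg.environment, cfg.fitness)
                    rls = (
                        _rate_limiting(g, cfg.environment, cfg.rls_perturbation)
                        if st.converged else 0
                    )
                    rec = GenerationRecord(gen, g, st.flux if st.converged else 0.0,
                                           f, rls, None)
                    records.append(rec)
                    if progress is not None:
                        progress(rep, gen, rec)
                    if gen == total:
                        break
                    g = origin_fixation_step(
                        g, cfg.environment, cfg.fitness, mcfg,
                        cfg.origin_fixation, rng, haldane=haldane,
                    )
        except DegeneratePopulationError as err:
            raise DegeneratePopulationError(err.generation, rep) from err
        results.append(ReplicateResult(rep, ss.entropy, records))
    return results
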