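"""Fitness functions mapping pathway behaviour to reproductive success.

Five selection schemes are supported:

``mutation_only``
    No selection; fitness is 1 for every individual.
``flux_only``
    F1: a logistic function of steady-state flux,
    ``F1 = 1 / (1 + exp(-slope * (flux - mid)))`` with midpoint 650 and
    slope 0.07, reflecting a ceiling on utilisable flux.
``flux_intermediate``
    Fm = F1 * F2 with ``F2 = exp(-s * [B])`` penalising accumulation of the
    toxic intermediate B (a methylglyoxal-like metabolite), s = 9.4e-4.
``flux_cost``
    Fp = F1 * F3 with ``F3 = 1 / (1 + s * (cost_protein + cost_mRNA))``
    penalising the biosynthetic cost of enzyme expression; per-unit costs
    cost_AA = 30.3 (protein) and cost_nuc = 49.2 (mRNA), s = 1e-6.
``positive_control``
    Same composition as ``flux_intermediate`` (F1 * F2) but intended to be
    run with the *neutral* mutation regime, selecting the first reaction to
    stay rate limiting without mutational pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .pathway_kinetics import Genotype, SteadyState

__all__ = [
    "FitnessConfig",
    "SCHEMES",
    "fitness_flux",
    "fitness_intermediate",
    "fitness_cost",
    "fitness",
]

SCHEMES = (
    "mutation_only",
    "flux_only",
    "flux_intermediate",
    "flux_cost",
    "positive_control",
)

#: surrogate per-enzyme amino-acid lengths, spanning a glycolytic range
DEFAULT_LENGTHS = (450.0, 390.0, 350.0, 510.0, 330.0)


@dataclass(frozen=True)
class FitnessConfig:
    scheme: str = "flux_only"
    flux_mid: float = 650.0
    flux_slope: float = 0.07
    s_intermediate: float = 9.4e-4
    s_cost: float = 1.0e-6
    cost_AA: float = 30.3
    cost_nuc: float = 49.2
    lengths: Sequence[float] = field(default_factory=lambda: DEFAULT_LENGTHS)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        for name in ("flux_mid", "flux_slope", "s_intermediate", "s_cost",
                     "cost_AA", "cost_nuc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.lengths) != 5 or any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must hold exactly 5 positive entries")


def fitness_flux(flux: float, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Logistic flux-to-fitness map F1, strictly increasing in flux."""
    if flux < 0:
        raise ValueError(f"flux must be >= 0, got {flux}")
    z = -cfg.flux_slope * (flux - cfg.flux_mid)
    if z > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def fitness_intermediate(conc_B: float, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Toxic-intermediate penalty F2 = exp(-s*[B]), strictly decreasing."""
    if conc_B < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_B}")
    return math.exp(-cfg.s_intermediate * conc_B)


def fitness_cost(g: Genotype, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Expression-cost penalty F3 over protein and mRNA synthesis."""
    cost_protein = cfg.cost_AA * sum(
        e.enzyme_conc * L for e, L in zip(g.enzymes, cfg.lengths)
    )
    cost_mRNA = cfg.cost_nuc * sum(
        3.0 * L * e.enzyme_conc / 1000.0 for e, L in zip(g.enzymes, cfg.lengths)
    )
    return 1.0 / (1.0 + cfg.s_cost * (cost_protein + cost_mRNA))


def fitness(g: Genotype, st: SteadyState, cfg: FitnessConfig) -> float:
    """Dispatch the configured selection scheme; non-converged states get 0.

    Under ``mutation_only`` fitness is identically 1 (no selection acts, not
    even against a broken pathway).
    """
    if cfg.scheme == "mutation_only":
        return 1.0
    if not st.converged:
        return 0.0
    f1 = fitness_flux(max(st.flux, 0.0), cfg)
    if cfg.scheme == "flux_only":
        return f1
    if cfg.scheme in ("flux_intermediate", "positive_control"):
        return f1 * fitness_intermediate(st.concentration("B"), cfg)
    if cfg.scheme == "flux_cost":
        return f1 * fitness_cost(g, cfg)
    raise ValueError(f"unknown scheme {cfg.scheme!r}")
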