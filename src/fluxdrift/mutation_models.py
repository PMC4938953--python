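"""Mutational effect distributions acting on kinetic parameters.

Three regimes are supported:

``biological``
    Activity-dependent bias: the mean percent effect of a mutation becomes
    more negative as the current parameter value grows, so highly expressed
    or highly active enzymes predominantly receive degrading changes.  For
    concentration-like and catalytic parameters the mean is

        mu_1(p) = -0.01 * exp(c * p)        (percent)

    and for binding constants (K_M, K_Mr, K_I)

        mu_2(K) = 1 / (-0.01 * exp(c * K))  (percent, clamped to [-25, 0])

    with a per-class scaling index ``c``.  The clamp bounds the reciprocal
    form, which otherwise diverges to -100% as K -> 0; only the direction
    and activity-dependence of the bias are meaningful at that extreme.

``neutral``
    Mean-zero, parameter-independent effects (control regime).

``haldane``
    Thermodynamically constrained mutation: K_M, K_Mr and k_cat receive
    independent percent effects with mean -1, and k_catr is recomputed from
    Haldane's relationship Keq = (k_cat*K_Mr)/(k_catr*K_M) so the reaction's
    equilibrium constant is preserved exactly.

Effects are percent changes applied multiplicatively: a draw delta (in
percent) maps to a multiplier ``max(1 + delta/100, 1e-3)``; the floor keeps
every parameter strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pathway_kinetics import EnzymeParams, Genotype

__all__ = [
    "MutationConfig",
    "HaldaneConfig",
    "DEFAULT_C_TABLE",
    "effect_mean_biological",
    "effect_mean",
    "sample_effect",
    "apply_mutations",
    "mutate_haldane",
    "MULTIPLIER_FLOOR",
]

PARAM_CLASSES = ("enzyme_conc", "k_cat", "K_M", "k_catr", "K_Mr", "K_I")

#: scaling index c of the activity-dependent mean, per parameter class
DEFAULT_C_TABLE: dict[str, float] = {
    "enzyme_conc": 2.5e-2,
    "K_I": 2.5e-2,
    "k_cat": 1.0e-2,
    "k_catr": 3.33e-4,
    "K_M": 1.0,
    "K_Mr": 3.33e-2,
}

#: parameter classes whose biological mean follows mu_1 (activity-like)
MU1_CLASSES = frozenset({"enzyme_conc", "k_cat", "k_catr"})
#: binding constants, whose biological mean follows the clamped mu_2
MU2_CLASSES = frozenset({"K_M", "K_Mr", "K_I"})

#: clamp interval (percent) for the reciprocal binding-constant mean
MU2_CLAMP = (-25.0, 0.0)

#: smallest multiplier a single mutation may apply (keeps parameters > 0)
MULTIPLIER_FLOOR = 1e-3

MODES = ("biological", "neutral", "haldane")


@dataclass(frozen=True)
class MutationConfig:
    """Mutation process settings.

    ``per_param_rate`` is the probability that any one of the 26 kinetic
    parameters mutates in one individual in one generation; ``effect_sd``
    is the standard deviation (percent) of the effect distribution.
    """

    per_param_rate: float = 3e-3
    c_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_C_TABLE)
    )
    effect_sd: float = 1.0
    mode: str = "biological"

    def __post_init__(self) -> None:
        if not (0 <= self.per_param_rate < 1):
            raise ValueError(
                f"per_param_rate must lie in [0, 1), got {self.per_param_rate}"
            )
        if self.effect_sd <= 0:
            raise ValueError(f"effect_sd must be > 0, got {self.effect_sd}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        missing = set(PARAM_CLASSES) - set(self.c_table)
        if missing:
            raise ValueError(f"c_table missing parameter classes: {sorted(missing)}")
        if any(c <= 0 for c in self.c_table.values()):
            raise ValueError("all c_table values must be > 0")


@dataclass(frozen=True)
class HaldaneConfig:
    """Equilibrium constants per reaction plus the constrained-effect scale."""

    Keq_per_reaction: Sequence[float]
    haldane_mean: float = -1.0
    haldane_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.Keq_per_reaction) != 5:
            raise ValueError("Keq_per_reaction needs exactly 5 entries")
        if any(k <= 0 for k in self.Keq_per_reaction):
            raise ValueError("every Keq must be > 0")
        if self.haldane_sd <= 0:
            raise ValueError("haldane_sd must be > 0")

    @classmethod
    def from_genotype(cls, g: Genotype, **kw) -> "HaldaneConfig":
        return cls(tuple(e.keq for e in g.enzymes), **kw)


def effect_mean_biological(
    param_class: str, current_value: float, c_table: Mapping[str, float] | None = None
) -> float:
    """Mean percent effect of a mutation under the activity-dependent regime.

    Always <= 0 (degradation bias); its magnitude grows with the current
    value for mu_1 classes and is clamped to [-25, 0] for binding constants.
    """
    if param_class not in PARAM_CLASSES:
        raise ValueError(f"unknown parameter class {param_class!r}")
    if current_value <= 0:
        raise ValueError(f"current_value must be > 0, got {current_value}")
    c = (c_table or DEFAULT_C_TABLE)[param_class]
    if param_class in MU1_CLASSES:
        try:
            return -0.01 * math.exp(c * current_value)
        except OverflowError:
            return -math.inf  # floored later at the multiplier stage
    # binding constants: reciprocal form, clamped
    mean = 1.0 / (-0.01 * math.exp(c * current_value))
    return min(max(mean, MU2_CLAMP[0]), MU2_CLAMP[1])


def effect_mean(cfg: MutationConfig, param_class: str, current_value: float) -> float:
    """Mean percent effect under the configured mutation mode."""
    if cfg.mode == "neutral":
        if param_class not in PARAM_CLASSES:
            raise ValueError(f"unknown parameter class {param_class!r}")
        return 0.0
    if cfg.mode == "haldane":
        # conc and K_I are unconstrained by Haldane; they share the -1% mean
        return -1.0
    return effect_mean_biological(param_class, current_value, cfg.c_table)


def sample_effect(
    cfg: MutationConfig,
    param_class: str,
    current_value: float,
    rng: np.random.Generator,
) -> float:
    """Draw one mutational effect and return its (strictly positive) multiplier."""
    mean = effect_mean(cfg, param_class, current_value)
    delta = rng.normal(mean, cfg.effect_sd) if math.isfinite(mean) else -math.inf
    return max(1.0 + delta / 100.0, MULTIPLIER_FLOOR)


def apply_mutations(
    g: Genotype,
    cfg: MutationConfig,
    rng: np.random.Generator,
    haldane: HaldaneConfig | None = None,
) -> Genotype:
    """Mutate each of the 26 parameters independently with ``per_param_rate``.

    Returns the *same* object when nothing mutates (so evaluation caches on
    the genotype stay valid); otherwise a fresh genotype.  In ``haldane``
    mode, k_catr is never hit directly: whenever any of k_cat, K_M or K_Mr
    of an enzyme mutates, k_catr is recomputed to preserve that reaction's
    equilibrium constant.
    """
    items = g.param_items()
    if cfg.mode == "haldane":
        items = [(i, f) for (i, f) in items if f != "k_catr"]
    hits = np.flatnonzero(rng.random(len(items)) < cfg.per_param_rate)
    if hits.size == 0:
        return g
    enzymes = list(g.enzymes)
    haldane_touched: set[int] = set()
    for h in hits:
        enz_i, fname = items[h]
        mult = sample_effect(cfg, fname, getattr(enzymes[enz_i], fname), rng)
        enzymes[enz_i] = enzymes[enz_i].evolve(**{fname: getattr(enzymes[enz_i], fname) * mult})
        if cfg.mode == "haldane" and fname in ("k_cat", "K_M", "K_Mr"):
            haldane_touched.add(enz_i)
    if haldane_touched:
        if haldane is None:
            raise ValueError("haldane mode requires a HaldaneConfig")
        for enz_i in haldane_touched:
            e = enzymes[enz_i]
            keq = haldane.Keq_per_reaction[enz_i]
            enzymes[enz_i] = e.evolve(k_catr=(e.k_cat * e.K_Mr) / (keq * e.K_M))
    return Genotype(enzymes)


def mutate_haldane(
    e: EnzymeParams,
    hcfg: HaldaneConfig,
    rng: np.random.Generator,
    reaction_index: int = 0,
) -> EnzymeParams:
    """Jointly mutate K_M, K_Mr and k_cat, then restore k_catr from Keq.

    The input enzyme must already satisfy Haldane's relationship for the
    configured Keq of its reaction (to 1e-9 relative); the output satisfies
    it exactly by construction.
    """
    keq = hcfg.Keq_per_reaction[reaction_index]
    if abs(e.keq - keq) > 1e-9 * keq:
        raise ValueError(
            f"enzyme violates Haldane's relationship: Keq={e.keq!r}, expected {keq!r}"
        )
    changes = {}
    for fname in ("K_M", "K_Mr", "k_cat"):
        delta = rng.normal(hcfg.haldane_mean, hcfg.haldane_sd)
        mult = max(1.0 + delta / 100.0, MULTIPLIER_FLOOR)
        changes[fname] = getattr(e, fname) * mult
    k_catr = (changes["k_cat"] * changes["K_Mr"]) / (keq * changes["K_M"])
    return e.evolve(k_catr=k_catr, **changes)
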