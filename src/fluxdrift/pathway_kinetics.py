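"""Kinetic model of the five-reaction linear pathway and its steady state.

The pathway converts a boundary metabolite A through intermediates B, C, D
and E into a final product F (``A -> B -> C -> D -> E -> F``).  Each reaction
is catalysed by one enzyme and follows reversible Michaelis-Menten kinetics

    v = [E] * (k_cat*S/K_M - k_catr*P/K_Mr) / (1 + S/K_M + P/K_Mr + [I]/K_I)

where the inhibitor term is present only on the single feedback-inhibited
enzyme (by default the end product F inhibits the first enzyme, a
glycolysis-like regulatory loop).  [A] is clamped, and F is consumed by a
first-order mass-action sink with rate constant ``k_use``, so at steady
state the common chain flux J equals ``k_use * [F]``.

The steady-state solver exploits the chain structure: for a trial value of
[F] the flux is J = k_use*[F], and because each rate law is *linear* in its
substrate concentration at fixed product concentration, the required
substrate of every reaction can be back-substituted in closed form from the
bottom of the chain upwards.  The one remaining scalar residual — supply by
reaction 1 from the clamped [A] minus the demanded flux — is bracketed and
solved with Brent's method.  A brute-force ODE integration of the full
system is provided both as an independent cross-check and as a fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "EnzymeParams",
    "Genotype",
    "KineticEnvironment",
    "SteadyState",
    "reaction_rate",
    "solve_steady_state",
    "flux",
    "integrate_to_steady",
    "ode_rhs",
    "genotype_to_sbml",
]

ENZYME_NAMES = ("A", "B", "C", "D", "E")
METABOLITE_NAMES = ("A", "B", "C", "D", "E", "F")

#: kinetic fields of one enzyme, in canonical serialisation order
ENZYME_FIELDS = ("enzyme_conc", "k_cat", "K_M", "k_catr", "K_Mr")


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic parameters of one enzyme (all concentrations mmol/l, rates /s).

    ``K_I`` is present (not ``None``) only on the single inhibited enzyme of
    a genotype.  ``enzyme_conc`` may be exactly 0 to represent a deleted
    enzyme (a broken chain); the kinetic constants must be strictly positive.
    """

    enzyme_conc: float
    k_cat: float
    K_M: float
    k_catr: float
    K_Mr: float
    K_I: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.enzyme_conc) and self.enzyme_conc >= 0):
            raise ValueError(
                f"enzyme_conc must be finite and >= 0, got {self.enzyme_conc!r}"
            )
        for name in ENZYME_FIELDS[1:]:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.K_I is not None and not (math.isfinite(self.K_I) and self.K_I > 0):
            raise ValueError(f"K_I must be finite and > 0, got {self.K_I!r}")

    @property
    def keq(self) -> float:
        """Equilibrium constant implied by Haldane's relationship."""
        return (self.k_cat * self.K_Mr) / (self.k_catr * self.K_M)

    def evolve(self, **changes: float) -> "EnzymeParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


class Genotype:
    """Ordered kinetic parameters of the five enzymes — one heritable state.

    Genotypes are treated as immutable; mutation produces a fresh object.
    That convention lets the evolutionary engines cache steady-state and
    fitness evaluations on the object itself (the private ``_cache`` slot),
    so clonal individuals in a population share a single evaluation.
    """

    __slots__ = ("enzymes", "_cache")

    def __init__(self, enzymes: Sequence[EnzymeParams]):
        enzymes = tuple(enzymes)
        if len(enzymes) != 5:
            raise ValueError(f"a genotype has exactly 5 enzymes, got {len(enzymes)}")
        n_inhibited = sum(1 for e in enzymes if e.K_I is not None)
        if n_inhibited != 1:
            raise ValueError(
                f"exactly one enzyme must carry K_I, found {n_inhibited}"
            )
        self.enzymes = enzymes
        self._cache: dict = {}

    # -- parameter bookkeeping -------------------------------------------------

    @property
    def inhibited_index(self) -> int:
        """0-based index of the enzyme carrying the inhibition constant."""
        for i, e in enumerate(self.enzymes):
            if e.K_I is not None:
                return i
        raise AssertionError("unreachable: invariant enforced in __init__")

    def param_names(self) -> list[str]:
        """Names of the 26 mutable parameters, e.g. ``A_conc``, ``C_KMr``."""
        short = {"enzyme_conc": "conc", "k_cat": "kcat", "K_M": "KM",
                 "k_catr": "kcatr", "K_Mr": "KMr", "K_I": "KI"}
        names = []
        for enz_name, e in zip(ENZYME_NAMES, self.enzymes):
            for f in ENZYME_FIELDS:
                names.append(f"{enz_name}_{short[f]}")
            if e.K_I is not None:
                names.append(f"{enz_name}_KI")
        return names

    def param_items(self) -> list[tuple[int, str]]:
        """(enzyme index, field name) for each of the 26 mutable parameters."""
        items = []
        for i, e in enumerate(self.enzymes):
            for f in ENZYME_FIELDS:
                items.append((i, f))
            if e.K_I is not None:
                items.append((i, "K_I"))
        return items

    def param_vector(self) -> np.ndarray:
        """The 26 parameter values in ``param_names`` order."""
        vals = []
        for e in self.enzymes:
            vals.extend(getattr(e, f) for f in ENZYME_FIELDS)
            if e.K_I is not None:
                vals.append(e.K_I)
        return np.asarray(vals, dtype=float)

    def with_param(self, enzyme_index: int, field_name: str, value: float) -> "Genotype":
        """Return a new genotype with one parameter replaced."""
        enzymes = list(self.enzymes)
        enzymes[enzyme_index] = enzymes[enzyme_index].evolve(**{field_name: value})
        return Genotype(enzymes)

    def with_enzyme(self, enzyme_index: int, enzyme: EnzymeParams) -> "Genotype":
        enzymes = list(self.enzymes)
        enzymes[enzyme_index] = enzyme
        return Genotype(enzymes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and self.enzymes == other.enzymes

    def __hash__(self) -> int:
        return hash(self.enzymes)

    def __repr__(self) -> str:
        return f"Genotype({list(self.enzymes)!r})"


@dataclass(frozen=True)
class KineticEnvironment:
    """Boundary conditions and solver settings shared by all genotypes.

    ``conc_A`` is the clamped concentration of the pathway substrate;
    ``k_use`` the first-order rate constant consuming the end product F.
    The inhibitor species for the feedback loop is F by default
    (``inhibitor_species``); any internal metabolite may be configured.
    """

    conc_A: float = 5.0
    k_use: float = 1.0
    solver_tol: float = 1e-9
    max_time: float = 1e6
    inhibitor_species: str = "F"

    def __post_init__(self) -> None:
        if not (self.conc_A > 0 and self.k_use > 0 and self.solver_tol > 0):
            raise ValueError("conc_A, k_use and solver_tol must be > 0")
        if self.inhibitor_species not in METABOLITE_NAMES[1:]:
            raise ValueError(
                f"inhibitor_species must be one of {METABOLITE_NAMES[1:]}"
            )

    @property
    def inhibitor_index(self) -> int:
        """Index of the inhibitor in the full metabolite vector A..F."""
        return METABOLITE_NAMES.index(self.inhibitor_species)


@dataclass(frozen=True)
class SteadyState:
    """Steady-state metabolite concentrations (B..F) and pathway flux."""

    concentrations: tuple  # (B, C, D, E, F)
    flux: float
    converged: bool

    def concentration(self, species: str) -> float:
        return self.concentrations[METABOLITE_NAMES.index(species) - 1]


def reaction_rate(
    e: EnzymeParams,
    S: float,
    P: float,
    I: Optional[float] = None,
) -> float:
    """Net rate of one reversible Michaelis-Menten reaction (mmol/l/s).

    ``I`` is the inhibitor concentration and is only meaningful when the
    enzyme carries ``K_I``; it is ignored otherwise.
    """
    if not (math.isfinite(S) and S >= 0) or not (math.isfinite(P) and P >= 0):
        raise ValueError(f"concentrations must be finite and >= 0, got S={S}, P={P}")
    denom = 1.0 + S / e.K_M + P / e.K_Mr
    if e.K_I is not None and I is not None:
        if not (math.isfinite(I) and I >= 0):
            raise ValueError(f"inhibitor concentration must be finite and >= 0, got {I}")
        denom += I / e.K_I
    return e.enzyme_conc * (e.k_cat * S / e.K_M - e.k_catr * P / e.K_Mr) / denom


# -- steady-state solver -------------------------------------------------------


def _back_substitute(g: Genotype, env: KineticEnvironment, F: float):
    """Metabolite concentrations A..F consistent with flux J = k_use*F.

    Works from reaction 5 upwards: each rate law is linear in its substrate,
    so the substrate concentration required to carry J at the already-known
    product concentration has a closed form.  Returns ``None`` if no
    physical (non-negative, finite) solution exists at this flux.
    """
    J = env.k_use * F
    conc = [0.0] * 6  # A..F
    conc[0] = env.conc_A
    conc[5] = F
    inh_enzyme = g.inhibited_index
    inh_species = env.inhibitor_index
    # reactions 5..2 (enzymes index 4..1); reaction i: m[i-1] -> m[i]
    for i in range(4, 0, -1):
        e = g.enzymes[i]
        P = conc[i + 1]
        cap = e.enzyme_conc * e.k_cat
        if cap <= J:
            return None
        extra = 0.0
        if i == inh_enzyme and e.K_I is not None:
            # inhibitor of a non-first enzyme: only resolvable if the
            # inhibitor concentration is already known (downstream species)
            if inh_species <= i:
                return None  # upstream inhibitor: fall back to ODE solver
            extra = conc[inh_species] / e.K_I
        try:
            S = e.K_M * (J * (1.0 + P / e.K_Mr + extra)
                         + e.enzyme_conc * e.k_catr * P / e.K_Mr) / (cap - J)
        except OverflowError:
            return None
        if not math.isfinite(S):
            return None
        conc[i] = S
    return conc


def _supply_residual(g: Genotype, env: KineticEnvironment, F: float) -> float:
    """Rate of reaction 1 at the back-substituted state minus the demanded flux."""
    conc = _back_substitute(g, env, F)
    if conc is None:
        return -math.inf
    e0 = g.enzymes[0]
    I = conc[env.inhibitor_index] if (g.inhibited_index == 0 and e0.K_I is not None) else None
    try:
        v1 = reaction_rate(e0, conc[0], conc[1], I)
    except (ValueError, OverflowError):
        return -math.inf
    return v1 - env.k_use * F


def solve_steady_state(g: Genotype, env: KineticEnvironment) -> SteadyState:
    """Steady state of the pathway: d[X]/dt = 0 for X in B..F with [A] clamped.

    Never raises on a pathologically parameterised genotype: a chain that
    cannot carry flux reports ``flux=0``, and a state the solver cannot pin
    down is returned with ``converged=False`` so the caller (the
    evolutionary engine) can assign its floor fitness.
    """
    # flux ceiling from the forward capacity of reactions 2..5
    cap = min(e.enzyme_conc * e.k_cat for e in g.enzymes[1:])
    F_hi = cap / env.k_use * (1.0 - 1e-12)
    r0 = _supply_residual(g, env, 0.0)
    if r0 <= 0.0 or F_hi <= 0.0:
        # no forward supply at zero flux (dead or reversed chain): flux 0
        return SteadyState((0.0, 0.0, 0.0, 0.0, 0.0), 0.0, True)

    r_hi = _supply_residual(g, env, F_hi)
    if not (r_hi < 0.0):
        # capacity never binds within floating range; fall back to integration
        return integrate_to_steady(g, env)

    # shrink the bracket away from the -inf sentinel region so brentq sees
    # finite values at both ends
    lo, hi = 0.0, F_hi
    while not math.isfinite(_supply_residual(g, env, hi)):
        hi = lo + 0.5 * (hi - lo)
        if hi - lo < 1e-300:
            return integrate_to_steady(g, env)

    if _supply_residual(g, env, hi) > 0.0:
        # residual positive at the largest finite point: root lies in the
        # overflow shadow; hand over to the integrator
        return integrate_to_steady(g, env)

    try:
        F_star = brentq(
            lambda x: _supply_residual(g, env, x),
            lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200,
        )
    except (ValueError, RuntimeError):
        return integrate_to_steady(g, env)

    conc = _back_substitute(g, env, F_star)
    if conc is None:
        return integrate_to_steady(g, env)
    J = env.k_use * F_star
    resid = _supply_residual(g, env, F_star)
    if abs(resid) <= 5.0 * env.solver_tol:
        return SteadyState(tuple(conc[1:]), J, True)
    # ill-conditioned along F (deep bottleneck): polish the 5-D rate-balance
    # system directly in concentration space, seeded by the 1-D solution
    return _polish_5d(g, env, np.asarray(conc[1:]))


def _polish_5d(g: Genotype, env: KineticEnvironment, y0: np.ndarray) -> SteadyState:
    """Newton-polish the full 5-D rate-balance system from a seed state.

    Variables are scaled by the seed concentrations so the Jacobian stays
    well conditioned even when metabolite levels span many orders of
    magnitude.  Reports ``converged=False`` (never raises) when the
    residual cannot be brought under the solver tolerance.
    """
    from scipy.optimize import root as _root

    scale = np.where(y0 > 0, y0, 1.0)

    def fun(x: np.ndarray) -> np.ndarray:
        return ode_rhs(g, env, np.maximum(x, 0.0) * scale)

    best = np.maximum(y0, 0.0)
    sol = _root(fun, np.ones(5), method="hybr", options={"xtol": 1e-13})
    cand = np.maximum(sol.x, 0.0) * scale
    if np.max(np.abs(ode_rhs(g, env, cand))) < np.max(np.abs(ode_rhs(g, env, best))):
        best = cand
    e4 = g.enzymes[4]
    I = best[4] if (g.inhibited_index == 4 and env.inhibitor_index == 5) else None
    J = reaction_rate(e4, best[3], best[4], I)
    if J < 0:
        J = 0.0
    resid = float(np.max(np.abs(ode_rhs(g, env, best))))
    converged = resid <= env.solver_tol * max(1.0, J)
    return SteadyState(tuple(best), float(J), converged)


def flux(g: Genotype, env: KineticEnvironment) -> float:
    """Steady-state pathway flux; 0 when the solver did not converge."""
    st = solve_steady_state(g, env)
    return st.flux if st.converged else 0.0


# -- brute-force ODE path (oracle and fallback) --------------------------------


def ode_rhs(g: Genotype, env: KineticEnvironment, y: np.ndarray) -> np.ndarray:
    """Time derivatives of (B, C, D, E, F) for the full kinetic system."""
    conc = [env.conc_A, *np.maximum(y, 0.0)]
    inh = g.inhibited_index
    I = conc[env.inhibitor_index]
    v = [
        reaction_rate(e, conc[i], conc[i + 1], I if i == inh else None)
        for i, e in enumerate(g.enzymes)
    ]
    return np.array([
        v[0] - v[1],
        v[1] - v[2],
        v[2] - v[3],
        v[3] - v[4],
        v[4] - env.k_use * conc[5],
    ])


def integrate_to_steady(g: Genotype, env: KineticEnvironment) -> SteadyState:
    """Integrate the ODE system from an empty pathway until quiescence.

    Used as an independent oracle for the algebraic solver and as its
    fallback.  Convergence requires every |d[X]/dt| below ``solver_tol``
    within ``env.max_time``.
    """
    y0 = np.zeros(5)
    t_end = env.max_time
    sol = solve_ivp(
        lambda _t, y: ode_rhs(g, env, y),
        (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-12,
    )
    y = np.maximum(sol.y[:, -1], 0.0)
    rates = ode_rhs(g, env, y)
    converged = bool(sol.success and np.max(np.abs(rates)) < env.solver_tol)
    e4 = g.enzymes[4]
    I = y[4] if (g.inhibited_index == 4 and env.inhibitor_index == 5) else None
    J = reaction_rate(e4, y[3], y[4], I)
    if J < 0:
        J = 0.0
    return SteadyState(tuple(y), float(J), converged)


# -- serialisation -------------------------------------------------------------


def genotype_to_sbml(g: Genotype, env: KineticEnvironment) -> str:
    """Render the pathway as an SBML Level 3 document (one compartment,
    7 species including the F sink, 5 reversible reactions plus the
    mass-action utilisation of F).  Intended for cross-checking the model
    in any SBML-capable simulator."""
    from lxml import etree

    NS = "http://www.sbml.org/sbml/level3/version2/core"
    sbml = etree.Element("sbml", nsmap={None: NS}, level="3", version="2")
    model = etree.SubElement(sbml, "model", id="fluxdrift_pathway")
    comps = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(comps, "compartment", id="cell", constant="true", size="1")
    species = etree.SubElement(model, "listOfSpecies")
    init = {"A": env.conc_A}
    for name in METABOLITE_NAMES:
        etree.SubElement(
            species, "species", id=f"met_{name}", compartment="cell",
            initialConcentration=str(init.get(name, 0.0)),
            boundaryCondition="true" if name == "A" else "false",
            hasOnlySubstanceUnits="false", constant="false",
        )
    etree.SubElement(
        species, "species", id="met_sink", compartment="cell",
        initialConcentration="0", boundaryCondition="true",
        hasOnlySubstanceUnits="false", constant="false",
    )
    params = etree.SubElement(model, "listOfParameters")
    for enz_name, e in zip(ENZYME_NAMES, g.enzymes):
        fields = dict(zip(ENZYME_FIELDS, (e.enzyme_conc, e.k_cat, e.K_M, e.k_catr, e.K_Mr)))
        if e.K_I is not None:
            fields["K_I"] = e.K_I
        for f, v in fields.items():
            etree.SubElement(params, "parameter", id=f"{enz_name}_{f}",
                             value=str(v), constant="true")
    etree.SubElement(params, "parameter", id="k_use", value=str(env.k_use),
                     constant="true")
    reactions = etree.SubElement(model, "listOfReactions")
    for i, enz_name in enumerate(ENZYME_NAMES):
        rx = etree.SubElement(reactions, "reaction", id=f"reaction_{i + 1}",
                              reversible="true")
        sub = etree.SubElement(rx, "listOfReactants")
        etree.SubElement(sub, "speciesReference",
                         species=f"met_{METABOLITE_NAMES[i]}", stoichiometry="1",
                         constant="true")
        prod = etree.SubElement(rx, "listOfProducts")
        etree.SubElement(prod, "speciesReference",
                         species=f"met_{METABOLITE_NAMES[i + 1]}", stoichiometry="1",
                         constant="true")
    sink = etree.SubElement(reactions, "reaction", id="utilization_F",
                            reversible="false")
    sub = etree.SubElement(sink, "listOfReactants")
    etree.SubElement(sub, "speciesReference", species="met_F", stoichiometry="1",
                     constant="true")
    prod = etree.SubElement(sink, "listOfProducts")
    etree.SubElement(prod, "speciesReference", species="met_sink",
                     stoichiometry="1", constant="true")
    return etree.tostring(sbml, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
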