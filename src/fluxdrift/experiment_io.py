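"""Configuration, presets, fixtures and orchestration.

The canonical experiment description is a JSON document mirroring
:class:`~fluxdrift.evolution_engines.ExperimentConfig`; YAML is accepted
when PyYAML is importable and is converted on load.  Every run persists its
fully resolved configuration next to its outputs, so any trajectory can be
regenerated from its sidecar alone.

Presets reproduce the published experiment geometries: the five explicit
selection schemes at 22,000 generations x 5 replicates (population 100) and
the origin-fixation variants at 200,000 generations x 30 replicates.  The
initial kinetic values are this package's own surrogate parameterisation
(the same for every enzyme, flux just below the logistic midpoint so
selection pressure exists at generation 0); they are config-overridable.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evolution_engines import (
    ExperimentConfig,
    OriginFixationConfig,
    ReplicateResult,
)
from .fitness_models import FitnessConfig
from .mutation_models import HaldaneConfig, MutationConfig
from .pathway_kinetics import ENZYME_FIELDS, EnzymeParams, Genotype, KineticEnvironment
from . import pathway_analysis as pa

__all__ = [
    "PRESETS",
    "ConfigError",
    "default_genotype",
    "preset_config",
    "scale_config",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "genotype_to_flat",
    "genotype_from_flat",
    "write_trajectories",
    "read_trajectories",
    "summarize_experiment",
    "write_report",
]


class ConfigError(ValueError):
    """A configuration document failed validation."""


# -- initial genotype ----------------------------------------------------------

#: surrogate initial kinetic values shared by all five enzymes
DEFAULT_ENZYME = dict(enzyme_conc=5.0, k_cat=300.0, K_M=2.0, k_catr=3.0, K_Mr=20.0)
DEFAULT_K_I = 250.0


def default_genotype(inhibited: int = 0) -> Genotype:
    """The homogeneous starting genotype: identical enzymes, end-product F
    feedback-inhibiting reaction 1 (glycolysis-like wiring).  Its initial
    steady-state flux sits in the rising region just below the fitness
    midpoint of 650, so selection pressure exists at generation 0."""
    enzymes = [
        EnzymeParams(**DEFAULT_ENZYME, K_I=DEFAULT_K_I if i == inhibited else None)
        for i in range(5)
    ]
    return Genotype(enzymes)


# -- genotype <-> flat row -----------------------------------------------------


def genotype_to_flat(g: Genotype) -> dict:
    """Flatten a genotype to 26 named scalars (A_conc, A_kcat, ...)."""
    return dict(zip(g.param_names(), g.param_vector()))


def genotype_from_flat(d: dict) -> Genotype:
    short = {"conc": "enzyme_conc", "kcat": "k_cat", "KM": "K_M",
             "kcatr": "k_catr", "KMr": "K_Mr", "KI": "K_I"}
    enzymes = []
    for enz in ("A", "B", "C", "D", "E"):
        kw = {}
        for suffix, fname in short.items():
            key = f"{enz}_{suffix}"
            if key in d:
                kw[fname] = float(d[key])
        missing = set(ENZYME_FIELDS) - set(kw)
        if missing:
            raise ConfigError(f"enzyme {enz} missing fields {sorted(missing)}")
        enzymes.append(EnzymeParams(**kw))
    return Genotype(enzymes)


# -- config (de)serialisation --------------------------------------------------


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = {
        "engine": cfg.engine,
        "fitness": dataclasses.asdict(cfg.fitness),
        "mutation": dataclasses.asdict(cfg.mutation),
        "environment": dataclasses.asdict(cfg.environment),
        "initial_genotype": genotype_to_flat(
            cfg.initial_genotype if cfg.initial_genotype is not None
            else default_genotype()
        ),
        "population_size": cfg.population_size,
        "origin_fixation": dataclasses.asdict(cfg.origin_fixation),
        "total_generations": cfg.total_generations,
        "equilibrium_generation": cfg.equilibrium_generation,
        "replicates": cfg.replicates,
        "seed": cfg.seed,
        "rls_perturbation": cfg.rls_perturbation,
    }
    d["fitness"]["lengths"] = list(cfg.fitness.lengths)
    if cfg.haldane is not None:
        d["haldane"] = {
            "Keq_per_reaction": list(cfg.haldane.Keq_per_reaction),
            "haldane_mean": cfg.haldane.haldane_mean,
            "haldane_sd": cfg.haldane.haldane_sd,
        }
    return d


def _build(cls, d: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**d)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid {where}: {err}") from err


def config_from_dict(doc: dict) -> ExperimentConfig:
    """Resolve a configuration document, rejecting unknown keys."""
    doc = dict(doc)
    top_allowed = {
        "engine", "fitness", "mutation", "environment", "initial_genotype",
        "haldane", "population_size", "origin_fixation", "total_generations",
        "equilibrium_generation", "replicates", "seed", "rls_perturbation",
        "preset",
    }
    unknown = set(doc) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "preset" in doc:
        base = config_to_dict(preset_config(doc.pop("preset")))
        base.update(doc)
        doc = base
    fitness_d = dict(doc.get("fitness", {}))
    if "lengths" in fitness_d:
        fitness_d["lengths"] = tuple(fitness_d["lengths"])
    kw = dict(
        engine=doc.get("engine", "explicit"),
        fitness=_build(FitnessConfig, fitness_d, "fitness"),
        mutation=_build(MutationConfig, dict(doc.get("mutation", {})), "mutation"),
        environment=_build(
            KineticEnvironment, dict(doc.get("environment", {})), "environment"
        ),
        population_size=doc.get("population_size", 100),
        origin_fixation=_build(
            OriginFixationConfig, dict(doc.get("origin_fixation", {})),
            "origin_fixation",
        ),
        total_generations=doc.get("total_generations", 22_000),
        equilibrium_generation=doc.get("equilibrium_generation", 20_000),
        replicates=doc.get("replicates", 5),
        seed=doc.get("seed", 0),
        rls_perturbation=doc.get("rls_perturbation", "enzyme_conc"),
    )
    if "initial_genotype" in doc:
        kw["initial_genotype"] = genotype_from_flat(doc["initial_genotype"])
    else:
        kw["initial_genotype"] = default_genotype()
    if "haldane" in doc and doc["haldane"] is not None:
        h = dict(doc["haldane"])
        if "Keq_per_reaction" in h:
            h["Keq_per_reaction"] = tuple(h["Keq_per_reaction"])
        kw["haldane"] = _build(HaldaneConfig, h, "haldane")
    try:
        return ExperimentConfig(**kw)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def load_config(path_or_preset: str | Path) -> ExperimentConfig:
    """Load a JSON (or YAML) experiment config, or resolve a preset name."""
    if isinstance(path_or_preset, str) and path_or_preset in PRESETS:
        return preset_config(path_or_preset)
    path = Path(path_or_preset)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml  # optional dependency

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return config_from_dict(doc)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2) + "\n")


# -- presets -------------------------------------------------------------------


def _explicit(scheme: str, mode: str = "biological") -> ExperimentConfig:
    return ExperimentConfig(
        engine="explicit",
        fitness=FitnessConfig(scheme=scheme),
        mutation=MutationConfig(mode=mode),
        initial_genotype=default_genotype(),
        population_size=100,
        total_generations=22_000,
        equilibrium_generation=20_000,
        replicates=5,
    )


def _origin_fixation(Ne: float, mode: str = "biological") -> ExperimentConfig:
    g = default_genotype()
    cfg = ExperimentConfig(
        engine="origin_fixation",
        fitness=FitnessConfig(scheme="flux_only"),
        mutation=MutationConfig(mode=mode),
        initial_genotype=g,
        origin_fixation=OriginFixationConfig(
            Ne=Ne, generations=200_000, replicates=30
        ),
        total_generations=200_000,
        equilibrium_generation=20_000,
        replicates=30,
        haldane=HaldaneConfig.from_genotype(g) if mode == "haldane" else None,
    )
    return cfg


PRESETS = (
    "mutation_only",
    "flux_only",
    "flux_intermediate",
    "flux_cost",
    "positive_control",
    "origin_fixation_small",
    "origin_fixation_large",
    "haldane",
)


def preset_config(name: str) -> ExperimentConfig:
    """A fully resolved configuration for one of the named experiments."""
    if name == "mutation_only":
        return _explicit("mutation_only")
    if name == "flux_only":
        return _explicit("flux_only")
    if name == "flux_intermediate":
        return _explicit("flux_intermediate")
    if name == "flux_cost":
        return _explicit("flux_cost")
    if name == "positive_control":
        return _explicit("positive_control", mode="neutral")
    if name == "origin_fixation_small":
        return _origin_fixation(1e2)
    if name == "origin_fixation_large":
        return _origin_fixation(1e6)
    if name == "haldane":
        return _origin_fixation(1e6, mode="haldane")
    raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")


def scale_config(cfg: ExperimentConfig, scale: float) -> ExperimentConfig:
    """Divide run length and replicate count by ``scale``, keeping every
    rate constant fixed.  Mutation-selection-balance properties, not
    absolute durations, are the test surface of scaled runs."""
    if scale <= 0:
        raise ConfigError("scale must be > 0")
    total = max(2, int(cfg.total_generations / scale))
    return dataclasses.replace(
        cfg,
        total_generations=total,
        equilibrium_generation=min(cfg.equilibrium_generation, total // 2),
        replicates=max(1, int(math.ceil(cfg.replicates / scale))),
        origin_fixation=dataclasses.replace(
            cfg.origin_fixation,
            generations=max(2, int(cfg.origin_fixation.generations / scale)),
            replicates=max(1, int(math.ceil(cfg.origin_fixation.replicates / scale))),
        ),
    )


# -- trajectory files ----------------------------------------------------------


def write_trajectories(
    results: Sequence[ReplicateResult],
    outdir: str | Path,
    cfg: ExperimentConfig,
    compress: bool = True,
) -> list[Path]:
    """One TSV per replicate plus a JSON sidecar with the resolved config
    and the spawned replicate seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for res in results:
        suffix = ".tsv.gz" if compress else ".tsv"
        path = outdir / f"trajectory_rep{res.replicate:02d}{suffix}"
        res.frame().to_csv(path, sep="\t", index=False)
        paths.append(path)
    sidecar = {
        "config": config_to_dict(cfg),
        "replicate_seeds": {r.replicate: r.seed_entropy for r in results},
    }
    (outdir / "config.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return paths


def read_trajectories(outdir: str | Path) -> tuple[list[pd.DataFrame], dict]:
    """Load all replicate trajectory tables and the config sidecar."""
    outdir = Path(outdir)
    frames = []
    for path in sorted(outdir.glob("trajectory_rep*.tsv*")):
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            frames.append(pd.read_csv(fh, sep="\t", float_precision="round_trip"))
    if not frames:
        raise FileNotFoundError(f"no trajectory_rep*.tsv[.gz] files in {outdir}")
    sidecar_path = outdir / "config.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return frames, sidecar


# -- fixtures ------------------------------------------------------------------


def bottleneck_genotype(reaction: int = 2, factor: float = 0.01) -> Genotype:
    """Default genotype with one enzyme's concentration deeply reduced, so
    the planted reaction is unambiguously rate limiting."""
    g = default_genotype()
    i = reaction - 1
    return g.with_enzyme(
        i, g.enzymes[i].evolve(enzyme_conc=g.enzymes[i].enzyme_conc * factor)
    )


def broken_chain_genotype(reaction: int = 3) -> Genotype:
    """Default genotype with one enzyme deleted (concentration 0)."""
    g = default_genotype()
    return g.with_enzyme(reaction - 1, g.enzymes[reaction - 1].evolve(enzyme_conc=0.0))


def planted_block_rates(
    n_gen: int,
    blocks: Sequence[Sequence[str]],
    within_r: float = 0.9,
    rng: np.random.Generator | None = None,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic detrended-rate matrix with a planted correlation-block
    structure: parameters within a block share a latent factor giving
    pairwise correlation ``within_r``; blocks are mutually independent."""
    rng = rng or np.random.default_rng()
    cols = [p for b in blocks for p in b]
    rows_per_rep = n_gen
    data = np.empty((rows_per_rep * n_replicates, len(cols)))
    rep_ids = np.repeat(np.arange(n_replicates), rows_per_rep)
    a = math.sqrt(within_r)
    b = math.sqrt(1.0 - within_r)
    j = 0
    for block in blocks:
        factor = rng.standard_normal(data.shape[0])
        for _ in block:
            data[:, j] = a * factor + b * rng.standard_normal(data.shape[0])
            j += 1
    return pd.DataFrame(data, columns=cols), rep_ids


def known_runlength_series() -> tuple[list, dict]:
    """A hand-enumerable rate-limiting series and its expected summary."""
    series = [1, 1, 2, 2, 2, 1]
    expected = {
        "runs": {1: [2, 1], 2: [3], 3: [], 4: [], 5: []},
        "means": {1: 1.5, 2: 3.0},
        "proportions": {1: 0.5, 2: 0.5, 3: 0.0, 4: 0.0, 5: 0.0},
    }
    return series, expected


def geometric_runs(
    mean_length: float,
    n_runs: int,
    rng: np.random.Generator,
) -> list:
    """Geometric run lengths (support >= 1) with the requested mean."""
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1")
    p = 1.0 / mean_length
    return list(rng.geometric(p, size=n_runs))


def make_fixture(name: str, seed: int = 0, **kw):
    """Dispatch deterministic toy inputs for the analysis layer."""
    rng = np.random.default_rng(seed)
    if name == "default_genotype":
        return default_genotype(**kw)
    if name == "bottleneck":
        return bottleneck_genotype(**kw)
    if name == "broken_chain":
        return broken_chain_genotype(**kw)
    if name == "planted_blocks":
        return planted_block_rates(rng=rng, **kw)
    if name == "runlength_series":
        return known_runlength_series()
    if name == "geometric_runs":
        return geometric_runs(rng=rng, **kw)
    raise ConfigError(f"unknown fixture {name!r}")


# -- experiment summary --------------------------------------------------------


def _post_equilibrium(frame: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    return frame[frame["generation"] > cfg.equilibrium_generation]


def summarize_experiment(
    frames: Sequence[pd.DataFrame],
    cfg: ExperimentConfig,
    n_perm: int = 100_000,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    cluster: bool = True,
) -> dict:
    """Combined report over completed replicate trajectories.

    Covers the post-equilibrium window: run-length means with permutation
    p-value and bootstrap CIs, the proportion-of-generations table, the
    allele-segregation summary (explicit engine), an equilibrium diagnostic
    (sign balance of median-fitness changes), and the co-evolution cluster
    report.  Deterministic given the rng state.
    """
    rng = rng or np.random.default_rng()
    post = [_post_equilibrium(f, cfg) for f in frames]
    if any(len(p) < 2 for p in post):
        raise ValueError("a replicate has no post-equilibrium window")
    series_list = [p["rate_limiting_reaction"].astype(int).tolist() for p in post]
    rl = pa.summarize_run_lengths(series_list, n_perm=n_perm, n_boot=n_boot, rng=rng)

    report: dict = {
        "scheme": cfg.fitness.scheme,
        "engine": cfg.engine,
        "no_selection": cfg.fitness.scheme == "mutation_only",
        "replicates": len(frames),
        "run_lengths": {
            "means": rl.means,
            "mean_run_length": rl.mean_run_length,
            "permutation_p": rl.permutation_p,
            "ci": rl.ci,
        },
        "proportions": rl.proportions,
    }

    # equilibrium diagnostic: sign balance of median-fitness changes
    balance = {}
    for rep, p in enumerate(post):
        d = np.diff(p["fitness"].to_numpy())
        nz = d[d != 0]
        balance[rep] = float((nz > 0).mean()) if nz.size else float("nan")
    report["fitness_sign_balance"] = balance

    allele_cols = [c for c in frames[0].columns if c.startswith("alleles_")]
    if allele_cols:
        counts = pd.concat([p[allele_cols] for p in post], ignore_index=True)
        seg = pa.allele_segregation(
            counts, Ne=cfg.population_size, mu=cfg.mutation.per_param_rate
        )
        report["allele_segregation"] = {
            "mean": seg.mean, "sd": seg.sd, "min": seg.min, "max": seg.max,
            "forward_mean": seg.forward_mean, "forward_sd": seg.forward_sd,
            "forward_min": seg.forward_min, "forward_max": seg.forward_max,
            "expected_neutral": seg.expected_neutral,
        }

    if cluster:
        rates, rep_ids = pa.coevolution_rates(post)
        cl = pa.coevolution_clusters(
            rates, rep_ids, n_boot=n_boot, alpha=alpha, rng=rng
        )
        report["coevolution"] = {
            "clusters": cl.clusters,
            "support": {",".join(sorted(k)): v for k, v in cl.support.items()
                        if len(k) >= 2},
            "unclustered": cl.unclustered,
            "newick": cl.newick,
            "alpha": alpha,
        }
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Persist a summary as TSV/JSON/Newick files (runlengths.tsv,
    proportions.tsv, alleles.tsv, clusters.json, dendrogram.nwk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = report["run_lengths"]
    rows = []
    for r in pa.REACTIONS:
        ci = (rl["ci"] or {}).get(r)
        rows.append({
            "reaction": r,
            "mean_run_length": rl["means"].get(r),
            "ci_lo": ci[0] if ci else float("nan"),
            "ci_hi": ci[1] if ci else float("nan"),
            "permutation_p": rl["permutation_p"],
        })
    pd.DataFrame(rows).to_csv(outdir / "runlengths.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"reaction": r, "proportion": report["proportions"][r]}
         for r in pa.REACTIONS]
    ).to_csv(outdir / "proportions.tsv", sep="\t", index=False)
    if "allele_segregation" in report:
        pd.DataFrame([report["allele_segregation"]]).to_csv(
            outdir / "alleles.tsv", sep="\t", index=False
        )
    if "coevolution" in report:
        co = report["coevolution"]
        (outdir / "clusters.json").write_text(json.dumps(
            {k: co[k] for k in ("clusters", "support", "unclustered", "alpha")},
            indent=2,
        ) + "\n")
        (outdir / "dendrogram.nwk").write_text(co["newick"] + "\n")
    scalar = {k: v for k, v in report.items()
              if k in ("scheme", "engine", "no_selection", "replicates",
                       "fitness_sign_balance")}
    scalar["mean_run_length"] = rl["mean_run_length"]
    (outdir / "summary.json").write_text(json.dumps(scalar, indent=2) + "\n")
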