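"""Post-simulation statistics for pathway-evolution trajectories.

This module quantifies the paper-level questions about a finished run:

* which reaction is rate limiting (flux controlling) at a generation, via a
  10% finite perturbation of each reaction's capacity;
* how long each reaction *stays* rate limiting (run lengths), with a
  permutation test of the null that all reactions share the same average
  run length and nested bootstrap confidence intervals;
* how much allelic variation segregates per parameter, against the neutral
  Kimura-Crow expectation n = 2*Ne*mu + 1;
* which parameters co-evolve, via complete-linkage clustering of absolute
  correlations between detrended per-generation rates of change, with
  bootstrap cluster support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .pathway_kinetics import Genotype, KineticEnvironment, solve_steady_state

__all__ = [
    "identify_rate_limiting",
    "rate_limiting_sensitivities",
    "run_lengths",
    "RunLengthSummary",
    "permutation_test",
    "bootstrap_ci",
    "expected_allele_number",
    "allele_segregation",
    "AlleleSegregationSummary",
    "coevolution_rates",
    "coevolution_clusters",
    "CoevolutionResult",
    "linkage_to_newick",
    "summarize_run_lengths",
]

REACTIONS = (1, 2, 3, 4, 5)

#: parameter classes retained in the co-evolution analysis (reverse and
#: inhibitory constants have minimal impact on the system and are dropped)
COEVOLUTION_CLASSES = ("conc", "kcat", "KM")


# -- rate-limiting step --------------------------------------------------------


def rate_limiting_sensitivities(
    g: Genotype,
    env: KineticEnvironment,
    method: str = "enzyme_conc",
    factor: float = 0.9,
) -> Optional[np.ndarray]:
    """Flux drop caused by scaling each reaction's capacity by ``factor``.

    ``method`` selects how a reaction is slowed: ``"enzyme_conc"`` scales
    the enzyme concentration (multiplies the whole rate law, hence exactly
    a 10% rate reduction at fixed metabolite concentrations);
    ``"catalytic"`` scales k_cat and k_catr together instead.
    Returns ``None`` when the unperturbed genotype does not converge.
    """
    if method not in ("enzyme_conc", "catalytic"):
        raise ValueError(f"unknown perturbation method {method!r}")
    base = solve_steady_state(g, env)
    if not base.converged:
        return None
    sens = np.empty(5)
    for i, e in enumerate(g.enzymes):
        if method == "enzyme_conc":
            perturbed = g.with_enzyme(i, e.evolve(enzyme_conc=e.enzyme_conc * factor))
        else:
            perturbed = g.with_enzyme(
                i, e.evolve(k_cat=e.k_cat * factor, k_catr=e.k_catr * factor)
            )
        st = solve_steady_state(perturbed, env)
        sens[i] = base.flux - (st.flux if st.converged else 0.0)
    return sens


def identify_rate_limiting(
    g: Genotype,
    env: KineticEnvironment,
    method: str = "enzyme_conc",
    factor: float = 0.9,
) -> int:
    """The 1-based index of the most flux-controlling reaction.

    The reaction whose 10% slowdown causes the largest flux drop; ties are
    broken by the lowest reaction index.  Returns 0 when the unperturbed
    genotype does not converge (flagged record).
    """
    sens = rate_limiting_sensitivities(g, env, method=method, factor=factor)
    if sens is None:
        return 0
    return int(np.argmax(sens)) + 1


# -- run lengths ---------------------------------------------------------------


@dataclass
class RunLengthSummary:
    """Per-reaction run lengths of the rate-limiting step."""

    runs: dict  # reaction -> list[int], pooled across replicates
    runs_by_replicate: list  # list[dict[reaction, list[int]]]
    means: dict  # reaction -> mean run length (NaN if never limiting)
    proportions: dict  # reaction -> share of generations spent limiting
    permutation_p: Optional[float] = None
    ci: Optional[dict] = None  # reaction -> (lo, hi) or None

    @property
    def mean_run_length(self) -> float:
        """Grand mean over all runs of all reactions."""
        pooled = [x for lengths in self.runs.values() for x in lengths]
        return float(np.mean(pooled)) if pooled else float("nan")


def _extract_runs(series: Sequence[int]) -> dict:
    runs: dict = {r: [] for r in REACTIONS}
    current, length = None, 0
    for x in series:
        if x == current:
            length += 1
        else:
            if current in runs:
                runs[current].append(length)
            current, length = x, 1
    if current in runs:
        runs[current].append(length)
    return runs


def run_lengths(series: Sequence[int]) -> RunLengthSummary:
    """Maximal constant runs of the rate-limiting reaction index.

    ``series`` holds per-generation indices in 1..5 (0 marks flagged
    generations whose steady state did not converge; they break runs and
    are excluded from the proportion denominator).
    """
    series = list(series)
    if not series:
        raise ValueError("series must be non-empty")
    runs = _extract_runs(series)
    valid = sum(1 for x in series if x in REACTIONS)
    means = {
        r: (float(np.mean(v)) if v else float("nan")) for r, v in runs.items()
    }
    proportions = {
        r: (sum(v) / valid if valid else float("nan")) for r, v in runs.items()
    }
    return RunLengthSummary(
        runs=runs, runs_by_replicate=[runs], means=means, proportions=proportions
    )


def permutation_test(
    mean_matrix: np.ndarray,
    n_perm: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the null of equal average run lengths.

    ``mean_matrix`` is (replicates x 5): the mean run length of each
    reaction within each replicate (NaN where a reaction never became rate
    limiting).  The observed statistic is the average absolute deviation of
    the per-reaction means (averaged across replicates) from their overall
    mean; the null is built by permuting the reaction labels independently
    within each replicate.  Uses the standard +1-corrected empirical
    p-value, so the result is never exactly 0.
    """
    rng = rng or np.random.default_rng()
    m = np.asarray(mean_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 5:
        raise ValueError("mean_matrix must have shape (replicates, 5)")
    if np.all(np.isnan(m)):
        raise ValueError("mean_matrix holds no data")

    def stat(mat: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pooled = np.nanmean(mat, axis=-2)  # (..., 5)
        overall = np.nanmean(pooled, axis=-1, keepdims=True)
        return np.nanmean(np.abs(pooled - overall), axis=-1)

    observed = float(stat(m))
    n_rep = m.shape[0]
    # vectorised label permutations within each replicate
    perms = np.argsort(rng.random((n_perm, n_rep, 5)), axis=-1)
    null = stat(np.take_along_axis(np.broadcast_to(m, perms.shape), perms, axis=-1))
    exceed = int(np.sum(null >= observed))
    return (1 + exceed) / (1 + n_perm)


def bootstrap_ci(
    runs_by_replicate: Sequence[dict],
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    percentiles: tuple = (2.5, 97.5),
) -> dict:
    """Nested bootstrap CI of each reaction's mean run length.

    Replicates are resampled with replacement first, then the consecutive
    runs within each selected replicate; the interval is the (2.5, 97.5)
    percentile pair of the resulting distribution of means.  A reaction
    that never became rate limiting in any replicate maps to ``None``.
    """
    rng = rng or np.random.default_rng()
    n_rep = len(runs_by_replicate)
    if n_rep == 0:
        raise ValueError("need at least one replicate")
    out: dict = {}
    for r in REACTIONS:
        per_rep = [np.asarray(d.get(r, []), dtype=float) for d in runs_by_replicate]
        if all(a.size == 0 for a in per_rep):
            out[r] = None
            continue
        boot_means = np.full(n_boot, np.nan)
        rep_draws = rng.integers(0, n_rep, size=(n_boot, n_rep))
        for b in range(n_boot):
            pooled_sum = 0.0
            pooled_n = 0
            for ri in rep_draws[b]:
                a = per_rep[ri]
                if a.size:
                    pooled_sum += a[rng.integers(0, a.size, size=a.size)].sum()
                    pooled_n += a.size
            if pooled_n:
                boot_means[b] = pooled_sum / pooled_n
        good = boot_means[~np.isnan(boot_means)]
        out[r] = tuple(np.percentile(good, percentiles)) if good.size else None
    return out


def summarize_run_lengths(
    series_list: Sequence[Sequence[int]],
    n_perm: int = 100_000,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> RunLengthSummary:
    """Full run-length summary over replicate series: pooled runs and
    proportions, permutation p-value and nested bootstrap CIs."""
    rng = rng or np.random.default_rng()
    per_rep = [run_lengths(s) for s in series_list]
    pooled = {r: [x for s in per_rep for x in s.runs[r]] for r in REACTIONS}
    valid = sum(
        1 for s in series_list for x in s if x in REACTIONS
    )
    means = {r: (float(np.mean(v)) if v else float("nan")) for r, v in pooled.items()}
    proportions = {r: sum(v) / valid for r, v in pooled.items()}
    mean_matrix = np.array([[s.means[r] for r in REACTIONS] for s in per_rep])
    p = permutation_test(mean_matrix, n_perm=n_perm, rng=rng)
    runs_by_rep = [s.runs for s in per_rep]
    ci = bootstrap_ci(runs_by_rep, n_boot=n_boot, rng=rng)
    return RunLengthSummary(
        runs=pooled, runs_by_replicate=runs_by_rep, means=means,
        proportions=proportions, permutation_p=p, ci=ci,
    )


# -- allele segregation --------------------------------------------------------


def expected_allele_number(Ne: float, mu: float) -> float:
    """Kimura-Crow expected number of segregating alleles per neutral locus."""
    return 2.0 * Ne * mu + 1.0


@dataclass
class AlleleSegregationSummary:
    per_param_mean: pd.Series  # mean allele count per parameter over snapshots
    mean: float  # across all parameters
    sd: float
    min: float
    max: float
    forward_mean: float  # across forward-only parameters (conc, kcat, KM)
    forward_sd: float
    forward_min: float
    forward_max: float
    expected_neutral: float


def _is_forward_param(name: str) -> bool:
    return name.rsplit("_", 1)[-1] in COEVOLUTION_CLASSES


def allele_segregation(
    counts: pd.DataFrame,
    Ne: float,
    mu: float,
    every: int = 10,
) -> AlleleSegregationSummary:
    """Summarise distinct-allele counts against the neutral expectation.

    ``counts`` has one row per recorded generation and one column per
    parameter (``alleles_<param>`` column names are accepted and
    stripped).  Rows are thinned to every ``every``-th generation before
    summarising, matching a sampling cadence of one snapshot per 10
    generations.
    """
    counts = counts.rename(columns=lambda c: c.removeprefix("alleles_"))
    thinned = counts.iloc[::every]
    per_param = thinned.mean(axis=0)
    fwd = per_param[[c for c in per_param.index if _is_forward_param(c)]]
    return AlleleSegregationSummary(
        per_param_mean=per_param,
        mean=float(per_param.mean()),
        sd=float(per_param.std(ddof=1)),
        min=float(per_param.min()),
        max=float(per_param.max()),
        forward_mean=float(fwd.mean()),
        forward_sd=float(fwd.std(ddof=1)),
        forward_min=float(fwd.min()),
        forward_max=float(fwd.max()),
        expected_neutral=expected_allele_number(Ne, mu),
    )


# -- co-evolution --------------------------------------------------------------


def coevolution_rates(
    frames: Sequence[pd.DataFrame],
    relative: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Detrended per-generation rates of change of the retained parameters.

    Only enzyme concentrations, catalytic constants and substrate binding
    constants are retained (15 parameters); reverse and inhibitory
    constants are excluded.  The rate is the per-generation first
    difference of the median-individual value (``relative=True`` divides by
    the previous value).  To control for directional change, the
    per-generation mean of each parameter group {conc, kcat, KM} is
    subtracted within the group.  Returns the stacked rate matrix (rows =
    generations of all replicates) and the replicate id of each row.
    """
    if not frames:
        raise ValueError("need at least one replicate frame")
    blocks, rep_ids = [], []
    for rep, f in enumerate(frames):
        cols = [c for c in f.columns if _is_forward_param(c)
                and not c.startswith("alleles_")]
        if len(cols) != 15:
            raise ValueError(f"expected 15 retained parameters, found {len(cols)}")
        vals = f[cols].to_numpy(dtype=float)
        if vals.shape[0] < 2:
            raise ValueError("each replicate needs at least 2 generations")
        rates = np.diff(vals, axis=0)
        if relative:
            rates = rates / vals[:-1]
        block = pd.DataFrame(rates, columns=cols)
        for cls in COEVOLUTION_CLASSES:
            grp = [c for c in cols if c.endswith("_" + cls)]
            block[grp] = block[grp].sub(block[grp].mean(axis=1), axis=0)
        blocks.append(block)
        rep_ids.extend([rep] * len(block))
    return pd.concat(blocks, ignore_index=True), np.asarray(rep_ids)


@dataclass
class CoevolutionResult:
    parameters: list  # retained parameter names (zero-variance ones dropped)
    correlation: pd.DataFrame  # absolute-correlation matrix
    linkage: np.ndarray  # scipy complete-linkage matrix on 1 - |r|
    clusters: list  # maximal significant clusters, each a sorted list of names
    support: dict  # frozenset(names) -> bootstrap support in [0, 1]
    unclustered: list  # parameters outside every significant cluster
    alpha: float
    newick: str = ""


def _clades(Z: np.ndarray, names: Sequence[str]) -> set:
    """Leaf sets of all internal nodes except the root (trivial) clade."""
    n = len(names)
    members: dict[int, frozenset] = {i: frozenset([names[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _h, _c) in enumerate(Z):
        m = members[int(a)] | members[int(b)]
        members[n + k] = m
        if len(m) < n:
            out.add(m)
    return out


def linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{names[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"


def coevolution_clusters(
    rates: pd.DataFrame,
    replicate_ids: np.ndarray,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> CoevolutionResult:
    """Complete-linkage clustering of parameters by absolute correlation.

    Distance is ``1 - |r|`` between detrended rate series.  Cluster support
    is the fraction of ``n_boot`` bootstrap dendrograms (generation rows
    resampled with replacement within each replicate) that contain the
    identical leaf set; clusters with support >= 1 - alpha are significant,
    and the maximal ones are reported.  Parameters in no significant
    cluster are reported as unclustered.
    """
    rng = rng or np.random.default_rng()
    X = rates.to_numpy(dtype=float)
    names = list(rates.columns)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance parameters: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if len(names) < 3:
        raise ValueError("need at least 3 parameters with variance")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 generations of rates")

    def tree_of(mat: np.ndarray):
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - np.abs(corr)
        dist = (dist + dist.T) / 2.0
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="complete")
        return corr, Z

    corr, Z = tree_of(X)
    observed = _clades(Z, names)

    rep_rows = {r: np.flatnonzero(replicate_ids == r) for r in np.unique(replicate_ids)}
    counts = {c: 0 for c in observed}
    for _ in range(n_boot):
        rows = np.concatenate([
            idx[rng.integers(0, idx.size, size=idx.size)] for idx in rep_rows.values()
        ])
        _, Zb = tree_of(X[rows])
        boot_clades = _clades(Zb, names)
        for c in observed:
            if c in boot_clades:
                counts[c] += 1

    support = {c: counts[c] / n_boot for c in observed}
    significant = {c for c, s in support.items() if s >= 1.0 - alpha and len(c) >= 2}
    maximal = [
        c for c in significant
        if not any(c < other for other in significant)
    ]
    clustered = set().union(*maximal) if maximal else set()
    return CoevolutionResult(
        parameters=names,
        correlation=pd.DataFrame(np.abs(corr), index=names, columns=names),
        linkage=Z,
        clusters=[sorted(c) for c in sorted(maximal, key=lambda c: (-len(c), sorted(c)))],
        support=support,
        unclustered=sorted(set(names) - clustered),
        alpha=alpha,
        newick=linkage_to_newick(Z, names),
    )
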