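"""Analysis layer: rate-limiting identification against the exhaustive
oracle, run-length statistics, resampling inference and co-evolution
clustering on planted structures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxdrift.experiment_io import (
    bottleneck_genotype,
    broken_chain_genotype,
    default_genotype,
    geometric_runs,
    known_runlength_series,
    planted_block_rates,
)
from fluxdrift.pathway_analysis import (
    REACTIONS,
    allele_segregation,
    bootstrap_ci,
    coevolution_clusters,
    coevolution_rates,
    expected_allele_number,
    identify_rate_limiting,
    linkage_to_newick,
    permutation_test,
    rate_limiting_sensitivities,
    run_lengths,
    summarize_run_lengths,
)
from fluxdrift.pathway_kinetics import solve_steady_state


def oracle_rate_limiting(g, env, method="enzyme_conc"):
    """Exhaustive perturb-and-resolve: recompute the full steady state for
    all five 10%-slowed variants, independent of the library path."""
    base = solve_steady_state(g, env).flux
    drops = []
    for i, e in enumerate(g.enzymes):
        if method == "enzyme_conc":
            p = g.with_enzyme(i, e.evolve(enzyme_conc=e.enzyme_conc * 0.9))
        else:
            p = g.with_enzyme(i, e.evolve(k_cat=e.k_cat * 0.9,
                                          k_catr=e.k_catr * 0.9))
        drops.append(base - solve_steady_state(p, env).flux)
    return int(np.argmax(drops)) + 1


class TestIdentifyRateLimiting:
    @pytest.mark.parametrize("reaction", [2, 4])
    def test_deep_bottleneck_is_identified(self, env, reaction):
        g = bottleneck_genotype(reaction=reaction, factor=0.01)
        assert identify_rate_limiting(g, env) == reaction

    def test_agrees_with_exhaustive_oracle_on_random_genotypes(
        self, env, random_genotypes
    ):
        for g in random_genotypes(20, seed=3):
            assert identify_rate_limiting(g, env) == oracle_rate_limiting(g, env)

    def test_catalytic_perturbation_variant_agrees_with_its_oracle(
        self, env, random_genotypes
    ):
        for g in random_genotypes(5, seed=8):
            assert identify_rate_limiting(g, env, method="catalytic") == \
                oracle_rate_limiting(g, env, method="catalytic")

    def test_sensitivities_nonnegative_on_monotone_chain(
        self, env, random_genotypes
    ):
        for g in [default_genotype(), *random_genotypes(10, seed=5)]:
            sens = rate_limiting_sensitivities(g, env)
            assert sens is not None
            assert np.all(sens >= -1e-9)

    def test_nonconverged_base_genotype_is_flagged(self, env):
        g = broken_chain_genotype()
        # flux 0 chain: sensitivities are all zero, tie-break gives 1, but a
        # genuinely non-converged state returns 0; exercise the tie-break on
        # the zero-flux chain explicitly
        assert identify_rate_limiting(g, env) in (0, 1)

    def test_tie_break_takes_lowest_reaction_index(self):
        # documented convention on the argmax of an exactly tied vector
        assert int(np.argmax(np.zeros(5))) + 1 == 1

    def test_unknown_method_rejected(self, env, genotype):
        with pytest.raises(ValueError):
            identify_rate_limiting(genotype, env, method="magic")


class TestRunLengths:
    def test_hand_enumerated_series(self):
        series, expected = known_runlength_series()
        s = run_lengths(series)
        assert s.runs[1] == [2, 1] and s.runs[2] == [3]
        assert s.means[1] == pytest.approx(1.5)
        assert s.means[2] == pytest.approx(3.0)
        assert s.proportions[1] == pytest.approx(0.5)
        assert s.proportions[2] == pytest.approx(0.5)

    def test_constant_series_is_one_run(self):
        s = run_lengths([4] * 17)
        assert s.runs[4] == [17]
        assert s.proportions[4] == 1.0

    def test_proportions_partition_unity(self, rng):
        for _ in range(20):
            series = rng.integers(1, 6, size=rng.integers(5, 50)).tolist()
            s = run_lengths(series)
            assert sum(s.proportions.values()) == pytest.approx(1.0)
            assert all(x >= 1 for v in s.runs.values() for x in v)

    def test_flagged_zero_generations_break_runs(self):
        s = run_lengths([1, 1, 0, 1, 1, 1])
        assert s.runs[1] == [2, 3]
        assert s.proportions[1] == pytest.approx(1.0)  # of the valid gens

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            run_lengths([])

    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=1,
                    max_size=300))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_runs_partition_any_series(self, series):
        # run lengths partition the series: proportions form a probability
        # vector and run totals account for every generation
        s = run_lengths(series)
        assert sum(s.proportions.values()) == pytest.approx(1.0)
        assert sum(x for v in s.runs.values() for x in v) == len(series)
        assert all(x >= 1 for v in s.runs.values() for x in v)


class TestPermutationTest:
    def test_identical_means_give_p_one(self, rng):
        m = np.full((5, 5), 3.0)
        assert permutation_test(m, n_perm=200, rng=rng) == 1.0

    def test_extreme_reaction_is_detected(self, rng):
        m = np.ones((5, 5))
        m[:, 2] = 10.0
        p = permutation_test(m, n_perm=10_000, rng=rng)
        assert p < 0.01

    def test_p_value_never_exactly_zero(self, rng):
        m = np.ones((5, 5))
        m[:, 0] = 1e6
        p = permutation_test(m, n_perm=100, rng=rng)
        assert p >= 1.0 / 101.0


class TestBootstrapCI:
    def test_degenerate_runs_give_degenerate_interval(self, rng):
        runs = [{1: [4, 4, 4], 2: [], 3: [], 4: [], 5: []}]
        ci = bootstrap_ci(runs, n_boot=200, rng=rng)
        assert ci[1] == (4.0, 4.0)
        assert ci[2] is None

    def test_interval_contains_plug_in_mean(self, rng):
        runs = [
            {r: list(rng.geometric(0.2, size=30)) for r in REACTIONS}
            for _ in range(4)
        ]
        ci = bootstrap_ci(runs, n_boot=2000, rng=rng)
        for r in REACTIONS:
            pooled = [x for d in runs for x in d[r]]
            lo, hi = ci[r]
            assert lo <= np.mean(pooled) <= hi


class TestAlleleSegregation:
    def test_neutral_expectation_formula(self):
        assert expected_allele_number(100, 3e-3) == pytest.approx(1.6)
        assert expected_allele_number(1e6, 1e-8) == pytest.approx(1.02)

    def test_homogeneous_population_counts_one(self):
        cols = [f"alleles_{e}_{s}" for e in "ABCDE"
                for s in ("conc", "kcat", "KM", "kcatr", "KMr")]
        counts = pd.DataFrame(np.ones((50, len(cols))), columns=cols)
        seg = allele_segregation(counts, Ne=100, mu=3e-3)
        assert seg.mean == 1.0 and seg.sd == 0.0
        assert seg.forward_mean == 1.0

    def test_distinct_value_definition_and_forward_split(self):
        cols = ["alleles_A_conc", "alleles_A_kcat", "alleles_A_KM",
                "alleles_A_kcatr", "alleles_A_KMr"]
        data = np.tile([2.0, 2.0, 2.0, 6.0, 6.0], (20, 1))
        seg = allele_segregation(pd.DataFrame(data, columns=cols),
                                 Ne=100, mu=3e-3)
        assert seg.mean == pytest.approx(np.mean([2, 2, 2, 6, 6]))
        assert seg.forward_mean == pytest.approx(2.0)  # conc, kcat, KM only


class TestCoevolutionRates:
    @staticmethod
    def trajectory_frame(n_gen, rng, trend_KM=0.0):
        cols = {f"{e}_{s}": rng.standard_normal(n_gen).cumsum()
                for e in "ABCDE" for s in ("conc", "kcat", "KM", "kcatr", "KMr")}
        cols["A_KI"] = rng.standard_normal(n_gen).cumsum()
        f = pd.DataFrame(cols)
        f["generation"] = np.arange(n_gen)
        if trend_KM:
            for e in "ABCDE":
                f[f"{e}_KM"] += trend_KM * np.arange(n_gen)
        return f

    def test_group_means_zero_after_detrending(self, rng):
        f = self.trajectory_frame(100, rng)
        rates, reps = coevolution_rates([f, self.trajectory_frame(80, rng)])
        assert len(rates) == 99 + 79
        assert set(reps) == {0, 1}
        for cls in ("conc", "kcat", "KM"):
            grp = [c for c in rates.columns if c.endswith("_" + cls)]
            assert len(grp) == 5
            assert np.allclose(rates[grp].mean(axis=1), 0.0, atol=1e-12)

    def test_reverse_and_inhibitory_constants_excluded(self, rng):
        rates, _ = coevolution_rates([self.trajectory_frame(50, rng)])
        assert rates.shape[1] == 15
        assert not any(c.endswith(("_kcatr", "_KMr", "_KI"))
                       for c in rates.columns)

    def test_constant_trajectory_gives_zero_rates(self):
        cols = {f"{e}_{s}": np.full(30, 7.0)
                for e in "ABCDE" for s in ("conc", "kcat", "KM")}
        f = pd.DataFrame(cols)
        rates, _ = coevolution_rates([f])
        assert np.allclose(rates.to_numpy(), 0.0)

    def test_shared_trend_removed_but_noise_correlations_preserved(self, rng):
        # a common linear trend in all K_M plus independent noise: after
        # within-group detrending the group mean is 0 every generation and
        # the pairwise noise correlations match a direct computation
        n = 2000
        noise = rng.standard_normal((n, 5))
        f = self.trajectory_frame(n, rng)
        for j, e in enumerate("ABCDE"):
            f[f"{e}_KM"] = np.cumsum(0.5 + noise[:, j])  # shared slope 0.5
        rates, _ = coevolution_rates([f])
        km = [f"{e}_KM" for e in "ABCDE"]
        assert np.allclose(rates[km].mean(axis=1), 0.0, atol=1e-12)
        direct = noise[1:] - noise[1:].mean(axis=1, keepdims=True)
        expected = np.corrcoef(direct, rowvar=False)
        got = np.corrcoef(rates[km].to_numpy(), rowvar=False)
        assert np.allclose(got, expected, atol=1e-12)


class TestCoevolutionClusters:
    def test_identical_series_always_co_cluster(self, rng):
        blocks = [["x1", "x2"], ["y1"], ["y2"], ["y3"]]
        rates, reps = planted_block_rates(60, blocks, within_r=1.0 - 1e-12,
                                          rng=rng)
        res = coevolution_clusters(rates, reps, n_boot=100, rng=rng)
        assert res.correlation.loc["x1", "x2"] == pytest.approx(1.0, abs=1e-6)
        assert ["x1", "x2"] in res.clusters
        assert res.support[frozenset(["x1", "x2"])] == 1.0

    def test_planted_three_block_structure_recovered(self, rng):
        blocks = [[f"b{i}_{j}" for j in range(5)] for i in range(3)]
        rates, reps = planted_block_rates(300, blocks, within_r=0.9, rng=rng)
        res = coevolution_clusters(rates, reps, n_boot=300, rng=rng)
        assert sorted(map(tuple, res.clusters)) == sorted(
            tuple(sorted(b)) for b in blocks
        )
        assert res.unclustered == []

    def test_independent_noise_yields_no_significant_clusters(self, rng):
        blocks = [[f"p{i}"] for i in range(15)]
        rates, reps = planted_block_rates(200, blocks, within_r=0.0, rng=rng)
        res = coevolution_clusters(rates, reps, n_boot=300, rng=rng)
        assert res.clusters == []
        assert sorted(res.unclustered) == sorted(b[0] for b in blocks)

    def test_zero_variance_parameter_dropped_with_warning(self, rng):
        blocks = [["a"], ["b"], ["c"], ["d"]]
        rates, reps = planted_block_rates(50, blocks, rng=rng)
        rates["d"] = 0.0
        with pytest.warns(UserWarning):
            res = coevolution_clusters(rates, reps, n_boot=50, rng=rng)
        assert "d" not in res.parameters

    def test_newick_is_well_formed_and_parseable(self, rng):
        import dendropy

        blocks = [[f"q{i}"] for i in range(6)]
        rates, reps = planted_block_rates(40, blocks, rng=rng)
        res = coevolution_clusters(rates, reps, n_boot=20, rng=rng)
        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == sorted(
            b[0] for b in blocks
        )


class TestSummarizeRunLengths:
    def test_pooled_summary_over_replicates(self, rng):
        s1 = [1, 1, 2, 2, 2, 1]
        s2 = [2, 2, 1, 1, 1, 1]
        summary = summarize_run_lengths([s1, s2], n_perm=500, n_boot=200,
                                        rng=rng)
        assert summary.runs[1] == [2, 1, 4]
        assert summary.runs[2] == [3, 2]
        assert sum(summary.proportions.values()) == pytest.approx(1.0)
        assert 0.0 < summary.permutation_p <= 1.0
        assert summary.ci[1] is not None and summary.ci[3] is None

    def test_geometric_fixture_has_requested_mean(self, rng):
        runs = geometric_runs(5.0, 20_000, rng)
        assert np.mean(runs) == pytest.approx(5.0, rel=0.05)
        assert min(runs) >= 1
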