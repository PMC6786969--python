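"""Linear birth-death model: transitions, likelihood, estimation, simulation."""

import math

import numpy as np
import pytest

from fernwgd.bd import (
    BDParams, GeneCountMatrix, RootPrior, estimate_rates, family_loglik,
    matrix_loglik, root_spanning_probability, sample_root_count,
    simulate_gene_tree, simulate_null, transition_matrix, transition_prob,
)
from fernwgd.simulate import fern_species_tree, sim_gene_counts
from fernwgd.trees import parse_newick

import pandas as pd


class TestTransitionProb:
    def test_zero_time_is_identity(self):
        p = BDParams(0.1, 0.2)
        assert transition_prob(3, 3, 0.0, p) == 1.0
        assert transition_prob(3, 5, 0.0, p) == 0.0

    def test_extinction_is_absorbing(self):
        p = BDParams(0.5, 0.5)
        assert transition_prob(0, 0, 7.0, p) == 1.0
        assert transition_prob(0, 2, 7.0, p) == 0.0

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(-1, 0, 1.0, BDParams(0.1, 0.1))
        with pytest.raises(ValueError):
            transition_prob(1, 0, -1.0, BDParams(0.1, 0.1))

    def test_matches_event_driven_simulation(self, rng):
        """Closed form vs 1e5 exact Gillespie runs, n=1, lambda=0.1,
        mu=0.05, t=10: each end state m <= 10 within 3 Monte-Carlo SEs."""
        lam, mu, t, n_sim = 0.1, 0.05, 10.0, 100_000
        counts = np.zeros(50, dtype=int)
        for _ in range(n_sim):
            cur, now = 1, 0.0
            while cur > 0:
                rate = cur * (lam + mu)
                wait = rng.exponential(1.0 / rate)
                if now + wait > t:
                    break
                now += wait
                cur += 1 if rng.random() < lam / (lam + mu) else -1
            if cur < len(counts):
                counts[cur] += 1
        p = BDParams(lam, mu)
        for m in range(11):
            emp = counts[m] / n_sim
            theo = transition_prob(1, m, t, p)
            se = math.sqrt(max(theo * (1 - theo), 1e-12) / n_sim)
            assert abs(emp - theo) <= 3 * se + 1e-9

    @pytest.mark.parametrize("lam,mu,t", [
        (0.1, 0.05, 10.0), (0.05, 0.05, 20.0), (0.0, 0.1, 5.0),
        (0.1, 0.0, 5.0), (0.0031, 0.0039, 100.0),
    ])
    def test_truncated_rows_sum_to_one_minus_small_deficit(self, lam, mu, t):
        T = transition_matrix(t, BDParams(lam, mu), 100)
        deficits = 1.0 - T.sum(axis=1)
        assert deficits.min() > -1e-12
        assert deficits[:20].max() < 1e-8  # rows used by the data

    def test_equal_rates_special_case_matches_neighbour(self):
        near = transition_prob(2, 3, 4.0, BDParams(0.1, 0.1 + 1e-9))
        exact = transition_prob(2, 3, 4.0, BDParams(0.1, 0.1))
        assert near == pytest.approx(exact, rel=1e-5)


TWO_TAXON = parse_newick("(A:5,B:7);")


def _enumeration_loglik(counts, params, prior, m_max, condition):
    """Brute-force likelihood for the 2-taxon tree by summing root states,
    built only from scalar transition probabilities."""
    tA, tB = 5.0, 7.0
    num = sum(
        prior.pmf(s)
        * transition_prob(s, counts["A"], tA, params)
        * transition_prob(s, counts["B"], tB, params)
        for s in range(1, m_max + 1)
    )
    if condition == "none":
        return math.log(num)
    span = sum(
        prior.pmf(s)
        * (1 - transition_prob(s, 0, tA, params))
        * (1 - transition_prob(s, 0, tB, params))
        for s in range(1, 400)  # effectively untruncated for mean 1.5
    )
    return math.log(num) - math.log(span)


class TestFamilyLoglik:
    def test_frozen_process_returns_log_prior_mass(self):
        """With lambda = mu = 0 the count never changes, so the likelihood
        of equal observed counts k is exactly the prior mass at k."""
        prior = RootPrior(1.5)
        for k in (1, 2, 5):
            ll = family_loglik({"A": k, "B": k}, TWO_TAXON, BDParams(0, 0),
                               prior, condition="none", m_max=10)
            assert ll == pytest.approx(math.log(prior.pmf(k)), rel=1e-12)

    def test_conditioning_never_decreases_loglik(self):
        params = BDParams(0.02, 0.03)
        prior = RootPrior(1.5)
        for counts in ({"A": 1, "B": 1}, {"A": 2, "B": 1}, {"A": 3, "B": 2}):
            plain = family_loglik(counts, TWO_TAXON, params, prior, "none")
            cond = family_loglik(counts, TWO_TAXON, params, prior, "root_spanning")
            assert cond >= plain

    @pytest.mark.parametrize("counts", [
        {"A": 0, "B": 1}, {"A": 1, "B": 1}, {"A": 2, "B": 3}, {"A": 3, "B": 0},
    ])
    @pytest.mark.parametrize("condition", ["none", "root_spanning"])
    def test_matches_exhaustive_state_enumeration(self, counts, condition):
        params = BDParams(0.04, 0.06)
        prior = RootPrior(1.5)
        if condition == "root_spanning" and (counts["A"] == 0 or counts["B"] == 0):
            with pytest.raises(ValueError):
                family_loglik(counts, TWO_TAXON, params, prior, condition, m_max=3)
            return
        ll = family_loglik(counts, TWO_TAXON, params, prior, condition, m_max=3)
        oracle = _enumeration_loglik(counts, params, prior, 3, condition)
        assert ll == pytest.approx(oracle, rel=1e-9)

    def test_invariant_under_taxon_reordering(self, fern_tree):
        params = BDParams(0.0031, 0.0039)
        prior = RootPrior(1.5)
        mat, _ = sim_gene_counts(fern_tree, params, prior, 50, seed=3)
        ll1 = matrix_loglik(mat, fern_tree, params, prior, "none")
        shuffled = GeneCountMatrix(
            mat.counts[list(reversed(mat.counts.columns))], mat.m_max)
        ll2 = matrix_loglik(shuffled, fern_tree, params, prior, "none")
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_root_spanning_probability_matches_simulation(self, fern_tree):
        params = BDParams(0.0031, 0.0039)
        prior = RootPrior(1.5)
        theo = root_spanning_probability(fern_tree, params, prior)
        _, truth = sim_gene_counts(fern_tree, params, prior, 4000, seed=11)
        emp = truth.root_spanning.mean()
        se = math.sqrt(theo * (1 - theo) / 4000)
        assert abs(emp - theo) <= 3 * se


class TestEstimateRates:
    def test_no_losses_pushes_mu_to_the_boundary(self):
        tree = fern_species_tree()
        prior = RootPrior(1.5)
        mat, _ = sim_gene_counts(tree, BDParams(0.004, 0.0), prior, 400, seed=2)
        est = estimate_rates(mat, tree, prior)
        assert est.params.mu < 2e-4  # at (or within tolerance of) zero

    def test_small_instance_matches_grid_search(self):
        """Optimizer vs a dense log-rate grid on 3 taxa, M = 5."""
        tree = parse_newick("((A:30,B:30):30,C:60);")
        prior = RootPrior(1.5)
        mat, _ = sim_gene_counts(tree, BDParams(0.004, 0.003), prior, 200, seed=4)
        work = GeneCountMatrix(mat.counts.clip(upper=5), m_max=5)
        est = estimate_rates(work, tree, prior)
        grid = np.exp(np.linspace(np.log(5e-4), np.log(2e-2), 60))
        best, best_ll = None, -np.inf
        spanning = work.root_spanning(tree)
        sub = GeneCountMatrix(work.counts.loc[spanning], 5)
        for lam in grid:
            for mu in grid:
                ll = matrix_loglik(sub, tree, BDParams(lam, mu), prior,
                                   "root_spanning")
                if ll > best_ll:
                    best, best_ll = (lam, mu), ll
        assert est.params.lam == pytest.approx(best[0], rel=0.05)
        assert est.params.mu == pytest.approx(best[1], rel=0.05)
        assert est.loglik >= best_ll - 1e-6

    def test_bias_shrinks_with_more_families(self):
        tree = fern_species_tree()
        prior = RootPrior(1.5)
        true = BDParams(0.0031, 0.0039)

        def err(n, seed):
            mat, _ = sim_gene_counts(tree, true, prior, n, seed=seed)
            est = estimate_rates(mat, tree, prior)
            return (abs(est.params.lam - true.lam) / true.lam
                    + abs(est.params.mu - true.mu) / true.mu)

        small = np.mean([err(500, s) for s in (0, 1, 2)])
        large = np.mean([err(5000, s) for s in (0, 1, 2)])
        assert large < small


class TestSimulation:
    def test_zero_rates_reproduce_the_species_tree(self, fern_tree):
        gt = simulate_gene_tree(fern_tree, BDParams(0, 0), seed=1)
        assert {lab.split("@")[0] for lab in gt.leaf_labels()} == fern_tree.taxa
        sp_parts = {frozenset(lab for lab in bp) for bp in fern_tree.bipartitions()}
        gt_parts = {frozenset(lab.split("@")[0] for lab in bp)
                    for bp in gt.bipartitions()}
        assert gt_parts == sp_parts

    def test_require_all_taxa_guarantees_full_coverage(self, fern_tree, rng):
        params = BDParams(0.0031 * 3, 0.0039 * 3)
        for _ in range(50):
            gt = simulate_gene_tree(fern_tree, params, require_all_taxa=True,
                                    rng=rng)
            assert gt.taxa == fern_tree.taxa

    def test_mean_tip_count_matches_branching_process_expectation(self, fern_tree):
        """Without rejection, E[tips] = sum over leaves of exp((lambda-mu)
        * depth), the branching-process mean composed along the tree."""
        lam, mu = 0.01, 0.006
        depths = {}
        for node in fern_tree.preorder():
            depths[node] = ((depths[node.parent] if node.parent else 0.0)
                            + (node.length or 0.0))
        expected = sum(math.exp((lam - mu) * depths[leaf])
                       for leaf in fern_tree.leaves())
        rng = np.random.default_rng(17)
        sizes = [len(simulate_gene_tree(fern_tree, BDParams(lam, mu),
                                        require_all_taxa=False, rng=rng).leaves())
                 for _ in range(1000)]
        se = np.std(sizes, ddof=1) / math.sqrt(len(sizes))
        assert abs(np.mean(sizes) - expected) <= 3 * se

    def test_null_sets_have_requested_shape_and_reproduce(self, fern_tree):
        nulls = simulate_null(fern_tree, BDParams(0.0031, 0.0039),
                              n_per_condition=5, seed=42)
        assert sorted(nulls) == ["0.5x", "1x", "3x", "5x"]
        assert all(len(trees) == 5 for trees in nulls.values())
        again = simulate_null(fern_tree, BDParams(0.0031, 0.0039),
                              n_per_condition=5, seed=42)
        for cond in nulls:
            assert [t.to_newick() for t in nulls[cond]] == \
                   [t.to_newick() for t in again[cond]]

    def test_empty_null_request_is_fine(self, fern_tree):
        nulls = simulate_null(fern_tree, BDParams(0.0031, 0.0039),
                              n_per_condition=0, seed=0)
        assert all(trees == [] for trees in nulls.values())


class TestRootPrior:
    def test_mean_below_one_rejected(self):
        with pytest.raises(ValueError):
            RootPrior(1.0)

    def test_expectation_is_exactly_the_mean(self):
        prior = RootPrior(1.5)
        assert prior.expectation() == 1.5
        series = sum(n * prior.pmf(n) for n in range(1, 5000))
        assert series == pytest.approx(1.5, abs=1e-12)

    def test_mass_concentrates_at_one_as_mean_approaches_one(self):
        assert RootPrior(1.0001).pmf(1) > 0.9999

    def test_sample_mean_matches_analytic_expectation(self, rng):
        prior = RootPrior(1.5)
        draws = np.array([sample_root_count(prior, rng) for _ in range(100_000)])
        assert draws.min() >= 1
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 1.5) <= 3 * se


class TestGeneCountMatrix:
    def test_families_beyond_bound_are_excluded_and_counted(self):
        df = pd.DataFrame({"A": [1, 200, 3], "B": [2, 1, 1]},
                          index=["f1", "f2", "f3"])
        mat = GeneCountMatrix(df, m_max=100)
        assert mat.n_excluded() == 1
        assert mat.within_bound().families == ["f1", "f3"]

    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame({"A": [1, 0], "B": [2, 4]}, index=["f1", "f2"])
        path = tmp_path / "counts.tsv"
        GeneCountMatrix(df).to_tsv(path)
        back = GeneCountMatrix.from_tsv(path)
        assert (back.counts == df).all().all()
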