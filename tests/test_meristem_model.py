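"""Unit and property tests of the stem-cell / oDNA division mechanics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from odrift.meristem_model import (
    ModelParams,
    REGIMES,
    build_population,
    divide_plastid,
    partition_plastids,
    perform_division,
    replicate_and_split_pool,
    symmetric_replacement_target,
)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

class TestModelParams:
    def test_defaults_match_study_conditions(self, mt_params, pt_params):
        assert (mt_params.n, mt_params.N, mt_params.G) == (40, 20, 40.0)
        assert mt_params.P_sym == 0.01 and mt_params.strat_ratio == 10.0
        assert pt_params.n == 216 and pt_params.n_pt == 12 and pt_params.n_rep == 18
        assert pt_params.mode == "pt" and mt_params.mode == "mt"
        assert mt_params.L == 0.05

    @pytest.mark.parametrize("bad", [
        dict(n=0), dict(N=10), dict(N=3), dict(P_sym=1.5), dict(E_part=0.6),
        dict(L=0.7), dict(n_pt=5, n_rep=5),  # 25 != 40
        dict(n_pt=4),  # n_rep missing
        dict(strat_ratio=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_regime_presets(self):
        assert REGIMES["strict"].B_sex == 3.0 and REGIMES["strict"].B_branch == 0.25
        assert REGIMES["clone"].B_sex == 1000.0 and REGIMES["clone"].B_branch == 0.25
        assert REGIMES["relaxed"].B_sex == 100.0 and REGIMES["relaxed"].B_branch == 1.0
        assert REGIMES["no"].B_sex is None and REGIMES["no"].B_branch is None
        # years -> population divisions at N*G = 800 per year
        p = ModelParams.mitochondrial()
        assert REGIMES["strict"].sex_divisions(p) == 2400
        assert REGIMES["strict"].branch_divisions(p) == 200


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

class TestBuildPopulation:
    def test_all_wild_type(self, mt_params):
        pop = build_population(mt_params)
        assert pop.n_live == 20
        assert pop.total_mutant() == 0
        assert pop.counts.shape == (20,)
        pop.validate()

    def test_single_fully_mutant_cell_tissue_af(self, mt_params):
        pop = build_population(mt_params, mutant_cell=0, mutant_copies=40)
        assert pop.total_mutant() == 40
        # 40 mutant copies of 20 cells x 40 copies = 800 total
        assert pop.cell_frequencies()[0] == 1.0
        assert pop.total_mutant() / (20 * 40) == pytest.approx(0.05)

    def test_plastid_single_mutant_copy(self, pt_params):
        pop = build_population(pt_params, mutant_cell=3, mutant_copies=1)
        assert pop.counts[3].sum() == 1
        assert (pop.counts[3] > 0).sum() == 1
        others = np.delete(pop.counts, 3, axis=0)
        assert not others.any()  # 239 other plastids wild type
        pop.validate()

    def test_capacity_and_layout_errors(self, mt_params, pt_params):
        with pytest.raises(ValueError):
            build_population(mt_params, mutant_cell=25, mutant_copies=1)
        with pytest.raises(ValueError):
            build_population(mt_params, mutant_cell=0, mutant_copies=41)
        with pytest.raises(ValueError):
            build_population(pt_params, mutant_cell=0, mutant_copies=19)


# ---------------------------------------------------------------------------
# pool replication/segregation
# ---------------------------------------------------------------------------

class TestReplicateAndSplit:
    def test_boundary_cases(self, rng):
        assert replicate_and_split_pool(0, 40, rng) == (0, 0)
        assert replicate_and_split_pool(40, 40, rng) == (40, 40)
        with pytest.raises(ValueError):
            replicate_and_split_pool(41, 40, rng)

    def test_split_distribution_matches_enumeration(self, rng):
        # equal splits of a 6-copy pool carrying 2 mutants, enumerated
        # exhaustively: of the C(6,3)=20 splits, m1 counts follow 4:12:4
        pool = [1, 1, 0, 0, 0, 0]
        counts = {0: 0, 1: 0, 2: 0}
        for picked in itertools.combinations(range(6), 3):
            counts[sum(pool[i] for i in picked)] += 1
        expected = np.array([counts[k] / 20 for k in (0, 1, 2)])
        draws = np.array([replicate_and_split_pool(1, 3, rng)[0]
                          for _ in range(20000)])
        observed = np.bincount(draws, minlength=3)
        chi = stats.chisquare(observed, expected * len(draws))
        assert chi.pvalue > 1e-4

    @given(m=st.integers(0, 30), n=st.integers(1, 30))
    @settings(max_examples=200, deadline=None)
    def test_mutant_conservation_and_bounds(self, m, n):
        if m > n:
            return
        rng = np.random.default_rng(m * 31 + n)
        m1, m2 = replicate_and_split_pool(m, n, rng)
        assert m1 + m2 == 2 * m
        assert 0 <= m1 <= n and 0 <= m2 <= n

    def test_divide_plastid_enumeration(self, rng):
        # 2-copy plastid with 1 mutant: split of 4 copies (2 mutant) into 2+2
        draws = np.array([divide_plastid(1, 2, rng)[0] for _ in range(20000)])
        observed = np.bincount(draws, minlength=3)
        # C(4,2)=6 splits: m1=0 and m1=2 once via choosing both wild/mutant,
        # m1=1 in 4 of 6
        expected = np.array([1 / 6, 4 / 6, 1 / 6]) * len(draws)
        chi = stats.chisquare(observed, expected)
        assert chi.pvalue > 1e-4
        assert abs(observed[0] - observed[2]) < 5 * math.sqrt(len(draws) / 6)


# ---------------------------------------------------------------------------
# plastid partition
# ---------------------------------------------------------------------------

class TestPartitionPlastids:
    def test_error_free_partition_splits_every_pair(self, rng):
        pairs = np.array([[i * 10, i * 10 + 1] for i in range(12)])
        a, b = partition_plastids(pairs, 0.0, rng)
        assert len(a) == len(b) == 12
        assert sorted(np.r_[a, b].tolist()) == sorted(pairs.ravel().tolist())
        for s1, s2 in pairs:
            assert (s1 in a) != (s1 in b)
            assert (s1 in a) == (s2 in b)

    def test_random_partition_is_uniform_over_equal_splits(self, rng):
        # 2 labelled pairs: daughter A compositions must be uniform over the
        # C(4,2)=6 equal partitions
        outcomes = {}
        n = 30000
        for _ in range(n):
            a, _ = partition_plastids([[10, 11], [20, 21]], 0.5, rng)
            key = tuple(sorted(a.tolist()))
            outcomes[key] = outcomes.get(key, 0) + 1
        assert len(outcomes) == 6
        chi = stats.chisquare(list(outcomes.values()))
        assert chi.pvalue > 1e-4

    def test_random_partition_uniform_three_pairs(self, rng):
        # E_part = 0.5 vs exhaustive uniform enumeration for n_pt = 3
        labels = np.array([[0, 1], [2, 3], [4, 5]])
        outcomes = {}
        n = 40000
        for _ in range(n):
            a, _ = partition_plastids(labels, 0.5, rng)
            outcomes[tuple(sorted(a.tolist()))] = \
                outcomes.get(tuple(sorted(a.tolist())), 0) + 1
        assert len(outcomes) == math.comb(6, 3)
        chi = stats.chisquare(list(outcomes.values()))
        assert chi.pvalue > 1e-4

    def test_small_error_cosegregation_rate_and_balance(self, rng):
        # at small E_part, acceptance conditions on an even number of
        # co-segregating pairs, which come in side-balanced sets
        e, n = 0.02, 40000
        n_coseg = 0
        for _ in range(n):
            pairs = np.array([[i * 10, i * 10 + 1] for i in range(12)])
            a, b = partition_plastids(pairs, e, rng)
            together_in_a = sum(1 for s1, s2 in pairs if s1 in a and s2 in a)
            together_in_b = sum(1 for s1, s2 in pairs if s1 in b and s2 in b)
            assert together_in_a == together_in_b  # side balance
            if together_in_a:
                n_coseg += 1
        # acceptance requires k co-segregating pairs (k ~ Binomial(12, e))
        # AND a balanced side draw, probability C(k, k/2) / 2^k; the
        # conditioned rate of >=1 co-segregation follows by enumeration
        from scipy.stats import binom
        ks = np.arange(13)
        accept = np.where(ks % 2 == 0,
                          [math.comb(k, k // 2) / 2 ** k for k in ks], 0.0)
        w = binom.pmf(ks, 12, e) * accept
        p_expected = w[2:].sum() / w.sum()
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(n_coseg / n - p_expected) < 4 * se


# ---------------------------------------------------------------------------
# stratification scheme
# ---------------------------------------------------------------------------

class TestReplacementTarget:
    def test_periclinal_fraction_at_default_ratio(self, mt_params, rng):
        pop = build_population(mt_params)
        n = 20000
        kinds = [symmetric_replacement_target(pop, 2, None, rng)[1]
                 for _ in range(n)]
        frac = kinds.count("periclinal") / n
        p = 1 / 11
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_corpus_never_divides_periclinally(self, mt_params, rng):
        pop = build_population(mt_params)
        for _ in range(2000):
            target, kind = symmetric_replacement_target(pop, 15, None, rng)
            assert kind == "anticlinal"
            assert target >= 10  # layer closure: corpus stays in corpus

    def test_custom_ratio(self, mt_params, rng):
        pop = build_population(mt_params)
        n = 30000
        kinds = [symmetric_replacement_target(pop, 0, 30.0, rng)[1]
                 for _ in range(n)]
        frac = kinds.count("periclinal") / n
        p = 1 / 31
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_targets_are_neighbours_with_periodic_rows(self, mt_params, rng):
        pop = build_population(mt_params)
        # slot 0 (tunica row 0, col 0): row neighbours 1 and 4 (periodic),
        # other tunica row slot 5, periclinal corpus slot 10
        seen = {symmetric_replacement_target(pop, 0, None, rng)[0]
                for _ in range(3000)}
        assert seen == {1, 4, 5, 10}


# ---------------------------------------------------------------------------
# whole divisions
# ---------------------------------------------------------------------------

class TestPerformDivision:
    def test_wild_type_closure(self, mt_params, rng):
        pop = build_population(mt_params)
        for _ in range(300):
            perform_division(pop, mt_params, rng)
            assert pop.total_mutant() == 0
            pop.validate()

    def test_copy_number_conserved_every_step(self, pt_params, rng):
        pop = build_population(pt_params, mutant_cell=4, mutant_copies=9)
        for _ in range(400):
            perform_division(pop, pt_params, rng)
            pop.validate()  # every cell keeps n_pt plastids x n_rep copies

    def test_asymmetric_marginal_matches_hypergeometric(self, rng):
        params = ModelParams.mitochondrial(P_sym=0.0)  # asymmetric only
        m0, n = 10, 40
        draws = []
        for _ in range(4000):
            pop = build_population(params, mutant_cell=7, mutant_copies=m0)
            while True:
                _, ev = perform_division(pop, params, rng)
                if ev.dividing_cell == 7:
                    break
            draws.append(int(pop.counts[7]))
        observed = np.bincount(draws, minlength=2 * m0 + 1)
        expected = stats.hypergeom.pmf(np.arange(2 * m0 + 1),
                                       2 * n, 2 * m0, n) * len(draws)
        keep = expected > 5
        chi = stats.chisquare(observed[keep],
                              expected[keep] * observed[keep].sum()
                              / expected[keep].sum())
        assert chi.pvalue > 1e-4

    def test_proliferation_requires_room(self, mt_params, rng):
        pop = build_population(mt_params)
        with pytest.raises(ValueError):
            perform_division(pop, mt_params, rng, phase="proliferation")

    def test_symmetric_replacement_can_erase_the_mutation(self, rng):
        # force symmetric divisions; when the only mutant cell is replaced by
        # a wild-type daughter the mutation is lost in that time unit
        params = ModelParams.mitochondrial(P_sym=1.0)
        lost = False
        for _ in range(200):
            pop = build_population(params, mutant_cell=5, mutant_copies=1)
            _, ev = perform_division(pop, params, rng)
            if ev.replaced_cell == 5 and ev.dividing_cell != 5 \
                    and pop.total_mutant() == 0:
                lost = True
                break
        assert lost
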