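"""Selection problems, protocols, and the pseudoweight frontier pick."""

from itertools import combinations

import numpy as np
import pytest

from breedopt import (
    SelectionProblem,
    ibs_kinship,
    ocs_subset_problem,
    ohv_select,
    ohv_values,
    pseudoweight_pick,
    random_select,
    select,
    truncation_select,
    weighted_gs_scores,
    within_family_select,
)

from conftest import make_genomes


class TestSelectionProblem:
    def make_problem(self, **overrides):
        kwargs = dict(
            n_candidates=6,
            subset_size=2,
            latent=lambda x: np.array([float(x.sum()), float(x.max())]),
            n_obj=2,
        )
        kwargs.update(overrides)
        return SelectionProblem(**kwargs)

    def test_identity_transform_passes_latent_through(self):
        prob = self.make_problem()
        obj, ineq, eq = prob.evaluate([1, 4])
        np.testing.assert_allclose(obj, [5.0, 4.0])
        assert ineq.size == 0 and eq.size == 0

    def test_repartition_latent_into_constraint(self):
        # move the second latent element into an inequality constraint
        prob = self.make_problem(
            n_obj=1,
            t_obj=lambda lat: lat[:1],
            t_ineq=lambda lat: lat[1:] - 3.0,
            n_ineq=1,
        )
        obj, ineq, _ = prob.evaluate([1, 4])
        assert obj.tolist() == [5.0]
        assert ineq.tolist() == [1.0]
        assert prob.violation([1, 4]) == pytest.approx(1.0)
        assert prob.violation([0, 1]) == 0.0

    @pytest.mark.parametrize(
        "bad", [[1], [1, 1], [0, 99], [-1, 2], [0, 1, 2]]
    )
    def test_invalid_decisions_rejected(self, bad):
        with pytest.raises(ValueError):
            self.make_problem().evaluate(bad)

    def test_evaluate_is_pure(self):
        prob = self.make_problem()
        a = prob.evaluate([2, 5])
        b = prob.evaluate([2, 5])
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestOcsSubsetProblem:
    def test_full_selection_identity(self, rng):
        n, t = 8, 2
        bv = rng.normal(size=(n, t))
        K = np.eye(n) * 0.5 + 0.5
        prob = ocs_subset_problem(bv, K, J=n)
        lat = prob.latent(np.arange(n))
        np.testing.assert_allclose(lat[:t], bv.mean(axis=0))
        assert lat[t] == pytest.approx(K.mean())

    def test_clone_kinship_degenerate(self):
        bv = np.zeros((4, 1))
        K = np.ones((4, 4))
        prob = ocs_subset_problem(bv, K, J=2)
        for pair in combinations(range(4), 2):
            assert prob.latent(np.array(pair))[-1] == pytest.approx(1.0)

    def test_matches_brute_force_on_all_subsets(self, rng):
        n, J = 12, 4
        bv = rng.normal(size=(n, 2))
        A = rng.normal(size=(n, n))
        K = (A @ A.T) / n
        prob = ocs_subset_problem(bv, K, J)
        for subset in combinations(range(n), J):
            x = np.array(subset)
            # independent brute-force arithmetic with explicit loops
            mean1 = sum(bv[i, 0] for i in subset) / J
            mean2 = sum(bv[i, 1] for i in subset) / J
            kin = sum(K[i, j] for i in subset for j in subset) / J**2
            obj = prob.objectives(x)
            np.testing.assert_allclose(obj, [-mean1, -mean2, kin], atol=1e-12)

    def test_infeasible_subset_size(self):
        with pytest.raises(ValueError):
            ocs_subset_problem(np.zeros((3, 1)), np.eye(3), J=5)


class TestTruncationSelect:
    def test_hand_example(self):
        idx = truncation_select(np.array([[3.0], [1.0], [2.0]]), 2)
        assert set(idx.tolist()) == {0, 2}

    def test_tie_break_by_ascending_index(self):
        idx = truncation_select(np.ones((4, 2)), 2)
        assert idx.tolist() == [0, 1]

    def test_matches_sort_oracle(self, rng):
        scores = rng.normal(size=(40, 2))
        idx = truncation_select(scores, 10)
        oracle = sorted(range(40), key=lambda i: (-scores[i].sum(), i))[:10]
        assert idx.tolist() == oracle

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            truncation_select(np.zeros((3, 1)), 4)


class TestWithinFamilySelect:
    def test_five_percent_of_eighty_keeps_four(self, rng):
        scores = rng.normal(size=(80, 2))
        fam = np.zeros(80, dtype=int)
        kept = within_family_select(scores, fam, 0.05)
        assert kept.size == 4

    def test_proportion_one_keeps_all(self, rng):
        scores = rng.normal(size=(7, 1))
        kept = within_family_select(scores, np.zeros(7, dtype=int), 1.0)
        assert kept.tolist() == list(range(7))

    def test_two_families_against_per_family_oracle(self, rng):
        scores = rng.normal(size=(20, 1))
        fam = np.repeat([0, 1], 10)
        kept = set(within_family_select(scores, fam, 0.2).tolist())
        expected = set()
        for f in (0, 1):
            members = [i for i in range(20) if fam[i] == f]
            members.sort(key=lambda i: (-scores[i].sum(), i))
            expected.update(members[:2])
        assert kept == expected

    def test_round_half_up(self):
        # family of 10 at 25%: 2.5 rounds up to 3
        scores = np.arange(10, dtype=float)[:, None]
        kept = within_family_select(scores, np.zeros(10, dtype=int), 0.25)
        assert kept.size == 3

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            within_family_select(np.zeros((4, 1)), np.zeros(4), 0.0)


class TestWeightedGs:
    def test_unit_weights_recover_unweighted_scores(self):
        Z = np.array([[0, 1], [2, 2]])
        U = np.array([[1.0], [2.0]])
        scores = weighted_gs_scores(Z, U, np.ones(2))
        np.testing.assert_allclose(scores, Z @ U)

    def test_rare_favorable_allele_upweighted(self):
        # f_fav = 0.25 -> weight 1/sqrt(0.25) = 2 (clamp 1/(2n) inactive at n=4)
        Z = [[1], [0], [0], [1]]
        scores = weighted_gs_scores(Z, [[3.0]], [0.25])
        assert scores[0, 0] == pytest.approx(6.0)

    def test_negative_effect_uses_other_allele(self):
        # effect < 0: favorable allele is code 0 with frequency 1 - f
        Z = [[1], [0], [0], [1]]
        scores = weighted_gs_scores(Z, [[-3.0]], [0.75])
        assert scores[0, 0] == pytest.approx(-6.0)

    def test_zero_frequency_clamped_finite(self):
        scores = weighted_gs_scores(np.ones((4, 1)), [[1.0]], [0.0])
        assert np.all(np.isfinite(scores))
        # clamp at 1/(2n) with n=4 -> weight sqrt(8)
        assert scores[0, 0] == pytest.approx(np.sqrt(8.0))


class TestOhv:
    def test_homozygote_equals_additive_contribution(self):
        alleles = np.zeros((1, 4, 2), dtype=np.int8)
        alleles[0, [0, 2], :] = 1
        g = make_genomes(alleles)
        U = np.array([[1.0], [2.0], [3.0], [4.0]])
        ohv = ohv_values(g, U, 1)
        assert ohv[0, 0] == pytest.approx(float(g.dosage[0] @ U[:, 0]))

    def test_single_block_hand_max(self):
        alleles = np.zeros((1, 2, 2), dtype=np.int8)
        alleles[0, 0, 0] = 1  # phase 0: (1, 0)
        alleles[0, 1, 1] = 1  # phase 1: (0, 1)
        g = make_genomes(alleles)
        U = np.array([[3.0], [5.0]])
        assert ohv_values(g, U, 1)[0, 0] == pytest.approx(10.0)  # 2*max(3,5)

    def test_block_refinement_is_monotone(self):
        alleles = np.zeros((1, 2, 2), dtype=np.int8)
        alleles[0, 0, 0] = 1
        alleles[0, 1, 1] = 1
        g = make_genomes(alleles)
        U = np.array([[3.0], [5.0]])
        two_block = ohv_values(g, U, 2)[0, 0]
        assert two_block == pytest.approx(16.0)  # 2*(3+5)
        assert two_block >= ohv_values(g, U, 1)[0, 0]

    def test_select_returns_top_k(self, rng):
        alleles = (rng.random((6, 10, 2)) < 0.5).astype(np.int8)
        g = make_genomes(alleles)
        U = rng.normal(size=(10, 1))
        idx = ohv_select(g, U, 2, 3)
        vals = ohv_values(g, U, 2).sum(axis=1)
        oracle = sorted(range(6), key=lambda i: (-vals[i], i))[:3]
        assert idx.tolist() == oracle


class TestRandomSelect:
    def test_k_equals_n(self, rng):
        assert set(random_select(5, 5, rng).tolist()) == set(range(5))

    def test_seed_reproducible(self):
        a = random_select(20, 6, np.random.default_rng(3))
        b = random_select(20, 6, np.random.default_rng(3))
        assert a.tolist() == b.tolist()

    def test_uniformity(self):
        rng = np.random.default_rng(8)
        counts = np.zeros(10)
        draws = 30000
        for _ in range(draws):
            counts[random_select(10, 3, rng)] += 1
        np.testing.assert_allclose(counts / draws, 0.3, atol=0.01)


class TestPseudoweightPick:
    def test_single_point_front(self):
        assert pseudoweight_pick(np.array([[1.0, 2.0]]), [0.5, 0.5]) == 0

    def test_axis_preference_picks_best_in_that_objective(self):
        front = np.array([[0.0, 3.0], [1.0, 1.0], [3.0, 0.0]])  # minimized
        assert pseudoweight_pick(front, [1.0, 0.0]) == 0
        assert pseudoweight_pick(front, [0.0, 1.0]) == 2

    def test_hand_computed_distances(self):
        front = np.array([[0.0, 1.0], [1.0, 0.0]])  # minimized objectives
        # scaled (larger=better): point0 -> (1, 0), point1 -> (0, 1)
        # distances to (0.5, 0.5): equal -> tie broken to index 0
        assert pseudoweight_pick(front, [0.5, 0.5]) == 0
        # preference (0.9, 0.1) is closer to point0
        assert pseudoweight_pick(front, [0.9, 0.1]) == 0

    def test_affine_rescaling_invariance(self, rng):
        front = rng.normal(size=(8, 3))
        pref = np.array([0.2, 0.4, 0.4])
        base = pseudoweight_pick(front, pref)
        scaled = front * np.array([3.0, 0.5, 10.0]) + np.array([5.0, -2.0, 0.1])
        assert pseudoweight_pick(scaled, pref) == base

    def test_constant_column_scales_to_zero(self):
        front = np.array([[1.0, 5.0], [2.0, 5.0]])
        # constant column contributes the same distance to every point
        assert pseudoweight_pick(front, [1.0, 0.0]) == 0

    def test_max_sense_orientation(self):
        front = np.array([[0.0], [5.0]])
        assert pseudoweight_pick(front, [1.0], senses=["max"]) == 1
        assert pseudoweight_pick(front, [1.0], senses=["min"]) == 0


class TestSelectDriver:
    def test_single_objective_passthrough(self, rng):
        scores = rng.normal(size=10)
        prob = SelectionProblem(
            n_candidates=10,
            subset_size=3,
            latent=lambda x: np.array([-scores[x].sum()]),
            n_obj=1,
        )
        config = select(prob, np.random.default_rng(0), generations=100, pop_size=30)
        oracle = truncation_select(scores[:, None], 3)
        assert set(config.selected.tolist()) == set(oracle.tolist())

    def test_tiny_ocs_matches_enumeration_pick(self, tiny_ocs_instance):
        genomes, model = tiny_ocs_instance
        bv = model.breeding_values(genomes.dosage)
        K = ibs_kinship(genomes)
        prob = ocs_subset_problem(bv, K, 4)
        # oracle: enumerate all subsets, find exact front, pick by distance
        from breedopt import exhaustive_pareto

        exact = exhaustive_pareto(prob)
        pref = np.full(3, 1 / 3)
        oracle_pick = pseudoweight_pick(exact.objectives, pref)
        oracle_obj = exact.objectives[oracle_pick]

        config = select(
            prob,
            np.random.default_rng(2),
            preference=pref,
            pop_size=120,
            generations=250,
        )
        np.testing.assert_allclose(config.objectives, oracle_obj, atol=1e-9)

    def test_empty_front_impossible_by_contract(self, rng):
        prob = SelectionProblem(
            n_candidates=4,
            subset_size=2,
            latent=lambda x: np.array([0.0, 0.0]),
            n_obj=2,
        )
        config = select(prob, rng, generations=5, pop_size=10)
        assert config.selected.size == 2
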