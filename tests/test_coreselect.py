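import numpy as np
import pytest

from apycore import (GenotypeMatrix, RankExhaustedError, ValidationError, build_grm,
                     expand_core, reduced_rank, select_conditional,
                     select_conditional_min, select_diagonal, select_random,
                     select_weighted, spectral)

from conftest import gaussian_gm, random_gm


def wrap(W, v=1.0):
    W = np.asarray(W, dtype=float)
    return GenotypeMatrix(ids=[str(i + 1) for i in range(W.shape[0])],
                          counts=None, p=None, W=W, v=v)


def brute_force_conditional(W, k):
    """Reference greedy loop computing every conditional variance from scratch.

    At each step the conditional covariance of all animals given the chosen
    set is recomputed as a Schur complement of the full covariance matrix.
    """
    W = np.asarray(W, dtype=float)
    C = W @ W.T
    picks, variances = [], []
    for _ in range(k):
        if picks:
            S = C[np.ix_(picks, picks)]
            B = C[:, picks]
            cond = C - B @ np.linalg.solve(S, B.T)
        else:
            cond = C
        d = np.diag(cond).copy()
        d[picks] = -np.inf
        i = int(np.argmax(d))
        picks.append(i)
        variances.append(d[i])
    return picks, np.array(variances), cond if k else C


class TestSelectRandom:
    def test_exhaustive_and_empty(self):
        ids = ["a", "b", "c"]
        assert sorted(select_random(ids, 3, seed=0).core_ids) == sorted(ids)
        assert select_random(ids, 0, seed=0).core_ids == []

    def test_seeded_determinism(self):
        ids = [str(i) for i in range(100)]
        assert select_random(ids, 10, seed=5).core_ids == \
            select_random(ids, 10, seed=5).core_ids

    def test_oversized_k_rejected(self):
        with pytest.raises(ValidationError):
            select_random(["a"], 2, seed=0)

    def test_different_seeds_barely_overlap(self):
        # the instability that motivates deterministic constructions
        ids = [str(i) for i in range(100)]
        a = set(select_random(ids, 10, seed=1).core_ids)
        b = set(select_random(ids, 10, seed=2).core_ids)
        assert len(a & b) < 10


class TestSelectDiagonal:
    def make_rm(self, diag):
        n = len(diag)
        return build_grm(wrap(np.diag(np.sqrt(diag))), 0.0), n

    def test_largest_diagonals_chosen(self):
        rm, _ = self.make_rm([3.0, 1.0, 2.0])
        assert set(select_diagonal(rm, 2).core_ids) == {"1", "3"}

    def test_ties_broken_by_input_order(self):
        rm, _ = self.make_rm([2.0, 2.0, 1.0])
        assert select_diagonal(rm, 1).core_ids == ["1"]

    def test_full_core(self):
        rm, n = self.make_rm([1.0, 2.0, 3.0])
        assert sorted(select_diagonal(rm, n).core_ids) == ["1", "2", "3"]


class TestSelectWeighted:
    def test_zero_weight_animals_excluded(self):
        rm = build_grm(wrap(np.diag([1.0, 1.0, 0.0])), 0.0)
        assert set(select_weighted(rm, 2, seed=0).core_ids) == {"1", "2"}
        with pytest.raises(ValidationError):
            select_weighted(rm, 3, seed=0)

    def test_empty(self):
        rm = build_grm(wrap(np.eye(2)), 0.0)
        assert select_weighted(rm, 0, seed=0).core_ids == []

    def test_sampling_law(self):
        # weights (3, 1): animal 1 should be drawn with probability 0.75
        rm = build_grm(wrap(np.diag([np.sqrt(3.0), 1.0])), 0.0)
        rng_seeds = range(10_000)
        hits = sum(select_weighted(rm, 1, seed=s).core_ids == ["1"]
                   for s in rng_seeds)
        assert hits / len(rng_seeds) == pytest.approx(0.75, abs=0.015)


class TestSelectConditional:
    def test_three_animal_example(self):
        gm = wrap([[3, 0], [0, 2], [1, 0]])
        cs = select_conditional(gm, 2)
        assert cs.core_ids == ["1", "2"]
        # at selection time: animal 1 had variance 9, animal 2 had 4 (its
        # variance is untouched by conditioning on the orthogonal animal 1)
        assert np.allclose(cs.selection_variances, [9.0, 4.0])
        # conditioning on animal 1 annihilates animals 1 and 3
        C = gm.W @ gm.W.T
        cond = C - np.outer(C[:, 0], C[0, :]) / C[0, 0]
        assert np.allclose(np.diag(cond), [0.0, 4.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        gm = gaussian_gm(12, 8, seed)
        k = 6
        exp_picks, exp_vars, _ = brute_force_conditional(gm.W, k)
        cs = select_conditional(gm, k)
        assert [int(a) - 1 for a in cs.core_ids] == exp_picks
        assert np.allclose(cs.selection_variances, exp_vars, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_covariance_and_genotype_modes_agree(self, seed):
        gm = gaussian_gm(50, 30, seed)
        a = select_conditional(gm, 20, mode="genotype")
        b = select_conditional(gm, 20, mode="covariance")
        assert a.core_ids == b.core_ids
        assert np.allclose(a.selection_variances, b.selection_variances, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_selection_variances_non_increasing(self, seed):
        gm = random_gm(40, 25, seed)
        cs = select_conditional(gm, 20)
        assert np.all(np.diff(cs.selection_variances) <= 1e-9)
        assert np.all(cs.selection_variances > 0)

    def test_repeated_runs_identical(self):
        gm = random_gm(30, 20, 7)
        assert select_conditional(gm, 10).core_ids == \
            select_conditional(gm, 10).core_ids

    def test_rank_exhaustion_reports_progress(self):
        W = np.zeros((5, 4))
        W[0, 0] = 2.0
        W[1, 1] = 1.0
        W[2, 0] = 1.0  # dependent on animal 1
        with pytest.raises(RankExhaustedError) as exc:
            select_conditional(wrap(W), 4)
        assert exc.value.n_selected == 2

    def test_starts_from_largest_diagonal(self):
        gm = wrap([[1, 0], [0, 3], [2, 0]])
        assert select_conditional(gm, 1).core_ids == ["2"]


class TestSelectConditionalMin:
    def test_mean_criterion_first_pick(self):
        gm = wrap([[1, 0], [0, 1], [2, 0]])
        cs = select_conditional_min(gm, 1, criterion="mean")
        assert cs.core_ids == ["3"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_max_criterion_matches_exhaustive_oracle(self, seed):
        gm = gaussian_gm(6, 4, seed)
        W = gm.W
        C = W @ W.T
        best, best_score = None, np.inf
        for j in range(6):
            cond = C - np.outer(C[:, j], C[:, j]) / C[j, j]
            others = [i for i in range(6) if i != j]
            score = np.diag(cond)[others].max()
            if score < best_score - 1e-15:
                best, best_score = j, score
        cs = select_conditional_min(gm, 1, criterion="max")
        assert cs.core_ids == [str(best + 1)]

    def test_full_rank_selection_exhausts_variance(self):
        gm = gaussian_gm(5, 4, 5)  # centred rows: rank 4
        cs = select_conditional_min(gm, 4, criterion="mean")
        # conditioning on a row-space-spanning core annihilates every animal
        picks = [int(a) - 1 for a in cs.core_ids]
        C = gm.W @ gm.W.T
        S = C[np.ix_(picks, picks)]
        residual = C - C[:, picks] @ np.linalg.solve(S, C[picks, :])
        assert np.allclose(np.diag(residual), 0.0, atol=1e-8)


class TestExpandCore:
    def test_zero_new_returns_old_core(self):
        cs = expand_core(np.eye(2), np.ones((1, 2)), 0, old_core_ids=["a", "b"])
        assert cs.core_ids == ["a", "b"]

    def test_three_animal_expansion(self):
        W = np.array([[3.0, 0], [0, 2], [1, 0]])
        gm = wrap(W)
        combined = select_conditional(gm, 2)
        assert combined.core_ids == ["1", "2"]
        cs = expand_core(W[[0]], W[1:], 1, old_core_ids=["1"], new_ids=["2", "3"])
        assert cs.core_ids == combined.core_ids

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("j,k_new", [(3, 4), (5, 8), (10, 5)])
    def test_expansion_equals_combined_optimisation(self, seed, j, k_new):
        """Conditioning on a conditional-algorithm prefix reproduces the
        greedy state, so expansion and a fresh combined run coincide."""
        gm = gaussian_gm(40, 20, seed)
        combined = select_conditional(gm, j + k_new)
        prefix = combined.core_ids[:j]
        rows = gm.index_of(prefix)
        new_rows = [i for i in range(40) if gm.ids[i] not in set(prefix)]
        expanded = expand_core(gm.W[rows], gm.W[new_rows], k_new,
                               old_core_ids=prefix,
                               new_ids=[gm.ids[i] for i in new_rows])
        assert expanded.core_ids == combined.core_ids
        assert np.allclose(expanded.selection_variances[j:],
                           combined.selection_variances[j:], atol=1e-8)

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            expand_core(np.eye(2), np.ones((1, 3)), 1)


class TestReducedRank:
    def test_full_fraction_preserves_covariance(self):
        gm = random_gm(20, 30, 4)
        rr = reduced_rank(gm, 1.0)
        assert np.allclose(rr.W @ rr.W.T, gm.W @ gm.W.T, atol=1e-8)

    def test_rank_one_input(self):
        gm = wrap([[0.0, 0], [2, 2]])
        assert reduced_rank(gm, 0.5).W.shape[1] == 1

    @pytest.mark.parametrize("fraction", [0.5, 0.9])
    def test_truncation_error_equals_discarded_eigenvalues(self, fraction):
        gm = random_gm(25, 40, 6)
        spec = spectral(gm)
        rr = reduced_rank(gm, fraction)
        r = rr.W.shape[1]
        discarded = spec.eigenvalues[r:].sum() * gm.v
        err = np.trace(gm.W @ gm.W.T - rr.W @ rr.W.T)
        assert err == pytest.approx(discarded, abs=1e-8)

    def test_selection_on_reduced_matrix_runs(self):
        gm = random_gm(30, 40, 8)
        rr = reduced_rank(gm, 0.9)
        cs = select_conditional(rr, 5)
        assert len(cs.core_ids) == 5
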