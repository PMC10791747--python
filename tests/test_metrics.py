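"""Structure metrics: NODF, Barber modularity, null models, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triguild import (
    CommunityState,
    barber_modularity,
    correlation_suite,
    energy_budgets,
    integrate_to_equilibrium,
    nodf,
    null_ensemble,
    plant_stats,
    relative_metric,
    structure_report,
    z_score_one_tailed,
)
from triguild.metrics import NullEnsemble, modularity_value

from conftest import make_system


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def nodf_pair_loop(A):
    """Independent O(n^2 m) pair-loop NODF oracle."""
    A = (np.asarray(A) != 0).astype(int)
    n_r, n_c = A.shape
    total = 0.0
    for i, j in itertools.combinations(range(n_r), 2):
        ki, kj = A[i].sum(), A[j].sum()
        if ki != kj and min(ki, kj) > 0:
            shared = int(np.sum(A[i] & A[j]))
            total += shared / min(ki, kj)
    for i, j in itertools.combinations(range(n_c), 2):
        ki, kj = A[:, i].sum(), A[:, j].sum()
        if ki != kj and min(ki, kj) > 0:
            shared = int(np.sum(A[:, i] & A[:, j]))
            total += shared / min(ki, kj)
    n_pairs = n_r * (n_r - 1) / 2 + n_c * (n_c - 1) / 2
    return 100.0 * total / n_pairs


def exhaustive_modularity(A):
    """Exact maximum of Barber's Q by enumerating row partitions.

    For a fixed partition of the rows, each column's optimal module can be
    chosen independently (its contribution is additive), taking an empty
    module (contribution 0) when every row-module score is negative.
    """
    A = (np.asarray(A) != 0).astype(float)
    m = A.sum()
    k, d = A.sum(axis=1), A.sum(axis=0)
    B = A - np.outer(k, d) / m
    n_r = A.shape[0]

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = 0.0
    for part in partitions(list(range(n_r))):
        q = 0.0
        for j in range(A.shape[1]):
            q += max(0.0, max(B[rows, j].sum() for rows in part))
        best = max(best, q / m)
    return best


def spearman_oracle(x, y):
    """Rank-based Spearman rho with average ranks on ties."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

class TestNodf:
    def test_perfectly_nested_staircase(self):
        assert nodf([[1, 1, 1], [1, 1, 0], [1, 0, 0]]) == pytest.approx(100.0)

    def test_identity_has_no_overlap(self):
        assert nodf(np.eye(2)) == 0.0

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert nodf(np.zeros((3, 3))) == 0.0

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            nodf(np.ones((1, 5)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((rng.integers(2, 12), rng.integers(2, 12))) < 0.4)
        assert nodf(A) == pytest.approx(nodf_pair_loop(A), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_transpose_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed + 50)
        A = (rng.random((7, 9)) < 0.35).astype(float)
        if A.sum() == 0:
            A[0, 0] = 1
        base = nodf(A)
        assert nodf(A.T) == pytest.approx(base, abs=1e-12)
        perm = A[rng.permutation(7)][:, rng.permutation(9)]
        assert nodf(perm) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

class TestBarberModularity:
    def test_two_block_diagonal(self):
        A = np.zeros((4, 4))
        A[:2, :2] = 1
        A[2:, 2:] = 1
        q, (row, col) = barber_modularity(A, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        # the two blocks land in different modules
        assert row[0] == row[1] != row[2] == row[3]

    def test_complete_bipartite_is_unstructured(self):
        q, _ = barber_modularity(np.ones((3, 4)), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            barber_modularity(np.zeros((3, 3)))

    def test_never_below_single_module_baseline(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = (rng.random((6, 6)) < 0.3).astype(float)
            if A.sum() == 0:
                continue
            q, _ = barber_modularity(A, seed=1)
            assert q >= 0.0

    def test_heuristic_equals_exhaustive_on_small_matrices(self):
        """On every matrix up to 3x3 with >= 1 link the heuristic attains
        the exact optimum found by enumerating all row partitions."""
        for shape in [(2, 2), (2, 3), (3, 2), (3, 3)]:
            n = shape[0] * shape[1]
            for bits in range(1, 2**n):
                A = np.array([(bits >> i) & 1 for i in range(n)],
                             dtype=float).reshape(shape)
                q, _ = barber_modularity(A, n_restarts=10, seed=0)
                assert q == pytest.approx(exhaustive_modularity(A), abs=1e-10), A

    @pytest.mark.parametrize("seed", range(40))
    def test_heuristic_equals_exhaustive_on_random_4x4(self, seed):
        rng = np.random.default_rng(seed)
        A = (rng.random((4, 4)) < 0.4).astype(float)
        if A.sum() == 0:
            A[rng.integers(4), rng.integers(4)] = 1.0
        q, _ = barber_modularity(A, n_restarts=20, seed=1)
        assert q == pytest.approx(exhaustive_modularity(A), abs=1e-10)

    def test_partition_value_consistency(self):
        rng = np.random.default_rng(9)
        A = (rng.random((8, 8)) < 0.3).astype(float)
        A[0, 0] = 1.0
        q, (row, col) = barber_modularity(A, seed=2)
        assert modularity_value(A, row, col) == pytest.approx(q, abs=1e-12)


# ---------------------------------------------------------------------------
# null models and z-scores
# ---------------------------------------------------------------------------

class TestNullModels:
    def test_minimal_ensemble_mean(self):
        rng = np.random.default_rng(0)
        A = (rng.random((5, 5)) < 0.5).astype(float)
        ens = null_ensemble(A, n=2, seed=1)
        assert ens.mean == pytest.approx(ens.values.mean())
        assert ens.n_replicates == 2

    def test_full_matrix_null_is_degenerate(self):
        ens = null_ensemble(np.ones((4, 4)), n=10, seed=0)
        assert ens.sd == 0.0
        with pytest.raises(ValueError):
            z_score_one_tailed(50.0, ens)

    def test_invalid_arguments(self):
        A = np.ones((3, 3))
        with pytest.raises(ValueError):
            null_ensemble(A, n=1)
        with pytest.raises(ValueError):
            null_ensemble(A, metric="banana")
        with pytest.raises(ValueError):
            null_ensemble(A, model_name="banana")

    def test_equiprobable_mean_self_consistent(self):
        """Two independent equiprobable ensembles of the same matrix agree
        in mean NODF within 3 combined standard errors."""
        rng = np.random.default_rng(4)
        A = (rng.random((10, 10)) < 0.3).astype(float)
        e1 = null_ensemble(A, n=400, seed=10)
        e2 = null_ensemble(A, n=400, seed=20)
        se = np.sqrt(e1.sd**2 / e1.n_replicates + e2.sd**2 / e2.n_replicates)
        assert abs(e1.mean - e2.mean) < 3 * se

    def test_degree_probabilistic_preserves_expected_degrees(self):
        rng = np.random.default_rng(5)
        A = (rng.random((12, 10)) < 0.3).astype(float)
        from triguild.metrics import _null_probabilities
        p = _null_probabilities(A, "degree_probabilistic")
        np.testing.assert_allclose(p.sum(), A.sum(), rtol=1e-12)

    def test_significance_rate_under_own_null(self):
        """Matrices drawn from the null are declared significant at the
        z > 1.645 one-tailed threshold at roughly the nominal 5% rate."""
        rng = np.random.default_rng(6)
        A = (rng.random((20, 20)) < 0.3).astype(float)
        ens = null_ensemble(A, metric="nodf", n=1000, seed=30)
        p = A.sum() / A.size
        n_draws = 2000
        hits = 0
        for _ in range(n_draws):
            rep = (rng.random(A.shape) < p).astype(float)
            z = (nodf(rep) - ens.mean) / ens.sd
            hits += z > 1.645
        rate = hits / n_draws
        se = np.sqrt(0.05 * 0.95 / n_draws)
        assert abs(rate - 0.05) < 2 * se


class TestZAndRelative:
    def test_z_examples(self):
        ens = NullEnsemble("equiprobable", "nodf", np.array([10.0, 20.0, 30.0]))
        z, sig = z_score_one_tailed(ens.mean, ens)
        assert z == 0.0 and not sig
        z, sig = z_score_one_tailed(ens.mean + 2 * ens.sd, ens)
        assert z == pytest.approx(2.0) and sig

    def test_threshold_is_strict(self):
        ens = NullEnsemble("equiprobable", "nodf", np.array([0.0, 2.0]))
        z, sig = z_score_one_tailed(ens.mean + 1.645 * ens.sd, ens)
        assert z == pytest.approx(1.645) and not sig

    @pytest.mark.parametrize("obs,mean,expected", [
        (5.0, 5.0, 0.0), (10.0, 5.0, 1.0), (0.0, 5.0, -1.0)])
    def test_relative_metric(self, obs, mean, expected):
        assert relative_metric(obs, mean) == pytest.approx(expected)

    def test_relative_metric_needs_positive_null_mean(self):
        with pytest.raises(ValueError):
            relative_metric(1.0, 0.0)


# ---------------------------------------------------------------------------
# plant statistics and correlations
# ---------------------------------------------------------------------------

class TestPlantStats:
    def test_degree_centralities(self):
        mats, params = make_system(seed=20, S=6)
        mats.theta_mp[:, 0] = 1.0  # plant 0 linked to every pollinator
        mats.theta_hp[:, 1] = 0.0
        mats.theta_hp[0, 1] = 1.0  # plant 1 has 1 of 6 herbivores
        eq = integrate_to_equilibrium(CommunityState.uniform(mats), mats, params)
        table = plant_stats(mats, eq, params)
        assert table.loc[0, "d_mut"] == 1.0
        assert table.loc[1, "d_ant"] == pytest.approx(1 / 6)

    def test_budget_columns_match_energy_budgets(self):
        mats, params = make_system(seed=21, S=5)
        eq = integrate_to_equilibrium(CommunityState.uniform(mats), mats, params)
        table = plant_stats(mats, eq, params)
        b_mut, b_ant = energy_budgets(eq.state, mats, params)
        np.testing.assert_array_equal(table["b_mut"].to_numpy(), b_mut)
        np.testing.assert_array_equal(table["b_ant"].to_numpy(), b_ant)


class TestCorrelationSuite:
    @staticmethod
    def _table(d_mut, d_ant, b_mut, b_ant):
        d_mut, d_ant = np.asarray(d_mut, float), np.asarray(d_ant, float)
        b_mut, b_ant = np.asarray(b_mut, float), np.asarray(b_ant, float)
        return pd.DataFrame({
            "d_mut": d_mut, "d_ant": d_ant, "b_mut": b_mut, "b_ant": b_ant,
            "d_diff": d_mut - d_ant, "b_diff": b_mut - b_ant,
        })

    def test_perfect_monotone_pair(self):
        t = self._table([0.1, 0.2, 0.3, 0.4], [0.2, 0.5, 0.6, 0.9],
                        np.zeros(4), np.zeros(4))
        t["b_diff"] = [1, 2, 3, 4.0]
        out = correlation_suite(t)
        assert out["spearman_dd"] == pytest.approx(1.0)

    def test_exact_linear_budget_relationship(self):
        d_diff = np.array([-0.2, 0.0, 0.1, 0.4])
        t = self._table([0.1, 0.2, 0.4, 0.8], [0.3, 0.2, 0.3, 0.4],
                        2 * d_diff, np.zeros(4))
        t["d_diff"] = d_diff
        t["b_diff"] = 2 * d_diff
        out = correlation_suite(t)
        assert out["slope_db"] == pytest.approx(2.0)
        assert out["r2_db"] == pytest.approx(1.0)

    def test_zero_variance_is_flagged(self):
        t = self._table([0.5] * 4, [0.1, 0.2, 0.3, 0.4], np.zeros(4), np.zeros(4))
        assert correlation_suite(t)["degenerate"]

    def test_too_few_plants_rejected(self):
        t = self._table([0.1, 0.2], [0.3, 0.4], [0, 0], [0, 0])
        with pytest.raises(ValueError):
            correlation_suite(t)

    @pytest.mark.parametrize("seed", range(10))
    def test_spearman_matches_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        d_mut = rng.integers(0, 6, n) / 6  # discrete, with ties
        d_ant = rng.integers(0, 6, n) / 6
        if d_mut.std() == 0 or d_ant.std() == 0 or (d_mut - d_ant).std() == 0:
            return
        b_mut, b_ant = rng.random(n), rng.random(n)
        out = correlation_suite(self._table(d_mut, d_ant, b_mut, b_ant))
        assert out["spearman_dd"] == pytest.approx(
            spearman_oracle(d_mut, d_ant), abs=1e-12)
        assert out["spearman_db"] == pytest.approx(
            spearman_oracle(d_mut - d_ant, b_mut - b_ant), abs=1e-12)


class TestStructureReport:
    def test_report_without_nulls(self):
        mats, _ = make_system(seed=22, S=6)
        rep = structure_report(mats, n_null=0, seed=1)
        assert 0 <= rep.N_mut <= 100
        assert rep.Q_mut >= 0
        assert rep.z_N_mut is None

    def test_report_flags_match_threshold(self):
        mats, _ = make_system(seed=23, S=8)
        rep = structure_report(mats, n_null=50, seed=2)
        for name in ("N_mut", "N_ant", "Q_mut", "Q_ant"):
            z = getattr(rep, f"z_{name}")
            sig = getattr(rep, f"sig_{name}")
            if z is not None:
                assert sig == (z > 1.645)
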