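"""Structural and statistical analysis of bipartite incidence matrices.

Implements the metric suite used to characterise the mutualistic and
antagonistic sub-networks: NODF nestedness (paired overlap with strictly
decreasing fill, 0-100 scale), Barber's bipartite modularity maximised by a
BRIM-style label-update heuristic with refinement, null-model ensembles
(equiprobable and degree-probabilistic) with one-tailed z-tests at the
1.645 threshold, relative nestedness/modularity, per-plant degree
centralities and energy budgets, and the Spearman/least-squares correlation
suite relating a plant's roles in the two sub-networks.

All metrics operate on the *binary* incidence matrices; quantitative
interaction strengths never enter the structural analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import EquilibriumResult, energy_budgets
from .niche import InteractionMatrices, ModelParams

__all__ = [
    "NullEnsemble",
    "StructureReport",
    "nodf",
    "barber_modularity",
    "modularity_value",
    "null_ensemble",
    "z_score_one_tailed",
    "relative_metric",
    "structure_report",
    "plant_stats",
    "correlation_suite",
    "Z_THRESHOLD",
]

#: one-tailed significance threshold (upper 5% point of the standard normal)
Z_THRESHOLD = 1.645


# ---------------------------------------------------------------------------
# nestedness
# ---------------------------------------------------------------------------

def nodf(matrix: np.ndarray) -> float:
    """NODF nestedness of a binary matrix on the 0-100 scale.

    For every unordered pair of rows (and of columns) the pair contributes
    the paired overlap — shared links divided by the smaller marginal total
    — when the two marginal totals differ (decreasing fill), and exactly 0
    when they are equal or the smaller is empty. The score is the average
    contribution over all row and column pairs, scaled to [0, 100]. The
    definition is symmetric under transposition and invariant to row/column
    permutations.
    """
    A = np.asarray(matrix)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("NODF requires a matrix with >= 2 rows and >= 2 columns")
    A = (A != 0).astype(float)
    if A.sum() == 0:
        warnings.warn("NODF of an all-zero matrix is defined as 0", stacklevel=2)
        return 0.0

    def _axis_sum(B: np.ndarray) -> float:
        k = B.sum(axis=1)
        overlap = B @ B.T
        kmin = np.minimum(k[:, None], k[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(
                (k[:, None] != k[None, :]) & (kmin > 0), overlap / kmin, 0.0
            )
        iu = np.triu_indices(B.shape[0], k=1)
        return float(contrib[iu].sum())

    n_r, n_c = A.shape
    n_pairs = n_r * (n_r - 1) / 2 + n_c * (n_c - 1) / 2
    return 100.0 * (_axis_sum(A) + _axis_sum(A.T)) / n_pairs


# ---------------------------------------------------------------------------
# Barber bipartite modularity
# ---------------------------------------------------------------------------

def modularity_value(A: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber's bipartite Q for a given module assignment.

    Q = (1/m) * sum_ij (A_ij - k_i d_j / m) * [row i and column j share a
    module], with m the number of links and k, d the marginal totals.
    """
    A = (np.asarray(A) != 0).astype(float)
    m = A.sum()
    if m == 0:
        raise ValueError("modularity is undefined for an empty matrix")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    q = 0.0
    for lab in np.union1d(row_labels, col_labels):
        rows = row_labels == lab
        cols = col_labels == lab
        if rows.any() and cols.any():
            q += A[np.ix_(rows, cols)].sum() / m - (
                k[rows].sum() * d[cols].sum()
            ) / m**2
    return float(q)


def _brim_alternate(B: np.ndarray, row: np.ndarray, col: np.ndarray, K: int):
    """Alternate optimal row labels given column labels and vice versa until
    stable. Each half-update is exactly optimal because module shares are
    additive over nodes of one side when the other side is fixed."""
    n_r, n_c = B.shape
    for _ in range(200):
        C = np.zeros((n_c, K))
        C[np.arange(n_c), col] = 1.0
        row_new = np.argmax(B @ C, axis=1)
        R = np.zeros((n_r, K))
        R[np.arange(n_r), row_new] = 1.0
        col_new = np.argmax(B.T @ R, axis=1)
        if np.array_equal(row_new, row) and np.array_equal(col_new, col):
            break
        row, col = row_new, col_new
    return row, col


def _best_merge(B: np.ndarray, row: np.ndarray, col: np.ndarray):
    """Best pairwise module merge and its Q gain (times m)."""
    labels = np.union1d(row, col)
    best_gain, best_pair = 0.0, None
    for a_idx in range(labels.size):
        for b_idx in range(a_idx + 1, labels.size):
            la, lb = labels[a_idx], labels[b_idx]
            r_a, c_a = row == la, col == la
            r_b, c_b = row == lb, col == lb
            gain = 0.0
            if r_a.any() and c_b.any():
                gain += B[np.ix_(r_a, c_b)].sum()
            if r_b.any() and c_a.any():
                gain += B[np.ix_(r_b, c_a)].sum()
            if gain > best_gain + 1e-12:
                best_gain, best_pair = gain, (la, lb)
    return best_pair


def barber_modularity(matrix: np.ndarray, n_restarts: int = 20, seed=None):
    """Maximise Barber's bipartite modularity heuristically.

    Each of ``n_restarts`` runs starts from a random column partition
    (module count capped at min(rows, cols)), alternates optimal one-sided
    label updates (BRIM) to a local optimum, then greedily merges module
    pairs whenever merging raises Q, re-running the alternation after every
    merge. The best ``(Q, (row_labels, col_labels))`` over restarts is
    returned; Q of the single-module partition is 0 by construction, so the
    result is always >= 0.
    """
    A = (np.asarray(matrix) != 0).astype(float)
    if A.ndim != 2 or A.sum() == 0:
        raise ValueError("modularity requires a 2-d matrix with at least one link")
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / m
    K = max(2, min(A.shape))
    rng = np.random.default_rng(seed)
    best_q = 0.0  # single-module baseline
    best_part = (np.zeros(A.shape[0], dtype=np.int64), np.zeros(A.shape[1], dtype=np.int64))
    for _ in range(n_restarts):
        col = rng.integers(K, size=A.shape[1])
        row = np.zeros(A.shape[0], dtype=np.int64)
        row, col = _brim_alternate(B, row, col, K)
        while True:
            pair = _best_merge(B, row, col)
            if pair is None:
                break
            la, lb = pair
            row = np.where(row == lb, la, row)
            col = np.where(col == lb, la, col)
            row, col = _brim_alternate(B, row, col, K)
        q = modularity_value(A, row, col)
        if q > best_q + 1e-12:
            best_q, best_part = q, (row, col)
    return best_q, best_part


# ---------------------------------------------------------------------------
# null models and z-tests
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Metric values over randomised replicates of an incidence matrix."""

    model_name: str
    metric: str
    values: np.ndarray
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a null ensemble needs at least 2 replicates")

    @property
    def n_replicates(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


def _null_probabilities(A: np.ndarray, model_name: str) -> np.ndarray:
    n_r, n_c = A.shape
    if model_name == "equiprobable":
        return np.full((n_r, n_c), A.sum() / A.size)
    if model_name == "degree_probabilistic":
        k = A.sum(axis=1) / n_c
        d = A.sum(axis=0) / n_r
        return (k[:, None] + d[None, :]) / 2.0
    raise ValueError(f"unknown null model {model_name!r}")


def null_ensemble(
    matrix: np.ndarray,
    metric: str = "nodf",
    model_name: str = "equiprobable",
    n: int = 1000,
    seed=None,
    n_restarts: int = 20,
) -> NullEnsemble:
    """Metric distribution over ``n`` null randomisations of ``matrix``.

    The equiprobable model fills every cell with probability equal to the
    realised connectance; the degree-probabilistic model uses cell
    probability (k_i/n_cols + d_j/n_rows)/2, preserving expected marginal
    totals. Replicates on which the metric is undefined (all-zero draws)
    are redrawn and counted.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if metric not in ("nodf", "modularity"):
        raise ValueError(f"unknown metric {metric!r}")
    A = (np.asarray(matrix) != 0).astype(float)
    p = _null_probabilities(A, model_name)
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    n_redrawn = 0
    for i in range(n):
        while True:
            rep = (rng.random(A.shape) < p).astype(float)
            if rep.sum() > 0:
                break
            n_redrawn += 1
        if metric == "nodf":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values[i] = nodf(rep)
        else:
            values[i], _ = barber_modularity(
                rep, n_restarts=n_restarts, seed=rng.integers(2**31))
    return NullEnsemble(model_name=model_name, metric=metric,
                        values=values, n_redrawn=n_redrawn)


def z_score_one_tailed(observed: float, ensemble: NullEnsemble):
    """One-tailed z-test of an observed metric against a null ensemble.

    Returns ``(z, significant)`` with ``z = (observed - mean)/sd`` and
    significance declared for ``z`` strictly above 1.645.
    """
    sd = ensemble.sd
    if sd == 0:
        raise ValueError("z-score undefined: null ensemble has zero spread")
    z = (observed - ensemble.mean) / sd
    return float(z), bool(z > Z_THRESHOLD)


def relative_metric(observed: float, null_mean: float) -> float:
    """Relative departure (observed - null mean) / null mean."""
    if null_mean <= 0:
        raise ValueError("relative metric undefined for null mean <= 0")
    return (observed - null_mean) / null_mean


@dataclass
class StructureReport:
    """Nestedness and modularity of both sub-networks with null statistics."""

    N_mut: float
    N_ant: float
    Q_mut: float
    Q_ant: float
    z_N_mut: float | None = None
    z_N_ant: float | None = None
    z_Q_mut: float | None = None
    z_Q_ant: float | None = None
    N_rel_mut: float | None = None
    N_rel_ant: float | None = None
    Q_rel_mut: float | None = None
    Q_rel_ant: float | None = None
    sig_N_mut: bool | None = None
    sig_N_ant: bool | None = None
    sig_Q_mut: bool | None = None
    sig_Q_ant: bool | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def structure_report(
    mats: InteractionMatrices,
    n_null: int = 1000,
    model_name: str = "equiprobable",
    seed=None,
    n_restarts: int = 20,
) -> StructureReport:
    """Full structural report for one community.

    Computes NODF and Barber Q of both incidence matrices; with
    ``n_null >= 2`` also the null-ensemble z-scores (one-tailed, threshold
    1.645) and relative metrics. ``n_null=0`` skips the null analysis.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_q1, s_q2, *s_null = ss.spawn(6)
    q_mut, _ = barber_modularity(mats.theta_mp, n_restarts=n_restarts, seed=s_q1)
    q_ant, _ = barber_modularity(mats.theta_hp, n_restarts=n_restarts, seed=s_q2)
    rep = StructureReport(
        N_mut=nodf(mats.theta_mp), N_ant=nodf(mats.theta_hp),
        Q_mut=q_mut, Q_ant=q_ant,
    )
    if n_null >= 2:
        specs = [
            ("N_mut", mats.theta_mp, "nodf", rep.N_mut),
            ("N_ant", mats.theta_hp, "nodf", rep.N_ant),
            ("Q_mut", mats.theta_mp, "modularity", rep.Q_mut),
            ("Q_ant", mats.theta_hp, "modularity", rep.Q_ant),
        ]
        for (name, theta, metric, obs), s in zip(specs, s_null):
            ens = null_ensemble(theta, metric=metric, model_name=model_name,
                                n=n_null, seed=s, n_restarts=n_restarts)
            try:
                z, sig = z_score_one_tailed(obs, ens)
            except ValueError:
                z, sig = None, None
            setattr(rep, f"z_{name}", z)
            setattr(rep, f"sig_{name}", sig)
            try:
                setattr(rep, f"{'N_rel' if name.startswith('N') else 'Q_rel'}"
                             f"_{name.split('_')[1]}",
                        relative_metric(obs, ens.mean))
            except ValueError:
                pass
    return rep


# ---------------------------------------------------------------------------
# per-plant statistics and correlations
# ---------------------------------------------------------------------------

def plant_stats(
    mats: InteractionMatrices,
    eq: EquilibriumResult,
    params: ModelParams,
) -> pd.DataFrame:
    """Per-plant degree centralities, energy budgets and biomass.

    ``d_mut`` (``d_ant``) is the plant's pollinator (herbivore) partner
    count divided by the guild size, i.e. degree over maximum possible
    degree; ``b_mut``/``b_ant`` are the per-capita energy intake and loss
    at the supplied equilibrium.
    """
    d_mut = mats.theta_mp.sum(axis=0) / mats.S_M
    d_ant = mats.theta_hp.sum(axis=0) / mats.S_H
    b_mut, b_ant = energy_budgets(eq.state, mats, params)
    return pd.DataFrame({
        "plant": np.arange(mats.S_P),
        "d_mut": d_mut,
        "d_ant": d_ant,
        "b_mut": b_mut,
        "b_ant": b_ant,
        "biomass": eq.state.P,
        "d_diff": d_mut - d_ant,
        "b_diff": b_mut - b_ant,
    })


def correlation_suite(table: pd.DataFrame) -> dict:
    """Correlation and regression summary of a plant-statistics table.

    Reports the Spearman correlation (average ranks on ties) between the
    two degree centralities, the least-squares fit of the energy-budget
    difference on the degree difference (slope and r^2), the r^2 of the
    d_mut ~ d_ant regression, and the Spearman correlation of the
    difference pair. Degenerate inputs (zero variance) yield NaNs with
    ``degenerate=True``.
    """
    if len(table) < 3:
        raise ValueError("correlation suite requires >= 3 plants")
    d_mut = table["d_mut"].to_numpy()
    d_ant = table["d_ant"].to_numpy()
    d_diff = table["d_diff"].to_numpy()
    b_diff = table["b_diff"].to_numpy()
    out = {
        "spearman_dd": np.nan, "spearman_db": np.nan,
        "slope_db": np.nan, "r2_db": np.nan, "r2_dd": np.nan,
        "p_spearman_dd": np.nan, "degenerate": False,
    }
    if d_mut.std() == 0 or d_ant.std() == 0 or d_diff.std() == 0:
        out["degenerate"] = True
        return out
    rho_dd, p_dd = stats.spearmanr(d_mut, d_ant)
    out["spearman_dd"] = float(rho_dd)
    out["p_spearman_dd"] = float(p_dd)
    lin_dd = stats.linregress(d_mut, d_ant)
    out["r2_dd"] = float(lin_dd.rvalue**2)
    if b_diff.std() > 0:
        rho_db, _ = stats.spearmanr(d_diff, b_diff)
        out["spearman_db"] = float(rho_db)
        lin_db = stats.linregress(d_diff, b_diff)
        out["slope_db"] = float(lin_db.slope)
        out["r2_db"] = float(lin_db.rvalue**2)
    else:
        out["degenerate"] = True
    return out
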