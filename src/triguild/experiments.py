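"""Orchestration of the computational experiments.

Covers the interaction-strength sweep over a ternary simplex of 55
(Omega_c, Omega_p, Omega_m) combinations with replication, fixed-strength
line scans, asymmetric sub-network complexity scenarios, and a Latin
hypercube sensitivity design over the six remaining model parameters.
Each replicate builds a random community, records the pre-rewiring
("random-counterpart") equilibrium statistics, runs adaptive rewiring, and
records the same statistics for the adapted network, so that relative
quantities (adaptive minus random) are always recomputable from the stored
rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import correlation_suite, plant_stats, structure_report
from .niche import ModelParams, generate_community
from .rewiring import RewiringEngine, UnstableNetworkError

__all__ = [
    "SweepDesign",
    "ReplicateResult",
    "enumerate_strength_grid",
    "run_replicate",
    "run_sweep",
    "aggregate_sweep",
    "asymmetric_scenarios",
    "lhs_sensitivity",
]

log = logging.getLogger(__name__)

OMEGA_C_STEP = 0.01
OMEGA_MP_STEP = 0.035
SIMPLEX_ORDER = 9  # compositions a+b+c = 9 give C(11, 2) = 55 grid points


@dataclass
class SweepDesign:
    """A list of design points with replication and seeding policy.

    Each point is a dict carrying at least ``omega_c``, ``omega_p``,
    ``omega_m`` and optionally per-point structural overrides (guild sizes,
    connectances, or any :class:`ModelParams` field).
    """

    points: list = field(default_factory=list)
    replicates: int = 60
    base_seed: int = 0
    scenario: str = "symmetric"

    def __len__(self) -> int:
        return len(self.points)


def enumerate_strength_grid() -> SweepDesign:
    """The default 55-point interaction-strength grid.

    Indexed by integer compositions a + b + c = 9 (a, b, c >= 0) mapped as
    Omega_c = 0.01 (a+1), Omega_p = 0.035 (b+1), Omega_m = 0.035 (c+1),
    giving a ternary-simplex grid whose margins span Omega_c in
    [0.01, 0.1] step 0.01 and Omega_p, Omega_m in [0.035, 0.35] step 0.035.
    """
    points = []
    for a in range(SIMPLEX_ORDER + 1):
        for b in range(SIMPLEX_ORDER + 1 - a):
            c = SIMPLEX_ORDER - a - b
            points.append({
                "omega_c": round(OMEGA_C_STEP * (a + 1), 10),
                "omega_p": round(OMEGA_MP_STEP * (b + 1), 10),
                "omega_m": round(OMEGA_MP_STEP * (c + 1), 10),
            })
    assert len({tuple(sorted(p.items())) for p in points}) == len(points)
    return SweepDesign(points=points, scenario="symmetric")


def _point_params(base: ModelParams, point: dict) -> ModelParams:
    overrides = {k: v for k, v in point.items()
                 if k in ModelParams.__dataclass_fields__}
    return replace(base, **overrides)


@dataclass
class ReplicateResult:
    """Flat record of one replicate at one design point."""

    row: dict

    def to_dict(self) -> dict:
        return dict(self.row)


def replicate_seed(base_seed: int, design_index: int, replicate_index: int,
                   redraw: int = 0) -> np.random.SeedSequence:
    """Deterministic child seed for (design point, replicate)."""
    return np.random.SeedSequence(
        entropy=base_seed, spawn_key=(design_index, replicate_index, redraw))


def run_replicate(
    point: dict,
    seed,
    base_params: ModelParams | None = None,
    S_P: int = 30,
    S_M: int = 30,
    S_H: int = 30,
    n_attempts: int = 100_000,
    n_null: int = 0,
    max_redraws: int = 10,
    snapshot_every: int = 1000,
    design_index: int = 0,
    replicate_index: int = 0,
) -> ReplicateResult:
    """Build, equilibrate, rewire and measure one community.

    Records the pre-rewiring equilibrium ("random" columns) and the
    post-rewiring equilibrium ("adaptive" columns) side by side. A
    community whose initial equilibrium is not locally stable is logged and
    redrawn with the next sub-seed, up to ``max_redraws`` times.
    ``n_null`` > 1 adds null-model z-scores to the structure reports.
    """
    params = _point_params(base_params or ModelParams(), point)
    S_M_pt = int(point.get("S_M", S_M))
    S_H_pt = int(point.get("S_H", S_H))
    S_P_pt = int(point.get("S_P", S_P))
    last_err = None
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(int(seed)))
    sub_seeds = root.spawn(max_redraws)
    for redraw in range(max_redraws):
        s_comm, s_rewire, s_struct_r, s_struct_a = sub_seeds[redraw].spawn(4)
        mats = generate_community(
            params, S_P=S_P_pt, S_M=S_M_pt, S_H=S_H_pt, seed=s_comm)
        try:
            engine = RewiringEngine(
                mats.copy(), params, seed=s_rewire,
                snapshot_every=snapshot_every, record_attempts=False,
            )
        except UnstableNetworkError as err:
            last_err = err
            log.warning("replicate redrawn (unstable initial network): %s", err)
            continue
        eq_random = engine.eq
        stats_r = plant_stats(engine.mats, eq_random, params)
        corr_r = correlation_suite(stats_r)
        struct_r = structure_report(engine.mats, n_null=n_null, seed=s_struct_r)
        traj = engine.run(n_attempts)
        eq_adapt = traj.final_eq
        stats_a = plant_stats(engine.mats, eq_adapt, params)
        corr_a = correlation_suite(stats_a)
        struct_a = structure_report(engine.mats, n_null=n_null, seed=s_struct_a)
        res_a = eq_adapt.resilience
        res_r = eq_random.resilience
        row = {
            "design_index": design_index,
            "replicate_index": replicate_index,
            "n_redraws": redraw,
            "omega_c": params.omega_c,
            "omega_p": params.omega_p,
            "omega_m": params.omega_m,
            "S_P": S_P_pt, "S_M": S_M_pt, "S_H": S_H_pt,
            "C_mut": params.C_mut, "C_ant": params.C_ant,
            "n_attempts": n_attempts,
            "n_accepted": traj.n_accepted,
            "n_proposed": traj.n_proposed,
            "log_complexity_mut": math.log(S_M_pt * params.C_mut),
            "log_complexity_ant": math.log(S_H_pt * params.C_ant),
            "resilience_adaptive": res_a,
            "resilience_random": res_r,
            "relative_resilience": (
                res_a - res_r if res_a is not None and res_r is not None else None
            ),
            "min_biomass_adaptive": eq_adapt.min_biomass,
            "min_biomass_random": eq_random.min_biomass,
            "total_P": float(eq_adapt.state.P.sum()),
            "total_M": float(eq_adapt.state.M.sum()),
            "total_H": float(eq_adapt.state.H.sum()),
            "total_P_random": float(eq_random.state.P.sum()),
            "total_M_random": float(eq_random.state.M.sum()),
            "total_H_random": float(eq_random.state.H.sum()),
        }
        for label, struct in (("random", struct_r), ("adaptive", struct_a)):
            for key, val in struct.to_dict().items():
                row[f"{key}_{label}"] = val
        for label, corr in (("random", corr_r), ("adaptive", corr_a)):
            for key, val in corr.items():
                row[f"{key}_{label}"] = val
        return ReplicateResult(row=row)
    raise RuntimeError(
        f"no locally stable initial network in {max_redraws} redraws: {last_err}")


def _entropy_of(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        ent = seed.entropy
        return ent if isinstance(ent, int) else int(ent[0])
    return int(seed)


def run_sweep(
    design: SweepDesign,
    n_jobs: int = 1,
    **replicate_kwargs,
) -> pd.DataFrame:
    """All replicates of a sweep as one tidy DataFrame.

    Replicates are independent and seeded from ``(base_seed, design index,
    replicate index)``, so parallel execution (``n_jobs > 1``, via joblib)
    is byte-identical to serial execution.
    """
    tasks = [
        (di, ri, point)
        for di, point in enumerate(design.points)
        for ri in range(design.replicates)
    ]

    def _one(di, ri, point):
        seed = replicate_seed(design.base_seed, di, ri)
        res = run_replicate(
            point, seed, design_index=di, replicate_index=ri,
            **replicate_kwargs,
        )
        return res.to_dict()

    if n_jobs == 1:
        rows = [_one(*t) for t in tasks]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_one)(*t) for t in tasks)
    return pd.DataFrame(rows)


def aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per design point of every numeric replicate column."""
    numeric = df.select_dtypes("number").columns.difference(
        ["design_index", "replicate_index"])
    grouped = df.groupby("design_index")[list(numeric)]
    agg = grouped.agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


def asymmetric_scenarios(
    base_params: ModelParams,
    vary: str,
    levels: list[tuple[int, float]],
) -> SweepDesign:
    """Design points with unequal sub-network size and connectance.

    ``vary`` selects which sub-network changes ("mutualistic" varies
    {S_M, C_mut}; "antagonistic" varies {S_H, C_ant}); the other
    sub-network keeps the baseline complexity. The natural-log complexity
    covariate log(S * C) is attached to each point.
    """
    if vary not in ("mutualistic", "antagonistic"):
        raise ValueError("vary must be 'mutualistic' or 'antagonistic'")
    if not levels:
        raise ValueError("at least one (S, C) level is required")
    points = []
    for S, C in levels:
        if S <= 0 or C <= 0:
            raise ValueError("sub-network size and connectance must be positive")
        if vary == "mutualistic":
            point = {"S_M": int(S), "C_mut": float(C),
                     "log_complexity_varied": math.log(S * C)}
        else:
            point = {"S_H": int(S), "C_ant": float(C),
                     "log_complexity_varied": math.log(S * C)}
        point.update(
            omega_c=base_params.omega_c,
            omega_p=base_params.omega_p,
            omega_m=base_params.omega_m,
        )
        points.append(point)
    return SweepDesign(points=points, scenario="asymmetric")


LHS_PARAMETERS = ("S", "C", "r", "h", "eps", "sigma")


def lhs_sensitivity(
    baseline: ModelParams,
    S_baseline: int = 30,
    frac: float = 0.3,
    n: int = 10,
    seed=0,
) -> SweepDesign:
    """Latin hypercube design over six parameters within +/- ``frac``.

    Dimensions are guild size S (applied to all three guilds, rounded to
    the nearest integer >= 2), connectance C (applied to both
    sub-networks), growth rate r (all guilds), half-saturation constant h,
    conversion efficiency eps, and niche breadth sigma. Each of the ``n``
    equal-probability strata of every dimension is used exactly once.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    base_values = {
        "S": float(S_baseline),
        "C": baseline.C_mut,
        "r": baseline.r_P,
        "h": baseline.h,
        "eps": baseline.eps,
        "sigma": baseline.sigma,
    }
    # stratified samples: one point per stratum per dimension, strata permuted
    unit = np.empty((n, len(LHS_PARAMETERS)))
    strata = np.empty((n, len(LHS_PARAMETERS)), dtype=int)
    for j in range(len(LHS_PARAMETERS)):
        perm = rng.permutation(n)
        strata[:, j] = perm
        unit[:, j] = (perm + rng.random(n)) / n
    points = []
    for i in range(n):
        point = {"omega_c": baseline.omega_c, "omega_p": baseline.omega_p,
                 "omega_m": baseline.omega_m}
        for j, name in enumerate(LHS_PARAMETERS):
            lo = base_values[name] * (1 - frac)
            hi = base_values[name] * (1 + frac)
            val = lo + unit[i, j] * (hi - lo)
            if name == "S":
                S = max(2, int(round(val)))
                point.update(S_P=S, S_M=S, S_H=S)
            elif name == "C":
                point.update(C_mut=val, C_ant=val)
            elif name == "r":
                point.update(r_P=val, r_M=val, r_H=val)
            elif name == "eps":
                point["eps"] = min(val, 1.0)
            else:
                point[name] = val
            point[f"stratum_{name}"] = int(strata[i, j])
        points.append(point)
    return SweepDesign(points=points, scenario="lhs", base_seed=_entropy_of(seed))
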