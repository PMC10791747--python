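"""Lotka-Volterra dynamics of the three-guild network.

The biomass of plant i (P_i), pollinator i (M_i) and herbivore i (H_i)
follows a Lotka-Volterra system with within-guild competition and type II
(saturating) cross-guild functional responses:

    dP_i/dt = P_i ( r_P - sum_j beta^P_ij P_j
                    + sum_j gamma_ij M_j / (1 + h * sum_{k in mut(P_i)} M_k)
                    - sum_j tau_ij  H_j / (1 + h * sum_{k in ant(H_j)} P_k) )
    dM_i/dt = M_i ( r_M - sum_j beta^M_ij M_j
                    + sum_j gamma_ji P_j / (1 + h * sum_{k in mut(M_i)} P_k) )
    dH_i/dt = H_i ( r_H - sum_j beta^H_ij H_j
                    + eps * sum_j tau_ji P_j / (1 + h * sum_{k in ant(H_i)} P_k) )

``mut(x)`` / ``ant(x)`` are the cross-guild partner sets given by the binary
incidence matrices. Note the asymmetry in the plant equation: the herbivory
loss saturates over the plant partners of herbivore j (each herbivore's
intake is divided among *its* plants), not over plant i's own herbivores.

Stability at an equilibrium X* is read off the community Jacobian
J = diag(g) + diag(X*) dg/dX (g the per-capita growth vector); the system is
locally stable when all eigenvalues have negative real part, and resilience
— the asymptotic recovery rate after a small perturbation — is
|max Re(lambda)|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .niche import InteractionMatrices, ModelParams

__all__ = [
    "CommunityState",
    "EquilibriumResult",
    "IntegrationError",
    "rhs",
    "analytic_jacobian",
    "integrate_to_equilibrium",
    "stability_from_jacobian",
    "resilience",
    "energy_budgets",
]

#: biomass floor applied after every integration chunk; species are clamped
#: here rather than removed so that community dimensions stay fixed.
BIOMASS_FLOOR = 1e-9


@dataclass
class CommunityState:
    """Biomass vectors of the three guilds at model time ``t``."""

    P: np.ndarray
    M: np.ndarray
    H: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.H = np.asarray(self.H, dtype=float)

    @classmethod
    def uniform(cls, mats: InteractionMatrices, value: float = 1.0) -> "CommunityState":
        return cls(
            P=np.full(mats.S_P, value),
            M=np.full(mats.S_M, value),
            H=np.full(mats.S_H, value),
        )

    @classmethod
    def from_vector(cls, x: np.ndarray, S_P: int, S_M: int, t: float = 0.0) -> "CommunityState":
        x = np.asarray(x, dtype=float)
        return cls(P=x[:S_P], M=x[S_P:S_P + S_M], H=x[S_P + S_M:], t=t)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.P, self.M, self.H])

    @property
    def min_biomass(self) -> float:
        return float(self.vector.min())

    def copy(self) -> "CommunityState":
        return CommunityState(self.P.copy(), self.M.copy(), self.H.copy(), self.t)


@dataclass
class EquilibriumResult:
    """Outcome of an equilibration: final state plus local-stability report.

    ``resilience`` is defined only when the equilibrium is locally stable,
    in which case it equals ``-leading_eigen_real > 0``; otherwise ``None``.
    """

    state: CommunityState
    converged: bool
    locally_stable: bool
    leading_eigen_real: float
    resilience: float | None
    min_biomass: float
    jacobian: np.ndarray | None = None
    n_floored: int = 0


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last valid state."""

    def __init__(self, message: str, state: CommunityState):
        super().__init__(message)
        self.state = state


def _percapita_growth(x, mats: InteractionMatrices, params: ModelParams):
    """Per-capita growth vector g and the caches needed by the Jacobian."""
    sp, sm = mats.S_P, mats.S_M
    P, M, H = x[:sp], x[sp:sp + sm], x[sp + sm:]
    h = params.h
    D_P = 1.0 + h * (mats.theta_mp.T @ M)  # per-plant pollinator saturation
    D_M = 1.0 + h * (mats.theta_mp @ P)    # per-pollinator plant saturation
    D_H = 1.0 + h * (mats.theta_hp @ P)    # per-herbivore plant saturation
    mut_gain_P = mats.gamma @ M            # raw plant mutualistic intake
    mut_gain_M = mats.gamma.T @ P
    ant_gain_H = mats.tau.T @ P
    gP = params.r_P - mats.beta_P @ P + mut_gain_P / D_P - mats.tau @ (H / D_H)
    gM = params.r_M - mats.beta_M @ M + mut_gain_M / D_M
    gH = params.r_H - mats.beta_H @ H + params.eps * ant_gain_H / D_H
    g = np.concatenate([gP, gM, gH])
    caches = (P, M, H, D_P, D_M, D_H, mut_gain_P, mut_gain_M, ant_gain_H)
    return g, caches


def rhs(state: CommunityState, mats: InteractionMatrices, params: ModelParams) -> np.ndarray:
    """Time derivative of all biomasses, ordered plants, pollinators, herbivores."""
    x = state.vector
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("state contains non-finite biomasses")
    g, _ = _percapita_growth(x, mats, params)
    return x * g


def _rhs_vec(x, mats, params):
    g, _ = _percapita_growth(x, mats, params)
    return x * g


def analytic_jacobian(
    state: CommunityState, mats: InteractionMatrices, params: ModelParams
) -> np.ndarray:
    """Exact Jacobian of the full system at ``state``.

    Includes the quotient-rule terms from the type II denominators; in
    particular the derivative of plant i's herbivory loss with respect to
    plant k != i is nonzero whenever both plants feed a common herbivore.
    """
    x = state.vector
    return _jacobian_vec(x, mats, params)


def _jacobian_vec(x, mats: InteractionMatrices, params: ModelParams) -> np.ndarray:
    sp, sm, sh = mats.S_P, mats.S_M, mats.S_H
    h, eps = params.h, params.eps
    g, (P, M, H, D_P, D_M, D_H, mut_gain_P, mut_gain_M, ant_gain_H) = _percapita_growth(
        x, mats, params
    )
    # blocks of dg/dX
    G_PP = -mats.beta_P + (mats.tau * (h * H / D_H**2)[None, :]) @ mats.theta_hp
    G_PM = mats.gamma / D_P[:, None] - (
        (h * mut_gain_P / D_P**2)[:, None] * mats.theta_mp.T
    )
    G_PH = -mats.tau / D_H[None, :]
    G_MP = mats.gamma.T / D_M[:, None] - (
        (h * mut_gain_M / D_M**2)[:, None] * mats.theta_mp
    )
    G_MM = -mats.beta_M
    G_HP = eps * (
        mats.tau.T / D_H[:, None] - (h * ant_gain_H / D_H**2)[:, None] * mats.theta_hp
    )
    G_HH = -mats.beta_H
    n = sp + sm + sh
    G = np.zeros((n, n))
    G[:sp, :sp] = G_PP
    G[:sp, sp:sp + sm] = G_PM
    G[:sp, sp + sm:] = G_PH
    G[sp:sp + sm, :sp] = G_MP
    G[sp:sp + sm, sp:sp + sm] = G_MM
    G[sp + sm:, :sp] = G_HP
    G[sp + sm:, sp + sm:] = G_HH
    J = x[:, None] * G
    J[np.diag_indices(n)] += g
    return J


def stability_from_jacobian(J: np.ndarray):
    """(leading real part, locally_stable flag, resilience or None)."""
    lead = float(np.max(np.linalg.eigvals(J).real))
    stable = lead < 0
    return lead, stable, (-lead if stable else None)


def resilience(eq: EquilibriumResult) -> float | None:
    """Recovery rate |max Re(lambda)| when locally stable, else ``None``."""
    return eq.resilience


def integrate_to_equilibrium(
    state0: CommunityState,
    mats: InteractionMatrices,
    params: ModelParams,
    chunk: float = 50.0,
    max_time: float = 5000.0,
    tol: float = 1e-8,
    floor: float = BIOMASS_FLOOR,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    compute_stability: bool = True,
) -> EquilibriumResult:
    """Integrate in chunks until the per-species relative derivative is small.

    Integration proceeds in spans of length ``chunk`` (default 50, the
    interval between successive rewiring events) until
    ``|dX_i/dt| < tol * (1 + |X_i|)`` for every species, or ``max_time`` is
    reached. A biomass floor is applied after each chunk to species that
    entered the call with positive biomass; biomasses that are exactly zero
    are absorbing and stay zero. LSODA with the analytic Jacobian handles
    the stiffness arising at strong mutualism / high connectance.
    """
    if chunk <= 0 or tol <= 0:
        raise ValueError("chunk and tol must be > 0")
    x = state0.vector.copy()
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("initial biomasses must be finite and non-negative")
    alive = x > 0
    t0 = state0.t
    elapsed = 0.0
    converged = False

    def f(y, t):
        return _rhs_vec(y, mats, params)

    def jac(y, t):
        return _jacobian_vec(y, mats, params)

    while elapsed < max_time:
        span = min(chunk, max_time - elapsed)
        ys, info = odeint(
            f, x, [0.0, span], Dfun=jac, rtol=rtol, atol=atol,
            mxstep=10_000, full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE solver failed: {info['message']}",
                CommunityState.from_vector(x, mats.S_P, mats.S_M, t=t0 + elapsed),
            )
        x = ys[-1]
        np.maximum(x, floor, where=alive, out=x)
        x[~alive] = 0.0
        elapsed += span
        dx = _rhs_vec(x, mats, params)
        if np.all(np.abs(dx) < tol * (1.0 + np.abs(x))):
            converged = True
            break

    state = CommunityState.from_vector(x, mats.S_P, mats.S_M, t=t0 + elapsed)
    n_floored = int(np.count_nonzero(alive & (x <= floor)))
    if compute_stability:
        J = _jacobian_vec(x, mats, params)
        lead, stable, res = stability_from_jacobian(J)
    else:
        J, lead, stable, res = None, np.nan, False, None
    return EquilibriumResult(
        state=state,
        converged=converged,
        locally_stable=stable,
        leading_eigen_real=lead,
        resilience=res,
        min_biomass=state.min_biomass,
        jacobian=J,
        n_floored=n_floored,
    )


def simulate_trajectory(
    state0: CommunityState,
    mats: InteractionMatrices,
    params: ModelParams,
    t_max: float,
    stride: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Tidy biomass trajectory sampled every ``stride`` time units.

    Returns a DataFrame with columns (t, guild, species_index, biomass),
    suitable for direct CSV export; decimation is controlled by ``stride``.
    """
    import pandas as pd

    if t_max <= 0 or stride <= 0:
        raise ValueError("t_max and stride must be > 0")
    times = np.arange(0.0, t_max + 0.5 * stride, stride)
    ys, info = odeint(
        lambda y, t: _rhs_vec(y, mats, params), state0.vector, times,
        Dfun=lambda y, t: _jacobian_vec(y, mats, params),
        rtol=rtol, atol=atol, mxstep=10_000, full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"ODE solver failed: {info['message']}",
            CommunityState.from_vector(ys[-1], mats.S_P, mats.S_M))
    frames = []
    for guild, sl in (("plant", slice(0, mats.S_P)),
                      ("pollinator", slice(mats.S_P, mats.S_P + mats.S_M)),
                      ("herbivore", slice(mats.S_P + mats.S_M, None))):
        block = ys[:, sl]
        frames.append(pd.DataFrame({
            "t": np.repeat(times + state0.t, block.shape[1]),
            "guild": guild,
            "species_index": np.tile(np.arange(block.shape[1]), len(times)),
            "biomass": block.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def energy_budgets(
    state: CommunityState, mats: InteractionMatrices, params: ModelParams
):
    """Per-plant per-capita energy intake from pollination and loss to herbivory.

    ``b_mut[i]`` is plant i's saturating mutualistic intake and ``b_ant[i]``
    its herbivory loss — exactly the gain and loss terms of the plant growth
    equation, evaluated at ``state``.
    """
    h = params.h
    D_P = 1.0 + h * (mats.theta_mp.T @ state.M)
    D_H = 1.0 + h * (mats.theta_hp @ state.P)
    b_mut = (mats.gamma @ state.M) / D_P
    b_ant = mats.tau @ (state.H / D_H)
    return b_mut, b_ant
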