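"""Niche-based generation of three-guild plant-animal communities.

A community consists of three guilds — plants, pollinators, and herbivores —
whose species each occupy a central position on a one-dimensional niche axis
``[0, 1]``. Every species carries a Gaussian niche profile of common breadth
``sigma`` around its central position, and the propensity of any two species
to interact is the ratio of their interspecific niche overlap to the
conspecific overlap,

    alpha_ij = exp(-(s_i - s_j)^2 / (4 sigma^2)),

which lies in ``(0, 1]`` and is symmetric in the pair. Binary incidence
matrices decide *which* cross-guild links are realised (pollinator-plant and
herbivore-plant), while ``alpha`` scales *how strong* each realised link is.
Three scalars set the strength of each interaction type at perfect overlap:
``Omega_c`` (within-guild competition), ``Omega_m`` (mutualism), and
``Omega_p`` (antagonism/herbivory).

Matrix orientation convention
-----------------------------
Incidence matrices are animal-rows x plant-columns (``theta_mp`` is
S_M x S_P, ``theta_hp`` is S_H x S_P). Quantitative strength matrices
``gamma`` (mutualism) and ``tau`` (herbivory) are plant-rows x
animal-columns, mirroring the plant growth equation; the transpose is the
only adapter between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParams",
    "NicheCommunity",
    "InteractionMatrices",
    "sample_niche_positions",
    "niche_overlap_coefficient",
    "alpha_matrix",
    "build_incidence",
    "assemble_matrices",
    "generate_community",
]


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the three-guild model.

    Defaults are the reference values used throughout: unit intrinsic growth
    rates, half-saturation constant ``h = 0.1`` for the type II functional
    responses, predation conversion efficiency ``eps = 0.8``, sub-network
    connectances 0.15 and niche breadth ``sigma = 0.1``.
    """

    omega_c: float = 0.1
    omega_m: float = 0.1
    omega_p: float = 0.1
    r_P: float = 1.0
    r_M: float = 1.0
    r_H: float = 1.0
    h: float = 0.1
    eps: float = 0.8
    C_mut: float = 0.15
    C_ant: float = 0.15
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if min(self.omega_c, self.omega_m, self.omega_p) < 0:
            raise ValueError("interaction strengths Omega must be >= 0")
        if self.h < 0:
            raise ValueError("half-saturation constant h must be >= 0")
        if not 0 < self.eps <= 1:
            raise ValueError("conversion coefficient eps must be in (0, 1]")
        for name, C in (("C_mut", self.C_mut), ("C_ant", self.C_ant)):
            if not 0 <= C <= 1:
                raise ValueError(f"connectance {name} must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("niche breadth sigma must be > 0")

    def with_omegas(self, omega_c: float, omega_p: float, omega_m: float) -> "ModelParams":
        """Copy of the parameter set with new interaction strengths."""
        return replace(self, omega_c=omega_c, omega_p=omega_p, omega_m=omega_m)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class NicheCommunity:
    """Guild sizes and per-species niche central positions.

    Positions are unitless coordinates on ``[0, 1]``; ``sigma`` is the common
    niche breadth. Species identity is (guild, index, position) and is fixed
    for the lifetime of a community: rewiring changes partners, never niches.
    """

    pos_P: np.ndarray
    pos_M: np.ndarray
    pos_H: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        for name in ("pos_P", "pos_M", "pos_H"):
            pos = np.asarray(getattr(self, name), dtype=float)
            if pos.ndim != 1 or pos.size < 1:
                raise ValueError(f"{name} must be a non-empty 1-d vector")
            if np.any(pos < 0) or np.any(pos > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
            object.__setattr__(self, name, pos)
        if self.sigma <= 0:
            raise ValueError("niche breadth sigma must be > 0")

    @property
    def S_P(self) -> int:
        return self.pos_P.size

    @property
    def S_M(self) -> int:
        return self.pos_M.size

    @property
    def S_H(self) -> int:
        return self.pos_H.size


@dataclass
class InteractionMatrices:
    """All binary and quantitative interaction matrices of one community.

    ``theta_mp`` / ``theta_hp`` are binary (0/1 floats) incidence matrices,
    animal rows by plant columns. ``beta_*`` are within-guild competition
    matrices with off-diagonal ``Omega_c * alpha`` and exact unit diagonal.
    ``gamma`` / ``tau`` are the plant-by-animal mutualistic and antagonistic
    strength matrices ``Omega * theta * alpha``; the same value serves both
    the plant-side and animal-side equations because ``alpha`` is symmetric
    and a single ``Omega`` scalar applies per interaction type.
    """

    theta_mp: np.ndarray  # S_M x S_P
    theta_hp: np.ndarray  # S_H x S_P
    alpha_PP: np.ndarray
    alpha_MM: np.ndarray
    alpha_HH: np.ndarray
    alpha_PM: np.ndarray  # S_P x S_M
    alpha_PH: np.ndarray  # S_P x S_H
    beta_P: np.ndarray
    beta_M: np.ndarray
    beta_H: np.ndarray
    gamma: np.ndarray  # S_P x S_M
    tau: np.ndarray  # S_P x S_H
    community: NicheCommunity | None = field(default=None, repr=False)
    params: ModelParams | None = field(default=None, repr=False)

    @property
    def S_P(self) -> int:
        return self.theta_mp.shape[1]

    @property
    def S_M(self) -> int:
        return self.theta_mp.shape[0]

    @property
    def S_H(self) -> int:
        return self.theta_hp.shape[0]

    @property
    def n_links_mut(self) -> int:
        return int(round(self.theta_mp.sum()))

    @property
    def n_links_ant(self) -> int:
        return int(round(self.theta_hp.sum()))

    def copy(self) -> "InteractionMatrices":
        return InteractionMatrices(
            theta_mp=self.theta_mp.copy(),
            theta_hp=self.theta_hp.copy(),
            alpha_PP=self.alpha_PP,
            alpha_MM=self.alpha_MM,
            alpha_HH=self.alpha_HH,
            alpha_PM=self.alpha_PM,
            alpha_PH=self.alpha_PH,
            beta_P=self.beta_P,
            beta_M=self.beta_M,
            beta_H=self.beta_H,
            gamma=self.gamma.copy(),
            tau=self.tau.copy(),
            community=self.community,
            params=self.params,
        )


def sample_niche_positions(n: int, seed=None) -> np.ndarray:
    """Draw ``n`` niche central positions uniformly on [0, 1].

    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`,
    including an existing generator.
    """
    if n < 1:
        raise ValueError("a guild must contain at least one species (n >= 1)")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=n)


def niche_overlap_coefficient(s_i, s_j, sigma: float):
    """Interaction coefficient from Gaussian niche overlap.

    Returns ``exp(-(s_i - s_j)^2 / (4 sigma^2))``, the interspecific overlap
    of two unit-breadth-normalised Gaussian niche profiles divided by the
    conspecific overlap. Symmetric in the pair; 1 at zero distance and
    strictly decreasing with distance.
    """
    if sigma <= 0:
        raise ValueError("niche breadth sigma must be > 0")
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    return np.exp(-((s_i - s_j) ** 2) / (4.0 * sigma**2))


def alpha_matrix(pos_a: np.ndarray, pos_b: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise overlap coefficients between two position vectors."""
    return niche_overlap_coefficient(
        np.asarray(pos_a)[:, None], np.asarray(pos_b)[None, :], sigma
    )


def build_incidence(
    n_rows: int,
    n_cols: int,
    C: float,
    seed=None,
    ensure_animal_degree: bool = True,
    exact_fill: bool = False,
    max_redraws: int = 10_000,
) -> np.ndarray:
    """Random binary incidence matrix (animal rows x plant columns).

    Each cell is an independent Bernoulli(``C``) draw, so the realised
    connectance fluctuates around ``C``. With ``exact_fill`` the matrix
    instead receives exactly ``round(C * n_rows * n_cols)`` links placed
    uniformly at random (a variance-reduction mode).

    ``ensure_animal_degree`` redraws the whole matrix until every animal row
    carries at least one link: an animal with no partner can never rewire
    (it has nothing to drop) and would stay disconnected forever, which
    would leave the rewiring process ill-defined.
    """
    if not 0 <= C <= 1:
        raise ValueError("connectance C must be in [0, 1]")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    n_fill = int(round(C * n_rows * n_cols))
    for _ in range(max_redraws):
        if exact_fill:
            theta = np.zeros(n_rows * n_cols)
            cells = rng.choice(n_rows * n_cols, size=n_fill, replace=False)
            theta[cells] = 1.0
            theta = theta.reshape(n_rows, n_cols)
        else:
            theta = (rng.random((n_rows, n_cols)) < C).astype(float)
        if not ensure_animal_degree or theta.sum(axis=1).min() >= 1:
            return theta
    raise RuntimeError(
        f"could not realise a matrix with all {n_rows} animal rows linked "
        f"at connectance C={C} within {max_redraws} redraws"
    )


def assemble_matrices(
    community: NicheCommunity,
    params: ModelParams,
    theta_mp: np.ndarray,
    theta_hp: np.ndarray,
) -> InteractionMatrices:
    """Populate all strength matrices from niche overlap and the incidences.

    Within-guild competition is ``beta_ij = Omega_c * alpha_ij`` off the
    diagonal with ``beta_ii = 1`` exactly (intraspecific competition).
    Mutualistic strength is ``gamma[i, j] = Omega_m * theta_mp[j, i] *
    alpha_PM[i, j]`` for plant ``i`` and pollinator ``j``; herbivory ``tau``
    is analogous with ``Omega_p`` and ``theta_hp``.
    """
    theta_mp = np.asarray(theta_mp, dtype=float)
    theta_hp = np.asarray(theta_hp, dtype=float)
    if theta_mp.shape != (community.S_M, community.S_P):
        raise ValueError(
            f"theta_mp shape {theta_mp.shape} does not match "
            f"(S_M, S_P)=({community.S_M}, {community.S_P})"
        )
    if theta_hp.shape != (community.S_H, community.S_P):
        raise ValueError(
            f"theta_hp shape {theta_hp.shape} does not match "
            f"(S_H, S_P)=({community.S_H}, {community.S_P})"
        )
    sigma = community.sigma
    alpha_PP = alpha_matrix(community.pos_P, community.pos_P, sigma)
    alpha_MM = alpha_matrix(community.pos_M, community.pos_M, sigma)
    alpha_HH = alpha_matrix(community.pos_H, community.pos_H, sigma)
    alpha_PM = alpha_matrix(community.pos_P, community.pos_M, sigma)
    alpha_PH = alpha_matrix(community.pos_P, community.pos_H, sigma)

    def _beta(alpha: np.ndarray) -> np.ndarray:
        beta = params.omega_c * alpha
        np.fill_diagonal(beta, 1.0)
        return beta

    gamma = params.omega_m * theta_mp.T * alpha_PM
    tau = params.omega_p * theta_hp.T * alpha_PH
    return InteractionMatrices(
        theta_mp=theta_mp,
        theta_hp=theta_hp,
        alpha_PP=alpha_PP,
        alpha_MM=alpha_MM,
        alpha_HH=alpha_HH,
        alpha_PM=alpha_PM,
        alpha_PH=alpha_PH,
        beta_P=_beta(alpha_PP),
        beta_M=_beta(alpha_MM),
        beta_H=_beta(alpha_HH),
        gamma=gamma,
        tau=tau,
        community=community,
        params=params,
    )


def generate_community(
    params: ModelParams,
    S_P: int = 30,
    S_M: int = 30,
    S_H: int = 30,
    seed=0,
    ensure_animal_degree: bool = True,
    exact_fill: bool = False,
) -> InteractionMatrices:
    """Generate a full random community in one call.

    A single root seed drives five documented child streams in fixed order —
    plant positions, pollinator positions, herbivore positions, mutualistic
    incidence, antagonistic incidence — so runs are bit-reproducible.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_pos_p, s_pos_m, s_pos_h, s_inc_m, s_inc_a = ss.spawn(5)
    community = NicheCommunity(
        pos_P=sample_niche_positions(S_P, s_pos_p),
        pos_M=sample_niche_positions(S_M, s_pos_m),
        pos_H=sample_niche_positions(S_H, s_pos_h),
        sigma=params.sigma,
    )
    theta_mp = build_incidence(
        S_M, S_P, params.C_mut, s_inc_m,
        ensure_animal_degree=ensure_animal_degree, exact_fill=exact_fill,
    )
    theta_hp = build_incidence(
        S_H, S_P, params.C_ant, s_inc_a,
        ensure_animal_degree=ensure_animal_degree, exact_fill=exact_fill,
    )
    return assemble_matrices(community, params, theta_mp, theta_hp)
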