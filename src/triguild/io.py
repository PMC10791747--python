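"""Plain-text import/export of communities, incidence matrices and configs.

Formats are deliberately minimal: dense 0/1 CSV incidence matrices with a
plant-label header row, three-column edge lists (animal_id, plant_id,
guild), a tidy per-species community table, and JSON/TOML configuration
files covering every model parameter plus seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .niche import ModelParams, NicheCommunity

__all__ = [
    "write_incidence_csv",
    "read_incidence_csv",
    "write_edge_list",
    "read_edge_list",
    "write_community_csv",
    "read_community_csv",
    "load_config",
    "write_manifest",
]


def write_incidence_csv(theta: np.ndarray, path, animal_prefix: str = "A") -> None:
    """Dense 0/1 CSV with header row of plant labels and animal row index."""
    theta = np.asarray(theta)
    df = pd.DataFrame(
        theta.astype(int),
        index=[f"{animal_prefix}{i}" for i in range(theta.shape[0])],
        columns=[f"P{j}" for j in range(theta.shape[1])],
    )
    df.to_csv(path)


def read_incidence_csv(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    theta = df.to_numpy(dtype=float)
    if not np.isin(theta, (0.0, 1.0)).all():
        raise ValueError(f"{path}: incidence matrix entries must be 0 or 1")
    return theta


def write_edge_list(theta: np.ndarray, guild: str, path) -> None:
    """Three-column edge list (animal_id, plant_id, guild) of realised links."""
    rows, cols = np.nonzero(np.asarray(theta))
    pd.DataFrame({
        "animal_id": rows, "plant_id": cols, "guild": guild,
    }).to_csv(path, index=False)


def read_edge_list(path, n_animals: int | None = None, n_plants: int | None = None):
    """Rebuild one incidence matrix per guild from an edge list file."""
    df = pd.read_csv(path)
    required = {"animal_id", "plant_id", "guild"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    out = {}
    n_p = n_plants if n_plants is not None else int(df["plant_id"].max()) + 1
    for guild, grp in df.groupby("guild"):
        n_a = n_animals if n_animals is not None else int(grp["animal_id"].max()) + 1
        theta = np.zeros((n_a, n_p))
        theta[grp["animal_id"].to_numpy(), grp["plant_id"].to_numpy()] = 1.0
        out[str(guild)] = theta
    return out


def write_community_csv(community: NicheCommunity, path) -> None:
    rows = []
    for guild, pos in (("plant", community.pos_P),
                       ("pollinator", community.pos_M),
                       ("herbivore", community.pos_H)):
        for i, s in enumerate(pos):
            rows.append({"guild": guild, "species_index": i, "niche_position": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_community_csv(path, sigma: float) -> NicheCommunity:
    df = pd.read_csv(path)
    def _pos(guild):
        grp = df[df["guild"] == guild].sort_values("species_index")
        return grp["niche_position"].to_numpy()
    return NicheCommunity(
        pos_P=_pos("plant"), pos_M=_pos("pollinator"), pos_H=_pos("herbivore"),
        sigma=sigma,
    )


def load_config(path) -> tuple[ModelParams, dict]:
    """Read a JSON or TOML config; returns (ModelParams, extras).

    Keys matching :class:`ModelParams` fields populate the parameter set;
    everything else (seeds, guild sizes, attempt counts, ...) is returned
    verbatim in ``extras``.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    param_fields = set(ModelParams.__dataclass_fields__)
    params = ModelParams(**{k: v for k, v in raw.items() if k in param_fields})
    extras = {k: v for k, v in raw.items() if k not in param_fields}
    return params, extras


def write_manifest(path, params: ModelParams, **extra) -> None:
    """JSON run manifest: parameters, seeds, and package version."""
    from . import __version__

    payload = {"version": __version__, "params": params.to_dict(), **extra}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
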