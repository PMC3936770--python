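"""Island-in-a-sea geometry and spatially restricted collaboration.

A high-density CpG island (unit spacing between CpGs) sits next to a
low-density "sea" (spacing 10, reflecting the lower CpG density outside
islands).  Collaborative methylation becomes local — the mediator must be the
nearest-neighbour CpG on either side — while collaborative demethylation acts
at a distance with contact probability decaying as 1/(x + alpha) in DNA
distance units (alpha ~ one nucleosome spacing mimics DNA stiffness at short
range).  Demethylation mediators can additionally be restricted to island
sites, modelling demethylase recruitment that requires high local CpG
density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .engine import (
    SimulationConfig,
    Trajectory,
    _draw_attempt_count,
    state_counts,
)
from .model_core import (
    MEDIATOR_CODES,
    PRODUCT_CODES,
    TARGET_CODES,
    ReactionScheme,
)

__all__ = [
    "Geometry",
    "SpatialRules",
    "build_geometry",
    "neighbor_mediator",
    "distance_weighted_mediator",
    "run_spatial_trajectory",
]


@dataclass(frozen=True)
class Geometry:
    """CpG coordinates (DNA-distance units) and island membership."""

    coords: np.ndarray
    island_mask: np.ndarray
    island_spacing: float
    sea_spacing: float
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if np.any(np.diff(self.coords) <= 0):
            raise ValueError("coordinates must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.coords.size)

    @property
    def island_L(self) -> int:
        return int(self.island_mask.sum())

    def distance(self, i: int, j: int) -> float:
        return abs(float(self.coords[i] - self.coords[j]))

    def contact_weight(self, i: int, j: int) -> float:
        """Contact weight 1/(x + alpha) between sites i and j."""
        return 1.0 / (self.distance(i, j) + self.alpha)

    def weight_matrix(self) -> np.ndarray:
        """Pairwise contact weights with zeroed diagonal (no self-contact)."""
        d = np.abs(self.coords[:, None] - self.coords[None, :])
        w = 1.0 / (d + self.alpha)
        np.fill_diagonal(w, 0.0)
        return w


@dataclass(frozen=True)
class SpatialRules:
    """Locality rules: nearest-neighbour collaborative methylation,
    distance-decayed collaborative demethylation, optionally with mediators
    restricted to island sites.  Non-collaborative reactions are unaffected."""

    demethylation_restricted_to_island: bool = True


def build_geometry(
    island_L: int,
    sea_L: int,
    island_spacing: float = 1.0,
    sea_spacing: float = 10.0,
    alpha: float = 20.0,
) -> Geometry:
    """Island sites first (unit spacing by default), then sea sites.

    The gap between the last island site and the first sea site equals
    ``sea_spacing``, reflecting the low CpG density immediately outside the
    island.  ``sea_L = 0`` reduces to a pure island.
    """
    if island_L < 0 or sea_L < 0 or island_L + sea_L < 2:
        raise ValueError("need island_L >= 0, sea_L >= 0 and at least 2 sites")
    if island_spacing <= 0 or sea_spacing <= 0:
        raise ValueError("spacings must be positive")
    island = np.arange(island_L, dtype=float) * island_spacing
    start = island[-1] + sea_spacing if island_L else 0.0
    sea = start + np.arange(sea_L, dtype=float) * sea_spacing
    coords = np.concatenate([island, sea])
    mask = np.zeros(island_L + sea_L, bool)
    mask[:island_L] = True
    return Geometry(coords, mask, float(island_spacing), float(sea_spacing), float(alpha))


def neighbor_mediator(geometry: Geometry, target: int, rng: np.random.Generator) -> int:
    """Left or right adjacent CpG with probability 1/2; chain ends use their
    unique neighbour."""
    n = geometry.n_sites
    if n < 2:
        raise ValueError("chain must have at least 2 sites")
    if target == 0:
        return 1
    if target == n - 1:
        return n - 2
    return target - 1 if rng.random() < 0.5 else target + 1


def distance_weighted_mediator(
    geometry: Geometry,
    target: int,
    eligible: Sequence[int],
    rng: np.random.Generator,
) -> Optional[int]:
    """Mediator drawn from ``eligible`` with probability proportional to
    1/(x + alpha); None when the eligible set is empty (the attempt fails)."""
    idx = np.asarray(list(eligible), int)
    if idx.size == 0:
        return None
    if np.any(idx == target):
        raise ValueError("eligible set must exclude the target")
    w = 1.0 / (np.abs(geometry.coords[idx] - geometry.coords[target]) + geometry.alpha)
    cum = np.cumsum(w)
    x = rng.random() * cum[-1]
    return int(idx[np.searchsorted(cum, x, side="right")])


def run_spatial_trajectory(
    init: np.ndarray,
    scheme: ReactionScheme,
    config: SimulationConfig,
    geometry: Geometry,
    rules: SpatialRules = SpatialRules(),
    rng: Optional[np.random.Generator] = None,
    stop_rule: Optional[Callable[[int, int, int, int], bool]] = None,
) -> Trajectory:
    """Like :func:`cpgsim.engine.run_trajectory` with spatial collaboration.

    Collaborative methylation recruits through the nearest-neighbour CpG
    (either side with probability 1/2).  Collaborative demethylation contacts
    a site drawn over the whole chain with probability proportional to
    1/(x + alpha) — :func:`distance_weighted_mediator` with eligible = all
    other sites — and the attempt completes only if the contacted site
    matches the mediator state and, when the island restriction is on, lies
    within the island.  Full per-site states are always recorded, and
    per-position completion counts are accumulated on
    ``Trajectory.position_completions``.
    """
    n = geometry.n_sites
    if init.size != n:
        raise ValueError(f"init has {init.size} sites but geometry has {n}")
    if config.L != n:
        raise ValueError(f"config.L = {config.L} must equal the site count {n}")
    if rng is None:
        rng = config.rng()

    w = geometry.weight_matrix()
    cum_w = np.cumsum(w, axis=1)
    totals = np.ascontiguousarray(cum_w[:, -1])
    cum_w = np.ascontiguousarray(cum_w)

    G = config.generations
    cum_rates = np.cumsum(scheme.rate_vector())
    n_u = np.empty(G, np.int64)
    n_h = np.empty(G, np.int64)
    n_m = np.empty(G, np.int64)
    completions = np.zeros((G, 12), np.int64)
    attempts = np.empty(G, np.int64)
    states = np.empty((G, n), np.int8)
    pos_completions = np.zeros((n, 12), np.int64)

    state = init.copy()
    termination = "horizon"
    n_done = 0
    for g in range(G):
        a = _draw_attempt_count(config, rng)
        _kernels.replicate_inplace(state, rng)
        _kernels.run_attempts_spatial(
            state, cum_rates, TARGET_CODES, PRODUCT_CODES, MEDIATOR_CODES,
            cum_w, totals, geometry.island_mask,
            rules.demethylation_restricted_to_island, a, rng,
            completions[g], pos_completions,
        )
        u, h, m = state_counts(state)
        n_u[g], n_h[g], n_m[g] = u, h, m
        attempts[g] = a
        states[g] = state
        n_done = g + 1
        if stop_rule is not None and stop_rule(g + 1, u, h, m):
            termination = "stopped"
            break

    return Trajectory(
        scheme, config,
        n_u[:n_done], n_h[:n_done], n_m[:n_done],
        completions[:n_done], attempts[:n_done],
        states[:n_done].copy(), termination,
        position_completions=pos_completions,
    )
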