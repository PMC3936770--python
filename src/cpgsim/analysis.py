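"""State classification, lifetimes, density statistics and the mean-field model.

The collective state of an island is summarised by its methylation level
f = (2 n_m + n_h) / (2 L), the fraction of methylated strand-sites.  An
island classifies as hypomethylated (U) when f is below the lower threshold,
hypermethylated (M) above the upper threshold, and intermediate in between.
The default thresholds (0.4, 0.6) sit symmetrically around the mixed state
f ~ 1/2 into which non-collaborative schemes converge, so they separate the
two basins of a bistable system.

For non-collaborative ("standard") schemes the sites are independent and a
mean-field recursion describes the expected dynamics exactly up to the
within-generation discretisation; its analytic consequence is the lifetime
bound 1/(N_t * u+) on the expected persistence of a methylation state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import Trajectory
from .model_core import COLLABORATIVE_IDS, REACTION_IDS, ReactionScheme

__all__ = [
    "StateClass",
    "DEFAULT_THRESHOLDS",
    "LifetimeEstimate",
    "methylation_level",
    "classify_level",
    "classify",
    "first_flip",
    "flip_stop_rule",
    "estimate_lifetime",
    "steady_densities",
    "completion_rates",
    "positional_averages",
    "bimodality_summary",
    "lifetime_bound",
    "meanfield_trajectory",
    "meanfield_fixed_point",
]


class StateClass(Enum):
    U = "U"
    INTERMEDIATE = "intermediate"
    M = "M"

    def opposite(self) -> "StateClass":
        if self is StateClass.U:
            return StateClass.M
        if self is StateClass.M:
            return StateClass.U
        raise ValueError("the intermediate class has no opposite")


#: (lower, upper) thresholds on the methylation level f.
DEFAULT_THRESHOLDS: Tuple[float, float] = (0.4, 0.6)


def _check_thresholds(thresholds) -> Tuple[float, float]:
    lower, upper = thresholds
    if not (0.0 <= lower < upper <= 1.0):
        raise ValueError(f"invalid thresholds {thresholds}")
    return lower, upper


def methylation_level(state: np.ndarray) -> float:
    """f = (2 n_m + n_h) / (2 L): the fraction of methylated strand-sites."""
    n_h = int(np.count_nonzero(state == 1))
    n_m = int(np.count_nonzero(state == 2))
    return (2.0 * n_m + n_h) / (2.0 * state.size)


def classify_level(f: float, thresholds=DEFAULT_THRESHOLDS) -> StateClass:
    lower, upper = _check_thresholds(thresholds)
    if f < lower:
        return StateClass.U
    if f > upper:
        return StateClass.M
    return StateClass.INTERMEDIATE


def classify(state: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> StateClass:
    """Threshold rule on the methylation level of an island state."""
    return classify_level(methylation_level(state), thresholds)


def flip_stop_rule(init_class: StateClass, L: int, thresholds=DEFAULT_THRESHOLDS):
    """Stop rule for :func:`cpgsim.engine.run_trajectory`: fire on a state flip
    (the island classifies as the class opposite to ``init_class``)."""
    opposite = init_class.opposite()
    lower, upper = _check_thresholds(thresholds)

    def rule(generation: int, n_u: int, n_h: int, n_m: int) -> bool:
        f = (2.0 * n_m + n_h) / (2.0 * L)
        return classify_level(f, (lower, upper)) is opposite

    return rule


def band_exit_stop_rule(init_class: StateClass, L: int, thresholds=DEFAULT_THRESHOLDS):
    """Stop rule that fires as soon as the island stops classifying as
    ``init_class`` — i.e. the state is no longer maintained.  For bistable
    schemes this coincides with the flip rule (transitions cross the
    intermediate band within a generation), but it also correctly fails
    schemes that merely park both initialisations at an intermediate level."""
    lower, upper = _check_thresholds(thresholds)

    def rule(generation: int, n_u: int, n_h: int, n_m: int) -> bool:
        f = (2.0 * n_m + n_h) / (2.0 * L)
        return classify_level(f, (lower, upper)) is not init_class

    return rule


def first_flip(
    trajectory: Trajectory,
    init_class: StateClass,
    thresholds=DEFAULT_THRESHOLDS,
) -> Optional[int]:
    """First generation classified opposite to ``init_class``; None if censored."""
    if init_class is StateClass.INTERMEDIATE:
        raise ValueError("init_class must be U or M")
    opposite = init_class.opposite()
    for i, f in enumerate(trajectory.methylation_level()):
        if classify_level(float(f), thresholds) is opposite:
            return i + 1
    return None


@dataclass(frozen=True)
class LifetimeEstimate:
    """Survival-based lifetime estimate from (possibly censored) flip times.

    ``estimate`` is the constant-hazard (censored-exponential) maximum-
    likelihood value, total observed time / number of observed flips.  When
    every sample is censored there is no flip to anchor a point value and
    ``estimate`` equals the mean censoring horizon, flagged as a lower bound.
    ``score`` (total time / max(events, 1)) is monotone in stability and is
    what the refinement loop compares.
    """

    times: np.ndarray
    censored: np.ndarray
    estimate: float
    is_lower_bound: bool

    @property
    def n_events(self) -> int:
        return int(np.count_nonzero(~self.censored))

    @property
    def score(self) -> float:
        return float(self.times.sum()) / max(self.n_events, 1)


def estimate_lifetime(times: Sequence[float], censored: Optional[Sequence[bool]] = None) -> LifetimeEstimate:
    """Censoring-aware mean lifetime from first-flip samples.

    ``times[i]`` is the first-flip generation of replicate i, or the horizon
    at which it was censored (``censored[i]`` True).
    """
    t = np.asarray(times, float)
    if t.size == 0:
        raise ValueError("estimate_lifetime needs at least one sample")
    c = np.zeros(t.size, bool) if censored is None else np.asarray(censored, bool)
    if c.shape != t.shape:
        raise ValueError("times and censored must have the same length")
    events = int(np.count_nonzero(~c))
    if events == 0:
        return LifetimeEstimate(t, c, float(t.mean()), True)
    return LifetimeEstimate(t, c, float(t.sum()) / events, False)


def steady_densities(trajectory: Trajectory, burn_in: int = 0) -> np.ndarray:
    """Mean end-of-generation (u, h, m) fractions after ``burn_in`` generations."""
    if trajectory.n_generations <= burn_in:
        raise ValueError("trajectory is not longer than burn_in")
    sl = slice(burn_in, None)
    L = trajectory.L
    return np.array([
        trajectory.n_u[sl].mean() / L,
        trajectory.n_h[sl].mean() / L,
        trajectory.n_m[sl].mean() / L,
    ])


def completion_rates(trajectory: Trajectory) -> pd.Series:
    """Completed reactions per CpG per generation, per reaction id plus 'total'."""
    denom = trajectory.L * trajectory.n_generations
    per = trajectory.completions.sum(axis=0) / denom
    s = pd.Series(per, index=list(REACTION_IDS))
    s["total"] = per.sum()
    return s


def positional_averages(trajectory: Trajectory, burn_in: int = 0) -> pd.DataFrame:
    """Per-position time-averaged u/h/m densities (requires full state records)."""
    if trajectory.states is None:
        raise ValueError("trajectory has no full state records")
    if trajectory.n_generations <= burn_in:
        raise ValueError("trajectory is not longer than burn_in")
    states = trajectory.states[burn_in:]
    out = pd.DataFrame({
        "u": (states == 0).mean(axis=0),
        "h": (states == 1).mean(axis=0),
        "m": (states == 2).mean(axis=0),
    })
    out.index.name = "position"
    return out


def bimodality_summary(levels: Sequence[float], thresholds=DEFAULT_THRESHOLDS):
    """(fraction U, fraction intermediate, fraction M) of leaf methylation levels."""
    f = np.asarray(levels, float)
    if f.size == 0:
        raise ValueError("bimodality_summary needs at least one leaf")
    lower, upper = _check_thresholds(thresholds)
    frac_u = float(np.mean(f < lower))
    frac_m = float(np.mean(f > upper))
    return frac_u, 1.0 - frac_u - frac_m, frac_m


def lifetime_bound(attempts_per_site: float, u_plus: float) -> float:
    """Upper bound 1/(N_t * u+) on the expected lifetime of a methylation state.

    De novo methylation at rate u+ hits each CpG N_t * u+ times per
    generation, so a hypomethylated state is expected to survive at most
    1/(N_t * u+) generations regardless of the other rates.
    """
    if attempts_per_site <= 0 or u_plus <= 0:
        raise ValueError("attempts_per_site and u_plus must be positive")
    return 1.0 / (attempts_per_site * u_plus)


# ---------------------------------------------------------------------------
# Mean-field companion for the standard (non-collaborative) model
# ---------------------------------------------------------------------------

def _standard_rates(scheme: ReactionScheme):
    for rid in COLLABORATIVE_IDS:
        if scheme.rates[rid] != 0.0:
            raise ValueError(
                "mean-field model is defined for non-collaborative schemes only; "
                f"{rid} has rate {scheme.rates[rid]}"
            )
    r = scheme.rates
    return r["u+"], r["h+"], r["h-"], r["m-"]


def meanfield_trajectory(
    scheme: ReactionScheme,
    init: Sequence[float],
    generations: int,
    attempts_per_site: int = 100,
) -> np.ndarray:
    """Deterministic expected dynamics of the standard model.

    Each generation applies the replication map
    (u, h, m) -> (u + h/2, h/2 + m, 0) and then N_t expected-change substeps,
    each moving mass u->h at rate u+*u, h->m at h+*h, h->u at h-*h and
    m->h at m-*m.  Returns an array of shape (generations + 1, 3) whose row g
    is the (u, h, m) fractions at the end of generation g (row 0 = init).
    """
    up, hp, hminus, mminus = _standard_rates(scheme)
    u, h, m = (float(x) for x in init)
    if not np.isclose(u + h + m, 1.0):
        raise ValueError("init fractions must sum to 1")
    n_t = int(round(attempts_per_site))
    out = np.empty((generations + 1, 3))
    out[0] = (u, h, m)
    for g in range(1, generations + 1):
        u, h, m = u + h / 2.0, h / 2.0 + m, 0.0
        for _ in range(n_t):
            d_uh = up * u
            d_hm = hp * h
            d_hu = hminus * h
            d_mh = mminus * m
            u += d_hu - d_uh
            h += d_uh + d_mh - d_hm - d_hu
            m += d_hm - d_mh
        out[g] = (u, h, m)
    return out


def meanfield_fixed_point(
    scheme: ReactionScheme,
    attempts_per_site: int = 100,
    tol: float = 1e-10,
    max_generations: int = 100_000,
) -> np.ndarray:
    """Iterate the mean-field map from (1, 0, 0) until the per-generation
    change falls below ``tol``; returns the fixed-point (u, h, m)."""
    state = np.array([1.0, 0.0, 0.0])
    for _ in range(max_generations):
        nxt = meanfield_trajectory(scheme, state, 1, attempts_per_site)[1]
        if np.abs(nxt - state).max() < tol:
            return nxt
        state = nxt
    return state
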