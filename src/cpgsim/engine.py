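"""Stochastic simulation core: attempt loop, replication, generations, lineages.

An island is an ordered vector of CpG dyad states, stored as an int8 numpy
array with codes u=0, h=1, m=2 (see :class:`cpgsim.model_core.SiteState`).

One cell generation consists of DNA replication (which maps u->u, m->h and
h->h/u with probability 1/2 each, following the daughter duplex), followed by
``attempts_per_site * L`` reaction attempts.  Each attempt picks one reaction
according to the scheme's rates (the leftover probability is a no-op), a
uniform random target site and, for collaborative reactions, a uniform random
mediator site distinct from the target; the target changes iff the reaction
applies.  Counts are recorded at the end of each generation, i.e. just before
the next replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import (
    MEDIATOR_CODES,
    PRODUCT_CODES,
    REACTION_IDS,
    TARGET_CODES,
    ReactionScheme,
    SiteState,
)

__all__ = [
    "SimulationConfig",
    "GenerationRecord",
    "Trajectory",
    "all_u",
    "all_h",
    "all_m",
    "from_string",
    "to_string",
    "state_counts",
    "choose_event",
    "attempt",
    "replicate",
    "run_generation",
    "run_trajectory",
    "population_run",
]


# ---------------------------------------------------------------------------
# Island state helpers
# ---------------------------------------------------------------------------

def all_u(L: int) -> np.ndarray:
    return np.zeros(L, np.int8)


def all_h(L: int) -> np.ndarray:
    return np.full(L, 1, np.int8)


def all_m(L: int) -> np.ndarray:
    return np.full(L, 2, np.int8)


def from_string(s: str) -> np.ndarray:
    """Parse a state string over the alphabet ``uhm`` (position = CpG index)."""
    return np.array([SiteState.from_char(c) for c in s], np.int8)


def to_string(state: np.ndarray) -> str:
    return "".join("uhm"[int(v)] for v in state)


def state_counts(state: np.ndarray):
    """(n_u, n_h, n_m) of an island state vector."""
    n_u = int(np.count_nonzero(state == 0))
    n_h = int(np.count_nonzero(state == 1))
    return n_u, n_h, int(state.size - n_u - n_h)


# ---------------------------------------------------------------------------
# Configuration and records
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of a single-island run.

    ``attempts_per_site`` is N_t, the mean number of reaction attempts per
    CpG per generation (default 100, i.e. 8000 attempts for the default
    80-site island).  ``attempt_count_mode`` is ``"fixed"`` (exactly
    ``N_t * L`` attempts) or ``"poisson"`` (Poisson with that mean).
    """

    L: int = 80
    attempts_per_site: float = 100.0
    generations: int = 100
    attempt_count_mode: str = "fixed"
    record_full_states: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.attempts_per_site <= 0:
            raise ValueError("attempts_per_site must be > 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.attempt_count_mode not in ("fixed", "poisson"):
            raise ValueError("attempt_count_mode must be 'fixed' or 'poisson'")

    @property
    def attempts_per_generation(self) -> int:
        return int(round(self.attempts_per_site * self.L))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class GenerationRecord(NamedTuple):
    """End-of-generation snapshot: counts, per-reaction completions, attempts."""

    generation: int
    n_u: int
    n_h: int
    n_m: int
    completions: np.ndarray  # length 12, canonical reaction order
    attempts: int
    state: Optional[np.ndarray] = None


@dataclass
class Trajectory:
    """Per-generation records of one run.

    Generations are numbered from 1 (the first replication + attempt block).
    ``completions`` has one row per generation and one column per reaction in
    canonical order.  ``states`` (generations x L, int8) is present when full
    states were recorded.  ``termination`` is ``"horizon"``, ``"stopped"`` or
    ``"user"``.
    """

    scheme: ReactionScheme
    config: SimulationConfig
    n_u: np.ndarray
    n_h: np.ndarray
    n_m: np.ndarray
    completions: np.ndarray
    attempts: np.ndarray
    states: Optional[np.ndarray] = None
    termination: str = "horizon"
    position_completions: Optional[np.ndarray] = None

    @property
    def n_generations(self) -> int:
        return len(self.n_u)

    @property
    def L(self) -> int:
        return self.config.L

    def methylation_level(self) -> np.ndarray:
        """Fraction of methylated strand-sites, f = (2 n_m + n_h) / (2 L)."""
        return (2.0 * self.n_m + self.n_h) / (2.0 * self.L)

    def record(self, i: int) -> GenerationRecord:
        return GenerationRecord(
            i + 1, int(self.n_u[i]), int(self.n_h[i]), int(self.n_m[i]),
            self.completions[i], int(self.attempts[i]),
            None if self.states is None else self.states[i],
        )

    def records(self) -> Iterator[GenerationRecord]:
        for i in range(self.n_generations):
            yield self.record(i)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "generation": np.arange(1, self.n_generations + 1),
            "n_u": self.n_u,
            "n_h": self.n_h,
            "n_m": self.n_m,
        })
        for k, rid in enumerate(REACTION_IDS):
            df[f"completed[{rid}]"] = self.completions[:, k]
        df["attempts"] = self.attempts
        return df


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def choose_event(scheme: ReactionScheme, rng: np.random.Generator) -> Optional[str]:
    """Draw one reaction id with probability = its rate; None for a no-op."""
    r = rng.random()
    cum = 0.0
    for rid in REACTION_IDS:
        cum += scheme.rates[rid]
        if r < cum:
            return rid
    return None


def uniform_mediator(state: np.ndarray, target: int, rng: np.random.Generator) -> int:
    """Uniform random site distinct from the target (global collaboration)."""
    j = int(rng.integers(0, state.size - 1))
    return j + 1 if j >= target else j


def attempt(
    state: np.ndarray,
    scheme: ReactionScheme,
    rng: np.random.Generator,
    mediator_sampler: Callable = uniform_mediator,
):
    """One reaction attempt, mutating ``state`` in place.

    Returns ``(state, completed, reaction_id)`` where ``reaction_id`` is None
    for a no-op draw.  This is the readable reference implementation; the
    per-generation loop uses the compiled kernel with identical semantics.
    """
    rid = choose_event(scheme, rng)
    if rid is None:
        return state, False, None
    k = REACTION_IDS.index(rid)
    t = int(rng.integers(0, state.size))
    if state[t] != TARGET_CODES[k]:
        return state, False, rid
    if MEDIATOR_CODES[k] >= 0:
        j = mediator_sampler(state, t, rng)
        if j is None or state[j] != MEDIATOR_CODES[k]:
            return state, False, rid
    state[t] = PRODUCT_CODES[k]
    return state, True, rid


def replicate(state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One daughter duplex: u->u, m->h, h->h or u (probability 1/2 each).

    Never creates m sites and never destroys u sites; the returned state has
    n_m = 0.
    """
    out = state.copy()
    _kernels.replicate_inplace(out, rng)
    return out


def _draw_attempt_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.attempt_count_mode == "poisson":
        return int(rng.poisson(config.attempts_per_site * config.L))
    return config.attempts_per_generation


def _generation_inplace(state, cum, n_attempts, rng, completions):
    _kernels.replicate_inplace(state, rng)
    _kernels.run_attempts(
        state, cum, TARGET_CODES, PRODUCT_CODES, MEDIATOR_CODES,
        n_attempts, rng, completions,
    )


def run_generation(
    state: np.ndarray,
    scheme: ReactionScheme,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Replication followed by one generation of attempts.

    Returns ``(new_state, GenerationRecord)``; the input state is not
    modified.
    """
    out = state.copy()
    cum = np.cumsum(scheme.rate_vector())
    completions = np.zeros(12, np.int64)
    n_attempts = _draw_attempt_count(config, rng)
    _generation_inplace(out, cum, n_attempts, rng, completions)
    n_u, n_h, n_m = state_counts(out)
    rec = GenerationRecord(1, n_u, n_h, n_m, completions, n_attempts,
                           out.copy() if config.record_full_states else None)
    return out, rec


def run_trajectory(
    init: np.ndarray,
    scheme: ReactionScheme,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    stop_rule: Optional[Callable[[int, int, int, int], bool]] = None,
) -> Trajectory:
    """Iterate generations from ``init`` for the configured horizon.

    ``stop_rule(generation, n_u, n_h, n_m)`` is evaluated on end-of-generation
    counts; when it returns True the run terminates with
    ``termination="stopped"`` after recording that generation.  Runs are
    bit-reproducible given (seed, config, scheme).
    """
    if init.size != config.L:
        raise ValueError(f"init has {init.size} sites but config.L = {config.L}")
    if rng is None:
        rng = config.rng()
    G = config.generations
    cum = np.cumsum(scheme.rate_vector())
    n_u = np.empty(G, np.int64)
    n_h = np.empty(G, np.int64)
    n_m = np.empty(G, np.int64)
    completions = np.zeros((G, 12), np.int64)
    attempts = np.empty(G, np.int64)
    states = np.empty((G, config.L), np.int8) if config.record_full_states else None

    state = init.copy()
    termination = "horizon"
    n_done = 0
    for g in range(G):
        a = _draw_attempt_count(config, rng)
        _generation_inplace(state, cum, a, rng, completions[g])
        u, h, m = state_counts(state)
        n_u[g], n_h[g], n_m[g] = u, h, m
        attempts[g] = a
        if states is not None:
            states[g] = state
        n_done = g + 1
        if stop_rule is not None and stop_rule(g + 1, u, h, m):
            termination = "stopped"
            break

    return Trajectory(
        scheme, config,
        n_u[:n_done], n_h[:n_done], n_m[:n_done],
        completions[:n_done], attempts[:n_done],
        None if states is None else states[:n_done].copy(),
        termination,
    )


def population_run(
    founder: np.ndarray,
    scheme: ReactionScheme,
    config: SimulationConfig,
    divisions: int,
    rng: Optional[np.random.Generator] = None,
    max_divisions: int = 16,
) -> np.ndarray:
    """Simulate the full lineage tree from a founder cell.

    At each division both daughter duplexes are retained: each daughter's
    replication outcome (the h->h/u coin flips) is drawn independently, and
    each daughter then receives a full generation of reaction attempts.
    Returns the ``2**divisions`` leaf states as a (2**divisions, L) array.
    """
    if divisions < 0:
        raise ValueError("divisions must be >= 0")
    if divisions > max_divisions:
        raise ValueError(
            f"divisions = {divisions} exceeds the cap of {max_divisions} "
            f"(memory grows as 2**divisions)"
        )
    if rng is None:
        rng = config.rng()
    cum = np.cumsum(scheme.rate_vector())
    cells: List[np.ndarray] = [founder.copy()]
    scratch = np.zeros(12, np.int64)
    for _ in range(divisions):
        nxt: List[np.ndarray] = []
        for cell in cells:
            for _ in range(2):
                daughter = cell.copy()
                a = _draw_attempt_count(config, rng)
                _generation_inplace(daughter, cum, a, rng, scratch)
                nxt.append(daughter)
        cells = nxt
    return np.stack(cells)
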