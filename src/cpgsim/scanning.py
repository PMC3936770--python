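"""Random scheme sampling, bistability assays, scans, ablations, refinement.

A scheme is bistable at horizon G when paired runs started from the all-m
(M) and all-u (U) states both maintain their initial classification for G
generations, in every replicate.  Scans sample rates
log-uniformly over [1e-4, 1 - u+] (u+ drawn first; the floors u+ >= 1e-4 and
h+ >= 1e-4 keep irreducible noise in every scheme) and report the pass
fraction and the rate distributions among passing schemes.

Every sampled scheme receives its own child seed spawned from the scan seed,
so results are independent of evaluation order or worker count, and running
the same scan at a longer horizon replays the identical trajectories
(pass sets are nested in the horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import engine
from .analysis import (
    DEFAULT_THRESHOLDS,
    LifetimeEstimate,
    StateClass,
    band_exit_stop_rule,
    classify_level,
    estimate_lifetime,
    steady_densities,
)
from .model_core import (
    CATALOGUE,
    REACTION_IDS,
    MotifPreset,
    ReactionScheme,
    make_scheme,
    motif_preset,
)

__all__ = [
    "ScanConfig",
    "BistabilityOutcome",
    "ScanResult",
    "sample_scheme",
    "bistability_assay",
    "distinction_persistence",
    "scan",
    "ablation_scan",
    "refine",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a random-scheme scan.

    ``horizon`` is the bistability horizon G in generations; ``replicates``
    paired runs are made per initial state.  ``extra_zero`` adds zero
    constraints on top of the motif (used by ablation scans).
    """

    n_samples: int = 100
    motif: str = "collaborative_full"
    rate_min: float = 1e-4
    horizon: int = 1000
    replicates: int = 3
    L: int = 80
    attempts_per_site: float = 100.0
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS
    burn_in: int = 20
    early_stop: bool = True
    seed: Optional[int] = None
    extra_zero: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not (0 < self.rate_min <= 0.5):
            raise ValueError("rate_min must lie in (0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def sim_config(self, generations: Optional[int] = None) -> engine.SimulationConfig:
        return engine.SimulationConfig(
            L=self.L,
            attempts_per_site=self.attempts_per_site,
            generations=self.horizon if generations is None else generations,
        )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo > hi:
        raise ValueError(f"unsatisfiable rate bounds: min {lo} > max {hi}")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_scheme(rng: np.random.Generator, config: ScanConfig) -> ReactionScheme:
    """Draw one random scheme under the configured motif.

    u+ is drawn first, log-uniformly on [rate_min, 0.5]; every other free
    rate is log-uniform on [rate_min, 1 - u+] (the paper's stated maximum).
    Schemes whose rates sum beyond 1 are rejected and redrawn so rates stay
    interpretable as per-attempt probabilities.
    """
    preset = motif_preset(config.motif)
    zero = preset.zero_constraints | config.extra_zero
    for _ in range(10_000):
        rates = {}
        u_plus = _log_uniform(rng, config.rate_min, 0.5)
        rates["u+"] = u_plus
        hi = 1.0 - u_plus
        for rid in REACTION_IDS:
            if rid == "u+":
                continue
            rates[rid] = 0.0 if rid in zero else _log_uniform(rng, config.rate_min, hi)
        if "u+" in zero:
            raise ValueError("u+ cannot be zero-constrained (noise floor)")
        if sum(rates.values()) <= 1.0:
            scheme = make_scheme(rates, preset)
            if config.extra_zero:
                return ReactionScheme(scheme.rates, scheme.motif,
                                      scheme.zero_constraints | config.extra_zero)
            return scheme
    raise RuntimeError("could not sample a scheme with rate sum <= 1")


@dataclass(frozen=True)
class BistabilityOutcome:
    """Per-scheme assay result: the generation at which each replicate first
    left its initial classification band (None when censored at the horizon),
    the pass flag, and steady densities measured on a surviving replicate of
    each init."""

    scheme: ReactionScheme
    horizon: int
    flips_from_m: Tuple[Optional[int], ...]
    flips_from_u: Tuple[Optional[int], ...]
    passed: bool
    densities_m: Optional[np.ndarray] = None
    densities_u: Optional[np.ndarray] = None

    def lifetime_samples(self):
        """(times, censored) pooled over both inits, for survival estimates."""
        times, cens = [], []
        for flips in (self.flips_from_m, self.flips_from_u):
            for t in flips:
                times.append(self.horizon if t is None else t)
                cens.append(t is None)
        return np.array(times, float), np.array(cens, bool)


def bistability_assay(
    scheme: ReactionScheme,
    config: ScanConfig,
    rng: np.random.Generator,
) -> BistabilityOutcome:
    """Run replicate paired trajectories from all-m and all-u; pass iff every
    replicate maintains its initial classification (M stays M, U stays U)
    for the whole horizon.  Failing as soon as a trajectory leaves its band
    — rather than only on reaching the opposite band — also rejects schemes
    that park both initialisations at an intermediate level; for genuinely
    bistable schemes the two rules coincide because transitions cross the
    intermediate band within a generation.  With ``early_stop`` the assay
    abandons remaining replicates after the first exit (this cannot change
    the pass/fail decision)."""
    sim = config.sim_config()
    inits = (
        (engine.all_m(config.L), StateClass.M),
        (engine.all_u(config.L), StateClass.U),
    )
    flips: List[List[Optional[int]]] = [[], []]
    densities: List[Optional[np.ndarray]] = [None, None]
    flipped = False
    for i, (init, init_class) in enumerate(inits):
        rule = band_exit_stop_rule(init_class, config.L, config.thresholds)
        for _ in range(config.replicates):
            if flipped and config.early_stop:
                break
            traj = engine.run_trajectory(init, scheme, sim, rng, stop_rule=rule)
            if traj.termination == "stopped":
                flips[i].append(traj.n_generations)
                flipped = True
            else:
                flips[i].append(None)
                if densities[i] is None and traj.n_generations > config.burn_in:
                    densities[i] = steady_densities(traj, config.burn_in)
    passed = (not flipped
              and len(flips[0]) == config.replicates
              and len(flips[1]) == config.replicates)
    return BistabilityOutcome(
        scheme, config.horizon, tuple(flips[0]), tuple(flips[1]),
        passed, densities[0], densities[1],
    )


def distinction_persistence(
    scheme: ReactionScheme,
    config: ScanConfig,
    rng: np.random.Generator,
) -> int:
    """Generations for which paired runs keep the M/U distinction.

    Runs one trajectory from all-m and one from all-u; the distinction is
    maintained while the M-initialised island still classifies M and the
    U-initialised island still classifies U.  Returns the number of completed
    generations before the first of the two leaves its band, capped at the
    horizon (a censored pair returns the horizon itself).
    """
    sim = config.sim_config()
    exits = []
    for make_init, cls in ((engine.all_m, StateClass.M), (engine.all_u, StateClass.U)):
        def leaves_band(generation, n_u, n_h, n_m, cls=cls):
            f = (2.0 * n_m + n_h) / (2.0 * config.L)
            return classify_level(f, config.thresholds) is not cls

        traj = engine.run_trajectory(make_init(config.L), scheme, sim, rng,
                                     stop_rule=leaves_band)
        if traj.termination == "stopped":
            exits.append(traj.n_generations - 1)
        else:
            exits.append(config.horizon)
    return min(exits)


@dataclass
class ScanResult:
    """Aggregate of a scan: outcomes, pass fraction and rate tables."""

    config: ScanConfig
    outcomes: List[BistabilityOutcome]

    @property
    def n_samples(self) -> int:
        return len(self.outcomes)

    @property
    def n_passing(self) -> int:
        return sum(o.passed for o in self.outcomes)

    @property
    def pass_fraction(self) -> float:
        return self.n_passing / self.n_samples

    def passing_schemes(self) -> List[ReactionScheme]:
        return [o.scheme for o in self.outcomes if o.passed]

    def rate_table(self) -> pd.DataFrame:
        """One row per sampled scheme: the 12 rates, pass flag, earliest flip
        per init (horizon when censored) and steady densities if measured."""
        rows = []
        for o in self.outcomes:
            row = {rid: o.scheme.rates[rid] for rid in REACTION_IDS}
            row["pass"] = o.passed
            row["first_flip_m"] = min((t for t in o.flips_from_m if t is not None),
                                      default=o.horizon)
            row["first_flip_u"] = min((t for t in o.flips_from_u if t is not None),
                                      default=o.horizon)
            for name, dens in (("m_state", o.densities_m), ("u_state", o.densities_u)):
                for j, st in enumerate("uhm"):
                    row[f"{name}_{st}"] = np.nan if dens is None else dens[j]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_passing": self.n_passing,
            "pass_fraction": self.pass_fraction,
            "horizon": self.config.horizon,
            "motif": self.config.motif,
        }


def _child_rng(seed: Optional[int], index: int) -> np.random.Generator:
    # Per-sample child streams: results do not depend on evaluation order.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def scan(config: ScanConfig) -> ScanResult:
    """Sample ``n_samples`` schemes, assay each, aggregate.

    Deterministic given (seed, config); each sample uses its own child
    stream spawned from the scan seed.
    """
    outcomes = []
    for i in range(config.n_samples):
        rng = _child_rng(config.seed, i)
        scheme = sample_scheme(rng, config)
        outcomes.append(bistability_assay(scheme, config, rng))
    return ScanResult(config, outcomes)


def ablation_scan(motif: str, reaction_id: str, config: ScanConfig) -> ScanResult:
    """Scan with one reaction additionally pinned to zero."""
    if reaction_id not in CATALOGUE:
        raise ValueError(f"unknown reaction id {reaction_id!r}")
    cfg = replace(config, motif=motif,
                  extra_zero=config.extra_zero | frozenset({reaction_id}))
    return scan(cfg)


def refine(
    start: ReactionScheme,
    config: ScanConfig,
    rng: np.random.Generator,
    perturbation_scale: float = 0.2,
    target_horizon: int = 10_000,
    budget: int = 50,
) -> Tuple[ReactionScheme, LifetimeEstimate]:
    """Hill-climb toward longer-lived schemes.

    Each step multiplies every free non-zero rate by exp(eps) with eps drawn
    uniformly from [-scale, scale] (zero constraints are preserved; candidates
    violating the rate bounds or sum <= 1 are redrawn).  A candidate is
    accepted iff its survival score (total observed generations per flip, a
    censoring-aware lifetime lower bound) does not decrease.  Whenever the
    incumbent survives the current horizon fully censored, the horizon doubles
    toward ``target_horizon``.  Returns the best scheme and its lifetime
    estimate at the last horizon reached; exhausting the budget returns the
    best-so-far.
    """
    if perturbation_scale < 0:
        raise ValueError("perturbation_scale must be >= 0")
    free = [rid for rid in REACTION_IDS
            if rid not in start.zero_constraints and start.rates[rid] > 0]

    def perturb(scheme: ReactionScheme) -> ReactionScheme:
        for _ in range(1000):
            rates = dict(scheme.rates)
            u_plus = rates["u+"]
            for rid in free:
                eps = rng.uniform(-perturbation_scale, perturbation_scale)
                rates[rid] = float(np.clip(rates[rid] * np.exp(eps),
                                           config.rate_min, 1.0 - u_plus))
                u_plus = rates["u+"]
            if sum(rates.values()) <= 1.0:
                return make_scheme(rates, scheme.motif)
        return scheme

    def assess(scheme: ReactionScheme, horizon: int) -> LifetimeEstimate:
        cfg = replace(config, horizon=horizon)
        outcome = bistability_assay(scheme, cfg, rng)
        return estimate_lifetime(*outcome.lifetime_samples())

    horizon = config.horizon
    current = start
    est = assess(current, horizon)
    if est.n_events > 0:
        raise ValueError("start scheme does not pass the initial criterion "
                         f"(flipped within {horizon} generations)")
    evaluations = 1
    while evaluations < budget:
        if est.n_events == 0:
            if horizon >= target_horizon:
                break
            horizon = min(2 * horizon, target_horizon)
            est = assess(current, horizon)
            evaluations += 1
            continue
        candidate = perturb(current)
        cand_est = assess(candidate, horizon)
        evaluations += 1
        if cand_est.score >= est.score:
            current, est = candidate, cand_est
    return current, est
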