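"""Site states, the 12-reaction vocabulary, reaction schemes and motif presets.

A CpG dyad is in one of three states: unmethylated (``u``), hemimethylated
(``h``) or fully methylated (``m``).  Methylation (+) and demethylation (-)
reactions move a single methyl group at a time (u->h, h->m, m->h, h->u).
Non-collaborative reactions act on a target CpG alone; collaborative reactions
additionally require a mediator CpG — a second site whose methylation state
must match the reaction (modelling enzyme recruitment, e.g. a methylase bound
at an ``m`` site acting on a nearby ``u`` site).

The catalogue holds exactly twelve reactions: the four non-collaborative ones
(u+, h+, h-, m-), four collaborative methylations (u+m, u+h, h+m, h+h) and
four collaborative demethylations (m-u, m-h, h-u, h-h).  The four
"self-destruction" combinations — u-mediated methylation and m-mediated
demethylation, where a state would recruit enzymes destroying itself — are
deliberately absent.

Rates are dimensionless per-attempt selection probabilities.  Each reaction
attempt selects reaction ``r`` with probability ``rate(r)``; with probability
``1 - sum(rates)`` the attempt is a no-op.  The sum of all twelve rates must
therefore not exceed 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "SiteState",
    "ReactionSpec",
    "ReactionScheme",
    "MotifPreset",
    "REACTION_IDS",
    "NONCOLLABORATIVE_IDS",
    "COLLABORATIVE_METHYLATION_IDS",
    "COLLABORATIVE_DEMETHYLATION_IDS",
    "COLLABORATIVE_IDS",
    "CATALOGUE",
    "MOTIFS",
    "make_scheme",
    "motif_preset",
    "reaction_applicability",
]


class SiteState(IntEnum):
    """Methylation state of one CpG dyad."""

    U = 0  # unmethylated
    H = 1  # hemimethylated (one strand carries the methyl mark)
    M = 2  # fully methylated

    @property
    def char(self) -> str:
        return "uhm"[int(self)]

    @classmethod
    def from_char(cls, c: str) -> "SiteState":
        try:
            return cls("uhm".index(c))
        except ValueError:
            raise ValueError(f"unknown site state character {c!r}") from None


#: Canonical reaction order used for all rate vectors and completion counters.
REACTION_IDS = (
    "u+", "h+", "h-", "m-",          # non-collaborative
    "u+m", "u+h", "h+m", "h+h",      # collaborative methylation
    "m-u", "m-h", "h-u", "h-h",      # collaborative demethylation
)
NONCOLLABORATIVE_IDS = REACTION_IDS[:4]
COLLABORATIVE_METHYLATION_IDS = REACTION_IDS[4:8]
COLLABORATIVE_DEMETHYLATION_IDS = REACTION_IDS[8:12]
COLLABORATIVE_IDS = REACTION_IDS[4:]

REACTION_INDEX = {rid: k for k, rid in enumerate(REACTION_IDS)}


@dataclass(frozen=True)
class ReactionSpec:
    """One entry of the reaction catalogue.

    ``direction`` is +1 for methylation, -1 for demethylation.
    ``mediator_state`` is ``None`` for the non-collaborative reactions.
    """

    id: str
    target_state: SiteState
    product_state: SiteState
    direction: int
    mediator_state: Optional[SiteState] = None

    @property
    def is_collaborative(self) -> bool:
        return self.mediator_state is not None


def _build_catalogue() -> dict:
    U, H, M = SiteState.U, SiteState.H, SiteState.M
    entries = [
        ReactionSpec("u+", U, H, +1),
        ReactionSpec("h+", H, M, +1),
        ReactionSpec("h-", H, U, -1),
        ReactionSpec("m-", M, H, -1),
        ReactionSpec("u+m", U, H, +1, M),
        ReactionSpec("u+h", U, H, +1, H),
        ReactionSpec("h+m", H, M, +1, M),
        ReactionSpec("h+h", H, M, +1, H),
        ReactionSpec("m-u", M, H, -1, U),
        ReactionSpec("m-h", M, H, -1, H),
        ReactionSpec("h-u", H, U, -1, U),
        ReactionSpec("h-h", H, U, -1, H),
    ]
    return {e.id: e for e in entries}


CATALOGUE: Mapping[str, ReactionSpec] = _build_catalogue()

# Integer tables in canonical order, consumed by the numba kernels.
TARGET_CODES = np.array([int(CATALOGUE[r].target_state) for r in REACTION_IDS], np.int8)
PRODUCT_CODES = np.array([int(CATALOGUE[r].product_state) for r in REACTION_IDS], np.int8)
MEDIATOR_CODES = np.array(
    [-1 if CATALOGUE[r].mediator_state is None else int(CATALOGUE[r].mediator_state)
     for r in REACTION_IDS],
    np.int8,
)


def reaction_applicability(
    reaction: Union[str, ReactionSpec],
    target: SiteState,
    mediator: Optional[SiteState] = None,
) -> bool:
    """Whether a chosen reaction can act on ``target`` given ``mediator``.

    The mediator must be ``None`` exactly when the reaction is
    non-collaborative.  The reaction applies iff the target state matches
    and, for collaborative reactions, the mediator state matches too.
    """
    spec = CATALOGUE[reaction] if isinstance(reaction, str) else reaction
    if spec.is_collaborative:
        if mediator is None:
            raise ValueError(f"collaborative reaction {spec.id} needs a mediator state")
        return target == spec.target_state and mediator == spec.mediator_state
    if mediator is not None:
        raise ValueError(f"non-collaborative reaction {spec.id} takes no mediator")
    return target == spec.target_state


@dataclass(frozen=True)
class MotifPreset:
    """A named constraint set pinning a subset of collaborative rates to zero."""

    name: str
    zero_constraints: frozenset
    suggested_rates: Optional[Mapping[str, float]] = None


def _motifs() -> dict:
    collab = frozenset(COLLABORATIVE_IDS)
    standard = MotifPreset(
        "standard",
        collab,
        {"u+": 1e-4, "h+": 0.9, "h-": 1e-3, "m-": 1e-3},
    )
    collaborative_full = MotifPreset("collaborative_full", frozenset())
    # Smallest collaborative reaction set supporting bistability: the three
    # favourable collaborative methylations plus non-collaborative
    # demethylation.  Without collaborative demethylation the two states make
    # opposing demands on the noise rates (the U state needs m- high enough to
    # clear methylation nuclei before u+m amplifies them; the M state needs h-
    # low enough not to drain the post-replication h pool that h+h must
    # re-methylate), so the bistable window is far narrower than for the
    # full-feedback motif and the suggested rates sit inside it rather than at
    # the favoured peaks.
    minimal = MotifPreset(
        "minimal",
        frozenset({"u+h", "m-u", "m-h", "h-u", "h-h"}),
        {"u+": 1e-4, "h+": 1e-4, "h-": 0.02, "m-": 0.12,
         "u+m": 0.12, "h+m": 0.3, "h+h": 0.2},
    )
    # Minimal motif plus u-mediated collaborative demethylation: positive
    # feedback in both directions.  Collaborative methylation near 0.2 and
    # collaborative demethylation near 0.05 are the favoured rates; the
    # non-collaborative demethylation noise (h-, m- = 0.03) sits in the
    # favoured low-noise band and is what makes the U state long-lived —
    # it clears stray h/m sites before the methylation feedback can seed a
    # flip (collaborative systems tolerate far more such noise than the
    # standard model does).
    full_feedback = MotifPreset(
        "full_feedback",
        frozenset({"u+h", "m-h", "h-h"}),
        {"u+": 1e-4, "h+": 1e-4, "h-": 0.03, "m-": 0.03,
         "u+m": 0.2, "h+m": 0.2, "h+h": 0.2, "h-u": 0.05, "m-u": 0.05},
    )
    # Tuned for the island-in-a-sea geometry.  Collaborative methylation keeps
    # the favoured 0.2 but acts locally (nearest neighbour); collaborative
    # demethylation at 0.15, distance-decayed and mediated only by island u
    # sites, is strong enough for the island to defend its edge against
    # methylation invasion yet decays enough for the sea to stay methylated
    # about 20 sites beyond the island boundary.
    spatial_default = MotifPreset(
        "spatial_default",
        frozenset({"u+h", "m-h", "h-h"}),
        {"u+": 1e-4, "h+": 1e-4, "h-": 1e-3, "m-": 1e-3,
         "u+m": 0.2, "h+m": 0.2, "h+h": 0.2, "h-u": 0.15, "m-u": 0.15},
    )
    return {p.name: p for p in
            (standard, collaborative_full, minimal, full_feedback, spatial_default)}


MOTIFS: Mapping[str, MotifPreset] = _motifs()


def motif_preset(name: str) -> MotifPreset:
    """Look up a motif preset by name."""
    try:
        return MOTIFS[name]
    except KeyError:
        raise ValueError(
            f"unknown motif {name!r}; available: {sorted(MOTIFS)}"
        ) from None


@dataclass(frozen=True)
class ReactionScheme:
    """A complete assignment of the twelve reaction rates.

    Rates are per-attempt selection probabilities; their sum must be <= 1,
    the remainder being the no-op probability.  Use :func:`make_scheme` to
    construct a validated instance.
    """

    rates: Mapping[str, float]
    motif: str = "collaborative_full"
    zero_constraints: frozenset = field(default_factory=frozenset)

    def rate(self, reaction_id: str) -> float:
        return self.rates[reaction_id]

    def rate_vector(self) -> np.ndarray:
        """Rates as a float64 vector in canonical :data:`REACTION_IDS` order."""
        return np.array([self.rates[r] for r in REACTION_IDS], np.float64)

    @property
    def total_rate(self) -> float:
        return float(sum(self.rates.values()))

    def replace(self, **rate_updates: float) -> "ReactionScheme":
        """Return a new validated scheme with some rates replaced."""
        rates = dict(self.rates)
        rates.update(rate_updates)
        return make_scheme(rates, self.motif)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {r: self.rates[r] for r in REACTION_IDS}
        d["motif"] = self.motif
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionScheme":
        d = dict(d)
        motif = d.pop("motif", "collaborative_full")
        return make_scheme(d, motif)

    @classmethod
    def load(cls, path) -> "ReactionScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_scheme(
    rates: Mapping[str, float],
    motif: Union[str, MotifPreset] = "collaborative_full",
) -> ReactionScheme:
    """Build and validate a reaction scheme.

    Missing reaction ids default to rate 0.  Raises ``ValueError`` for
    unknown ids, negative rates, non-zero rates on reactions the motif pins
    to zero, or a rate sum exceeding 1.
    """
    preset = motif_preset(motif) if isinstance(motif, str) else motif
    unknown = set(rates) - set(REACTION_IDS)
    if unknown:
        raise ValueError(f"unknown reaction id(s): {sorted(unknown)}")
    full = {r: float(rates.get(r, 0.0)) for r in REACTION_IDS}
    for rid, v in full.items():
        if v < 0:
            raise ValueError(f"negative rate for {rid}: {v}")
        if rid in preset.zero_constraints and v != 0.0:
            raise ValueError(
                f"reaction {rid} is pinned to 0 by motif {preset.name!r} but has rate {v}"
            )
    total = sum(full.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"rates sum to {total}, which exceeds 1")
    if total > 0.99:
        warnings.warn(
            f"rates sum to {total:.4f}; almost every attempt selects a "
            "reaction, leaving no no-op headroom",
            stacklevel=2,
        )
    return ReactionScheme(full, preset.name, preset.zero_constraints)


def preset_scheme(motif: Union[str, MotifPreset]) -> ReactionScheme:
    """The suggested-rates scheme of a motif preset, validated."""
    preset = motif_preset(motif) if isinstance(motif, str) else motif
    if preset.suggested_rates is None:
        raise ValueError(f"motif {preset.name!r} has no suggested rates")
    return make_scheme(preset.suggested_rates, preset)
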