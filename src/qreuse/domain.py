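"""Monsters, worlds, trial arrays, and hypothesis spaces.

The task world consists of three monsters (one blue, one red, one purple),
each with a head shape (square or circle) and a number of legs (1-3).  A
*trial array* reveals some features and hides others; the *hypothesis space*
of a trial array is the set of complete worlds consistent with everything
revealed, under a uniform prior.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

COLORS: tuple[str, ...] = ("Blue", "Red", "Purple")
SHAPES: tuple[str, ...] = ("Square", "Circle")
LEG_VALUES: tuple[int, ...] = (1, 2, 3)

#: Sentinel for an occluded feature in a trial array.
HIDDEN = None


@dataclass(frozen=True)
class Monster:
    """A single monster: color, head shape, and number of legs."""

    color: str
    head: str
    legs: int

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.head not in SHAPES:
            raise ValueError(f"unknown head shape {self.head!r}")
        if self.legs not in LEG_VALUES:
            raise ValueError(f"invalid leg count {self.legs!r}")


@dataclass(frozen=True)
class World:
    """A full assignment of features to the three monsters (one hypothesis).

    ``monsters`` are ordered Blue, Red, Purple.  ``as_tuple()`` gives the
    compact ``((head, legs), ...)`` form the interpreter consumes.
    """

    monsters: tuple[Monster, Monster, Monster]

    def __post_init__(self) -> None:
        if tuple(m.color for m in self.monsters) != COLORS:
            raise ValueError("world must contain one monster per color, ordered Blue, Red, Purple")

    @classmethod
    def from_features(cls, features: dict[str, tuple[str, int]]) -> "World":
        return cls(tuple(Monster(c, *features[c]) for c in COLORS))  # type: ignore[arg-type]

    def monster(self, color: str) -> Monster:
        return self.monsters[COLORS.index(color)]

    def as_tuple(self) -> tuple[tuple[str, int], ...]:
        return tuple((m.head, m.legs) for m in self.monsters)

    def to_json(self) -> dict:
        return {m.color: {"head": m.head, "legs": m.legs} for m in self.monsters}


@dataclass(frozen=True)
class TrialArray:
    """A partially observed set of three monsters.

    ``observations`` maps each color to ``{"head": shape-or-None,
    "legs": legs-or-None}`` where ``None`` encodes a hidden feature.  The
    hidden counts ``h`` (heads) and ``l`` (legs) are derived, never stored.
    An optional ``truth`` world is carried for answer simulation only;
    scoring operations never consult it.
    """

    array_id: str
    observations: dict[str, dict[str, object]]
    truth: World | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for color in COLORS:
            obs = self.observations.get(color)
            if obs is None:
                raise ValueError(f"missing observations for {color}")
            head, legs = obs.get("head"), obs.get("legs")
            if head is not HIDDEN and head not in SHAPES:
                raise ValueError(f"bad head observation {head!r} for {color}")
            if legs is not HIDDEN and legs not in LEG_VALUES:
                raise ValueError(f"bad legs observation {legs!r} for {color}")
        if self.truth is not None and not self.consistent_with(self.truth):
            raise ValueError("stored true world contradicts the revealed observations")

    @property
    def hidden_heads(self) -> int:
        return sum(1 for c in COLORS if self.observations[c]["head"] is HIDDEN)

    @property
    def hidden_legs(self) -> int:
        return sum(1 for c in COLORS if self.observations[c]["legs"] is HIDDEN)

    @property
    def pattern(self) -> tuple[int, int]:
        return (self.hidden_heads, self.hidden_legs)

    def n_hidden(self, color: str) -> int:
        obs = self.observations[color]
        return (obs["head"] is HIDDEN) + (obs["legs"] is HIDDEN)

    @property
    def display_order(self) -> tuple[str, ...]:
        """Colors left-to-right: fewest hidden features first, ties by Blue<Red<Purple."""
        return tuple(sorted(COLORS, key=lambda c: (self.n_hidden(c), COLORS.index(c))))

    def consistent_with(self, world: World) -> bool:
        for color in COLORS:
            obs = self.observations[color]
            m = world.monster(color)
            if obs["head"] is not HIDDEN and obs["head"] != m.head:
                return False
            if obs["legs"] is not HIDDEN and obs["legs"] != m.legs:
                return False
        return True

    def key(self) -> str:
        """Canonical string identifying the observation pattern (cache key)."""
        parts = []
        for color in COLORS:
            obs = self.observations[color]
            parts.append(f"{color}:{obs['head']}/{obs['legs']}")
        return ";".join(parts)

    def to_json(self) -> dict:
        out = {"array_id": self.array_id, "observations": self.observations}
        if self.truth is not None:
            out["truth"] = self.truth.to_json()
        return out

    @classmethod
    def from_json(cls, obj: dict) -> "TrialArray":
        truth = None
        if obj.get("truth"):
            truth = World.from_features(
                {c: (v["head"], v["legs"]) for c, v in obj["truth"].items()}
            )
        observations = {
            c: {"head": v.get("head"), "legs": v.get("legs")}
            for c, v in obj["observations"].items()
        }
        return cls(array_id=obj["array_id"], observations=observations, truth=truth)

    def dumps(self) -> str:
        return json.dumps(self.to_json())


@dataclass(frozen=True)
class HypothesisSpace:
    """The worlds consistent with a trial array, with a uniform prior."""

    worlds: tuple[World, ...]

    def __post_init__(self) -> None:
        if not self.worlds:
            raise ValueError("hypothesis space is empty")

    @property
    def size(self) -> int:
        return len(self.worlds)

    @property
    def prior(self) -> np.ndarray:
        return np.full(self.size, 1.0 / self.size)


def enumerate_monsters() -> tuple[Monster, ...]:
    """All 18 distinct monsters, in (color, head, legs) lexicographic order."""
    return tuple(
        Monster(c, h, n) for c in COLORS for h in SHAPES for n in LEG_VALUES
    )


def enumerate_worlds() -> tuple[World, ...]:
    """All 216 complete worlds (6 feature combinations per color)."""
    per_color = [[(h, n) for h in SHAPES for n in LEG_VALUES] for _ in COLORS]
    return tuple(
        World.from_features(dict(zip(COLORS, combo)))
        for combo in itertools.product(*per_color)
    )


def enumerate_hidden_patterns() -> tuple[tuple[int, int], ...]:
    """The 14 canonical (hidden heads, hidden legs) patterns.

    Every way of covering 0-3 heads and 0-3 legs, excluding nothing-covered
    (0, 0) and everything-covered (3, 3).
    """
    return tuple(
        (h, l)
        for h in range(4)
        for l in range(4)
        if (h, l) not in ((0, 0), (3, 3))
    )


def make_trial_array(
    pattern: tuple[int, int],
    rng_seed: int | np.random.Generator,
    array_id: str | None = None,
    canonical_only: bool = True,
) -> TrialArray:
    """Construct a random trial array with the given hidden-feature pattern.

    The three monsters' features are sampled first, then which monsters'
    heads/legs are covered.  The true world is stored alongside for answer
    simulation.  The same seed always yields the same array.

    Parameters
    ----------
    pattern : (h, l)
        Number of hidden heads and hidden legs, each 0-3.
    rng_seed : int or Generator
        Seed (or generator) driving all sampling.
    canonical_only : bool
        If True (default), reject the patterns (0, 0) and (3, 3) that are
        excluded from the canonical 14-array set.
    """
    h, l = pattern
    if not (0 <= h <= 3 and 0 <= l <= 3):
        raise ValueError(f"pattern {pattern} out of bounds")
    if canonical_only and (h, l) in ((0, 0), (3, 3)):
        raise ValueError(f"pattern {pattern} is excluded from the canonical array set")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    features = {
        c: (SHAPES[rng.integers(2)], LEG_VALUES[rng.integers(3)]) for c in COLORS
    }
    truth = World.from_features(features)
    head_hidden = set(rng.choice(len(COLORS), size=h, replace=False).tolist())
    legs_hidden = set(rng.choice(len(COLORS), size=l, replace=False).tolist())
    observations = {}
    for i, c in enumerate(COLORS):
        observations[c] = {
            "head": HIDDEN if i in head_hidden else features[c][0],
            "legs": HIDDEN if i in legs_hidden else features[c][1],
        }
    if array_id is None:
        array_id = f"h{h}l{l}"
    return TrialArray(array_id=array_id, observations=observations, truth=truth)


def hypothesis_space(array: TrialArray) -> HypothesisSpace:
    """All worlds consistent with a trial array (size 2^h * 3^l), uniform prior."""
    per_color = []
    for c in COLORS:
        obs = array.observations[c]
        heads = SHAPES if obs["head"] is HIDDEN else (obs["head"],)
        legs = LEG_VALUES if obs["legs"] is HIDDEN else (obs["legs"],)
        per_color.append([(hd, lg) for hd in heads for lg in legs])
    worlds = tuple(
        World.from_features(dict(zip(COLORS, combo)))
        for combo in itertools.product(*per_color)
    )
    return HypothesisSpace(worlds)


def canonical_arrays(seed: int = 0) -> dict[str, TrialArray]:
    """One seeded trial array for each of the 14 canonical patterns."""
    rng = np.random.default_rng(seed)
    return {
        f"h{h}l{l}": make_trial_array((h, l), rng, array_id=f"h{h}l{l}")
        for h, l in enumerate_hidden_patterns()
    }
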