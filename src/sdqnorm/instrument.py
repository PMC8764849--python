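"""The SDQ instrument definition: scales, item membership, reverse coding.

The SDQ has 25 items rated 0/1/2 (*not true*, *somewhat true*, *certainly
true*), evenly divided over five 5-item scales: emotional problems, conduct
problems, hyperactivity/inattention, social (peer) problems, and prosocial
behaviour. Composite difficulties scales are formed by pooling items:
externalizing = conduct + hyperactivity, internalizing = emotional + social,
total = all 20 difficulties items. Five positively worded items on the
difficulties scales are reverse-coded before summation.

The item-to-scale map below is the standard published SDQ key (1-based item
numbers). It ships as a versioned built-in and can be overridden from a JSON
document for translated or re-ordered forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

N_ITEMS = 25
ITEM_CATEGORIES = (0, 1, 2)

#: Standard SDQ key, 1-based item numbers.
_BASE_ITEMS = {
    "emotional": (3, 8, 13, 16, 24),
    "conduct": (5, 7, 12, 18, 22),
    "hyperactivity": (2, 10, 15, 21, 25),
    "social": (6, 11, 14, 19, 23),
    "prosocial": (1, 4, 9, 17, 20),
}

#: The five positively worded, reverse-coded items (all on difficulties scales).
_REVERSED_ITEMS = (7, 11, 14, 21, 25)

BASE_SCALES = tuple(_BASE_ITEMS)
DIFFICULTY_BASE_SCALES = ("emotional", "conduct", "hyperactivity", "social")
COMPOSITE_SCALES = ("externalizing", "internalizing", "total")
ALL_SCALES = BASE_SCALES + COMPOSITE_SCALES


@dataclass(frozen=True)
class ScaleDefinition:
    """One SDQ scale: member items, reversed subset, score range, direction.

    ``direction`` is ``"problem"`` for the difficulties scales (high score =
    many problems) and ``"strength"`` for prosocial (high score = many
    strengths); classification rules mirror across the two directions.
    """

    name: str
    member_items: tuple[int, ...]
    reversed_items: tuple[int, ...]
    score_max: int
    direction: str  # "problem" | "strength"

    def __post_init__(self) -> None:
        if not set(self.reversed_items) <= set(self.member_items):
            raise ValueError(f"{self.name}: reversed items not a subset of members")
        if self.score_max != 2 * len(self.member_items):
            raise ValueError(f"{self.name}: score_max must be 2 * number of items")
        if self.direction not in ("problem", "strength"):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")

    @property
    def score_range(self) -> tuple[int, int]:
        return (0, self.score_max)

    @property
    def n_items(self) -> int:
        return len(self.member_items)


@dataclass(frozen=True)
class Instrument:
    """A versioned set of scale definitions forming one questionnaire key."""

    version: str
    scales: dict[str, ScaleDefinition] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ScaleDefinition:
        return self.scales[name]

    def __iter__(self) -> Iterable[str]:
        return iter(self.scales)

    @property
    def scale_names(self) -> tuple[str, ...]:
        return tuple(self.scales)

    def validate(self) -> None:
        """Check the structural invariants of the SDQ key."""
        for name in BASE_SCALES:
            if self.scales[name].n_items != 5:
                raise ValueError(f"base scale {name} must have 5 items")
        conduct = set(self.scales["conduct"].member_items)
        hyper = set(self.scales["hyperactivity"].member_items)
        emo = set(self.scales["emotional"].member_items)
        soc = set(self.scales["social"].member_items)
        if set(self.scales["externalizing"].member_items) != conduct | hyper:
            raise ValueError("externalizing must pool conduct and hyperactivity items")
        if set(self.scales["internalizing"].member_items) != emo | soc:
            raise ValueError("internalizing must pool emotional and social items")
        if set(self.scales["total"].member_items) != conduct | hyper | emo | soc:
            raise ValueError("total must pool all 20 difficulties items")
        reversed_all = {
            i for s in self.scales.values() if s.direction == "problem"
            for i in s.reversed_items
        }
        if len(reversed_all) != 5:
            raise ValueError("exactly five reversed items expected on difficulties scales")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "version": self.version,
            "scales": {
                name: {
                    "member_items": list(s.member_items),
                    "reversed_items": list(s.reversed_items),
                    "score_max": s.score_max,
                    "direction": s.direction,
                }
                for name, s in self.scales.items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Instrument":
        doc = json.loads(Path(path).read_text())
        scales = {
            name: ScaleDefinition(
                name=name,
                member_items=tuple(d["member_items"]),
                reversed_items=tuple(d["reversed_items"]),
                score_max=int(d["score_max"]),
                direction=d["direction"],
            )
            for name, d in doc["scales"].items()
        }
        inst = cls(version=doc["version"], scales=scales)
        inst.validate()
        return inst


def _build_default() -> Instrument:
    rev = set(_REVERSED_ITEMS)
    scales: dict[str, ScaleDefinition] = {}
    for name, items in _BASE_ITEMS.items():
        scales[name] = ScaleDefinition(
            name=name,
            member_items=items,
            reversed_items=tuple(sorted(rev & set(items))),
            score_max=10,
            direction="strength" if name == "prosocial" else "problem",
        )
    ext = tuple(sorted(_BASE_ITEMS["conduct"] + _BASE_ITEMS["hyperactivity"]))
    intl = tuple(sorted(_BASE_ITEMS["emotional"] + _BASE_ITEMS["social"]))
    tot = tuple(sorted(ext + intl))
    for name, items, mx in (
        ("externalizing", ext, 20),
        ("internalizing", intl, 20),
        ("total", tot, 40),
    ):
        scales[name] = ScaleDefinition(
            name=name,
            member_items=items,
            reversed_items=tuple(sorted(rev & set(items))),
            score_max=mx,
            direction="problem",
        )
    inst = Instrument(version="sdq-standard-1", scales=scales)
    inst.validate()
    return inst


SDQ_INSTRUMENT = _build_default()
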