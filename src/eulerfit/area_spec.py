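"""Textual area specifications: parsing, validation, derived quantities.

An *area specification* lists the set intersections (zones) that should
appear in the diagram, one per line, as whitespace-separated set labels
followed by the desired cardinality, e.g.::

    cell_adhesion extracellular_matrix 3

Only the relative sizes of the cardinalities matter for layout; the
absolute numbers are shown as region value labels in the rendered
diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = [
    "AreaSpecification",
    "AreaSpecError",
    "parse_area_spec",
    "serialize_area_spec",
    "desired_proportions",
    "equivalence_classes",
    "zone_key",
]

logger = logging.getLogger("eulerfit")

#: Separator used in canonical zone keys. Labels are whitespace-free
#: tokens, so a space can never occur inside a label.
ZONE_KEY_SEP = " "


class AreaSpecError(ValueError):
    """Raised for malformed or empty area specifications."""


def zone_key(zone: frozenset[str]) -> str:
    """Canonical string key for a zone: labels sorted, space-joined."""
    return ZONE_KEY_SEP.join(sorted(zone))


@dataclass
class AreaSpecification:
    """Desired zones (nonempty label sets) mapped to positive cardinalities.

    Attributes
    ----------
    zones:
        Mapping from frozenset of labels to cardinality (> 0).
    labels:
        Union of all zone labels, ordered by first appearance.
    """

    zones: dict[frozenset[str], float]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            seen: dict[str, None] = {}
            for zone in self.zones:
                for lab in sorted(zone):
                    seen.setdefault(lab, None)
            self.labels = list(seen)
        self.validate()

    def validate(self) -> None:
        if not self.zones:
            raise AreaSpecError("empty specification")
        for zone, card in self.zones.items():
            if not zone:
                raise AreaSpecError("zone with no labels")
            if not all(isinstance(lab, str) and lab for lab in zone):
                raise AreaSpecError(f"invalid label in zone {zone!r}")
            if not card > 0:
                raise AreaSpecError(
                    f"non-positive cardinality {card!r} for zone {zone_key(zone)!r}"
                )
        union = set().union(*self.zones)
        if set(self.labels) != union:
            raise AreaSpecError("labels do not match the union of zone labels")

    @property
    def total(self) -> float:
        return float(sum(self.zones.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AreaSpecification):
            return NotImplemented
        return self.zones == other.zones and set(self.labels) == set(other.labels)


def parse_area_spec(text: str) -> AreaSpecification:
    """Parse an area specification from text.

    One zone per non-blank line: labels then a cardinality, whitespace
    separated. Lines starting with ``//`` are comments. Duplicate
    label-set lines are merged by summing their cardinalities (with a
    logged warning).
    """
    zones: dict[frozenset[str], float] = {}
    labels: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise AreaSpecError(
                f"line {lineno}: expected labels followed by a cardinality: {line!r}"
            )
        try:
            card = float(tokens[-1])
        except ValueError:
            raise AreaSpecError(
                f"line {lineno}: last token {tokens[-1]!r} is not a number"
            ) from None
        if not card > 0:
            raise AreaSpecError(f"line {lineno}: cardinality must be > 0, got {card}")
        zone = frozenset(tokens[:-1])
        for lab in tokens[:-1]:
            labels.setdefault(lab, None)
        if zone in zones:
            logger.warning(
                "duplicate zone %r on line %d: cardinalities summed",
                zone_key(zone),
                lineno,
            )
            zones[zone] += card
        else:
            zones[zone] = card
    if not zones:
        raise AreaSpecError("empty specification")
    return AreaSpecification(zones=zones, labels=list(labels))


def serialize_area_spec(spec: AreaSpecification) -> str:
    """Write a specification back to its text format (one zone per line)."""
    lines = []
    for zone in sorted(spec.zones, key=zone_key):
        card = spec.zones[zone]
        num = f"{card:g}"
        if float(num) != card:  # keep full precision for awkward floats
            num = repr(float(card))
        lines.append(f"{zone_key(zone)} {num}")
    return "\n".join(lines) + "\n"


def desired_proportions(spec: AreaSpecification) -> dict[frozenset[str], float]:
    """Desired fraction of total diagram area for each zone.

    Each proportion is ``cardinality / total``; values sum to 1.
    """
    total = spec.total
    return {zone: card / total for zone, card in spec.zones.items()}


def equivalence_classes(spec: AreaSpecification) -> list[frozenset[str]]:
    """Partition labels into classes occurring in exactly the same zones.

    Labels in one class must be drawn as coincident ellipses, so the
    optimizer gives them one shared parameter set. Classes are ordered
    by first appearance of their first label.
    """
    membership: dict[str, frozenset[frozenset[str]]] = {
        lab: frozenset(z for z in spec.zones if lab in z) for lab in spec.labels
    }
    classes: dict[frozenset[frozenset[str]], list[str]] = {}
    for lab in spec.labels:
        classes.setdefault(membership[lab], []).append(lab)
    return [frozenset(labs) for labs in classes.values()]
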