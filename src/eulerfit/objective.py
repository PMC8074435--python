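"""The multi-criteria objective: five penalties, normalized and weighted.

The layout quality of a candidate diagram is scored as ``sum(W_i * c_i)``
over five criteria, each normalized to [0, 1]:

C1  region area difference — how far the sampled region proportions are
    from the desired ones (missing regions contribute their desired
    proportion, unwanted regions their actual proportion);
C2  missing one-label region — pull apart an ellipse that should be
    disjoint from everything but is not;
C3  missing two-or-more-label region — pull ellipses towards (or push
    extraneous ellipses away from) the region that best matches a
    desired but absent intersection;
C4  unwanted region — absorb stray one-label slivers of contained
    ellipses, and separate ellipse pairs that meet in a region nobody
    asked for;
C5  unwanted expanded overlap — keep a visible gap between ellipses
    that should not touch, by penalizing overlap of 15%-expanded
    copies.

The weights were tuned once and are treated as constants:
W1=16.35, W2=23.6, W3=6.35, W4=0.01, W5=3.6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

from .area_spec import AreaSpecification, desired_proportions, zone_key
from .geometry import (
    GRID_STEP,
    BitmapCache,
    DiagramLayout,
    Ellipse,
    RegionSample,
    expand_ellipse,
    ideal_separation,
    pair_overlap_area,
    sample_regions,
)

__all__ = [
    "Weights",
    "RegionClassification",
    "CriterionTerms",
    "FitnessBreakdown",
    "classify_regions",
    "region_area_difference",
    "missing_one_label_penalty",
    "missing_multi_label_penalty",
    "unwanted_region_penalty",
    "unwanted_expanded_overlap_penalty",
    "normalize_criteria",
    "total_fitness",
]


@dataclass(frozen=True)
class Weights:
    """Objective weights, in criterion order C1..C5."""

    region_area_difference: float = 16.35
    missing_one_label: float = 23.6
    missing_multi_label: float = 6.35
    unwanted_region: float = 0.01
    unwanted_expanded_overlap: float = 3.6

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.region_area_difference,
            self.missing_one_label,
            self.missing_multi_label,
            self.unwanted_region,
            self.unwanted_expanded_overlap,
        )


@dataclass
class RegionClassification:
    """Partition of desired and actual zones by agreement status."""

    matched: set[frozenset[str]]
    missing_one: set[frozenset[str]]
    missing_multi: set[frozenset[str]]
    unwanted: set[frozenset[str]]


def classify_regions(
    desired: set[frozenset[str]], actual: set[frozenset[str]]
) -> RegionClassification:
    """Split zones into matched / missing (by size) / unwanted."""
    matched = desired & actual
    missing = desired - actual
    return RegionClassification(
        matched=matched,
        missing_one={z for z in missing if len(z) == 1},
        missing_multi={z for z in missing if len(z) >= 2},
        unwanted=actual - desired,
    )


@dataclass
class CriterionTerms:
    """Raw value of one criterion, split by the kind of its summands.

    Area summands are normalized against the total covered area;
    distance summands against (term count x diagram diameter).
    """

    area: float = 0.0
    dist_sum: float = 0.0
    n_dist: int = 0

    @property
    def raw(self) -> float:
        return self.area + self.dist_sum


def region_area_difference(
    desired: dict[frozenset[str], float], actual: RegionSample
) -> float:
    """Raw C1: sum of |desired - actual| proportion differences.

    Matched zones contribute the absolute difference, unwanted zones
    their full actual proportion, missing zones their full desired
    proportion. Ranges over [0, 2].
    """
    value = 0.0
    for zone, d in desired.items():
        a = actual.proportions.get(zone)
        value += abs(d - a) if a is not None else d
    for zone, a in actual.proportions.items():
        if zone not in desired:
            value += a
    return value


def _centre_distance(e1: Ellipse, e2: Ellipse) -> float:
    return math.hypot(e1.cx - e2.cx, e1.cy - e2.cy)


def _separation_deficit(e1: Ellipse, e2: Ellipse) -> float:
    """max(0, ideal separation - centre distance); 0 once clear."""
    return max(0.0, ideal_separation(e1, e2) - _centre_distance(e1, e2))


def missing_one_label_penalty(
    cls: RegionClassification, layout: DiagramLayout, actual: RegionSample
) -> CriterionTerms:
    """Raw C2: push an ellipse with a missing one-label region off all overlaps.

    Overlap is read from the sampled zone map: another ellipse overlaps
    when some realized zone contains both labels.
    """
    terms = CriterionTerms()
    actual_pairs = _co_occurring_pairs(actual.proportions)
    for zone in sorted(cls.missing_one, key=zone_key):
        (label,) = zone
        e_missing = layout.ellipses[label]
        for other in layout.labels:
            if other == label:
                continue
            if frozenset((label, other)) in actual_pairs:
                terms.dist_sum += _separation_deficit(
                    e_missing, layout.ellipses[other]
                )
                terms.n_dist += 1
    return terms


def _zone_at(layout: DiagramLayout, p: tuple[float, float]) -> frozenset[str]:
    """Labels of all ellipses containing point ``p`` (direct evaluation)."""
    return frozenset(
        lab for lab, e in layout.ellipses.items() if bool(e.contains(p[0], p[1]))
    )


def _viable_anchor(
    layout: DiagramLayout, actual: RegionSample, zone: frozenset[str]
) -> tuple[float, float]:
    """A point known to lie in ``zone``: the point average if it still
    falls in the zone (it may not, e.g. for split regions), else the
    first sampled point."""
    p_first, p_average = actual.anchors[zone]
    if _zone_at(layout, p_average) == zone:
        return p_average
    return p_first


def missing_multi_label_penalty(
    cls: RegionClassification, layout: DiagramLayout, actual: RegionSample
) -> CriterionTerms:
    """Raw C3: steer ellipses so each missing multi-label region can form.

    For each missing zone the realized zone sharing the most labels is
    selected (ties: fewest total labels, then lexicographic). If it
    lacks some of the missing zone's labels, those ellipses are pulled
    towards an anchor point inside it; if it covers the zone but has
    extras, each extraneous ellipse is pushed off every ellipse of the
    missing zone.
    """
    terms = CriterionTerms()
    actual_zones = sorted(actual.proportions, key=zone_key)
    for m in sorted(cls.missing_multi, key=zone_key):
        sharing = [z for z in actual_zones if z & m]
        if not sharing:
            # nothing shares a label: pull every ellipse of the zone
            # towards the layout centroid
            n = len(layout.ellipses)
            gx = sum(e.cx for e in layout.ellipses.values()) / n
            gy = sum(e.cy for e in layout.ellipses.values()) / n
            for lab in sorted(m):
                e = layout.ellipses[lab]
                terms.dist_sum += math.hypot(e.cx - gx, e.cy - gy)
                terms.n_dist += 1
            continue
        r_common = min(sharing, key=lambda z: (-len(z & m), len(z), zone_key(z)))
        if not m <= r_common:
            anchor = _viable_anchor(layout, actual, r_common)
            for lab in sorted(m - r_common):
                e = layout.ellipses[lab]
                terms.dist_sum += math.hypot(e.cx - anchor[0], e.cy - anchor[1])
                terms.n_dist += 1
        else:
            for extra in sorted(r_common - m):
                for lab in sorted(m):
                    terms.dist_sum += _separation_deficit(
                        layout.ellipses[extra], layout.ellipses[lab]
                    )
                    terms.n_dist += 1
    return terms


def _co_occurring_pairs(zones) -> set[frozenset[str]]:
    """All unordered label pairs that appear together in some zone."""
    pairs: set[frozenset[str]] = set()
    for z in zones:
        if len(z) >= 2:
            pairs.update(frozenset(p) for p in combinations(z, 2))
    return pairs


def unwanted_region_penalty(
    cls: RegionClassification,
    layout: DiagramLayout,
    actual: RegionSample,
    desired: set[frozenset[str]],
) -> CriterionTerms:
    """Raw C4: remove regions nobody asked for.

    Case 1 — the unwanted region has a single label and some desired
    zone contains it: the ellipse should sit inside another, so its
    stray area is penalized directly. Case 2 — no desired zone covers
    the unwanted region's labels: every label pair that never co-occurs
    in a desired zone is pushed apart, with a tie-breaking factor that
    starts at 1 and grows by 0.1 per matching pair. Unwanted
    multi-label regions covered by a desired zone are left to C1.
    """
    terms = CriterionTerms()
    desired_pairs = _co_occurring_pairs(desired)
    for u in sorted(cls.unwanted, key=zone_key):
        covered = any(u <= d for d in desired)
        if covered:
            if len(u) == 1:
                terms.area += actual.zone_area(u)
        else:
            factor = 1.0
            for la, lb in combinations(sorted(u), 2):
                if frozenset((la, lb)) in desired_pairs:
                    continue
                terms.dist_sum += factor * _separation_deficit(
                    layout.ellipses[la], layout.ellipses[lb]
                )
                terms.n_dist += 1
                factor += 0.1
    return terms


def unwanted_expanded_overlap_penalty(
    spec: AreaSpecification, layout: DiagramLayout, grid_step: float = GRID_STEP
) -> CriterionTerms:
    """Raw C5: overlap area of 15%-expanded ellipses that should not touch.

    Only label pairs that co-occur in no desired zone contribute, so
    the criterion never fights a wanted intersection; it just opens a
    small visual gap between unrelated ellipses.
    """
    terms = CriterionTerms()
    labels = layout.labels
    desired_pairs = _co_occurring_pairs(spec.zones)
    for la, lb in combinations(labels, 2):
        if frozenset((la, lb)) in desired_pairs:
            continue
        terms.area += pair_overlap_area(
            expand_ellipse(layout.ellipses[la]),
            expand_ellipse(layout.ellipses[lb]),
            grid_step,
        )
    return terms


def normalize_criteria(
    raw: dict[str, CriterionTerms | float],
    layout: DiagramLayout,
    actual: RegionSample,
) -> dict[str, float]:
    """Map raw criterion values into [0, 1].

    C1 is divided by its analytic maximum of 2. Distance summands are
    divided by (term count x union bounding-box diagonal); area
    summands by the total covered area. Everything is clamped to
    [0, 1]; criteria with no contributing terms normalize to 0.
    """
    diameter = layout.diameter()
    total_area = actual.covered_area
    out: dict[str, float] = {}
    for name, val in raw.items():
        if name == "C1":
            out["c1"] = min(1.0, max(0.0, float(val) / 2.0))
            continue
        assert isinstance(val, CriterionTerms)
        v = 0.0
        if val.area > 0 and total_area > 0:
            v += val.area / total_area
        if val.n_dist > 0 and diameter > 0:
            v += val.dist_sum / (val.n_dist * diameter)
        out[name.lower()] = min(1.0, max(0.0, v))
    return out


@dataclass
class FitnessBreakdown:
    """Raw and normalized criteria plus the weighted total."""

    raw: dict[str, float]
    normalized: dict[str, float]
    total: float
    weights: Weights = field(default_factory=Weights)

    def to_dict(self) -> dict:
        return {
            "raw": dict(self.raw),
            "normalized": dict(self.normalized),
            "weights": list(self.weights.as_tuple()),
            "total": self.total,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def total_fitness(
    layout: DiagramLayout,
    spec: AreaSpecification,
    w: Weights | None = None,
    grid_step: float = GRID_STEP,
    cache: BitmapCache | None = None,
    sample: RegionSample | None = None,
) -> FitnessBreakdown:
    """Sample the layout once and score all five criteria."""
    if w is None:
        w = Weights()
    if sample is None:
        sample = sample_regions(layout, grid_step, cache=cache, keep_grid=False)
    desired = desired_proportions(spec)
    cls = classify_regions(set(desired), sample.zones)

    c1_raw = region_area_difference(desired, sample)
    c2 = missing_one_label_penalty(cls, layout, sample)
    c3 = missing_multi_label_penalty(cls, layout, sample)
    c4 = unwanted_region_penalty(cls, layout, sample, set(desired))
    c5 = unwanted_expanded_overlap_penalty(spec, layout, grid_step)

    normalized = normalize_criteria(
        {"C1": c1_raw, "C2": c2, "C3": c3, "C4": c4, "C5": c5}, layout, sample
    )
    weights = w.as_tuple()
    total = sum(
        weights[i] * normalized[f"c{i + 1}"] for i in range(5)
    )
    return FitnessBreakdown(
        raw={
            "C1": c1_raw,
            "C2": c2.raw,
            "C3": c3.raw,
            "C4": c4.raw,
            "C5": c5.raw,
        },
        normalized=normalized,
        total=total,
        weights=w,
    )
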