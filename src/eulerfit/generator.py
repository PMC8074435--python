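"""Random area-specification generators for tuning and benchmarking.

``random_spec`` draws a fixed number of distinct zones: each zone's
size is uniform in [1, max_zone_size], its labels are a uniform sample
without replacement, and its cardinality is a uniform integer in
[1, 10]. Draws that duplicate an existing zone are rejected, and a
whole draw is retried until every declared set appears in at least one
zone, so the requested set and intersection counts are properties of
the output, not just of the request.

``scalability_suite`` produces the 90-specification benchmark: for
every set count s in 3..20, five specs with intersection counts
round(s * m) for m in {1, 1.5, 2, 2.5, 3}, zone sizes in 1..4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .area_spec import AreaSpecification

__all__ = [
    "GeneratorConfig",
    "random_spec",
    "scalability_suite",
    "possible_zone_count",
    "group_config",
    "TUNING_GROUPS",
    "COMPARISON_GROUPS",
]

#: (n_sets, n_zones, max_zone_size) per group of the weight-tuning dataset.
TUNING_GROUPS = {
    "a": (3, 4, 2),
    "b": (3, 6, 3),
    "c": (5, 7, 3),
    "d": (5, 11, 5),
    "e": (7, 10, 4),
    "f": (7, 15, 7),
}

#: Groups used for the hill-climbing vs simulated-annealing comparison.
COMPARISON_GROUPS = {
    "a": (3, 3, 2),
    "b": (3, 7, 3),
    "c": (5, 6, 4),
    "d": (5, 12, 6),
    "e": (7, 9, 4),
    "f": (7, 14, 6),
}

CARDINALITY_RANGE = (1, 10)


def group_config(
    groups: dict[str, tuple[int, int, int]], name: str, seed: int = 0
) -> "GeneratorConfig":
    """Config for one named benchmark group.

    The published group tables state a nominal maximum intersection
    size that can exceed the set count (group d of the comparison
    table); the effective maximum is capped at the number of sets.
    """
    n_sets, n_zones, max_size = groups[name]
    return GeneratorConfig(
        n_sets=n_sets,
        n_zones=n_zones,
        max_zone_size=min(max_size, n_sets),
        seed=seed,
    )


def possible_zone_count(n_sets: int, max_zone_size: int) -> int:
    """Number of distinct nonempty zones with at most ``max_zone_size`` labels."""
    return sum(math.comb(n_sets, k) for k in range(1, max_zone_size + 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of one random specification draw."""

    n_sets: int
    n_zones: int
    max_zone_size: int
    cardinality_range: tuple[int, int] = CARDINALITY_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_zone_size <= self.n_sets:
            raise ValueError("need 1 <= max_zone_size <= n_sets")
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        lo, hi = self.cardinality_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid cardinality range")


def _set_labels(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def random_spec(cfg: GeneratorConfig) -> AreaSpecification:
    """Draw one random area specification.

    Raises ``ValueError`` when the requested number of distinct zones
    exceeds the number of possible zones, or when full label coverage
    is combinatorially impossible.
    """
    possible = possible_zone_count(cfg.n_sets, cfg.max_zone_size)
    if cfg.n_zones > possible:
        raise ValueError(
            f"{cfg.n_zones} distinct zones requested but only {possible} exist "
            f"for {cfg.n_sets} sets with zone size <= {cfg.max_zone_size}"
        )
    if cfg.n_zones * cfg.max_zone_size < cfg.n_sets:
        raise ValueError("not enough zone slots to cover every set")
    rng = np.random.default_rng(cfg.seed)
    labels = _set_labels(cfg.n_sets)
    lo, hi = cfg.cardinality_range
    for _ in range(1000):  # retry until every set is covered
        zones: dict[frozenset[str], float] = {}
        guard = 0
        while len(zones) < cfg.n_zones:
            guard += 1
            if guard > 1000 * cfg.n_zones:  # pragma: no cover - defensive
                break
            size = int(rng.integers(1, cfg.max_zone_size + 1))
            pick = rng.choice(cfg.n_sets, size=size, replace=False)
            zone = frozenset(labels[i] for i in sorted(pick))
            if zone in zones:
                continue
            zones[zone] = float(rng.integers(lo, hi + 1))
        if len(zones) == cfg.n_zones and set().union(*zones) == set(labels):
            return AreaSpecification(zones=zones, labels=labels)
    raise RuntimeError("failed to draw a covering specification")  # pragma: no cover


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def scalability_suite(seed: int = 0) -> list[tuple[str, AreaSpecification]]:
    """The 90-spec scalability benchmark, as (name, spec) pairs.

    Zone sizes are uniform in [1, min(4, s)]; the requested zone count
    round(s * m) is capped at the number of combinatorially possible
    distinct zones (this only binds for the smallest set counts).
    """
    rng = np.random.default_rng(seed)
    suite: list[tuple[str, AreaSpecification]] = []
    for s in range(3, 21):
        for m in (1.0, 1.5, 2.0, 2.5, 3.0):
            max_size = min(4, s)
            n_zones = min(_round_half_up(s * m), possible_zone_count(s, max_size))
            cfg = GeneratorConfig(
                n_sets=s,
                n_zones=n_zones,
                max_zone_size=max_size,
                seed=int(rng.integers(0, 2**31)),
            )
            suite.append((f"s{s:02d}_m{m:g}", random_spec(cfg)))
    return suite
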