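"""Evaluation metrics shared by tests, benchmarking and the CLI.

Two accuracy measures are reported for a finished layout:

* **area difference** — the sum over zones of absolute differences
  between desired and achieved area proportions (missing zones count
  their desired share, unwanted zones their achieved share), reported
  x100 as a percentage in [0, 200];
* **stress** — the normalized residual sum of squares between achieved
  region areas and desired areas after fitting a no-intercept
  least-squares scale beta, in [0, 1]. The unscaled variant (beta
  fixed at 1 on the proportion scale) is also emitted for
  transparency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .area_spec import AreaSpecification, desired_proportions, zone_key
from .geometry import GRID_STEP, DiagramLayout, RegionSample, sample_regions
from .objective import FitnessBreakdown, Weights, region_area_difference, total_fitness

__all__ = [
    "EvaluationReport",
    "area_difference_pct",
    "stress",
    "stress_unscaled",
    "evaluate",
]


def area_difference_pct(
    spec: AreaSpecification,
    layout: DiagramLayout,
    grid_step: float = GRID_STEP,
    sample: RegionSample | None = None,
) -> float:
    """Area difference on the percentage scale: 100 x raw C1, in [0, 200]."""
    if sample is None:
        sample = sample_regions(layout, grid_step, keep_grid=False)
    return 100.0 * region_area_difference(desired_proportions(spec), sample)


def _area_vectors(
    spec: AreaSpecification, sample: RegionSample, proportions: bool
) -> tuple[list[float], list[float]]:
    zones = sorted(set(spec.zones) | sample.zones, key=zone_key)
    if proportions:
        desired = desired_proportions(spec)
        d = [desired.get(z, 0.0) for z in zones]
        a = [sample.proportions.get(z, 0.0) for z in zones]
    else:
        d = [spec.zones.get(z, 0.0) for z in zones]
        a = [sample.zone_area(z) for z in zones]
    return d, a


def stress(
    spec: AreaSpecification,
    layout: DiagramLayout,
    grid_step: float = GRID_STEP,
    sample: RegionSample | None = None,
) -> float:
    """Normalized residual sum of squares, with a fitted scale.

    Over the union of desired and achieved zones (absent side = 0),
    with desired areas D and achieved areas A: beta = sum(A*D) /
    sum(D^2), stress = sum((A - beta*D)^2) / sum(A^2). Scale-free in
    both D and A; always in [0, 1].
    """
    if sample is None:
        sample = sample_regions(layout, grid_step, keep_grid=False)
    d, a = _area_vectors(spec, sample, proportions=False)
    ss_a = sum(x * x for x in a)
    if ss_a == 0:
        raise ValueError("empty layout: all achieved areas are zero")
    ss_d = sum(x * x for x in d)
    beta = sum(x * y for x, y in zip(a, d)) / ss_d if ss_d > 0 else 0.0
    return sum((x - beta * y) ** 2 for x, y in zip(a, d)) / ss_a


def stress_unscaled(
    spec: AreaSpecification,
    layout: DiagramLayout,
    grid_step: float = GRID_STEP,
    sample: RegionSample | None = None,
) -> float:
    """Stress without the fitted scale, on the proportion scale (beta = 1)."""
    if sample is None:
        sample = sample_regions(layout, grid_step, keep_grid=False)
    d, a = _area_vectors(spec, sample, proportions=True)
    ss_a = sum(x * x for x in a)
    if ss_a == 0:
        raise ValueError("empty layout: all achieved areas are zero")
    return sum((x - y) ** 2 for x, y in zip(a, d)) / ss_a


@dataclass
class EvaluationReport:
    """Everything a benchmarking run wants to know about one layout."""

    area_difference_pct: float
    area_difference: float
    stress: float
    stress_unscaled: float
    per_zone: list[dict] = field(default_factory=list)
    fitness: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    evaluated_solutions: int | None = None

    def to_dict(self) -> dict:
        out = {
            "area_difference_pct": self.area_difference_pct,
            "area_difference": self.area_difference,
            "stress": self.stress,
            "stress_unscaled": self.stress_unscaled,
            "per_zone": self.per_zone,
            "fitness": self.fitness,
            "wall_time_s": self.wall_time_s,
        }
        if self.evaluated_solutions is not None:
            out["evaluated_solutions"] = self.evaluated_solutions
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def evaluate(
    spec: AreaSpecification,
    layout: DiagramLayout,
    grid_step: float = GRID_STEP,
    w: Weights | None = None,
    wall_time_s: float = 0.0,
    evaluated_solutions: int | None = None,
) -> EvaluationReport:
    """Full accuracy report for one layout against its specification."""
    sample = sample_regions(layout, grid_step, keep_grid=False)
    desired = desired_proportions(spec)
    fb: FitnessBreakdown = total_fitness(
        layout, spec, w=w, grid_step=grid_step, sample=sample
    )
    per_zone = []
    for z in sorted(set(spec.zones) | sample.zones, key=zone_key):
        per_zone.append(
            {
                "zone": zone_key(z),
                "desired_proportion": desired.get(z, 0.0),
                "achieved_proportion": sample.proportions.get(z, 0.0),
            }
        )
    return EvaluationReport(
        area_difference_pct=area_difference_pct(spec, layout, grid_step, sample),
        area_difference=region_area_difference(desired, sample),
        stress=stress(spec, layout, grid_step, sample),
        stress_unscaled=stress_unscaled(spec, layout, grid_step, sample),
        per_zone=per_zone,
        fitness=fb.to_dict(),
        wall_time_s=wall_time_s,
        evaluated_solutions=evaluated_solutions,
    )
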