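"""Neighbourhood search over ellipse parameters.

Hill climbing is the default: from the stacked-circle start, every
sweep enumerates ten systematic moves per equivalence class (four
centre translations, four semi-axis edits, two rotations), scores each
candidate with the weighted objective, and accepts the best strictly
improving one. The method is deterministic; the objective trace is
non-increasing and the loop stops when no candidate improves (or at the
sweep cap). A simulated-annealing alternative with the same move set is
provided for comparison; it accepts worsening moves with probability
exp(-delta/T) under geometric cooling.

Candidate evaluation shares a bitmap cache so that, within a sweep,
only the moved class is re-rasterized (when the grid anchor allows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .area_spec import AreaSpecification
from .geometry import GRID_STEP, BitmapCache, DiagramLayout, Ellipse, initial_layout
from .objective import FitnessBreakdown, Weights, total_fitness

__all__ = [
    "HillClimbParams",
    "SAParams",
    "OptimizationTrace",
    "candidate_moves",
    "hill_climb",
    "simulated_annealing",
]

#: Minimum objective decrease counted as an improvement; guards against
#: non-termination on sampling-noise plateaus.
IMPROVEMENT_EPS = 1e-12


@dataclass(frozen=True)
class HillClimbParams:
    """Hill-climbing step sizes and limits (diagram units / radians)."""

    center_shift: float = 0.13
    radius_length: float = 0.03
    angle: float = 0.1
    grid_step: float = GRID_STEP
    max_sweeps: int = 1000

    def __post_init__(self) -> None:
        if min(self.center_shift, self.radius_length, self.angle) <= 0:
            raise ValueError("step sizes must be positive")
        if self.grid_step <= 0 or self.max_sweeps < 1:
            raise ValueError("invalid grid_step or max_sweeps")


@dataclass(frozen=True)
class SAParams:
    """Simulated-annealing schedule; move steps match hill climbing."""

    initial_temp: float | None = None  # None: start at the initial objective
    cooling: float = 0.95
    max_iters: int = 10000
    iters_per_temp: int = 30
    min_temp: float = 1e-4
    seed: int = 0
    center_shift: float = 0.13
    radius_length: float = 0.03
    angle: float = 0.1
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValueError("cooling rate must be in (0, 1)")
        if self.max_iters < 1 or self.iters_per_temp < 1:
            raise ValueError("iteration counts must be positive")


@dataclass
class OptimizationTrace:
    """Accepted-move log plus the count of evaluated candidates."""

    entries: list[tuple[int, str, float]] = field(default_factory=list)
    evaluated: int = 0
    converged: bool = False

    @property
    def totals(self) -> list[float]:
        return [t for _, _, t in self.entries]


def candidate_moves(
    layout: DiagramLayout, class_idx: int, p: HillClimbParams
) -> list[tuple[str, DiagramLayout]]:
    """The ten systematic neighbourhood moves for one equivalence class.

    Four centre translations (+-center_shift per axis), four semi-axis
    edits (+-radius_length on a and b), two rotations (+-angle). A move
    that would drive a semi-axis to zero or below is dropped. The move
    is applied to every ellipse in the class.
    """
    cls = layout.classes[class_idx]
    rep = layout.ellipses[sorted(cls)[0]]
    name = "+".join(sorted(cls))
    s, r, ang = p.center_shift, p.radius_length, p.angle
    edits: list[tuple[str, Ellipse]] = [
        (f"{name}:up", Ellipse(rep.cx, rep.cy + s, rep.a, rep.b, rep.theta)),
        (f"{name}:down", Ellipse(rep.cx, rep.cy - s, rep.a, rep.b, rep.theta)),
        (f"{name}:left", Ellipse(rep.cx - s, rep.cy, rep.a, rep.b, rep.theta)),
        (f"{name}:right", Ellipse(rep.cx + s, rep.cy, rep.a, rep.b, rep.theta)),
    ]
    if rep.a + r > 0:
        edits.append((f"{name}:a+", Ellipse(rep.cx, rep.cy, rep.a + r, rep.b, rep.theta)))
    if rep.a - r > 0:
        edits.append((f"{name}:a-", Ellipse(rep.cx, rep.cy, rep.a - r, rep.b, rep.theta)))
    if rep.b + r > 0:
        edits.append((f"{name}:b+", Ellipse(rep.cx, rep.cy, rep.a, rep.b + r, rep.theta)))
    if rep.b - r > 0:
        edits.append((f"{name}:b-", Ellipse(rep.cx, rep.cy, rep.a, rep.b - r, rep.theta)))
    edits.append((f"{name}:rot+", Ellipse(rep.cx, rep.cy, rep.a, rep.b, rep.theta + ang)))
    edits.append((f"{name}:rot-", Ellipse(rep.cx, rep.cy, rep.a, rep.b, rep.theta - ang)))
    return [(desc, layout.with_class(class_idx, e)) for desc, e in edits]


def hill_climb(
    spec: AreaSpecification,
    w: Weights | None = None,
    p: HillClimbParams | None = None,
    start: DiagramLayout | None = None,
) -> tuple[DiagramLayout, OptimizationTrace]:
    """Best-improvement hill climbing from the stacked-circle start.

    Each sweep evaluates all candidates over all classes and accepts
    the best strictly improving one (ties go to the first candidate in
    enumeration order). Terminates when no candidate improves or after
    ``max_sweeps`` sweeps. Deterministic: two runs with identical
    inputs produce identical traces.
    """
    if w is None:
        w = Weights()
    if p is None:
        p = HillClimbParams()
    layout = start if start is not None else initial_layout(spec)
    cache = BitmapCache()
    current = total_fitness(layout, spec, w, p.grid_step, cache=cache)
    trace = OptimizationTrace(entries=[(0, "initial", current.total)], evaluated=1)
    for sweep in range(1, p.max_sweeps + 1):
        best: tuple[FitnessBreakdown, str, DiagramLayout] | None = None
        for ci in range(len(layout.classes)):
            for desc, cand in candidate_moves(layout, ci, p):
                fb = total_fitness(cand, spec, w, p.grid_step, cache=cache)
                trace.evaluated += 1
                if best is None or fb.total < best[0].total:
                    best = (fb, desc, cand)
        if best is None or best[0].total >= current.total - IMPROVEMENT_EPS:
            trace.converged = True
            break
        current, layout = best[0], best[2]
        trace.entries.append((sweep, best[1], current.total))
    return layout, trace


def simulated_annealing(
    spec: AreaSpecification,
    w: Weights | None = None,
    sp: SAParams | None = None,
) -> tuple[DiagramLayout, OptimizationTrace]:
    """Simulated annealing with the hill-climbing move set.

    At each step a random class and a random one of its moves are
    drawn; improving moves are always taken, worsening ones with
    probability exp(-delta/T). The temperature cools geometrically and
    the best layout ever seen is returned. Fully reproducible for a
    fixed seed.
    """
    if w is None:
        w = Weights()
    if sp is None:
        sp = SAParams()
    hc = HillClimbParams(
        center_shift=sp.center_shift,
        radius_length=sp.radius_length,
        angle=sp.angle,
        grid_step=sp.grid_step,
    )
    rng = np.random.default_rng(sp.seed)
    layout = initial_layout(spec)
    cache = BitmapCache()
    current = total_fitness(layout, spec, w, sp.grid_step, cache=cache)
    best_layout, best_total = layout, current.total
    trace = OptimizationTrace(entries=[(0, "initial", current.total)], evaluated=1)
    temp = sp.initial_temp if sp.initial_temp is not None else max(current.total, 1e-9)
    step = 0
    while temp > sp.min_temp and step < sp.max_iters:
        for _ in range(sp.iters_per_temp):
            if step >= sp.max_iters:
                break
            step += 1
            ci = int(rng.integers(0, len(layout.classes)))
            moves = candidate_moves(layout, ci, hc)
            desc, cand = moves[int(rng.integers(0, len(moves)))]
            fb = total_fitness(cand, spec, w, sp.grid_step, cache=cache)
            trace.evaluated += 1
            delta = fb.total - current.total
            accept = delta < 0 or (
                temp > 0 and rng.random() < math.exp(-delta / temp)
            )
            if accept:
                layout, current = cand, fb
                trace.entries.append((step, desc, fb.total))
                if fb.total < best_total:
                    best_layout, best_total = cand, fb.total
        temp *= sp.cooling
    return best_layout, trace
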