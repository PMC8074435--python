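"""Label placement: set labels on ellipse boundaries, value labels in regions.

Set labels should sit where they are least ambiguous. For every
ellipse, 36 boundary points (10 degree parameter increments) are
scored by *depth* (how many other ellipses contain the point) and
*distance* (to the nearest of any other ellipse's 36 boundary points).
The points are partitioned into circular runs of equal depth, split
further at points whose distance falls under an ambiguity threshold;
the label goes on the longest run of lowest depth, at that run's
farthest point.

Region value labels start from an anchor known to lie in the region
(the mean sampled point when it is still inside — it may not be, for a
split region — else the first sampled point) and are centred by a few
alternating vertical/horizontal scans over the sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import DiagramLayout, RegionSample

__all__ = [
    "BoundaryProfile",
    "LabelPlacement",
    "boundary_profile",
    "place_set_label",
    "place_set_labels",
    "place_region_labels",
    "place_labels",
]

N_BOUNDARY_POINTS = 36
DEFAULT_SCAN_ITERATIONS = 3


@dataclass
class BoundaryProfile:
    """36 boundary points of one ellipse with depth and distance scores."""

    label: str
    points: list[tuple[float, float]]
    depths: list[int]
    distances: list[float]  # math.inf when no other ellipse exists


@dataclass
class LabelPlacement:
    """Chosen positions for coloured set labels and black value labels."""

    set_label_positions: dict[str, tuple[float, float, str]] = field(
        default_factory=dict
    )
    region_label_positions: dict[frozenset[str], tuple[float, float]] = field(
        default_factory=dict
    )


def boundary_profile(layout: DiagramLayout, label: str) -> BoundaryProfile:
    """Score the 36 boundary points of one ellipse against all others."""
    e = layout.ellipses[label]
    ts = [math.radians(10 * k) for k in range(N_BOUNDARY_POINTS)]
    points = [e.boundary_point(t) for t in ts]
    others = [(lab, o) for lab, o in layout.ellipses.items() if lab != label]
    depths = []
    for p in points:
        depths.append(sum(1 for _, o in others if bool(o.contains(p[0], p[1]))))
    if not others:
        distances = [math.inf] * N_BOUNDARY_POINTS
    else:
        foreign = np.array(
            [o.boundary_point(t) for _, o in others for t in ts]
        )
        pts = np.array(points)
        d = np.hypot(
            pts[:, None, 0] - foreign[None, :, 0],
            pts[:, None, 1] - foreign[None, :, 1],
        )
        distances = d.min(axis=1).tolist()
    return BoundaryProfile(label=label, points=points, depths=depths, distances=distances)


def _circular_runs(profile: BoundaryProfile, threshold: float) -> list[list[int]]:
    """Maximal circular runs of consecutive non-ambiguous points of equal depth."""
    n = len(profile.points)
    ok = [profile.distances[i] >= threshold for i in range(n)]
    if not any(ok):
        return []
    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(n):
        if not ok[i]:
            if current:
                runs.append(current)
                current = []
            continue
        if current and profile.depths[i] != profile.depths[current[-1]]:
            runs.append(current)
            current = []
        current.append(i)
    if current:
        runs.append(current)
    # wrap-around: merge the tail run into the head run when contiguous
    if (
        len(runs) > 1
        and runs[0][0] == 0
        and runs[-1][-1] == n - 1
        and profile.depths[runs[0][0]] == profile.depths[runs[-1][-1]]
    ):
        runs[0] = runs[-1] + runs[0]
        runs.pop()
    return runs


def place_set_label(
    profile: BoundaryProfile, ambiguity_threshold: float
) -> tuple[float, float]:
    """Pick the boundary point for one set label.

    Longest run of minimal depth wins (tie: first in angular order);
    within it, the point of maximum distance (ties: topmost point,
    then lowest index — an isolated ellipse gets its top point).
    """
    runs = _circular_runs(profile, ambiguity_threshold)
    if not runs:
        # every point ambiguous: global maximum-distance point
        idx = max(
            range(len(profile.points)),
            key=lambda i: (profile.distances[i], profile.points[i][1], -i),
        )
        return profile.points[idx]
    min_depth = min(profile.depths[r[0]] for r in runs)
    candidates = [r for r in runs if profile.depths[r[0]] == min_depth]
    run = max(candidates, key=len)  # max is stable: first longest wins
    idx = max(
        run, key=lambda i: (profile.distances[i], profile.points[i][1], -i)
    )
    return profile.points[idx]


def _default_threshold(layout: DiagramLayout) -> float:
    return 0.2 * min(min(e.a, e.b) for e in layout.ellipses.values())


def _anchor_side(layout: DiagramLayout, label: str, p: tuple[float, float]) -> str:
    """SVG text-anchor so the label text extends away from the ellipse."""
    e = layout.ellipses[label]
    dx = p[0] - e.cx
    if abs(dx) < 0.25 * max(e.a, e.b):
        return "middle"
    return "start" if dx > 0 else "end"


def place_set_labels(
    layout: DiagramLayout, ambiguity_threshold: float | None = None
) -> dict[str, tuple[float, float, str]]:
    """Boundary-point label position plus anchor side for every set."""
    if ambiguity_threshold is None:
        ambiguity_threshold = _default_threshold(layout)
    out: dict[str, tuple[float, float, str]] = {}
    for label in layout.labels:
        profile = boundary_profile(layout, label)
        x, y = place_set_label(profile, ambiguity_threshold)
        out[label] = (x, y, _anchor_side(layout, label, (x, y)))
    return out


def _zone_at(layout: DiagramLayout, p: tuple[float, float]) -> frozenset[str]:
    return frozenset(
        lab for lab, e in layout.ellipses.items() if bool(e.contains(p[0], p[1]))
    )


def _run_containing(col: np.ndarray, code: int, j: int) -> tuple[int, int] | None:
    """Bounds of the contiguous run of ``code`` cells nearest to index j."""
    hits = np.flatnonzero(col == code)
    if hits.size == 0:
        return None
    nearest = int(hits[np.argmin(np.abs(hits - j))])
    lo = hi = nearest
    while lo - 1 >= 0 and col[lo - 1] == code:
        lo -= 1
    while hi + 1 < col.size and col[hi + 1] == code:
        hi += 1
    return lo, hi


def place_region_labels(
    sample: RegionSample,
    layout: DiagramLayout,
    iterations: int = DEFAULT_SCAN_ITERATIONS,
) -> dict[frozenset[str], tuple[float, float]]:
    """Centre a value label inside every realized region.

    Starting from the region's viable anchor, alternately scan the
    sampling grid column for the region's vertical extent and the row
    for its horizontal extent, moving the point to the centre of the
    bounds each time.
    """
    if sample.code_grid is None:
        raise ValueError("sample was taken without keeping the grid")
    grid = sample.code_grid
    x0, y0 = sample.origin
    step = sample.grid_step
    ny, nx = grid.shape
    out: dict[frozenset[str], tuple[float, float]] = {}
    for zone in sorted(sample.proportions, key=lambda z: sorted(z)):
        code = np.uint64(sample.code_of(zone))
        p_first, p_average = sample.anchors[zone]
        p = p_average if _zone_at(layout, p_average) == zone else p_first
        i = min(nx - 1, max(0, round((p[0] - x0) / step)))
        j = min(ny - 1, max(0, round((p[1] - y0) / step)))
        if grid[j, i] != code:
            # fall back to the first sampled point, a grid point of the zone
            i = min(nx - 1, max(0, round((p_first[0] - x0) / step)))
            j = min(ny - 1, max(0, round((p_first[1] - y0) / step)))
        for _ in range(iterations):
            vert = _run_containing(grid[:, i], code, j)
            if vert is not None:
                j = (vert[0] + vert[1]) // 2
            horiz = _run_containing(grid[j, :], code, i)
            if horiz is not None:
                i = (horiz[0] + horiz[1]) // 2
        out[zone] = (x0 + i * step, y0 + j * step)
    return out


def place_labels(
    layout: DiagramLayout,
    sample: RegionSample,
    ambiguity_threshold: float | None = None,
    iterations: int = DEFAULT_SCAN_ITERATIONS,
) -> LabelPlacement:
    """Full label placement for a finished layout."""
    return LabelPlacement(
        set_label_positions=place_set_labels(layout, ambiguity_threshold),
        region_label_positions=place_region_labels(sample, layout, iterations),
    )
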