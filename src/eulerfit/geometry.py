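"""Ellipse primitives, initial layout and point-grid region sampling.

Region areas of overlapping ellipses have no general closed form, so all
region areas are measured by overlaying a fixed-pitch point grid on the
diagram and counting, for every grid point, which ellipses contain it.
The grid spans the union bounding box of all ellipses padded by one
step, anchored at the padded box's minimum corner; each covered point is
assigned to the zone named by the labels of all ellipses containing it.

The diagram is normalized so that the total desired area is 1, which
makes the default grid pitch of 0.026 give stable point counts
regardless of the absolute cardinalities in the specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .area_spec import AreaSpecification, desired_proportions, equivalence_classes

__all__ = [
    "Ellipse",
    "DiagramLayout",
    "RegionSample",
    "BitmapCache",
    "GRID_STEP",
    "ellipse_contains",
    "ellipse_area",
    "initial_layout",
    "sample_regions",
    "ideal_separation",
    "expand_ellipse",
    "pair_overlap_area",
]

#: Default sampling grid pitch (diagram units), for diagrams normalized
#: to total desired area 1. Chosen as the coarsest pitch whose region
#: proportions stay within 0.5% of a 0.0002 reference grid.
GRID_STEP = 0.026

#: Reference grid pitch used when validating sampling fidelity.
REFERENCE_GRID_STEP = 0.0002

# Row chunking bound for large grids: max points evaluated per chunk.
_CHUNK_POINTS = 1 << 22


@dataclass(frozen=True)
class Ellipse:
    """An ellipse: centre ``(cx, cy)``, semi-axes ``a``/``b``, rotation ``theta``.

    ``theta`` is in radians, measured anticlockwise; ``a`` is the
    semi-axis along the rotated x direction (not necessarily the major
    one).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be positive, got a={self.a}, b={self.b}")
        if not math.isfinite(self.theta):
            raise ValueError("rotation must be finite")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def bounding_box(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding box (xmin, ymin, xmax, ymax)."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        hw = math.hypot(self.a * ct, self.b * st)
        hh = math.hypot(self.a * st, self.b * ct)
        return self.cx - hw, self.cy - hh, self.cx + hw, self.cy + hh

    def contains(self, x, y):
        """Vectorized containment test; the boundary counts as inside."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        ct, st = math.cos(self.theta), math.sin(self.theta)
        xp = dx * ct + dy * st
        yp = -dx * st + dy * ct
        return (xp / self.a) ** 2 + (yp / self.b) ** 2 <= 1.0

    def boundary_point(self, t: float) -> tuple[float, float]:
        """Point at parameter angle ``t`` (radians, before rotation)."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        px, py = self.a * math.cos(t), self.b * math.sin(t)
        return self.cx + px * ct - py * st, self.cy + px * st + py * ct


def ellipse_contains(e: Ellipse, p: tuple[float, float]) -> bool:
    """Scalar containment test for a single point."""
    return bool(e.contains(p[0], p[1]))


def ellipse_area(e: Ellipse) -> float:
    """Analytic area pi * a * b."""
    return e.area


def ideal_separation(e1: Ellipse, e2: Ellipse) -> float:
    """Centre distance at which two ellipses are guaranteed just clear.

    Defined as the sum of each ellipse's larger semi-axis.
    """
    return max(e1.a, e1.b) + max(e2.a, e2.b)


def expand_ellipse(e: Ellipse) -> Ellipse:
    """Grow both semi-axes by 15% of the larger one (centre, rotation kept)."""
    grow = 0.15 * max(e.a, e.b)
    return Ellipse(e.cx, e.cy, e.a + grow, e.b + grow, e.theta)


@dataclass
class DiagramLayout:
    """One ellipse per set label, plus the label equivalence classes.

    Labels whose sets occur in exactly the same zones must coincide, so
    they share one parameter set; ``classes`` partitions the labels and
    all ellipses within a class hold identical parameters.
    """

    ellipses: dict[str, Ellipse]
    classes: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = [frozenset([lab]) for lab in self.ellipses]
        covered = set().union(*self.classes) if self.classes else set()
        if covered != set(self.ellipses):
            raise ValueError("equivalence classes do not partition the labels")
        for cls in self.classes:
            params = {self.ellipses[lab] for lab in cls}
            if len(params) != 1:
                raise ValueError(f"class {sorted(cls)} has divergent parameters")

    @property
    def labels(self) -> list[str]:
        return list(self.ellipses)

    def class_index(self, label: str) -> int:
        for i, cls in enumerate(self.classes):
            if label in cls:
                return i
        raise KeyError(label)

    def with_class(self, class_idx: int, e: Ellipse) -> "DiagramLayout":
        """New layout with every ellipse of one class replaced by ``e``."""
        cls = self.classes[class_idx]
        new = {lab: (e if lab in cls else old) for lab, old in self.ellipses.items()}
        return DiagramLayout(ellipses=new, classes=self.classes)

    def translated(self, dx: float, dy: float) -> "DiagramLayout":
        new = {
            lab: Ellipse(e.cx + dx, e.cy + dy, e.a, e.b, e.theta)
            for lab, e in self.ellipses.items()
        }
        return DiagramLayout(ellipses=new, classes=self.classes)

    def bounding_box(self) -> tuple[float, float, float, float]:
        boxes = [e.bounding_box() for e in self.ellipses.values()]
        xs0, ys0, xs1, ys1 = zip(*boxes)
        return min(xs0), min(ys0), max(xs1), max(ys1)

    def diameter(self) -> float:
        """Diagonal of the union bounding box."""
        x0, y0, x1, y1 = self.bounding_box()
        return math.hypot(x1 - x0, y1 - y0)


def initial_layout(spec: AreaSpecification) -> DiagramLayout:
    """Stacked-circle starting layout.

    Every set is a circle centred at the origin. The diagram's total
    desired area is normalized to 1, and each circle's area equals the
    summed desired proportions of the zones containing its label (the
    area the set would occupy in a correct diagram).
    """
    props = desired_proportions(spec)
    classes = equivalence_classes(spec)
    ellipses: dict[str, Ellipse] = {}
    for lab in spec.labels:
        area = sum(p for zone, p in props.items() if lab in zone)
        r = math.sqrt(area / math.pi)
        ellipses[lab] = Ellipse(0.0, 0.0, r, r, 0.0)
    # share one object per class so parameters are exactly identical
    for cls in classes:
        rep = ellipses[sorted(cls)[0]]
        for lab in cls:
            ellipses[lab] = rep
    return DiagramLayout(ellipses=ellipses, classes=classes)


class BitmapCache:
    """Per-ellipse boolean rasters keyed by (parameters, grid geometry).

    During candidate evaluation only one equivalence class moves, so the
    rasters of all other ellipses can be reused as long as the grid
    anchor is unchanged. Lookups agree exactly with direct containment
    evaluation because the cache stores the very rasters that direct
    evaluation computes.
    """

    def __init__(self, max_entries: int = 4096):
        self._store: dict[tuple, tuple[int, int, np.ndarray]] = {}
        self.max_entries = max_entries
        self.hits = 0
        self.misses = 0

    def get_mask(
        self, e: Ellipse, x0: float, y0: float, step: float, nx: int, ny: int
    ) -> tuple[int, int, np.ndarray]:
        key = (e.cx, e.cy, e.a, e.b, e.theta, x0, y0, step)
        found = self._store.get(key)
        if found is not None:
            self.hits += 1
            return found
        self.misses += 1
        result = _ellipse_submask(e, x0, y0, step, nx, ny)
        if len(self._store) >= self.max_entries:
            self._store.clear()
        self._store[key] = result
        return result


def _ellipse_submask(
    e: Ellipse, x0: float, y0: float, step: float, nx: int, ny: int
) -> tuple[int, int, np.ndarray]:
    """Containment raster of ``e`` over its bounding-box portion of the grid.

    Returns (i0, j0, mask) where mask[j, i] covers grid columns
    ``i0 + i`` and rows ``j0 + j``.
    """
    bx0, by0, bx1, by1 = e.bounding_box()
    i0 = max(0, int(math.floor((bx0 - x0) / step)))
    i1 = min(nx - 1, int(math.ceil((bx1 - x0) / step)))
    j0 = max(0, int(math.floor((by0 - y0) / step)))
    j1 = min(ny - 1, int(math.ceil((by1 - y0) / step)))
    if i1 < i0 or j1 < j0:
        return 0, 0, np.zeros((0, 0), dtype=bool)
    xs = x0 + np.arange(i0, i1 + 1) * step
    ys = y0 + np.arange(j0, j1 + 1) * step
    mask = e.contains(xs[None, :], ys[:, None])
    return i0, j0, mask


@dataclass
class RegionSample:
    """Grid-sampled region map of a layout.

    ``proportions`` are fractions of the covered area per zone;
    ``anchors`` holds, per zone, the first covered point encountered in
    row-major scan order (``p_first``) and the mean of the zone's points
    (``p_average``). ``code_grid`` (when kept) is the full per-point
    zone bitmask raster used by the label placer.
    """

    proportions: dict[frozenset[str], float]
    counts: dict[frozenset[str], int]
    total_covered: int
    anchors: dict[frozenset[str], tuple[tuple[float, float], tuple[float, float]]]
    grid_step: float
    origin: tuple[float, float]
    shape: tuple[int, int]  # (ny, nx)
    label_order: list[str]
    code_grid: np.ndarray | None = None

    @property
    def zones(self) -> set[frozenset[str]]:
        return set(self.proportions)

    def zone_area(self, zone: frozenset[str]) -> float:
        """Absolute sampled area of one zone (count x step^2)."""
        return self.counts.get(zone, 0) * self.grid_step**2

    @property
    def covered_area(self) -> float:
        return self.total_covered * self.grid_step**2

    def code_of(self, zone: frozenset[str]) -> int:
        code = 0
        for bit, lab in enumerate(self.label_order):
            if lab in zone:
                code |= 1 << bit
        return code

    def zone_of_code(self, code: int) -> frozenset[str]:
        return frozenset(
            lab for bit, lab in enumerate(self.label_order) if code >> bit & 1
        )


def sample_regions(
    layout: DiagramLayout,
    grid_step: float = GRID_STEP,
    cache: BitmapCache | None = None,
    keep_grid: bool = True,
) -> RegionSample:
    """Measure region areas of a layout by point-grid sampling.

    The grid spans the union bounding box of all ellipses padded by one
    step on every side, anchored at the padded box's minimum corner.
    Rows are scanned bottom-up, left to right within a row. Large grids
    are processed in row chunks to bound memory; chunking does not
    change any count.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not layout.ellipses:
        raise ValueError("layout has no ellipses")
    if len(layout.labels) > 64:
        raise ValueError("more than 64 sets is not supported")

    bx0, by0, bx1, by1 = layout.bounding_box()
    x0, y0 = bx0 - grid_step, by0 - grid_step
    nx = int(math.floor((bx1 + grid_step - x0) / grid_step)) + 1
    ny = int(math.floor((by1 + grid_step - y0) / grid_step)) + 1

    submasks = []
    for lab in layout.labels:
        e = layout.ellipses[lab]
        if cache is not None:
            submasks.append(cache.get_mask(e, x0, y0, grid_step, nx, ny))
        else:
            submasks.append(_ellipse_submask(e, x0, y0, grid_step, nx, ny))

    counts: dict[int, int] = {}
    sums: dict[int, tuple[float, float]] = {}
    firsts: dict[int, int] = {}

    rows_per_chunk = max(1, _CHUNK_POINTS // nx)
    keep = keep_grid and ny * nx <= _CHUNK_POINTS
    full_grid = np.zeros((ny, nx), dtype=np.uint64) if keep else None

    for j_start in range(0, ny, rows_per_chunk):
        j_end = min(ny, j_start + rows_per_chunk)
        codes = np.zeros((j_end - j_start, nx), dtype=np.uint64)
        for bit, (i0, j0, mask) in enumerate(submasks):
            mj0 = max(j0, j_start)
            mj1 = min(j0 + mask.shape[0], j_end)
            if mj1 <= mj0 or mask.size == 0:
                continue
            sub = mask[mj0 - j0 : mj1 - j0]
            codes[mj0 - j_start : mj1 - j_start, i0 : i0 + mask.shape[1]] |= np.where(
                sub, np.uint64(1 << bit), np.uint64(0)
            )
        if full_grid is not None:
            full_grid[j_start:j_end] = codes
        flat = codes.ravel()
        covered_idx = np.flatnonzero(flat)
        if covered_idx.size == 0:
            continue
        vals = flat[covered_idx]
        uniq, first_pos, inverse, cnt = np.unique(
            vals, return_index=True, return_inverse=True, return_counts=True
        )
        ii = covered_idx % nx
        jj = covered_idx // nx
        px = x0 + ii * grid_step
        py = y0 + (jj + j_start) * grid_step
        sx = np.bincount(inverse, weights=px, minlength=uniq.size)
        sy = np.bincount(inverse, weights=py, minlength=uniq.size)
        base = j_start * nx
        for k, code in enumerate(uniq.tolist()):
            counts[code] = counts.get(code, 0) + int(cnt[k])
            osx, osy = sums.get(code, (0.0, 0.0))
            sums[code] = (osx + float(sx[k]), osy + float(sy[k]))
            if code not in firsts:
                firsts[code] = base + int(covered_idx[first_pos[k]])

    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty sample: no grid point falls inside any ellipse")

    label_order = layout.labels

    def zone_of(code: int) -> frozenset[str]:
        return frozenset(
            lab for bit, lab in enumerate(label_order) if code >> bit & 1
        )

    proportions: dict[frozenset[str], float] = {}
    zone_counts: dict[frozenset[str], int] = {}
    anchors: dict[frozenset[str], tuple[tuple[float, float], tuple[float, float]]] = {}
    for code, n in counts.items():
        zone = zone_of(code)
        zone_counts[zone] = n
        proportions[zone] = n / total
        fi = firsts[code]
        p_first = (x0 + (fi % nx) * grid_step, y0 + (fi // nx) * grid_step)
        sx, sy = sums[code]
        anchors[zone] = (p_first, (sx / n, sy / n))

    return RegionSample(
        proportions=proportions,
        counts=zone_counts,
        total_covered=total,
        anchors=anchors,
        grid_step=grid_step,
        origin=(x0, y0),
        shape=(ny, nx),
        label_order=label_order,
        code_grid=full_grid,
    )


def pair_overlap_area(e1: Ellipse, e2: Ellipse, grid_step: float = GRID_STEP) -> float:
    """Sampled area of the intersection of two ellipses.

    The grid covers the intersection of the bounding boxes, anchored at
    its minimum corner; returns 0 when the boxes are disjoint.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    a0, b0, a1, b1 = e1.bounding_box()
    c0, d0, c1, d1 = e2.bounding_box()
    x0, y0 = max(a0, c0), max(b0, d0)
    x1, y1 = min(a1, c1), min(b1, d1)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    xs = np.arange(x0, x1 + grid_step / 2, grid_step)
    ys = np.arange(y0, y1 + grid_step / 2, grid_step)
    inside = e1.contains(xs[None, :], ys[:, None]) & e2.contains(
        xs[None, :], ys[:, None]
    )
    return float(inside.sum()) * grid_step**2
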