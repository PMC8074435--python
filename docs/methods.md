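# Methods

## Problem and model

The input is an *area specification*: a set of zones (nonempty label
sets) with positive cardinalities. The goal is a diagram with one
ellipse per label in which, ideally, exactly the specified zones
appear as regions and each region's share of the total diagram area
equals its cardinality's share of the total. Ellipses are
parameterized by centre (cx, cy), semi-axes (a, b) and rotation θ;
a is the semi-axis along the rotated x direction and is not required
to be the major one, so the parameterization is redundant under
(a↔b, θ+π/2) — harmless for optimization.

Cardinalities are accepted as any positive real (only relative sizes
matter); duplicate zone lines are merged by summation with a warning;
labels are case-sensitive, whitespace-free tokens. Labels that occur
in exactly the same zones ("equivalent" labels) must be drawn as
coincident ellipses, so they share one parameter set but are counted
as individual ellipses in the objective.

## Area measurement by grid sampling

Region areas of ≥2 overlapping ellipses have no practical closed
form, so all region areas are sampled: a square point grid spans the
union bounding box of all ellipses padded by one step, anchored at
the padded box's minimum corner, and each covered point is assigned
to the zone given by the ellipses containing it (boundary counts as
inside; row-major scan order, rows bottom-up, fixes the "first point"
anchor deterministically). Proportions are counts over the total
covered count. The diagram is normalized to total desired area 1 so
the default pitch 0.026 yields stable point counts; the reference
pitch for fidelity checks is 0.0002, evaluated in row chunks of ≤2²²
points to bound memory (chunking cannot change a count). The
per-ellipse *bitmap cache* stores each ellipse's boolean raster keyed
by its parameters and the grid geometry; cached and direct sampling
are identical by construction, and during candidate evaluation only
the moved equivalence class is re-rasterized (a move that changes the
grid anchor invalidates the cache for that candidate, which costs
time, never correctness).

The normalization reading deserves a note: the initial-scaling rule
is ambiguous between "each ellipse has area 1" and "the correct
diagram has area 1". We normalize the *diagram* to area 1 and size
each initial circle by its set's desired share, which keeps grid
resolution independent of the specification's absolute numbers — the
stated purpose of the scaling.

## Objective

Five criteria, each normalized to [0, 1] and weighted
(W₁..W₅ = 16.35, 23.6, 6.35, 0.01, 3.6 — tuned once, treated as
constants):

* **C1, region area difference** — matched zones contribute
  |desired − achieved| proportion, unwanted zones their achieved
  proportion, missing zones their desired proportion; range [0, 2],
  normalized by the analytic maximum 2.
* **C2, missing one-label region** — for each desired-but-absent
  one-label zone, every overlapping ellipse (overlap read from the
  sampled zone map) contributes (ideal separation − centre distance),
  where the *ideal separation* is the sum of the two larger semi-axes.
* **C3, missing multi-label region** — the realized zone sharing the
  most labels with the missing zone is selected (ties: fewest total
  labels, then lexicographic on the canonical zone key). If it lacks
  labels, those ellipses are pulled towards an anchor inside it (the
  zone's mean sampled point when that still lies in the zone — it may
  not, e.g. for split regions — else the first sampled point); if it
  covers the zone with extras, each extraneous ellipse is pushed off
  every ellipse of the zone. If nothing shares a label, ellipses are
  pulled towards the layout centroid (our choice; the situation is
  otherwise unspecified).
* **C4, unwanted region** — a one-label unwanted region whose label
  is covered by some desired zone contributes its sampled area
  (the ellipse belongs inside another); an unwanted region covered by
  no desired zone contributes, per label pair not co-occurring in any
  desired zone, factor × (ideal separation − centre distance), the
  factor starting at 1 and rising 0.1 per matching pair (pairs in
  sorted order; factor resets per region). Multi-label unwanted
  regions covered by a desired zone are left to C1 (our reading: the
  area-absorption case is stated only for single labels).
* **C5, unwanted expanded overlap** — pairs of ellipses that co-occur
  in no desired zone should not even touch: both ellipses are
  expanded by 15 % of their larger semi-axis and the sampled overlap
  area of the expanded pair is penalized.

Normalization divisors are not prescribed beyond the [0, 1] contract,
so we use analytic/geometric maxima: area summands are divided by the
total covered area, distance summands by (term count × union
bounding-box diagonal), C1 by 2; sums are clamped to [0, 1] and empty
criteria score 0. Negative (ideal − actual) summands are clamped at 0:
once centres are farther apart than the ideal separation the goal is
met and a negative reward would distort the sum. This scheme is
parameter-free and layout-adaptive but need not match any other
implementation's internal scaling.

## Optimization

Hill climbing, best-improvement: each sweep evaluates all ten moves
(±0.13 translations on each axis, ±0.03 on each semi-axis, ±0.1 rad
rotations) for every equivalence class and accepts the best candidate
that improves the total by more than 10⁻¹², stopping otherwise or
after `max_sweeps` (default 1000; the epsilon and cap guard against
sampling-noise plateaus). Best-improvement was chosen over
first-improvement because it is deterministic under any enumeration
and fits a systematic move list; axis moves that would make a
semi-axis non-positive are dropped. The trace of accepted totals is
non-increasing by construction, and the method is fully deterministic.

Simulated annealing shares the move set: a uniformly random class and
move per step, worsening moves accepted with probability
exp(−Δ/T), geometric cooling (defaults: T₀ = initial objective,
rate 0.95, 30 steps per temperature, stop at T < 10⁻⁴ or at the step
cap), seeded RNG, best-seen layout returned. The published tuning of
these schedule constants was not printed, so the defaults are ours.
Rotation steps are radians (0.1 rad ≈ 5.7°); the step constant is
given as a bare number and radians are the natural unit of the
parameterization.

## Label placement

Set labels: 36 boundary points per ellipse at 10° parameter
increments (parameter, not arc length — the simplest reading), each
scored by depth (other ellipses containing it) and distance (to the
nearest of the other ellipses' 36 points; ∞ when alone). Points are
split into circular runs of equal depth, further split at points
whose distance falls below an ambiguity threshold (default
0.2 × the smallest semi-axis in the layout, so it scales with the
diagram); the label goes on the longest minimal-depth run, at its
maximum-distance point (ties: topmost, so an isolated ellipse is
labelled at its top). If every point is ambiguous the global
maximum-distance point is used.

Region value labels: starting from the zone's viable anchor, three
alternating vertical/horizontal scans over the sampling grid move the
point to the centre of the zone's contiguous extent in its column and
row. Scans run on the sampling grid rather than continuously, which
keeps one code path and guarantees the final cell belongs to the
zone.

## Generators

`random_spec` draws a requested number of *distinct* zones (sizes
uniform in [1, max_zone_size], labels uniform without replacement,
cardinalities uniform integers in [1, 10]) and redraws until every
declared set is covered, so the requested counts are real properties
of the output. The benchmark group tables are shipped as constants;
one published group nominally allows intersections larger than its
set count, so the effective maximum zone size is capped at the set
count. The 90-spec scalability suite uses set counts 3..20 with
intersection counts round(s·m), m ∈ {1, 1.5, 2, 2.5, 3}
(round-half-up) and zone sizes in [1, min(4, s)]; for the smallest
set counts the requested intersection count can exceed the number of
possible distinct zones (e.g. 9 requested vs 7 possible for 3 sets),
in which case it is capped at the possible count — the suite always
contains exactly 90 specifications.

What the generator emulates is the shape of benchmark set systems
(counts, zone sizes, cardinality range), not the skewed zone-size and
cardinality distributions of real gene-ontology or social-network
exports; passing tests on generated specs demonstrate the layout
machinery, not domain-calibrated accuracy.

## Metrics

Area difference is raw C1 × 100 (range 0–200, shared code path with
the objective). Stress is the normalized residual sum of squares
between achieved areas A and desired areas D over the union of zone
sets (absent side zero-filled): β = ΣAD/ΣD², stress = Σ(A−βD)²/ΣA².
The fitted no-intercept scale β makes the measure scale-free in both
directions and bounded by 1; the unscaled variant (β = 1 on the
proportion scale) is also reported for transparency.

## Problem sizes and numerical choices

The fidelity check optimizes ten specs over 3–5 sets (sweep cap 120)
and compares pitches 0.026 vs 0.0002; convergence and improvement
checks run the twelve benchmark group configurations with a sweep cap
of 80 (the climbs typically converge in 10–30 sweeps); the
20-set completion check uses a sweep cap of 3. Containment uses ≤ on
the ellipse quadratic form (boundary inside) for determinism;
candidate ties break to the first move in enumeration order; the
improvement epsilon is 10⁻¹².

## Known limitations

* Sampled areas quantize at the grid pitch: regions thinner than
  ~0.026 diagram units may be missed or gained, and the fidelity
  discrepancy of an optimized layout can sit right at the 0.5 % level
  depending on how many sliver regions it has.
* The objective is a local-search guide, not a drawability oracle:
  specifications that no ellipse arrangement can realize simply
  converge to a compromise layout with a nonzero area difference.
* Hill climbing can stall in local optima (the known cost of the
  method's speed); simulated annealing escapes some of them at a much
  higher evaluation count.
* Normalization divisors are this package's own; objective *totals*
  are not comparable across implementations, though the reported
  metrics (area difference, stress) are.
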