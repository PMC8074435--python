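# eulerfit

Area-proportional Euler diagrams drawn with ellipses.

Euler diagrams are the standard way to show how a handful of sets
overlap — which genes are shared between functional categories, which
users belong to several interest groups. An *area-proportional* Euler
diagram additionally makes every region's area proportional to its
cardinality, so the picture itself carries the quantities. Circles do
not have enough degrees of freedom to do this accurately beyond two
sets; ellipses do much better and still read as smooth, familiar
curves. `eulerfit` lays out one ellipse per set for any number of sets
(tested to 20), from a plain-text *area specification*:

```
cell_adhesion extracellular_matrix 3
```

one set intersection per line — labels, then the cardinality the
corresponding region should represent.

## Method

Each set is an ellipse with five parameters (centre x, y, semi-axes
a, b, rotation θ). Starting from concentric circles sized so each
set's area matches its share of the (normalized, total = 1) diagram,
a hill climber repeatedly tries ten systematic moves per ellipse —
four centre translations (±0.13), four semi-axis edits (±0.03), two
rotations (±0.1 rad) — and accepts the best strictly improving
candidate under the weighted objective

&nbsp;&nbsp;&nbsp;&nbsp;F = Σᵢ Wᵢ·cᵢ,&nbsp;&nbsp; i = 1..5,

where each criterion cᵢ is normalized to [0, 1]:

| i | criterion | weight Wᵢ |
|---|-----------|-----------|
| 1 | region area difference (desired vs achieved proportions) | 16.35 |
| 2 | missing one-label region (ellipse should be disjoint but is not) | 23.6 |
| 3 | missing two-or-more-label region (pull/push ellipses to create it) | 6.35 |
| 4 | unwanted region (absorb or separate regions nobody asked for) | 0.01 |
| 5 | unwanted expanded overlap (keep a visible gap: 15 %-expanded ellipses must not intersect) | 3.6 |

Region areas have no closed form for arbitrarily many overlapping
ellipses, so they are measured by point-grid sampling (pitch 0.026 on
the area-1 diagram), with per-ellipse bitmap caching so a candidate
move only re-rasterizes the moved ellipse. Labels whose sets occur in
exactly the same intersections are drawn as one shared ellipse
("equivalent ellipses"). Set labels are placed on each ellipse's least
ambiguous boundary arc; region values are centred by alternating
vertical/horizontal scans. Output is SVG 1.1. A seeded
simulated-annealing optimizer with the same move set is included for
comparison.

Two accuracy measures are reported: **area difference** (sum of
|desired − achieved| region proportions, ×100, range 0–200) and
**stress** (normalized residual sum of squares with a fitted scale,
range 0–1).

## Worked example

The four-set interest-group specification:

```
Programming News 26         News 1
Programming News Music 6    Music 1
Programming Music 10        Camping 9
Camping News 12             Programming 16
```

(one intersection per line in the actual file) is laid out with:

```
$ eulerfit layout --input snap.txt --output snap.svg --report snap.json --verbose
snap.txt: 24 accepted moves, 1001 evaluations, 0.45s
```

The JSON report contains, among other fields:

```
area_difference_pct  8.90
stress               0.0106
```

meaning the drawn regions' area proportions differ from the requested
ones by 8.9 percentage points in total (out of a possible 200), with a
stress of about 0.01 — e.g. the largest region, Programming ∩ News,
was requested at 26/81 ≈ 0.321 of the diagram and is drawn at 0.296.
The SVG shows four translucent ellipses with coloured set labels on
their boundaries and black cardinality labels inside each region.

Other subcommands: `eulerfit generate` writes random specifications
(including the 90-spec scalability suite with `--scalability`),
`eulerfit evaluate` scores a stored layout, `eulerfit bench` runs the
optimizer over a directory of specifications. `--optimizer sa` selects
simulated annealing; every optimizer and sampling parameter is a flag.

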