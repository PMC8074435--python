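import math

import pytest

from eulerfit import (
    DiagramLayout,
    Ellipse,
    RegionSample,
    Weights,
    classify_regions,
    desired_proportions,
    parse_area_spec,
    region_area_difference,
    sample_regions,
    total_fitness,
)
from eulerfit.objective import (
    missing_multi_label_penalty,
    missing_one_label_penalty,
    normalize_criteria,
    unwanted_expanded_overlap_penalty,
    unwanted_region_penalty,
)

from conftest import disjoint_circle_layout


def Z(*labels):
    return frozenset(labels)


def fake_sample(proportions, step=0.026, total=10000):
    """RegionSample stub carrying just proportions/counts for C1 math."""
    counts = {z: int(round(p * total)) for z, p in proportions.items()}
    return RegionSample(
        proportions=proportions,
        counts=counts,
        total_covered=total,
        anchors={z: ((0.0, 0.0), (0.0, 0.0)) for z in proportions},
        grid_step=step,
        origin=(0.0, 0.0),
        shape=(1, 1),
        label_order=sorted({lab for z in proportions for lab in z}),
    )


class TestClassification:
    def test_all_matched(self):
        cls = classify_regions({Z("A"), Z("B")}, {Z("A"), Z("B")})
        assert cls.matched == {Z("A"), Z("B")}
        assert not (cls.missing_one | cls.missing_multi | cls.unwanted)

    def test_unwanted_overlap(self):
        cls = classify_regions({Z("A"), Z("B")}, {Z("A"), Z("B"), Z("A", "B")})
        assert cls.unwanted == {Z("A", "B")}

    def test_missing_one_label(self):
        cls = classify_regions({Z("A"), Z("A", "B")}, {Z("A", "B")})
        assert cls.missing_one == {Z("A")}
        assert not cls.missing_multi


class TestRegionAreaDifference:
    def test_perfect_agreement_is_zero(self):
        desired = {Z("A"): 0.5, Z("B"): 0.5}
        assert region_area_difference(desired, fake_sample(desired)) == 0

    def test_three_case_rule(self):
        desired = {Z("A"): 0.5, Z("B"): 0.5}
        actual = fake_sample({Z("A"): 0.4, Z("B"): 0.4, Z("A", "B"): 0.2})
        assert region_area_difference(desired, actual) == pytest.approx(0.4)

    def test_maximum_is_two(self):
        desired = {Z("A", "B"): 1.0}
        actual = fake_sample({Z("A"): 0.5, Z("B"): 0.5})
        assert region_area_difference(desired, actual) == pytest.approx(2.0)


class TestMissingOneLabel:
    def test_no_missing_zone_contributes_nothing(self):
        layout = disjoint_circle_layout(parse_area_spec("A 1\nB 1\n"))
        sample = sample_regions(layout)
        cls = classify_regions({Z("A"), Z("B")}, sample.zones)
        assert missing_one_label_penalty(cls, layout, sample).raw == 0

    def test_concentric_pair_pays_full_ideal_separation(self):
        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(0, 0, 2, 2, 0)}
        )
        sample = sample_regions(layout)
        cls = classify_regions({Z("A"), Z("B")}, sample.zones)
        assert cls.missing_one == {Z("A")}
        terms = missing_one_label_penalty(cls, layout, sample)
        assert terms.raw == pytest.approx(3.0)

    def test_barely_overlapping_pair_pays_residual_distance(self):
        from eulerfit.objective import RegionClassification

        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(2.9, 0, 2, 2, 0)}
        )
        sample = sample_regions(layout)
        assert Z("A", "B") in sample.zones  # the circles do still overlap
        cls = RegionClassification(
            matched=set(), missing_one={Z("A")}, missing_multi=set(), unwanted=set()
        )
        terms = missing_one_label_penalty(cls, layout, sample)
        assert terms.raw == pytest.approx(3.0 - 2.9)


class TestMissingMultiLabel:
    def test_none_missing_contributes_nothing(self):
        layout = disjoint_circle_layout(parse_area_spec("A 1\nB 1\n"))
        sample = sample_regions(layout)
        cls = classify_regions({Z("A"), Z("B")}, sample.zones)
        assert missing_multi_label_penalty(cls, layout, sample).raw == 0

    def test_pull_absent_label_towards_best_region(self):
        # a and c overlap; b is far away; desired region {a,b,c} is missing
        # and the best-matching actual region is the {a,c} lens.
        layout = DiagramLayout(
            {
                "a": Ellipse(-0.4, 0, 1, 1, 0),
                "c": Ellipse(0.4, 0, 1, 1, 0),
                "b": Ellipse(5, 0, 1, 1, 0),
            }
        )
        sample = sample_regions(layout)
        cls = classify_regions({Z("a", "c"), Z("a", "b", "c"), Z("b")}, sample.zones)
        assert cls.missing_multi == {Z("a", "b", "c")}
        terms = missing_multi_label_penalty(cls, layout, sample)
        # one term: distance from b's centre to an anchor inside the lens,
        # which straddles the origin by symmetry
        assert terms.n_dist == 1
        assert terms.raw == pytest.approx(5.0, abs=0.05)

    def test_push_extraneous_label_out_of_covering_region(self):
        # desired {a,c} exists only inside {a,b,c}: push b off a and c
        layout = DiagramLayout(
            {
                "a": Ellipse(-0.5, 0, 1, 1, 0),
                "c": Ellipse(0.5, 0, 1, 1, 0),
                "b": Ellipse(0, 0, 1, 1, 0),
            }
        )
        sample = sample_regions(layout)
        assert Z("a", "c") not in sample.zones
        assert Z("a", "b", "c") in sample.zones
        cls = classify_regions({Z("a"), Z("c"), Z("a", "c")}, sample.zones)
        terms = missing_multi_label_penalty(cls, layout, sample)
        # pairs (b,a) and (b,c), each ideal 2 minus distance 0.5
        assert terms.n_dist == 2
        assert terms.raw == pytest.approx(2 * (2 - 0.5))


class TestUnwantedRegion:
    def test_stray_one_label_region_penalized_by_area(self):
        # a should sit inside b (desired {a,b} and {b}) but pokes out
        layout = DiagramLayout(
            {"a": Ellipse(0.8, 0, 0.5, 0.5, 0), "b": Ellipse(0, 0, 1, 1, 0)}
        )
        sample = sample_regions(layout)
        assert Z("a") in sample.zones  # the stray sliver exists
        cls = classify_regions({Z("a", "b"), Z("b")}, sample.zones)
        terms = unwanted_region_penalty(cls, layout, sample, {Z("a", "b"), Z("b")})
        assert terms.area == pytest.approx(sample.zone_area(Z("a")))
        assert terms.n_dist == 0

    def test_uncovered_pair_pushed_apart(self):
        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(1.5, 0, 1, 1, 0)}
        )
        sample = sample_regions(layout)
        desired = {Z("A"), Z("B")}
        cls = classify_regions(desired, sample.zones)
        assert cls.unwanted == {Z("A", "B")}
        terms = unwanted_region_penalty(cls, layout, sample, desired)
        assert terms.raw == pytest.approx(1.0 * (2 - 1.5))

    def test_tie_factor_grows_per_matching_pair(self):
        # one unwanted three-label region; none of its pairs co-occur in
        # any desired zone, so factors 1.0, 1.1, 1.2 apply in sorted order
        layout = DiagramLayout(
            {
                "a": Ellipse(-0.5, 0, 1, 1, 0),
                "b": Ellipse(0.5, 0, 1, 1, 0),
                "c": Ellipse(0, 0.5, 1, 1, 0),
            }
        )
        sample = sample_regions(layout)
        desired = {Z("a"), Z("b"), Z("c")}
        cls = classify_regions(desired, sample.zones)
        terms = unwanted_region_penalty(cls, layout, sample, desired)

        def deficit(l1, l2):
            e1, e2 = layout.ellipses[l1], layout.ellipses[l2]
            return 2 - math.hypot(e1.cx - e2.cx, e1.cy - e2.cy)

        # unwanted zones: {a,b}, {a,c}, {b,c}, {a,b,c}; within each the
        # factor restarts at 1 and grows by 0.1 per pair in sorted order
        expected = (
            deficit("a", "b")  # zone {a,b}
            + deficit("a", "c")  # zone {a,c}
            + deficit("b", "c")  # zone {b,c}
            + 1.0 * deficit("a", "b")  # zone {a,b,c}
            + 1.1 * deficit("a", "c")
            + 1.2 * deficit("b", "c")
        )
        assert terms.dist_sum == pytest.approx(expected)


class TestUnwantedExpandedOverlap:
    def test_expanded_but_disjoint(self):
        spec = parse_area_spec("A 1\nB 1\n")
        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(2.4, 0, 1, 1, 0)}
        )
        assert unwanted_expanded_overlap_penalty(spec, layout).raw == 0

    def test_expanded_overlap_positive(self):
        spec = parse_area_spec("A 1\nB 1\n")
        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(2.1, 0, 1, 1, 0)}
        )
        terms = unwanted_expanded_overlap_penalty(spec, layout, 0.01)
        # lens of two r=1.15 circles at centre distance 2.1
        r, d = 1.15, 2.1
        half = d / 2
        lens = 2 * (r * r * math.acos(half / r) - half * math.sqrt(r * r - half * half))
        assert terms.raw == pytest.approx(lens, rel=0.05)

    def test_pair_sharing_a_desired_zone_excluded(self):
        spec = parse_area_spec("A B 1\n")
        layout = DiagramLayout(
            {"A": Ellipse(0, 0, 1, 1, 0), "B": Ellipse(0.5, 0, 1, 1, 0)}
        )
        assert unwanted_expanded_overlap_penalty(spec, layout).raw == 0


class TestNormalizationAndTotal:
    def test_c1_maximum_normalizes_to_one(self):
        layout = DiagramLayout({"A": Ellipse(0, 0, 1, 1, 0)})
        sample = sample_regions(layout)
        out = normalize_criteria({"C1": 2.0}, layout, sample)
        assert out["c1"] == 1.0

    def test_default_weights(self):
        assert Weights().as_tuple() == (16.35, 23.6, 6.35, 0.01, 3.6)

    def test_disjoint_exact_layout_scores_near_zero(self, two_set_spec):
        layout = disjoint_circle_layout(two_set_spec)
        fb = total_fitness(layout, two_set_spec)
        for i in range(2, 6):
            assert fb.normalized[f"c{i}"] == 0
        assert fb.raw["C1"] < 0.01

    def test_doubling_weights_doubles_total(self, snap_spec):
        from eulerfit.geometry import initial_layout

        layout = initial_layout(snap_spec)
        fb1 = total_fitness(layout, snap_spec)
        w2 = Weights(*(2 * w for w in Weights().as_tuple()))
        fb2 = total_fitness(layout, snap_spec, w=w2)
        assert fb2.total == pytest.approx(2 * fb1.total)

    def test_all_normalized_in_unit_interval(self, snap_spec):
        from eulerfit.geometry import initial_layout

        fb = total_fitness(initial_layout(snap_spec), snap_spec)
        for i in range(1, 6):
            assert 0 <= fb.normalized[f"c{i}"] <= 1
            assert fb.raw[f"C{i}"] >= 0
        assert fb.total >= 0

    def test_breakdown_json_round_trips(self, snap_spec):
        import json

        from eulerfit.geometry import initial_layout

        fb = total_fitness(initial_layout(snap_spec), snap_spec)
        data = json.loads(fb.to_json())
        assert data["total"] == fb.total
        assert set(data["normalized"]) == {"c1", "c2", "c3", "c4", "c5"}

    def test_criteria_invariant_under_translation(self, snap_spec):
        from eulerfit.geometry import initial_layout

        layout = initial_layout(snap_spec)
        fb0 = total_fitness(layout, snap_spec)
        fb1 = total_fitness(layout.translated(3.7, -2.2), snap_spec)
        for i in range(1, 6):
            assert fb0.normalized[f"c{i}"] == pytest.approx(
                fb1.normalized[f"c{i}"], abs=0.03
            )
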