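import math

import pytest

from eulerfit import (
    AreaSpecification,
    DiagramLayout,
    Ellipse,
    desired_proportions,
    parse_area_spec,
)

SNAP_TEXT = """Programming News 26
News 1
Programming News Music 6
Music 1
Programming Music 10
Camping 9
Camping News 12
Programming 16
"""


@pytest.fixture
def snap_spec() -> AreaSpecification:
    """The four-set Twitter interest-group worked example."""
    return parse_area_spec(SNAP_TEXT)


@pytest.fixture
def two_set_spec() -> AreaSpecification:
    return parse_area_spec("A 1\nB 1\n")


def disjoint_circle_layout(spec: AreaSpecification, gap: float = 0.5) -> DiagramLayout:
    """Exact layout for an all-one-label spec: disjoint circles in a row."""
    props = desired_proportions(spec)
    ellipses = {}
    x = 0.0
    for lab in spec.labels:
        r = math.sqrt(props[frozenset({lab})] / math.pi)
        ellipses[lab] = Ellipse(x + r, 0.0, r, r, 0.0)
        x += 2 * r + gap
    return DiagramLayout(ellipses)
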