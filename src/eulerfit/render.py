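"""SVG output.

The diagram is mapped into the viewport with a single uniform scale
(aspect ratio preserved, y axis flipped to SVG screen coordinates), so
ellipse eccentricities are unchanged by rendering. Fills are
translucent so overlap regions read as colour blends, as is usual for
Euler diagrams. Rendering is pure: identical inputs give byte-identical
SVG text.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .area_spec import AreaSpecification
from .geometry import DiagramLayout
from .labeling import LabelPlacement

__all__ = ["RenderOptions", "render"]

#: Default fill palette, cycled when there are more sets than colours.
DEFAULT_PALETTE = [
    "#1f77b4",
    "#ff7f0e",
    "#2ca02c",
    "#d62728",
    "#9467bd",
    "#8c564b",
    "#e377c2",
    "#7f7f7f",
    "#bcbd22",
    "#17becf",
]


@dataclass
class RenderOptions:
    """User-facing rendering knobs: size, palette and label sizes."""

    width: int = 600
    height: int = 600
    palette: list[str] = field(default_factory=lambda: list(DEFAULT_PALETTE))
    fill_opacity: float = 0.4
    set_label_size: float = 16.0
    value_label_size: float = 13.0
    show_values: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("viewport must have positive width and height")
        if not self.palette:
            raise ValueError("palette must not be empty")


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def render(
    layout: DiagramLayout,
    labels: LabelPlacement,
    spec: AreaSpecification,
    opts: RenderOptions | None = None,
) -> str:
    """Serialize a finished layout (with labels) to SVG 1.1 text."""
    if opts is None:
        opts = RenderOptions()
    x0, y0, x1, y1 = layout.bounding_box()
    pad = 0.06 * max(x1 - x0, y1 - y0)
    x0, y0, x1, y1 = x0 - pad, y0 - pad, x1 + pad, y1 + pad
    bw, bh = x1 - x0, y1 - y0
    scale = min(opts.width / bw, opts.height / bh)
    mx = (opts.width - bw * scale) / 2
    my = (opts.height - bh * scale) / 2

    def to_view(x: float, y: float) -> tuple[float, float]:
        return mx + (x - x0) * scale, my + (y1 - y) * scale

    colour = {
        lab: opts.palette[i % len(opts.palette)]
        for i, lab in enumerate(spec.labels)
    }

    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(opts.width),
            "height": str(opts.height),
            "viewBox": f"0 0 {opts.width} {opts.height}",
        },
    )
    for lab in spec.labels:
        e = layout.ellipses[lab]
        cx, cy = to_view(e.cx, e.cy)
        attrs = {
            "cx": _fmt(cx),
            "cy": _fmt(cy),
            "rx": _fmt(e.a * scale),
            "ry": _fmt(e.b * scale),
            "fill": colour[lab],
            "fill-opacity": _fmt(opts.fill_opacity),
        }
        deg = -math.degrees(e.theta)  # y flip reverses the rotation sense
        if abs(deg) > 1e-9:
            attrs["transform"] = f"rotate({_fmt(deg)} {_fmt(cx)} {_fmt(cy)})"
        ET.SubElement(root, "ellipse", attrs)
    for lab in spec.labels:
        if lab not in labels.set_label_positions:
            continue
        x, y, anchor = labels.set_label_positions[lab]
        vx, vy = to_view(x, y)
        el = ET.SubElement(
            root,
            "text",
            {
                "x": _fmt(vx),
                "y": _fmt(vy),
                "fill": colour[lab],
                "font-size": _fmt(opts.set_label_size),
                "text-anchor": anchor,
                "font-family": "sans-serif",
            },
        )
        el.text = lab
    if opts.show_values:
        for zone, (x, y) in sorted(
            labels.region_label_positions.items(), key=lambda kv: sorted(kv[0])
        ):
            card = spec.zones.get(zone)
            if card is None:
                continue  # regions not in the specification carry no value
            vx, vy = to_view(x, y)
            el = ET.SubElement(
                root,
                "text",
                {
                    "x": _fmt(vx),
                    "y": _fmt(vy),
                    "fill": "black",
                    "font-size": _fmt(opts.value_label_size),
                    "text-anchor": "middle",
                    "font-family": "sans-serif",
                },
            )
            el.text = f"{card:g}"
    return ET.tostring(root, encoding="unicode")
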