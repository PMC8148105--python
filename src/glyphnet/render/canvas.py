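"""Minimal deterministic drawing canvases.

Both output backends implement the same primitive set (rect, line,
circle, text), so every glyph style is written once and rendered to SVG
text and to a raster through the identical code path.  The SVG backend
emits plain SVG 1.1 with fixed number formatting and no timestamps or
generated ids, so identical inputs yield byte-identical documents.
Text metrics are approximated with a fixed per-character width to keep
the output platform independent.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from PIL import Image, ImageDraw

__all__ = ["SvgCanvas", "RasterCanvas", "text_width"]

FONT_FAMILY = "sans-serif"
CHAR_WIDTH_RATIO = 0.6  # approximate advance width per character, in em


def text_width(text: str, font_size: float) -> float:
    return len(text) * font_size * CHAR_WIDTH_RATIO


def _fmt(x: float) -> str:
    s = f"{x:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


class SvgCanvas:
    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self._parts: List[str] = []

    def rect(
        self,
        x: float,
        y: float,
        w: float,
        h: float,
        fill: str = "none",
        stroke: Optional[str] = None,
        stroke_width: float = 1.0,
    ) -> None:
        attrs = f'x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" height="{_fmt(h)}" fill="{fill}"'
        if stroke:
            attrs += f' stroke="{stroke}" stroke-width="{_fmt(stroke_width)}"'
        self._parts.append(f"<rect {attrs}/>")

    def line(
        self,
        points: Sequence[Tuple[float, float]],
        stroke: str = "#000000",
        stroke_width: float = 1.0,
    ) -> None:
        if len(points) < 2:
            return
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        self._parts.append(
            f'<polyline points="{pts}" fill="none" stroke="{stroke}" '
            f'stroke-width="{_fmt(stroke_width)}"/>'
        )

    def circle(self, cx: float, cy: float, r: float, fill: str = "#000000") -> None:
        self._parts.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="{fill}"/>'
        )

    def text(
        self,
        x: float,
        y: float,
        content: str,
        size: float = 10.0,
        anchor: str = "start",
        fill: str = "#000000",
    ) -> None:
        content = (
            content.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        )
        self._parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="{FONT_FAMILY}" '
            f'font-size="{_fmt(size)}" text-anchor="{anchor}" fill="{fill}">'
            f"{content}</text>"
        )

    def tostring(self) -> str:
        header = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(self.width)}" height="{_fmt(self.height)}" '
            f'viewBox="0 0 {_fmt(self.width)} {_fmt(self.height)}">\n'
        )
        return header + "\n".join(self._parts) + "\n</svg>\n"


class RasterCanvas:
    """Draws the same primitives onto a Pillow image at a scale factor."""

    def __init__(self, width: float, height: float, scale: float = 2.0) -> None:
        self.width = width
        self.height = height
        self.scale = scale
        self.image = Image.new(
            "RGB", (max(1, round(width * scale)), max(1, round(height * scale))), "white"
        )
        self._draw = ImageDraw.Draw(self.image)

    def _s(self, v: float) -> float:
        return v * self.scale

    def rect(self, x, y, w, h, fill="none", stroke=None, stroke_width=1.0) -> None:
        box = [self._s(x), self._s(y), self._s(x + w), self._s(y + h)]
        self._draw.rectangle(
            box,
            fill=None if fill == "none" else fill,
            outline=stroke,
            width=max(1, round(stroke_width * self.scale)) if stroke else 0,
        )

    def line(self, points, stroke="#000000", stroke_width=1.0) -> None:
        if len(points) < 2:
            return
        pts = [(self._s(x), self._s(y)) for x, y in points]
        self._draw.line(pts, fill=stroke, width=max(1, round(stroke_width * self.scale)))

    def circle(self, cx, cy, r, fill="#000000") -> None:
        box = [self._s(cx - r), self._s(cy - r), self._s(cx + r), self._s(cy + r)]
        self._draw.ellipse(box, fill=fill)

    def text(self, x, y, content, size=10.0, anchor="start", fill="#000000") -> None:
        w = text_width(content, size) * self.scale
        px = self._s(x)
        if anchor == "middle":
            px -= w / 2
        elif anchor == "end":
            px -= w
        # Pillow anchors text at the top-left; SVG y is the baseline
        self._draw.text((px, self._s(y - size * 0.8)), content, fill=fill)

    def save(self, path: str) -> None:
        self.image.save(path, format="PNG")
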