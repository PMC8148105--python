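"""Glyph style registry and the built-in cell drawers.

A style is a callable ``drawer(canvas, x, y, w, h, values, dataset)``
that paints one glyph region: ``values`` holds one number (or missing)
per dataset column falling inside the region.  Built-ins: ``heatmap``
(one colored rectangle per column), ``bar`` (column bars), ``line`` /
``timeseries`` (polyline over columns), ``scatter`` (points).  Missing
values render blank; a region with no data at all stays an empty frame.
New styles register under a fresh name and are immediately usable by
datasets.
"""

from __future__ import annotations

from typing import Callable, Dict, List

from ..omics import ColorScale, OmicsDataset, is_missing

__all__ = ["StyleRegistry", "default_registry", "StyleError"]

Drawer = Callable[[object, float, float, float, float, List[float], OmicsDataset], None]

BLANK_FILL = "#ffffff"
FRAME_STROKE = "#bbbbbb"
SERIES_COLOR = "#1f6f9f"
BAR_COLOR = "#e0883a"


class StyleError(ValueError):
    pass


class StyleRegistry:
    def __init__(self) -> None:
        self._drawers: Dict[str, Drawer] = {}

    def register(self, name: str, drawer: Drawer) -> "StyleRegistry":
        if name in self._drawers:
            raise StyleError(f"style {name!r} is already registered")
        self._drawers[name] = drawer
        return self

    def get(self, name: str) -> Drawer:
        try:
            return self._drawers[name]
        except KeyError:
            raise StyleError(
                f"no style named {name!r}; registered: {sorted(self._drawers)}"
            ) from None

    def names(self) -> List[str]:
        return sorted(self._drawers)

    def __contains__(self, name: str) -> bool:
        return name in self._drawers


def _axis_range(ds: OmicsDataset) -> tuple:
    scale = ds.scale
    return scale.vmin, scale.vmax


def _norm(value: float, lo: float, hi: float) -> float:
    if hi == lo:
        return 0.5
    return min(max((value - lo) / (hi - lo), 0.0), 1.0)


def draw_heatmap(canvas, x, y, w, h, values, ds: OmicsDataset) -> None:
    n = max(len(values), 1)
    cw = w / n
    scale: ColorScale = ds.scale
    for i, v in enumerate(values):
        fill = scale.color(v) if not is_missing(v) else scale.missing_color
        canvas.rect(x + i * cw, y, cw, h, fill=fill, stroke=FRAME_STROKE, stroke_width=0.5)


def draw_bar(canvas, x, y, w, h, values, ds: OmicsDataset) -> None:
    lo, hi = _axis_range(ds)
    n = max(len(values), 1)
    cw = w / n
    pad = cw * 0.15
    for i, v in enumerate(values):
        canvas.rect(x + i * cw, y, cw, h, fill=BLANK_FILL, stroke=FRAME_STROKE, stroke_width=0.5)
        if is_missing(v):
            continue
        frac = _norm(v, lo, hi)
        bh = frac * (h - 2)
        canvas.rect(x + i * cw + pad, y + h - 1 - bh, cw - 2 * pad, bh, fill=BAR_COLOR)


def _points(x, y, w, h, values, ds: OmicsDataset):
    lo, hi = _axis_range(ds)
    n = len(values)
    pts = []
    for i, v in enumerate(values):
        if is_missing(v):
            continue
        px = x + (i + 0.5) * (w / n) if n else x + w / 2
        py = y + h - 1 - _norm(v, lo, hi) * (h - 2)
        pts.append((px, py))
    return pts


def draw_line(canvas, x, y, w, h, values, ds: OmicsDataset) -> None:
    canvas.rect(x, y, w, h, fill=BLANK_FILL, stroke=FRAME_STROKE, stroke_width=0.5)
    pts = _points(x, y, w, h, values, ds)
    if len(pts) >= 2:
        canvas.line(pts, stroke=SERIES_COLOR, stroke_width=1.2)
    elif len(pts) == 1:
        canvas.circle(pts[0][0], pts[0][1], 1.5, fill=SERIES_COLOR)


def draw_timeseries(canvas, x, y, w, h, values, ds: OmicsDataset) -> None:
    # line plus a baseline axis emphasising the time dimension
    draw_line(canvas, x, y, w, h, values, ds)
    canvas.line([(x, y + h - 1), (x + w, y + h - 1)], stroke="#888888", stroke_width=0.6)


def draw_scatter(canvas, x, y, w, h, values, ds: OmicsDataset) -> None:
    canvas.rect(x, y, w, h, fill=BLANK_FILL, stroke=FRAME_STROKE, stroke_width=0.5)
    for px, py in _points(x, y, w, h, values, ds):
        canvas.circle(px, py, 1.5, fill=SERIES_COLOR)


def default_registry() -> StyleRegistry:
    reg = StyleRegistry()
    reg.register("heatmap", draw_heatmap)
    reg.register("bar", draw_bar)
    reg.register("line", draw_line)
    reg.register("timeseries", draw_timeseries)
    reg.register("scatter", draw_scatter)
    return reg
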