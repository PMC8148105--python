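"""Metanode and legend image composition and export.

A metanode image is the per-node composite glyph: a label band on top
and one glyph region per dataset cell of the node type's layout, drawn
by the dataset's style.  Every node of one node type shares one layout,
so all its images have identical dimensions and a single legend
explains them: one entry per dataset with name, description, a style
swatch and the color bar or axis range.

Rendering is deterministic — identical inputs produce byte-identical
SVG.  Export writes ``node_<id>.<ext>`` / ``legend_<sig>.<ext>`` files
plus a JSON manifest recording the node → files and node → legend
mapping.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set

from ..model import NodeRecord
from ..omics import MISSING, NodeTypeSignature, OmicsDataset
from .canvas import RasterCanvas, SvgCanvas
from .layout import LayoutSpec
from .styles import StyleRegistry, default_registry

__all__ = ["MetanodeImage", "LegendImage", "render_node", "render_legend", "export_images"]

logger = logging.getLogger(__name__)

LABEL_FONT = 9.0
LEGEND_WIDTH = 220.0
LEGEND_ENTRY_HEIGHT = 44.0
LEGEND_HEADER = 18.0


@dataclass
class MetanodeImage:
    node_id: str
    signature_id: str
    svg: str
    label: str
    width: float
    height: float
    draw: Callable[[object], None] = field(repr=False, default=None)


@dataclass
class LegendImage:
    signature_id: str
    svg: str
    entries: List[Dict[str, str]]
    width: float
    height: float
    draw: Callable[[object], None] = field(repr=False, default=None)


def _node_values(
    node: NodeRecord, ds: OmicsDataset, n_needed: int
) -> List[float]:
    row = ds.row(node.id, node.attributes.get("data_id"))
    if row is None:
        return [MISSING] * n_needed
    return list(row)


def _draw_node(
    canvas,
    node: NodeRecord,
    signature: NodeTypeSignature,
    datasets: Dict[str, OmicsDataset],
    layout: LayoutSpec,
    styles: StyleRegistry,
    label: str,
) -> None:
    width, height = layout.canvas_width, layout.canvas_height
    canvas.rect(0, 0, width, height, fill="#ffffff", stroke="#333333")
    canvas.text(
        width / 2, layout.label_band - 4, label, size=LABEL_FONT, anchor="middle"
    )
    y = layout.label_band
    for row in layout.grid:
        x = 0.0
        # contiguous cells of one dataset form a single glyph region
        i = 0
        while i < len(row):
            ds_id = row[i].dataset_id
            span = row[i].span
            j = i + 1
            while j < len(row) and row[j].dataset_id == ds_id:
                span += row[j].span
                j += 1
            ds = datasets[ds_id]
            w = span * layout.cell_width
            values = _node_values(node, ds, len(ds.headers))
            if ds.kind == "single":
                values = values[:1]
            drawer = styles.get(ds.style)
            drawer(canvas, x, y, w, layout.cell_height, values, ds)
            x += w
            i = j
        y += layout.cell_height


def render_node(
    node: NodeRecord,
    signature: NodeTypeSignature,
    datasets: Sequence[OmicsDataset],
    layout: LayoutSpec,
    styles: Optional[StyleRegistry] = None,
) -> MetanodeImage:
    """Render one node's composite glyph image.

    The node must be a member of the signature; missing values (or a
    dataset with no row for this node) render as blank cells.  The
    displayed label is the node's label attribute, falling back to its
    id.
    """
    if node.id not in set(signature.member_ids):
        raise ValueError(
            f"node {node.id!r} is not a member of node type {signature.id!r}"
        )
    styles = styles or default_registry()
    by_id = {ds.id: ds for ds in datasets}
    for ds_id in layout.dataset_ids():
        if ds_id not in by_id:
            raise ValueError(f"layout references unknown dataset {ds_id!r}")
        by_id[ds_id].scale  # materialised at dataset construction
    label = node.label or node.id

    def draw(canvas) -> None:
        _draw_node(canvas, node, signature, by_id, layout, styles, label)

    svg_canvas = SvgCanvas(layout.canvas_width, layout.canvas_height)
    draw(svg_canvas)
    return MetanodeImage(
        node_id=node.id,
        signature_id=signature.id,
        svg=svg_canvas.tostring(),
        label=label,
        width=layout.canvas_width,
        height=layout.canvas_height,
        draw=draw,
    )


def _draw_legend(
    canvas,
    signature: NodeTypeSignature,
    datasets: Dict[str, OmicsDataset],
    styles: StyleRegistry,
    height: float,
) -> None:
    canvas.rect(0, 0, LEGEND_WIDTH, height, fill="#ffffff", stroke="#333333")
    canvas.text(8, 13, f"Node type: {signature.id}", size=10.0)
    y = LEGEND_HEADER
    swatch_w, swatch_h = 60.0, 16.0
    for ds_id in signature.dataset_ids:
        ds = datasets[ds_id]
        canvas.text(8, y + 11, ds.name, size=9.0)
        if ds.description:
            canvas.text(8, y + 22, ds.description, size=7.0, fill="#555555")
        # style swatch drawn with representative values
        demo = _demo_values(ds)
        drawer = styles.get(ds.style)
        sx = LEGEND_WIDTH - swatch_w - 8
        drawer(canvas, sx, y + 2, swatch_w, swatch_h, demo, ds)
        lo, hi = ds.scale.vmin, ds.scale.vmax
        canvas.text(sx, y + swatch_h + 11, _num(lo), size=7.0)
        canvas.text(sx + swatch_w, y + swatch_h + 11, _num(hi), size=7.0, anchor="end")
        y += LEGEND_ENTRY_HEIGHT


def _num(x: float) -> str:
    return f"{x:.3g}"


def _demo_values(ds: OmicsDataset) -> List[float]:
    lo, hi = ds.scale.vmin, ds.scale.vmax
    n = 8 if ds.style == "heatmap" else max(len(ds.headers), 2)
    n = min(n, 12)
    return [lo + (hi - lo) * i / (n - 1) for i in range(n)]


def render_legend(
    signature: NodeTypeSignature,
    datasets: Sequence[OmicsDataset],
    layout: Optional[LayoutSpec] = None,
    styles: Optional[StyleRegistry] = None,
) -> LegendImage:
    """Render the legend for one node type: one entry per dataset.

    Entries appear in dataset registration order and show the name,
    description, a style swatch and the numeric scale endpoints.
    """
    if not signature.dataset_ids:
        raise ValueError("cannot render a legend for an empty node type")
    styles = styles or default_registry()
    by_id = {ds.id: ds for ds in datasets}
    height = LEGEND_HEADER + LEGEND_ENTRY_HEIGHT * len(signature.dataset_ids) + 4

    def draw(canvas) -> None:
        _draw_legend(canvas, signature, by_id, styles, height)

    svg_canvas = SvgCanvas(LEGEND_WIDTH, height)
    draw(svg_canvas)
    entries = [
        {
            "dataset": ds_id,
            "name": by_id[ds_id].name,
            "description": by_id[ds_id].description,
            "style": by_id[ds_id].style,
            "scale": f"{_num(by_id[ds_id].scale.vmin)}..{_num(by_id[ds_id].scale.vmax)}",
        }
        for ds_id in signature.dataset_ids
    ]
    return LegendImage(
        signature_id=signature.id,
        svg=svg_canvas.tostring(),
        entries=entries,
        width=LEGEND_WIDTH,
        height=height,
        draw=draw,
    )


_SAFE_RE = re.compile(r"[^A-Za-z0-9_.-]+")


def _safe(name: str) -> str:
    return _SAFE_RE.sub("_", name)


def export_images(
    images: Sequence[MetanodeImage],
    legends: Sequence[LegendImage],
    out_dir: str,
    formats: Set[str] = frozenset({"svg"}),
    dpi: int = 192,
) -> Dict[str, object]:
    """Write image/legend files and the node-legend manifest.

    ``formats`` is a subset of ``{"svg", "png"}``; PNG raster dimensions
    equal the SVG canvas scaled by ``dpi``/96.  Per-file I/O failures
    are logged and recorded in the manifest's ``errors`` list; the
    export continues.  Returns the manifest (also written to
    ``manifest.json``).
    """
    unknown = set(formats) - {"svg", "png"}
    if unknown:
        raise ValueError(f"unknown export formats: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    scale = dpi / 96.0
    manifest: Dict[str, object] = {"nodes": {}, "legends": {}, "node_legend": {}, "errors": []}

    def _write(base: str, svg: str, draw, width: float, height: float) -> List[str]:
        files = []
        if "svg" in formats:
            path = os.path.join(out_dir, base + ".svg")
            try:
                with open(path, "w") as handle:
                    handle.write(svg)
                files.append(os.path.basename(path))
            except OSError as exc:
                logger.error("failed to write %s: %s", path, exc)
                manifest["errors"].append(f"{path}: {exc}")
        if "png" in formats:
            path = os.path.join(out_dir, base + ".png")
            try:
                canvas = RasterCanvas(width, height, scale=scale)
                draw(canvas)
                canvas.save(path)
                files.append(os.path.basename(path))
            except OSError as exc:
                logger.error("failed to write %s: %s", path, exc)
                manifest["errors"].append(f"{path}: {exc}")
        return files

    for image in images:
        files = _write(
            f"node_{_safe(image.node_id)}", image.svg, image.draw, image.width, image.height
        )
        manifest["nodes"][image.node_id] = files
        manifest["node_legend"][image.node_id] = image.signature_id
    for legend in legends:
        files = _write(
            f"legend_{_safe(legend.signature_id)}",
            legend.svg,
            legend.draw,
            legend.width,
            legend.height,
        )
        manifest["legends"][legend.signature_id] = files

    with open(os.path.join(out_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
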