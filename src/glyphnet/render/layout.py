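"""Automatic glyph grid layout for metanode images.

All nodes of one node type share one layout, so their images have
identical dimensions and datasets always appear in the same place.  The
automatic rule is simple and deterministic: array datasets (time series
etc.) each occupy a full-width row of one cell per column, single-value
datasets are packed left-to-right into shared rows of up to four cells,
and a label band sits on top.  A manual layout can be supplied as JSON
and is validated against the node type's dataset set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from ..omics import OmicsDataset
from ..omics import NodeTypeSignature

__all__ = ["Cell", "LayoutSpec", "auto_layout", "layout_from_json", "LayoutError"]

DEFAULT_CELL_WIDTH = 40.0
DEFAULT_CELL_HEIGHT = 20.0
DEFAULT_LABEL_BAND = 16.0
MAX_SINGLE_CELLS_PER_ROW = 4


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class Cell:
    dataset_id: str
    span: int = 1


@dataclass
class LayoutSpec:
    grid: List[List[Cell]]
    cell_width: float = DEFAULT_CELL_WIDTH
    cell_height: float = DEFAULT_CELL_HEIGHT
    label_band: float = DEFAULT_LABEL_BAND

    @property
    def n_columns(self) -> int:
        return max((sum(c.span for c in row) for row in self.grid), default=0)

    @property
    def canvas_width(self) -> float:
        return self.n_columns * self.cell_width

    @property
    def canvas_height(self) -> float:
        return self.label_band + len(self.grid) * self.cell_height

    def dataset_ids(self) -> List[str]:
        seen: List[str] = []
        for row in self.grid:
            for cell in row:
                if cell.dataset_id not in seen:
                    seen.append(cell.dataset_id)
        return seen

    def validate(self, signature: NodeTypeSignature) -> None:
        placed = set(self.dataset_ids())
        wanted = set(signature.dataset_ids)
        missing = wanted - placed
        if missing:
            raise LayoutError(f"layout misses datasets: {sorted(missing)}")
        extra = placed - wanted
        if extra:
            raise LayoutError(f"layout places unknown datasets: {sorted(extra)}")


def auto_layout(
    signature: NodeTypeSignature,
    datasets: Sequence[OmicsDataset],
    cell_width: float = DEFAULT_CELL_WIDTH,
    cell_height: float = DEFAULT_CELL_HEIGHT,
    label_band: float = DEFAULT_LABEL_BAND,
) -> LayoutSpec:
    """Lay out a node type's datasets on the default grid rules.

    Datasets keep their registration order.  Each array dataset becomes
    one full-width row with one cell per column; single-value datasets
    are packed into shared rows of up to four cells.
    """
    if not signature.dataset_ids:
        raise LayoutError("empty node type signature")
    by_id: Dict[str, OmicsDataset] = {ds.id: ds for ds in datasets}
    grid: List[List[Cell]] = []
    single_row: List[Cell] = []
    for ds_id in signature.dataset_ids:
        ds = by_id.get(ds_id)
        if ds is None:
            raise LayoutError(f"signature references unknown dataset {ds_id!r}")
        if ds.kind == "array":
            if single_row:
                grid.append(single_row)
                single_row = []
            grid.append([Cell(ds_id) for _ in ds.headers])
        else:
            single_row.append(Cell(ds_id))
            if len(single_row) == MAX_SINGLE_CELLS_PER_ROW:
                grid.append(single_row)
                single_row = []
    if single_row:
        grid.append(single_row)
    return LayoutSpec(
        grid=grid, cell_width=cell_width, cell_height=cell_height, label_band=label_band
    )


def layout_from_json(path: str, signature: NodeTypeSignature) -> LayoutSpec:
    """Load a manual layout override and validate it against a node type.

    Schema: ``{"grid": [[{"dataset": id, "span": n}, ...], ...],
    "cell_width": px, "cell_height": px, "label_band": px}`` — the size
    keys are optional.
    """
    with open(path) as handle:
        raw = json.load(handle)
    try:
        grid = [
            [Cell(cell["dataset"], int(cell.get("span", 1))) for cell in row]
            for row in raw["grid"]
        ]
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"malformed layout file {path}: {exc}") from exc
    spec = LayoutSpec(
        grid=grid,
        cell_width=float(raw.get("cell_width", DEFAULT_CELL_WIDTH)),
        cell_height=float(raw.get("cell_height", DEFAULT_CELL_HEIGHT)),
        label_band=float(raw.get("label_band", DEFAULT_LABEL_BAND)),
    )
    spec.validate(signature)
    return spec
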