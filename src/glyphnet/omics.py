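"""Omics tables: reading, node mapping and node-type derivation.

A dataset is a node-keyed value matrix: single-value (one column, e.g. a
fold change) or array (several columns, e.g. time points).  Datasets map
onto network nodes by id — falling back to the ``data_id`` attribute so
hub replicates inherit the original node's data — and the combination of
datasets available for a node defines its *node type*, which in turn
decides the glyph layout and legend it receives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import pandas as pd

from .model import Network

__all__ = [
    "OmicsDataset",
    "ColorScale",
    "NodeTypeSignature",
    "CoverageReport",
    "OmicsError",
    "read_table",
    "match_nodes",
    "derive_node_types",
]

MISSING = float("nan")


class OmicsError(ValueError):
    pass


def is_missing(value: float) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass
class ColorScale:
    """Linear color scale quantised to 256 steps; missing values stay blank.

    ``diverging`` interpolates low→mid→high (blue/white/red by default);
    ``sequential`` interpolates low→high.
    """

    mode: Literal["sequential", "diverging"] = "sequential"
    domain: Tuple[float, ...] = (0.0, 1.0)  # (min, max) or (min, mid, max)
    low_color: str = "#f7fbff"
    mid_color: str = "#f7f7f7"
    high_color: str = "#b2182b"
    missing_color: str = "#ffffff"

    def __post_init__(self) -> None:
        if self.mode == "diverging":
            if len(self.domain) != 3:
                raise OmicsError("diverging scale needs (min, mid, max) domain")
            lo, mid, hi = self.domain
            if not (lo < mid < hi):
                raise OmicsError("diverging domain must satisfy min < mid < max")
            self.low_color = "#2166ac"
        else:
            if len(self.domain) != 2:
                raise OmicsError("sequential scale needs (min, max) domain")
            lo, hi = self.domain
            if not lo < hi:
                raise OmicsError("scale domain must satisfy min < max")

    @property
    def vmin(self) -> float:
        return self.domain[0]

    @property
    def vmax(self) -> float:
        return self.domain[-1]

    def color(self, value: float) -> str:
        """Hex color for a value, clamped to the domain; blank if missing."""
        if is_missing(value):
            return self.missing_color
        v = min(max(value, self.vmin), self.vmax)
        if self.mode == "diverging":
            lo, mid, hi = self.domain
            if v <= mid:
                t = 0.0 if mid == lo else (v - lo) / (mid - lo)
                return _lerp_hex(self.low_color, self.mid_color, _quantize(t))
            t = 0.0 if hi == mid else (v - mid) / (hi - mid)
            return _lerp_hex(self.mid_color, self.high_color, _quantize(t))
        t = (v - self.vmin) / (self.vmax - self.vmin)
        return _lerp_hex(self.low_color, self.high_color, _quantize(t))


def _quantize(t: float, steps: int = 256) -> float:
    # snap to one of `steps` levels so colors are reproducible exactly
    return round(t * (steps - 1)) / (steps - 1)


def _lerp_hex(a: str, b: str, t: float) -> str:
    av = [int(a[i : i + 2], 16) for i in (1, 3, 5)]
    bv = [int(b[i : i + 2], 16) for i in (1, 3, 5)]
    mixed = [round(x + (y - x) * t) for x, y in zip(av, bv)]
    return "#" + "".join(f"{c:02x}" for c in mixed)


@dataclass
class OmicsDataset:
    id: str
    name: str
    headers: List[str]
    values: Dict[str, List[float]]
    kind: Literal["single", "array"] = "array"
    style: Literal["heatmap", "line", "scatter", "timeseries", "bar"] = "heatmap"
    description: str = ""
    scale: Optional[ColorScale] = None

    def __post_init__(self) -> None:
        if self.kind == "single" and len(self.headers) != 1:
            raise OmicsError(
                f"dataset {self.id!r}: kind=single requires exactly 1 column"
            )
        if self.style in ("line", "scatter", "timeseries") and self.kind != "array":
            raise OmicsError(
                f"dataset {self.id!r}: style {self.style!r} requires kind=array"
            )
        ncol = len(self.headers)
        for nid, row in self.values.items():
            if len(row) != ncol:
                raise OmicsError(
                    f"dataset {self.id!r}: row {nid!r} has {len(row)} values, "
                    f"expected {ncol}"
                )
        if not any(not is_missing(v) for row in self.values.values() for v in row):
            raise OmicsError(f"dataset {self.id!r} contains no values at all")
        if self.scale is None:
            self.scale = self.default_scale()

    def default_scale(self) -> ColorScale:
        """Symmetric diverging around 0 if both signs occur, else sequential."""
        flat = [v for row in self.values.values() for v in row if not is_missing(v)]
        lo, hi = min(flat), max(flat)
        if lo < 0 < hi:
            bound = max(abs(lo), abs(hi))
            return ColorScale(mode="diverging", domain=(-bound, 0.0, bound))
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return ColorScale(mode="sequential", domain=(lo, hi))

    def row(self, node_id: str, data_id: Optional[str] = None) -> Optional[List[float]]:
        if node_id in self.values:
            return self.values[node_id]
        if data_id is not None and data_id in self.values:
            return self.values[data_id]
        return None

    def has_data(self, node_id: str, data_id: Optional[str] = None) -> bool:
        row = self.row(node_id, data_id)
        return row is not None and any(not is_missing(v) for v in row)


@dataclass
class NodeTypeSignature:
    """A distinct combination of available datasets and its member nodes."""

    id: str
    dataset_ids: List[str]  # ordered as the datasets were registered
    member_ids: List[str]


@dataclass
class CoverageReport:
    matched: List[str]
    unmatched_dataset: List[str]  # dataset rows with no network node
    unmatched_network: List[str]  # data-less network nodes

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def read_table(
    path: str,
    format: Literal["csv", "tsv", "xlsx"] = "csv",
    id_column: Optional[str] = None,
    kind: Literal["single", "array"] = "array",
    style: str = "heatmap",
    name: Optional[str] = None,
    description: str = "",
    dataset_id: Optional[str] = None,
    sheet: Optional[str] = None,
) -> OmicsDataset:
    """Read an omics table (CSV / TSV / XLSX) into a dataset.

    The first column is the node-id column unless ``id_column`` names
    another; remaining columns must be numeric or empty (empty cells
    become missing values).  Duplicate ids, a missing id column or
    non-numeric cells raise :class:`OmicsError` with row/column context.
    Decimal separator is fixed to ``"."``; thousands separators are
    rejected as non-numeric.
    """
    path = str(path)
    if format == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif format == "xlsx":
        frame = pd.read_excel(path, sheet_name=sheet or 0, dtype=str)
        frame = frame.fillna("")
    else:
        raise OmicsError(f"unknown table format {format!r}")

    if frame.shape[1] < 2:
        raise OmicsError(f"{path}: need an id column plus >=1 value column")
    id_col = id_column if id_column is not None else frame.columns[0]
    if id_col not in frame.columns:
        raise OmicsError(f"{path}: id column {id_col!r} not found")
    headers = [c for c in frame.columns if c != id_col]

    values: Dict[str, List[float]] = {}
    for i, raw in enumerate(frame[id_col]):
        nid = str(raw).strip()
        if not nid:
            raise OmicsError(f"{path}: empty id in row {i + 2}")
        if nid in values:
            raise OmicsError(f"{path}: duplicate node id {nid!r} in row {i + 2}")
        row: List[float] = []
        for col in headers:
            cell = str(frame[col].iloc[i]).strip()
            if cell == "":
                row.append(MISSING)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise OmicsError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 2}, "
                    f"column {col!r}"
                ) from None
        values[nid] = row

    base = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return OmicsDataset(
        id=dataset_id or base,
        name=name or base,
        headers=headers,
        values=values,
        kind=kind,
        style=style,  # type: ignore[arg-type]
        description=description,
    )


def write_table(ds: OmicsDataset, path: str, id_column: str = "id") -> None:
    """Write a dataset back to CSV at full precision (round-trip aid)."""
    rows = []
    for nid in ds.values:
        rows.append([nid] + [("" if is_missing(v) else repr(v)) for v in ds.values[nid]])
    frame = pd.DataFrame(rows, columns=[id_column] + ds.headers)
    frame.to_csv(path, index=False)


def match_nodes(ds: OmicsDataset, net: Network) -> CoverageReport:
    """Report which dataset rows map onto the network and vice versa.

    Matching is by node id with a fallback to the node's ``data_id``
    attribute, so replicates of a duplicated hub all match the data
    stored under the original id.
    """
    matched = []
    covered_keys = set()
    for node in net.nodes:
        data_id = node.attributes.get("data_id")
        key = node.id if node.id in ds.values else (
            data_id if data_id in ds.values else None
        )
        if key is not None:
            matched.append(node.id)
            covered_keys.add(key)
    unmatched_dataset = sorted(set(ds.values) - covered_keys)
    unmatched_network = sorted(set(net.node_ids()) - set(matched))
    return CoverageReport(sorted(matched), unmatched_dataset, unmatched_network)


def derive_node_types(
    datasets: Sequence[OmicsDataset],
    net: Network,
    mode: Literal["uniform", "per_subset"] = "uniform",
) -> List[NodeTypeSignature]:
    """Group data-bearing nodes into node types by dataset availability.

    ``uniform``: one signature holding *all* datasets; members are every
    node with data in at least one of them (missing data renders blank,
    keeping the representation consistent across nodes).  ``per_subset``:
    one signature per distinct non-empty presence pattern, partitioning
    the data-bearing nodes.  Dataset order inside signatures follows the
    registration order of ``datasets``; nodes without any data appear in
    no signature.
    """
    if not datasets:
        raise OmicsError("need at least one dataset")
    ids = [ds.id for ds in datasets]
    if len(set(ids)) != len(ids):
        raise OmicsError("dataset ids must be unique")

    presence: Dict[str, Tuple[bool, ...]] = {}
    for node in net.nodes:
        data_id = node.attributes.get("data_id")
        pattern = tuple(ds.has_data(node.id, data_id) for ds in datasets)
        if any(pattern):
            presence[node.id] = pattern

    if mode == "uniform":
        members = sorted(presence)
        if not members:
            return []
        return [NodeTypeSignature(id="all", dataset_ids=list(ids), member_ids=members)]

    by_pattern: Dict[Tuple[bool, ...], List[str]] = {}
    for nid, pattern in presence.items():
        by_pattern.setdefault(pattern, []).append(nid)
    signatures = []
    for pattern in sorted(by_pattern, reverse=True):
        ds_ids = [ds.id for ds, there in zip(datasets, pattern) if there]
        sig_id = "+".join(ds_ids)
        signatures.append(
            NodeTypeSignature(
                id=sig_id, dataset_ids=ds_ids, member_ids=sorted(by_pattern[pattern])
            )
        )
    return signatures
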