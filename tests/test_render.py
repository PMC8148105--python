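"""Glyph rendering: layout rules, determinism, blanks, legends, export."""

import json
import random

import pytest
from PIL import Image

from glyphnet.model import NodeRecord
from glyphnet.omics import NodeTypeSignature, OmicsDataset
from glyphnet.render import (
    LayoutSpec,
    StyleError,
    auto_layout,
    default_registry,
    export_images,
    render_legend,
    render_node,
)
from glyphnet.render.layout import Cell, LayoutError, layout_from_json


def _array_ds(ds_id, n_cols, values, style="heatmap"):
    return OmicsDataset(
        id=ds_id,
        name=ds_id,
        headers=[f"t{i}" for i in range(n_cols)],
        values=values,
        kind="array",
        style=style,
    )


def _single_ds(ds_id, values):
    return OmicsDataset(
        id=ds_id, name=ds_id, headers=["v"], values=values, kind="single",
        style="heatmap",
    )


@pytest.fixture
def two_dataset_setup():
    ds1 = _array_ds("expr", 4, {"A": [0.1, 0.5, -0.3, 1.0], "B": [1.0, 2.0, 0.5, 0.1]})
    nan = float("nan")
    ds2 = _array_ds("metab", 3, {"A": [nan, nan, nan], "B": [0.2, 0.4, 0.8]}, style="line")
    sig = NodeTypeSignature(id="all", dataset_ids=["expr", "metab"], member_ids=["A", "B"])
    return [ds1, ds2], sig


class TestAutoLayout:
    def test_array_dataset_gets_full_width_row(self):
        ds = _array_ds("d", 8, {"A": [0.0] * 8})
        sig = NodeTypeSignature(id="s", dataset_ids=["d"], member_ids=["A"])
        layout = auto_layout(sig, [ds])
        assert len(layout.grid) == 1
        assert len(layout.grid[0]) == 8
        assert layout.n_columns == 8

    def test_five_singles_pack_into_two_rows(self):
        datasets = [_single_ds(f"s{i}", {"A": [float(i)]}) for i in range(5)]
        sig = NodeTypeSignature(
            id="s", dataset_ids=[d.id for d in datasets], member_ids=["A"]
        )
        layout = auto_layout(sig, datasets)
        assert [len(r) for r in layout.grid] == [4, 1]

    def test_mixed_packing_matches_rule_oracle(self):
        """Random mixes agree with an independent simulation of the two
        packing rules (array row flushes pending singles; 4-cell rows)."""
        rng = random.Random(6)
        for _ in range(25):
            datasets = []
            for i in range(rng.randint(1, 8)):
                if rng.random() < 0.5:
                    n = rng.randint(2, 6)
                    datasets.append(_array_ds(f"a{i}", n, {"A": [0.0] * n}))
                else:
                    datasets.append(_single_ds(f"s{i}", {"A": [1.0]}))
            sig = NodeTypeSignature(
                id="s", dataset_ids=[d.id for d in datasets], member_ids=["A"]
            )
            layout = auto_layout(sig, datasets)
            expected_rows = []
            pending = []
            for ds in datasets:
                if ds.kind == "array":
                    if pending:
                        expected_rows.append(pending)
                        pending = []
                    expected_rows.append([ds.id] * len(ds.headers))
                else:
                    pending.append(ds.id)
                    if len(pending) == 4:
                        expected_rows.append(pending)
                        pending = []
            if pending:
                expected_rows.append(pending)
            assert [[c.dataset_id for c in row] for row in layout.grid] == expected_rows

    def test_manual_layout_validated_against_signature(self, tmp_path):
        ds = _single_ds("d", {"A": [1.0]})
        sig = NodeTypeSignature(id="s", dataset_ids=["d"], member_ids=["A"])
        good = tmp_path / "layout.json"
        good.write_text(json.dumps({"grid": [[{"dataset": "d"}]]}))
        spec = layout_from_json(good, sig)
        assert spec.grid == [[Cell("d", 1)]]
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps({"grid": [[{"dataset": "other"}]]}))
        with pytest.raises(LayoutError):
            layout_from_json(bad, sig)


class TestRenderNode:
    def test_two_renders_byte_identical(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        node = NodeRecord(id="A", label="Node A")
        svg1 = render_node(node, sig, datasets, layout).svg
        svg2 = render_node(node, sig, datasets, layout).svg
        assert svg1 == svg2

    def test_same_node_type_identical_dimensions(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        images = [
            render_node(NodeRecord(id=nid), sig, datasets, layout)
            for nid in sig.member_ids
        ]
        assert len({(im.width, im.height) for im in images}) == 1

    def test_missing_dataset_renders_blank_cells(self, two_dataset_setup):
        """Node A has no metab values: that row must be blank (white),
        while its expr row still carries heatmap colors."""
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        svg_a = render_node(NodeRecord(id="A"), sig, datasets, layout).svg
        svg_b = render_node(NodeRecord(id="B"), sig, datasets, layout).svg
        # line style draws a polyline for B but nothing for the all-missing A
        assert "polyline" in svg_b
        assert svg_a.count("polyline") == 0
        # A still shows interpolated heatmap colors for expr
        import re

        fills = set(re.findall(r'fill="(#[0-9a-f]{6})"', svg_a))
        assert fills - {"#ffffff", "#000000"}

    def test_heatmap_endpoint_color_exact(self):
        ds = _array_ds("d", 2, {"A": [2.0, -2.0]})
        ds.scale.high_color = "#ff0000"
        ds.scale.low_color = "#0000ff"
        sig = NodeTypeSignature(id="s", dataset_ids=["d"], member_ids=["A"])
        layout = auto_layout(sig, [ds])
        svg = render_node(NodeRecord(id="A"), sig, [ds], layout).svg
        assert 'fill="#ff0000"' in svg
        assert 'fill="#0000ff"' in svg

    def test_label_falls_back_to_id(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        image = render_node(NodeRecord(id="A"), sig, datasets, layout)
        assert image.label == "A"
        assert ">A</text>" in image.svg

    def test_non_member_rejected(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        with pytest.raises(ValueError, match="not a member"):
            render_node(NodeRecord(id="zzz"), sig, datasets, layout)


class TestStyles:
    def test_register_custom_style_invoked(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        calls = []
        registry = default_registry()
        registry.register("sparkline", lambda *args: calls.append(args))
        datasets[1].style = "sparkline"
        render_node(NodeRecord(id="B"), sig, datasets, layout, registry)
        assert len(calls) == 1  # one region for the metab row

    def test_duplicate_registration_rejected(self):
        registry = default_registry()
        with pytest.raises(StyleError, match="already registered"):
            registry.register("heatmap", lambda *a: None)

    def test_unregistered_style_clear_error(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        datasets[0].style = "nope"
        layout = auto_layout(sig, datasets)
        with pytest.raises(StyleError, match="no style named 'nope'"):
            render_node(NodeRecord(id="A"), sig, datasets, layout)


class TestLegend:
    def test_color_bar_labelled_with_domain(self):
        ds = _array_ds("d", 2, {"A": [-2.0, 2.0]})
        sig = NodeTypeSignature(id="s", dataset_ids=["d"], member_ids=["A"])
        legend = render_legend(sig, [ds])
        assert ">-2</text>" in legend.svg
        assert ">2</text>" in legend.svg

    def test_entries_in_registration_order(self, two_dataset_setup):
        datasets, sig = two_dataset_setup
        legend = render_legend(sig, datasets)
        assert [e["dataset"] for e in legend.entries] == ["expr", "metab"]

    def test_entries_match_signature_for_random_subsets(self):
        rng = random.Random(11)
        pool = [
            _single_ds(f"p{i}", {"A": [float(i + 1)]}) for i in range(6)
        ]
        for _ in range(50):
            k = rng.randint(1, 6)
            chosen = rng.sample(pool, k)
            # keep registration order
            chosen = [d for d in pool if d in chosen]
            sig = NodeTypeSignature(
                id="s", dataset_ids=[d.id for d in chosen], member_ids=["A"]
            )
            legend = render_legend(sig, pool)
            assert [e["dataset"] for e in legend.entries] == [d.id for d in chosen]


class TestExport:
    def test_file_counts_and_manifest(self, tmp_path, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        images = [
            render_node(NodeRecord(id=nid), sig, datasets, layout)
            for nid in sig.member_ids
        ]
        legend = render_legend(sig, datasets)
        out = tmp_path / "img"
        manifest = export_images(images, [legend], out, formats={"svg"})
        files = sorted(p.name for p in out.iterdir())
        assert files == ["legend_all.svg", "manifest.json", "node_A.svg", "node_B.svg"]
        assert manifest["node_legend"] == {"A": "all", "B": "all"}
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk["node_legend"] == manifest["node_legend"]

    def test_png_dimensions_scale_with_dpi(self, tmp_path, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        image = render_node(NodeRecord(id="A"), sig, datasets, layout)
        export_images([image], [], tmp_path, formats={"png"}, dpi=192)
        with Image.open(tmp_path / "node_A.png") as png:
            assert png.size == (round(image.width * 2), round(image.height * 2))

    def test_unknown_format_rejected(self, tmp_path, two_dataset_setup):
        datasets, sig = two_dataset_setup
        layout = auto_layout(sig, datasets)
        image = render_node(NodeRecord(id="A"), sig, datasets, layout)
        with pytest.raises(ValueError, match="unknown export formats"):
            export_images([image], [], tmp_path, formats={"pdf"})
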