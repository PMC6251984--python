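"""Layout arithmetic and SVG rendering (determinism, validity, counts)."""

import xml.etree.ElementTree as ET

import pytest
from lxml import etree

from famviz.cigar_core import cigars_from_msa
from famviz.comparison import SegmentKind, build_comparison_track
from famviz.io_formats import parse_gff3, parse_newick_nhx
from famviz.synthetic import SimParams, simulate_family
from famviz.tree_homology import leaf_order
from famviz.viz import (
    ViewOptions,
    common_scale,
    layout_exon_focused,
    layout_proportional,
    render_genetree_svg,
    render_pairwise_svg,
)

from conftest import make_gene, make_transcript


def _self_track(exon_spans, cds_spans, n_res, strand="+", gene_id="g1"):
    t = make_transcript(exon_spans, cds_spans, strand=strand, gene_id=gene_id)
    gene = make_gene(t, gene_id)
    cigars, _ = cigars_from_msa({gene_id: "M" * n_res})
    return build_comparison_track(gene, cigars[gene_id], gene, cigars[gene_id])


def _rects(st, style):
    return [s for s in st.shapes if s.kind == "rect" and s.style == style]


def _intron_lines(st):
    return [s for s in st.shapes if s.kind == "line" and s.style == "intron"]


class TestExonFocusedLayout:
    def test_exon_widths_proportional(self):
        track = _self_track([(0, 300), (800, 950)], [(0, 300), (800, 950)], 150)
        st = layout_exon_focused(track, ViewOptions())
        exons = _rects(st, "exon")
        assert exons[0].width == pytest.approx(2 * exons[1].width)

    def test_introns_all_fixed_width(self):
        track = _self_track(
            [(0, 300), (800, 1100), (51_100, 51_400)],
            [(0, 300), (800, 1100), (51_100, 51_400)],
            300,
        )
        opts = ViewOptions(fixed_intron_px=6.0)
        st = layout_exon_focused(track, opts)
        widths = {l.width for l in _intron_lines(st)}
        assert widths == {6.0}  # 500 nt and 50,000 nt introns draw alike

    def test_single_exon_no_intron(self):
        track = _self_track([(0, 300)], [(0, 300)], 100)
        st = layout_exon_focused(track, ViewOptions())
        assert not _intron_lines(st)
        assert len(_rects(st, "exon")) == 1

    def test_row_fills_canvas(self):
        track = _self_track([(0, 300), (800, 950)], [(0, 300), (800, 950)], 150)
        opts = ViewOptions(canvas_width=900.0)
        st = layout_exon_focused(track, opts)
        assert st.width == pytest.approx(opts.canvas_width, abs=10)  # + arrow


class TestProportionalLayout:
    def test_single_scale(self):
        track = _self_track([(0, 10_000)], [(0, 9_999)], 3333)
        # span 10,000 nt on a 1,000 px canvas -> 0.1 px/nt
        opts = ViewOptions(mode="proportional", canvas_width=1000.0)
        st = layout_proportional(track, opts)
        total = sum(s.width for s in st.shapes if s.kind in ("rect",))
        assert total == pytest.approx(1000.0)

    def test_shorter_gene_shorter_row(self):
        long_track = _self_track([(0, 9_000)], [(0, 9_000)], 3000, gene_id="gl")
        short_track = _self_track([(0, 4_500)], [(0, 4_500)], 1500, gene_id="gs")
        opts = ViewOptions(mode="proportional", canvas_width=1000.0)
        scale = common_scale([long_track, short_track], opts, "proportional")
        st_long = layout_proportional(long_track, opts, scale=scale)
        st_short = layout_proportional(short_track, opts, scale=scale)
        w_long = sum(s.width for s in st_long.shapes if s.kind == "rect")
        w_short = sum(s.width for s in st_short.shapes if s.kind == "rect")
        assert w_long == pytest.approx(1000.0)
        assert w_short == pytest.approx(500.0)

    def test_pixel_ratio_matches_nt_ratio(self):
        track = _self_track(
            [(0, 333), (1000, 1333)], [(0, 333), (1000, 1333)], 222
        )
        opts = ViewOptions(mode="proportional")
        st = layout_proportional(track, opts)
        intron = _intron_lines(st)[0]
        exon = _rects(st, "exon")[0]
        assert intron.width / exon.width == pytest.approx(667 / 333)


class TestModesAgreeOnStructure:
    def test_exon_order_and_count_preserved(self, family):
        genes = parse_gff3(family.gff3)
        cigars, _ = cigars_from_msa(family.msa_rows)
        guide = family.truth.guide_gene
        for g in genes:
            track = build_comparison_track(
                genes[guide], cigars[guide], genes[g], cigars[g]
            )
            a = layout_exon_focused(track, ViewOptions())
            b = layout_proportional(track, ViewOptions(mode="proportional"))
            kinds_a = [(s.kind, s.style, s.color_index) for s in a.shapes]
            kinds_b = [(s.kind, s.style, s.color_index) for s in b.shapes]
            assert kinds_a == kinds_b
            for st in (a, b):
                for s in st.shapes:
                    assert s.x >= 0
                    assert s.x + s.width <= ViewOptions().canvas_width + 10


def _view_inputs(fx):
    genes = parse_gff3(fx.gff3)
    tree = parse_newick_nhx(fx.newick, {g: m.species for g, m in genes.items()})
    cigars, _ = cigars_from_msa(fx.msa_rows)
    guide = fx.truth.guide_gene
    tracks = {
        g: build_comparison_track(genes[guide], cigars[guide], genes[g], cigars[g])
        for g in genes
    }
    return genes, tree, cigars, guide, tracks


class TestGeneTreeSvg:
    def test_well_formed_and_counts(self, family):
        genes, tree, cigars, guide, tracks = _view_inputs(family)
        svg = render_genetree_svg(tree, tracks)
        root = etree.fromstring(svg.encode())
        ns = {"s": "http://www.w3.org/2000/svg"}
        exon_rects = root.findall(".//s:rect[@class='exon']", ns)
        n_fragments = sum(
            len(t.segments_of_kind(SegmentKind.MATCH)) for t in tracks.values()
        )
        assert len(exon_rects) == n_fragments

    def test_one_red_guide_label(self, family):
        _, tree, _, guide, tracks = _view_inputs(family)
        svg = render_genetree_svg(tree, tracks)
        root = etree.fromstring(svg.encode())
        ns = {"s": "http://www.w3.org/2000/svg"}
        labels = root.findall(".//s:text[@class='guide-label']", ns)
        assert len(labels) == 1
        assert labels[0].text == guide
        assert len(root.findall(".//s:circle[@class='guide-node']", ns)) == 1

    def test_event_circles_match_internal_nodes(self, family):
        _, tree, _, _, tracks = _view_inputs(family)
        svg = render_genetree_svg(tree, tracks)
        root = etree.fromstring(svg.encode())
        circles = [
            c for c in root.iter("{http://www.w3.org/2000/svg}circle")
            if (c.get("class") or "").startswith("node-")
        ]
        assert len(circles) == len(tree.internal_nodes())

    def test_missing_track_rejected(self, family):
        _, tree, _, _, tracks = _view_inputs(family)
        victim = leaf_order(tree)[0]
        del tracks[victim]
        with pytest.raises(Exception, match=victim):
            render_genetree_svg(tree, tracks)

    def test_deterministic(self, family):
        _, tree, _, _, tracks = _view_inputs(family)
        assert render_genetree_svg(tree, tracks) == render_genetree_svg(tree, tracks)


class TestPairwiseSvg:
    def test_identical_genes_connector_per_exon(self):
        track = _self_track([(0, 30), (60, 90)], [(0, 30), (60, 90)], 20)
        svg = render_pairwise_svg(track, track, "M" * 20, "M" * 20)
        root = etree.fromstring(svg.encode())
        ns = {"s": "http://www.w3.org/2000/svg"}
        connectors = root.findall(".//s:polygon[@class='connector']", ns)
        assert len(connectors) == 2  # one per coding exon

    def test_wrapped_text_blocks(self):
        track = _self_track([(0, 180)], [(0, 180)], 60)
        opts = ViewOptions(wrap_columns=30)
        svg = render_pairwise_svg(track, track, "M" * 60, "M" * 60, opts)
        root = etree.fromstring(svg.encode())
        texts = [
            t for t in root.iter("{http://www.w3.org/2000/svg}text")
            if t.get("class") == "seq-text"
        ]
        assert len(texts) == 6  # 2 blocks x (guide, match, target)

    def test_random_pairs_well_formed_and_deterministic(self):
        for seed in (0, 3):
            fx = simulate_family(SimParams(seed=seed))
            genes, tree, cigars, guide, tracks = _view_inputs(fx)
            target = next(g for g in genes if g != guide)
            args = (
                tracks[guide], tracks[target],
                fx.msa_rows[guide], fx.msa_rows[target],
            )
            svg = render_pairwise_svg(*args)
            ET.fromstring(svg)  # stdlib parser accepts it too
            assert svg == render_pairwise_svg(*args)
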