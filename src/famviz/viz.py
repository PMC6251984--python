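"""Deterministic layout and static SVG rendering of the browser views.

Two layout modes mirror the browser's "Introns" setting: *exon_focused*
collapses every intron to a fixed pixel width so exon structure dominates
(the default), *proportional* draws introns and exons on one shared
nt-to-pixel scale so the longest gene spans exactly the canvas width.

Rendering is intentionally boring: no timestamps, no randomness, fixed
float formatting — identical inputs give byte-identical SVG.  All styling
goes through class attributes plus one embedded stylesheet block so the
output can be restyled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .comparison import ComparisonTrack, Segment, SegmentKind
from .errors import ModelError
from .tree_homology import GeneTree, TreeNode, leaf_order

__all__ = [
    "ViewOptions",
    "Shape",
    "ScreenTrack",
    "layout_exon_focused",
    "layout_proportional",
    "common_scale",
    "render_genetree_svg",
    "render_pairwise_svg",
    "DEFAULT_PALETTE",
]

# 12 visually distinct fills, cycled by color_index mod 12
DEFAULT_PALETTE = (
    "#4e79a7", "#f28e2b", "#59a14f", "#e15759", "#b07aa1", "#edc948",
    "#76b7b2", "#ff9da7", "#9c755f", "#bab0ac", "#86bcb6", "#d37295",
)

EVENT_COLORS = {  # node fills in the tree panel
    "speciation": "#2166ac",   # blue
    "duplication": "#b2182b",  # red
    "gene_split": "#00bcd4",   # cyan
}


@dataclass(frozen=True)
class ViewOptions:
    """Knobs shared by all views; defaults are documented in docs/methods.md."""

    mode: str = "exon_focused"            # or "proportional"
    fixed_intron_px: float = 6.0
    canvas_width: float = 1200.0
    row_height: float = 24.0
    palette: tuple[str, ...] = DEFAULT_PALETTE
    show_labels: bool = True
    phylogram: bool = False
    wrap_columns: int = 60                # pairwise text panel

    def __post_init__(self):
        if self.fixed_intron_px <= 0 or self.canvas_width <= 0:
            raise ModelError("fixed_intron_px and canvas_width must be positive")
        if self.mode not in ("exon_focused", "proportional"):
            raise ModelError(f"unknown layout mode {self.mode!r}")

    def color(self, color_index: int) -> str:
        return self.palette[color_index % len(self.palette)]


@dataclass(frozen=True)
class Shape:
    kind: str          # rect | line | arrow | text
    x: float
    y: float
    width: float
    height: float
    style: str         # class attribute
    color_index: Optional[int] = None
    text: Optional[str] = None


@dataclass(frozen=True)
class ScreenTrack:
    gene_id: str
    shapes: tuple[Shape, ...]

    @property
    def width(self) -> float:
        return max((s.x + s.width for s in self.shapes), default=0.0)


_SEG_STYLE = {
    SegmentKind.MATCH: "exon",
    SegmentKind.INSERTION: "insertion",
    SegmentKind.UTR5: "utr",
    SegmentKind.UTR3: "utr",
}


def _exonic_nt(track: ComparisonTrack) -> int:
    return sum(
        len(s.interval) for s in track.segments if s.kind is not SegmentKind.NONCODING
    )


def _n_introns(track: ComparisonTrack) -> int:
    return sum(1 for s in track.segments if s.kind is SegmentKind.NONCODING)


def _span_nt(track: ComparisonTrack) -> int:
    return sum(len(s.interval) for s in track.segments)


def _fit_scale(track: ComparisonTrack, options: ViewOptions, mode: str) -> float:
    if mode == "exon_focused":
        exonic = _exonic_nt(track)
        avail = options.canvas_width - _n_introns(track) * options.fixed_intron_px
        return avail / exonic if exonic else 0.0
    span = _span_nt(track)
    return options.canvas_width / span if span else 0.0


def common_scale(
    tracks: Sequence[ComparisonTrack], options: ViewOptions, mode: str | None = None
) -> float:
    """One nt->px scale for a whole view: the widest row exactly fits."""
    mode = mode or options.mode
    scales = [_fit_scale(t, options, mode) for t in tracks if t.segments]
    return min(scales) if scales else 0.0


class _Transform:
    """Maps genomic positions of one laid-out track to pixel x."""

    def __init__(self):
        self.pieces: list[tuple[Segment, float, float]] = []  # (seg, x, w)
        self.strand = "+"

    def x_of(self, genomic_pos: int) -> float:
        """Pixel x of a genomic *point* (a coordinate between bases)."""
        last_end: Optional[float] = None
        for seg, x, w in self.pieces:
            iv = seg.interval
            n = len(iv)
            if self.strand == "+":
                if iv.start <= genomic_pos < iv.end:
                    return x + (genomic_pos - iv.start) / n * w
                if genomic_pos == iv.end:  # transcription-order tail
                    last_end = x + w
            else:
                if iv.start < genomic_pos <= iv.end:
                    return x + (iv.end - genomic_pos) / n * w
                if genomic_pos == iv.start:
                    last_end = x + w
        if last_end is not None:
            return last_end
        raise ModelError(f"position {genomic_pos} outside the laid-out track")


def _layout(
    track: ComparisonTrack, options: ViewOptions, mode: str, scale: Optional[float]
) -> tuple[ScreenTrack, _Transform]:
    if scale is None:
        scale = _fit_scale(track, options, mode)
    rh = options.row_height
    exon_h = rh * 0.6
    utr_h = rh * 0.4
    y_exon = (rh - exon_h) / 2.0
    y_utr = (rh - utr_h) / 2.0
    x = 0.0
    shapes: list[Shape] = []
    tf = _Transform()
    tf.strand = track.strand
    for seg in track.segments:
        nt = len(seg.interval)
        if seg.kind is SegmentKind.NONCODING:
            w = options.fixed_intron_px if mode == "exon_focused" else nt * scale
            shapes.append(Shape("line", x, rh / 2.0, w, 0.0, "intron"))
        else:
            w = nt * scale
            style = _SEG_STYLE[seg.kind]
            h = utr_h if style == "utr" else exon_h
            y = y_utr if style == "utr" else y_exon
            shapes.append(Shape("rect", x, y, w, h, style, seg.color_index))
        tf.pieces.append((seg, x, w))
        x += w
    for mark in track.deletion_marks:
        shapes.append(Shape("line", tf.x_of(mark), y_exon, 0.0, exon_h, "deletion"))
    # tiny arrow marking the coding strand, past the 3' end of the row
    shapes.append(Shape("arrow", x + 2.0, rh / 2.0, 6.0, 6.0, "strand-arrow"))
    if options.show_labels:
        shapes.append(
            Shape("text", 0.0, rh / 2.0, 0.0, 0.0, "label", text=track.gene_id)
        )
    return ScreenTrack(gene_id=track.gene_id, shapes=tuple(shapes)), tf


def layout_exon_focused(
    track: ComparisonTrack, options: ViewOptions, scale: Optional[float] = None
) -> ScreenTrack:
    """Introns at ``fixed_intron_px``; exon widths proportional to nt."""
    return _layout(track, options, "exon_focused", scale)[0]


def layout_proportional(
    track: ComparisonTrack, options: ViewOptions, scale: Optional[float] = None
) -> ScreenTrack:
    """Everything on one nt->px scale."""
    return _layout(track, options, "proportional", scale)[0]


# ---------------------------------------------------------------------------
# SVG emission


def _fmt(v: float) -> str:
    s = f"{v:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


STYLESHEET = """
  .exon { stroke: #333333; stroke-width: 0.5; }
  .insertion { fill: #000000; }
  .deletion { stroke: #d00000; stroke-width: 1.5; }
  .utr { fill: #9e9e9e; }
  .intron { stroke: #666666; stroke-width: 1; }
  .strand-arrow { fill: #444444; }
  .label { font: 10px sans-serif; fill: #222222; }
  .guide-label { font: bold 10px sans-serif; fill: #d00000; }
  .edge { stroke: #555555; stroke-width: 1; fill: none; }
  .leaf-node { fill: #555555; }
  .guide-node { fill: #000000; }
  .node-speciation { fill: %(spec)s; }
  .node-duplication { fill: %(dup)s; }
  .node-gene_split { fill: %(split)s; }
  .connector { stroke: none; fill-opacity: 0.35; }
  .seq-text { font: 11px monospace; fill: #111111; white-space: pre; }
  .gene-box { stroke: #333333; stroke-width: 1; }
  .gene-box-white { fill: #ffffff; stroke: #999999; stroke-width: 1; }
  .focal { stroke: #d00000; stroke-width: 2; }
""" % {
    "spec": EVENT_COLORS["speciation"],
    "dup": EVENT_COLORS["duplication"],
    "split": EVENT_COLORS["gene_split"],
}


class _Svg:
    def __init__(self, width: float, height: float):
        self.parts: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(width)}" height="{_fmt(height)}" '
            f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
            f"<style>{STYLESHEET}</style>",
        ]

    def rect(self, x, y, w, h, cls, fill=None):
        fill_attr = f' fill="{fill}"' if fill else ""
        self.parts.append(
            f'<rect class="{cls}" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'width="{_fmt(max(w, 0.0))}" height="{_fmt(h)}"{fill_attr}/>'
        )

    def line(self, x1, y1, x2, y2, cls):
        self.parts.append(
            f'<line class="{cls}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}"/>'
        )

    def circle(self, cx, cy, r, cls):
        self.parts.append(
            f'<circle class="{cls}" cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}"/>'
        )

    def polygon(self, points, cls, fill=None):
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        fill_attr = f' fill="{fill}"' if fill else ""
        self.parts.append(f'<polygon class="{cls}" points="{pts}"{fill_attr}/>')

    def path(self, d, cls):
        self.parts.append(f'<path class="{cls}" d="{d}"/>')

    def text(self, x, y, content, cls, anchor="start"):
        self.parts.append(
            f'<text class="{cls}" x="{_fmt(x)}" y="{_fmt(y)}" '
            f'text-anchor="{anchor}">{_esc(content)}</text>'
        )

    def tostring(self) -> str:
        return "\n".join(self.parts + ["</svg>"]) + "\n"


def _draw_screen_track(
    svg: _Svg, st: ScreenTrack, options: ViewOptions, dx: float, dy: float,
    guide: bool = False,
) -> None:
    for s in st.shapes:
        x, y = s.x + dx, s.y + dy
        if s.kind == "rect":
            fill = options.color(s.color_index) if s.color_index is not None else None
            svg.rect(x, y, s.width, s.height, s.style, fill=fill)
        elif s.kind == "line":
            if s.width and not s.height:     # horizontal (intron)
                svg.line(x, y, x + s.width, y, s.style)
            else:                            # vertical (deletion mark)
                svg.line(x, y, x, y + s.height, s.style)
        elif s.kind == "arrow":
            half = s.height / 2.0
            svg.polygon(
                [(x, y - half), (x + s.width, y), (x, y + half)], s.style
            )
        elif s.kind == "text":
            cls = "guide-label" if guide else s.style
            svg.text(x - 6.0, y + 3.0, s.text or "", cls, anchor="end")


def _node_positions(
    tree: GeneTree, options: ViewOptions, tree_w: float, row_h: float, top: float
) -> dict[int, tuple[float, float]]:
    order = leaf_order(tree)
    leaf_y = {g: top + i * row_h + row_h / 2.0 for i, g in enumerate(order)}
    pos: dict[int, tuple[float, float]] = {}

    def depth_of(node: TreeNode) -> int:
        return 1 + (max(depth_of(c) for c in node.children) if node.children else 0)

    if options.phylogram:
        def xcoord(node: TreeNode, acc: float) -> None:
            pos[id(node)] = (acc, 0.0)
            for c in node.children:
                xcoord(c, acc + (c.branch_length or 1.0))
        xcoord(tree.root, 0.0)
        max_x = max(x for x, _ in pos.values()) or 1.0
        scale = tree_w / max_x
        for key, (x, _) in list(pos.items()):
            pos[key] = (x * scale, 0.0)
    else:
        max_d = depth_of(tree.root) - 1 or 1

        def xcoord(node: TreeNode, d: int) -> None:
            x = tree_w if node.is_leaf else tree_w * d / max_d
            pos[id(node)] = (x, 0.0)
            for c in node.children:
                xcoord(c, d + 1)
        xcoord(tree.root, 0)

    def ycoord(node: TreeNode) -> float:
        if node.is_leaf:
            y = leaf_y[node.gene_id]  # type: ignore[index]
        else:
            ys = [ycoord(c) for c in node.children]
            y = sum(ys) / len(ys)
        pos[id(node)] = (pos[id(node)][0], y)
        return y

    ycoord(tree.root)
    if options.phylogram:
        for leaf in tree.root.iter_leaves():
            pos[id(leaf)] = (tree_w, pos[id(leaf)][1])
    return pos


def render_genetree_svg(
    tree: GeneTree,
    tracks: Mapping[str, ComparisonTrack],
    options: ViewOptions = ViewOptions(),
) -> str:
    """The main view: tree panel left, one structure row per leaf right.

    The guide row's leaf is a larger black circle and its label is red;
    internal nodes are colored by their evolutionary event.
    """
    order = leaf_order(tree)
    missing = [g for g in order if g not in tracks]
    if missing:
        raise ModelError(f"no track for tree leaves: {', '.join(missing)}")
    rh = options.row_height
    tree_w, label_w, margin = 180.0, 130.0, 10.0
    top = margin
    track_x = margin + tree_w + label_w
    width = track_x + options.canvas_width + margin
    height = 2 * margin + rh * len(order)
    svg = _Svg(width, height)

    pos = _node_positions(tree, options, tree_w, rh, top)

    def draw_edges(node: TreeNode) -> None:
        x, y = pos[id(node)]
        for c in node.children:
            cx, cy = pos[id(c)]
            svg.path(
                f"M {_fmt(margin + x)} {_fmt(y)} V {_fmt(cy)} H {_fmt(margin + cx)}",
                "edge",
            )
            draw_edges(c)

    draw_edges(tree.root)
    guide_id = next((g for g, t in tracks.items() if t.guide_flag), None)
    for node in tree.root.iter_preorder():
        x, y = pos[id(node)]
        if node.is_leaf:
            if node.gene_id == guide_id:
                svg.circle(margin + x, y, 4.5, "guide-node")
            else:
                svg.circle(margin + x, y, 2.5, "leaf-node")
        else:
            svg.circle(margin + x, y, 3.5, f"node-{node.event}")

    scale = common_scale([tracks[g] for g in order], options)
    layout = layout_exon_focused if options.mode == "exon_focused" else layout_proportional
    for i, gene_id in enumerate(order):
        st = layout(tracks[gene_id], options, scale=scale)
        _draw_screen_track(
            svg, st, options, dx=track_x, dy=top + i * rh,
            guide=gene_id == guide_id,
        )
    return svg.tostring()


def render_pairwise_svg(
    guide_track: ComparisonTrack,
    target_track: ComparisonTrack,
    aligned_guide: str,
    aligned_target: str,
    options: ViewOptions = ViewOptions(),
) -> str:
    """1-to-1 view: two structure rows joined by per-block connector
    polygons, then the textual pairwise alignment wrapped underneath.

    In the text panel the middle line carries ``|`` where the residues
    are identical and a space elsewhere (gaps included).
    """
    if len(aligned_guide) != len(aligned_target):
        raise ModelError("aligned sequences differ in length")
    rh = options.row_height
    margin, label_w = 10.0, 130.0
    gap_rows = rh * 2.5            # vertical space between the two rows
    track_x = margin + label_w
    width = track_x + options.canvas_width + margin

    mode = options.mode
    scale = common_scale([guide_track, target_track], options, mode)
    layout = layout_exon_focused if mode == "exon_focused" else layout_proportional
    st_g, tf_g = _layout(guide_track, options, mode, scale)
    st_t, tf_t = _layout(target_track, options, mode, scale)

    line_h = 13.0
    n_blocks = (len(aligned_guide) + options.wrap_columns - 1) // options.wrap_columns
    text_top = 2 * margin + 2 * rh + gap_rows
    height = text_top + n_blocks * (3 * line_h + 8.0) + margin
    svg = _Svg(width, height)

    y_guide = margin
    y_target = margin + rh + gap_rows
    # connectors first so the rows draw on top of them
    for chunk in target_track.match_chunks:
        gx = [tf_g.x_of(p) for iv in chunk.guide_intervals for p in (iv.start, iv.end)]
        tx = [tf_t.x_of(p) for iv in chunk.target_intervals for p in (iv.start, iv.end)]
        g0, g1 = min(gx), max(gx)
        t0, t1 = min(tx), max(tx)
        y0 = y_guide + rh * 0.8
        y1 = y_target + rh * 0.2
        svg.polygon(
            [
                (track_x + g0, y0), (track_x + g1, y0),
                (track_x + t1, y1), (track_x + t0, y1),
            ],
            "connector",
            fill=options.color(chunk.color_index),
        )
    _draw_screen_track(svg, st_g, options, dx=track_x, dy=y_guide, guide=True)
    _draw_screen_track(svg, st_t, options, dx=track_x, dy=y_target)

    wrap = options.wrap_columns
    y = text_top
    for b in range(n_blocks):
        ga = aligned_guide[b * wrap : (b + 1) * wrap]
        ta = aligned_target[b * wrap : (b + 1) * wrap]
        mid = "".join(
            "|" if (a == c and a != "-") else " " for a, c in zip(ga, ta)
        )
        for row_text in (ga, mid, ta):
            y += line_h
            svg.parts.append(
                f'<text class="seq-text" x="{_fmt(track_x)}" y="{_fmt(y)}" '
                f'xml:space="preserve">{_esc(row_text)}</text>'
            )
        y += 8.0
    return svg.tostring()
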