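"""Gene-order view: neighborhoods around homologues, colored by homology.

One row per species: the focal homologue plus up to *k* neighbors on each
side, in genomic order.  The reference row's genes get sequential color
indices; a gene in any other row inherits the color of its homologue in
the reference row, but only if that homologue is inside the visible
window — otherwise it stays white.  Coloring always goes through the
reference row, never transitively across other rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ModelError
from .io_formats import GenomicInterval
from .viz import ViewOptions, _Svg

__all__ = [
    "SyntenyGene",
    "SyntenyRow",
    "neighborhood",
    "color_synteny",
    "render_gene_order_svg",
]

WHITE = None  # color_index of a gene without a visible homologue


@dataclass(frozen=True)
class SyntenyGene:
    gene_id: str
    interval: GenomicInterval
    strand: str
    color_index: Optional[int] = WHITE
    focal_flag: bool = False


@dataclass(frozen=True)
class SyntenyRow:
    species: str
    seq_id: str
    genes: tuple[SyntenyGene, ...]

    def __post_init__(self):
        starts = [g.interval.start for g in self.genes]
        if starts != sorted(starts):
            raise ModelError(f"row {self.species!r}: genes not in genomic order")
        if sum(1 for g in self.genes if g.focal_flag) != 1:
            raise ModelError(f"row {self.species!r}: exactly one focal gene required")


def neighborhood(
    genes: Sequence[SyntenyGene], focal_gene: str, k: int
) -> list[SyntenyGene]:
    """Up to ``k`` genes each side of the focal, truncated at the ends."""
    if k < 0:
        raise ModelError("k must be non-negative")
    ordered = sorted(genes, key=lambda g: g.interval.start)
    idx = next((i for i, g in enumerate(ordered) if g.gene_id == focal_gene), None)
    if idx is None:
        raise ModelError(f"focal gene {focal_gene!r} not on this sequence")
    window = ordered[max(0, idx - k) : idx + k + 1]
    return [
        SyntenyGene(
            g.gene_id, g.interval, g.strand,
            color_index=g.color_index, focal_flag=g.gene_id == focal_gene,
        )
        for g in window
    ]


def color_synteny(
    reference: SyntenyRow,
    others: Sequence[SyntenyRow],
    homology_pairs: Iterable[tuple[str, str]],
) -> list[SyntenyRow]:
    """Assign color indices: reference genes sequentially, other genes via
    their homologue in the (visible) reference row, else white."""
    partners: dict[str, set[str]] = {}
    for a, b in homology_pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    ref_color = {g.gene_id: i for i, g in enumerate(reference.genes)}
    ref_row = SyntenyRow(
        species=reference.species,
        seq_id=reference.seq_id,
        genes=tuple(
            SyntenyGene(g.gene_id, g.interval, g.strand,
                        color_index=ref_color[g.gene_id], focal_flag=g.focal_flag)
            for g in reference.genes
        ),
    )
    out = [ref_row]
    for row in others:
        recolored = []
        for g in row.genes:
            visible = sorted(
                ref_color[p] for p in partners.get(g.gene_id, ()) if p in ref_color
            )
            color = visible[0] if visible else WHITE
            recolored.append(
                SyntenyGene(g.gene_id, g.interval, g.strand,
                            color_index=color, focal_flag=g.focal_flag)
            )
        out.append(SyntenyRow(row.species, row.seq_id, tuple(recolored)))
    return out


def rows_to_tsv(rows: Sequence[SyntenyRow]) -> str:
    """Tab-separated dump of colored rows, for testing and inspection."""
    lines = ["#species\tseq_id\tgene_id\tstart\tend\tstrand\tcolor_index\tfocal"]
    for row in rows:
        for g in row.genes:
            color = "WHITE" if g.color_index is None else str(g.color_index)
            lines.append(
                "\t".join([row.species, row.seq_id, g.gene_id,
                           str(g.interval.start), str(g.interval.end), g.strand,
                           color, "1" if g.focal_flag else "0"])
            )
    return "\n".join(lines) + "\n"


def render_gene_order_svg(
    rows: Sequence[SyntenyRow], options: ViewOptions = ViewOptions()
) -> str:
    """One horizontal row per species; pentagon gene boxes point along the
    coding strand; the focal gene and its homologues carry a red border."""
    if not rows:
        raise ModelError("at least one synteny row is required")
    margin, label_w = 10.0, 110.0
    rh = options.row_height * 1.6
    box_h = options.row_height
    width = margin + label_w + options.canvas_width + margin
    height = 2 * margin + rh * len(rows)
    svg = _Svg(width, height)
    for i, row in enumerate(rows):
        y = margin + i * rh + (rh - box_h) / 2.0
        svg.text(margin + label_w - 8.0, y + box_h / 2.0 + 3.0,
                 row.species, "label", anchor="end")
        lo = min(g.interval.start for g in row.genes)
        hi = max(g.interval.end for g in row.genes)
        scale = options.canvas_width / max(hi - lo, 1)
        for g in row.genes:
            x0 = margin + label_w + (g.interval.start - lo) * scale
            w = max(len(g.interval) * scale, 4.0)
            tip = min(8.0, w / 3.0)
            if g.strand == "+":
                pts = [(x0, y), (x0 + w - tip, y), (x0 + w, y + box_h / 2.0),
                       (x0 + w - tip, y + box_h), (x0, y + box_h)]
            else:
                pts = [(x0 + w, y), (x0 + tip, y), (x0, y + box_h / 2.0),
                       (x0 + tip, y + box_h), (x0 + w, y + box_h)]
            if g.color_index is None:
                cls, fill = "gene-box-white", None
            else:
                cls, fill = "gene-box", options.color(g.color_index)
            if g.focal_flag:
                cls += " focal"
            svg.polygon(pts, cls, fill=fill)
    return svg.tostring()
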