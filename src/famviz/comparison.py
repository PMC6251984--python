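"""Project the family alignment onto each homologue's gene structure.

For one guide/target pair the alignment columns are classified (BOTH /
INSERTION / DELETION / NEITHER, target relative to guide) and projected
back onto the *target's* genome:

* BOTH runs become MATCH segments.  Each run is split wherever the guide
  residues change owner exon, so every MATCH fragment carries exactly one
  guide-exon color index — this is what makes a single target exon that
  aligns across two adjacent guide exons show up as two fragments with
  consecutive colors.
* INSERTION runs (target-only residues) become black insertion segments
  inside the target's exons.
* DELETION runs (guide-only residues) collapse to a zero-width deletion
  mark at the genomic point between the flanking aligned target residues
  (the gene's 5' CDS end if there is no left flank).  Runs separated only
  by NEITHER columns merge into one mark; the same transparency rule is
  applied to every class, since NEITHER columns exist in neither member.
* UTRs and introns are emitted explicitly (UTR5/UTR3/NONCODING) so the
  renderer never re-derives gene structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .cigar_core import AlignmentCigar, ColumnClass, classify_columns
from .errors import ModelError
from .gene_models import (
    CdsMap,
    build_cds_map,
    cds_boundary_to_genomic,
    protein_to_genomic,
    residue_exon_owner,
)
from .io_formats import GeneModel, GenomicInterval

__all__ = [
    "SegmentKind",
    "Segment",
    "MatchChunk",
    "ComparisonTrack",
    "guide_exon_palette",
    "build_comparison_track",
    "track_to_bed",
]


class SegmentKind(str, Enum):
    MATCH = "MATCH"
    INSERTION = "INSERTION"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NONCODING = "NONCODING"


@dataclass(frozen=True)
class Segment:
    """One drawable piece of a track, in target genomic coordinates."""

    kind: SegmentKind
    interval: GenomicInterval
    color_index: Optional[int] = None

    def __post_init__(self):
        if self.kind is SegmentKind.MATCH and self.color_index is None:
            raise ModelError("MATCH segments must carry a color index")
        if self.kind is not SegmentKind.MATCH and self.color_index is not None:
            raise ModelError(f"{self.kind.value} segments carry no color index")


@dataclass(frozen=True)
class MatchChunk:
    """One maximal same-color aligned block, with both genomic footprints.

    Kept alongside the flat segment list so the pairwise view can draw a
    connector polygon from the guide's copy of the block to the target's.
    """

    color_index: int
    guide_intervals: tuple[GenomicInterval, ...]
    target_intervals: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class ComparisonTrack:
    """Everything needed to draw one homologue against the guide."""

    gene_id: str
    strand: str
    segments: tuple[Segment, ...]          # transcription (5'->3') order
    deletion_marks: tuple[int, ...]        # genomic points on the target
    match_chunks: tuple[MatchChunk, ...]
    guide_flag: bool = False

    def segments_of_kind(self, kind: SegmentKind) -> list[Segment]:
        return [s for s in self.segments if s.kind is kind]

    def total_length(self, kind: SegmentKind) -> int:
        return sum(len(s.interval) for s in self.segments_of_kind(kind))


def guide_exon_palette(guide: "GeneModel | object") -> list[int]:
    """Color index per coding exon of the guide: exon i -> i.

    Palette *cycling* (mod the number of actual colors) is a rendering
    concern; here indices just enumerate coding exons.
    """
    transcript = getattr(guide, "canonical_transcript", guide)
    n = len(transcript.coding_exon_indices())
    if n == 0:
        raise ModelError(
            f"transcript {transcript.transcript_id!r} has no coding exons"
        )
    return list(range(n))


def _simplified_runs(guide: AlignmentCigar, target: AlignmentCigar):
    """Classification runs with NEITHER dropped and same-class runs merged."""
    out: list[tuple[int, ColumnClass]] = []
    for count, cls in classify_columns(guide, target).runs:
        if cls is ColumnClass.NEITHER:
            continue
        if out and out[-1][1] is cls:
            out[-1] = (out[-1][0] + count, cls)
        else:
            out.append((count, cls))
    return out


def _split_by_guide_owner(guide_map: CdsMap, g0: int, n: int) -> list[tuple[int, int]]:
    """Split guide residues [g0, g0+n) into (offset, length) chunks of
    constant owner exon; returns [(rel_offset, length, owner), ...]."""
    chunks: list[tuple[int, int, int]] = []
    owner_prev = None
    start = 0
    for k in range(n):
        owner = residue_exon_owner(guide_map, g0 + k)
        if owner != owner_prev:
            if owner_prev is not None:
                chunks.append((start, k - start, owner_prev))
            owner_prev = owner
            start = k
    chunks.append((start, n - start, owner_prev))  # type: ignore[arg-type]
    return chunks  # type: ignore[return-value]


def build_comparison_track(
    guide: GeneModel,
    guide_cigar: AlignmentCigar,
    target: GeneModel,
    target_cigar: AlignmentCigar,
) -> ComparisonTrack:
    """Build the drawable track of ``target`` compared against ``guide``."""
    guide_t = guide.canonical_transcript
    target_t = target.canonical_transcript
    guide_map = build_cds_map(guide_t)
    target_map = build_cds_map(target_t)
    if 3 * guide_cigar.n_residues != guide_map.cds_len:
        raise ModelError(
            f"guide {guide.gene_id!r}: CIGAR encodes {guide_cigar.n_residues} "
            f"residues but CDS holds {guide_map.n_residues}"
        )
    if 3 * target_cigar.n_residues != target_map.cds_len:
        raise ModelError(
            f"target {target.gene_id!r}: CIGAR encodes {target_cigar.n_residues} "
            f"residues but CDS holds {target_map.n_residues}"
        )

    cds_segments: list[Segment] = []   # MATCH/INSERTION in target CDS order
    marks: list[int] = []
    chunks: list[MatchChunk] = []
    g_res = t_res = 0
    for count, cls in _simplified_runs(guide_cigar, target_cigar):
        if cls is ColumnClass.BOTH:
            for off, length, owner in _split_by_guide_owner(guide_map, g_res, count):
                g_ivs = protein_to_genomic(guide_map, g_res + off, g_res + off + length)
                t_ivs = protein_to_genomic(target_map, t_res + off, t_res + off + length)
                chunks.append(
                    MatchChunk(
                        color_index=owner,
                        guide_intervals=tuple(g_ivs),
                        target_intervals=tuple(t_ivs),
                    )
                )
                for iv in t_ivs:
                    cds_segments.append(Segment(SegmentKind.MATCH, iv, owner))
            g_res += count
            t_res += count
        elif cls is ColumnClass.INSERTION:
            for iv in protein_to_genomic(target_map, t_res, t_res + count):
                cds_segments.append(Segment(SegmentKind.INSERTION, iv))
            t_res += count
        else:  # DELETION: guide-only residues collapse to a point on target
            marks.append(cds_boundary_to_genomic(target_map, 3 * t_res))
            g_res += count

    # assemble in transcription order: UTR5, CDS content with introns, UTR3
    segments: list[Segment] = [Segment(SegmentKind.UTR5, u) for u in target_t.utr5]
    # CDS-space segments are already in transcription order (t_res increases);
    # interleave an intron segment whenever consecutive pieces are split.
    ordered = _order_cds_segments(cds_segments, target_map)
    segments.extend(_with_introns(ordered, target_t))
    segments.extend(Segment(SegmentKind.UTR3, u) for u in target_t.utr3)

    return ComparisonTrack(
        gene_id=target.gene_id,
        strand=target_t.strand,
        segments=tuple(segments),
        deletion_marks=tuple(marks),
        match_chunks=tuple(chunks),
        guide_flag=target.gene_id == guide.gene_id,
    )


def _order_cds_segments(segs: list[Segment], cmap: CdsMap) -> list[Segment]:
    """Sort CDS-space segments by transcription order (they already are,
    construction-wise; this is a guard for the invariant, not a re-sort)."""

    def key(seg: Segment) -> int:
        iv = seg.interval
        return iv.start if cmap.strand == "+" else -iv.end

    return sorted(segs, key=key)


def _with_introns(segs: list[Segment], transcript) -> list[Segment]:
    """Insert NONCODING intron segments between exons of the transcript,
    placed where the walked CDS segments jump across them."""
    introns: list[GenomicInterval] = []
    exons = sorted(transcript.exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        introns.append(GenomicInterval(a.seq_id, a.end, b.start, a.strand))
    if transcript.strand == "-":
        introns = introns[::-1]
    out: list[Segment] = []
    intron_iter = iter(introns)
    pending = next(intron_iter, None)
    for seg in segs:
        while pending is not None and _is_before(pending, seg.interval, transcript.strand):
            out.append(Segment(SegmentKind.NONCODING, pending))
            pending = next(intron_iter, None)
        out.append(seg)
    while pending is not None:
        out.append(Segment(SegmentKind.NONCODING, pending))
        pending = next(intron_iter, None)
    return out


def _is_before(a: GenomicInterval, b: GenomicInterval, strand: str) -> bool:
    """True if interval a lies 5' of interval b in transcription order."""
    return a.end <= b.start if strand == "+" else a.start >= b.end


BED_HEADER = ["seq_id", "start", "end", "kind", "color_index", "gene_id"]


def track_to_bed(track: ComparisonTrack) -> str:
    """BED-like TSV (0-based half-open) of all segments plus deletion
    marks as zero-length DELETION records, for downstream inspection."""
    lines = ["#" + "\t".join(BED_HEADER)]
    for seg in track.segments:
        iv = seg.interval
        color = "." if seg.color_index is None else str(seg.color_index)
        lines.append(
            "\t".join([iv.seq_id, str(iv.start), str(iv.end), seg.kind.value,
                       color, track.gene_id])
        )
    seq_id = track.segments[0].interval.seq_id if track.segments else "."
    for mark in track.deletion_marks:
        lines.append(
            "\t".join([seq_id, str(mark), str(mark), "DELETION", ".", track.gene_id])
        )
    return "\n".join(lines) + "\n"
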