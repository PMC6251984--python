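"""Strand-aware mapping between protein residues, CDS bases and the genome.

The central object is :class:`CdsMap`: an ordered partition of the CDS
coordinate axis ``[0, cds_len)`` into pieces, one per coding exon, each
bound to a genomic interval.  CDS coordinate 0 is the first coding base
in transcription order, so on the minus strand increasing CDS positions
run *down* the genome.  Everything else — projecting residue ranges onto
genomic intervals (splitting at introns), finding which residues a given
exon carries, assigning an intron-split codon to an owner exon — is
integer arithmetic over that partition.

A codon split across two exons is owned, for coloring purposes, by the
exon holding at least two of its three bases; exact ties are impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ModelError
from .io_formats import GenomicInterval, TranscriptModel

__all__ = [
    "CdsMap",
    "build_cds_map",
    "protein_to_genomic",
    "cds_nt_to_genomic",
    "genomic_to_cds",
    "residue_ranges_of_exon",
    "residue_exon_owner",
]


@dataclass(frozen=True)
class CdsPiece:
    """One coding-exon slice of the CDS axis: CDS [cds_start, cds_end) lies
    on ``genomic``; ``exon_index`` addresses the transcript's exon list."""

    cds_start: int
    cds_end: int
    genomic: GenomicInterval
    exon_index: int

    def __post_init__(self):
        if self.cds_end - self.cds_start != len(self.genomic):
            raise ModelError("CDS piece length disagrees with its genomic interval")


@dataclass(frozen=True)
class CdsMap:
    transcript_id: str
    strand: str
    pieces: tuple[CdsPiece, ...]

    def __post_init__(self):
        expect = 0
        for p in self.pieces:
            if p.cds_start != expect:
                raise ModelError(
                    f"CDS pieces of {self.transcript_id!r} do not partition the CDS"
                )
            expect = p.cds_end
        if expect % 3 != 0:
            raise ModelError(
                f"CDS length {expect} of {self.transcript_id!r} is not a multiple of 3"
            )

    @property
    def cds_len(self) -> int:
        return self.pieces[-1].cds_end if self.pieces else 0

    @property
    def n_residues(self) -> int:
        return self.cds_len // 3


def build_cds_map(transcript: TranscriptModel) -> CdsMap:
    """Lay the transcript's CDS segments end to end along the CDS axis."""
    for a in transcript.cds_segments:
        for b in transcript.cds_segments:
            if a is not b and a.overlaps(b):
                raise ModelError(
                    f"overlapping CDS segments in transcript {transcript.transcript_id!r}"
                )
    exon_of_cds: list[int] = []
    for cds in transcript.cds_segments:
        for i, ex in enumerate(transcript.exons):
            if ex.contains(cds):
                exon_of_cds.append(i)
                break
    pieces: list[CdsPiece] = []
    pos = 0
    for cds, exon_index in zip(transcript.cds_segments, exon_of_cds):
        pieces.append(
            CdsPiece(
                cds_start=pos,
                cds_end=pos + len(cds),
                genomic=cds,
                exon_index=exon_index,
            )
        )
        pos += len(cds)
    return CdsMap(
        transcript_id=transcript.transcript_id,
        strand=transcript.strand,
        pieces=tuple(pieces),
    )


def cds_nt_to_genomic(cmap: CdsMap, nt_start: int, nt_end: int) -> list[GenomicInterval]:
    """Genomic intervals covering CDS bases [nt_start, nt_end), 5'->3'."""
    if not (0 <= nt_start < nt_end <= cmap.cds_len):
        raise ModelError(
            f"CDS range [{nt_start},{nt_end}) outside [0,{cmap.cds_len})"
        )
    out: list[GenomicInterval] = []
    for p in cmap.pieces:
        lo = max(nt_start, p.cds_start)
        hi = min(nt_end, p.cds_end)
        if lo >= hi:
            continue
        if cmap.strand == "+":
            g0 = p.genomic.start + (lo - p.cds_start)
            g1 = p.genomic.start + (hi - p.cds_start)
        else:
            g1 = p.genomic.end - (lo - p.cds_start)
            g0 = p.genomic.end - (hi - p.cds_start)
        out.append(GenomicInterval(p.genomic.seq_id, g0, g1, cmap.strand))
    return out


def protein_to_genomic(cmap: CdsMap, aa_start: int, aa_end: int) -> list[GenomicInterval]:
    """Genomic footprint of residues [aa_start, aa_end), split at introns.

    Total returned length is always exactly ``3 * (aa_end - aa_start)``.
    """
    if not (0 <= aa_start < aa_end <= cmap.n_residues):
        raise ModelError(
            f"residue range [{aa_start},{aa_end}) outside protein of "
            f"length {cmap.n_residues}"
        )
    return cds_nt_to_genomic(cmap, 3 * aa_start, 3 * aa_end)


def cds_boundary_to_genomic(cmap: CdsMap, nt_boundary: int) -> int:
    """Genomic coordinate of the CDS boundary *before* base ``nt_boundary``.

    For ``nt_boundary == cds_len`` the position just past the last coding
    base (transcription order) is returned.  Used to place deletion marks.
    """
    if not (0 <= nt_boundary <= cmap.cds_len):
        raise ModelError(f"CDS boundary {nt_boundary} outside [0,{cmap.cds_len}]")
    if nt_boundary == cmap.cds_len:
        p = cmap.pieces[-1]
        return p.genomic.end if cmap.strand == "+" else p.genomic.start
    for p in cmap.pieces:
        if p.cds_start <= nt_boundary < p.cds_end:
            off = nt_boundary - p.cds_start
            return p.genomic.start + off if cmap.strand == "+" else p.genomic.end - off
    raise ModelError("unreachable")  # pragma: no cover


def genomic_to_cds(cmap: CdsMap, genomic_pos: int) -> int:
    """CDS coordinate of one genomic base; error if non-coding."""
    for p in cmap.pieces:
        if p.genomic.start <= genomic_pos < p.genomic.end:
            if cmap.strand == "+":
                return p.cds_start + (genomic_pos - p.genomic.start)
            return p.cds_start + (p.genomic.end - 1 - genomic_pos)
    raise ModelError(f"genomic position {genomic_pos} is not a coding base")


def residue_ranges_of_exon(cmap: CdsMap, exon_index: int) -> tuple[int, int, tuple[bool, bool]]:
    """Residues whose codons touch the CDS bases of one coding exon.

    Returns ``(aa_lo, aa_hi, (first_shared, last_shared))`` where the
    flags mark boundary codons shared with a neighboring exon.
    """
    pieces = [p for p in cmap.pieces if p.exon_index == exon_index]
    if not pieces:
        raise ModelError(f"exon {exon_index} carries no CDS")
    cs = min(p.cds_start for p in pieces)
    ce = max(p.cds_end for p in pieces)
    aa_lo = cs // 3
    aa_hi = (ce + 2) // 3
    return aa_lo, aa_hi, (cs % 3 != 0, ce % 3 != 0)


def residue_exon_owner(cmap: CdsMap, aa_index: int) -> int:
    """Coding-exon ordinal owning a residue's codon (>=2 of 3 bases).

    The returned index counts *coding* exons in transcription order
    (piece order), which is also the palette index of that exon.
    """
    nt0 = 3 * aa_index
    best_piece = -1
    best_bases = 0
    for k, p in enumerate(cmap.pieces):
        overlap = min(nt0 + 3, p.cds_end) - max(nt0, p.cds_start)
        if overlap > best_bases:
            best_bases = overlap
            best_piece = k
    if best_piece < 0:
        raise ModelError(f"residue {aa_index} outside the CDS")
    return best_piece
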