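"""Readers and writers for every external representation.

GFF3 gene models (via gffutils), FASTA alignments (via Biopython),
Newick/NHX gene trees (parsed via dendropy; NHX tags ``D``, ``S`` and the
custom ``Ev`` tag are interpreted here), protein-space CIGAR strings, CSV
homology tables and a JSON tree dialect mirroring the Newick content.

All genomic coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted exactly once, at this boundary.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, TextIO

import dendropy
import gffutils

from .cigar_core import parse_cigar
from .errors import (
    LinkageError,
    MalformedRecordError,
    ModelError,
    NewickParseError,
)
from .tree_homology import GeneTree, HomologyRecord, TreeNode

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "parse_gff3",
    "write_gff3",
    "parse_newick_nhx",
    "write_newick_nhx",
    "tree_to_json",
    "tree_from_json",
    "read_fasta",
    "write_fasta",
    "parse_cigar",
    "write_homology_csv",
    "read_homology_csv",
    "write_id_list",
    "HOMOLOGY_CSV_HEADER",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence, stranded."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def _check_transcription_order(ivs: list[GenomicInterval], strand: str, what: str):
    for a, b in zip(ivs, ivs[1:]):
        ok = a.end <= b.start if strand == "+" else b.end <= a.start
        if not ok:
            raise ModelError(f"{what} not in 5'->3' order / overlapping on strand {strand}")


@dataclass(frozen=True)
class TranscriptModel:
    """One mRNA: exons, CDS segments and UTRs in transcription order.

    Exons and CDS segments are stored 5'->3' — descending genomic
    coordinates on the minus strand.  The total CDS length must be a
    whole number of codons.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds_segments: tuple[GenomicInterval, ...]
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id!r} has no exons")
        strand = self.strand
        for iv in self.exons + self.cds_segments + self.utr5 + self.utr3:
            if iv.strand != strand or iv.seq_id != self.exons[0].seq_id:
                raise ModelError(
                    f"transcript {self.transcript_id!r} mixes strands or sequences"
                )
        _check_transcription_order(list(self.exons), strand, "exons")
        _check_transcription_order(list(self.cds_segments), strand, "CDS segments")
        for cds in self.cds_segments:
            n_hosts = sum(1 for ex in self.exons if ex.contains(cds))
            if n_hosts != 1:
                raise ModelError(
                    f"CDS segment [{cds.start},{cds.end}) of transcript "
                    f"{self.transcript_id!r} is not contained in exactly one exon"
                )
        if self.cds_len % 3 != 0:
            raise ModelError(
                f"CDS of transcript {self.transcript_id!r} has length "
                f"{self.cds_len}, not a multiple of 3"
            )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def cds_len(self) -> int:
        return sum(len(c) for c in self.cds_segments)

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.seq_id, lo, hi, self.strand)

    def coding_exon_indices(self) -> list[int]:
        """Indices (transcription order) of exons containing a CDS segment."""
        out = []
        for i, ex in enumerate(self.exons):
            if any(ex.contains(c) for c in self.cds_segments):
                out.append(i)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene with its canonical transcript and overall genomic extent."""

    gene_id: str
    symbol: str
    species: str
    interval: GenomicInterval
    canonical_transcript: TranscriptModel

    def __post_init__(self):
        if self.canonical_transcript.gene_id != self.gene_id:
            raise ModelError(
                f"canonical transcript of {self.gene_id!r} belongs to "
                f"{self.canonical_transcript.gene_id!r}"
            )
        for ex in self.canonical_transcript.exons:
            if not self.interval.contains(ex):
                raise ModelError(
                    f"exon [{ex.start},{ex.end}) of {self.gene_id!r} lies "
                    "outside the gene interval"
                )


# ---------------------------------------------------------------------------
# GFF3


def _attr_first(feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def parse_gff3(source: str | TextIO) -> dict[str, GeneModel]:
    """Parse GFF3 text (or a file handle) into GeneModels keyed by gene id.

    Features gene / mRNA / exon / CDS / five_prime_UTR / three_prime_UTR
    linked by ID/Parent are recognized; the canonical transcript of a
    multi-transcript gene is the mRNA with the longest total CDS (ties
    broken by smallest transcript id).  Coordinates come out 0-based
    half-open, features ordered 5'->3'.
    """
    text = source if isinstance(source, str) else source.read()
    _prevalidate_gff3(text)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # sqlite/gffutils internals vary
        raise MalformedRecordError(f"GFF3 could not be parsed: {exc}") from exc

    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise LinkageError(
                    f"feature {feat.id!r} references missing Parent {parent_id!r}"
                )

    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            transcripts.append(_build_transcript(db, gene, mrna))
        if not transcripts:
            raise ModelError(f"gene {gene.id!r} has no mRNA children")
        canonical = min(transcripts, key=lambda t: (-t.cds_len, t.transcript_id))
        strand = gene.strand if gene.strand in ("+", "-") else canonical.strand
        interval = GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            symbol=_attr_first(gene, "Name") or gene.id,
            species=_attr_first(gene, "species") or "",
            interval=interval,
            canonical_transcript=canonical,
        )
    return genes


def _prevalidate_gff3(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise MalformedRecordError(f"GFF3 line {lineno}: expected 9 columns")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise MalformedRecordError(
                f"GFF3 line {lineno}: non-numeric coordinates"
            ) from None
        if start > end:
            raise MalformedRecordError(
                f"GFF3 line {lineno}: start {start} > end {end}"
            )


def _build_transcript(db, gene, mrna) -> TranscriptModel:
    strand = mrna.strand
    reverse = strand == "-"

    def collect(ftype: str) -> list[GenomicInterval]:
        feats = list(db.children(mrna, featuretype=ftype, order_by="start"))
        ivs = [
            GenomicInterval(f.seqid, f.start - 1, f.end, strand) for f in feats
        ]
        ivs.sort(key=lambda iv: iv.start, reverse=reverse)
        return ivs

    exons = collect("exon")
    cds = collect("CDS")
    utr5 = collect("five_prime_UTR")
    utr3 = collect("three_prime_UTR")
    if not exons:
        raise ModelError(f"transcript {mrna.id!r} has no exons")
    total_cds = sum(len(c) for c in cds)
    if total_cds % 3 != 0:
        raise ModelError(
            f"transcript {mrna.id!r}: CDS length {total_cds} is not a multiple of 3"
        )
    return TranscriptModel(
        transcript_id=mrna.id,
        gene_id=gene.id,
        exons=tuple(exons),
        cds_segments=tuple(cds),
        utr5=tuple(utr5),
        utr3=tuple(utr3),
    )


def write_gff3(genes: Mapping[str, GeneModel]) -> str:
    """Serialize GeneModels back to GFF3 (canonical transcript only)."""
    lines = ["##gff-version 3"]

    def row(seq_id, ftype, iv: GenomicInterval, attrs: str, phase: str = ".") -> str:
        return "\t".join(
            [seq_id, "famviz", ftype, str(iv.start + 1), str(iv.end), ".",
             iv.strand, phase, attrs]
        )

    for gene_id in sorted(genes):
        gene = genes[gene_id]
        t = gene.canonical_transcript
        attrs = f"ID={gene.gene_id};Name={gene.symbol}"
        if gene.species:
            attrs += f";species={gene.species}"
        lines.append(row(gene.interval.seq_id, "gene", gene.interval, attrs))
        lines.append(
            row(t.seq_id, "mRNA", t.span, f"ID={t.transcript_id};Parent={gene.gene_id}")
        )
        for i, ex in enumerate(sorted(t.exons, key=lambda e: e.start), start=1):
            lines.append(
                row(t.seq_id, "exon", ex,
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}")
            )
        cds_before = 0
        phased = []
        for c in t.cds_segments:  # transcription order for phase computation
            phase = (3 - cds_before % 3) % 3
            phased.append((c, str(phase)))
            cds_before += len(c)
        for i, (c, phase) in enumerate(
            sorted(phased, key=lambda p: p[0].start), start=1
        ):
            lines.append(
                row(t.seq_id, "CDS", c,
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}", phase)
            )
        for kind, ivs in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
            for i, u in enumerate(sorted(ivs, key=lambda u: u.start), start=1):
                lines.append(
                    row(t.seq_id, kind, u,
                        f"ID={t.transcript_id}.{kind}{i};Parent={t.transcript_id}")
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick / NHX


def _parse_nhx_comment(comment: str) -> dict[str, str]:
    comment = comment.strip()
    if comment.startswith("&&NHX"):
        comment = comment[len("&&NHX"):]
    tags: dict[str, str] = {}
    for piece in comment.split(":"):
        if "=" in piece:
            key, _, value = piece.partition("=")
            tags[key] = value
    return tags


def _check_parentheses(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced parentheses", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced parentheses", offset=len(text))


def parse_newick_nhx(
    text: str, species_by_gene: Mapping[str, str] | None = None
) -> GeneTree:
    """Parse Newick with optional NHX comments into a labeled GeneTree.

    ``[&&NHX:D=Y]`` marks a duplication node; ``[&&NHX:Ev=gene_split]``
    marks a gene split; everything else is a speciation.  Leaf species
    come from the ``S`` tag or, failing that, from ``species_by_gene``.
    """
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise NewickParseError(str(exc)) from exc

    def convert(dnode) -> TreeNode:
        tags: dict[str, str] = {}
        for comment in dnode.comments or []:
            tags.update(_parse_nhx_comment(comment))
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            species = tags.get("S")
            if species is None and species_by_gene is not None:
                species = species_by_gene.get(name)
            node = TreeNode(
                event="leaf", species=species, gene_id=name,
                branch_length=dnode.edge.length,
            )
        else:
            if tags.get("D") == "Y":
                event = "duplication"
            elif tags.get("Ev") == "gene_split":
                event = "gene_split"
            else:
                event = "speciation"
            node = TreeNode(event=event, branch_length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    seen: set[str] = set()
    for leaf in root.iter_leaves():
        if leaf.gene_id in seen:
            raise NewickParseError(f"duplicate leaf name {leaf.gene_id!r}")
        seen.add(leaf.gene_id)  # type: ignore[arg-type]
    return GeneTree(root)


def _nhx_for(node: TreeNode) -> str:
    tags: list[str] = []
    if node.is_leaf:
        if node.species:
            tags.append(f"S={node.species}")
    elif node.event == "duplication":
        tags.append("D=Y")
    elif node.event == "gene_split":
        tags.append("Ev=gene_split")
    return f"[&&NHX:{':'.join(tags)}]" if tags else ""


def write_newick_nhx(tree: GeneTree) -> str:
    """Serialize a GeneTree to Newick with NHX event/species tags.

    Written by hand because the custom ``Ev`` tag falls outside what the
    standard writers emit; output re-parses to an isomorphic tree.
    """

    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.gene_id or ""
        else:
            body = "(" + ",".join(emit(c) for c in node.children) + ")"
        if node.branch_length is not None:
            body += f":{node.branch_length:.10g}"
        return body + _nhx_for(node)

    return emit(tree.root) + ";"


def tree_to_json(tree: GeneTree) -> str:
    """JSON dialect mirroring the Newick content (see README)."""

    def as_dict(node: TreeNode) -> dict:
        d: dict = {"event": node.event}
        if node.branch_length is not None:
            d["branch_length"] = node.branch_length
        if node.is_leaf:
            d["gene_id"] = node.gene_id
            if node.species:
                d["species"] = node.species
        else:
            d["children"] = [as_dict(c) for c in node.children]
        return d

    return json.dumps({"gene_tree": as_dict(tree.root)}, indent=2)


def tree_from_json(text: str) -> GeneTree:
    data = json.loads(text)["gene_tree"]

    def build(d: dict) -> TreeNode:
        node = TreeNode(
            event=d.get("event", "speciation") if d.get("children") else "leaf",
            branch_length=d.get("branch_length"),
            species=d.get("species"),
            gene_id=d.get("gene_id"),
        )
        for child in d.get("children", []):
            node.add_child(build(child))
        return node

    return GeneTree(build(data))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: str | TextIO) -> dict[str, str]:
    """Ordered mapping id -> sequence.  Aligned FASTA keeps '-' gaps."""
    from Bio import SeqIO

    handle = io.StringIO(source) if isinstance(source, str) else source
    out: dict[str, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        out[record.id] = str(record.seq)
    return out


def write_fasta(seqs: Mapping[str, str], width: int = 60) -> str:
    chunks: list[str] = []
    for name, seq in seqs.items():
        chunks.append(f">{name}")
        for i in range(0, len(seq), width):
            chunks.append(seq[i : i + width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# CSV / id list


HOMOLOGY_CSV_HEADER = [
    "guide_gene",
    "target_gene",
    "target_species",
    "homology_type",
    "coarse_type",
    "perc_id_guide",
    "perc_id_target",
    "perc_pos_guide",
    "perc_pos_target",
    "perc_cov_guide",
    "perc_cov_target",
]


def write_homology_csv(records: Iterable[HomologyRecord]) -> str:
    """RFC 4180 CSV with a fixed header; percentages to one decimal."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(HOMOLOGY_CSV_HEADER)
    for r in records:
        s = r.stats
        writer.writerow(
            [
                r.guide_gene, r.target_gene, r.target_species,
                r.homology_type, r.coarse_type,
                f"{s.perc_id_a:.1f}", f"{s.perc_id_b:.1f}",
                f"{s.perc_pos_a:.1f}", f"{s.perc_pos_b:.1f}",
                f"{s.perc_cov_a:.1f}", f"{s.perc_cov_b:.1f}",
            ]
        )
    return buf.getvalue()


def read_homology_csv(text: str) -> list[dict[str, str]]:
    return list(csv.DictReader(io.StringIO(text)))


def write_id_list(ids: Iterable[str]) -> str:
    return "\n".join(ids) + "\n"
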