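"""Synthetic gene families with full ground truth.

The simulator builds one ancestral multi-exon gene, grows a gene tree
over a set of species (speciations split the species set, duplications
copy the whole lineage), and derives each extant gene from the ancestor
by planting whole-residue insertions and deletions.  Because the MSA is
assembled *by construction* — one column per surviving ancestral residue
plus dedicated columns for every planted insertion — the gap pattern,
the per-member CIGARs, the exon structures and the event log all agree
exactly, which is what makes the rest of the package testable without
any external data.

What this emulates: gene-structure divergence (indels, exon length
changes) and gene-family histories with duplications.  What it does not:
substitution processes (member proteins are identical to the ancestor
within aligned blocks), alignment error, split or partial gene models.
Events are planted strictly inside exons and away from each other, so
every planted insertion is recoverable as one contiguous block.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ModelError
from .io_formats import (
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_fasta,
    write_gff3,
    write_newick_nhx,
)
from .synteny import SyntenyGene, SyntenyRow
from .tree_homology import GeneTree, TreeNode

__all__ = [
    "SimParams",
    "PlantedEvent",
    "GroundTruth",
    "FamilyFixture",
    "simulate_family",
    "simulate_synteny",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated family.

    Rates are expected planted events per extant gene (Poisson); indel
    lengths are whole residues, so reading frames stay valid by
    construction.  Ranges are inclusive on both ends.
    """

    n_species: int = 4
    duplication_prob: float = 0.3
    max_duplications: int = 2
    n_exons: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (60, 200)        # nt
    intron_len: tuple[int, int] = (100, 2000)    # nt
    utr_len: tuple[int, int] = (30, 120)         # nt
    insertion_rate: float = 0.8
    deletion_rate: float = 0.8
    indel_len: tuple[int, int] = (1, 6)          # residues
    neighborhood_size: int = 11                  # genes per chromosome
    loss_prob: float = 0.15                      # per-gene loss in synteny rows
    guide_clean: bool = True                     # first leaf carries no events
    seed: int = 0

    def __post_init__(self):
        for p in (self.duplication_prob, self.insertion_rate, self.deletion_rate):
            if p < 0:
                raise ModelError("rates must be non-negative")
        if not (0.0 <= self.duplication_prob <= 1.0):
            raise ModelError("duplication_prob must be a probability")
        for lo, hi in (self.n_exons, self.exon_len, self.intron_len,
                       self.indel_len, self.utr_len):
            if not (0 < lo <= hi):
                raise ModelError("ranges must be non-empty and positive")
        if self.n_species < 1:
            raise ModelError("need at least one species")


@dataclass(frozen=True)
class PlantedEvent:
    """One indel planted into one extant gene.

    ``protein_pos`` is in the *member's own* protein coordinates: for an
    insertion, the first inserted residue; for a deletion, the residue
    index before which the gap sits.  ``ancestor_pos`` is the anchor in
    ancestral residue coordinates.
    """

    gene_id: str
    kind: str                 # "insertion" | "deletion"
    protein_pos: int
    length: int
    ancestor_pos: int


@dataclass
class GroundTruth:
    events: list[PlantedEvent]
    pair_types: dict[tuple[str, str], str]   # key sorted (a, b)
    species_of: dict[str, str]
    guide_gene: str

    def events_of(self, gene_id: str, kind: str | None = None) -> list[PlantedEvent]:
        return [
            e for e in self.events
            if e.gene_id == gene_id and (kind is None or e.kind == kind)
        ]

    def pair_type(self, a: str, b: str) -> str:
        return self.pair_types[tuple(sorted((a, b)))]

    def to_json(self) -> str:
        return json.dumps(
            {
                "guide_gene": self.guide_gene,
                "species_of": self.species_of,
                "events": [
                    {"gene_id": e.gene_id, "kind": e.kind,
                     "protein_pos": e.protein_pos, "length": e.length,
                     "ancestor_pos": e.ancestor_pos}
                    for e in self.events
                ],
                "pair_types": {
                    f"{a}|{b}": t for (a, b), t in sorted(self.pair_types.items())
                },
            },
            indent=2,
        )


@dataclass
class FamilyFixture:
    """Everything one family needs: file texts plus the in-memory truth."""

    gff3: str
    msa_fasta: str
    newick: str
    truth: GroundTruth
    genes: dict[str, GeneModel]
    msa_rows: dict[str, str]
    tree: GeneTree


# ---------------------------------------------------------------------------
# tree growth


def _species_names(n: int) -> list[str]:
    # spA, spB, ... spZ, spAA ...
    names = []
    for i in range(n):
        label = ""
        k = i
        while True:
            label = string.ascii_uppercase[k % 26] + label
            k = k // 26 - 1
            if k < 0:
                break
        names.append("sp" + label)
    return names


def _grow_tree(params: SimParams, rng: np.random.Generator) -> TreeNode:
    counter = {s: 0 for s in _species_names(params.n_species)}
    budget = [params.max_duplications]

    def grow(species: list[str]) -> TreeNode:
        if (
            budget[0] > 0
            and rng.random() < params.duplication_prob
        ):
            budget[0] -= 1
            node = TreeNode(event="duplication", branch_length=1.0)
            node.add_child(grow(species))
            node.add_child(grow(species))
            return node
        if len(species) == 1:
            sp = species[0]
            counter[sp] += 1
            return TreeNode(
                event="leaf", species=sp,
                gene_id=f"{sp}_g{counter[sp]}", branch_length=1.0,
            )
        cut = int(rng.integers(1, len(species)))
        node = TreeNode(event="speciation", branch_length=1.0)
        node.add_child(grow(species[:cut]))
        node.add_child(grow(species[cut:]))
        return node

    root = grow(_species_names(params.n_species))
    if root.is_leaf:  # single-species, no duplication: wrap is unnecessary
        return root
    return root


def _truth_pair_types(root: TreeNode) -> dict[tuple[str, str], str]:
    """Pair types read off the construction events, bottom-up.

    For every internal node the species copy-counts of each child subtree
    are tallied while merging; a pair joining at a duplication node is a
    paralog, a pair joining at a speciation node is typed by the two
    copy-counts.  Independent bookkeeping from ``classify_pair`` (which
    walks leaf paths on the parsed tree).
    """
    out: dict[tuple[str, str], str] = {}

    def walk(node: TreeNode) -> list[tuple[str, str]]:
        if node.is_leaf:
            return [(node.gene_id, node.species)]  # type: ignore[list-item]
        sides = [walk(c) for c in node.children]
        for i in range(len(sides)):
            for j in range(i + 1, len(sides)):
                for gene_a, sp_a in sides[i]:
                    for gene_b, sp_b in sides[j]:
                        key = tuple(sorted((gene_a, gene_b)))
                        if sp_a == sp_b:
                            out[key] = "within_species_paralog"
                        elif node.event == "duplication":
                            out[key] = "between_species_paralog"
                        else:
                            n_a = sum(1 for _, s in sides[i] if s == sp_a)
                            n_b = sum(1 for _, s in sides[j] if s == sp_b)
                            if n_a == 1 and n_b == 1:
                                out[key] = "ortholog_one2one"
                            elif n_a == 1 or n_b == 1:
                                out[key] = "ortholog_one2many"
                            else:
                                out[key] = "ortholog_many2many"
        return [g for side in sides for g in side]

    walk(root)
    return out


# ---------------------------------------------------------------------------
# ancestor + member construction


def _draw_ancestor(params: SimParams, rng: np.random.Generator):
    n_exons = int(rng.integers(params.n_exons[0], params.n_exons[1] + 1))
    lens = [
        int(rng.integers(params.exon_len[0], params.exon_len[1] + 1))
        for _ in range(n_exons)
    ]
    excess = sum(lens) % 3
    if excess:
        if lens[-1] - excess < 1:
            lens[-1] += 3 - excess
        else:
            lens[-1] -= excess
    protein = "".join(rng.choice(list(AMINO_ACIDS), size=sum(lens) // 3))
    boundaries = [0]
    for ln in lens:
        boundaries.append(boundaries[-1] + ln)
    return protein, boundaries  # CDS-nt exon boundaries of the ancestor


@dataclass
class _MemberEvents:
    deletions: list[tuple[int, int]] = field(default_factory=list)  # residue [d0,d1)
    insertions: list[tuple[int, int]] = field(default_factory=list)  # (anchor, len)


def _sample_events(
    L: int, boundaries: list[int], params: SimParams, rng: np.random.Generator
) -> _MemberEvents:
    ev = _MemberEvents()
    n_del = int(rng.poisson(params.deletion_rate))
    tries = 0
    while len(ev.deletions) < n_del and tries < 200:
        tries += 1
        length = int(rng.integers(params.indel_len[0], params.indel_len[1] + 1))
        if length >= L:
            continue
        d0 = int(rng.integers(0, L - length + 1))
        d1 = d0 + length
        if any(d0 <= e1 and s1 <= d1 for s1, e1 in ev.deletions):
            continue
        if sum(e - s for s, e in ev.deletions) + length > L // 2:
            continue
        ev.deletions.append((d0, d1))
    ev.deletions.sort()

    def f_del(nt: int) -> int:  # member-nt of an ancestor-nt boundary, deletions only
        removed = sum(
            max(0, min(nt, 3 * e) - 3 * s) for s, e in ev.deletions
        )
        return nt - removed

    member_bounds = sorted({f_del(b) for b in boundaries})
    n_ins = int(rng.poisson(params.insertion_rate))
    tries = 0
    while len(ev.insertions) < n_ins and tries < 200:
        tries += 1
        length = int(rng.integers(params.indel_len[0], params.indel_len[1] + 1))
        p = int(rng.integers(0, L + 1))
        # keep anchors clear of deletions (closed) and other anchors
        if any(s <= p <= e for s, e in ev.deletions):
            continue
        if any(p == q for q, _ in ev.insertions):
            continue
        m = f_del(3 * p)
        # strictly inside a member exon so the insertion stays one block
        inside = any(a < m < b for a, b in zip(member_bounds, member_bounds[1:]))
        if not inside:
            continue
        ev.insertions.append((p, length))
    ev.insertions.sort()
    return ev


def _member_protein(
    ancestor: str, ev: _MemberEvents, rng: np.random.Generator
) -> str:
    deleted = set()
    for s, e in ev.deletions:
        deleted.update(range(s, e))
    ins_at: dict[int, str] = {
        p: "".join(rng.choice(list(AMINO_ACIDS), size=ln)) for p, ln in ev.insertions
    }
    out: list[str] = []
    for p in range(len(ancestor) + 1):
        if p in ins_at:
            out.append(ins_at[p])
        if p < len(ancestor) and p not in deleted:
            out.append(ancestor[p])
    return "".join(out)


def _member_exon_bounds(boundaries: list[int], ev: _MemberEvents) -> list[int]:
    """Ancestor CDS-nt exon boundaries mapped through this member's indels."""

    def f(nt: int) -> int:
        removed = sum(max(0, min(nt, 3 * e) - 3 * s) for s, e in ev.deletions)
        added = sum(3 * ln for p, ln in ev.insertions if 3 * p < nt)
        return nt - removed + added

    out = [f(b) for b in boundaries]
    # drop exons deleted away entirely
    dedup = [out[0]]
    for b in out[1:]:
        if b > dedup[-1]:
            dedup.append(b)
    return dedup


def _place_gene(
    gene_id: str,
    species: str,
    exon_bounds: list[int],
    params: SimParams,
    rng: np.random.Generator,
    seq_id: Optional[str] = None,
    offset: Optional[int] = None,
) -> GeneModel:
    """Lay the member's exons on a chromosome with introns and UTRs."""
    strand = "+" if rng.random() < 0.5 else "-"
    seq_id = seq_id or f"{species}_chr1"
    start0 = int(rng.integers(10_000, 50_000)) if offset is None else offset
    u5 = int(rng.integers(params.utr_len[0], params.utr_len[1] + 1))
    u3 = int(rng.integers(params.utr_len[0], params.utr_len[1] + 1))
    exon_lens = [b - a for a, b in zip(exon_bounds, exon_bounds[1:])]
    introns = [
        int(rng.integers(params.intron_len[0], params.intron_len[1] + 1))
        for _ in exon_lens[1:]
    ]
    # transcription-coordinate feature spans
    tau = 0
    exons_t: list[tuple[int, int]] = []
    cds_t: list[tuple[int, int]] = []
    utr5_t = (0, u5)
    tau = u5
    for i, ln in enumerate(exon_lens):
        ex_start = tau if i > 0 else 0          # first exon swallows the 5' UTR
        cds_t.append((tau, tau + ln))
        tau += ln
        ex_end = tau if i < len(exon_lens) - 1 else tau + u3  # last swallows 3' UTR
        exons_t.append((ex_start, ex_end))
        if i < len(introns):
            tau += introns[i]
    utr3_t = (tau, tau + u3)
    gene_len = tau + u3

    def to_genomic(a: int, b: int) -> GenomicInterval:
        if strand == "+":
            return GenomicInterval(seq_id, start0 + a, start0 + b, strand)
        return GenomicInterval(seq_id, start0 + gene_len - b, start0 + gene_len - a, strand)

    transcript = TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        exons=tuple(to_genomic(a, b) for a, b in exons_t),
        cds_segments=tuple(to_genomic(a, b) for a, b in cds_t),
        utr5=(to_genomic(*utr5_t),),
        utr3=(to_genomic(*utr3_t),),
    )
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id,
        species=species,
        interval=GenomicInterval(seq_id, start0, start0 + gene_len, strand),
        canonical_transcript=transcript,
    )


def _build_msa(
    ancestor_len: int, order: list[str], events: dict[str, _MemberEvents],
    proteins: dict[str, str],
) -> dict[str, str]:
    """Column layout: for each ancestor position p, first every member's
    insertion anchored at p (member order), then the ancestor column p."""
    rows = {g: [] for g in order}
    cursor = {g: 0 for g in order}

    def emit_member_residues(gene: str, count: int):
        for g in order:
            if g == gene:
                seq = proteins[g]
                rows[g].append(seq[cursor[g] : cursor[g] + count])
                cursor[g] += count
            else:
                rows[g].append("-" * count)

    deleted = {
        g: {p for s, e in ev.deletions for p in range(s, e)}
        for g, ev in events.items()
    }
    ins_index = {
        g: dict(ev.insertions) for g, ev in events.items()
    }
    for p in range(ancestor_len + 1):
        for g in order:
            ln = ins_index[g].get(p)
            if ln:
                emit_member_residues(g, ln)
        if p < ancestor_len:
            for g in order:
                if p in deleted[g]:
                    rows[g].append("-")
                else:
                    seq = proteins[g]
                    rows[g].append(seq[cursor[g]])
                    cursor[g] += 1
    for g in order:
        assert cursor[g] == len(proteins[g])
    return {g: "".join(parts) for g, parts in rows.items()}


def simulate_family(params: SimParams) -> FamilyFixture:
    """One internally consistent family: GFF3 + MSA + NHX + ground truth."""
    rng = np.random.default_rng(params.seed)
    root = _grow_tree(params, rng)
    tree = GeneTree(root)
    order = [leaf.gene_id for leaf in root.iter_leaves()]
    species_of = {leaf.gene_id: leaf.species for leaf in root.iter_leaves()}

    ancestor, boundaries = _draw_ancestor(params, rng)
    L = len(ancestor)

    events: dict[str, _MemberEvents] = {}
    for i, gene_id in enumerate(order):
        if params.guide_clean and i == 0:
            events[gene_id] = _MemberEvents()
        else:
            events[gene_id] = _sample_events(L, boundaries, params, rng)

    proteins = {g: _member_protein(ancestor, events[g], rng) for g in order}
    msa_rows = _build_msa(L, order, events, proteins)

    genes: dict[str, GeneModel] = {}
    for gene_id in order:
        bounds = _member_exon_bounds(boundaries, events[gene_id])
        genes[gene_id] = _place_gene(
            gene_id, species_of[gene_id] or "", bounds, params, rng
        )

    planted: list[PlantedEvent] = []
    for gene_id in order:
        ev = events[gene_id]
        deleted_before = lambda p: sum(
            min(p, e) - s for s, e in ev.deletions if s < p
        )
        ins_before = lambda p, strict: sum(
            ln for q, ln in ev.insertions if (q < p if strict else q <= p)
        )
        for p, ln in ev.insertions:
            planted.append(
                PlantedEvent(
                    gene_id=gene_id, kind="insertion",
                    protein_pos=p - deleted_before(p) + ins_before(p, True),
                    length=ln, ancestor_pos=p,
                )
            )
        for d0, d1 in ev.deletions:
            planted.append(
                PlantedEvent(
                    gene_id=gene_id, kind="deletion",
                    protein_pos=d0 - deleted_before(d0) + ins_before(d0, True),
                    length=d1 - d0, ancestor_pos=d0,
                )
            )

    truth = GroundTruth(
        events=planted,
        pair_types=_truth_pair_types(root),
        species_of={g: s or "" for g, s in species_of.items()},
        guide_gene=order[0],
    )
    return FamilyFixture(
        gff3=write_gff3(genes),
        msa_fasta=write_fasta(msa_rows),
        newick=write_newick_nhx(tree),
        truth=truth,
        genes=genes,
        msa_rows=msa_rows,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# synteny fixtures


def simulate_synteny(
    params: SimParams,
) -> tuple[list[SyntenyRow], list[tuple[str, str]], dict[str, int]]:
    """A conserved block across species with optional per-species losses.

    Returns ``(rows, homology_pairs, ancestral_index_of_gene)``; the
    focal column (block middle) is never lost.  Cross-species genes with
    the same ancestral index are homologues.
    """
    rng = np.random.default_rng(params.seed + 1)
    n = params.neighborhood_size
    focal_idx = n // 2
    species = _species_names(params.n_species)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    rows: list[SyntenyRow] = []
    pairs: list[tuple[str, str]] = []
    index_of: dict[str, int] = {}
    by_index: dict[int, list[str]] = {i: [] for i in range(n)}
    for sp in species:
        kept = [
            i for i in range(n)
            if i == focal_idx or rng.random() >= params.loss_prob
        ]
        genes = []
        pos = int(rng.integers(5_000, 20_000))
        for i in kept:
            gene_id = f"{sp}_n{i}"
            length = int(rng.integers(2_000, 12_000))
            iv = GenomicInterval(f"{sp}_chr2", pos, pos + length, strands[i])
            genes.append(
                SyntenyGene(gene_id, iv, strands[i], focal_flag=i == focal_idx)
            )
            index_of[gene_id] = i
            by_index[i].append(gene_id)
            pos += length + int(rng.integers(1_000, 8_000))
        rows.append(SyntenyRow(species=sp, seq_id=f"{sp}_chr2", genes=tuple(genes)))
    for members in by_index.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return rows, pairs, index_of
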