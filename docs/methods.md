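# Methods

## The problem

A gene family is a set of homologous genes across (and within) species,
related by a gene tree whose internal nodes are speciation, duplication or
gene-split events.  Comparative annotation pipelines store, for each family,
a protein multiple sequence alignment together with a per-member run-length
encoding of each row — a protein-space CIGAR string in which `M` means "this
member contributes a residue to the column" and `D` means "gap".  famviz
takes those three artifacts (gene models in GFF3, the family MSA or the
CIGARs plus unaligned proteins, the event-labeled tree in Newick/NHX) and
answers the questions a homology browser answers: *where* on each
homologue's exon/intron structure does it match a chosen guide gene, what
is inserted or deleted relative to the guide, what kind of homologue is
each member, and what does the conserved neighborhood look like — all as
deterministic, restylable SVG plus CSV/Newick/JSON exports.

## Column classification and pair statistics

For a guide/target pair sharing one alignment, every column falls into one
of four classes by the (guide, target) op pair: `(M,M)` BOTH, `(D,M)`
INSERTION (target-only residue), `(M,D)` DELETION (guide-only residue),
`(D,D)` NEITHER (column owed to a third family member).  The
classification is computed directly on the run-length encodings in
O(runs), and is checked in the tests against an oracle that expands both
CIGARs to column strings and compares elementwise.

Pair statistics follow the convention of comparative-genomics homology
tables: over BOTH columns, count identical residue pairs (n_id), pairs
with a positive substitution score (n_pos; BLOSUM62 by default, any
NCBI-format matrix can be injected), and all aligned pairs (n_cov); each
count is reported as a percentage of *each member's own* sequence length,
so identity/positivity/coverage come in two directions and obey
id ≤ pos ≤ cov ≤ 100 per member.  NEITHER columns contribute to nothing.

## Coordinate mapping

All genomic coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly once at parse time.  A transcript's coding
sequence is laid out on a CDS axis `[0, cds_len)` in transcription order
(descending genomic coordinates on the minus strand), one piece per coding
exon.  Residue *i* occupies CDS nucleotides `[3i, 3i+3)`; projecting a
residue range to the genome intersects the nucleotide range with the
pieces, so a codon split by an intron yields both genomic fragments, and
the total projected length is always exactly 3 nt per residue.

A split codon needs an owner exon for coloring: it belongs to the exon
holding at least two of its three bases.  With two-exon splits a tie is
impossible; the degenerate case of a ≤1 nt exon is outside the supported
model space.

Boundary *points* (used for deletion marks) sit at the 5' edge of the
following base: on the plus strand the boundary before base g is g, on the
minus strand it is g+1.  This is the only place where strand affects a
point rather than an interval.

## Comparison tracks

The drawable comparison of a target against the guide is assembled from
the column classes, after removing NEITHER columns and re-merging runs
(legitimate because those columns exist in neither member; it also makes
insertion/deletion roles exactly complementary under guide/target swap):

* each BOTH run is split wherever its guide residues change owner exon;
  every resulting chunk is projected onto the target's genome as MATCH
  segments carrying the guide exon's color index.  A single target exon
  aligned across two adjacent guide exons therefore renders as two
  fragments with consecutive colors — the visual cue for suspected gene
  splits or mis-annotation;
* INSERTION runs project to black bars inside the target's exons;
* each DELETION run collapses to a zero-width red mark at the boundary
  before the next aligned target residue (the first CDS base when the gap
  is at the extreme 5' end — a convention, documented here because the
  display itself cannot distinguish the choices);
* UTRs (gray end blocks) and introns are emitted explicitly so renderers
  never re-derive gene structure.

Conservation invariants: total MATCH length is 3× the BOTH column count
and total INSERTION length 3× the INSERTION column count, for every pair.

## Layout and rendering

Two modes mirror a browser's intron setting.  *Exon-focused* (default)
draws every intron at a fixed width (6 px) and exon widths proportional
to nucleotide length under one per-view scale chosen so the widest row
exactly fits the canvas (1200 px).  *Proportional* uses a single global
nt→px scale with the longest gene spanning exactly the canvas.  Row
height is 24 px; the 12-color palette is cycled by `color_index mod 12`.
Tree x-positions are cladogram-style by default (a phylogram flag uses
branch lengths); node circles are colored by event — speciation blue,
duplication red, gene split cyan — and the guide leaf is a larger black
circle with a red label.  Rendering uses fixed float formatting, no
timestamps and no randomness, so identical inputs give byte-identical
SVG; all styling goes through class attributes and one embedded
stylesheet.  The pairwise view adds connector polygons between
corresponding match chunks and a wrapped text alignment (60 columns per
block; `|` marks identical residues).

## Homology typing

Same-species pairs are within-species paralogs.  Cross-species pairs
under a duplication ancestor are reported with the explicit type
`between_species_paralog` rather than being folded into a generic bucket;
the CSV additionally carries a coarse ortholog/paralog column for
three-bucket filtering.  Cross-species pairs under a speciation ancestor
are typed by the copy number of each species within its side of the
ancestor: (1,1) one2one, exactly one side >1 one2many, both many2many.
Gene-split nodes are treated as speciation for typing (their effect on
homology semantics is genuinely underdetermined; they keep their own
node color in the views).

## Synteny view

Each row is the up-to-k-neighbors window around one homologue (default
k=10).  Reference-row genes are colored sequentially; a gene in another
row inherits the color of its homologue in the reference row only if that
homologue is inside the visible window, otherwise it stays white.
Coloring goes through the reference row only — never transitively — so it
is stable under permutation of the other rows.  The focal gene of every
row carries a red border.

## The simulator

`synthetic.simulate_family` builds one ancestral gene (3–6 exons of
60–200 nt, total CDS forced to a codon multiple, introns 100–2000 nt,
UTRs 30–120 nt), grows a gene tree over 4 species (speciations split the
species set; duplications copy the lineage, probability 0.3 per node with
at most two per family), and derives each extant gene by planting
whole-residue indels (Poisson, 0.8 expected insertions and deletions per
gene, lengths 1–6 residues).  The MSA is assembled by construction — one
column per surviving ancestral residue plus dedicated columns per planted
insertion — so gap patterns, CIGARs, exon structures and the event log
agree exactly.  The first leaf is kept event-free and is the default
guide, making every planted event guide-relative by construction.
Insertions are anchored strictly inside exons and all events are mutually
separated by at least one surviving residue, so each planted event is
recoverable as exactly one block/mark.  Everything is driven by one
`numpy` generator seed; the same seed reproduces byte-identical fixtures.

What the simulator does *not* emulate: substitution processes (aligned
residues are identical to the ancestor, so identity percentages on
simulated data are high and the statistics code is instead validated
against per-column oracles on random sequences), alignment error,
alternative transcripts, trans-splicing, and fragmented gene models.
Passing tests therefore demonstrate correctness of the projection,
typing, statistics and rendering machinery — not robustness to noisy
real-world annotation.

`simulate_synteny` emits a conserved block of 11 genes across the same
species with 15% per-gene loss (the focal middle gene is never lost),
plus the homology pairing that defines ground-truth colors.

## Numerical and degenerate-input choices

* Canonical transcript of a multi-mRNA gene: longest total CDS, ties by
  lexicographically smallest transcript id.
* CIGAR alphabet is strictly {M, D}; SAM-style ops (I/N/S/X) are rejected
  loudly rather than reinterpreted.
* Percentages are kept at full precision internally and written with one
  decimal in CSV.
* Empty tracks lay out to empty shape lists; a gene tree with a single
  leaf yields an empty homology table; `k = 0` synteny windows contain
  only the focal gene.
* Exact float equality is asserted only where the arithmetic is exact
  (pixel ratios of integer nucleotide lengths under one shared scale);
  everything else uses 1e-9 tolerances.

## Known limitations

One transcript per gene is drawn (the canonical one); nucleotide-level
mismatches inside MATCH blocks are not displayed; reconciliation,
alignment and tree inference are upstream concerns; the JSON tree dialect
is a plain nested mirror of the Newick content, not a general
interchange schema.
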