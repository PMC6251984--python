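# famviz

Gene-family homology browsing as a file-based library and CLI.

Comparative annotation pipelines precompute, for every gene family, a
protein multiple sequence alignment (stored per member as a protein-space
CIGAR string: `M` = residue in the column, `D` = gap), an event-labeled
gene tree, and per-species gene models.  famviz turns those three inputs
into the views a homology browser shows:

* **gene-tree view** — the family tree on the left, one exon/intron
  structure per gene on the right, every homologue aligned against a
  chosen *guide* gene: matching regions colored by guide exon, black bars
  for insertions, red lines for deletions, gray UTR blocks, strand arrows;
* **pairwise view** — two gene structures joined by per-exon connector
  polygons, above the wrapped textual alignment;
* **homologue table** — one CSV row per guide/target pair with the
  homology type and bidirectional identity / positivity / coverage;
* **gene-order view** — the conserved neighborhood around each homologue,
  colored by homology to the reference row (white = no homologue visible).

The machinery underneath: run-length CIGAR algebra (column classes BOTH /
INSERTION / DELETION / NEITHER for target vs guide), strand-aware mapping
between protein residues, CDS nucleotides and genomic intervals, homology
typing from the tree (one2one / one2many / many2many orthologs,
within- and between-species paralogs by copy counts under the pair's
last common ancestor), and a simulator that generates fully consistent
families with a ground-truth event log so everything is testable offline.

Statistics follow the homology-table convention: over columns where both
members have a residue, n_id (identical), n_pos (substitution score > 0,
BLOSUM62 by default) and n_cov (all aligned) are each reported as
percentages of *each member's own* length, so
`perc_id ≤ perc_pos ≤ perc_cov` per member.

## Worked example

Simulate a family and browse it (every subcommand also accepts real GFF3
+ aligned FASTA + NHX files):

```sh
famviz simulate --seed 11 --out-dir demo
famviz homologs --gff3 demo/family.gff3 --msa demo/family_msa.fasta \
                --tree demo/family.nhx --guide spA_g1
```

prints (abridged):

```
guide_gene,target_gene,target_species,homology_type,coarse_type,perc_id_guide,perc_id_target,...
spA_g1,spB_g1,spB,ortholog_one2one,ortholog,94.3,99.4,...
spA_g1,spA_g2,spA,within_species_paralog,paralog,96.0,100.0,...
spA_g1,spB_g2,spB,between_species_paralog,paralog,100.0,100.0,...
spA_g1,spC_g1,spC,ortholog_one2many,ortholog,100.0,97.8,...
```

Read: `spB_g1` is the one-to-one ortholog of the guide; it aligns over
94.3% of the guide's residues (the guide is longer, so the reverse
coverage is 99.4%); `spA_g2` is a within-species paralog created by the
duplication node that the tree (`demo/family.nhx`) tags with `D=Y`;
`spC_g1` is a one-to-many ortholog because species C kept two copies
under the speciation ancestor.  Identity equals coverage here because
the simulator plants structural events, not substitutions.

```sh
famviz view --gff3 demo/family.gff3 --msa demo/family_msa.fasta \
            --tree demo/family.nhx --guide spA_g1 --mode exon_focused \
            --out demo/tree.svg
```

writes a deterministic SVG (`--mode proportional` switches introns from
fixed 6 px to true scale); for seed 11 it contains 84 exon-colored match
fragments across the 10 family members.  `famviz pairwise`, `famviz
synteny` and `famviz export` produce the 1-to-1 view, the gene-order view
and Newick/JSON/id exports; `--type`/`--species` filter the table the way
a browser's tabular filter does.

Filtering example — keep only the strict orthologs:

```sh
famviz homologs ... --guide spA_g1 --type ortholog_one2one
```

## Library use

```python
from famviz import (SimParams, simulate_family, parse_gff3, parse_newick_nhx,
                    cigars_from_msa, build_comparison_track, render_genetree_svg)

fx = simulate_family(SimParams(seed=11))
genes = parse_gff3(fx.gff3)
tree = parse_newick_nhx(fx.newick, {g: m.species for g, m in genes.items()})
cigars, seqs = cigars_from_msa(fx.msa_rows)
guide = fx.truth.guide_gene
tracks = {g: build_comparison_track(genes[guide], cigars[guide], genes[g], cigars[g])
          for g in genes}
svg = render_genetree_svg(tree, tracks)
```

See `docs/methods.md` for the model, conventions (coordinate systems,
codon ownership, deletion-mark placement) and simulator details.

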