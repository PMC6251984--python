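"""Comparison tracks: match coloring, insertions, deletion marks."""

import pytest

from famviz.cigar_core import ColumnClass, cigars_from_msa, classify_columns
from famviz.comparison import (
    SegmentKind,
    build_comparison_track,
    guide_exon_palette,
    track_to_bed,
)
from famviz.errors import ModelError
from famviz.gene_models import build_cds_map, protein_to_genomic, cds_boundary_to_genomic
from famviz.io_formats import parse_gff3
from famviz.synthetic import SimParams, simulate_family

from conftest import make_gene, make_transcript


def family_tracks(fx):
    genes = parse_gff3(fx.gff3)
    cigars, _ = cigars_from_msa(fx.msa_rows)
    guide = fx.truth.guide_gene
    return genes, cigars, guide, {
        g: build_comparison_track(genes[guide], cigars[guide], genes[g], cigars[g])
        for g in genes
    }


class TestPalette:
    def test_indices_enumerate_coding_exons(self):
        t = make_transcript([(0, 30), (60, 90), (120, 150)],
                            [(0, 30), (60, 90), (120, 150)])
        assert guide_exon_palette(make_gene(t)) == [0, 1, 2]

    def test_single_exon(self):
        t = make_transcript([(0, 30)], [(0, 30)])
        assert guide_exon_palette(make_gene(t)) == [0]

    def test_noncoding_transcript_rejected(self):
        t = make_transcript([(0, 30)], [])
        with pytest.raises(ModelError):
            guide_exon_palette(make_gene(t))


class TestSelfTrack:
    def test_self_comparison_identity(self):
        # codon-aligned exon boundaries: MATCH segments == coding exons
        t = make_transcript([(0, 30), (60, 90)], [(0, 30), (60, 90)])
        gene = make_gene(t)
        cigars, _ = cigars_from_msa({"g1": "M" * 20})
        track = build_comparison_track(gene, cigars["g1"], gene, cigars["g1"])
        matches = track.segments_of_kind(SegmentKind.MATCH)
        assert [(m.interval.start, m.interval.end) for m in matches] == [(0, 30), (60, 90)]
        assert [m.color_index for m in matches] == [0, 1]
        assert not track.segments_of_kind(SegmentKind.INSERTION)
        assert not track.deletion_marks
        assert track.guide_flag

    def test_self_track_clean_for_simulated_genes(self, family):
        genes = parse_gff3(family.gff3)
        cigars, _ = cigars_from_msa(family.msa_rows)
        for g, gene in genes.items():
            track = build_comparison_track(gene, cigars[g], gene, cigars[g])
            assert not track.segments_of_kind(SegmentKind.INSERTION)
            assert not track.deletion_marks
            assert track.total_length(SegmentKind.MATCH) == 3 * cigars[g].n_residues


class TestPlantedEvents:
    def test_planted_insertions_recovered(self):
        for seed in range(10):
            fx = simulate_family(SimParams(seed=seed, insertion_rate=1.5))
            genes, cigars, guide, tracks = family_tracks(fx)
            for g, track in tracks.items():
                truth = fx.truth.events_of(g, "insertion")
                segs = track.segments_of_kind(SegmentKind.INSERTION)
                assert len(segs) == len(truth)
                cmap = build_cds_map(genes[g].canonical_transcript)
                for ev in truth:
                    ivs = protein_to_genomic(
                        cmap, ev.protein_pos, ev.protein_pos + ev.length
                    )
                    assert len(ivs) == 1  # planted strictly inside one exon
                    assert len(ivs[0]) == 3 * ev.length
                    assert any(s.interval == ivs[0] for s in segs)

    def test_planted_deletions_recovered(self):
        for seed in range(10):
            fx = simulate_family(SimParams(seed=seed, deletion_rate=1.5))
            genes, cigars, guide, tracks = family_tracks(fx)
            for g, track in tracks.items():
                truth = fx.truth.events_of(g, "deletion")
                assert len(track.deletion_marks) == len(truth)
                cmap = build_cds_map(genes[g].canonical_transcript)
                for ev in truth:
                    want = cds_boundary_to_genomic(cmap, 3 * ev.protein_pos)
                    assert want in track.deletion_marks

    def test_removing_the_event_removes_the_segment(self):
        with_events = simulate_family(SimParams(seed=4))
        without = simulate_family(
            SimParams(seed=4, insertion_rate=0.0, deletion_rate=0.0)
        )
        _, _, _, tracks_with = family_tracks(with_events)
        _, _, _, tracks_without = family_tracks(without)
        n_ins_with = sum(
            len(t.segments_of_kind(SegmentKind.INSERTION))
            for t in tracks_with.values()
        )
        assert n_ins_with == len(
            [e for e in with_events.truth.events if e.kind == "insertion"]
        )
        for t in tracks_without.values():
            assert not t.segments_of_kind(SegmentKind.INSERTION)
            assert not t.deletion_marks


class TestSplitMatching:
    def test_target_exon_spanning_two_guide_exons_splits_in_two(self):
        """One target exon aligned across two adjacent guide exons must
        render as two MATCH fragments with consecutive color indices."""
        guide_t = make_transcript(
            [(0, 30), (100, 130)], [(0, 30), (100, 130)],
            transcript_id="tg", gene_id="guide",
        )
        target_t = make_transcript(
            [(500, 560)], [(500, 560)], transcript_id="tt", gene_id="target",
        )
        cigars, _ = cigars_from_msa({"guide": "M" * 20, "target": "M" * 20})
        track = build_comparison_track(
            make_gene(guide_t, "guide"), cigars["guide"],
            make_gene(target_t, "target"), cigars["target"],
        )
        matches = track.segments_of_kind(SegmentKind.MATCH)
        assert len(matches) == 2
        assert [m.color_index for m in matches] == [0, 1]
        assert [(m.interval.start, m.interval.end) for m in matches] == [
            (500, 530), (530, 560),
        ]


class TestInvariants:
    def test_conservation_of_column_counts(self):
        for seed in range(8):
            fx = simulate_family(SimParams(seed=seed))
            genes, cigars, guide, tracks = family_tracks(fx)
            for g, track in tracks.items():
                counts = classify_columns(cigars[guide], cigars[g]).counts()
                assert track.total_length(SegmentKind.MATCH) == 3 * counts[ColumnClass.BOTH]
                assert track.total_length(SegmentKind.INSERTION) == (
                    3 * counts[ColumnClass.INSERTION]
                )

    def test_swap_complementarity(self):
        for seed in range(8):
            fx = simulate_family(SimParams(seed=seed, guide_clean=False))
            genes = parse_gff3(fx.gff3)
            cigars, _ = cigars_from_msa(fx.msa_rows)
            ids = list(genes)
            a, b = ids[0], ids[1]
            fwd = build_comparison_track(genes[a], cigars[a], genes[b], cigars[b])
            rev = build_comparison_track(genes[b], cigars[b], genes[a], cigars[a])
            # insertion runs of b vs a == deletion marks of a vs b
            assert len(_insertion_runs(cigars[a], cigars[b])) == len(rev.deletion_marks)
            assert len(_insertion_runs(cigars[b], cigars[a])) == len(fwd.deletion_marks)

    def test_segments_non_overlapping(self, family):
        _, _, _, tracks = family_tracks(family)
        for track in tracks.values():
            ivs = sorted(
                (s.interval.start, s.interval.end) for s in track.segments
            )
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


def _insertion_runs(guide_cigar, target_cigar):
    """Maximal INSERTION runs, NEITHER-transparent (mirrors mark merging)."""
    runs = []
    prev = None
    for count, cls in classify_columns(guide_cigar, target_cigar).runs:
        if cls is ColumnClass.NEITHER:
            continue
        if cls is ColumnClass.INSERTION and prev is not ColumnClass.INSERTION:
            runs.append(count)
        prev = cls
    return runs


def test_bed_export_shape(family):
    _, _, _, tracks = family_tracks(family)
    track = next(iter(tracks.values()))
    lines = track_to_bed(track).strip().splitlines()
    assert lines[0].startswith("#seq_id")
    n_del = sum(1 for l in lines[1:] if l.split("\t")[3] == "DELETION")
    assert n_del == len(track.deletion_marks)
    assert len(lines) - 1 == len(track.segments) + n_del
    for line in lines[1:]:
        cols = line.split("\t")
        assert len(cols) == 6
        assert int(cols[1]) <= int(cols[2])
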