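import pytest

from famviz.io_formats import GenomicInterval, TranscriptModel, GeneModel
from famviz.synthetic import SimParams, simulate_family


def make_transcript(
    exon_spans,
    cds_spans,
    strand="+",
    seq_id="chr1",
    transcript_id="t1",
    gene_id="g1",
    utr5=(),
    utr3=(),
):
    """Build a TranscriptModel from plain (start, end) genomic spans.

    Spans are given in genomic order; this helper flips them into
    transcription order for the minus strand.
    """

    def ivs(spans):
        out = [GenomicInterval(seq_id, a, b, strand) for a, b in spans]
        out.sort(key=lambda iv: iv.start, reverse=strand == "-")
        return tuple(out)

    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        exons=ivs(exon_spans),
        cds_segments=ivs(cds_spans),
        utr5=ivs(utr5),
        utr3=ivs(utr3),
    )


def make_gene(transcript, gene_id=None, species="spA"):
    span = transcript.span
    lo = min(e.start for e in transcript.exons)
    hi = max(e.end for e in transcript.exons)
    return GeneModel(
        gene_id=gene_id or transcript.gene_id,
        symbol=gene_id or transcript.gene_id,
        species=species,
        interval=GenomicInterval(span.seq_id, lo, hi, span.strand),
        canonical_transcript=transcript,
    )


@pytest.fixture(scope="session")
def family():
    """One mid-sized simulated family reused by read-only tests."""
    return simulate_family(SimParams(seed=11))


@pytest.fixture(scope="session")
def quiet_family():
    """A family without any planted indels: every track is all-MATCH."""
    return simulate_family(SimParams(seed=5, insertion_rate=0.0, deletion_rate=0.0))
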