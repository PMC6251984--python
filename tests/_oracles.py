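"""Independent brute-force oracles the tests check the package against.

Everything here works on fully expanded representations (per-column
strings, per-base lookup tables) so that it shares no code path with the
run-length / interval arithmetic under test.
"""

from __future__ import annotations

import random

from famviz.cigar_core import AlignmentCigar, ColumnClass
from famviz.io_formats import TranscriptModel


def expand_cigar(cigar: AlignmentCigar) -> str:
    return "".join(op * count for count, op in cigar.runs)


def classify_brute(guide: AlignmentCigar, target: AlignmentCigar) -> list[ColumnClass]:
    """Column classes by elementwise comparison of the expanded strings."""
    table = {
        ("M", "M"): ColumnClass.BOTH,
        ("D", "M"): ColumnClass.INSERTION,
        ("M", "D"): ColumnClass.DELETION,
        ("D", "D"): ColumnClass.NEITHER,
    }
    return [
        table[(g, t)] for g, t in zip(expand_cigar(guide), expand_cigar(target))
    ]


def stats_brute(cigar_a, seq_a, cigar_b, seq_b, matrix):
    """Identity/positivity/coverage by walking expanded columns."""
    ia = ib = 0
    n_id = n_pos = n_cov = 0
    for g, t in zip(expand_cigar(cigar_a), expand_cigar(cigar_b)):
        if g == "M" and t == "M":
            ra, rb = seq_a[ia], seq_b[ib]
            n_cov += 1
            if ra == rb:
                n_id += 1
                n_pos += 1
            elif float(matrix[ra, rb]) > 0:
                n_pos += 1
        if g == "M":
            ia += 1
        if t == "M":
            ib += 1
    la, lb = len(seq_a), len(seq_b)
    return {
        "perc_id_a": 100.0 * n_id / la, "perc_id_b": 100.0 * n_id / lb,
        "perc_pos_a": 100.0 * n_pos / la, "perc_pos_b": 100.0 * n_pos / lb,
        "perc_cov_a": 100.0 * n_cov / la, "perc_cov_b": 100.0 * n_cov / lb,
    }


def random_cigar_pair(rng: random.Random, max_cols: int = 40):
    """Two same-length CIGARs with at least one M each."""
    n = rng.randint(2, max_cols)
    while True:
        a = "".join(rng.choice("MD") for _ in range(n))
        b = "".join(rng.choice("MD") for _ in range(n))
        if "M" in a and "M" in b:
            break

    def pack(s, name):
        runs = []
        for ch in s:
            if runs and runs[-1][1] == ch:
                runs[-1] = (runs[-1][0] + 1, ch)
            else:
                runs.append((1, ch))
        return AlignmentCigar(member_id=name, runs=tuple(runs))

    return pack(a, "a"), pack(b, "b")


def cds_base_table(transcript: TranscriptModel) -> list[int]:
    """Genomic coordinate of every CDS base, in transcription order."""
    table: list[int] = []
    for cds in transcript.cds_segments:
        if transcript.strand == "+":
            table.extend(range(cds.start, cds.end))
        else:
            table.extend(range(cds.end - 1, cds.start - 1, -1))
    return table
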