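"""Protein-space CIGAR algebra.

A family multiple sequence alignment is carried around as one run-length
encoded string per member, in the Ensembl-Compara per-member convention:
``M`` means the member contributes a residue to that alignment column,
``D`` means the member has a gap there.  (This is *not* the SAM CIGAR
alphabet: there is no ``I``, and coordinates are amino-acid columns.)

The module converts an MSA to CIGARs and back, classifies the columns of
a homologue against a guide member, and computes the bidirectional
identity / positivity / coverage percentages that homology tables report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import CigarError, ModelError

__all__ = [
    "AlignmentCigar",
    "ColumnClass",
    "ColumnClassification",
    "PairStats",
    "parse_cigar",
    "cigars_from_msa",
    "rebuild_row",
    "classify_columns",
    "pairwise_stats",
    "load_scoring_matrix",
    "default_scoring_matrix",
]

_CIGAR_TOKEN = re.compile(r"(\d*)([A-Za-z*=])")

Run = tuple[int, str]


def _normalize_runs(runs: Iterable[Run]) -> tuple[Run, ...]:
    """Merge adjacent runs with the same op and drop zero counts."""
    out: list[list[int | str]] = []
    for count, op in runs:
        if count == 0:
            continue
        if out and out[-1][1] == op:
            out[-1][0] += count  # type: ignore[operator]
        else:
            out.append([count, op])
    return tuple((int(c), str(o)) for c, o in out)


@dataclass(frozen=True)
class AlignmentCigar:
    """One member's row of the family alignment as (count, op) runs.

    ``runs`` is kept normalized: no two adjacent runs share an op, all
    counts are positive.  ``alignment_length`` is the number of columns,
    i.e. the sum of all counts; the number of residues the member itself
    contributes is ``n_residues`` (sum of M counts).
    """

    member_id: str
    runs: tuple[Run, ...]

    def __post_init__(self):
        if not self.runs:
            raise CigarError(f"empty CIGAR for member {self.member_id!r}")
        for count, op in self.runs:
            if op not in ("M", "D"):
                raise CigarError(
                    f"unsupported CIGAR op {op!r} for member {self.member_id!r}; "
                    "only M and D are allowed"
                )
            if count <= 0:
                raise CigarError(f"non-positive run count in CIGAR for {self.member_id!r}")
        object.__setattr__(self, "runs", _normalize_runs(self.runs))

    @property
    def alignment_length(self) -> int:
        return sum(c for c, _ in self.runs)

    @property
    def n_residues(self) -> int:
        return sum(c for c, op in self.runs if op == "M")

    def expand(self) -> str:
        """Column string, e.g. ``'MMDDM'``.  For oracles and tests."""
        return "".join(op * c for c, op in self.runs)

    def __str__(self) -> str:
        return "".join(f"{c}{op}" if c > 1 else op for c, op in self.runs)


def parse_cigar(text: str, member_id: str = "") -> AlignmentCigar:
    """Parse ``[count]op`` repetitions; a missing count means 1.

    Only M and D are accepted.  Anything else — including the SAM-style
    ops I/N/S/X — raises :class:`CigarError` naming the offending op.
    """
    if not text or not text.strip():
        raise CigarError("empty CIGAR string")
    text = text.strip()
    pos = 0
    runs: list[Run] = []
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"unparsable CIGAR fragment {text[pos:m.start()]!r}")
        count = int(m.group(1)) if m.group(1) else 1
        runs.append((count, m.group(2)))
        pos = m.end()
    if pos != len(text):
        raise CigarError(f"unparsable CIGAR fragment {text[pos:]!r}")
    return AlignmentCigar(member_id=member_id, runs=tuple(runs))


def cigars_from_msa(
    rows: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[dict[str, AlignmentCigar], dict[str, str]]:
    """Convert aligned rows (gap char ``-``) into per-member CIGARs.

    Returns ``(cigars, unaligned)`` keyed by member id.  Reconstructing
    the gap pattern from a member's CIGAR and unaligned sequence yields
    the original row exactly (see :func:`rebuild_row`).
    """
    items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
    if not items:
        raise CigarError("empty alignment")
    width = len(items[0][1])
    cigars: dict[str, AlignmentCigar] = {}
    unaligned: dict[str, str] = {}
    for member_id, row in items:
        if len(row) != width:
            raise CigarError(
                f"ragged MSA: member {member_id!r} has length {len(row)}, expected {width}"
            )
        runs: list[Run] = []
        for ch in row:
            op = "D" if ch == "-" else "M"
            if runs and runs[-1][1] == op:
                runs[-1] = (runs[-1][0] + 1, op)
            else:
                runs.append((1, op))
        if all(op == "D" for _, op in runs):
            raise CigarError(f"member {member_id!r} is an all-gap row")
        cigars[member_id] = AlignmentCigar(member_id=member_id, runs=tuple(runs))
        unaligned[member_id] = row.replace("-", "")
    return cigars, unaligned


def rebuild_row(cigar: AlignmentCigar, seq: str) -> str:
    """Inverse of :func:`cigars_from_msa` for one member."""
    if cigar.n_residues != len(seq):
        raise ModelError(
            f"CIGAR of {cigar.member_id!r} encodes {cigar.n_residues} residues "
            f"but sequence has {len(seq)}"
        )
    out: list[str] = []
    i = 0
    for count, op in cigar.runs:
        if op == "M":
            out.append(seq[i : i + count])
            i += count
        else:
            out.append("-" * count)
    return "".join(out)


class ColumnClass(str, Enum):
    """Per-column relation of the target member to the guide member."""

    BOTH = "BOTH"            # residue in guide and target
    INSERTION = "INSERTION"  # target-only residue
    DELETION = "DELETION"    # guide-only residue
    NEITHER = "NEITHER"      # gap in both (columns owed to third members)


_CLASS_TABLE = {
    ("M", "M"): ColumnClass.BOTH,
    ("D", "M"): ColumnClass.INSERTION,
    ("M", "D"): ColumnClass.DELETION,
    ("D", "D"): ColumnClass.NEITHER,
}


@dataclass(frozen=True)
class ColumnClassification:
    """Run-length classification of alignment columns, target vs guide."""

    runs: tuple[tuple[int, ColumnClass], ...]
    total_columns: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(self, "total_columns", sum(c for c, _ in self.runs))

    def expand(self) -> list[ColumnClass]:
        out: list[ColumnClass] = []
        for count, cls in self.runs:
            out.extend([cls] * count)
        return out

    def counts(self) -> dict[ColumnClass, int]:
        tally = {cls: 0 for cls in ColumnClass}
        for count, cls in self.runs:
            tally[cls] += count
        return tally


def classify_columns(guide: AlignmentCigar, target: AlignmentCigar) -> ColumnClassification:
    """Column-wise comparison of ``target`` against ``guide``.

    (guide M, target M) -> BOTH; (D, M) -> INSERTION; (M, D) -> DELETION;
    (D, D) -> NEITHER.  Works directly on the run-length encodings, so it
    is linear in the number of runs, not columns.
    """
    if guide.alignment_length != target.alignment_length:
        raise ModelError(
            f"alignment length mismatch: guide {guide.member_id!r} has "
            f"{guide.alignment_length} columns, target {target.member_id!r} "
            f"has {target.alignment_length}"
        )
    out: list[tuple[int, ColumnClass]] = []
    gi = ti = 0          # run indices
    g_left = guide.runs[0][0]
    t_left = target.runs[0][0]
    while gi < len(guide.runs) and ti < len(target.runs):
        step = min(g_left, t_left)
        cls = _CLASS_TABLE[(guide.runs[gi][1], target.runs[ti][1])]
        if out and out[-1][1] is cls:
            out[-1] = (out[-1][0] + step, cls)
        else:
            out.append((step, cls))
        g_left -= step
        t_left -= step
        if g_left == 0:
            gi += 1
            if gi < len(guide.runs):
                g_left = guide.runs[gi][0]
        if t_left == 0:
            ti += 1
            if ti < len(target.runs):
                t_left = target.runs[ti][0]
    return ColumnClassification(runs=tuple(out))


@dataclass(frozen=True)
class PairStats:
    """Bidirectional homology-pair statistics, in percent of each member.

    For member *x* with sequence length ``len_x``: identity is the share
    of columns where both members carry the identical residue; positivity
    additionally counts residue pairs with a positive substitution score;
    coverage counts all columns where both members carry a residue.  Each
    is divided by ``len_x``, so the two directions generally differ.
    """

    perc_id_a: float
    perc_id_b: float
    perc_pos_a: float
    perc_pos_b: float
    perc_cov_a: float
    perc_cov_b: float

    def __post_init__(self):
        for side in ("a", "b"):
            pid = getattr(self, f"perc_id_{side}")
            ppos = getattr(self, f"perc_pos_{side}")
            pcov = getattr(self, f"perc_cov_{side}")
            if not (0.0 <= pid <= ppos <= pcov <= 100.0):
                raise ModelError(
                    f"statistics ordering violated for member {side}: "
                    f"id={pid} pos={ppos} cov={pcov}"
                )

    def swapped(self) -> "PairStats":
        return PairStats(
            perc_id_a=self.perc_id_b, perc_id_b=self.perc_id_a,
            perc_pos_a=self.perc_pos_b, perc_pos_b=self.perc_pos_a,
            perc_cov_a=self.perc_cov_b, perc_cov_b=self.perc_cov_a,
        )


_DEFAULT_MATRIX = None


def default_scoring_matrix():
    """BLOSUM62, loaded once.  ``score > 0`` defines a 'positive' pair."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        from Bio.Align import substitution_matrices

        _DEFAULT_MATRIX = substitution_matrices.load("BLOSUM62")
    return _DEFAULT_MATRIX


def load_scoring_matrix(path) -> object:
    """Load an NCBI-format substitution matrix from a text file."""
    from Bio.Align import substitution_matrices

    with open(path) as fh:
        return substitution_matrices.read(fh)


def _score(matrix, ra: str, rb: str) -> float:
    try:
        return float(matrix[ra, rb])
    except (KeyError, IndexError):
        missing = ra if ra not in getattr(matrix, "alphabet", ra) else rb
        raise ModelError(f"residue {missing!r} absent from scoring matrix") from None


def pairwise_stats(
    cigar_a: AlignmentCigar,
    seq_a: str,
    cigar_b: AlignmentCigar,
    seq_b: str,
    matrix=None,
) -> PairStats:
    """Identity / positivity / coverage for one aligned member pair.

    Counts are taken over BOTH columns only and normalized by each
    member's own unaligned length, mirroring the convention of Compara
    homology tables.  NEITHER columns never contribute.
    """
    if matrix is None:
        matrix = default_scoring_matrix()
    if cigar_a.alignment_length != cigar_b.alignment_length:
        raise ModelError(
            f"alignment length mismatch: {cigar_a.alignment_length} vs "
            f"{cigar_b.alignment_length}"
        )
    for cig, seq in ((cigar_a, seq_a), (cigar_b, seq_b)):
        if cig.n_residues != len(seq):
            raise ModelError(
                f"CIGAR of {cig.member_id!r} encodes {cig.n_residues} residues "
                f"but sequence has {len(seq)}"
            )
    n_id = n_pos = n_cov = 0
    ia = ib = 0
    for count, cls in classify_columns(cigar_a, cigar_b).runs:
        if cls is ColumnClass.BOTH:
            for k in range(count):
                ra, rb = seq_a[ia + k], seq_b[ib + k]
                if ra == rb:
                    n_id += 1
                    n_pos += 1
                elif _score(matrix, ra, rb) > 0:
                    n_pos += 1
            n_cov += count
            ia += count
            ib += count
        elif cls is ColumnClass.DELETION:   # residue in a only
            ia += count
        elif cls is ColumnClass.INSERTION:  # residue in b only
            ib += count
    la, lb = len(seq_a), len(seq_b)
    return PairStats(
        perc_id_a=100.0 * n_id / la, perc_id_b=100.0 * n_id / lb,
        perc_pos_a=100.0 * n_pos / la, perc_pos_b=100.0 * n_pos / lb,
        perc_cov_a=100.0 * n_cov / la, perc_cov_b=100.0 * n_cov / lb,
    )
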