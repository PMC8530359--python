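"""Sequence containers, FASTA/FASTQ/BED I/O, and global pairwise alignment.

The aligner is an end-to-end (end gaps penalized) Needleman-Wunsch/Gotoh
implementation with an explicit, deterministic traceback preference
(diagonal over gap-in-b over gap-in-a).  Identity is defined as
matches / alignment columns, counting gap columns; under the default
scores (match=1, mismatch=-1, gap open=-1, gap extend=-1) this is the
convention used throughout the protospacer flank filter and the
direct-repeat comparison utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NEG_INF = float("-inf")


class SequenceFormatError(ValueError):
    """Raised for malformed records or illegal characters in sequence files."""


@dataclass(frozen=True)
class SeqRecord:
    """A named uppercase DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    seq: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one global pairwise alignment."""

    score: int
    matches: int
    mismatches: int
    gap_columns: int
    alignment_length: int
    aligned_a: str = field(default="", compare=False)
    aligned_b: str = field(default="", compare=False)

    @property
    def identity(self) -> float:
        return self.matches / self.alignment_length


def _validate(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceFormatError(f"{name}: illegal characters {sorted(bad)!r}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases."""
    seq = _validate(seq)
    counted = len(seq) - seq.count("N")
    if counted == 0:
        raise ValueError("gc_content undefined for all-N sequence")
    return (seq.count("G") + seq.count("C")) / counted


# ---------------------------------------------------------------------------
# FASTA / FASTQ / BED I/O (Biopython-backed, with alphabet validation)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceFormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise SequenceFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() or None
        try:
            records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        try:
            records.append(SeqRecord(rec.id, str(rec.seq).upper()))
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_bed(intervals: Iterable[Interval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    """BED6 writer; coordinates are 0-based half-open throughout."""
    ivals = list(intervals)
    if names is None:
        names = [f"region_{i}" for i in range(len(ivals))]
    with open(path, "w") as handle:
        for iv, name in zip(ivals, names):
            handle.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Global alignment (Gotoh affine gaps; end gaps penalized)
# ---------------------------------------------------------------------------

_M, _X, _Y = 0, 1, 2  # diagonal / gap-in-b (consume a) / gap-in-a (consume b)


def global_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap_open: int = -1, gap_extend: int = -1) -> AlignmentResult:
    """Optimal end-to-end alignment under affine gap scores.

    End gaps are penalized.  Traceback tie-break is deterministic:
    diagonal (match preferred over mismatch by construction, since the
    diagonal substitution score is fixed by the characters) is preferred
    over a gap in ``b``, which is preferred over a gap in ``a``.
    N is never counted as a match.
    """
    a = _validate(a, "a")
    b = _validate(b, "b")
    n, m = len(a), len(b)

    # DP tables for three states; python lists are adequate at flank/repeat scale
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            sub = match if (ai == bj and ai != "N") else mismatch
            Mi[j] = sub + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + gap_open, Xp[j] + gap_extend, Yp[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend,
                        Xi[j - 1] + gap_open)

    # traceback: state preference M > X > Y at every tie
    i, j = n, m
    scores = (M[n][m], X[n][m], Y[n][m])
    best = max(scores)
    state = scores.index(best)

    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            target = M[i][j] - sub
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            cands = (M[i][j], X[i][j], Y[i][j])
            state = next(s for s in (_M, _X, _Y) if cands[s] == target)
        elif state == _X:
            cols_a.append(a[i - 1])
            cols_b.append("-")
            if i == 1 and j == 0:
                i = 0
                break
            if M[i - 1][j] + gap_open == X[i][j]:
                state = _M
            elif X[i - 1][j] + gap_extend == X[i][j]:
                state = _X
            else:
                state = _Y
            i -= 1
        else:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            if j == 1 and i == 0:
                j = 0
                break
            if M[i][j - 1] + gap_open == Y[i][j]:
                state = _M
            elif Y[i][j - 1] + gap_extend == Y[i][j]:
                state = _Y
            else:
                state = _X
            j -= 1

    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    matches = mismatches = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
        elif ca == cb and ca != "N":
            matches += 1
        else:
            mismatches += 1
    return AlignmentResult(
        score=int(best),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        alignment_length=len(aligned_a),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )
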