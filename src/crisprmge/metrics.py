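"""Per-record genomic metrics and marker-gene classification.

Singleton coverage — the number of k-mers occurring exactly once in a
(circularized) sequence divided by its length — approaches 1 for
repeat-free genomes.  k is chosen automatically as the smallest value
with 4^k >= 100 * L^2, which keeps the expected number of chance
doubletons in a random sequence of length L below ~0.01, so large
genomes are scored with larger k.

The coding ratio is the fraction of the circular genome covered by
predicted open reading frames.  ORFs are called by a simple 6-frame
start(ATG/GTG/TTG)-to-stop scanner on the doubled sequence (so genes
spanning the origin are recovered), keeping the longest ORF per stop.

Classification applies a fixed marker-gene precedence to an annotation
table: a detectable capsid assigns the viral taxon (HK97 fold capsid ->
Caudovirales; Microviridae MCP -> Microviridae; Inoviridae MCP ->
Inoviridae); capsid-less records carrying ParA/ParB/ParM/MobM are
Plasmid-like; everything else is Unclassified.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .seqcore import Interval, gc_content, revcomp

SIZE_SPLIT = 20_000          # small/large boundary (bases)
GC_SPLIT = 0.55              # low/high GC boundary

ANNOTATION_LABELS = frozenset({
    "HK97_capsid", "portal", "Microviridae_MCP", "Inoviridae_MCP",
    "ParA", "ParB", "ParM", "MobM", "Zot", "Rep", "other",
})
PLASMID_MARKERS = frozenset({"ParA", "ParB", "ParM", "MobM"})

_STARTS = ("ATG", "GTG", "TTG")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class RecordMetrics:
    tr_id: str
    length: int
    gc: float
    singleton_coverage: float
    k_used: int
    coding_ratio: float

    @property
    def size_class(self) -> str:
        return "large" if self.length > SIZE_SPLIT else "small"

    @property
    def gc_class(self) -> str:
        return "high" if self.gc > GC_SPLIT else "low"


def auto_k(length: int) -> int:
    """Smallest k with 4^k >= 100 * L^2 (expected chance doubletons < ~0.01)."""
    return max(1, math.ceil(math.log(100.0 * length * length, 4)))


def singleton_coverage(seq: str, k: int | None = None) -> tuple[float, int]:
    """Fraction of positions starting a unique k-mer on the circularized sequence.

    Counting is on the forward strand and includes wrap-around k-mers, so
    a doubled sequence scores exactly 0 and the metric is invariant under
    rotation.
    """
    L = len(seq)
    if k is None:
        k = auto_k(L)
    if k >= L:
        raise ValueError(f"k={k} must be smaller than sequence length {L}")
    doubled = seq + seq[:k - 1]
    counts = Counter(doubled[i:i + k] for i in range(L))
    singletons = sum(1 for c in counts.values() if c == 1)
    return singletons / L, k


def _frame_orfs(frame_seq: str, min_len_codons: int) -> list[tuple[int, int]]:
    """(start, end) nucleotide offsets of longest-per-stop ORFs in one frame."""
    orfs = []
    start: int | None = None
    for i in range(0, len(frame_seq) - 2, 3):
        codon = frame_seq[i:i + 3]
        if codon in _STOPS:
            if start is not None and (i + 3 - start) // 3 >= min_len_codons:
                orfs.append((start, i + 3))
            start = None
        elif start is None and codon in _STARTS:
            start = i
    return orfs


def call_orfs(seq: str, min_len_codons: int = 33, circular: bool = True,
              ) -> list[Interval]:
    """6-frame ORFs on the (doubled, if circular) sequence in circular coords.

    Intervals may wrap: end is taken modulo L conceptually, represented
    as start < end <= start + L with coordinates reduced modulo L at
    projection time.  Length of an ORF never exceeds the genome length.
    """
    L = len(seq)
    scan = seq + seq if circular else seq
    found: set[tuple[int, int, str]] = set()
    out: list[Interval] = []
    for strand in ("+", "-"):
        s = scan if strand == "+" else revcomp(scan)
        for off in range(3):
            for a, b in _frame_orfs(s[off:], min_len_codons):
                a, b = a + off, b + off
                if strand == "-":
                    a, b = len(scan) - b, len(scan) - a
                if b - a > L:
                    continue  # longer than the genome: artifact of doubling
                key = (a % L, b % L if b % L else L, strand) if circular \
                    else (a, b, strand)
                if key in found:
                    continue
                found.add(key)
                start = a % L if circular else a
                out.append(Interval("orf", start, start + (b - a), strand))
    out.sort(key=lambda iv: (iv.start, iv.end, iv.strand))
    return out


def coding_ratio(seq: str, orfs: list[Interval]) -> float:
    """Fraction of circular positions covered by the union of ORF spans."""
    L = len(seq)
    covered = np.zeros(L, dtype=bool)
    for orf in orfs:
        idx = np.arange(orf.start, orf.end) % L
        covered[idx] = True
    return float(covered.mean())


def classify(tr_id: str, annotations: list[tuple[str, str]]) -> str:
    """Marker-precedence taxon call from (gene_id, label) annotation rows."""
    labels = set()
    for _gene, label in annotations:
        if label not in ANNOTATION_LABELS:
            raise ValueError(f"unknown annotation label {label!r} for {tr_id}")
        labels.add(label)
    if "HK97_capsid" in labels:
        return "Caudovirales"
    if "Microviridae_MCP" in labels:
        return "Microviridae"
    if "Inoviridae_MCP" in labels:
        return "Inoviridae"
    if labels & PLASMID_MARKERS:
        return "Plasmid-like"
    return "Unclassified"


def compute_metrics(tr_id: str, circular_seq: str, k: int | None = None,
                    min_len_codons: int = 33) -> RecordMetrics:
    cov, k_used = singleton_coverage(circular_seq, k)
    orfs = call_orfs(circular_seq, min_len_codons)
    return RecordMetrics(
        tr_id=tr_id,
        length=len(circular_seq),
        gc=gc_content(circular_seq),
        singleton_coverage=cov,
        k_used=k_used,
        coding_ratio=coding_ratio(circular_seq, orfs),
    )
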