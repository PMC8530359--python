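"""CRISPR-based host prediction, PAM inference, and the remnant-spacer sweep.

Direct repeats are mapped to reference genomes with known lineages; a
genome supports a DR only through a validated CRISPR locus (>= 3 hits
whose consecutive start-to-start gaps are each <= 100 bases).  A DR is
assigned at a taxonomic rank only when all supporting genomes agree at
that rank.  A record's targeting host at a rank is the top taxon among
its taxonomically assigned protospacer loci when at least 10 loci are
assigned and the top taxon holds more than 90% of them; with >= 10
assigned loci but lower exclusiveness the call is AMBIGUOUS, with < 10
it is NA.

PAM profiles accumulate base counts over the 10 positions flanking each
protospacer, oriented so every protospacer reads spacer-strand 5'->3'.

The remnant-spacer sweep maps all unique spacers to TR sequences and to
length/composition-matched scrambled controls across a descending range
of identity thresholds; counts of spacers with at least one hit are
monotonically non-increasing in the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _scan
from .crispr import DirectRepeat, Spacer
from .protospacer import ProtospacerLocus
from .seqcore import Interval, SeqRecord, revcomp

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Lineage:
    """Names per rank, domain -> species; lower ranks may be unset (None)."""

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError("lineage must cover all seven ranks")
        seen_unset = False
        for name in self.names:
            if name is None:
                seen_unset = True
            elif seen_unset:
                raise ValueError("a set rank below an unset rank")

    def at(self, rank: str) -> str | None:
        return self.names[RANKS.index(rank)]


@dataclass
class DrTaxonomy:
    dr_id: str
    assignment: dict[str, str]                       # rank -> name or UNASSIGNED
    supporting_loci: list[tuple[str, Interval]] = field(default_factory=list)


@dataclass
class HostCall:
    tr_id: str
    rank: str
    call: str                                        # taxon | AMBIGUOUS | NA
    assigned_protospacers: int
    top_fraction: float


@dataclass
class PamProfile:
    tr_id: str
    side: str                                        # 5prime | 3prime
    counts: np.ndarray                               # (positions, 4) A,C,G,T
    n_protospacers: int
    low_support: bool

    def consensus(self, threshold: float = 0.75) -> str:
        out = []
        for row in self.counts:
            total = row.sum()
            if total == 0:
                out.append("N")
                continue
            i = int(np.argmax(row))
            out.append("ACGT"[i] if row[i] / total >= threshold else "N")
        return "".join(out)


def read_lineages(path) -> dict[str, Lineage]:
    """Lineage TSV: genome_id + one column per rank (empty cell = unset)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        names = tuple(row[r] if row.get(r, "") else None for r in RANKS)
        out[row["genome_id"]] = Lineage(names)
    return out


def _validated_loci(starts: list[int], max_gap: int = 100,
                    min_hits: int = 3) -> list[tuple[int, int]]:
    """Runs of >= min_hits hits with consecutive start-to-start gaps <= max_gap."""
    if not starts:
        return []
    starts = sorted(starts)
    runs = []
    run = [starts[0]]
    for s in starts[1:]:
        if s - run[-1] <= max_gap:
            run.append(s)
        else:
            runs.append(run)
            run = [s]
    runs.append(run)
    return [(r[0], r[-1]) for r in runs if len(r) >= min_hits]


def assign_dr_taxonomy(drs: list[DirectRepeat], ref_genomes: list[SeqRecord],
                       lineages: dict[str, Lineage], min_identity: float = 0.9,
                       locus_max_gap: int = 100, locus_min_hits: int = 3,
                       ) -> list[DrTaxonomy]:
    """Per-rank taxonomy of each DR from validated reference CRISPR loci."""
    for g in ref_genomes:
        if g.id not in lineages:
            raise ValueError(f"reference genome {g.id!r} has no lineage")
    encoded = [(g, _scan.encode_text(g.seq)) for g in ref_genomes]
    out: list[DrTaxonomy] = []
    for dr in drs:
        L = len(dr.seq)
        max_mm = math.floor((1.0 - min_identity) * L + 1e-9)
        supporting: list[tuple[str, Interval]] = []
        genomes: list[str] = []
        for genome, text in encoded:
            starts: list[int] = []
            for pat_seq in {dr.seq, revcomp(dr.seq)}:
                pat = _scan.encode_pattern(pat_seq)
                starts.extend(int(p) for p in _scan.scan_hits(text, pat, max_mm))
            loci = _validated_loci(starts, locus_max_gap, locus_min_hits)
            if loci:
                genomes.append(genome.id)
                supporting.extend(
                    (genome.id, Interval(genome.id, s, e + L)) for s, e in loci)
        assignment = {}
        for rank in RANKS:
            names = {lineages[g].at(rank) for g in genomes}
            names.discard(None)
            assignment[rank] = names.pop() if len(names) == 1 else UNASSIGNED
        out.append(DrTaxonomy(dr.dr_id, assignment, supporting))
    return out


def _locus_taxon(locus: ProtospacerLocus, tax_by_dr: dict[str, DrTaxonomy],
                 rank: str) -> str:
    names = {tax_by_dr[d].assignment[rank]
             for d in locus.dr_ids if d in tax_by_dr}
    names.discard(UNASSIGNED)
    return names.pop() if len(names) == 1 else UNASSIGNED


def call_host(tr_id: str, loci: list[ProtospacerLocus],
              dr_taxonomies: list[DrTaxonomy], rank: str,
              min_count: int = 10, min_exclusiveness: float = 0.9) -> HostCall:
    """Targeting-host call for one record from its protospacer loci."""
    tax_by_dr = {t.dr_id: t for t in dr_taxonomies}
    counts: dict[str, int] = {}
    for locus in loci:
        taxon = _locus_taxon(locus, tax_by_dr, rank)
        if taxon != UNASSIGNED:
            counts[taxon] = counts.get(taxon, 0) + 1
    assigned = sum(counts.values())
    if assigned == 0:
        return HostCall(tr_id, rank, "NA", 0, 0.0)
    top_taxon, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    frac = top / assigned
    if assigned < min_count:
        call = "NA"
    elif frac > min_exclusiveness:
        call = top_taxon
    else:
        call = "AMBIGUOUS"
    return HostCall(tr_id, rank, call, assigned, frac)


def infer_pam(tr_id: str, loci: list[ProtospacerLocus],
              contig_seqs: dict[str, str], flank: int = 10,
              min_support: int = 3) -> tuple[PamProfile, PamProfile]:
    """Position count matrices of the 5' and 3' protospacer flanks.

    Matrix rows run outward-to-inward for the 5' side (row ``flank-1`` is
    the base immediately 5' of the protospacer) and inward-to-outward for
    the 3' side (row 0 immediately 3').  Contig-end-clipped flanks
    contribute only their available positions.
    """
    base_idx = {b: i for i, b in enumerate("ACGT")}
    c5 = np.zeros((flank, 4), dtype=np.int64)
    c3 = np.zeros((flank, 4), dtype=np.int64)
    n = 0
    for locus in loci:
        seq = contig_seqs[locus.interval.contig_id]
        up = seq[max(0, locus.interval.start - flank):locus.interval.start]
        down = seq[locus.interval.end:locus.interval.end + flank]
        if locus.interval.strand == "-":
            up, down = revcomp(down), revcomp(up)
        n += 1
        for i, b in enumerate(reversed(up)):      # fill inward-out, store out-in
            if b in base_idx:
                c5[flank - 1 - i, base_idx[b]] += 1
        for i, b in enumerate(down):
            if b in base_idx:
                c3[i, base_idx[b]] += 1
    low = n < min_support
    return (PamProfile(tr_id, "5prime", c5, n, low),
            PamProfile(tr_id, "3prime", c3, n, low))


def scramble(records: list[SeqRecord], seed: int,
             n_replicates: int = 1) -> list[SeqRecord]:
    """Length-matched random sequences drawn i.i.d. from the records'
    aggregate nucleotide frequency."""
    rng = np.random.default_rng(seed)
    total = sum(len(r.seq) for r in records)
    freqs = np.array([sum(r.seq.count(b) for r in records) for b in "ACGT"],
                     dtype=np.float64)
    if freqs.sum() == 0:
        raise ValueError("cannot scramble an all-N record set")
    freqs /= freqs.sum()
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    out = []
    for rep in range(n_replicates):
        for r in records:
            draw = rng.choice(bases, size=len(r.seq), p=freqs)
            out.append(SeqRecord(f"scrambled_{rep}_{r.id}",
                                 draw.tobytes().decode("ascii")))
    return out


def remnant_sweep(spacers: list[Spacer], tr_records: list[SeqRecord],
                  scrambled: list[SeqRecord],
                  thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Unique spacers with >= 1 full-length hit per identity threshold.

    Mapping is the same substitution-only contract as protospacer
    mapping, without CRISPR masking.  Each sequence set is scanned once
    per spacer for its best achievable identity; counts at every
    threshold follow by comparison, which makes the monotonicity of the
    sweep explicit.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.80, 1.0001, 0.01), 2)
    patterns = [s.seq for s in spacers]
    rows = {"threshold": thresholds}
    for name, recs in (("mapped_to_TR", tr_records),
                       ("mapped_to_scrambled", scrambled)):
        if recs and patterns:
            pad = max(len(p) for p in patterns)
            text = _scan.ConcatText.from_seqs(
                [r.id for r in recs], [r.seq for r in recs], pad=pad)
            best = np.zeros(len(patterns))
            for i, p in enumerate(patterns):
                fwd = _scan.mismatch_counts(text.data, _scan.encode_pattern(p))
                rev = _scan.mismatch_counts(text.data,
                                            _scan.encode_pattern(revcomp(p)))
                mm = min(fwd.min(initial=len(p)), rev.min(initial=len(p)))
                best[i] = 1.0 - mm / len(p)
            rows[name] = [int((best >= t - 1e-9).sum()) for t in thresholds]
        else:
            rows[name] = [0] * len(thresholds)
    return pd.DataFrame(rows)
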