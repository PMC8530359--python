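"""Extraction of CRISPR-targeted sequences and terminal-redundancy handling.

Regions of a contig targeted by more than 30% of a spacer cluster's
members are marked (chaining member loci with a gap bound of
max(mean adjacent-locus distance, 1 kb)), nearby regions are joined
(<= 1 kb), gapless sequences are extracted, and sequences whose two ends
share an exact repeat of at least ``min_tr`` bases are reported as
terminally redundant (TR) — the assembler's signature of a completely
assembled circular genome.  TR sequences are deduplicated
rotation-aware: a sequence joins a representative when it aligns at
>= 95% identity over >= 95% of both lengths against the representative's
doubled circular sequence on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .clustering import SpacerCluster
from .protospacer import ProtospacerLocus
from .seqcore import Interval, SeqRecord, revcomp


@dataclass
class TargetRegion:
    cluster_id: str
    interval: Interval
    spacer_ids: set[str]
    cluster_size: int

    @property
    def distinct_spacers(self) -> int:
        return len(self.spacer_ids)

    @property
    def fraction_of_cluster(self) -> float:
        return self.distinct_spacers / self.cluster_size


@dataclass
class TRRecord:
    tr_id: str
    source: Interval
    linear_seq: str
    tr_len: int
    circular_seq: str
    cluster_id: str
    protospacer_count: int
    members: list["TRRecord"] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.circular_seq)


def mark_regions(cluster: SpacerCluster, loci: list[ProtospacerLocus],
                 min_fraction: float = 0.30, min_chain_gap: int = 1000,
                 ) -> list[TargetRegion]:
    """Chain member loci into blocks; keep blocks targeted by > min_fraction.

    The chaining gap is max(cluster mean adjacent-locus distance,
    ``min_chain_gap``); the block interval spans first locus start to
    last locus end; the fraction counts distinct member spacers in the
    block over the cluster size (strict inequality).
    """
    gap = max(cluster.mean_adjacent_locus_distance, float(min_chain_gap))
    member_loci = [l for l in loci if l.spacer_id in cluster.spacer_ids]
    by_contig: dict[str, list[ProtospacerLocus]] = {}
    for l in member_loci:
        by_contig.setdefault(l.interval.contig_id, []).append(l)
    regions: list[TargetRegion] = []
    for contig_id in sorted(by_contig):
        group = sorted(by_contig[contig_id], key=lambda l: l.interval.start)
        block = [group[0]]
        block_end = group[0].interval.end
        blocks = []
        for l in group[1:]:
            if l.interval.start - block_end <= gap:
                block.append(l)
                block_end = max(block_end, l.interval.end)
            else:
                blocks.append(block)
                block = [l]
                block_end = l.interval.end
        blocks.append(block)
        for block in blocks:
            spacers = {l.spacer_id for l in block}
            if len(spacers) > min_fraction * cluster.size:
                regions.append(TargetRegion(
                    cluster.cluster_id,
                    Interval(contig_id, block[0].interval.start,
                             max(l.interval.end for l in block)),
                    spacers, cluster.size))
    return regions


def join_regions(regions: list[TargetRegion], max_gap: int = 1000,
                 ) -> list[TargetRegion]:
    """Merge same-contig regions separated by <= max_gap (idempotent)."""
    by_contig: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_contig.setdefault(r.interval.contig_id, []).append(r)
    out: list[TargetRegion] = []
    for contig_id in sorted(by_contig):
        group = sorted(by_contig[contig_id], key=lambda r: r.interval.start)
        cur = group[0]
        for r in group[1:]:
            if r.interval.start - cur.interval.end <= max_gap:
                cur = TargetRegion(
                    cur.cluster_id,
                    Interval(contig_id, cur.interval.start,
                             max(cur.interval.end, r.interval.end)),
                    cur.spacer_ids | r.spacer_ids, cur.cluster_size)
            else:
                out.append(cur)
                cur = r
        out.append(cur)
    return out


def extract_gapless(region: TargetRegion, contigs: list[SeqRecord],
                    ) -> SeqRecord | None:
    """Region subsequence, or None when it contains an assembly gap (N)."""
    by_id = {c.id: c for c in contigs}
    contig = by_id.get(region.interval.contig_id)
    if contig is None or region.interval.end > len(contig.seq):
        raise ValueError(f"region {region.interval} outside contig bounds")
    seq = contig.seq[region.interval.start:region.interval.end]
    if "N" in seq:
        return None
    return SeqRecord(
        f"{region.cluster_id}|{region.interval.contig_id}"
        f":{region.interval.start}-{region.interval.end}", seq)


def _borders(seq: str) -> list[int]:
    """All lengths L with prefix(seq, L) == suffix(seq, L), via KMP failure."""
    n = len(seq)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    out = []
    b = fail[-1]
    while b > 0:
        out.append(b)
        b = fail[b - 1]
    return out  # descending


def detect_tr(seq: str, min_tr: int = 20, max_tr_fraction: float = 0.5,
              ) -> tuple[int, str] | None:
    """Longest exact terminal repeat within [min_tr, max_tr_fraction*len].

    Returns (tr_len, circular_seq) where circular_seq is the input with
    its terminal repeat removed, or None when no qualifying repeat
    exists or the sequence is too short (len <= 2*min_tr).
    """
    n = len(seq)
    if n <= 2 * min_tr:
        return None
    cap = int(max_tr_fraction * n)
    for b in _borders(seq):
        if b > cap:
            continue
        if b >= min_tr:
            return b, seq[:n - b]
        break
    return None


def make_tr_records(regions: list[TargetRegion], contigs: list[SeqRecord],
                    loci: list[ProtospacerLocus], min_tr: int = 20,
                    max_tr_fraction: float = 0.5,
                    ) -> tuple[list[TRRecord], list[SeqRecord]]:
    """Extract regions and split them into TR records and linear leftovers."""
    tr_records: list[TRRecord] = []
    linear: list[SeqRecord] = []
    for region in regions:
        rec = extract_gapless(region, contigs)
        if rec is None:
            continue
        hit = detect_tr(rec.seq, min_tr, max_tr_fraction)
        count = sum(1 for l in loci
                    if l.spacer_id in region.spacer_ids
                    and l.interval.contig_id == region.interval.contig_id
                    and l.interval.start >= region.interval.start
                    and l.interval.end <= region.interval.end)
        if hit is None:
            linear.append(rec)
            continue
        tr_len, circ = hit
        tr_records.append(TRRecord(
            tr_id=f"TR{len(tr_records) + 1:04d}",
            source=region.interval,
            linear_seq=rec.seq,
            tr_len=tr_len,
            circular_seq=circ,
            cluster_id=region.cluster_id,
            protospacer_count=count))
    return tr_records, linear


def _circular_match(circ: str, rep_circ: str, min_identity: float,
                    min_coverage: float) -> bool:
    if min(len(circ), len(rep_circ)) / max(len(circ), len(rep_circ)) < min_coverage:
        return False
    doubled = rep_circ + rep_circ
    budget = int((1.0 - min_identity) * len(circ))
    for query in (circ, revcomp(circ)):
        res = edlib.align(query, doubled, mode="HW", task="distance", k=budget)
        if res["editDistance"] != -1:
            return True
    return False


def dedup_circular(records: list[TRRecord], min_identity: float = 0.95,
                   min_coverage: float = 0.95) -> list[TRRecord]:
    """Greedy longest-first rotation-aware clustering of circular sequences.

    A record joins the first (longest) representative whose doubled
    circular sequence it matches at >= min_identity over >= min_coverage
    of both lengths, on either strand.
    """
    ordered = sorted(records, key=lambda r: (-r.length, r.tr_id))
    reps: list[TRRecord] = []
    for rec in ordered:
        for rep in reps:
            if _circular_match(rec.circular_seq, rep.circular_seq,
                               min_identity, min_coverage):
                rep.members.append(rec)
                break
        else:
            reps.append(rec)
    return reps
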