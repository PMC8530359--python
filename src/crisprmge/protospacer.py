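"""Protospacer detection: CRISPR-locus masking, spacer mapping, flank filter.

Direct repeats are first mapped back to contigs (>= 93% full-length
identity, either strand) and every hit plus 60 flanking bases is masked
as a CRISPR locus, so that spacers matching their own arrays are never
mistaken for protospacers.  Spacers are then mapped full-length
(substitution-only) to the masked contigs; any hit overlapping a mask by
one or more bases is suppressed.

Remaining candidates pass a flank-alignment filter: the regions
immediately 5' and 3' of the hit are globally aligned against each other
and against the associated DR; a locus is discarded when any alignment
score divided by the shorter sequence length exceeds 0.5.  This catches
unmasked repeat remnants whose flanks look like DR sequence or like each
other (tandem-repeat context).
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from . import _scan
from .crispr import DirectRepeat, Spacer
from .seqcore import Interval, SeqRecord, global_align, revcomp


@dataclass
class MaskedContigSet:
    contigs: list[SeqRecord]
    crispr_mask: dict[str, list[tuple[int, int]]]  # per contig, sorted, merged

    def is_masked(self, contig_id: str, start: int, end: int) -> bool:
        ivals = self.crispr_mask.get(contig_id, [])
        i = bisect_left(ivals, (start,)) - 1
        for s, e in ivals[max(i, 0):]:
            if s >= end:
                break
            if start < e and s < end:
                return True
        return False


@dataclass
class ProtospacerLocus:
    spacer_id: str
    interval: Interval
    identity: float
    flank5: str = ""
    flank3: str = ""
    validated: bool = False
    reason: str = ""
    dr_ids: frozenset[str] = field(default_factory=frozenset)


def _merge(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not pairs:
        return []
    pairs = sorted(pairs)
    out = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(p) for p in out]


def mask_crispr_loci(contigs: list[SeqRecord], drs: list[DirectRepeat],
                     min_identity: float = 0.93, flank: int = 60) -> MaskedContigSet:
    """Mask every full-length DR hit (either strand) plus ``flank`` bases."""
    masks: dict[str, list[tuple[int, int]]] = {}
    for contig in contigs:
        text = _scan.encode_text(contig.seq)
        pairs: list[tuple[int, int]] = []
        for dr in drs:
            L = len(dr.seq)
            max_mm = math.floor((1.0 - min_identity) * L + 1e-9)
            for pat_seq in {dr.seq, revcomp(dr.seq)}:
                pat = _scan.encode_pattern(pat_seq)
                for p in _scan.scan_hits(text, pat, max_mm):
                    pairs.append((max(0, int(p) - flank),
                                  min(len(contig.seq), int(p) + L + flank)))
        if pairs:
            masks[contig.id] = _merge(pairs)
    return MaskedContigSet(contigs, masks)


def map_spacers(spacers: list[Spacer], masked: MaskedContigSet,
                min_identity: float = 0.93) -> list[ProtospacerLocus]:
    """Full-length substitution-only spacer hits outside CRISPR masks.

    Identity is matching positions / spacer length.  Hits on the minus
    strand are reported on forward coordinates with strand '-'.
    """
    if not spacers or not masked.contigs:
        return []
    pad = max(len(s.seq) for s in spacers)
    text = _scan.ConcatText.from_seqs([c.id for c in masked.contigs],
                                      [c.seq for c in masked.contigs], pad=pad)
    loci: list[ProtospacerLocus] = []
    for sp in spacers:
        query = sp.oriented_seq or sp.seq
        L = len(query)
        max_mm = math.floor((1.0 - min_identity) * L + 1e-9)
        for strand, pat_seq in (("+", query), ("-", revcomp(query))):
            if strand == "-" and pat_seq == query:
                continue  # palindromic spacer: avoid double-reporting
            pat = _scan.encode_pattern(pat_seq)
            mism = _scan.mismatch_counts(text.data, pat)
            pos = np.nonzero(mism <= max_mm)[0]
            if len(pos) == 0:
                continue
            idx, off = text.locate(pos)
            for k in range(len(pos)):
                cid = text.ids[int(idx[k])]
                s = int(off[k])
                e = s + L
                if e > int(text.lengths[int(idx[k])]):
                    continue  # window ran into separator padding
                if masked.is_masked(cid, s, e):
                    continue
                loci.append(ProtospacerLocus(
                    spacer_id=sp.spacer_id,
                    interval=Interval(cid, s, e, strand),
                    identity=1.0 - int(mism[pos[k]]) / L,
                    dr_ids=frozenset(sp.associated_drs),
                ))
    loci.sort(key=lambda l: (l.interval.contig_id, l.interval.start,
                             l.interval.strand, l.spacer_id))
    return loci


def extract_flanks(locus: ProtospacerLocus, contig_seq: str,
                   flank_len: int) -> tuple[str, str]:
    """Flanks in spacer-strand orientation, clipped at contig ends."""
    iv = locus.interval
    up = contig_seq[max(0, iv.start - flank_len):iv.start]
    down = contig_seq[iv.end:iv.end + flank_len]
    if iv.strand == "+":
        return up, down
    return revcomp(down), revcomp(up)


def validate_flanks(flank5: str, flank3: str, dr_seq: str,
                    ratio_cutoff: float = 0.5) -> bool:
    """Flank-alignment false-positive filter.

    Aligns flank5 vs flank3, flank5 vs DR and flank3 vs DR under the
    match=1/mismatch=-1/gap=-1 scores; the locus is rejected when any
    score divided by the shorter aligned sequence length exceeds the
    cutoff.  Zero-length flanks skip the comparisons involving them.
    """
    for a, b in ((flank5, flank3), (flank5, dr_seq), (flank3, dr_seq)):
        if not a or not b:
            continue
        res = global_align(a, b)
        if res.score / min(len(a), len(b)) > ratio_cutoff:
            return False
    return True


def find_protospacers(spacers: list[Spacer], contigs: list[SeqRecord],
                      drs: list[DirectRepeat], min_identity: float = 0.93,
                      mask_flank: int = 60, ratio_cutoff: float = 0.5,
                      ) -> tuple[list[ProtospacerLocus], MaskedContigSet]:
    """Full protospacer stage: mask, map, flank-validate.

    Every candidate locus is returned with ``validated`` set and a
    human-readable ``reason`` when rejected.
    """
    masked = mask_crispr_loci(contigs, drs, min_identity, mask_flank)
    loci = map_spacers(spacers, masked, min_identity)
    dr_by_id = {d.dr_id: d for d in drs}
    seq_by_id = {c.id: c.seq for c in contigs}
    for locus in loci:
        dr_seqs = [dr_by_id[d].seq for d in sorted(locus.dr_ids) if d in dr_by_id]
        flank_len = max((len(s) for s in dr_seqs), default=mask_flank)
        f5, f3 = extract_flanks(locus, seq_by_id[locus.interval.contig_id], flank_len)
        locus.flank5, locus.flank3 = f5, f3
        ok = all(validate_flanks(f5, f3, s, ratio_cutoff) for s in dr_seqs) \
            if dr_seqs else validate_flanks(f5, f3, "", ratio_cutoff)
        locus.validated = ok
        locus.reason = "" if ok else "flank_alignment_ratio"
    return loci, masked
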