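"""CRISPR array detection on contigs and spacer extraction from reads.

Array detection is a minimal CRT-style detector: it seeds on exact
repeated k-mers with regular spacing compatible with a repeat+spacer
period, extends each seed chain to the maximal repeat, and reports
arrays with at least ``min_copies`` copies whose repeat and spacer
lengths fall in the configured bounds.  The consensus direct repeat (DR)
is the column-wise majority over repeat copies.

Spacers are taken from raw reads, not contigs: every DR occurrence on a
read (either strand, including partial copies of at least
``min_dr_match_len`` bases at read ends) is masked, and sequences lying
strictly between two masked intervals are extracted as spacers.
Read-terminal fragments are never spacers — a segment must be bounded by
DR sequence on both sides.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import _scan
from .seqcore import Interval, SeqRecord, canonical, revcomp

DEFAULT_REPEAT_LEN = (23, 55)
DEFAULT_SPACER_LEN = (20, 60)


@dataclass
class CrisprArray:
    contig_id: str
    repeat_intervals: list[Interval]
    spacer_intervals: list[Interval]
    consensus_dr: str

    @property
    def start(self) -> int:
        return self.repeat_intervals[0].start

    @property
    def end(self) -> int:
        return self.repeat_intervals[-1].end

    @property
    def n_copies(self) -> int:
        return len(self.repeat_intervals)


@dataclass
class DirectRepeat:
    dr_id: str
    seq: str
    source_arrays: list[CrisprArray] = field(default_factory=list)


@dataclass
class Spacer:
    """A unique spacer.

    ``seq`` is the canonical orientation (lexicographic min of the
    sequence and its reverse complement) and defines uniqueness;
    ``oriented_seq`` is the majority orientation relative to the
    detected direct repeat, which keeps the spacers of one array in a
    consistent frame so that protospacer-adjacent motifs line up.
    """

    spacer_id: str
    seq: str                    # canonical orientation
    oriented_seq: str = ""      # DR-frame orientation
    associated_drs: set[str] = field(default_factory=set)
    read_support: int = 0

    def __post_init__(self) -> None:
        if not self.oriented_seq:
            self.oriented_seq = self.seq


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------

def _consensus(columns: list[str]) -> str:
    out = []
    for col in zip(*columns):
        counts = Counter(col)
        # deterministic majority: count desc, then base alphabetically
        out.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def detect_arrays(contig: SeqRecord, min_copies: int = 3,
                  repeat_len: tuple[int, int] = DEFAULT_REPEAT_LEN,
                  spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
                  max_repeat_mismatch: int = 1, seed_k: int = 13) -> list[CrisprArray]:
    """Detect CRISPR arrays in one contig (>= 1 kb) by seeded repeat extension."""
    seq = contig.seq
    n = len(seq)
    if n < 1000:
        return []
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    period_min, period_max = rmin + smin, rmax + smax

    kmer_pos: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        kmer_pos[seq[i:i + seed_k]].append(i)

    candidates: list[tuple[list[int], int, int]] = []  # (starts, left_ext, right_ext)
    seen_chains: set[tuple[int, ...]] = set()
    for positions in kmer_pos.values():
        if len(positions) < min_copies:
            continue
        # chain positions whose consecutive gaps look like repeat+spacer periods
        chain = [positions[0]]
        chains = []
        for p in positions[1:]:
            if period_min <= p - chain[-1] <= period_max:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for ch in chains:
            if len(ch) < min_copies:
                continue
            key = tuple(ch)
            if key in seen_chains:
                continue
            seen_chains.add(key)
            candidates.append(ch)

    arrays: list[CrisprArray] = []
    for chain in candidates:
        starts = list(chain)
        m = len(starts)
        # extend left/right while all copies agree; spacer bounds are
        # validated after extension, which discards any over-extension
        left = 0
        while (seed_k + left < rmax and starts[0] - left - 1 >= 0):
            col = {seq[s - left - 1] for s in starts}
            if len(col) != 1 or "N" in col:
                break
            left += 1
        right = 0
        while (seed_k + left + right < rmax and starts[-1] + seed_k + right < n):
            col = {seq[s + seed_k + right] for s in starts}
            if len(col) != 1 or "N" in col:
                break
            right += 1
        rep_len = seed_k + left + right
        if not (rmin <= rep_len <= rmax):
            continue
        rep_starts = [s - left for s in starts]
        spacer_ivals = []
        ok = True
        for i in range(m - 1):
            s0 = rep_starts[i] + rep_len
            s1 = rep_starts[i + 1]
            if not (smin <= s1 - s0 <= smax):
                ok = False
                break
            spacer_ivals.append(Interval(contig.id, s0, s1))
        if not ok:
            continue
        rep_ivals = [Interval(contig.id, s, s + rep_len) for s in rep_starts]
        copies = [seq[iv.start:iv.end] for iv in rep_ivals]
        ref = copies[0]
        if any(sum(a != b for a, b in zip(ref, c)) > max_repeat_mismatch
               for c in copies[1:]):
            continue
        arrays.append(CrisprArray(contig.id, rep_ivals, spacer_ivals,
                                  _consensus(copies)))

    # keep maximal non-overlapping arrays, preferring more copies then longer repeat
    arrays.sort(key=lambda a: (-a.n_copies, -(a.end - a.start), a.start))
    kept: list[CrisprArray] = []
    for arr in arrays:
        if all(arr.end <= k.start or arr.start >= k.end for k in kept):
            kept.append(arr)
    kept.sort(key=lambda a: a.start)
    return kept


def collect_drs(arrays: list[CrisprArray]) -> list[DirectRepeat]:
    """Deduplicate array consensus repeats at 100% identity incl. reverse complement."""
    by_canon: dict[str, DirectRepeat] = {}
    for arr in arrays:
        key = canonical(arr.consensus_dr)
        if key not in by_canon:
            by_canon[key] = DirectRepeat(f"DR{len(by_canon) + 1:04d}", arr.consensus_dr)
        by_canon[key].source_arrays.append(arr)
    return list(by_canon.values())


# ---------------------------------------------------------------------------
# read masking and spacer extraction
# ---------------------------------------------------------------------------

MaskIv = tuple[int, int, frozenset[str], str]  # start, end, dr_ids, DR orient


def _merge_intervals(ivals: list[MaskIv]) -> list[MaskIv]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [ivals[0]]
    for s, e, drs, orient in ivals[1:]:
        ms, me, mdrs, morient = merged[-1]
        if s <= me:
            merged[-1] = (ms, max(me, e), mdrs | drs, morient)
        else:
            merged.append((s, e, drs, orient))
    return merged


def mask_reads(reads: list[SeqRecord], drs: list[DirectRepeat],
               min_dr_match_len: int = 18, max_mismatch: int = 1,
               ) -> dict[str, list[MaskIv]]:
    """Mask every DR occurrence (either strand) in each read.

    Partial DR copies of at least ``min_dr_match_len`` bases at read ends
    are masked as well.  Returns, per read id, merged
    (start, end, dr_ids, orient) intervals, where orient records whether
    the stored DR orientation ('+') or its reverse complement ('-')
    matched; reads with no hit are absent from the result.
    """
    if not reads or not drs:
        return {}
    pad = max(len(d.seq) for d in drs)
    text = _scan.ConcatText.from_seqs([r.id for r in reads],
                                      [r.seq for r in reads], pad=pad)
    raw: dict[int, list[MaskIv]] = defaultdict(list)
    lengths = text.lengths
    for dr in drs:
        patterns = [("+", dr.seq)]
        if revcomp(dr.seq) != dr.seq:
            patterns.append(("-", revcomp(dr.seq)))
        for orient, pat_seq in patterns:
            pat = _scan.encode_pattern(pat_seq)
            L = len(pat)
            pos, _real = _scan.scan_hits_wildcard(
                text.data, pat, max_mismatch, min_dr_match_len)
            if len(pos) == 0:
                continue
            idx, off = text.locate(pos)
            tag = frozenset({dr.dr_id})
            for ridx, o in zip(idx, off):
                s = max(0, int(o))
                e = min(int(lengths[ridx]), int(o) + L)
                if e - s >= min_dr_match_len:
                    raw[int(ridx)].append((s, e, tag, orient))
    return {text.ids[ridx]: _merge_intervals(ivals) for ridx, ivals in raw.items()}


def extract_spacers(read: SeqRecord, masked: list[MaskIv],
                    spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
                    ) -> list[tuple[str, str, frozenset[str]]]:
    """Sequences strictly between two masked intervals.

    Returns (canonical sequence, DR-frame oriented sequence, union of
    bounding DR ids).  The oriented sequence follows the orientation of
    the left bounding DR hit, so spacers of one array stay in one frame
    regardless of which read strand they were seen on.
    """
    smin, smax = spacer_len
    out = []
    for (s0, e0, d0, o0), (s1, e1, d1, o1) in zip(masked, masked[1:]):
        seg = read.seq[e0:s1]
        if smin <= len(seg) <= smax and "N" not in seg:
            oriented = seg if o0 == "+" else revcomp(seg)
            out.append((canonical(seg), oriented, d0 | d1))
    return out


def dedupe_spacers(occurrences: list[tuple[str, str, frozenset[str]]],
                   ) -> list[Spacer]:
    """Collapse exact duplicates (canonical orientation), tallying support.

    The representative oriented sequence is the majority DR-frame
    orientation over occurrences (ties broken toward the canonical form).
    """
    by_seq: dict[str, Spacer] = {}
    votes: dict[str, Counter] = defaultdict(Counter)
    for canon, oriented, drs in occurrences:
        sp = by_seq.get(canon)
        if sp is None:
            sp = Spacer(f"SP{len(by_seq) + 1:05d}", canon)
            by_seq[canon] = sp
        sp.read_support += 1
        sp.associated_drs |= drs
        votes[canon][oriented] += 1
    for canon, sp in by_seq.items():
        best = sorted(votes[canon].items(), key=lambda kv: (-kv[1], kv[0]))
        sp.oriented_seq = best[0][0]
    return list(by_seq.values())


def extract_all_spacers(reads: list[SeqRecord], drs: list[DirectRepeat],
                        min_dr_match_len: int = 18, max_mismatch: int = 1,
                        spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
                        ) -> list[Spacer]:
    """mask_reads + extract_spacers + dedupe_spacers over a read set."""
    masks = mask_reads(reads, drs, min_dr_match_len, max_mismatch)
    by_id = {r.id: r for r in reads}
    occ: list[tuple[str, str, frozenset[str]]] = []
    for rid, ivals in masks.items():
        occ.extend(extract_spacers(by_id[rid], ivals, spacer_len))
    return dedupe_spacers(occ)
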