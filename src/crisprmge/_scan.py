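"""Vectorized fixed-length (Hamming) pattern scanning over DNA.

All mapping steps in the pipeline — read masking with direct repeats,
CRISPR-locus masking on contigs, spacer-to-contig mapping and the
remnant-spacer identity sweep — are full-length, substitution-only scans
with an identity threshold.  This module provides one shifted-equality
implementation for them: for a pattern of length L over a text of length
n it performs L vectorized comparisons of length n-L+1, accumulating
mismatch counts per window.

Texts may be concatenations of many sequences joined by separator runs;
separators never match.  A wildcard variant treats separator positions
as free matches so that pattern occurrences hanging off a sequence end
(read-end partial repeats) are still found, subject to a minimum number
of real (in-sequence) matched positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# encoding: A,C,G,T -> 1..4; N -> 0 in text (matches nothing; pattern N -> 255)
_TEXT_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _TEXT_LUT[ord(_b)] = _i
SEP_CODE = np.uint8(250)
_TEXT_LUT[ord("#")] = SEP_CODE

_PAT_LUT = _TEXT_LUT.copy()
_PAT_LUT[ord("N")] = 255


def encode_text(seq: str) -> np.ndarray:
    return _TEXT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_pattern(seq: str) -> np.ndarray:
    return _PAT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ConcatText:
    """Several sequences packed into one encoded array with separator runs."""

    ids: list[str]
    starts: np.ndarray   # start offset of each sequence in the packed array
    lengths: np.ndarray
    data: np.ndarray

    @classmethod
    def from_seqs(cls, ids: list[str], seqs: list[str], pad: int) -> "ConcatText":
        sep = "#" * pad
        packed = sep + sep.join(seqs) + sep  # outer runs allow end-overlaps
        starts = np.empty(len(seqs), dtype=np.int64)
        off = pad
        for i, s in enumerate(seqs):
            starts[i] = off
            off += len(s) + pad
        return cls(
            ids=list(ids),
            starts=starts,
            lengths=np.array([len(s) for s in seqs], dtype=np.int64),
            data=encode_text(packed),
        )

    def locate(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map packed window-start positions to (sequence index, offset).

        A window starting inside a separator run belongs to the
        following sequence (its offset is then negative): such windows
        arise from patterns hanging off a sequence start.
        """
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        idx0 = np.clip(idx, 0, None)
        off = pos - self.starts[idx0]
        roll = (idx < 0) | (off >= self.lengths[idx0])
        idx_final = np.clip(np.where(roll & (idx >= 0), idx0 + 1, idx0),
                            0, len(self.starts) - 1)
        return idx_final, pos - self.starts[idx_final]


def mismatch_counts(text: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Per-window mismatch counts of pattern against text (no wildcards)."""
    L = len(pattern)
    n = len(text) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mism += text[j:j + n] != pattern[j]
    return mism


def scan_hits(text: np.ndarray, pattern: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Window start positions where the pattern matches with <= max_mismatch."""
    mism = mismatch_counts(text, pattern)
    return np.nonzero(mism <= max_mismatch)[0]


def scan_hits_wildcard(text: np.ndarray, pattern: np.ndarray, max_mismatch: int,
                       min_real: int) -> tuple[np.ndarray, np.ndarray]:
    """Scan treating separator positions as free matches.

    Returns (positions, real_overlap) where real_overlap counts pattern
    positions landing on non-separator text.  A window is reported when
    its real mismatches are <= max_mismatch and real_overlap >= min_real.
    Windows spanning two sequences are impossible as long as the
    separator run is at least the pattern length.
    """
    L = len(pattern)
    n = len(text) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
    mism = np.zeros(n, dtype=np.int32)
    sep = np.zeros(n, dtype=np.int32)
    for j in range(L):
        window = text[j:j + n]
        is_sep = window == SEP_CODE
        mism += (window != pattern[j]) & ~is_sep
        sep += is_sep
    real = L - sep
    ok = (mism <= max_mismatch) & (real >= min_real)
    pos = np.nonzero(ok)[0]
    return pos, real[pos]


def best_identities(text: np.ndarray, patterns: list[np.ndarray]) -> np.ndarray:
    """Best full-length identity of each pattern anywhere in the text.

    Used by the remnant-spacer sweep: one scan yields the maximum over
    window positions of matches/L per pattern, after which hit counts at
    every identity threshold are threshold comparisons.
    """
    out = np.zeros(len(patterns), dtype=np.float64)
    for i, pat in enumerate(patterns):
        mism = mismatch_counts(text, pat)
        if len(mism):
            out[i] = 1.0 - mism.min() / len(pat)
    return out
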