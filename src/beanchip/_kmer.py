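"""Exact k-mer counting and seeded exact-match search over a scaffold set.

2-bit encodes ACGT k-mers into uint64 (k <= 31) and answers occurrence
queries with a sorted array + binary search.  Windows containing non-ACGT
characters are simply absent from the index, which matches the biology:
an N can never be part of an exact probe-arm match.
"""

from __future__ import annotations

import numpy as np

from .types import revcomp

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase


def encode_kmer(s: str) -> int | None:
    """2-bit encode one k-mer; None if it contains a non-ACGT character."""
    codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        return None
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping k-mers of ``seq`` as uint64, plus a validity mask."""
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit uint64 encoding")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    acc = np.zeros(n, dtype=np.uint64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        invalid |= window < 0
        acc = (acc << np.uint64(2)) | window.astype(np.uint64)
    return acc, ~invalid


class KmerIndex:
    """Sorted-array index of every valid k-mer position in a scaffold set."""

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.scaffold_ids = list(sequences)
        kmer_parts, scaf_parts, off_parts = [], [], []
        for si, sid in enumerate(self.scaffold_ids):
            kmers, valid = encode_kmers(sequences[sid], k)
            idx = np.flatnonzero(valid)
            kmer_parts.append(kmers[idx])
            scaf_parts.append(np.full(idx.size, si, dtype=np.int32))
            off_parts.append(idx.astype(np.int64))
        kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, dtype=np.uint64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._scaf = (
            np.concatenate(scaf_parts)[order] if scaf_parts else np.empty(0, dtype=np.int32)
        )
        self._off = np.concatenate(off_parts)[order] if off_parts else np.empty(0, dtype=np.int64)

    def _range(self, kmer_val: int) -> tuple[int, int]:
        v = np.uint64(kmer_val)
        lo = int(np.searchsorted(self._kmers, v, side="left"))
        hi = int(np.searchsorted(self._kmers, v, side="right"))
        return lo, hi

    def count(self, kmer: str) -> int:
        """Forward-strand occurrence count of ``kmer``."""
        val = encode_kmer(kmer)
        if val is None:
            return 0
        lo, hi = self._range(val)
        return hi - lo

    def count_both_strands(self, kmer: str) -> int:
        """Occurrences counting both strands; a k-mer and its reverse
        complement are the same occurrence (a palindrome counts once)."""
        rc = revcomp(kmer)
        n = self.count(kmer)
        if rc != kmer:
            n += self.count(rc)
        return n

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        """Forward-strand (scaffold_id, 0-based offset) hits of ``kmer``."""
        val = encode_kmer(kmer)
        if val is None:
            return []
        lo, hi = self._range(val)
        return [
            (self.scaffold_ids[int(s)], int(o))
            for s, o in zip(self._scaf[lo:hi], self._off[lo:hi])
        ]


def count_occurrences_bruteforce(sequences: dict[str, str], kmer: str) -> int:
    """Quadratic both-strand occurrence counter (test oracle for small genomes)."""
    rc = revcomp(kmer)
    total = 0
    for seq in sequences.values():
        for query in {kmer, rc}:
            start = 0
            while True:
                hit = seq.find(query, start)
                if hit < 0:
                    break
                total += 1
                start = hit + 1
    return total
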