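"""Internal short-read matcher.

An exact all-placements matcher under a Hamming-distance threshold
(substitutions only, no indels, both strands), used in place of an
external aligner for desk-scale work and in the test suite. The
implementation is a pigeonhole seed-and-extend search: a read is split
into ``max_mismatch + 1`` disjoint pieces, so any placement with at
most ``max_mismatch`` mismatches contains at least one exact piece; an
exact k-mer index over the targets then enumerates every candidate,
each verified by direct comparison. The placement set is therefore
identical to a naive full scan.

Ambiguity characters (N and anything outside A/C/G/T) never match,
including against themselves, so spacer sequence in pseudogenomes can
never be part of an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DEFAULT_MAX_MISMATCH = 2


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True, order=True, slots=True)
class Placement:
    """One alignment of a read: target name, 0-based start on the target's
    plus strand, read orientation, and mismatch count."""

    target: str
    pos: int
    strand: str
    mismatches: int


class KmerIndex:
    """Exact k-mer index over a set of target sequences.

    ``find`` returns every placement of a read with at most
    ``max_mismatch`` substitutions, on both strands, in deterministic
    (target, pos, strand) order.
    """

    def __init__(self, targets: Mapping[str, str], max_mismatch: int = DEFAULT_MAX_MISMATCH):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.max_mismatch = max_mismatch
        self.names: list[str] = list(targets)
        seqs = [targets[n] for n in self.names]
        if seqs:
            self._codes = np.concatenate([encode(s) for s in seqs])
        else:
            self._codes = np.zeros(0, dtype=np.uint8)
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        self._starts = np.zeros(len(seqs), dtype=np.int64)
        if len(seqs):
            self._starts[1:] = np.cumsum(lens)[:-1]
        self._ends = self._starts + lens
        # per-k sorted (hash, position) tables, built lazily
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _table(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        tab = self._tables.get(k)
        if tab is not None:
            return tab
        codes = self._codes
        n = codes.size
        if n < k:
            tab = (np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=np.int64))
            self._tables[k] = tab
            return tab
        h = np.zeros(n - k + 1, dtype=np.uint64)
        for j in range(k):
            h = (h << np.uint64(2)) | (codes[j : j + n - k + 1] & np.uint8(3)).astype(np.uint64)
        bad = (codes > 3).astype(np.int64)
        cb = np.concatenate([[0], np.cumsum(bad)])
        valid = (cb[k:] - cb[:-k]) == 0
        pos = np.flatnonzero(valid).astype(np.int64)
        hv = h[pos]
        order = np.argsort(hv, kind="stable")
        tab = (hv[order], pos[order])
        self._tables[k] = tab
        return tab

    @staticmethod
    def _seed_hash(codes: np.ndarray) -> int:
        h = 0
        for c in codes:
            h = (h << 2) | (int(c) & 3)
        return h

    def _find_oriented(self, codes: np.ndarray, m: int) -> Iterator[tuple[int, int, int]]:
        """Yield (target_index, local_pos, mismatches) for one orientation."""
        L = codes.size
        base = L // (m + 1)
        if base < 1:
            raise ValueError(f"read of length {L} too short for max_mismatch={m}")
        k = min(base, 31)
        sh, spos = self._table(k)
        if sh.size == 0:
            return
        cand_parts = []
        for i in range(m + 1):
            off = i * base
            h = np.uint64(self._seed_hash(codes[off : off + k]))
            lo = int(np.searchsorted(sh, h, side="left"))
            hi = int(np.searchsorted(sh, h, side="right"))
            if hi > lo:
                cand_parts.append(spos[lo:hi] - off)
        if not cand_parts:
            return
        c = np.unique(np.concatenate(cand_parts))
        c = c[(c >= 0) & (c + L <= self._codes.size)]
        if c.size == 0:
            return
        ti = np.searchsorted(self._starts, c, side="right") - 1
        ok = c + L <= self._ends[ti]
        c, ti = c[ok], ti[ok]
        if c.size == 0:
            return
        win = self._codes[c[:, None] + np.arange(L)]
        mm = ((win != codes[None, :]) | (win > 3) | (codes[None, :] > 3)).sum(axis=1)
        keep = mm <= m
        for s, t, q in zip(c[keep], ti[keep], mm[keep]):
            yield int(t), int(s - self._starts[t]), int(q)

    def find(self, read: str, max_mismatch: int | None = None) -> list[Placement]:
        m = self.max_mismatch if max_mismatch is None else max_mismatch
        hits: list[Placement] = []
        for strand, seq in (("+", read), ("-", revcomp(read))):
            codes = encode(seq)
            for t, p, q in self._find_oriented(codes, m):
                hits.append(Placement(self.names[t], p, strand, q))
        hits.sort()
        return hits

    def find_targets(self, read: str, max_mismatch: int | None = None) -> set[str]:
        """Names of targets with at least one placement of the read."""
        return {pl.target for pl in self.find(read, max_mismatch)}
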