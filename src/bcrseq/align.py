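"""Local (Smith-Waterman) alignment of reads against germline segments.

A single numba-compiled affine-gap kernel produces the optimal local score,
its coordinates, and the traceback path.  The path is what makes boundary
migration possible: reference anchor positions are projected onto the read
through the per-column coordinate pairs.

Conventions
-----------
* A gap of length L costs ``gap_open + L * gap_extend`` (both penalties are
  negative numbers).
* Ties on the optimal score are broken toward the smallest read start, then
  the smallest reference start, then the smallest end coordinates, so results
  are deterministic.
* Coordinates are 0-based half-open on both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring parameters (penalties negative)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentResult:
    """Optimal local alignment of a read region against one reference."""

    segment_id: str | None
    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    identity: float
    #: aligned (read_pos, ref_pos) pairs for match/mismatch columns
    pairs: np.ndarray = field(default=None, repr=False)

    def ref_to_read(self, ref_pos: int) -> int | None:
        """Read coordinate aligned to ``ref_pos``, or None if gapped/uncovered."""
        if self.pairs is None or len(self.pairs) == 0:
            return None
        idx = np.searchsorted(self.pairs[:, 1], ref_pos)
        if idx < len(self.pairs) and self.pairs[idx, 1] == ref_pos:
            return int(self.pairs[idx, 0])
        return None

    def shift_read(self, offset: int) -> "AlignmentResult":
        """Translate read coordinates by ``offset`` (for windowed searches)."""
        pairs = None if self.pairs is None else self.pairs + np.array([offset, 0])
        return AlignmentResult(self.segment_id, self.score,
                               self.read_start + offset, self.read_end + offset,
                               self.ref_start, self.ref_end, self.identity, pairs)


@njit(cache=True)
def _sw_kernel(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = r.shape[0]
    NEG = np.int32(-(10 ** 9) // 2)
    # interior cells are always written before being read (row-major sweep),
    # so only the boundary row/column needs initialization
    H = np.empty((n + 1, m + 1), np.int32)
    E = np.empty((n + 1, m + 1), np.int32)
    F = np.empty((n + 1, m + 1), np.int32)
    # origin (alignment start) of the best path into each H/E/F cell
    oHi = np.empty((n + 1, m + 1), np.int32)
    oHj = np.empty((n + 1, m + 1), np.int32)
    oEi = np.empty((n + 1, m + 1), np.int32)
    oEj = np.empty((n + 1, m + 1), np.int32)
    oFi = np.empty((n + 1, m + 1), np.int32)
    oFj = np.empty((n + 1, m + 1), np.int32)
    dH = np.empty((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    dE = np.empty((n + 1, m + 1), np.uint8)  # 1 open, 2 extend
    dF = np.empty((n + 1, m + 1), np.uint8)
    for j in range(m + 1):
        H[0, j] = 0
        E[0, j] = NEG
        F[0, j] = NEG
        oHi[0, j] = 0
        oHj[0, j] = j
        dH[0, j] = 0
    for i in range(n + 1):
        H[i, 0] = 0
        E[i, 0] = NEG
        F[i, 0] = NEG
        oHj[i, 0] = 0
        oHi[i, 0] = i
        dH[i, 0] = 0

    best = np.int32(0)
    boi = np.int32(0); boj = np.int32(0)
    bei = np.int32(0); bej = np.int32(0)
    found = False

    for i in range(1, n + 1):
        oHi[i, 0] = i
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open; dE[i, j] = 1
                oEi[i, j] = oHi[i, j - 1]; oEj[i, j] = oHj[i, j - 1]
            else:
                E[i, j] = e_ext; dE[i, j] = 2
                oEi[i, j] = oEi[i, j - 1]; oEj[i, j] = oEj[i, j - 1]
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open; dF[i, j] = 1
                oFi[i, j] = oHi[i - 1, j]; oFj[i, j] = oHj[i - 1, j]
            else:
                F[i, j] = f_ext; dF[i, j] = 2
                oFi[i, j] = oFi[i - 1, j]; oFj[i, j] = oFj[i - 1, j]
            s = match if q[i - 1] == r[j - 1] else mismatch
            hv = H[i - 1, j - 1] + s
            d = np.uint8(1)
            oi = oHi[i - 1, j - 1]; oj = oHj[i - 1, j - 1]
            if E[i, j] > hv:
                hv = E[i, j]; d = np.uint8(2)
                oi = oEi[i, j]; oj = oEj[i, j]
            if F[i, j] > hv:
                hv = F[i, j]; d = np.uint8(3)
                oi = oFi[i, j]; oj = oFj[i, j]
            if hv <= 0:
                hv = np.int32(0); d = np.uint8(0)
                oi = np.int32(i); oj = np.int32(j)
            H[i, j] = hv; dH[i, j] = d
            oHi[i, j] = oi; oHj[i, j] = oj
            if hv > 0:
                better = hv > best
                if (not better) and hv == best:
                    # tie: smallest (read_start, ref_start, read_end, ref_end)
                    if (oi, oj, np.int32(i), np.int32(j)) < (boi, boj, bei, bej):
                        better = True
                if better or not found:
                    if hv >= best:
                        best = hv
                        boi = oi; boj = oj
                        bei = np.int32(i); bej = np.int32(j)
                        found = True

    # traceback from (bei, bej) collecting aligned base pairs
    max_pairs = n if n < m else m
    pq = np.empty(max_pairs, np.int32)
    pr = np.empty(max_pairs, np.int32)
    npairs = 0
    matches = 0
    cols = 0
    if found:
        i = bei; j = bej
        state = np.uint8(1)  # 1=H, 2=E, 3=F
        while not (i == boi and j == boj):
            if state == 1:
                d = dH[i, j]
                if d == 1:
                    pq[npairs] = i - 1; pr[npairs] = j - 1
                    npairs += 1
                    cols += 1
                    if q[i - 1] == r[j - 1]:
                        matches += 1
                    i -= 1; j -= 1
                elif d == 2:
                    state = np.uint8(2)
                elif d == 3:
                    state = np.uint8(3)
                else:
                    break
            elif state == 2:
                cols += 1
                if dE[i, j] == 1:
                    state = np.uint8(1)
                j -= 1
            else:
                cols += 1
                if dF[i, j] == 1:
                    state = np.uint8(1)
                i -= 1
    return best, boi, boj, bei, bej, pq[:npairs][::-1], pr[:npairs][::-1], matches, cols


@njit(cache=True)
def _sw_score(q, r, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Optimal local score only (rolling rows, no traceback)."""
    n = q.shape[0]
    m = r.shape[0]
    NEG = np.int32(-(10 ** 9) // 2)
    Hp = np.zeros(m + 1, np.int32)   # previous row of H
    Hc = np.zeros(m + 1, np.int32)
    Fc = np.full(m + 1, NEG, np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        e = NEG
        Hc[0] = 0
        for j in range(1, m + 1):
            e_open = Hc[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            e = e_open if e_open >= e_ext else e_ext
            f_open = Hp[j] + gap_open + gap_extend
            f_ext = Fc[j] + gap_extend
            f = f_open if f_open >= f_ext else f_ext
            Fc[j] = f
            s = match if q[i - 1] == r[j - 1] else mismatch
            hv = Hp[j - 1] + s
            if e > hv:
                hv = e
            if f > hv:
                hv = f
            if hv < 0:
                hv = np.int32(0)
            Hc[j] = hv
            if hv > best:
                best = hv
        Hp, Hc = Hc, Hp
    return best


def sw_score(query: str, ref: str, scoring: Scoring = DEFAULT_SCORING) -> int:
    """Optimal local alignment score only (fast path for candidate ranking)."""
    if not query or not ref:
        raise ValueError("sw_score requires non-empty sequences")
    return int(_sw_score(_encode(query), _encode(ref),
                         np.int32(scoring.match), np.int32(scoring.mismatch),
                         np.int32(scoring.gap_open), np.int32(scoring.gap_extend)))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def smith_waterman(query: str, ref: str,
                   scoring: Scoring = DEFAULT_SCORING,
                   segment_id: str | None = None) -> AlignmentResult:
    """Optimal local alignment of ``query`` (read) against ``ref`` (germline).

    Returns a degenerate zero-score result (empty coordinates) when no
    positive-scoring alignment exists.
    """
    if not query or not ref:
        raise ValueError("smith_waterman requires non-empty sequences")
    score, qs, rs, qe, re_, pq, pr, matches, cols = _sw_kernel(
        _encode(query), _encode(ref),
        np.int32(scoring.match), np.int32(scoring.mismatch),
        np.int32(scoring.gap_open), np.int32(scoring.gap_extend))
    if score <= 0:
        return AlignmentResult(segment_id, 0, 0, 0, 0, 0, 0.0,
                               np.empty((0, 2), np.int32))
    pairs = np.column_stack((pq, pr)).astype(np.int32)
    identity = matches / cols if cols else 0.0
    return AlignmentResult(segment_id, int(score), int(qs), int(qe),
                           int(rs), int(re_), float(identity), pairs)
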