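"""Germline segment assignment, CDR3 boundary migration, productivity calls.

Merged reads are mapped by Smith-Waterman local alignment to germline V, D,
J and C references.  The CDR3 is then obtained by *boundary migration*: the
anchor codon positions annotated on the germline V and J references are
projected through the alignment coordinate maps onto the read, and the read
bases strictly between the two anchor codons are reported as the CDR3
(anchors excluded, so a heavy-chain CDR3 reads e.g. ``ARSIVGATFDY`` rather
than ``CARSIVGATFDYW``).

D segments are searched only inside the junction window between the V and J
alignments; isotype subclasses (IgG1 vs IgG3, ...) are reported only when
the best constant-region alignment clears the runner-up by a score margin,
otherwise the call falls back to class level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .align import (AlignmentResult, Scoring, DEFAULT_SCORING, smith_waterman,
                    sw_score)
from .germline import GermlineDatabase, CHAINS
from .reads import MergedRead
from .translate import translate, has_stop


@dataclass(frozen=True)
class AnnotatedRearrangement:
    """One fully annotated read: segment calls, CDR3, productivity."""

    read_id: str
    sample_id: str | None
    chain: str
    v_call: str
    j_call: str
    d_call: str | None
    c_call: str | None
    isotype: str | None          # heavy chain only; may be class-level ("IgG")
    cdr3_nt: str
    cdr3_aa: str                 # empty when out of frame
    junction_nt: str             # anchor-inclusive nucleotide junction
    in_frame: bool
    stop_codon: bool
    productive: bool
    v_score: int = 0
    j_score: int = 0


@dataclass(frozen=True)
class Reject:
    """Read that could not be annotated, with a coded reason."""

    read_id: str
    reason: str  # no_v | no_j | chain_mismatch | boundary_conflict | anchor_uncovered


@dataclass(frozen=True)
class AnnotationParams:
    scoring: Scoring = DEFAULT_SCORING
    min_score_v: int = 50
    min_score_j: int = 20
    min_score_c: int = 20
    min_score_d: int = 12
    subclass_margin: int = 8
    v_window: int = 340   # V genes sit at the 5' end of the amplicon


def _best_hit(query: str, segments, scoring: Scoring,
              offset: int = 0) -> tuple[AlignmentResult | None, int]:
    """Best-scoring alignment over ``segments``; also the runner-up score.

    Candidates are ranked with the score-only kernel; the full alignment
    (coordinates + traceback) is computed once, for the winner.  Score ties
    go to the first segment in database order.
    """
    best_seg = None
    best_score = 0
    runner = 0
    for seg in segments:
        score = sw_score(query, seg.sequence, scoring)
        if best_seg is None or score > best_score:
            runner = best_score
            best_score = score
            best_seg = seg
        elif score > runner:
            runner = score
    if best_seg is None:
        return None, 0
    best = smith_waterman(query, best_seg.sequence, scoring, best_seg.segment_id)
    if offset:
        best = best.shift_read(offset)
    return best, runner


def migrate_cdr3(m: MergedRead, v_aln: AlignmentResult, j_aln: AlignmentResult,
                 db: GermlineDatabase) -> tuple[int, int] | None:
    """Project germline anchor codons onto the read through the alignments.

    Returns half-open read coordinates ``(cdr3_start, cdr3_end)`` — the span
    strictly between the V anchor codon and the J anchor codon — or None if
    either anchor codon is not covered by its alignment.  An inverted span
    (``cdr3_start > cdr3_end``) signals a boundary conflict and is returned
    as such for the caller to reject.
    """
    v_anchor = db[v_aln.segment_id].anchor_pos
    j_anchor = db[j_aln.segment_id].anchor_pos
    if not (v_aln.ref_start <= v_anchor and v_aln.ref_end >= v_anchor + 3):
        return None
    if not (j_aln.ref_start <= j_anchor and j_aln.ref_end >= j_anchor + 3):
        return None
    start = _project_boundary(v_aln, v_anchor + 3, side="left")
    end = _project_boundary(j_aln, j_anchor, side="right")
    if start is None or end is None:
        return None
    return start, end


def _project_boundary(aln: AlignmentResult, ref_pos: int,
                      side: str) -> int | None:
    """Read coordinate of a reference boundary, lifted through the alignment.

    When the boundary base itself sits in a gap column, the coordinate is
    extrapolated from the nearest aligned pair on the anchor's side (5' pair
    for the V anchor end, 3' pair for the J anchor start), assuming local
    colinearity — the standard coordinate-lifting convention.
    """
    pairs = aln.pairs
    if pairs is None or len(pairs) == 0:
        return None
    refs = pairs[:, 1]
    if side == "left":
        idx = np.searchsorted(refs, ref_pos) - 1   # last pair with ref < ref_pos
        if idx < 0:
            return None
        qi, ri = pairs[idx]
        return int(qi + (ref_pos - ri))
    idx = np.searchsorted(refs, ref_pos)           # first pair with ref >= ref_pos
    if idx >= len(pairs):
        return None
    qi, ri = pairs[idx]
    return int(qi - (ri - ref_pos))


def call_productivity(cdr3_nt: str, flank5: str = "", flank3: str = ""
                      ) -> dict[str, bool]:
    """In-frame / stop-codon / productive flags for an extracted CDR3.

    ``flank5``/``flank3`` are the anchor codons read off the read itself, so
    a stop introduced into an anchor also marks the sequence non-functional.
    """
    in_frame = len(cdr3_nt) % 3 == 0
    stop = has_stop(flank5 + cdr3_nt + flank3) if in_frame else has_stop(cdr3_nt)
    return {"in_frame": in_frame, "stop_codon": stop,
            "productive": in_frame and not stop}


def _class_level(isotype: str) -> str:
    """IgG1 -> IgG, IgA2 -> IgA; IgM/IgD/IgE unchanged."""
    return isotype[:3]


def annotate_read(m: MergedRead, db: GermlineDatabase,
                  params: AnnotationParams = AnnotationParams()
                  ) -> AnnotatedRearrangement | Reject:
    """Assign germline segments to one merged read and extract its CDR3."""
    scoring = params.scoring
    # best V over all chains decides the chain
    best_v: AlignmentResult | None = None
    v_query = m.seq[:params.v_window]
    for chain in CHAINS:
        hit, _ = _best_hit(v_query, db.select(chain, "V"), scoring)
        if hit and (best_v is None or hit.score > best_v.score):
            best_v = hit
    if best_v is None or best_v.score < params.min_score_v:
        return Reject(m.read_id, "no_v")
    chain = db[best_v.segment_id].chain

    # best J over all chains (searched 3' of the V alignment); a stronger J
    # from another chain marks the read chimeric
    j_from = max(best_v.read_end - 6, 0)
    j_query = m.seq[j_from:]
    best_j: AlignmentResult | None = None
    for c in CHAINS:
        hit, _ = _best_hit(j_query, db.select(c, "J"), scoring, offset=j_from)
        if hit and (best_j is None or hit.score > best_j.score):
            best_j = hit
    if best_j is None or best_j.score < params.min_score_j:
        return Reject(m.read_id, "no_j")
    if db[best_j.segment_id].chain != chain:
        return Reject(m.read_id, "chain_mismatch")

    span = migrate_cdr3(m, best_v, best_j, db)
    if span is None:
        return Reject(m.read_id, "anchor_uncovered")
    cdr3_start, cdr3_end = span
    if cdr3_start > cdr3_end:
        # the projected V anchor lies 3' of the projected J anchor: the V/J
        # placements are inverted on the read
        return Reject(m.read_id, "boundary_conflict")
    cdr3_nt = m.seq[cdr3_start:cdr3_end]
    junction_nt = m.seq[cdr3_start - 3:cdr3_end + 3]
    flags = call_productivity(cdr3_nt, m.seq[cdr3_start - 3:cdr3_start],
                              m.seq[cdr3_end:cdr3_end + 3])

    # D: only inside the junction window, heavy chain only
    d_call = None
    if chain == "heavy":
        region = m.seq[best_v.read_end:best_j.read_start]
        if len(region) >= 5:
            hit, _ = _best_hit(region, db.select("heavy", "D"), scoring)
            if hit and hit.score >= params.min_score_d:
                d_call = hit.segment_id

    # C: 3' of the J alignment; subclass requires a margin over the runner-up
    c_call = None
    isotype = None
    c_query = m.seq[max(best_j.read_end - 4, 0):]
    if len(c_query) >= 10:
        hit, runner = _best_hit(c_query, db.select(chain, "C"), scoring)
        if hit and hit.score >= params.min_score_c:
            c_call = hit.segment_id
            label = db[c_call].isotype_label
            if label is not None:
                if hit.score - runner >= params.subclass_margin:
                    isotype = label
                else:
                    isotype = _class_level(label)

    return AnnotatedRearrangement(
        read_id=m.read_id, sample_id=m.sample_id, chain=chain,
        v_call=best_v.segment_id, j_call=best_j.segment_id,
        d_call=d_call, c_call=c_call, isotype=isotype,
        cdr3_nt=cdr3_nt, cdr3_aa=translate(cdr3_nt) if flags["in_frame"] else "",
        junction_nt=junction_nt, v_score=best_v.score, j_score=best_j.score,
        **flags)


def annotate_all(reads: Iterable[MergedRead], db: GermlineDatabase,
                 params: AnnotationParams = AnnotationParams()
                 ) -> tuple[list[AnnotatedRearrangement], Counter]:
    """Annotate a stream of merged reads; returns annotations + reject tally.

    Annotation is a pure function of the merged sequence, so identical
    sequences (duplicate reads of one clone) are aligned once and the result
    is re-labelled per read.
    """
    from dataclasses import replace as _dc_replace

    out: list[AnnotatedRearrangement] = []
    tally: Counter = Counter()
    cache: dict[str, AnnotatedRearrangement | Reject] = {}
    for m in reads:
        res = cache.get(m.seq)
        if res is None:
            res = annotate_read(m, db, params)
            cache[m.seq] = res
        if isinstance(res, Reject):
            tally[res.reason] += 1
        else:
            tally["annotated"] += 1
            out.append(_dc_replace(res, read_id=m.read_id,
                                   sample_id=m.sample_id))
    return out, tally


AIRR_COLUMNS = ["sequence_id", "sample_id", "locus", "v_call", "d_call",
                "j_call", "c_call", "isotype", "junction", "junction_aa",
                "cdr3", "cdr3_aa", "productive", "stop_codon", "vj_in_frame"]

_LOCUS = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}


def annotations_to_airr(annotations: Iterable[AnnotatedRearrangement]
                        ) -> pd.DataFrame:
    """AIRR Rearrangement-style table (one row per read).

    ``junction``/``junction_aa`` are anchor-inclusive per the AIRR
    convention; ``cdr3``/``cdr3_aa`` exclude the anchors and are the unit
    used by all repertoire analytics here.
    """
    rows = []
    for a in annotations:
        rows.append({
            "sequence_id": a.read_id, "sample_id": a.sample_id,
            "locus": _LOCUS[a.chain], "v_call": a.v_call,
            "d_call": a.d_call or "", "j_call": a.j_call,
            "c_call": a.c_call or "", "isotype": a.isotype or "",
            "junction": a.junction_nt,
            "junction_aa": translate(a.junction_nt) if a.in_frame else "",
            "cdr3": a.cdr3_nt, "cdr3_aa": a.cdr3_aa,
            "productive": a.productive, "stop_codon": a.stop_codon,
            "vj_in_frame": a.in_frame,
        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(annotations: Iterable[AnnotatedRearrangement],
               path: str | Path) -> pd.DataFrame:
    df = annotations_to_airr(annotations)
    df.to_csv(path, sep="\t", index=False)
    return df
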