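"""Germline V/D/J/C reference handling.

IMGT-style gene segment databases with CDR3 anchor annotations: the conserved
second cysteine (2nd-CYS) near the 3' end of every V segment and the conserved
tryptophan (J-TRP, heavy chain) or phenylalanine (J-PHE, light chains) inside
every J segment.  The region strictly between these two anchor codons is the
CDR3 as reported throughout this package (anchors excluded).

The same database drives both directions of the pipeline: the simulator
assembles rearrangements from it, and the annotator migrates CDR3 boundaries
from its anchor coordinates onto reads.  All coordinates are 0-based,
half-open; anchor positions index the first base of the anchor codon on the
ungapped sequence (IMGT gap characters are stripped on load).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CHAINS = ("heavy", "kappa", "lambda")
SEGMENT_CLASSES = ("V", "D", "J", "C")
ISOTYPES = ("IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2", "IgE")

#: isotype -> constant-gene prefix used for segment ids (IGHM, IGHG1, ...)
ISOTYPE_GENE = {
    "IgM": "IGHM", "IgD": "IGHD", "IgG1": "IGHG1", "IgG2": "IGHG2",
    "IgG3": "IGHG3", "IgG4": "IGHG4", "IgA1": "IGHA1", "IgA2": "IGHA2",
    "IgE": "IGHE",
}

_CYS_CODONS = frozenset({"TGT", "TGC"})
_TRP_CODONS = frozenset({"TGG"})
_PHE_CODONS = frozenset({"TTT", "TTC"})

_CHAIN_PREFIX = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}


class GermlineError(ValueError):
    """Raised on malformed or inconsistent germline input."""


@dataclass(frozen=True)
class GeneSegment:
    """One germline gene segment (a single allele)."""

    segment_id: str          # e.g. "IGHV3-23*01"
    segment_class: str       # V / D / J / C
    chain: str               # heavy / kappa / lambda
    sequence: str            # ungapped nucleotides over {A,C,G,T}
    anchor_pos: int | None = None   # V: 2nd-CYS codon start; J: J-TRP/J-PHE
    isotype_label: str | None = None  # heavy-chain C segments only

    @property
    def gene(self) -> str:
        """Gene name without the allele suffix (IGHV3-23*01 -> IGHV3-23)."""
        return self.segment_id.split("*")[0]

    @property
    def family(self) -> str:
        """Gene family (IGHV3-23 -> IGHV3)."""
        return self.gene.split("-")[0]

    def validate(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"{self.segment_id}: bad class {self.segment_class}")
        if self.chain not in CHAINS:
            raise GermlineError(f"{self.segment_id}: bad chain {self.chain}")
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise GermlineError(f"{self.segment_id}: sequence must be non-empty over ACGT")
        needs_anchor = self.segment_class in ("V", "J")
        if needs_anchor != (self.anchor_pos is not None):
            raise GermlineError(
                f"{self.segment_id}: anchor_pos required iff segment class is V or J"
            )
        if self.anchor_pos is not None:
            if not 0 <= self.anchor_pos <= len(self.sequence) - 3:
                raise GermlineError(f"{self.segment_id}: anchor_pos out of range")
            codon = self.anchor_codon
            allowed = _CYS_CODONS if self.segment_class == "V" else (
                _TRP_CODONS if self.chain == "heavy" else _TRP_CODONS | _PHE_CODONS
            )
            if codon not in allowed:
                raise GermlineError(
                    f"{self.segment_id}: anchor codon {codon} does not encode the "
                    f"conserved {'C' if self.segment_class == 'V' else 'W/F'} residue"
                )
        has_label = self.isotype_label is not None
        if has_label != (self.segment_class == "C" and self.chain == "heavy"):
            raise GermlineError(
                f"{self.segment_id}: isotype_label present iff heavy-chain C segment"
            )
        if has_label and self.isotype_label not in ISOTYPES:
            raise GermlineError(f"{self.segment_id}: unknown isotype {self.isotype_label}")

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_pos is None:
            return None
        return self.sequence[self.anchor_pos:self.anchor_pos + 3]


@dataclass
class GermlineDatabase:
    """Validated collection of gene segments with chain/class indexed lookup."""

    segments: list[GeneSegment]
    _by_id: dict[str, GeneSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seg in self.segments:
            if seg.segment_id in seen:
                raise GermlineError(f"duplicate segment_id {seg.segment_id}")
            seen.add(seg.segment_id)
            seg.validate()
        self._by_id = {s.segment_id: s for s in self.segments}
        for chain in CHAINS:
            if self.select(chain, "V") and not self.select(chain, "J"):
                raise GermlineError(f"chain {chain} has V segments but no J segment")

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other) -> bool:
        return isinstance(other, GermlineDatabase) and self.segments == other.segments

    def __getitem__(self, segment_id: str) -> GeneSegment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def select(self, chain: str, segment_class: str) -> list[GeneSegment]:
        return [s for s in self.segments
                if s.chain == chain and s.segment_class == segment_class]

    def chains(self) -> list[str]:
        return [c for c in CHAINS if self.select(c, "V")]

    def isotypes(self) -> list[str]:
        labels = {s.isotype_label for s in self.select("heavy", "C")}
        return [i for i in ISOTYPES if i in labels]

    def checksum(self) -> str:
        """md5 over sorted (id, sequence) pairs; recorded in output headers."""
        h = hashlib.md5()
        for seg in sorted(self.segments, key=lambda s: s.segment_id):
            h.update(seg.segment_id.encode())
            h.update(seg.sequence.encode())
        return h.hexdigest()


def _infer_class_and_chain(segment_id: str) -> tuple[str, str]:
    prefix = segment_id[:3]
    chain = {"IGH": "heavy", "IGK": "kappa", "IGL": "lambda"}.get(prefix)
    if chain is None:
        raise GermlineError(f"{segment_id}: cannot infer chain from id prefix")
    cls = segment_id[3]
    if cls in ("V", "D", "J"):
        # heavy-chain constant genes IGHM/IGHD/IGHG... collide with IGHD (diversity);
        # constant segments must therefore be listed in the anchor/metadata table
        return cls, chain
    return "C", chain


def load_germline(
    fasta_path: str | Path,
    anchor_table_path: str | Path,
    *,
    strict: bool = False,
) -> GermlineDatabase:
    """Load a germline database from FASTA plus an anchor annotation table.

    The FASTA headers carry segment ids.  The anchor table is tab-separated
    with columns ``segment_id``, ``anchor_pos`` and optional third column
    carrying either ``D``/``C`` class overrides or an isotype label for
    heavy-chain C segments (e.g. ``IGHM*01<TAB>.<TAB>C:IgM``).  IMGT gap
    characters (``.``) are stripped; anchor positions refer to the ungapped
    sequence.  Segments whose anchor codon does not encode the conserved
    residue are excluded with a warning (hard error when ``strict``).
    """
    anchors: dict[str, int | None] = {}
    overrides: dict[str, tuple[str, str | None]] = {}
    for line in Path(anchor_table_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        seg_id = parts[0]
        if seg_id == "segment_id":
            continue
        anchors[seg_id] = int(parts[1]) if parts[1] not in (".", "") else None
        if len(parts) > 2 and parts[2] not in (".", ""):
            cls, _, label = parts[2].partition(":")
            overrides[seg_id] = (cls, label or None)

    segments: list[GeneSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seg_id = rec.id
        if seg_id in seen:
            raise GermlineError(f"duplicate segment_id {seg_id} in FASTA")
        seen.add(seg_id)
        seq = str(rec.seq).upper().replace(".", "").replace("-", "")
        if seg_id in overrides:
            cls, label = overrides[seg_id]
            chain = _infer_class_and_chain(seg_id)[1]
        else:
            cls, chain = _infer_class_and_chain(seg_id)
            label = None
        anchor = anchors.get(seg_id)
        if cls in ("V", "J") and anchor is None:
            raise GermlineError(f"{seg_id}: V/J segment missing anchor annotation")
        seg = GeneSegment(seg_id, cls, chain, seq,
                          anchor_pos=anchor if cls in ("V", "J") else None,
                          isotype_label=label)
        try:
            seg.validate()
        except GermlineError as exc:
            if strict:
                raise
            warnings.warn(f"excluding segment: {exc}", stacklevel=2)
            continue
        segments.append(seg)
    return GermlineDatabase(segments)


def write_germline(db: GermlineDatabase, fasta_path: str | Path,
                   anchor_table_path: str | Path) -> None:
    """Write a database back to FASTA + anchor table (inverse of load)."""
    records = [SeqRecord(Seq(s.sequence), id=s.segment_id, description="")
               for s in db.segments]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["segment_id\tanchor_pos\tclass"]
    for s in db.segments:
        anchor = str(s.anchor_pos) if s.anchor_pos is not None else "."
        extra = s.segment_class if s.segment_class in ("D", "C") else "."
        if s.isotype_label:
            extra = f"C:{s.isotype_label}"
        lines.append(f"{s.segment_id}\t{anchor}\t{extra}")
    Path(anchor_table_path).write_text("\n".join(lines) + "\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _edit_distance(a: str, b: str) -> int:
    try:
        import edlib
        return edlib.align(a, b)["editDistance"]
    except ImportError:  # pragma: no cover - edlib present in supported envs
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


def build_toy_germline(
    n_v: int = 5,
    n_d: int = 3,
    n_j: int = 4,
    isotypes: tuple[str, ...] = ("IgM", "IgD", "IgG1", "IgG3", "IgA2"),
    seed: int = 0,
    *,
    chains: tuple[str, ...] = CHAINS,
    v_len: int = 285,
    j_len: int = 51,
    c_len: int = 72,
) -> GermlineDatabase:
    """Deterministically synthesize a small IMGT-style germline database.

    Every V ends with a TGT 2nd-CYS anchor followed by three codons of
    CDR3-forming sequence; every J carries its W/F anchor after a short
    CDR3 tail and an in-frame, stop-free FR4.  Heavy-chain C segments get
    mutually distant 5' ends (pairwise edit distance of the first 50-mers
    >= 20) so isotype assignment from a short constant fragment is well
    posed.  Lengths are codon-aligned so that a zero-trim rearrangement is
    in frame.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need n_v >= 1 and n_j >= 1")
    rng = np.random.default_rng(seed)
    segments: list[GeneSegment] = []

    for chain in chains:
        prefix = _CHAIN_PREFIX[chain]
        # V: [leader/FR1-3][TGT anchor][3 codons feeding the CDR3]
        anchor_pos = v_len - 12  # codon-aligned: v_len divisible by 3
        for i in range(n_v):
            seq = _random_seq(rng, v_len)
            seq = seq[:anchor_pos] + "TGT" + _strip_stops(seq[anchor_pos + 3:], rng)
            segments.append(GeneSegment(
                f"{prefix}V{i + 1}-{(i % 4) + 1}*01", "V", chain, seq,
                anchor_pos=anchor_pos))
        if chain == "heavy":
            for i in range(n_d):
                segments.append(GeneSegment(
                    f"{prefix}D{i + 1}-{i + 1}*01", "D", "heavy",
                    _random_seq(rng, int(rng.integers(12, 25)))))
        # J: [CDR3 tail][W/F anchor][FR4]; anchor codon-aligned from the start
        j_anchor = 12
        anchor_codon_choices = ["TGG"] if chain == "heavy" else ["TTT", "TTC"]
        for i in range(n_j):
            seq = _random_seq(rng, j_len)
            codon = anchor_codon_choices[i % len(anchor_codon_choices)]
            seq = seq[:j_anchor] + codon + _strip_stops(seq[j_anchor + 3:], rng)
            segments.append(GeneSegment(
                f"{prefix}J{i + 1}*01", "J", chain, seq, anchor_pos=j_anchor))
        # C 5' fragments (what the reverse primer captures)
        if chain == "heavy":
            c_seqs = _distant_seqs(rng, len(isotypes), c_len, min_dist=20)
            for iso, seq in zip(isotypes, c_seqs):
                segments.append(GeneSegment(
                    f"{ISOTYPE_GENE[iso]}*01", "C", "heavy", seq,
                    isotype_label=iso))
        else:
            segments.append(GeneSegment(
                f"{prefix}C*01", "C", chain, _random_seq(rng, c_len)))
    return GermlineDatabase(segments)


def _strip_stops(seq: str, rng: np.random.Generator) -> str:
    """Replace any in-frame stop codon with a random sense codon."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        while codon in stops:
            codon = _random_seq(rng, 3)
        out.append(codon)
    out.append(seq[len(seq) - len(seq) % 3:])
    return "".join(out)


def _distant_seqs(rng: np.random.Generator, n: int, length: int,
                  min_dist: int, probe: int = 50) -> list[str]:
    """Random sequences whose 5' ``probe``-mers are pairwise >= min_dist apart."""
    out: list[str] = []
    for _ in range(n):
        for _attempt in range(1000):
            cand = _random_seq(rng, length)
            if all(_edit_distance(cand[:probe], s[:probe]) >= min_dist for s in out):
                out.append(cand)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate mutually distant C segments")
    return out
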