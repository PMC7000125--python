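"""Ground-truthed simulation of subset-structured longitudinal BCR repertoires.

The simulator emulates the statistical structure of sorted-subset targeted
BCR sequencing from a single subject followed over time:

* four developmental B-cell subsets (immature, naive, memory, plasmacyte)
  with per-subset cell counts, the plasmacyte pool deliberately small;
* clone-size distributions drawn Dirichlet-multinomial with a per-subset
  concentration, so antigen-experienced subsets are clonal (skewed) and
  antigen-inexperienced subsets are flat;
* V(D)J rearrangement with biased segment usage, geometric-tailed
  exonucleolytic trimming and non-templated N insertions (one N region for
  light chains, two for heavy);
* subset-conditional isotype assignment, including a small class-switched
  fraction in immature/naive cells and no IgE;
* longitudinal persistence: a clone recurs at the next time point with a
  configurable probability, so most clones appear once;
* somatic hypermutation in antigen-experienced subsets, sparing the CDR3
  anchor codons so truth boundaries stay valid;
* 2 x 250 bp paired-end reads, the reverse read carrying a 6-nt sample
  barcode ahead of the constant region, with substitution errors and a
  simple two-level quality model.

Every read is linked to its generating rearrangement in a truth table, so
the whole downstream pipeline is verifiable by ground-truth recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import GermlineDatabase, GeneSegment, ISOTYPES
from .reads import revcomp, SequenceRead
from .translate import translate, has_stop

SUBSETS = ("immature", "naive", "memory", "plasmacyte")
ANTIGEN_EXPERIENCED = ("memory", "plasmacyte")
_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated longitudinal experiment.

    Defaults describe a desk-scale version of a single-subject design:
    four time points, all four subsets with realistic relative pool sizes,
    sequencing depth of five reads per cell, and a 2% early class-switched
    fraction.
    """

    n_timepoints: int = 4
    subsets: dict[str, int] = field(default_factory=lambda: {
        "immature": 300, "naive": 400, "memory": 250, "plasmacyte": 60})
    clones_per_subset: dict[str, int] = field(default_factory=lambda: {
        "immature": 500, "naive": 700, "memory": 250, "plasmacyte": 50})
    clone_size_concentration: dict[str, float] = field(default_factory=lambda: {
        "immature": 50.0, "naive": 50.0, "memory": 1.0, "plasmacyte": 0.3})
    chain_fractions: dict[str, float] = field(default_factory=lambda: {
        "heavy": 0.5, "kappa": 0.3, "lambda": 0.2})
    v_usage_bias: dict[str, dict[str, float]] | None = None
    j_usage_bias: dict[str, dict[str, float]] | None = None
    isotype_probs: dict[str, float] | None = None  # memory/plasmacyte vector
    persistence_prob: float = 0.2
    switch_rate_early: float = 0.02
    shm_rate: float = 0.002
    seq_error_rate: float = 0.001
    reads_per_cell: float = 5.0
    trim_mean: float = 3.0
    insert_mean: float = 3.0
    productive_fraction: float = 0.8
    read_len: int = 250
    barcode_len: int = 6
    quality_correct: int = 37
    quality_error: int = 12
    ramp_len: int = 0          # 3' bases with linearly decaying quality
    ramp_floor: int = 2
    barcode_map: dict[str, str] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("persistence_prob", "switch_rate_early", "shm_rate",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.chain_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("chain_fractions must sum to 1")
        for bias in (self.v_usage_bias, self.j_usage_bias):
            if bias:
                for chain, vec in bias.items():
                    if abs(sum(vec.values()) - 1.0) > 1e-9:
                        raise ValueError(f"usage bias for {chain} must sum to 1")
        if self.isotype_probs and abs(sum(self.isotype_probs.values()) - 1.0) > 1e-9:
            raise ValueError("isotype_probs must sum to 1")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")
        if self.barcode_map is not None:
            codes = list(self.barcode_map.values())
            if any(len(c) != self.barcode_len for c in codes):
                raise ValueError("barcodes must have the configured length")
            if len(set(codes)) != len(codes):
                raise ValueError("barcodes must be pairwise distinct")


@dataclass
class RecombinationEvent:
    """Ground truth for one simulated rearrangement (one clone occurrence)."""

    event_id: str
    clone_id: str
    chain: str
    subset: str | None = None
    timepoint: int | None = None
    v_id: str = ""
    d_id: str | None = None
    j_id: str = ""
    c_id: str | None = None
    isotype: str | None = None
    v_trim: int = 0
    d_trim_5: int = 0
    d_trim_3: int = 0
    j_trim: int = 0
    n1: str = ""
    n2: str = ""
    full_nt: str = ""
    cdr3_start: int = 0       # 0-based, first base after the V anchor codon
    cdr3_end: int = 0         # first base of the J anchor codon
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    abundance: int = 0

    @property
    def v_gene(self) -> str:
        return self.v_id.split("*")[0]

    @property
    def j_gene(self) -> str:
        return self.j_id.split("*")[0]


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric-tailed non-negative length with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _pick(rng: np.random.Generator, segments: list[GeneSegment],
          bias: dict[str, float] | None) -> GeneSegment:
    if bias is None:
        return segments[int(rng.integers(0, len(segments)))]
    ids = sorted(bias)
    probs = np.array([bias[i] for i in ids])
    chosen = ids[int(rng.choice(len(ids), p=probs / probs.sum()))]
    for s in segments:
        if s.segment_id == chosen or s.gene == chosen:
            return s
    raise KeyError(f"usage bias names unknown segment {chosen}")


def _assemble(event: RecombinationEvent, db: GermlineDatabase) -> None:
    """Recompute full_nt, CDR3 coordinates/sequence and productivity in place."""
    v = db[event.v_id]
    j = db[event.j_id]
    v_part = v.sequence[:len(v.sequence) - event.v_trim]
    d_part = ""
    if event.d_id is not None:
        d = db[event.d_id].sequence
        d_part = d[event.d_trim_5:len(d) - event.d_trim_3]
    j_part = j.sequence[event.j_trim:]
    c_part = db[event.c_id].sequence if event.c_id else ""
    event.full_nt = v_part + event.n1 + d_part + event.n2 + j_part + c_part
    event.cdr3_start = v.anchor_pos + 3
    event.cdr3_end = (len(v_part) + len(event.n1) + len(d_part)
                      + len(event.n2) + (j.anchor_pos - event.j_trim))
    event.cdr3_nt = event.full_nt[event.cdr3_start:event.cdr3_end]
    in_frame = len(event.cdr3_nt) % 3 == 0
    region = event.full_nt[event.cdr3_start - 3:event.cdr3_end + 3]
    stop = has_stop(region)
    event.productive = in_frame and not stop
    event.cdr3_aa = translate(event.cdr3_nt) if in_frame else ""


def sample_recombination(db: GermlineDatabase, cfg: SimulationConfig,
                         chain: str, rng: np.random.Generator,
                         clone_id: str = "clone") -> RecombinationEvent:
    """Draw one V(D)J rearrangement for the given chain.

    Heavy chains get V-N1-D-N2-J structure; light chains V-N1-J.  Junctions
    are resampled (biased toward productive outcomes at
    ``cfg.productive_fraction``) to mimic selection on expressed receptors.
    """
    vs = db.select(chain, "V")
    js = db.select(chain, "J")
    ds = db.select(chain, "D")
    if not vs or not js:
        raise ValueError(f"germline database has no V/J segments for {chain}")
    v = _pick(rng, vs, (cfg.v_usage_bias or {}).get(chain))
    j = _pick(rng, js, (cfg.j_usage_bias or {}).get(chain))
    d = ds[int(rng.integers(0, len(ds)))] if (chain == "heavy" and ds) else None
    light_c = None
    if chain != "heavy":
        light_c = db.select(chain, "C")[0].segment_id

    want_productive = bool(rng.random() < cfg.productive_fraction)
    event = RecombinationEvent(event_id=clone_id, clone_id=clone_id,
                               chain=chain, v_id=v.segment_id, j_id=j.segment_id,
                               c_id=light_c)
    v_max_trim = len(v.sequence) - (v.anchor_pos + 3)
    for _attempt in range(200):
        event.v_trim = min(_geometric(rng, cfg.trim_mean), v_max_trim)
        event.j_trim = min(_geometric(rng, cfg.trim_mean), j.anchor_pos)
        event.n1 = _random_nt(rng, _geometric(rng, cfg.insert_mean))
        if d is not None:
            d5 = _geometric(rng, cfg.trim_mean)
            d3 = _geometric(rng, cfg.trim_mean)
            if d5 + d3 >= len(d.sequence):
                event.d_id, event.d_trim_5, event.d_trim_3 = None, 0, 0
            else:
                event.d_id, event.d_trim_5, event.d_trim_3 = d.segment_id, d5, d3
            event.n2 = _random_nt(rng, _geometric(rng, cfg.insert_mean))
        else:
            event.d_id, event.n2 = None, ""
        _assemble(event, db)
        if event.productive == want_productive:
            break
    return event


def assign_isotype(event: RecombinationEvent, cfg: SimulationConfig,
                   rng: np.random.Generator, db: GermlineDatabase) -> RecombinationEvent:
    """Draw a heavy-chain isotype conditional on the B-cell subset.

    Memory and plasmacyte cells draw from the full configured isotype
    vector; immature and naive cells carry IgM/IgD except for a small
    class-switched fraction (``switch_rate_early``) that excludes IgE.
    """
    if event.chain != "heavy":
        return event
    available = db.isotypes()
    probs = cfg.isotype_probs or _default_isotype_probs(available)
    if event.subset in ANTIGEN_EXPERIENCED:
        isotypes = sorted(probs)
        p = np.array([probs[i] for i in isotypes])
        iso = isotypes[int(rng.choice(len(isotypes), p=p / p.sum()))]
    else:
        unswitched = [i for i in available if i in ("IgM", "IgD")]
        switched = [i for i in available if i not in ("IgM", "IgD", "IgE")]
        if switched and rng.random() < cfg.switch_rate_early:
            iso = switched[int(rng.integers(0, len(switched)))]
        else:
            iso = unswitched[int(rng.integers(0, len(unswitched)))]
    event.isotype = iso
    event.c_id = next(s.segment_id for s in db.select("heavy", "C")
                      if s.isotype_label == iso)
    _assemble(event, db)
    return event


def _default_isotype_probs(available: list[str]) -> dict[str, float]:
    """Memory/plasmacyte isotype mix: mostly switched, no IgE."""
    weights = {"IgM": 0.20, "IgD": 0.05}
    switched = [i for i in available if i not in ("IgM", "IgD", "IgE")]
    out = {i: weights[i] for i in available if i in weights}
    rest = 1.0 - sum(out.values())
    for i in switched:
        out[i] = rest / len(switched)
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def _apply_shm(full_nt: str, event: RecombinationEvent, rate: float,
               rng: np.random.Generator) -> str:
    """Uniform substitutions sparing the two CDR3 anchor codons."""
    if rate <= 0:
        return full_nt
    arr = np.frombuffer(full_nt.encode(), np.uint8).copy()
    mask = rng.random(arr.shape[0]) < rate
    mask[event.cdr3_start - 3:event.cdr3_start] = False
    mask[event.cdr3_end:event.cdr3_end + 3] = False
    for pos in np.flatnonzero(mask):
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def _make_barcodes(samples: list[str], length: int,
                   rng: np.random.Generator) -> dict[str, str]:
    """Deterministic barcodes with pairwise Hamming distance >= 3."""
    codes: list[str] = []
    while len(codes) < len(samples):
        cand = _random_nt(rng, length)
        if all(sum(a != b for a, b in zip(cand, c)) >= 3 for c in codes):
            codes.append(cand)
    return dict(zip(samples, codes))


def sample_name(subset: str, timepoint: int) -> str:
    return f"{subset}_tp{timepoint}"


def simulate_repertoire(db: GermlineDatabase, cfg: SimulationConfig
                        ) -> tuple[list[RecombinationEvent], dict]:
    """Simulate clone tables for every (subset, time point) sample.

    Returns one RecombinationEvent per clone occurrence (clone x time point
    with non-zero cells) plus a manifest describing the samples.  Clones
    enter at a uniform random time point and persist to each following one
    with ``persistence_prob``; per-sample abundances are
    Dirichlet-multinomial over the subset's active clones; antigen
    experienced occurrences accumulate somatic hypermutation.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows: list[RecombinationEvent] = []
    chains = [c for c in ("heavy", "kappa", "lambda")
              if cfg.chain_fractions.get(c, 0) > 0 and db.select(c, "V")]
    fracs = np.array([cfg.chain_fractions[c] for c in chains])
    fracs = fracs / fracs.sum()
    truncated: list[str] = []

    clone_serial = 0
    for subset, n_clones in cfg.clones_per_subset.items():
        if subset not in cfg.subsets:
            continue
        counts = rng.multinomial(n_clones, fracs)
        clones: list[tuple[RecombinationEvent, list[int]]] = []
        for chain, n_chain in zip(chains, counts):
            for _ in range(n_chain):
                clone_id = f"C{clone_serial:06d}"
                clone_serial += 1
                ev = sample_recombination(db, cfg, chain, rng, clone_id)
                ev.subset = subset
                ev = assign_isotype(ev, cfg, rng, db)
                entry = int(rng.integers(0, cfg.n_timepoints))
                tps = [entry]
                t = entry
                while t + 1 < cfg.n_timepoints and rng.random() < cfg.persistence_prob:
                    t += 1
                    tps.append(t)
                clones.append((ev, tps))
        conc = cfg.clone_size_concentration.get(subset, 1.0)
        n_cells = cfg.subsets[subset]
        for tp in range(cfg.n_timepoints):
            active = [ev for ev, tps in clones if tp in tps]
            if not active:
                continue
            weights = rng.dirichlet(np.full(len(active), conc))
            cells = rng.multinomial(n_cells, weights)
            for ev, n in zip(active, cells):
                if n == 0:
                    continue
                occ = replace(ev, event_id=f"{ev.clone_id}:t{tp}",
                              timepoint=tp, abundance=int(n))
                if subset in ANTIGEN_EXPERIENCED and cfg.shm_rate > 0:
                    occ.full_nt = _apply_shm(occ.full_nt, occ, cfg.shm_rate, rng)
                    occ.cdr3_nt = occ.full_nt[occ.cdr3_start:occ.cdr3_end]
                    occ.cdr3_aa = (translate(occ.cdr3_nt)
                                   if len(occ.cdr3_nt) % 3 == 0 else "")
                rows.append(occ)

    samples = [sample_name(s, t) for s in cfg.subsets for t in range(cfg.n_timepoints)]
    barcode_map = cfg.barcode_map or _make_barcodes(samples, cfg.barcode_len, rng)
    manifest = {
        "seed": cfg.seed,
        "germline_checksum": db.checksum(),
        "samples": [
            {"sample_id": sample_name(s, t), "subset": s, "timepoint": t,
             "sorted_cells": cfg.subsets[s], "barcode": barcode_map[sample_name(s, t)]}
            for s in cfg.subsets for t in range(cfg.n_timepoints)
        ],
        "truncated_amplicons": truncated,
        "config": {k: v for k, v in asdict(cfg).items() if k != "barcode_map"},
    }
    return rows, manifest


def emit_reads(clones: list[RecombinationEvent], db: GermlineDatabase,
               cfg: SimulationConfig, manifest: dict, out_dir: str | Path
               ) -> dict[str, Path]:
    """Write paired FASTQ (R1 V-side, R2 barcode+C-side) and a truth table.

    Per clone occurrence the number of read pairs is
    Poisson(reads_per_cell x abundance).  Substitution errors are applied at
    ``seq_error_rate`` with quality dropped at error positions.  Amplicons
    shorter than the read length yield truncated reads and are flagged in
    the manifest.
    """
    if not clones:
        raise ValueError("no clones to sequence")
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    barcodes = {s["sample_id"]: s["barcode"] for s in manifest["samples"]}

    r1_path = out_dir / "reads_R1.fastq.gz"
    r2_path = out_dir / "reads_R2.fastq.gz"
    truth_path = out_dir / "truth.tsv"
    manifest_path = out_dir / "manifest.json"
    truth_rows = []
    truncated: set[str] = set()

    import gzip
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for occ in clones:
            sample = sample_name(occ.subset, occ.timepoint)
            barcode = barcodes[sample]
            n_reads = int(rng.poisson(cfg.reads_per_cell * occ.abundance))
            amplicon = occ.full_nt
            if len(amplicon) < cfg.read_len:
                truncated.add(occ.event_id)
            r2_template = barcode + revcomp(amplicon)
            for k in range(n_reads):
                rid = f"{occ.event_id}.{k}"
                for mate, template, fh in (("R1", amplicon, f1),
                                           ("R2", r2_template, f2)):
                    seq, qual = _sequence_read(template[:cfg.read_len], cfg, rng)
                    fh.write(f"@{rid}\n{seq}\n+\n")
                    fh.write("".join(chr(q + 33) for q in qual) + "\n")
                truth_rows.append({
                    "read_id": rid, "event_id": occ.event_id,
                    "clone_id": occ.clone_id, "sample_id": sample,
                    "subset": occ.subset, "timepoint": occ.timepoint,
                    "chain": occ.chain, "v_id": occ.v_id, "j_id": occ.j_id,
                    "c_id": occ.c_id or "", "isotype": occ.isotype or "",
                    "cdr3_nt": occ.cdr3_nt, "cdr3_aa": occ.cdr3_aa,
                    "productive": occ.productive,
                })
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest = dict(manifest)
    manifest["truncated_amplicons"] = sorted(truncated)
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return {"r1": r1_path, "r2": r2_path, "truth": truth_path,
            "manifest": manifest_path}


def _sequence_read(template: str, cfg: SimulationConfig,
                   rng: np.random.Generator) -> tuple[str, list[int]]:
    arr = np.frombuffer(template.encode(), np.uint8).copy()
    qual = np.full(arr.shape[0], cfg.quality_correct, np.int64)
    if cfg.ramp_len > 0:
        ramp = np.linspace(cfg.quality_correct, cfg.ramp_floor,
                           min(cfg.ramp_len, arr.shape[0]))
        qual[-len(ramp):] = np.minimum(qual[-len(ramp):], ramp.astype(np.int64))
    if cfg.seq_error_rate > 0:
        mask = rng.random(arr.shape[0]) < cfg.seq_error_rate
        for pos in np.flatnonzero(mask):
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = choices[int(rng.integers(0, 3))]
            qual[pos] = cfg.quality_error
    return arr.tobytes().decode(), qual.tolist()


def load_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                     dtype={"cdr3_nt": str, "cdr3_aa": str, "isotype": str})
    df["productive"] = df["productive"].astype(str).str.lower().eq("true")
    return df


def simulate_dataset(db: GermlineDatabase, cfg: SimulationConfig,
                     out_dir: str | Path) -> dict[str, Path]:
    """Convenience wrapper: simulate clones and emit reads in one call."""
    clones, manifest = simulate_repertoire(db, cfg)
    return emit_reads(clones, db, cfg, manifest, out_dir)


def events_to_table(clones: list[RecombinationEvent],
                    cfg: SimulationConfig | None = None,
                    reads_per_cell: float | None = None):
    """Build a clonotype table directly from simulated truth.

    This is the perfectly observed repertoire — no sequencing, no error —
    with read counts proportional to cell abundance.  Useful for studying
    the analytics at scales where read-level simulation is unnecessary.
    Non-productive occurrences are carried with ``productive=False`` so the
    functional filter stays exercised.
    """
    from .filtering import RepertoireTable, TABLE_COLUMNS

    if reads_per_cell is None:
        reads_per_cell = cfg.reads_per_cell if cfg else 1.0
    rows = []
    for occ in clones:
        rows.append({
            "sample_id": sample_name(occ.subset, occ.timepoint),
            "timepoint": occ.timepoint, "subset": occ.subset,
            "chain": occ.chain, "cdr3_aa": occ.cdr3_aa, "cdr3_nt": occ.cdr3_nt,
            "v_gene": occ.v_gene, "j_gene": occ.j_gene,
            "c_isotype": occ.isotype or "", "productive": occ.productive,
            "read_count": max(int(round(occ.abundance * reads_per_cell)), 1),
        })
    df = (pd.DataFrame(rows, columns=TABLE_COLUMNS)
          .groupby([c for c in TABLE_COLUMNS if c != "read_count"],
                   as_index=False, dropna=False)["read_count"].sum())
    cells = {}
    if cfg is not None:
        cells = {sample_name(s, t): cfg.subsets[s]
                 for s in cfg.subsets for t in range(cfg.n_timepoints)}
    return RepertoireTable(df[TABLE_COLUMNS], cell_counts=cells)
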