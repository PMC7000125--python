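"""Clonotype aggregation, count filtering, and per-sample depth QC.

Annotated reads collapse into a clonotype count table keyed by
(sample, CDR3 amino-acid sequence, V gene, J gene, isotype).  Two filters
mirror standard practice for this chemistry: non-functional CDR3s are
removed, and clonotypes seen fewer than four times in a library are treated
as noise.  Samples sequenced below five reads per sorted cell are flagged so
depth-sensitive analyses can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotate import AnnotatedRearrangement

TABLE_COLUMNS = ["sample_id", "timepoint", "subset", "chain", "cdr3_aa",
                 "cdr3_nt", "v_gene", "j_gene", "c_isotype", "productive",
                 "read_count"]

#: aggregation key (cdr3_nt joins it only when collapsing at nucleotide level)
CLONOTYPE_KEY = ["sample_id", "cdr3_aa", "v_gene", "j_gene", "c_isotype"]


@dataclass
class RepertoireTable:
    """Clonotype counts plus sample metadata (the substrate of all analytics)."""

    df: pd.DataFrame
    cell_counts: dict[str, int] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def total_reads(self) -> pd.Series:
        return self.df.groupby("sample_id", observed=True)["read_count"].sum()

    def without_excluded(self) -> "RepertoireTable":
        """Drop depth-failing samples (for analyses that declare sensitivity)."""
        keep = ~self.df["sample_id"].isin(self.excluded_samples)
        return replace(self, df=self.df[keep].reset_index(drop=True))

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    total_reads: int
    sorted_cells: int | None
    reads_per_cell: float | None
    passed: bool | None  # None = unknown (missing cell count)


def _gene(call: str) -> str:
    return call.split("*")[0]


def aggregate(
    annotations: Iterable[AnnotatedRearrangement],
    metadata: dict[str, dict],
    *,
    by_nt: bool = False,
) -> RepertoireTable:
    """Roll annotated reads up into clonotype counts.

    ``metadata`` maps sample_id -> {subset, timepoint, sorted_cells}.  Total
    reads are conserved: the sum of ``read_count`` equals the number of
    annotated reads per sample.  With ``by_nt`` clonotypes are additionally
    split by nucleotide CDR3 (for cDNA-level analyses).
    """
    rows = []
    for a in annotations:
        if a.sample_id not in metadata:
            raise KeyError(f"annotation references unknown sample {a.sample_id}")
        meta = metadata[a.sample_id]
        rows.append({
            "sample_id": a.sample_id,
            "timepoint": meta["timepoint"],
            "subset": meta["subset"],
            "chain": a.chain,
            "cdr3_aa": a.cdr3_aa,
            "cdr3_nt": a.cdr3_nt,
            "v_gene": _gene(a.v_call),
            "j_gene": _gene(a.j_call),
            "c_isotype": a.isotype or "",
            "productive": a.productive,
        })
    if not rows:
        return RepertoireTable(pd.DataFrame(columns=TABLE_COLUMNS))
    df = pd.DataFrame(rows)
    key = CLONOTYPE_KEY + (["cdr3_nt"] if by_nt else []) + ["productive"]
    grouped = (df.groupby(key + ["timepoint", "subset", "chain"], dropna=False)
               .size().rename("read_count").reset_index())
    if not by_nt:
        # representative nucleotide sequence per amino-acid clonotype
        rep_nt = (df.groupby(key, dropna=False)["cdr3_nt"]
                  .agg(lambda s: s.mode().iloc[0]).rename("cdr3_nt"))
        grouped = grouped.merge(rep_nt, left_on=key, right_index=True,
                                how="left")
    cells = {s: m.get("sorted_cells") for s, m in metadata.items()}
    return RepertoireTable(grouped[TABLE_COLUMNS].reset_index(drop=True),
                           cell_counts=cells)


def filter_repertoire(t: RepertoireTable, min_count: int = 4,
                      functional_only: bool = True) -> RepertoireTable:
    """Apply the non-functional and minimum-count clonotype filters.

    Removes rows observed fewer than ``min_count`` times within their sample
    (each sequencing library is an independent unit) and, when
    ``functional_only``, any clonotype whose CDR3 is out of frame or carries
    a stop codon.  ``min_count=1`` with ``functional_only=False`` is the
    identity.
    """
    df = t.df
    if functional_only:
        df = df[df["productive"]]
    df = df[df["read_count"] >= min_count]
    return replace(t, df=df.reset_index(drop=True))


def sample_qc(t: RepertoireTable, min_depth: float = 5.0
              ) -> tuple[list[SampleQC], list[str]]:
    """Per-sample sequencing-depth QC against the reads-per-cell rule.

    A sample passes when ``total_reads / sorted_cells >= min_depth``.
    Returns QC rows and the list of failing sample ids; the ids are also
    recorded on the table so depth-sensitive analytics can honor them.
    """
    totals = t.total_reads()
    out: list[SampleQC] = []
    excluded: list[str] = []
    for sample_id, total in totals.items():
        cells = t.cell_counts.get(sample_id)
        if not cells:
            warnings.warn(f"{sample_id}: no sorted-cell count; depth unknown",
                          stacklevel=2)
            out.append(SampleQC(sample_id, int(total), None, None, None))
            continue
        depth = total / cells
        passed = depth >= min_depth
        out.append(SampleQC(sample_id, int(total), int(cells), depth, passed))
        if not passed:
            excluded.append(sample_id)
    t.excluded_samples = excluded
    return out, excluded


def qc_report(qc: list[SampleQC]) -> pd.DataFrame:
    return pd.DataFrame([q.__dict__ for q in qc])


def load_table(path: str | Path, cell_counts: dict[str, int] | None = None
               ) -> RepertoireTable:
    df = pd.read_csv(path, sep="\t",
                     dtype={"cdr3_aa": str, "cdr3_nt": str, "c_isotype": str},
                     keep_default_na=False,
                     na_values=[])
    df["productive"] = df["productive"].astype(bool)
    return RepertoireTable(df, cell_counts=cell_counts or {})
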