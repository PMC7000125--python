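"""End-to-end driver: FASTQ pairs -> filtered clonotype table.

Stage order is demultiplex (barcode bases must still be present), then
quality trim, overlap merge, V(D)J annotation, clonotype aggregation,
depth QC, and the non-functional / minimum-count filters.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import AnnotatedRearrangement, AnnotationParams, annotate_all
from .filtering import (RepertoireTable, SampleQC, aggregate,
                        filter_repertoire, sample_qc)
from .germline import GermlineDatabase
from .reads import demultiplex, process_sample, read_fastq


@dataclass
class PipelineResult:
    table: RepertoireTable                 # filtered clonotypes
    raw_table: RepertoireTable             # aggregated, pre-filter
    annotations: list[AnnotatedRearrangement]
    merge_tally: dict[str, Counter]
    annotate_tally: Counter
    qc: list[SampleQC]
    unassigned: int = 0
    excluded_samples: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for sample, tally in self.merge_tally.items():
            rows.append({"sample_id": sample, **tally})
        return pd.DataFrame(rows).fillna(0)


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def manifest_metadata(manifest: dict) -> dict[str, dict]:
    """sample_id -> {subset, timepoint, sorted_cells, barcode}."""
    return {s["sample_id"]: dict(s) for s in manifest["samples"]}


def run_pipeline(
    r1_path: str | Path,
    r2_path: str | Path,
    db: GermlineDatabase,
    manifest: dict,
    *,
    params: AnnotationParams = AnnotationParams(),
    max_barcode_mismatch: int = 0,
    q_min: int = 20,
    window: int = 2,
    min_overlap: int = 10,
    min_count: int = 4,
    min_depth: float = 5.0,
    functional_only: bool = True,
) -> PipelineResult:
    """Run the full read-processing and annotation pipeline on one run."""
    metadata = manifest_metadata(manifest)
    barcode_map = {s: m["barcode"] for s, m in metadata.items()}
    pairs = zip(read_fastq(r1_path, "R1"), read_fastq(r2_path, "R2"))
    by_sample, unassigned = demultiplex(pairs, barcode_map,
                                        max_mismatch=max_barcode_mismatch)
    merged_all = []
    merge_tally: dict[str, Counter] = {}
    for sample, sample_pairs in by_sample.items():
        merged, tally = process_sample(sample_pairs, window=window,
                                       q_min=q_min, min_overlap=min_overlap)
        merged_all.extend(merged)
        merge_tally[sample] = tally
    annotations, ann_tally = annotate_all(merged_all, db, params)
    raw = aggregate(annotations, metadata)
    qc, excluded = sample_qc(raw, min_depth=min_depth)
    filtered = filter_repertoire(raw, min_count=min_count,
                                 functional_only=functional_only)
    filtered.excluded_samples = excluded
    return PipelineResult(table=filtered, raw_table=raw,
                          annotations=annotations, merge_tally=merge_tally,
                          annotate_tally=ann_tally, qc=qc,
                          unassigned=unassigned, excluded_samples=excluded)
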