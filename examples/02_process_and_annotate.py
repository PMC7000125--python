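"""Run the full read-processing pipeline and check calls against truth.

Demultiplexes on the R2 barcode, quality-trims (2-base window, Q20), merges
pairs through their best perfect overlap, assigns germline V/D/J/C segments
by Smith-Waterman, migrates the CDR3 boundaries from the germline anchors,
and aggregates productive clonotypes with the >=4-read filter.

Run 01_simulate_repertoire.py first.
"""

from pathlib import Path

import pandas as pd

from bcrseq import (load_germline, load_manifest, load_truth, run_pipeline,
                    write_airr)

run = Path("example_output/simulated_run")
db = load_germline(run / "germline.fasta", run / "anchors.tsv")
manifest = load_manifest(run / "manifest.json")

result = run_pipeline(run / "reads_R1.fastq.gz", run / "reads_R2.fastq.gz",
                      db, manifest)
write_airr(result.annotations, run / "rearrangements.tsv")
result.table.write(run / "clonotypes.tsv")

print(f"unassigned pairs: {result.unassigned}")
print(f"annotation outcomes: {dict(result.annotate_tally)}")
print(f"clonotypes after functional + >=4-count filters: {len(result.table)}")

truth = load_truth(run / "truth.tsv")
ann = pd.DataFrame([{"read_id": a.read_id, "v": a.v_call, "j": a.j_call}
                    for a in result.annotations])
m = ann.merge(truth, on="read_id")
print(f"V gene call accuracy: {(m['v'] == m['v_id']).mean():.4f}")
print(f"J gene call accuracy: {(m['j'] == m['j_id']).mean():.4f}")
print("\nAccuracies are measured against the simulator's truth table;")
print("at a 0.1% error rate the strict merge keeps calls near-perfect.")
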