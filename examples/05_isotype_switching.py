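"""Isotype distributions and early class switching.

Memory/plasmacyte cells draw from a full isotype mix; immature and naive
cells are IgM/IgD apart from a small class-switched fraction (2% by
default, never IgE).  The analysis recovers that configuration and shows
the class-switched CDR3 overlap between subsets.
"""

from bcrseq import (SimulationConfig, build_toy_germline, events_to_table,
                    filter_repertoire, simulate_repertoire)
from bcrseq.analytics import (isotype_distribution, switched_fraction,
                              switched_overlap)

db = build_toy_germline(seed=0)
cfg = SimulationConfig(
    seed=4, n_timepoints=4,
    subsets={"immature": 1500, "naive": 2000, "memory": 900,
             "plasmacyte": 200},
    clones_per_subset={"immature": 4000, "naive": 5500, "memory": 1500,
                       "plasmacyte": 300},
    switch_rate_early=0.02)
clones, _ = simulate_repertoire(db, cfg)
table = filter_repertoire(events_to_table(clones, cfg), min_count=4)

dist = isotype_distribution(table, group_by=("subset",))
print("isotype fractions by subset (clonotype-weighted):")
print(dist.pivot_table(index="subset", columns="isotype",
                       values="fraction").fillna(0).round(3))

for subset in ("immature", "naive", "memory"):
    print(f"switched fraction in {subset}: "
          f"{switched_fraction(table, subset):.3f}")
print("Immature/naive sit near the configured 2% early-switch rate;")
print("memory is dominated by switched isotypes. IgE is absent by design.")

summary = switched_overlap(table)
print(f"\nclass-switched (IgA/IgG) CDR3s shared by all four subsets: "
      f"{summary.shared_by_all()}")
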