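"""Repertoire analytics: diversity, overlap, multiplicity, usage, isotypes.

All analyses operate on the filtered clonotype table and, unless stated
otherwise, on *unique CDR3 amino-acid sequences* — each observed CDR3 is
counted once per grouping unit irrespective of abundance.  Implemented
summaries:

* CDR3 length distributions and amino-acid usage by chain and subset;
* unique-CDR3 set algebra across the four developmental subsets (Venn
  region counts, percentage common to all subsets);
* time-point occurrence histograms (how many time points a CDR3 recurs in);
* CDR3 <-> VJ-combination multiplicity maps;
* V/J gene usage, optionally stratified by health status (self-reported
  illness with hs-CRP > 1.0 mg/L defines infected time points);
* D50 clonality (percentage of clonotypes, ranked by abundance, needed to
  account for half of all reads — low D50 means a clonal repertoire);
* isotype distributions and the early class-switched fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import RepertoireTable
from . import stats as _stats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNSWITCHED = ("IgM", "IgD")


# ---------------------------------------------------------------------------
# Health labels

@dataclass(frozen=True)
class HealthLabel:
    timepoint: int
    self_report_ill: bool
    hs_crp: float | None       # mg/L
    status: str                # healthy | infected | unknown


def label_health(metadata: Iterable[Mapping]) -> list[HealthLabel]:
    """Infected = self-reported illness AND hs-CRP strictly above 1.0 mg/L."""
    out = []
    for row in metadata:
        crp = row.get("hs_crp")
        ill = bool(row.get("self_report_ill", False))
        if crp is None or (isinstance(crp, float) and np.isnan(crp)):
            status = "unknown"
            crp = None
        else:
            status = "infected" if (ill and crp > 1.0) else "healthy"
        out.append(HealthLabel(int(row["timepoint"]), ill, crp, status))
    return out


# ---------------------------------------------------------------------------
# Unique-CDR3 set algebra

def unique_cdr3_sets(t: RepertoireTable,
                     group_by: Sequence[str] = ("chain", "subset")
                     ) -> dict[tuple, set[str]]:
    """Distinct CDR3-aa sets per group (abundance ignored)."""
    out: dict[tuple, set[str]] = {}
    for key, sub in t.df.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = set(sub["cdr3_aa"])
    return out


@dataclass
class OverlapSummary:
    """Venn decomposition of CDR3 sets across B-cell subsets."""

    chain: str | None
    region_counts: dict[frozenset, int]   # exclusive region -> count
    pct_common_all: float                 # 100 * |intersection| / |union|

    def shared_by_all(self) -> int:
        full = frozenset(itertools.chain.from_iterable(self.region_counts))
        return self.region_counts.get(full, 0)


def subset_overlap(sets_by_subset: Mapping[str, set[str]],
                   chain: str | None = None) -> OverlapSummary:
    """Exclusive Venn region counts over the given subset->CDR3-set mapping.

    Region counts sum to the distinct pooled CDR3 count; ``pct_common_all``
    is the intersection of all subsets as a percentage of their union.
    """
    names = sorted(sets_by_subset)
    universe = set().union(*sets_by_subset.values()) if names else set()
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets_by_subset[n] for n in combo))
            outside = set().union(*(sets_by_subset[n] for n in names
                                    if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    common = set.intersection(*(sets_by_subset[n] for n in names)) if names else set()
    pct = 100.0 * len(common) / len(universe) if universe else 0.0
    return OverlapSummary(chain, regions, pct)


def timepoint_occurrence(t: RepertoireTable,
                         group_by: Sequence[str] = ("chain", "subset"),
                         n_timepoints: int | None = None
                         ) -> dict[tuple, pd.Series]:
    """Histogram of the number of time points each CDR3 is seen in.

    Total mass per group equals the number of distinct CDR3s in the group.
    """
    if n_timepoints is None:
        n_timepoints = t.df["timepoint"].nunique()
    out: dict[tuple, pd.Series] = {}
    for key, sub in t.df.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        per_cdr3 = sub.groupby("cdr3_aa")["timepoint"].nunique()
        hist = per_cdr3.value_counts().reindex(
            range(1, n_timepoints + 1), fill_value=0).sort_index()
        out[key] = hist
    return out


# ---------------------------------------------------------------------------
# CDR3 composition

def length_distribution(t: RepertoireTable, by: str = "chain"
                        ) -> dict[tuple, pd.Series]:
    """Length frequencies over unique CDR3-aa per group (sums to 1)."""
    out: dict[tuple, pd.Series] = {}
    for key, sub in t.df.groupby([by] if isinstance(by, str) else list(by),
                                 observed=True):
        key = key if isinstance(key, tuple) else (key,)
        lengths = pd.Series(sorted({c for c in sub["cdr3_aa"]})).str.len()
        out[key] = lengths.value_counts(normalize=True).sort_index()
    return out


def aa_usage(t: RepertoireTable,
             group_by: Sequence[str] = ("chain", "subset")
             ) -> dict[tuple, pd.Series]:
    """Residue frequencies over all positions of unique CDR3s (sums to 1)."""
    out: dict[tuple, pd.Series] = {}
    for key, sub in t.df.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        pooled = "".join(sorted(set(sub["cdr3_aa"])))
        counts = pd.Series(
            {aa: pooled.count(aa) for aa in AA_ALPHABET}, dtype=float)
        total = counts.sum()
        out[key] = counts / total if total else counts
    return out


# ---------------------------------------------------------------------------
# Gene usage

def gene_usage(t: RepertoireTable, gene_class: str = "V",
               group_by: Sequence[str] = ("chain", "subset"),
               health: Sequence[HealthLabel] | None = None,
               use_qc: bool = True) -> pd.DataFrame:
    """Per-group gene usage fractions over unique clonotypes.

    With ``health`` given, groups are additionally stratified into
    healthy/infected time points (unknown time points dropped).  Fractions
    sum to 1 within each group.  Depth-failing samples are excluded when
    ``use_qc``.
    """
    col = {"V": "v_gene", "J": "j_gene"}[gene_class]
    table = t.without_excluded() if use_qc else t
    df = table.df.copy()
    keys = list(group_by)
    if health is not None:
        status = {h.timepoint: h.status for h in health}
        df["health"] = df["timepoint"].map(status)
        df = df[df["health"].isin(["healthy", "infected"])]
        keys = keys + ["health"]
    rows = []
    for key, sub in df.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        frac = sub[col].value_counts(normalize=True)
        for gene, f in frac.items():
            rows.append(dict(zip(keys, key)) | {"gene": gene, "fraction": f})
    return pd.DataFrame(rows)


def gene_usage_by_timepoint(t: RepertoireTable, gene_class: str = "V",
                            chain: str = "heavy", subset: str | None = None,
                            use_qc: bool = True) -> pd.DataFrame:
    """Gene x time point usage-fraction matrix (rows sum to 1)."""
    col = {"V": "v_gene", "J": "j_gene"}[gene_class]
    table = t.without_excluded() if use_qc else t
    df = table.df[table.df["chain"] == chain]
    if subset is not None:
        df = df[df["subset"] == subset]
    mat = (df.groupby(["timepoint", col], observed=True).size()
           .unstack(fill_value=0))
    return mat.div(mat.sum(axis=1), axis=0)


def gene_usage_health_test(t: RepertoireTable, health: Sequence[HealthLabel],
                           gene_class: str = "V", chain: str = "heavy",
                           subset: str | None = None, use_qc: bool = True
                           ) -> pd.DataFrame:
    """Kruskal-Wallis comparison of per-gene usage, healthy vs infected.

    Time points are the replicates: each gene's per-time-point usage
    fractions are split by health status and compared; p-values are BH
    adjusted across genes.
    """
    mat = gene_usage_by_timepoint(t, gene_class, chain, subset, use_qc)
    status = {h.timepoint: h.status for h in health}
    labels = mat.index.map(lambda tp: status.get(tp, "unknown"))
    rows = []
    for gene in mat.columns:
        groups = [mat.loc[labels == s, gene].to_numpy()
                  for s in ("healthy", "infected")]
        if any(len(g) == 0 for g in groups):
            continue
        res = _stats.kruskal_wallis(groups)
        rows.append({"gene": gene, "statistic": res.statistic,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = _stats.bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < 0.05
    return out


# ---------------------------------------------------------------------------
# VJ multiplicity

@dataclass
class MultiplicityMap:
    """Bidirectional CDR3 <-> (V gene, J gene) combination maps."""

    cdr3_to_vj: dict[str, set[tuple[str, str]]]
    vj_to_cdr3: dict[tuple[str, str], set[str]]

    def vj_per_cdr3(self) -> pd.Series:
        """Distribution of the number of VJ combinations per unique CDR3."""
        counts = pd.Series({c: len(v) for c, v in self.cdr3_to_vj.items()})
        return counts.value_counts().sort_index()

    def cdr3_per_vj(self) -> pd.Series:
        counts = pd.Series({vj: len(c) for vj, c in self.vj_to_cdr3.items()})
        return counts.value_counts().sort_index()


def vj_multiplicity(t: RepertoireTable, chain: str = "heavy",
                    exclude_plasmacyte: bool = True,
                    timepoint: int | None = None) -> MultiplicityMap:
    """How many VJ combinations make each CDR3, and vice versa.

    The plasmacyte subset is left out by default (low sorted-cell numbers
    make its clonotype sample unreliable); the two returned maps are exact
    transposes of each other.
    """
    df = t.df[t.df["chain"] == chain]
    if exclude_plasmacyte:
        df = df[df["subset"] != "plasmacyte"]
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    cdr3_to_vj: dict[str, set] = {}
    vj_to_cdr3: dict[tuple[str, str], set] = {}
    for cdr3, v, j in df[["cdr3_aa", "v_gene", "j_gene"]].itertuples(index=False):
        cdr3_to_vj.setdefault(cdr3, set()).add((v, j))
        vj_to_cdr3.setdefault((v, j), set()).add(cdr3)
    return MultiplicityMap(cdr3_to_vj, vj_to_cdr3)


# ---------------------------------------------------------------------------
# Diversity

def d50(t: RepertoireTable, group_by: Sequence[str] | str = "sample_id"
        ) -> dict[tuple, float]:
    """D50 clonality index per group, as a percentage.

    Clonotypes are ranked by descending read count (ties broken by CDR3-aa
    lexicographic order); D50 = 100 * k / N where k is the minimum number of
    top clonotypes whose cumulative reads reach 50% of the total and N is
    the number of distinct clonotypes.  Uniform even-sized groups give
    exactly 50; clonal repertoires give low values.  Empty groups are
    omitted.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    out: dict[tuple, float] = {}
    for key, sub in t.df.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if not len(sub):
            continue
        ordered = sub.sort_values(["read_count", "cdr3_aa"],
                                  ascending=[False, True])
        counts = ordered["read_count"].to_numpy()
        half = counts.sum() / 2.0
        k = int(np.searchsorted(np.cumsum(counts), half) + 1)
        out[key] = 100.0 * k / len(counts)
    return out


# ---------------------------------------------------------------------------
# Isotypes

def isotype_distribution(t: RepertoireTable,
                         group_by: Sequence[str] = ("subset", "timepoint"),
                         weight: str = "clonotype") -> pd.DataFrame:
    """Isotype fractions per group (heavy chain), plus the switched fraction.

    ``weight='clonotype'`` counts each clonotype once; ``weight='read'``
    weights by read count.  The switched fraction is the non-IgM/IgD mass.
    Subclass-ambiguous class-level calls (e.g. "IgG") count toward their
    class.  Fractions sum to 1 within each group.
    """
    df = t.df[(t.df["chain"] == "heavy") & (t.df["c_isotype"] != "")]
    rows = []
    for key, sub in df.groupby(list(group_by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if weight == "read":
            counts = sub.groupby("c_isotype")["read_count"].sum()
        else:
            counts = sub.groupby("c_isotype").size()
        frac = counts / counts.sum()
        switched = frac[~frac.index.str.startswith(UNSWITCHED)].sum()
        for iso, f in frac.items():
            rows.append(dict(zip(group_by, key))
                        | {"isotype": iso, "fraction": float(f),
                           "switched_fraction": float(switched)})
    return pd.DataFrame(rows)


def switched_fraction(t: RepertoireTable, subset: str,
                      weight: str = "clonotype") -> float:
    """Fraction of a subset's heavy-chain repertoire with non-IgM/IgD isotype."""
    dist = isotype_distribution(t, group_by=("subset",), weight=weight)
    sub = dist[dist["subset"] == subset]
    if not len(sub):
        return float("nan")
    return float(sub["switched_fraction"].iloc[0])


def switched_overlap(t: RepertoireTable) -> OverlapSummary:
    """Overlap of class-switched (IgA/IgG/IgE) CDR3s across the four subsets.

    IgM/IgD rows are excluded because naive cells co-express both, which
    would trivially inflate sharing.
    """
    df = t.df[(t.df["chain"] == "heavy")
              & t.df["c_isotype"].str.startswith(("IgA", "IgG", "IgE"))]
    sets = {s: set(sub["cdr3_aa"]) for s, sub in df.groupby("subset", observed=True)}
    return subset_overlap(sets, chain="heavy")
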