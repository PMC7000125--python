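"""Simulator contracts: rearrangement structure, isotypes, dynamics, reads."""

import numpy as np
import pandas as pd
import pytest

from bcrseq import (SimulationConfig, assign_isotype, build_toy_germline,
                    events_to_table, load_truth, sample_recombination,
                    simulate_dataset, simulate_repertoire)
from bcrseq.analytics import d50
from bcrseq.reads import revcomp
from bcrseq.simulate import RecombinationEvent


@pytest.fixture(scope="module")
def db():
    return build_toy_germline(seed=0)


class TestSampleRecombination:
    def test_light_chain_has_no_d_and_one_n_region(self, db, rng):
        for _ in range(50):
            ev = sample_recombination(db, SimulationConfig(), "kappa", rng)
            assert ev.d_id is None and ev.n2 == ""

    def test_event_reassembles_from_parts(self, db, rng):
        cfg = SimulationConfig()
        for chain in ("heavy", "kappa"):
            for _ in range(50):
                ev = sample_recombination(db, cfg, chain, rng)
                v = db[ev.v_id]
                j = db[ev.j_id]
                parts = v.sequence[:len(v.sequence) - ev.v_trim] + ev.n1
                if ev.d_id:
                    d = db[ev.d_id].sequence
                    parts += d[ev.d_trim_5:len(d) - ev.d_trim_3]
                parts += ev.n2 + j.sequence[ev.j_trim:]
                if ev.c_id:
                    parts += db[ev.c_id].sequence
                assert ev.full_nt == parts

    def test_zero_trim_junction_is_pure_anchor_arithmetic(self, db):
        """With no trims and no N bases the CDR3 is fixed by the anchors."""
        v = db.select("heavy", "V")[0]
        j = db.select("heavy", "J")[0]
        ev = RecombinationEvent(event_id="e", clone_id="e", chain="heavy",
                                v_id=v.segment_id, j_id=j.segment_id)
        from bcrseq.simulate import _assemble
        _assemble(ev, db)
        expected = (v.sequence[v.anchor_pos + 3:] + j.sequence[:j.anchor_pos])
        assert ev.cdr3_nt == expected

    def test_uniform_v_usage_recovered_within_3_sigma(self, db, rng):
        cfg = SimulationConfig()
        genes = [s.segment_id for s in db.select("heavy", "V")]
        n = 10_000
        counts = {g: 0 for g in genes}
        for _ in range(n):
            counts[sample_recombination(db, cfg, "heavy", rng).v_id] += 1
        p = 1 / len(genes)
        sigma = np.sqrt(p * (1 - p) / n)
        for g in genes:
            assert abs(counts[g] / n - p) < 3 * sigma + 1e-12


class TestAssignIsotype:
    def _event(self, db, rng, subset):
        ev = sample_recombination(db, SimulationConfig(), "heavy", rng)
        ev.subset = subset
        return ev

    def test_zero_switch_rate_gives_only_igm_igd(self, db, rng):
        cfg = SimulationConfig(switch_rate_early=0.0)
        for _ in range(200):
            ev = assign_isotype(self._event(db, rng, "immature"), cfg, rng, db)
            assert ev.isotype in ("IgM", "IgD")

    def test_early_switched_fraction_within_3_sigma_and_no_ige(self, db, rng):
        cfg = SimulationConfig(switch_rate_early=0.02)
        n = 10_000
        ev = self._event(db, rng, "immature")
        switched = ige = 0
        for _ in range(n):
            ev = assign_isotype(ev, cfg, rng, db)
            if ev.isotype not in ("IgM", "IgD"):
                switched += 1
            if ev.isotype == "IgE":
                ige += 1
        sigma = np.sqrt(0.02 * 0.98 / n)
        assert abs(switched / n - 0.02) < 3 * sigma
        assert ige == 0

    def test_memory_cells_express_switched_isotypes(self, db, rng):
        cfg = SimulationConfig()
        isotypes = {assign_isotype(self._event(db, rng, "memory"),
                                   cfg, rng, db).isotype for _ in range(300)}
        assert isotypes & {"IgG1", "IgG3", "IgA2"}


class TestSimulateRepertoire:
    def test_deterministic_for_fixed_seed(self, db):
        cfg = SimulationConfig(seed=3, n_timepoints=2,
                               subsets={"naive": 40, "memory": 30},
                               clones_per_subset={"naive": 60, "memory": 25})
        a, _ = simulate_repertoire(db, cfg)
        b, _ = simulate_repertoire(db, cfg)
        assert [e.__dict__ for e in a] == [e.__dict__ for e in b]

    def test_zero_persistence_means_single_timepoint_clones(self, db):
        cfg = SimulationConfig(seed=4, n_timepoints=4, persistence_prob=0.0,
                               subsets={"naive": 60},
                               clones_per_subset={"naive": 90})
        clones, _ = simulate_repertoire(db, cfg)
        per_clone = pd.Series([c.timepoint for c in clones],
                              index=[c.clone_id for c in clones])
        assert per_clone.groupby(level=0).nunique().max() == 1

    def test_high_concentration_limit_gives_d50_near_50(self, db):
        """Near-uniform clone sizes are the analytic D50 = 50% limit."""
        cfg = SimulationConfig(
            seed=5, n_timepoints=1, subsets={"naive": 2_000_000},
            clones_per_subset={"naive": 200},
            clone_size_concentration={"naive": 1e6},
            persistence_prob=0.0, productive_fraction=1.0)
        clones, _ = simulate_repertoire(db, cfg)
        table = events_to_table(clones, cfg)
        values = d50(table, group_by="sample_id")
        for v in values.values():
            assert abs(v - 50.0) < 1.0


class TestEmitReads:
    def test_error_free_reads_are_amplicon_substrings(self, db, tmp_path):
        cfg = SimulationConfig(seed=6, n_timepoints=1,
                               subsets={"naive": 30},
                               clones_per_subset={"naive": 40},
                               seq_error_rate=0.0, shm_rate=0.0)
        clones, manifest = simulate_repertoire(db, cfg)
        from bcrseq.simulate import emit_reads, sample_name
        paths = emit_reads(clones, db, cfg, manifest, tmp_path)
        truth = load_truth(paths["truth"])
        amplicons = {c.event_id: c.full_nt for c in clones}
        barcodes = {s["sample_id"]: s["barcode"] for s in manifest["samples"]}
        from bcrseq.reads import read_fastq
        r1 = {r.read_id: r.seq for r in read_fastq(paths["r1"])}
        r2 = {r.read_id: r.seq for r in read_fastq(paths["r2"])}
        for row in truth.itertuples():
            amp = amplicons[row.event_id]
            assert r1[row.read_id] == amp[:cfg.read_len]
            expect_r2 = (barcodes[row.sample_id] + revcomp(amp))[:cfg.read_len]
            assert r2[row.read_id] == expect_r2

    def test_truth_table_is_bijective_with_fastq(self, small_dataset):
        truth = small_dataset["truth"]
        from bcrseq.reads import read_fastq
        ids = [r.read_id for r in read_fastq(small_dataset["paths"]["r1"])]
        assert len(ids) == len(set(ids)) == len(truth)
        assert set(ids) == set(truth["read_id"])

    def test_total_reads_within_4_sigma_of_poisson_sum(self, db, small_dataset):
        truth = small_dataset["truth"]
        manifest = small_dataset["manifest"]
        cfg_dict = manifest["config"]
        rpc = cfg_dict["reads_per_cell"]
        # Poisson mean = reads_per_cell * total cells actually allocated
        cfg = SimulationConfig(seed=cfg_dict["seed"],
                               n_timepoints=cfg_dict["n_timepoints"],
                               subsets=cfg_dict["subsets"],
                               clones_per_subset=cfg_dict["clones_per_subset"],
                               seq_error_rate=0.0, shm_rate=0.0)
        clones, _ = simulate_repertoire(db, cfg)
        lam = rpc * sum(c.abundance for c in clones)
        assert abs(len(truth) - lam) < 4 * np.sqrt(lam)
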