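"""Read-length periodicity selection and P-site offset calibration."""

import numpy as np
import pytest

from riboflow.calibration import (
    CANONICAL_OFFSET,
    NoSignalError,
    OffsetTable,
    cds_start_profile,
    changepoint_offset,
    estimate_offsets,
    frame_usage,
    periodicity_test,
    psites_by_length,
    select_lengths,
    shift_to_psites,
    tis_profile,
    top_covered_cds,
)
from riboflow.ranges import CoverageVector
from riboflow.simulate import make_genome, simulate_riboseq, simulate_rnaseq

from conftest import read_table


def oracle_changepoint(values, positions, w=5):
    """Exhaustive-search oracle over all candidate changepoints."""
    idx0 = -int(positions[0])
    best = None
    for c in range(int(positions[0]) + w, 1):
        i = idx0 + c
        down = values[i : i + w].mean()
        up = values[i - w : i].mean()
        d = down - up
        if best is None or d > best[0] + 1e-12:
            best = (d, [-c])
        elif abs(d - best[0]) <= 1e-12:
            best[1].append(-c)
    offs = sorted(best[1], key=lambda o: (abs(o - 12), o))
    return offs[0]


class TestPeriodicity:
    def test_period3_impulse_train_passes(self):
        v = np.zeros(150)
        v[::3] = 9
        res = periodicity_test(CoverageVector(v), min_reads=100)
        assert res.passes and res.dominant_period == 3.0

    def test_period2_fails(self):
        v = np.zeros(150)
        v[::2] = 9
        res = periodicity_test(CoverageVector(v), min_reads=100)
        assert not res.passes
        assert res.dominant_period == pytest.approx(2.0)

    def test_min_reads_gate(self):
        """A perfectly periodic profile below the read floor is rejected."""
        v = np.zeros(150)
        v[::3] = 1
        v[0] += 999 - v.sum()
        assert v.sum() == 999
        assert not periodicity_test(CoverageVector(v), min_reads=1000).passes
        v[0] += 1
        assert periodicity_test(CoverageVector(v), min_reads=1000).passes

    def test_scale_invariance_of_argmax(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(5.0, 150).astype(float)
        v[::3] += 50
        a = periodicity_test(CoverageVector(v), min_reads=1)
        b = periodicity_test(CoverageVector(v * 7.5), min_reads=1)
        assert a.passes == b.passes
        assert a.dominant_period == b.dominant_period

    def test_all_zero_profile(self):
        res = periodicity_test(CoverageVector(np.zeros(150)))
        assert not res.passes and res.dominant_period is None


class TestTopCovered:
    def _setup(self):
        sim = make_genome(n_genes=10, exon_count_range=(1, 1), seed=5)
        reads, _ = simulate_riboseq(sim.annotation, depth=2000, seed=6)
        return sim.annotation, reads

    def test_fraction_counts(self):
        ann, reads = self._setup()
        assert len(top_covered_cds(reads, ann, fraction=0.10)) == 1
        assert len(top_covered_cds(reads, ann, fraction=1.0)) == 10

    def test_top_gene_is_max_coverage(self):
        ann, reads = self._setup()
        from riboflow.ranges import count_in_region, extract_region

        (winner,) = top_covered_cds(reads, ann, fraction=0.10)
        counts = {
            t.tx_id: count_in_region(reads, extract_region(t, "cds"))
            for t in ann.cds_transcripts()
        }
        assert counts[winner] == max(counts.values())

    def test_tie_breaks_lexicographically(self, tiny_annotation):
        from riboflow.ranges import ReadTable

        assert top_covered_cds(ReadTable.empty(), tiny_annotation, fraction=0.5) == {"txm"}


class TestProfiles:
    def test_cds_start_profile_anchor(self, calib_sim):
        sim, reads, truth = calib_sim
        ann = sim.annotation
        tx = ann.cds_transcripts()[0]
        g = tx.exons.local_to_genomic(tx.cds[0])
        single = read_table([(tx.chrom, tx.strand, g, 28, 5)])
        v = cds_start_profile(single, ann, {tx.tx_id}, 28)
        assert v.values[0] == 5 and v.total == 5

    def test_profile_additivity(self, calib_sim):
        sim, _, _ = calib_sim
        ann = sim.annotation
        txs = ann.cds_transcripts()[:2]
        rows = []
        for tx in txs:
            g = tx.exons.local_to_genomic(tx.cds[0] + 6)
            rows.append((tx.chrom, tx.strand, g, 28, 1))
        v = cds_start_profile(read_table(rows), ann, {t.tx_id for t in txs}, 28)
        assert v.values[6] == 2

    def test_upstream_read_excluded(self, calib_sim):
        sim, _, _ = calib_sim
        ann = sim.annotation
        tx = ann.cds_transcripts()[0]
        g = tx.exons.local_to_genomic(tx.cds[0] - 3)
        v = cds_start_profile(read_table([(tx.chrom, tx.strand, g, 28, 1)]), ann, {tx.tx_id}, 28)
        assert v.total == 0

    def test_tis_profile_position(self, calib_sim):
        sim, _, _ = calib_sim
        ann = sim.annotation
        tx = ann.cds_transcripts()[0]
        g = tx.exons.local_to_genomic(tx.cds[0] - 12)
        v = tis_profile(read_table([(tx.chrom, tx.strand, g, 28, 4)]), ann, 28)
        assert v.values[list(v.positions).index(-12)] == 4


class TestChangepoint:
    def test_step_at_minus_12(self):
        pos = np.arange(-30, 30)
        v = np.where(pos >= -12, 10.0, 0.0)
        assert changepoint_offset(CoverageVector(v, positions=pos)) == 12

    def test_step_at_minus_13(self):
        pos = np.arange(-30, 30)
        v = np.where(pos >= -13, 10.0, 0.0)
        assert changepoint_offset(CoverageVector(v, positions=pos)) == 13

    def test_flat_profile_tie_breaks_to_canonical(self):
        pos = np.arange(-30, 30)
        v = np.full(60, 3.0)
        assert changepoint_offset(CoverageVector(v, positions=pos)) == CANONICAL_OFFSET

    def test_matches_exhaustive_oracle_on_random_profiles(self):
        rng = np.random.default_rng(17)
        pos = np.arange(-30, 30)
        for _ in range(200):
            v = rng.poisson(4.0, 60).astype(float)
            got = changepoint_offset(CoverageVector(v, positions=pos))
            assert got == oracle_changepoint(v, pos)

    def test_no_signal_raises(self):
        pos = np.arange(-30, 30)
        with pytest.raises(NoSignalError):
            changepoint_offset(CoverageVector(np.zeros(60), positions=pos))


class TestSelectionAndShift:
    def test_select_lengths_recovers_periodic_set(self):
        sim = make_genome(n_genes=20, exon_count_range=(1, 1), seed=31)
        reads, _ = simulate_riboseq(
            sim.annotation,
            offsets={25: 12, 28: 12, 29: 13, 35: 12},
            frame0_frac={25: 1 / 3, 28: 0.6, 29: 0.6, 35: 1 / 3},
            depth=40000,
            seed=32,
        )
        results = select_lengths(reads, sim.annotation, min_reads=1000)
        passing = {r.read_length for r in results if r.passes}
        assert passing == {28, 29}

    def test_empty_library(self, tiny_annotation):
        from riboflow.ranges import ReadTable

        assert select_lengths(ReadTable.empty(), tiny_annotation) == []

    def test_offset_recovery(self, calib_sim):
        sim, reads, truth = calib_sim
        offsets = estimate_offsets(reads, sim.annotation, [28, 29])
        assert offsets.offsets == truth["offsets"]

    def test_shift_arithmetic(self):
        table = read_table([("chr1", "+", 100, 28, 1), ("chr1", "-", 127, 28, 2)])
        psites, dropped = shift_to_psites(table, OffsetTable({28: 12}))
        got = {(r.strand, r.pos5) for r in psites.df.itertuples()}
        assert got == {("+", 112), ("-", 115)}
        assert sum(dropped.values()) == 0

    def test_shift_conservation_and_drops(self):
        table = read_table(
            [("chr1", "+", 100, 28, 3), ("chr1", "+", 100, 31, 2), ("chr1", "-", 5, 28, 1)]
        )
        psites, dropped = shift_to_psites(table, OffsetTable({28: 12}))
        # length 31 unknown (2 dropped); '-' read shifted to -7 (1 dropped)
        assert dropped == {"dropped_unknown_length": 2, "dropped_out_of_bounds": 1}
        assert psites.total_weight == table.total_weight - 3

    def test_frame_usage_after_shift(self, calib_sim):
        sim, reads, truth = calib_sim
        offsets = estimate_offsets(reads, sim.annotation, [28, 29])
        psites = psites_by_length(reads, offsets, sim.annotation)
        usage = frame_usage(psites, sim.annotation, by_length=True)
        assert set(usage["length"]) == {28, 29}
        for _, row in usage.iterrows():
            assert row["frame0"] > row["frame1"] and row["frame0"] > row["frame2"]
            assert row[["frame0", "frame1", "frame2"]].sum() == pytest.approx(100.0)

    def test_frame_usage_pure_frame0(self, calib_sim):
        sim, _, _ = calib_sim
        ann = sim.annotation
        tx = ann.cds_transcripts()[0]
        rows = [
            (tx.chrom, tx.strand, tx.exons.local_to_genomic(tx.cds[0] + 3 * k), 1, 1)
            for k in range(5)
        ]
        usage = frame_usage(read_table(rows), ann)
        assert usage.iloc[0]["frame0"] == 100.0

    def test_uniform_reads_rarely_pass(self):
        """RNA-like uniform libraries should not show triplet periodicity."""
        sim = make_genome(n_genes=20, exon_count_range=(1, 1), seed=51)
        hits = 0
        for seed in range(5):
            reads, _ = simulate_rnaseq(sim.annotation, depth=8000, read_length=28, seed=seed)
            results = select_lengths(reads, sim.annotation, min_reads=1000)
            hits += sum(r.passes for r in results)
        assert hits == 0
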