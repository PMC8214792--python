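"""ORF finder vs a brute-force oracle; uORF candidates; negative regions."""

import numpy as np
import pytest

from riboflow.orfs import (
    OrfInterval,
    STOP_CODONS,
    find_orfs,
    near_cognate_starts,
    negative_regions,
    uorf_candidates,
)
from riboflow.simulate import make_genome


def brute_force_orfs(seq, starts, stops, longest_only=False, min_length=6, circular=False):
    """Independent oracle: position-by-position codon walk on the (doubled) sequence.

    For every candidate start position, walk downstream codon by codon until
    the first in-frame stop; report [start, stop_end).  Circular search walks
    the doubled sequence and reports wrap-spanning ORFs (width <= L) once.
    """
    seq = seq.upper()
    L = len(seq)
    s2 = seq + seq if circular else seq
    found = []
    for p in range(L):
        if s2[p : p + 3] not in starts:
            continue
        j = p + 3
        while j + 3 <= len(s2):
            if s2[j : j + 3] in stops:
                end = j + 3
                width = end - p
                if width < min_length:
                    break
                if end <= L:
                    found.append(OrfInterval(p, end, False))
                elif circular and width <= L:
                    found.append(OrfInterval(p, end, True))
                break
            j += 3
    if longest_only:
        best = {}
        for o in found:
            key = (o.end - (L if o.wrapped else 0), o.wrapped)
            if key not in best or o.start < best[key].start:
                best[key] = o
        found = list(best.values())
    return sorted(found, key=lambda o: (o.start, o.end))


class TestFindOrfs:
    def test_simple_orf(self):
        assert find_orfs("ATGAAATAA", {"ATG"}, {"TAA"}) == [OrfInterval(0, 9)]

    def test_nested_starts_longest_only(self):
        seq = "ATGATGAAATAA"
        both = find_orfs(seq, {"ATG"}, {"TAA"}, longest_only=False)
        assert [(o.start, o.end) for o in both] == [(0, 12), (3, 12)]
        longest = find_orfs(seq, {"ATG"}, {"TAA"}, longest_only=True)
        assert [(o.start, o.end) for o in longest] == [(0, 12)]

    def test_circular_wrap(self):
        orfs = find_orfs("TAACCCATG", {"ATG"}, {"TAA"}, circular=True)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.width, o.wrapped) == (6, 6, True)

    def test_no_open_ended_orfs(self):
        assert find_orfs("ATGAAAAAA", {"ATG"}, STOP_CODONS) == []

    def test_n_matches_nothing(self):
        assert find_orfs("ATGAAATNA", {"ATG"}, {"TAA", "TNA"}) == []
        assert find_orfs("ANGAAATAA", {"ATG"}, {"TAA"}) == []

    def test_empty_sequence(self):
        assert find_orfs("", {"ATG"}, {"TAA"}) == []

    def test_min_length_includes_stop(self):
        # ATG TAA has width 6: kept at min_length 6, dropped at 7
        assert find_orfs("ATGTAA", {"ATG"}, {"TAA"}, min_length=6) == [OrfInterval(0, 6)]
        assert find_orfs("ATGTAA", {"ATG"}, {"TAA"}, min_length=7) == []

    def test_overlapping_start_stop_sets_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGTAA", {"ATG", "TAA"}, {"TAA"})

    @pytest.mark.parametrize("longest_only", [False, True])
    @pytest.mark.parametrize("circular", [False, True])
    @pytest.mark.parametrize("start_set", ["atg", "near"])
    def test_oracle_equivalence_random(self, longest_only, circular, start_set):
        """Random-sequence equivalence with the codon-walk oracle."""
        starts = {"ATG"} if start_set == "atg" else set(near_cognate_starts())
        rng = np.random.default_rng(77)
        for _ in range(150):
            L = int(rng.integers(10, 301))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            got = find_orfs(seq, starts, STOP_CODONS, longest_only=longest_only, circular=circular)
            want = brute_force_orfs(seq, starts, STOP_CODONS, longest_only=longest_only, circular=circular)
            assert got == want, seq

    def test_circular_without_wrap_equals_linear(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            lin = find_orfs(seq, {"ATG"}, STOP_CODONS)
            circ = [o for o in find_orfs(seq, {"ATG"}, STOP_CODONS, circular=True) if not o.wrapped]
            assert lin == circ

    def test_no_internal_in_frame_stop(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            for o in find_orfs(seq, {"ATG"}, STOP_CODONS):
                inner = seq[o.start : o.end - 3]
                codons = {inner[i : i + 3] for i in range(3, len(inner), 3)}
                assert not (codons & STOP_CODONS)


class TestNearCognates:
    def test_set_contents(self):
        s = near_cognate_starts()
        assert "ATG" in s and "CTG" in s and "GTG" in s and "TTG" in s
        assert not (s & STOP_CODONS)
        # 1 + 3*3 single-substitution variants minus excluded stops
        assert len(s) == 10


@pytest.fixture(scope="module")
def planted():
    return make_genome(n_genes=8, exon_count_range=(1, 2), plant_uorf_genes=3, seed=21)


class TestUorfCandidates:
    def test_planted_uorfs_found(self, planted):
        recs, _ = uorf_candidates(planted.annotation, planted.genome)
        found = {(r.tx_id, r.start, r.end) for r in recs}
        for tx_id, (s, e) in planted.truth["planted_uorfs"].items():
            assert (tx_id, s, e) in found

    def test_start_codons_in_leader(self, planted):
        recs, _ = uorf_candidates(planted.annotation, planted.genome)
        for r in recs:
            cds_start = planted.annotation.transcripts[r.tx_id].cds[0]
            assert r.start + 3 <= cds_start
            assert r.start_codon == "ATG"
            assert r.stop_codon in STOP_CODONS

    def test_overlap_flagging_and_exclusion(self, planted):
        with_overlap, _ = uorf_candidates(planted.annotation, planted.genome, max_downstream_overlap=True)
        without, _ = uorf_candidates(planted.annotation, planted.genome, max_downstream_overlap=False)
        overlapping = [r for r in with_overlap if r.overlaps_cds]
        kept = {(r.tx_id, r.start, r.end) for r in without}
        for r in overlapping:
            assert (r.tx_id, r.start, r.end) not in kept
        for r in without:
            assert not r.overlaps_cds

    def test_short_leader_skipped(self):
        sim = make_genome(n_genes=3, exon_count_range=(1, 1), seed=2)
        # shrink a leader below one codon by rebuilding the model
        from riboflow.ranges import Annotation, TranscriptModel

        txs = dict(sim.annotation.transcripts)
        first = next(iter(txs))
        tx = txs[first]
        txs[first] = TranscriptModel(tx.tx_id, tx.gene_id, tx.exons, (2, tx.cds[1]))
        ann = Annotation(txs, sim.annotation.chrom_lengths)
        _, skipped = uorf_candidates(ann, sim.genome)
        assert skipped == 1


class TestNegativeRegions:
    def test_determinism(self, spliced_sim):
        a = negative_regions(spliced_sim.annotation, spliced_sim.genome, [30, 60], n=20, seed=4)
        b = negative_regions(spliced_sim.annotation, spliced_sim.genome, [30, 60], n=20, seed=4)
        assert [(r.tx_id, r.start, r.end) for r in a] == [(r.tx_id, r.start, r.end) for r in b]

    def test_widths_from_requested_set(self, spliced_sim):
        regions = negative_regions(spliced_sim.annotation, spliced_sim.genome, [30, 60], n=20, seed=4)
        assert regions
        assert {r.width for r in regions} <= {30, 60}

    def test_contained_in_trailers(self, spliced_sim):
        regions = negative_regions(spliced_sim.annotation, spliced_sim.genome, [30, 60], n=30, seed=5)
        for r in regions:
            tx = spliced_sim.annotation.transcripts[r.tx_id]
            assert tx.cds[1] <= r.start and r.end <= tx.length
            assert r.width % 3 == 0
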