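import random

import pytest

from pgcodec.io_fastq import SyntheticSpec, generate_synthetic_reads
from pgcodec.pg_builder import (OverlapParams, build_lq_and_n_pseudogenomes,
                                build_pseudogenome, dedupe_reads,
                                find_best_successor, verify_pseudogenome)

from _oracles import brute_scs_length


class TestDedupe:
    def test_duplicates_collapsed_in_first_occurrence_order(self):
        uniques, mult = dedupe_reads(["ACGT", "ACGT", "TTTT"])
        assert uniques == ["ACGT", "TTTT"]
        assert mult == {"ACGT": [0, 1], "TTTT": [2]}

    def test_all_distinct_is_identity(self):
        seqs = ["AAAA", "CCCC", "GGGG"]
        uniques, mult = dedupe_reads(seqs)
        assert uniques == seqs
        assert all(v == [i] for i, v in enumerate(mult.values()))

    def test_mass_duplication(self):
        uniques, mult = dedupe_reads(["ACGT"] * 1000)
        assert uniques == ["ACGT"]
        assert mult["ACGT"] == list(range(1000))


class TestBestSuccessor:
    def test_longest_overlap_wins(self):
        idx, ov = find_best_successor(
            "AAACCC", ["CCCGGG", "CCGGGG"], OverlapParams(min_overlap=3))
        assert (idx, ov) == (0, 3)

    def test_no_candidate_above_threshold(self):
        idx, ov = find_best_successor(
            "AAACCC", ["GGGGGG"], OverlapParams(min_overlap=3))
        assert idx is None

    def test_self_overlap_forbidden(self):
        idx, ov = find_best_successor(
            "AAAA", ["AAAA"], OverlapParams(min_overlap=2))
        assert idx is None

    def test_tie_broken_by_lowest_index(self):
        idx, ov = find_best_successor(
            "TTCCC", ["CCCAA", "CCCGG"], OverlapParams(min_overlap=3))
        assert (idx, ov) == (0, 3)


class TestBuildPseudogenome:
    def test_two_overlapping_reads_merge(self):
        pg, leftovers = build_pseudogenome(
            ["AAACCC", "CCCGGG"], OverlapParams(min_overlap=3))
        assert pg.text == "AAACCCGGG"
        assert len(pg.text) == brute_scs_length(["AAACCC", "CCCGGG"])
        assert not leftovers

    def test_non_overlapping_reads_become_leftovers(self):
        pg, leftovers = build_pseudogenome(
            ["AAAAAA", "CCCCCC", "GGGGGG"], OverlapParams(min_overlap=3))
        assert pg.text == "" and leftovers == [0, 1, 2]

    def test_singletons_kept_on_request(self):
        pg, leftovers = build_pseudogenome(
            ["AAAAAA", "CCCCCC"], OverlapParams(min_overlap=3),
            keep_singletons=True)
        assert pg.text == "AAAAAACCCCCC" and not leftovers
        assert verify_pseudogenome(pg, ["AAAAAA", "CCCCCC"])

    def test_high_coverage_collapse(self):
        """20x redundancy of error-free reads collapses the text."""
        ss = generate_synthetic_reads(
            SyntheticSpec(ref_length=10_000, coverage=20, read_length=100,
                          seed=3))
        seqs, _ = dedupe_reads([r.seq for r in ss.reads])
        pg, leftovers = build_pseudogenome(seqs, OverlapParams(min_overlap=50))
        total_bases = sum(len(r.seq) for r in ss.reads)
        assert len(pg.text) < 0.25 * total_bases
        assert verify_pseudogenome(pg, seqs)

    def test_reconstruction_invariant_on_noisy_reads(self, noisy_readset):
        seqs, _ = dedupe_reads([r.seq for r in noisy_readset.reads])
        pg, leftovers = build_pseudogenome(seqs)
        assert verify_pseudogenome(pg, seqs)
        placed = {pl.read_index for pl in pg.placements}
        assert placed.isdisjoint(leftovers)
        assert placed | set(leftovers) == set(range(len(seqs)))

    def test_determinism(self):
        rng = random.Random(5)
        seqs = list({"".join(rng.choice("ACGT") for _ in range(30))
                     for _ in range(200)})
        a, la = build_pseudogenome(seqs, OverlapParams(min_overlap=8))
        b, lb = build_pseudogenome(seqs, OverlapParams(min_overlap=8))
        assert a.text == b.text and a.placements == b.placements and la == lb

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_within_twice_optimal(self, seed):
        """Greedy superstring <= 2x the exact minimum (brute force oracle)."""
        rng = random.Random(seed)
        n = rng.randint(4, 7)
        seqs = list({"".join(rng.choice("ACGT") for _ in range(rng.randint(6, 12)))
                     for _ in range(n)})
        pg, leftovers = build_pseudogenome(
            seqs, OverlapParams(min_overlap=1), keep_singletons=True)
        assert not leftovers
        assert verify_pseudogenome(pg, seqs)
        assert len(pg.text) <= 2 * brute_scs_length(seqs)


class TestLqAndNPseudogenomes:
    def test_empty_lq_set(self):
        pg_lq, pg_n = build_lq_and_n_pseudogenomes([], ["ANNA"])
        assert pg_lq.text == ""
        assert pg_n.text == "ANNA"

    def test_every_read_recoverable(self, noisy_readset):
        from pgcodec.read_division import divide_reads
        part = divide_reads(noisy_readset.reads)
        lq = [noisy_readset.reads[i].seq for i in part.lq_rejected]
        nn = [noisy_readset.reads[i].seq for i in part.n_reads]
        lqu, _ = dedupe_reads(lq)
        nnu, _ = dedupe_reads(nn)
        pg_lq, pg_n = build_lq_and_n_pseudogenomes(lqu, nnu)
        assert verify_pseudogenome(pg_lq, lqu)
        assert verify_pseudogenome(pg_n, nnu)
        assert len(pg_lq.placements) == len(lqu)  # nothing discarded
        assert len(pg_n.placements) == len(nnu)
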