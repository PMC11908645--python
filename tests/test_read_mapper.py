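import random

import pytest

from pgcodec.io_fastq import reverse_complement
from pgcodec.read_mapper import (MapperParams, MappingResult,
                                 build_sparse_index, decode_mapping_streams,
                                 emit_mapping_streams, map_read,
                                 max_mismatches, reconstruct_read)

PARAMS = MapperParams(M=3, k=16, step=8)


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestMaxMismatches:
    @pytest.mark.parametrize("length,M,expected", [
        (100, 3, 33), (3, 3, 1), (149, 3, 49),
    ])
    def test_examples(self, length, M, expected):
        assert max_mismatches(length, M) == expected

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            max_mismatches(0, 3)


class TestSparseIndex:
    def test_text_of_length_k_single_entry(self):
        idx = build_sparse_index("A" * 16, PARAMS)
        assert idx.table == {"A" * 16: [0]}

    def test_homopolymer_sampling_count(self):
        idx = build_sparse_index("A" * 100, MapperParams(k=10, step=5))
        assert idx.table["A" * 10] == list(range(0, 95, 5))

    def test_n_windows_skipped(self):
        idx = build_sparse_index("ANAC" * 10, MapperParams(k=8, step=4))
        assert idx.table == {}

    def test_indexed_positions_respect_stride(self):
        rng = random.Random(0)
        idx = build_sparse_index(_random_dna(rng, 500), PARAMS)
        for positions in idx.table.values():
            for p in positions:
                assert p % idx.step == 0 and p + idx.k <= 500


class TestMapRead:
    def _pg(self, seed=1, n=2000):
        text = _random_dna(random.Random(seed), n)
        return text, build_sparse_index(text, PARAMS)

    def test_exact_substring_maps_with_zero_mismatches(self):
        text, idx = self._pg()
        res = map_read(text[500:600], idx, text, PARAMS)
        assert res.mapped and res.offset == 500 and res.strand == "fwd"
        assert res.mismatch_positions == ()

    def test_reverse_complement_substring_maps_rc(self):
        text, idx = self._pg()
        read = reverse_complement(text[700:800])
        res = map_read(read, idx, text, PARAMS)
        assert res.mapped and res.strand == "rc" and res.offset == 700
        assert reconstruct_read(res, text) == read

    def test_read_exceeding_mismatch_budget_is_unmapped(self):
        text, idx = self._pg()
        read = list(text[300:400])
        rng = random.Random(4)
        # plant 34 substitutions > floor(100/3), away from the seed region
        for p in rng.sample(range(24, 100), 34):
            read[p] = next(c for c in "ACGT" if c != read[p])
        res = map_read("".join(read), idx, text, PARAMS)
        assert not res.mapped

    def test_seed_guarantee_with_planted_mismatches(self):
        """All mismatches beyond the first k+step-1 symbols: must be found."""
        text, idx = self._pg(seed=8)
        guard = PARAMS.k + PARAMS.resolve_step() - 1
        rng = random.Random(9)
        for start in (0, 512, 1234):
            read = list(text[start:start + 100])
            budget = max_mismatches(100, PARAMS.M)
            for p in rng.sample(range(guard, 100), budget):
                read[p] = next(c for c in "ACGT" if c != read[p])
            res = map_read("".join(read), idx, text, PARAMS)
            assert res.mapped
            assert len(res.mismatch_positions) <= budget
            assert reconstruct_read(res, text) == "".join(read)

    def test_read_shorter_than_seed_is_unmapped(self):
        text, idx = self._pg()
        assert not map_read(text[10:20], idx, text, PARAMS).mapped

    def test_mismatch_record_invariants(self):
        text, idx = self._pg(seed=12)
        rng = random.Random(13)
        read = list(reverse_complement(text[900:1000]))
        # in read coordinates the rc target's seed region is the read's tail
        for p in rng.sample(range(5, 70), 10):
            read[p] = next(c for c in "ACGT" if c != read[p])
        res = map_read("".join(read), idx, text, PARAMS)
        assert res.mapped and res.strand == "rc"
        assert list(res.mismatch_positions) == sorted(set(res.mismatch_positions))
        assert all(p < 100 for p in res.mismatch_positions)
        assert reconstruct_read(res, text) == "".join(read)


class TestMappingStreams:
    def _results(self):
        return [
            MappingResult(0, True, 100, 10, "fwd", (3, 17, 40), "ACG"),
            MappingResult(1, False, 90),
            MappingResult(2, True, 100, 14, "rc", (), ""),
            MappingResult(3, True, 80, 14, "fwd", (0, 79), "TN"),
            MappingResult(4, False, 100),
        ]

    def test_round_trip_is_identity(self):
        results = self._results()
        assert decode_mapping_streams(emit_mapping_streams(results)) == results

    def test_offsets_delta_coded_in_sorted_order(self):
        streams = emit_mapping_streams(self._results())
        from pgcodec._util import ByteReader
        deltas = []
        r = ByteReader(streams.offsets)
        while not r.exhausted:
            deltas.append(r.read_uvarint())
        assert deltas == [10, 4, 0]

    def test_empty_result_list(self):
        assert decode_mapping_streams(emit_mapping_streams([])) == []
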