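import numpy as np
import pytest

from genomepair.formats import AlignmentBlock, SequenceRecord, \
    reverse_complement
from genomepair.structural import (RegionSummary, anchor_align,
                                   detect_inversions, detect_specific_regions,
                                   filter_blocks, summarize_region,
                                   summarize_table)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestAnchorAlign:
    def test_identical_sequences_single_full_block(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 10_000)
        a = [SequenceRecord("c", s)]
        (b,) = anchor_align(a, a, min_block=5_000)
        assert (b.ref_start, b.ref_end) == (0, 10_000)
        assert (b.qry_start, b.qry_end) == (0, 10_000)
        assert b.orientation == "forward" and b.percent_identity == 100.0

    def test_reverse_complement_single_reverse_block(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng, 10_000)
        ref = [SequenceRecord("c", s)]
        qry = [SequenceRecord("d", reverse_complement(s))]
        (b,) = anchor_align(ref, qry, min_block=5_000)
        assert b.orientation == "reverse" and b.percent_identity == 100.0
        assert (b.ref_start, b.ref_end) == (0, 10_000)
        assert (b.qry_start, b.qry_end) == (0, 10_000)

    def test_swapped_halves_give_two_blocks(self):
        rng = np.random.default_rng(2)
        s = _random_seq(rng, 10_000)
        swapped = s[5_000:] + s[:5_000]
        blocks = anchor_align([SequenceRecord("a", s)],
                              [SequenceRecord("b", swapped)],
                              min_block=4_000)
        assert len(blocks) == 2
        for b in sorted(blocks, key=lambda x: x.ref_start):
            # verify by direct substring comparison
            assert s[b.ref_start:b.ref_end] \
                == swapped[b.qry_start:b.qry_end]
        starts = sorted((b.ref_start, b.qry_start) for b in blocks)
        assert starts == [(0, 5_000), (5_000, 0)]

    def test_self_alignment_full_identity(self, small_pair):
        _, genome_a, _, _, _, _ = small_pair
        blocks = anchor_align(genome_a, genome_a, min_block=10_000)
        full = [b for b in blocks if b.orientation == "forward"
                and b.ref_seqid == b.qry_seqid
                and b.ref_start == 0 and b.ref_end == len(genome_a[0])]
        # every chromosome aligns to itself end to end at identity 100
        selfs = {b.ref_seqid for b in blocks
                 if b.ref_seqid == b.qry_seqid and b.ref_start == 0
                 and b.percent_identity == 100.0
                 and b.ref_span == b.qry_span}
        assert selfs == {g.id for g in genome_a}


class TestFilterBlocks:
    def _blk(self, ident=99.0, span=5_000):
        return AlignmentBlock("r", 0, span, "q", 0, span, "forward", ident)

    def test_identity_boundary(self):
        assert filter_blocks([self._blk(ident=94.9)]) == []
        assert len(filter_blocks([self._blk(ident=95.0)])) == 1

    def test_length_boundary(self):
        assert filter_blocks([self._blk(span=3_999)]) == []
        assert len(filter_blocks([self._blk(span=4_000)])) == 1

    def test_empty_input(self):
        assert filter_blocks([]) == []


def _cover_blocks(seqid, intervals):
    return [AlignmentBlock(seqid, s, e, "q", s, e, "forward", 99.0)
            for s, e in intervals]


class TestSpecificRegions:
    def test_hand_trace_gap(self):
        genome = [SequenceRecord("c", "A" * 10_000)]
        blocks = _cover_blocks("c", [(0, 4_000), (6_000, 10_000)])
        regs = detect_specific_regions(genome, [blocks], min_region=1_000,
                                       merge_gap=0)
        assert [(r.seqid, r.start, r.end) for r in regs] == [("c", 4_000,
                                                              6_000)]

    def test_full_coverage_no_regions(self):
        genome = [SequenceRecord("c", "A" * 10_000)]
        blocks = _cover_blocks("c", [(0, 10_000)])
        assert detect_specific_regions(genome, [blocks], 1_000, 0) == []

    def test_specific_means_specific_to_all_comparators(self):
        genome = [SequenceRecord("c", "A" * 10_000)]
        cmp1 = _cover_blocks("c", [(0, 4_000)])       # [4000,10000) uncovered
        cmp2 = _cover_blocks("c", [(3_000, 8_000)])   # covers part of it
        regs = detect_specific_regions(genome, [cmp1, cmp2], 1_000, 0)
        assert [(r.start, r.end) for r in regs] == [(8_000, 10_000)]

    def test_unknown_ref_seqid_rejected(self):
        genome = [SequenceRecord("c", "A" * 100)]
        bad = _cover_blocks("zzz", [(0, 50)])
        with pytest.raises(ValueError, match="zzz"):
            detect_specific_regions(genome, [bad], 10, 0)

    def test_merge_gap_glues_across_short_covered_stretch(self):
        genome = [SequenceRecord("c", "A" * 20_000)]
        blocks = _cover_blocks("c", [(5_000, 5_400), (10_000, 20_000)])
        regs = detect_specific_regions(genome, [blocks], min_region=1_000,
                                       merge_gap=500)
        assert [(r.start, r.end) for r in regs] == [(0, 10_000)]

    def test_brute_force_oracle_fuzz(self):
        """Region calls match per-base coverage counting on random
        instances."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            L = int(rng.integers(5_000, 100_000))
            genome = [SequenceRecord("c", "A" * L)]
            n_cmp = int(rng.integers(1, 4))
            block_sets, arrays = [], []
            for _c in range(n_cmp):
                n_blocks = int(rng.integers(0, 10))
                ivs = []
                for _b in range(n_blocks):
                    s = int(rng.integers(0, L - 1))
                    e = int(min(L, s + rng.integers(1, L // 2)))
                    if e > s:
                        ivs.append((s, e))
                block_sets.append(_cover_blocks("c", ivs))
                arr = np.zeros(L, dtype=bool)
                for s, e in ivs:
                    arr[s:e] = True
                arrays.append(arr)
            min_region = int(rng.integers(1, 5_000))
            regs = detect_specific_regions(genome, block_sets,
                                           min_region=min_region, merge_gap=0)
            uncovered = ~np.logical_or.reduce(
                [np.zeros(L, dtype=bool)] + arrays) \
                if not arrays else np.all(~np.array(arrays), axis=0)
            # brute-force runs of uncovered bases
            expected = []
            start = None
            for i in range(L + 1):
                if i < L and uncovered[i]:
                    if start is None:
                        start = i
                elif start is not None:
                    if i - start >= min_region:
                        expected.append((start, i))
                    start = None
            assert [(r.start, r.end) for r in regs] == expected

    def test_monotonicity_in_min_region(self):
        genome = [SequenceRecord("c", "A" * 50_000)]
        blocks = _cover_blocks("c", [(10_000, 12_000), (20_000, 40_000)])
        r_small = detect_specific_regions(genome, [blocks], 1_000, 0)
        r_large = detect_specific_regions(genome, [blocks], 9_000, 0)
        assert {(r.start, r.end) for r in r_large} \
            <= {(r.start, r.end) for r in r_small}


class TestInversions:
    def _rev(self, rs, re_, qs, qe):
        return AlignmentBlock("r", rs, re_, "q", qs, qe, "reverse", 99.0)

    def test_single_reverse_block(self):
        (c,) = detect_inversions([self._rev(100, 200, 500, 600)])
        assert (c.ref_start, c.ref_end) == (100, 200)
        assert (c.qry_start, c.qry_end) == (500, 600)
        assert c.n_blocks == 1

    def test_all_forward_empty(self):
        fwd = AlignmentBlock("r", 0, 100, "q", 0, 100, "forward", 99.0)
        assert detect_inversions([fwd]) == []

    def test_chain_within_gap(self):
        blocks = [self._rev(0, 1_000, 9_000, 10_000),
                  self._rev(1_500, 2_500, 7_500, 8_500)]
        (c,) = detect_inversions(blocks, chain_gap=1_000)
        assert c.n_blocks == 2
        assert (c.ref_start, c.ref_end) == (0, 2_500)
        assert (c.qry_start, c.qry_end) == (7_500, 10_000)

    def test_far_blocks_not_chained(self):
        blocks = [self._rev(0, 1_000, 9_000, 10_000),
                  self._rev(50_000, 51_000, 500, 1_500)]
        calls = detect_inversions(blocks, chain_gap=1_000)
        assert len(calls) == 2 and all(c.n_blocks == 1 for c in calls)


class TestSummarizeRegion:
    def test_n_and_gc_percent(self):
        rec = SequenceRecord("c", "NNNNNAAAAA")
        s = summarize_region(("c", 0, 10), rec, [])
        assert s.pct_n == 50.0 and s.pct_gc == 0.0

    def test_feature_clipping(self):
        from genomepair.formats import Annotation
        rec = SequenceRecord("c", "A" * 2_000)
        anns = [Annotation("c", "s", "gene", 101, 200),
                Annotation("c", "s", "gene", 951, 1_050)]
        s = summarize_region(("c", 0, 1_000), rec, anns)
        assert s.n_genes == 2 and s.cum_gene_len_bp == 150

    def test_no_overlapping_annotations(self):
        rec = SequenceRecord("c", "ACGT" * 100)
        s = summarize_region(("c", 0, 400), rec, [])
        assert (s.n_genes, s.n_tes, s.n_rdna) == (0, 0, 0)
        assert (s.cum_gene_len_bp, s.cum_te_len_bp, s.cum_rdna_len_bp) \
            == (0, 0, 0)

    def test_out_of_bounds_rejected(self):
        rec = SequenceRecord("c", "ACGT")
        with pytest.raises(ValueError, match="out of bounds"):
            summarize_region(("c", 0, 10), rec, [])


# The six published 'Z1'-specific regions of the B. rapa 'Z1' vs 'Chiifu'
# comparison, used as a fixed reference input.
REGION_ROWS = [
    # seqid, start, end, length, pct_n, pct_gc, n_genes, cum_gene, n_tes,
    # cum_te, n_rdna, cum_rdna
    ("A01", 16062101, 23330349, 7268248, 25.51, 30.39, 230, 360211, 3207,
     4608900, 47, 157414),
    ("A05", 0, 6383565, 6383565, 24.99, 35.01, 118, 709602, 2549,
     4337199, 7, 22711),
    ("A05", 19127968, 33629471, 14501503, 21.90, 36.61, 153, 947497, 6431,
     11118253, 18, 57395),
    ("A06", 12173305, 42412226, 30238921, 29.87, 32.49, 419, 2408139, 12363,
     19669728, 61, 193702),
    ("A08", 6540348, 8868417, 2328069, 27.25, 29.90, 8, 1953, 580,
     1554720, 0, 0),
    ("A09", 21830259, 34184774, 12354515, 54.00, 22.20, 35, 268743, 3370,
     5288282, 20, 64209),
]


def region_summaries():
    return [RegionSummary(seqid=r[0], start=r[1], end=r[2], length_bp=r[3],
                          pct_n=r[4], pct_gc=r[5], n_genes=r[6],
                          cum_gene_len_bp=r[7], n_tes=r[8],
                          cum_te_len_bp=r[9], n_rdna=r[10],
                          cum_rdna_len_bp=r[11])
            for r in REGION_ROWS]


class TestSummarizeTable:
    def test_region_length_statistics(self):
        stats = summarize_table(region_summaries())
        assert stats["length_bp"]["mean"] == 12_179_136
        assert stats["length_bp"]["median"] == 9_811_381
        assert stats["length_bp"]["sum"] == 73_074_821

    def test_gene_count_statistics(self):
        stats = summarize_table(region_summaries())
        assert stats["n_genes"]["sum"] == 963
        assert stats["n_genes"]["mean"] == 160.5
        assert stats["n_genes"]["median"] == 135.5

    def test_rdna_count_statistics(self):
        stats = summarize_table(region_summaries())
        assert stats["n_rdna"]["mean"] == 25.5
        assert stats["n_rdna"]["median"] == 19

    def test_n_percent_statistics(self):
        stats = summarize_table(region_summaries())
        assert stats["pct_n"]["mean"] == 30.59
        assert stats["pct_n"]["median"] == 26.38

    def test_even_count_median_is_midpoint(self):
        rows = region_summaries()[:2]
        stats = summarize_table(rows)
        assert stats["n_genes"]["median"] == (230 + 118) / 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_table([])
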