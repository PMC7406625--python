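import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dormqtl.binmap import (BinCallConfig, Breakpoint, WindowBinCaller,
                            binmap_summary, build_binmap, call_windows,
                            collapse_blocks)
from dormqtl.io import SNPMatrix

from _oracle import oracle_blocks_breakpoints, oracle_window_calls

CFG = BinCallConfig()


def _calls(s):
    return np.array(list(s), dtype="<U1")


class TestCallWindows:
    @pytest.mark.parametrize("a,b,expected", [
        (12, 3, "A"),   # the published 12:3 rule verbatim
        (3, 12, "B"),
        (8, 7, "U"),    # between thresholds
        (13, 2, "A"),   # more extreme than 12:3
        (2, 13, "B"),
    ])
    def test_ratio_rule_full_window(self, a, b, expected):
        wc, _ = call_windows(_calls("A" * a + "B" * b), CFG)
        assert wc[0] == expected

    def test_min_informative_guard(self):
        wc, _ = call_windows(_calls("-" * 14 + "A"), CFG)
        assert wc[0] == "U"

    def test_proportional_rule_with_missing(self):
        # 8 informative of 15, all donor: 8/8 >= 0.8 -> A
        wc, _ = call_windows(_calls("A" * 8 + "-" * 7), CFG)
        assert wc[0] == "A"
        # 8 informative, 6:2 = 0.75 < 0.8 -> undetermined
        wc, _ = call_windows(_calls("A" * 6 + "B" * 2 + "-" * 7), CFG)
        assert wc[0] == "U"

    def test_short_sequence_single_window(self):
        wc, starts = call_windows(_calls("A" * 10), CFG)
        assert len(wc) == 1 and starts[0] == 0 and wc[0] == "A"

    def test_window_count_and_step(self):
        wc, starts = call_windows(_calls("A" * 30), CFG)
        assert len(wc) == 16
        wc2, starts2 = call_windows(_calls("A" * 30),
                                    BinCallConfig(step=5))
        assert list(starts2) == [0, 5, 10, 15]


class TestCollapseBlocks:
    def test_homogeneous_line(self):
        pos = np.arange(1, 31) * 1000
        wc, ws = call_windows(_calls("A" * 30), CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, 40_000, CFG, "chr1", "L")
        assert len(blocks) == 1 and not breaks
        assert blocks[0].genotype == "A"
        assert (blocks[0].start_bp, blocks[0].end_bp) == (0, 40_000)

    def test_two_block_breakpoint_at_gap_midpoint(self):
        # 20 A then 20 B: one breakpoint at the midpoint of the central gap
        pos = np.arange(1, 41) * 1000
        wc, ws = call_windows(_calls("A" * 20 + "B" * 20), CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, 50_000, CFG, "chr1", "L")
        assert [b.genotype for b in blocks] == ["A", "B"]
        assert len(breaks) == 1
        assert breaks[0].pos == (20_000 + 21_000) // 2
        assert blocks[0].end_bp == breaks[0].pos == blocks[1].start_bp

    def test_undetermined_run_split_at_span_midpoint(self):
        # A-run, missing-data run (undetermined), B-run
        pos = np.arange(1, 51) * 1000
        seq = "A" * 20 + "-" * 10 + "B" * 20
        wc, ws = call_windows(_calls(seq), CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, 60_000, CFG, "chr1", "L")
        assert [b.genotype for b in blocks] == ["A", "B"]
        assert len(breaks) == 1
        # breakpoint inside the uncalled region between the determined flanks
        assert 20_000 < breaks[0].pos < 31_000

    def test_fully_undetermined_chromosome(self):
        pos = np.arange(1, 31) * 1000
        wc, ws = call_windows(_calls("-" * 30), CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, 40_000, CFG, "chr1", "L")
        assert len(blocks) == 1 and blocks[0].genotype == "U" and not breaks

    def test_blocks_tile_chromosome(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 10 ** 6), size=80, replace=False))
        seq = rng.choice(list("AB-"), size=80, p=[0.45, 0.45, 0.1])
        wc, ws = call_windows(seq.astype("<U1"), CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, 10 ** 6, CFG, "chr1", "L")
        assert blocks[0].start_bp == 0 and blocks[-1].end_bp == 10 ** 6
        for left, right in zip(blocks, blocks[1:]):
            assert left.end_bp == right.start_bp
            assert left.last + 1 == right.first


class TestOracleEquivalence:
    """The vectorized caller against an independent brute-force derivation."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("AB-H"), min_size=15, max_size=120),
           st.integers(0, 10 ** 6))
    def test_window_calls_match_bruteforce(self, seq, salt):
        calls = _calls("".join(seq))
        wc, starts = call_windows(calls, CFG)
        owc, ostarts = oracle_window_calls(calls, 15, 1, 12, 3, 8)
        assert list(wc) == owc and list(starts) == ostarts

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("AB-"), min_size=15, max_size=100))
    def test_blocks_and_breakpoints_match_bruteforce(self, seq):
        calls = _calls("".join(seq))
        n = len(calls)
        pos = np.arange(1, n + 1) * 997  # irregular-ish spacing
        chrom_len = int(pos[-1] + 500)
        wc, ws = call_windows(calls, CFG)
        blocks, breaks = collapse_blocks(wc, ws, pos, chrom_len, CFG, "c", "L")
        oblocks, obreaks = oracle_blocks_breakpoints(
            calls, pos, chrom_len, 15, 1, 12, 3, 8)
        assert [(b.genotype, b.first, b.last, b.start_bp, b.end_bp)
                for b in blocks] == oblocks
        assert [b.pos for b in breaks] == obreaks


class TestBuildBinMap:
    LENGTHS = {"chr1": 30_000, "chr2": 20_000}

    def test_no_breakpoints_one_bin_per_chromosome(self):
        bm = build_binmap([], self.LENGTHS)
        assert bm.n_bins == 2
        assert list(bm.bins["start"]) == [0, 0]
        assert list(bm.bins["end"]) == [30_000, 20_000]

    def test_partition_definition(self):
        bps = [Breakpoint("chr1", 10_000, "L1"), Breakpoint("chr1", 20_000, "L2")]
        bm = build_binmap(bps, {"chr1": 30_000})
        assert [(r.start, r.end) for r in bm.bins.itertuples()] == [
            (0, 10_000), (10_000, 20_000), (20_000, 30_000)]

    def test_n_unique_positions_gives_n_plus_one_bins(self, rng):
        pos = rng.choice(np.arange(1, 30_000), size=12, replace=False)
        bps = [Breakpoint("chr1", int(p), f"L{i}") for i, p in enumerate(pos)]
        bps.append(Breakpoint("chr1", int(pos[0]), "dup"))  # duplicate position
        bm = build_binmap(bps, {"chr1": 30_000})
        assert bm.n_bins == 13

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            build_binmap([Breakpoint("chr1", 30_000, "L")], {"chr1": 30_000})

    def test_merge_tolerance(self):
        bps = [Breakpoint("chr1", 10_000, "L1"), Breakpoint("chr1", 10_004, "L2")]
        assert build_binmap(bps, {"chr1": 30_000}, merge_tol=10).n_bins == 2
        assert build_binmap(bps, {"chr1": 30_000}, merge_tol=0).n_bins == 3

    def test_order_invariance(self, tiny, tiny_bins):
        # reversing line order leaves the bin partition unchanged
        reordered = tiny.snp.subset_lines(list(reversed(tiny.snp.line_ids)))
        caller2 = WindowBinCaller().fit(reordered, chrom_lengths=tiny.gmap.lengths_bp)
        assert caller2.bin_map_.bins[["chrom", "start", "end"]].equals(
            tiny_bins.bin_map_.bins[["chrom", "start", "end"]])


class TestSummary:
    def test_median_convention(self):
        bins = pd.DataFrame({"bin_id": ["Bin1", "Bin2", "Bin3"], "chrom": ["c"] * 3,
                             "start": [0, 1, 3], "end": [1, 3, 6]})
        from dormqtl.binmap import BinMap
        s = binmap_summary(BinMap(bins, {"c": 6}))
        assert s["median_length"] == 2 and s["min_length"] == 1 and s["max_length"] == 3
        even = BinMap(bins.iloc[:2].copy(), {"c": 3})
        assert binmap_summary(even)["median_length"] == 1.5

    def test_extremes(self):
        from dormqtl.binmap import BinMap
        bins = pd.DataFrame({"bin_id": ["Bin1", "Bin2"], "chrom": ["c"] * 2,
                             "start": [0, 30_000], "end": [30_000, 3_030_000]})
        s = binmap_summary(BinMap(bins, {"c": 3_030_000}))
        assert (s["min_length"], s["max_length"]) == (30_000, 3_000_000)


class TestGenotypeBins:
    def test_single_line_projection_identity(self):
        markers = pd.DataFrame({"chrom": ["chr1"] * 40,
                                "pos": np.arange(1, 41) * 1000,
                                "marker_id": [f"m{i}" for i in range(40)]})
        m = SNPMatrix(["L0"], markers,
                      np.array([list("A" * 20 + "B" * 20)], dtype="<U1"))
        caller = WindowBinCaller().fit(m, chrom_lengths={"chr1": 50_000})
        bg = caller.bin_genotypes_
        assert list(bg.calls[0]) == ["A", "B"]

    def test_no_bin_crosses_a_line_breakpoint(self, tiny_bins):
        # strict projection would raise otherwise; also check boundaries align
        bounds = set()
        for row in tiny_bins.bin_map_.bins.itertuples():
            bounds.add((row.chrom, row.start))
        for bp in tiny_bins.breakpoints_:
            assert (bp.chrom, bp.pos) in bounds

    def test_cssl_single_segment_bins(self):
        from dormqtl.sim import GeneticMap, PopulationSpec, simulate_cssl_population
        gmap = GeneticMap.regular(n_chrom=2, markers_per_chrom=60)
        spec = PopulationSpec("CSSL", 30, seed=21, max_donor_segments=1)
        snp, truth = simulate_cssl_population(spec, gmap)
        caller = WindowBinCaller().fit(snp, chrom_lengths=gmap.lengths_bp)
        bg = caller.bin_genotypes_
        bins = bg.bins
        for i, lid in enumerate(bg.line_ids):
            (chrom, s, e), = truth.donor_segments(lid)
            if e - s < 2 * 15 * 270_000:  # smaller than twice the window span
                continue
            inner = ((bins["chrom"] == chrom) & (bins["start"] >= s)
                     & (bins["end"] <= e)).to_numpy()
            assert (bg.calls[i, inner] == "A").all()
            outer = ((bins["chrom"] != chrom) | (bins["end"] <= s)
                     | (bins["start"] >= e)).to_numpy()
            assert "A" not in set(bg.calls[i, outer])

    def test_transform_on_fit_lines_reproduces_fit(self, tiny, tiny_bins):
        bg2 = tiny_bins.transform(tiny.snp)
        assert (bg2.calls == tiny_bins.bin_genotypes_.calls).all()

    def test_numeric_coding(self):
        from dormqtl.binmap import BinGenotypes
        bins = pd.DataFrame({"bin_id": ["Bin1", "Bin2", "Bin3"], "chrom": ["c"] * 3,
                             "start": [0, 1, 2], "end": [1, 2, 3]})
        calls = np.array([["A", "B", "A"], ["B", "-", "A"], ["A", "A", "A"]], dtype="<U1")
        X, kept, dropped = BinGenotypes(["a", "b", "c"], bins, calls).to_numeric()
        assert dropped == ["Bin3"]  # constant after imputation
        assert X.shape == (3, 2)
        assert X[1, 1] == pytest.approx(0.5)  # '-' imputed with the bin mean of {0, 1}
        assert list(X[:, 0]) == [1.0, 0.0, 1.0]
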