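"""Expression analysis: CPM, NB Wald DE calibration/power, Spearman and
Wilcoxon oracles, tristile integration, correspondence tables and genetic
summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pseudom6a import integrate as ig
from pseudom6a.merip import GeneM6ALevel
from pseudom6a.synthetic import (
    SimConfig,
    simulate_expression,
    simulate_genome_annotation,
)


def nb_counts(rng, mu, phi, size):
    lam = rng.gamma(1 / phi, np.asarray(mu) * phi, size=size)
    return rng.poisson(lam)


def make_matrix(counts, n_t, n_n, prefix="S"):
    samples = [f"{prefix}{i}" for i in range(n_t + n_n)]
    cond = pd.Series(["tumour"] * n_t + ["normal"] * n_n, index=samples)
    frame = pd.DataFrame(counts, columns=samples)
    frame.index = [f"g{i}" for i in range(len(frame))]
    return ig.ExpressionMatrix(frame, cond)


class TestNormalizeCpm:
    def test_single_gene_full_depth(self):
        out = ig.normalize_cpm(pd.DataFrame({"s": [10]}))
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s": [10, 30, 60]})
        a = ig.normalize_cpm(counts)
        b = ig.normalize_cpm(counts * 2)
        pd.testing.assert_frame_equal(a, b)

    def test_hand_computed_3x2(self):
        counts = pd.DataFrame({"a": [1, 2, 7], "b": [5, 5, 10]})
        out = ig.normalize_cpm(counts)
        assert out["a"].tolist() == [1e5, 2e5, 7e5]
        assert out["b"].tolist() == [2.5e5, 2.5e5, 5e5]

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError, match="zero-depth"):
            ig.normalize_cpm(pd.DataFrame({"a": [1], "b": [0]}))


class TestDifferentialExpression:
    def test_requires_two_samples_per_group(self):
        m = make_matrix(np.ones((5, 3), dtype=int), 1, 2)
        with pytest.raises(ValueError):
            ig.differential_expression(m)

    def test_identical_groups_elementwise_zero_lfc(self):
        rng = np.random.default_rng(0)
        block = nb_counts(rng, 100, 0.1, (50, 4))
        counts = np.column_stack([block, block])
        m = make_matrix(counts, 4, 4)
        res = ig.differential_expression(m)
        assert all(r.log2fc == pytest.approx(0.0, abs=1e-12) for r in res)

    def test_all_zero_gene_reported_ns(self):
        rng = np.random.default_rng(1)
        counts = nb_counts(rng, 100, 0.1, (20, 8))
        counts[3] = 0
        m = make_matrix(counts, 4, 4)
        res = ig.differential_expression(m)
        assert res[3].direction == "ns" and res[3].log2fc == 0.0

    def test_null_type_one_error_within_binomial_ci(self):
        rng = np.random.default_rng(10)
        mus = np.exp(rng.normal(np.log(100), 0.7, size=2000))
        counts = np.column_stack(
            [nb_counts(rng, mus, 0.1, 2000) for _ in range(20)])
        m = make_matrix(counts, 10, 10)
        res = ig.differential_expression(m)
        frac = np.mean([r.p_value < 0.05 for r in res])
        ci = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert 0.05 - ci <= frac <= 0.05 + ci

    def test_power_for_planted_fourfold(self):
        rng = np.random.default_rng(11)
        mus = np.exp(rng.normal(np.log(100), 0.7, size=2000))
        fold = np.ones(2000)
        fold[:100] = 4.0
        ct = np.column_stack([nb_counts(rng, mus * fold, 0.1, 2000)
                              for _ in range(10)])
        cn = np.column_stack([nb_counts(rng, mus, 0.1, 2000)
                              for _ in range(10)])
        m = make_matrix(np.column_stack([ct, cn]), 10, 10)
        res = ig.differential_expression(m)
        detected = np.mean([res[i].q_value < 0.05 and res[i].direction == "up"
                            for i in range(100)])
        assert detected >= 0.90


class TestSpearmanPairs:
    def _matrix_from_rows(self, rows, depth=10000):
        counts = pd.DataFrame(rows).T
        counts.columns = [f"S{i}" for i in range(counts.shape[1])]
        # filler gene equalizes library sizes so CPM stays proportional to
        # the raw counts (no compositional closure in the tiny fixture)
        counts.loc["filler"] = depth - counts.sum(axis=0)
        cond = pd.Series("tumour", index=counts.columns)
        return ig.ExpressionMatrix(counts.astype(int), cond)

    def test_strictly_increasing_pair_rho_one(self):
        m = self._matrix_from_rows({"pg": [1, 5, 20, 80, 300, 1000],
                                    "pa": [2, 6, 30, 90, 310, 1200]})
        rec = ig.spearman_pairs(m, [("pg", "pa")])[0]
        assert rec.rho == pytest.approx(1.0)
        assert rec.sign_class == "Positive"

    def test_matches_brute_force_rank_formula(self, rng):
        """rho equals the rank-correlation computed from average ranks (tie
        corrected) via the Pearson formula on n <= 8 vectors."""
        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            sv = np.asarray(v, dtype=float)[order]
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        for _ in range(30):
            n = int(rng.integers(5, 9))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx, ry = avg_ranks(x), avg_ranks(y)
            expected = float(np.corrcoef(rx, ry)[0, 1])
            got = float(stats.spearmanr(x, y)[0])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_parent_gives_no_class(self):
        m = self._matrix_from_rows({"pg": [1, 5, 20, 80, 300],
                                    "pa": [7, 7, 7, 7, 7]})
        rec = ig.spearman_pairs(m, [("pg", "pa")])[0]
        assert rec.sign_class == "No"
        assert np.isnan(rec.rho)

    def test_requires_five_samples(self):
        m = self._matrix_from_rows({"pg": [1, 2, 3], "pa": [1, 2, 3]})
        with pytest.raises(ValueError):
            ig.spearman_pairs(m, [("pg", "pa")])


class TestWilcoxon:
    def test_exact_matches_enumeration_small_groups(self, rng):
        """The two-sided rank-sum p equals exhaustive enumeration over all
        group assignments for n <= 8 per group (distinct values)."""
        for _ in range(10):
            nx, ny = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            pool = rng.choice(np.arange(100), size=nx + ny, replace=False)
            x, y = pool[:nx].astype(float), pool[nx:].astype(float)
            got = ig.wilcoxon_rank_sum(x, y)
            # enumeration: distribution of the rank sum of group x under
            # random assignment of the pooled values
            ranks = stats.rankdata(np.concatenate([x, y]))
            obs = ranks[:nx].sum()
            mean = nx * (nx + ny + 1) / 2.0
            sums = [
                sum(comb)
                for comb in itertools.combinations(ranks, nx)
            ]
            sums = np.array(sums)
            extreme = np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-9)
            assert got == pytest.approx(float(extreme), abs=1e-9)


class TestTristileIntegration:
    def _levels(self, genes, tertiles):
        return [GeneM6ALevel(g, 0.0, t, True) for g, t in zip(genes, tertiles)]

    def test_gamma_coupling_orders_expression(self):
        cfg = SimConfig(n_genes=300, seed=21, m6a_expression_gamma=0.5,
                        fraction_methylated=0.5, plant_candidate=False)
        catalog, _, truth = simulate_genome_annotation(cfg)
        m = simulate_expression(catalog, cfg, truth)
        level = np.where(truth["meth_tumour"], 2.0, 0.0)
        order = np.argsort(level, kind="stable")
        tertile = np.empty(len(level), dtype=object)
        n = len(level)
        tertile[order[: n // 3]] = "low"
        tertile[order[n // 3: 2 * n // 3]] = "median"
        tertile[order[2 * n // 3:]] = "high"
        levels = [GeneM6ALevel(g, float(l), t, bool(l > 0))
                  for g, l, t in zip(truth.index, level, tertile)]
        out = ig.tristile_integration(levels, m)
        tests = out["tests"].set_index(["group_a", "group_b"])
        row = tests.loc[("low", "high")]
        assert row["median_a"] > row["median_b"]
        assert row["p_value"] < 0.05

    def test_null_gamma_no_ordering(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_genes=120, seed=100 + seed,
                            m6a_expression_gamma=0.0, plant_candidate=False)
            catalog, _, truth = simulate_genome_annotation(cfg)
            m = simulate_expression(catalog, cfg, truth)
            rng = np.random.default_rng(seed)
            tertiles = rng.permutation(
                ["low"] * 40 + ["median"] * 40 + ["high"] * 40)
            levels = self._levels(truth.index, tertiles)
            out = ig.tristile_integration(levels, m)
            tests = out["tests"].set_index(["group_a", "group_b"])
            if tests.loc[("low", "high"), "p_value"] > 0.05:
                hits += 1
        assert hits >= 18

    def test_cdf_reaches_one(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, 100, 0.1, (30, 6))
        m = make_matrix(counts, 3, 3)
        levels = self._levels(m.counts.index,
                              ["low"] * 10 + ["median"] * 10 + ["high"] * 10)
        out = ig.tristile_integration(levels, m)
        last = out["cdf"].groupby("tertile")["cdf"].last()
        assert np.allclose(last, 1.0)

    def test_small_tertile_skipped(self):
        rng = np.random.default_rng(3)
        counts = nb_counts(rng, 100, 0.1, (5, 6))
        m = make_matrix(counts, 3, 3)
        levels = self._levels(m.counts.index,
                              ["low", "low", "low", "median", "high"])
        out = ig.tristile_integration(levels, m)
        assert ("low", "median") in out["skipped"]


class TestCorrelationByStrata:
    def test_attenuated_coupling_reduces_high_tertile_rho(self):
        cfg = SimConfig(n_genes=240, seed=31, cerna_coupling_rho=0.7,
                        cerna_m6a_attenuation=1.0, fraction_methylated=0.5,
                        plant_candidate=False)
        catalog, _, truth = simulate_genome_annotation(cfg)
        m = simulate_expression(catalog, cfg, truth)
        recs = ig.spearman_pairs(m, catalog.pairs)
        level = truth["meth_tumour"].astype(float) * 2.0
        order = np.argsort(level.to_numpy(), kind="stable")
        tert = np.empty(len(level), dtype=object)
        n = len(level)
        tert[order[: n // 3]] = "low"
        tert[order[n // 3: 2 * n // 3]] = "median"
        tert[order[2 * n // 3:]] = "high"
        levels = [GeneM6ALevel(g, float(l), t, True)
                  for g, l, t in zip(truth.index, level, tert)]
        subtypes = {g: catalog.pseudogenes[g].subtype
                    for g in catalog.pseudogenes}
        out = ig.correlation_by_m6a_strata(recs, levels, subtypes)
        tests = out["tests"]
        row = tests[(tests.subtype == "processed") & (tests.group_a == "low")
                    & (tests.group_b == "high")].iloc[0]
        assert row["mean_rho_a"] > row["mean_rho_b"]
        assert row["p_value"] < 0.05


class TestCorrespondenceTables:
    def test_constructed_contrast(self):
        """Proportions 57.9% vs 40.3% on a 1000-vs-1000 table give a
        chi-square p < .001."""
        a = pd.Series(["m6A"] * 1000 + ["no"] * 1000)
        b = pd.Series(["yes"] * 579 + ["no"] * 421 + ["yes"] * 403 + ["no"] * 597)
        out = ig.correspondence_tables(a, b)
        props = out["row_proportions"]
        assert props.loc["m6A", "yes"] == pytest.approx(0.579)
        assert props.loc["no", "yes"] == pytest.approx(0.403)
        assert out["p_value"] < 1e-3
        expected = stats.chi2_contingency(out["table"].to_numpy())[1]
        assert out["p_value"] == pytest.approx(expected)

    def test_independent_table_odds_near_one(self, rng):
        a = pd.Series(rng.choice(["x", "y"], size=4000))
        b = pd.Series(rng.choice(["u", "v"], size=4000))
        out = ig.correspondence_tables(a, b)
        t = out["table"].to_numpy()
        odds = (t[0, 0] * t[1, 1]) / max(1, t[0, 1] * t[1, 0])
        assert 0.8 < odds < 1.25

    def test_single_level_vector_errors(self):
        a = pd.Series(["x"] * 10)
        b = pd.Series(["u", "v"] * 5)
        with pytest.raises(ValueError):
            ig.correspondence_tables(a, b)

    def test_small_expected_cells_use_fisher(self):
        a = pd.Series(["x"] * 6 + ["y"] * 6)
        b = pd.Series(["u", "v"] * 6)
        out = ig.correspondence_tables(a, b)
        assert out["method"] == "fisher"


class TestGeneticSummary:
    def _inputs(self, rng, n_genes=10, n_samples=50):
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"S{i}" for i in range(n_samples)]
        mut = pd.DataFrame(0, index=genes, columns=samples)
        cnv = pd.DataFrame(0, index=genes, columns=samples)
        counts = pd.DataFrame(
            nb_counts(rng, 100, 0.1, (n_genes, n_samples)),
            index=genes, columns=samples)
        cond = pd.Series("tumour", index=samples)
        return mut, cnv, ig.ExpressionMatrix(counts, cond)

    def test_no_alterations_zero_frequency(self, rng):
        mut, cnv, m = self._inputs(rng)
        out = ig.genetic_summary(mut, cnv, m)
        assert all(s.mutation_frequency == 0.0 for s in out)

    def test_three_of_fifty_gives_six_percent(self, rng):
        mut, cnv, m = self._inputs(rng)
        mut.iloc[0, :3] = 1
        out = ig.genetic_summary(mut, cnv, m)
        assert out[0].mutation_frequency == pytest.approx(0.06)

    def test_perfectly_ordered_cnv_expression_rho_one(self, rng):
        mut, cnv, m = self._inputs(rng, n_genes=2, n_samples=5)
        cnv.iloc[0] = [-2, -1, 0, 1, 2]
        m.counts.iloc[0] = [10, 20, 40, 80, 160]
        # equal library sizes so log-CPM ordering follows the raw counts
        m.counts.iloc[1] = 1000 - m.counts.iloc[0]
        out = ig.genetic_summary(mut, cnv, m)
        assert out[0].cnv_expression_rho == pytest.approx(1.0)

    def test_disjoint_samples_error(self, rng):
        mut, cnv, m = self._inputs(rng)
        mut.columns = [f"X{i}" for i in range(mut.shape[1])]
        cnv.columns = mut.columns
        with pytest.raises(ValueError, match="disjoint"):
            ig.genetic_summary(mut, cnv, m)
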