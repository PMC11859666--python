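"""Expression analysis and cross-omic integration.

Differential expression uses an internal negative-binomial Wald test
(gene-wise method-of-moments dispersion shrunk toward a mean-trend) on
CPM-normalized counts; it is fully specified here rather than delegated to
an external package so that its calibration can be checked directly against
null simulations.  Correlation, rank tests and contingency tests go through
scipy/statsmodels.

Conventions: expression effect sizes are log2 fold changes on the
mean-CPM + 1 scale; pseudogene-parent correlation uses Spearman rank
correlation with the sign/significance classification Positive (rho > 0,
p < .05), Negative (rho < 0, p < .05), else No.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Integer count matrix (genes x samples) with condition labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    conditions: pd.Series  # sample_id -> {"tumour", "normal"}

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_of(self, condition: str) -> list:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str  # up | down | ns


@dataclass
class CorrelationRecord:
    pseudogene_id: str
    parent_gene_id: str
    rho: float  # NaN when undefined (constant input)
    p_value: float
    sign_class: str  # Positive | Negative | No


@dataclass
class GeneticSummary:
    gene_id: str
    mutation_frequency: float
    cnv_frequency: float
    cnv_expression_rho: float
    cnv_expression_p: float


# ---------------------------------------------------------------------------
# normalization

def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled to sum to 1e6."""
    depths = counts.sum(axis=0)
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"zero-depth sample(s): {bad}")
    return counts * 1e6 / depths


def log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(normalize_cpm(counts) + pseudocount)


# ---------------------------------------------------------------------------
# differential expression (NB Wald)

def _mom_dispersion(norm: np.ndarray, groups: list,
                    scales: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from CPM-normalized counts.

    On the CPM scale the sampling variance of sample j is
    mu * scale_j + phi * mu^2 with scale_j = 1e6 / depth_j, so the Poisson
    term subtracted is mu times the mean scale, not mu itself.
    """
    n_genes = norm.shape[0]
    ss = np.zeros(n_genes)
    df = 0
    mu_parts = []
    scale_parts = []
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1, keepdims=True)
        ss += ((sub - m) ** 2).sum(axis=1)
        df += len(idx) - 1
        mu_parts.append(m[:, 0] * len(idx))
        scale_parts.extend(scales[idx])
    var = ss / max(df, 1)
    mu = sum(mu_parts) / sum(len(idx) for idx in groups)
    mean_scale = float(np.mean(scale_parts))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var - mu * mean_scale) / mu**2
    phi[~np.isfinite(phi)] = 0.0
    # negative raw values (var < mu * scale) are kept: truncating them
    # before the trend average would bias the dispersion upward and make
    # the Wald test conservative; only the final shrunken value is floored.
    return np.clip(phi, -1.0, 10.0), mu


def _trend_shrink(phi: np.ndarray, mu: np.ndarray, weight: float = 0.5,
                  n_bins: int = 20) -> np.ndarray:
    """Shrink gene-wise dispersions toward the mean dispersion of genes with
    similar expression (binned trend on log mean)."""
    logmu = np.log1p(mu)
    order = np.argsort(logmu)
    trend = np.empty_like(phi)
    bins = np.array_split(order, min(n_bins, max(1, len(order) // 10) or 1))
    for b in bins:
        if len(b):
            trend[b] = phi[b].mean()
    return np.clip(weight * phi + (1 - weight) * trend, 0.0, 10.0)


def differential_expression(matrix: ExpressionMatrix, alpha: float = 0.05,
                            pseudocount: float = 1.0) -> list:
    """Tumour-vs-normal NB Wald test per gene.

    log2fc is computed on mean CPM + pseudocount; the Wald statistic uses a
    delta-method standard error with NB variance mu + phi mu^2 at the
    shrunken dispersion, referred to a t distribution with the within-group
    degrees of freedom.  BH correction across genes; direction is called at
    q < alpha.  All-zero genes are reported as ns with log2fc 0.
    """
    t_cols = matrix.samples_of("tumour")
    n_cols = matrix.samples_of("normal")
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >= 2 samples per condition")
    counts = matrix.counts
    depths = counts.sum(axis=0).to_numpy(dtype=float)
    cpm = (counts.to_numpy(dtype=float) * 1e6 / depths)
    cols = list(counts.columns)
    t_idx = [cols.index(c) for c in t_cols]
    n_idx = [cols.index(c) for c in n_cols]

    phi_raw, mu_norm = _mom_dispersion(cpm, [t_idx, n_idx], 1e6 / depths)
    phi = _trend_shrink(phi_raw, mu_norm)

    m_t = cpm[:, t_idx].mean(axis=1)
    m_n = cpm[:, n_idx].mean(axis=1)
    log2fc = np.log2((m_t + pseudocount) / (m_n + pseudocount))

    # delta-method variance of the group mean CPM under NB sampling
    def group_var(idx, mu_group):
        scale = (1e6 / depths[idx]) ** 2
        mu_counts = mu_group[:, None] * depths[idx] / 1e6
        var_counts = mu_counts + phi[:, None] * mu_counts**2
        return (var_counts * scale).sum(axis=1) / len(idx) ** 2

    var_t = group_var(t_idx, m_t)
    var_n = group_var(n_idx, m_n)
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        (var_t / (m_t + pseudocount) ** 2 + var_n / (m_n + pseudocount) ** 2) / ln2sq
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    # normal reference: the trend-shrunken dispersion is estimated from the
    # whole gene set, so the per-gene statistic is close to pivotal
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    allzero = (m_t == 0) & (m_n == 0)
    pvals[allzero] = 1.0
    log2fc[allzero] = 0.0
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    out = []
    for i, gene_id in enumerate(counts.index):
        if qvals[i] < alpha and log2fc[i] != 0:
            direction = "up" if log2fc[i] > 0 else "down"
        else:
            direction = "ns"
        out.append(DEResult(gene_id, float(log2fc[i]), float(pvals[i]),
                            float(qvals[i]), direction))
    return out


def de_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "log2fc": r.log2fc, "p_value": r.p_value,
             "q_value": r.q_value, "direction": r.direction}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# pseudogene-parent correlation

def spearman_pairs(matrix: ExpressionMatrix, pairs: list,
                   condition: Optional[str] = "tumour",
                   alpha: float = 0.05) -> list:
    """Spearman correlation (average ranks for ties) for each
    (pseudogene, parent) pair across samples of one condition."""
    cols = matrix.samples_of(condition) if condition else list(matrix.counts.columns)
    if len(cols) < 5:
        raise ValueError("need >= 5 samples for correlation")
    logc = log_cpm(matrix.counts[cols])
    out = []
    for pg, parent in pairs:
        if pg not in logc.index or parent not in logc.index:
            continue
        x = logc.loc[pg].to_numpy()
        y = logc.loc[parent].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationRecord(pg, parent, float("nan"), 1.0, "No"))
            continue
        rho, p = stats.spearmanr(x, y)
        if p < alpha and rho > 0:
            cls = "Positive"
        elif p < alpha and rho < 0:
            cls = "Negative"
        else:
            cls = "No"
        out.append(CorrelationRecord(pg, parent, float(rho), float(p), cls))
    return out


def correlations_to_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pseudogene_id": r.pseudogene_id, "parent_gene_id": r.parent_gene_id,
             "rho": r.rho, "p_value": r.p_value, "sign_class": r.sign_class}
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# rank tests

def wilcoxon_rank_sum(x, y, exact_max: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact enumeration for small
    groups, normal approximation with continuity correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) == 0:
        return float("nan")
    method = "exact" if max(len(x), len(y)) <= exact_max else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# tristile integration (m6A level vs expression)

def tristile_integration(m6a_levels: list, matrix: ExpressionMatrix,
                         subtypes: Optional[dict] = None,
                         subtype_filter: Optional[str] = None,
                         condition: str = "tumour",
                         min_genes: int = 3) -> dict:
    """Mean log2(CPM+1) per gene across the condition's samples, grouped by
    m6A tertile; pairwise two-sided Wilcoxon tests between tertiles and an
    empirical CDF table per tertile.

    Returns {"expression": DataFrame, "tests": DataFrame, "cdf": DataFrame,
    "skipped": [...]}.
    """
    cols = matrix.samples_of(condition)
    logc = log_cpm(matrix.counts[cols])
    mean_expr = logc.mean(axis=1)
    rows = []
    for g in m6a_levels:
        if g.gene_id not in mean_expr.index:
            continue
        if subtype_filter and subtypes is not None:
            if subtypes.get(g.gene_id) != subtype_filter:
                continue
        rows.append((g.gene_id, g.tertile, g.level, float(mean_expr[g.gene_id])))
    expr = pd.DataFrame(rows, columns=["gene_id", "tertile", "m6a_level", "mean_log2_cpm"])

    tests, skipped = [], []
    groups = {t: expr.loc[expr["tertile"] == t, "mean_log2_cpm"].to_numpy()
              for t in ("low", "median", "high")}
    for a, b in (("low", "median"), ("low", "high"), ("median", "high")):
        if len(groups[a]) < min_genes or len(groups[b]) < min_genes:
            skipped.append((a, b))
            continue
        tests.append(
            {"group_a": a, "group_b": b,
             "median_a": float(np.median(groups[a])),
             "median_b": float(np.median(groups[b])),
             "p_value": wilcoxon_rank_sum(groups[a], groups[b])}
        )
    # empirical CDF on a shared grid
    allvals = expr["mean_log2_cpm"].to_numpy()
    if len(allvals):
        grid = np.linspace(allvals.min(), allvals.max(), 101)
        cdf_rows = []
        for t, vals in groups.items():
            if len(vals) == 0:
                continue
            ec = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
            for x, f in zip(grid, ec):
                cdf_rows.append({"tertile": t, "x": float(x), "cdf": float(f)})
        cdf = pd.DataFrame(cdf_rows)
    else:
        cdf = pd.DataFrame(columns=["tertile", "x", "cdf"])
    return {"expression": expr, "tests": pd.DataFrame(tests), "cdf": cdf,
            "skipped": skipped}


def correlation_by_m6a_strata(records: list, m6a_levels: list,
                              subtypes: Optional[dict] = None,
                              min_pairs: int = 3) -> dict:
    """Distribution of pseudogene-parent rho per m6A tertile (optionally per
    pseudogene subtype) with pairwise Wilcoxon tests between tertiles."""
    tertile_of = {g.gene_id: g.tertile for g in m6a_levels}
    rows = []
    for r in records:
        t = tertile_of.get(r.pseudogene_id)
        if t is None or not np.isfinite(r.rho):
            continue
        rows.append(
            {"pseudogene_id": r.pseudogene_id, "tertile": t, "rho": r.rho,
             "subtype": (subtypes or {}).get(r.pseudogene_id, "all")}
        )
    table = pd.DataFrame(rows, columns=["pseudogene_id", "tertile", "rho", "subtype"])
    tests, skipped = [], []
    for subtype, sub in (
        table.groupby("subtype") if len(table) else []
    ):
        groups = {t: sub.loc[sub["tertile"] == t, "rho"].to_numpy()
                  for t in ("low", "median", "high")}
        for a, b in (("low", "median"), ("low", "high"), ("median", "high")):
            if len(groups[a]) < min_pairs or len(groups[b]) < min_pairs:
                skipped.append((subtype, a, b))
                continue
            tests.append(
                {"subtype": subtype, "group_a": a, "group_b": b,
                 "mean_rho_a": float(groups[a].mean()),
                 "mean_rho_b": float(groups[b].mean()),
                 "p_value": wilcoxon_rank_sum(groups[a], groups[b])}
            )
    return {"rho": table, "tests": pd.DataFrame(tests), "skipped": skipped}


# ---------------------------------------------------------------------------
# correspondence (Sankey-style) tables

def correspondence_tables(flags_a: pd.Series, flags_b: pd.Series) -> dict:
    """Cross-tabulate two categorical vectors over the same gene set.

    Uses the chi-square test, or Fisher's exact test for 2x2 tables with any
    expected cell < 5.  Returns the contingency table, row proportions and
    the test p-value.
    """
    common = flags_a.index.intersection(flags_b.index)
    a = flags_a.loc[common]
    b = flags_b.loc[common]
    if a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("both vectors need >= 2 levels")
    table = pd.crosstab(a, b)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, chi_p, dof, expected = stats.chi2_contingency(table.to_numpy())
    if table.shape == (2, 2) and (expected < 5).any():
        p = float(stats.fisher_exact(table.to_numpy())[1])
        method = "fisher"
    else:
        p = float(chi_p)
        method = "chi2"
    row_prop = table.div(table.sum(axis=1), axis=0)
    return {"table": table, "row_proportions": row_prop, "p_value": p,
            "method": method}


# ---------------------------------------------------------------------------
# genetic alteration summaries

def genetic_summary(mutations: pd.DataFrame, cnv: pd.DataFrame,
                    matrix: ExpressionMatrix) -> list:
    """Per-gene mutation/CNV frequencies and Spearman correlation of CNV
    state with log2(CPM+1) over shared samples."""
    shared = [s for s in mutations.columns if s in matrix.counts.columns]
    if not shared:
        raise ValueError("mutation/expression sample sets are disjoint")
    logc = log_cpm(matrix.counts[shared])
    out = []
    for gene_id in mutations.index:
        mut_freq = float((mutations.loc[gene_id, shared] != 0).mean())
        cnv_freq = float((cnv.loc[gene_id, shared] != 0).mean()) if gene_id in cnv.index else 0.0
        rho, p = float("nan"), 1.0
        if gene_id in logc.index and gene_id in cnv.index:
            states = cnv.loc[gene_id, shared].to_numpy(dtype=float)
            expr = logc.loc[gene_id].to_numpy()
            if np.ptp(states) > 0 and np.ptp(expr) > 0:
                rho, p = stats.spearmanr(states, expr)
        out.append(GeneticSummary(gene_id, mut_freq, cnv_freq, float(rho), float(p)))
    return out


def genetics_to_frame(summaries: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": s.gene_id, "mutation_frequency": s.mutation_frequency,
             "cnv_frequency": s.cnv_frequency,
             "cnv_expression_rho": s.cnv_expression_rho,
             "cnv_expression_p": s.cnv_expression_p}
            for s in summaries
        ]
    )
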