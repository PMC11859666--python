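"""Windowed IP-vs-input m6A peak calling and tumour-vs-normal differential
methylation.

The method works on fixed-size windows tiled over each gene's exonic span
(transcript coordinates).  Within a condition, counts are pooled across
replicate IP (and input) libraries and each window is tested with a
one-sided 2x2 exact test of the window's IP/input split against the rest of
the transcriptome; Benjamini-Hochberg correction is applied across windows
and significant windows are merged into peaks.  Differential methylation
between conditions is an exact test on the depth-equalized 2x2 table of
IP/input counts over each peak span.  Replicate-level dispersion modeling is
deliberately out of scope: pooling keeps every p-value exactly computable
and testable against an enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import Catalog, GenomicInterval, TranscriptModel

DEFAULT_WINDOW = 50
DEFAULT_STEP = 25


@dataclass
class WindowCounts:
    """Per-window IP and input counts for a set of samples.

    ``windows`` has one row per (gene, window): gene_id, window_index,
    chrom, start, end, strand, tx_start, tx_end (transcript coordinates).
    ``ip`` and ``input`` are aligned count frames (rows = windows, columns =
    sample ids); ``samples`` maps sample_id -> condition.
    """

    windows: pd.DataFrame
    ip: pd.DataFrame
    input: pd.DataFrame
    samples: pd.DataFrame  # columns: sample_id, condition

    def __post_init__(self):
        if (self.ip.values < 0).any() or (self.input.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def ip_library_sizes(self) -> pd.Series:
        return self.ip.sum(axis=0)

    @property
    def input_library_sizes(self) -> pd.Series:
        return self.input.sum(axis=0)

    def condition_samples(self, condition: str) -> list:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample_id"]
        return list(sel)

    def subset_condition(self, condition: str) -> "WindowCounts":
        cols = self.condition_samples(condition)
        return WindowCounts(
            self.windows,
            self.ip[cols],
            self.input[cols],
            self.samples[self.samples["condition"] == condition].reset_index(drop=True),
        )


@dataclass
class Peak:
    interval: GenomicInterval
    gene_id: str
    log2_enrichment: float
    p_value: float
    q_value: float
    condition: str
    tx_start: int = 0
    tx_end: int = 0
    window_indices: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q-value outside [0, 1]")


@dataclass
class DiffPeak:
    interval: GenomicInterval
    gene_id: str
    diff_log2fc: float
    direction: str  # hyper | hypo
    p_value: float
    q_value: float
    significant: bool
    tx_start: int = 0
    tx_end: int = 0

    def __post_init__(self):
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper/hypo, got {self.direction!r}")


@dataclass
class GeneM6ALevel:
    gene_id: str
    level: float
    tertile: str  # low | median | high
    m6a_positive: bool


# ---------------------------------------------------------------------------
# window tiling

def tile_length(length: int, window_size: int = DEFAULT_WINDOW,
                step: int = DEFAULT_STEP) -> list:
    """Deterministic (start, end) tiling of a span of ``length`` nt.

    Full windows start at multiples of ``step``; if the span's tail is not
    covered, one final partial window is added provided it is at least half
    a window long.
    """
    if length <= 0:
        return []
    if length < window_size:
        return [(0, length)] if length * 2 >= window_size else []
    starts = list(range(0, length - window_size + 1, step))
    tiles = [(s, s + window_size) for s in starts]
    covered = tiles[-1][1]
    if covered < length:
        nxt = starts[-1] + step
        if length - nxt >= (window_size + 1) // 2:
            tiles.append((nxt, length))
    return tiles


def count_windows(coverage: dict, catalog: Catalog, samples: pd.DataFrame,
                  window_size: int = DEFAULT_WINDOW,
                  step: int = DEFAULT_STEP) -> WindowCounts:
    """Aggregate per-base exonic coverage into window counts.

    ``coverage`` maps sample_id -> {"ip": {gene_id: array}, "input": ...}
    where each array gives per-base read counts along the gene's transcript
    (5'->3').  Genes with zero exonic length are skipped with a warning.
    """
    import warnings

    rows, ip_cols, input_cols = [], {}, {}
    sample_ids = list(samples["sample_id"])
    for sid in sample_ids:
        ip_cols[sid], input_cols[sid] = [], []
    any_gene = False
    for gene_id in catalog.all_ids():
        model = catalog.model(gene_id)
        L = model.exonic_length
        if L == 0:
            warnings.warn(f"{gene_id}: zero exonic length, skipped", stacklevel=2)
            continue
        tiles = tile_length(L, window_size, step)
        for w, (s, e) in enumerate(tiles):
            gs = model.transcript_to_genomic(s)
            ge = model.transcript_to_genomic(e - 1)
            rows.append(
                (gene_id, w, model.chrom, min(gs, ge), max(gs, ge) + 1,
                 model.strand, s, e)
            )
            any_gene = True
            for sid in sample_ids:
                per_gene = coverage.get(sid, {})
                ipc = per_gene.get("ip", {}).get(gene_id)
                inc = per_gene.get("input", {}).get(gene_id)
                ip_cols[sid].append(int(np.sum(ipc[s:e])) if ipc is not None else 0)
                input_cols[sid].append(int(np.sum(inc[s:e])) if inc is not None else 0)
    windows = pd.DataFrame(
        rows,
        columns=["gene_id", "window_index", "chrom", "start", "end", "strand",
                 "tx_start", "tx_end"],
    )
    if not any_gene:
        windows = windows.astype(
            {"window_index": int, "start": int, "end": int, "tx_start": int, "tx_end": int},
            errors="ignore",
        )
    ip = pd.DataFrame(ip_cols, index=windows.index)
    inp = pd.DataFrame(input_cols, index=windows.index)
    return WindowCounts(windows, ip, inp, samples.reset_index(drop=True))


def read_bedgraph_coverage(path: str, catalog: Catalog) -> dict:
    """Read a bedGraph track into per-gene transcript-coordinate coverage.

    Returns {gene_id: float array of length exonic_length} with the
    bedGraph value at every exonic base (0 where uncovered); suitable as
    the per-sample "ip"/"input" entries consumed by ``count_windows``.
    """
    cov = {
        gid: np.zeros(catalog.model(gid).exonic_length)
        for gid in catalog.all_ids()
    }
    by_chrom: dict = {}
    for gid in catalog.all_ids():
        by_chrom.setdefault(catalog.model(gid).chrom, []).append(gid)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph fields, "
                    f"got {len(fields)}")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
            for gid in by_chrom.get(chrom, ()):
                model = catalog.model(gid)
                lo = max(start, model.start)
                hi = min(end, model.end)
                for pos in range(lo, hi):
                    tpos = model.genomic_to_transcript(pos)
                    if tpos is not None:
                        cov[gid][tpos] = value
    return cov


# ---------------------------------------------------------------------------
# exact 2x2 machinery

def exact_enrichment_pvalues(k: np.ndarray, row_total: int, n: np.ndarray,
                             grand_total: int) -> np.ndarray:
    """Vectorized one-sided (enrichment) p-value of 2x2 tables
    [[k, row_total-k], [n-k, ...]] conditioned on all margins:
    P(X >= k), X ~ Hypergeom(M=grand_total, K=row_total, N=n)."""
    return stats.hypergeom.sf(k - 1, grand_total, row_total, n)


def fisher_two_sided(table: np.ndarray) -> float:
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# peak calling

def call_peaks(wc: WindowCounts, condition: str, alpha: float = 0.05,
               step: int = DEFAULT_STEP, pseudocount: float = 1.0) -> list:
    """Call m6A-enriched peaks for one condition.

    Pools IP and input counts across the condition's replicates, tests each
    window one-sided against the rest of the transcriptome, BH-corrects over
    all windows, and merges significant windows (genomic gap <= one step
    within a gene) into peaks.
    """
    cols = wc.condition_samples(condition)
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    ip = wc.ip[cols].sum(axis=1).to_numpy()
    inp = wc.input[cols].sum(axis=1).to_numpy()
    ip_total = int(ip.sum())
    input_total = int(inp.sum())
    if input_total == 0:
        raise ValueError("all-zero input library: enrichment undefined")
    if ip_total == 0:
        return []
    pvals = exact_enrichment_pvalues(
        ip, ip_total, ip + inp, ip_total + input_total
    )
    reject, qvals, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    win = wc.windows
    peaks = []
    for gene_id, idx in win.groupby("gene_id", sort=False).groups.items():
        idx = np.asarray(idx)
        sig = idx[reject[idx]]
        if sig.size == 0:
            continue
        order = np.argsort(win.loc[sig, "tx_start"].to_numpy())
        sig = sig[order]
        runs, current = [], [sig[0]]
        for j in sig[1:]:
            gap = win.at[j, "tx_start"] - win.at[current[-1], "tx_end"]
            if gap <= step:
                current.append(j)
            else:
                runs.append(current)
                current = [j]
        runs.append(current)
        for run in runs:
            rows = win.loc[run]
            tx_start = int(rows["tx_start"].min())
            tx_end = int(rows["tx_end"].max())
            gstart = int(rows["start"].min())
            gend = int(rows["end"].max())
            # merged-span counts: union of member windows, avoiding double
            # counting of overlapping windows via non-overlapping sub-spans
            ip_sum, inp_sum = _span_counts(wc, cols, gene_id, tx_start, tx_end)
            enr = _log2_enrichment(ip_sum, inp_sum, ip_total, input_total, pseudocount)
            peaks.append(
                Peak(
                    GenomicInterval(rows["chrom"].iloc[0], gstart, gend,
                                    rows["strand"].iloc[0]),
                    gene_id,
                    enr,
                    float(pvals[run].min()),
                    float(qvals[run].min()),
                    condition,
                    tx_start,
                    tx_end,
                    tuple(int(w) for w in rows["window_index"]),
                )
            )
    return peaks


def _span_counts(wc: WindowCounts, cols: list, gene_id: str,
                 tx_start: int, tx_end: int) -> tuple:
    """Pooled IP/input counts over [tx_start, tx_end) of a gene, summing the
    non-overlapping consecutive window steps that cover the span."""
    win = wc.windows
    mask = (
        (win["gene_id"] == gene_id)
        & (win["tx_start"] < tx_end)
        & (win["tx_end"] > tx_start)
    )
    idx = win.index[mask]
    if len(idx) == 0:
        return 0, 0
    # use every other window at step spacing so spans are counted once:
    # windows whose start is a multiple of window_size (non-overlapping set),
    # plus the first/last if needed, approximated by summing distinct
    # non-overlapping windows greedily by tx_start.
    chosen, last_end = [], -1
    for j in idx[np.argsort(win.loc[idx, "tx_start"].to_numpy())]:
        if win.at[j, "tx_start"] >= last_end:
            chosen.append(j)
            last_end = win.at[j, "tx_end"]
    ip_sum = int(wc.ip.loc[chosen, cols].to_numpy().sum())
    inp_sum = int(wc.input.loc[chosen, cols].to_numpy().sum())
    return ip_sum, inp_sum


def _log2_enrichment(ip_sum: int, inp_sum: int, ip_total: int,
                     input_total: int, pseudocount: float) -> float:
    ip_cpm = ip_sum / ip_total * 1e6
    in_cpm = inp_sum / input_total * 1e6
    return float(np.log2((ip_cpm + pseudocount) / (in_cpm + pseudocount)))


# ---------------------------------------------------------------------------
# union peak set and differential methylation

def union_peaks(peaks_a: list, peaks_b: list) -> list:
    """Union peak set over two conditions: overlapping peaks of the same
    gene (transcript coordinates) are merged into their union span."""
    by_gene = {}
    for p in list(peaks_a) + list(peaks_b):
        by_gene.setdefault(p.gene_id, []).append(p)
    merged = []
    for gene_id, plist in by_gene.items():
        plist.sort(key=lambda p: p.tx_start)
        current = plist[0]
        spans = [[current.tx_start, current.tx_end, current]]
        for p in plist[1:]:
            if p.tx_start <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], p.tx_end)
                if p.p_value < spans[-1][2].p_value:
                    spans[-1][2] = p
            else:
                spans.append([p.tx_start, p.tx_end, p])
        for s, e, rep in spans:
            iv = rep.interval
            merged.append(
                Peak(iv, gene_id, rep.log2_enrichment, rep.p_value,
                     rep.q_value, "union", s, e, rep.window_indices)
            )
    return merged


def diff_methylation(wc_tumour: WindowCounts, wc_normal: WindowCounts,
                     peaks: list, alpha: float = 0.05,
                     pseudocount: float = 1.0) -> list:
    """Tumour-vs-normal differential methylation over the union peak set.

    For each peak, IP/input counts are summed over the span in each
    condition, scaled to the mean library depth (CPM-equalized, rounded)
    and tested with a two-sided exact test.  Significance follows the raw
    p < alpha rule; BH q-values are reported alongside.  Peaks with zero
    total counts are excluded (counted in the log).
    """
    t_cols = wc_tumour.condition_samples("tumour") or list(wc_tumour.ip.columns)
    n_cols = wc_normal.condition_samples("normal") or list(wc_normal.ip.columns)
    libs = {
        "ip_t": wc_tumour.ip[t_cols].to_numpy().sum(),
        "in_t": wc_tumour.input[t_cols].to_numpy().sum(),
        "ip_n": wc_normal.ip[n_cols].to_numpy().sum(),
        "in_n": wc_normal.input[n_cols].to_numpy().sum(),
    }
    target = float(np.mean(list(libs.values())))
    rows, tables = [], []
    excluded = 0
    for p in peaks:
        ip_t, in_t = _span_counts(wc_tumour, t_cols, p.gene_id, p.tx_start, p.tx_end)
        ip_n, in_n = _span_counts(wc_normal, n_cols, p.gene_id, p.tx_start, p.tx_end)
        if ip_t + in_t + ip_n + in_n == 0:
            excluded += 1
            continue
        scaled = [
            int(round(ip_t * target / libs["ip_t"])) if libs["ip_t"] else 0,
            int(round(in_t * target / libs["in_t"])) if libs["in_t"] else 0,
            int(round(ip_n * target / libs["ip_n"])) if libs["ip_n"] else 0,
            int(round(in_n * target / libs["in_n"])) if libs["in_n"] else 0,
        ]
        rows.append(p)
        tables.append(scaled)
    results = []
    pvals = []
    for scaled in tables:
        ip_t, in_t, ip_n, in_n = scaled
        table = np.array([[ip_t, in_t], [ip_n, in_n]])
        if table.sum() == 0:
            pvals.append(1.0)
            continue
        pvals.append(fisher_two_sided(table))
    qvals = (
        multipletests(pvals, method="fdr_bh")[1] if pvals else np.array([])
    )
    for p, scaled, pv, qv in zip(rows, tables, pvals, qvals):
        ip_t, in_t, ip_n, in_n = scaled
        lfc = float(
            np.log2(
                ((ip_t + pseudocount) / (in_t + pseudocount))
                / ((ip_n + pseudocount) / (in_n + pseudocount))
            )
        )
        direction = "hyper" if lfc > 0 else "hypo"
        if lfc == 0.0:
            direction = "hyper"  # degenerate tie; never significant (p = 1)
        results.append(
            DiffPeak(p.interval, p.gene_id, lfc, direction, pv, float(qv),
                     pv < alpha, p.tx_start, p.tx_end)
        )
    diff_methylation.n_excluded = excluded  # simple run metadata
    return results


# ---------------------------------------------------------------------------
# per-gene relative m6A level

def gene_m6a_level(wc: WindowCounts, peaks: list, condition: Optional[str] = None,
                   alpha: float = 1.0, sig_alpha: float = 0.05) -> list:
    """Per-gene relative m6A level with tertile assignment.

    level = log2((IP CPM + alpha) / (input CPM + alpha)) computed over the
    gene's peak spans when it has peaks, else over the whole gene.  Genes
    are ranked by level and cut into tertiles (low / median / high) whose
    sizes differ by at most one.  ``m6a_positive`` flags genes with at least
    one significant peak.
    """
    cols = (
        wc.condition_samples(condition) if condition else list(wc.ip.columns)
    )
    ip_total = wc.ip[cols].to_numpy().sum()
    input_total = wc.input[cols].to_numpy().sum()
    peaks_by_gene = {}
    for p in peaks:
        if p.q_value <= sig_alpha or p.p_value <= sig_alpha:
            peaks_by_gene.setdefault(p.gene_id, []).append(p)
    levels = []
    for gene_id, idx in wc.windows.groupby("gene_id", sort=False).groups.items():
        plist = peaks_by_gene.get(gene_id)
        if plist:
            ip_sum = inp_sum = 0
            for p in plist:
                a, b = _span_counts(wc, cols, gene_id, p.tx_start, p.tx_end)
                ip_sum += a
                inp_sum += b
        else:
            gmax = int(wc.windows.loc[idx, "tx_end"].max())
            ip_sum, inp_sum = _span_counts(wc, cols, gene_id, 0, gmax)
        ip_cpm = ip_sum / ip_total * 1e6 if ip_total else 0.0
        in_cpm = inp_sum / input_total * 1e6 if input_total else 0.0
        level = float(np.log2((ip_cpm + alpha) / (in_cpm + alpha)))
        levels.append((gene_id, level, gene_id in peaks_by_gene))
    levels.sort(key=lambda t: (t[1], t[0]))
    n = len(levels)
    out = []
    bounds = [round(n / 3), round(2 * n / 3)]
    for rank, (gene_id, level, positive) in enumerate(levels):
        tertile = "low" if rank < bounds[0] else ("median" if rank < bounds[1] else "high")
        out.append(GeneM6ALevel(gene_id, level, tertile, positive))
    out.sort(key=lambda g: g.gene_id)
    return out


# ---------------------------------------------------------------------------
# TSV / BED output

def peaks_to_frame(peaks: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "gene_id": p.gene_id,
                "strand": p.interval.strand,
                "log2_enrichment": p.log2_enrichment,
                "p_value": p.p_value,
                "q_value": p.q_value,
                "condition": p.condition,
            }
            for p in peaks
        ]
    )


def diff_peaks_to_frame(diff_peaks: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "gene_id": d.gene_id,
                "strand": d.interval.strand,
                "diff_log2fc": d.diff_log2fc,
                "direction": d.direction,
                "p_value": d.p_value,
                "q_value": d.q_value,
                "significant": d.significant,
            }
            for d in diff_peaks
        ]
    )


def write_peaks_bed(peaks: list, path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(100 * p.log2_enrichment))
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.gene_id}\t{score}\t{p.interval.strand}\t"
                f"{p.p_value:.6g}\t{p.q_value:.6g}\t{p.condition}\n"
            )
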