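"""Diff-m6A candidate filter cascade and ranked report — the pipeline's
headline output — plus end-to-end orchestration over the synthetic
generator.

The cascade mirrors the integrative funnel that narrows all pseudogenes to
a handful of candidates:

1. significant differential m6A between tumour and normal (raw p < .05);
2. detectably expressed RNA (per-sample CPM >= 1 in at least half the
   samples of one cohort);
3. concurrent differential expression opposite in sign to the m6A change
   (hypomethylated -> up-regulated, hypermethylated -> down-regulated);
4. prognostic association (Cox p < .05) with direction consistent with the
   expression change (up + risk, down + protective);
5. no genetic confound (mutation frequency < 1%, CNV frequency < 5%);
6. optional ceRNA support (>= 1 shared miRNA with a positively correlated
   parent gene).

Each filter records its survivors; survivors always form a subset chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CascadeThresholds:
    diff_m6a_p: float = 0.05
    expressed_cpm: float = 1.0
    expressed_sample_fraction: float = 0.5
    de_q: float = 0.05
    directional: bool = True
    cox_p: float = 0.05
    mutation_frequency_max: float = 0.01
    cnv_frequency_max: float = 0.05
    require_cerna: bool = False


@dataclass
class CandidateReport:
    pseudogene_id: str
    subtype: str = ""
    diff_m6a: str = "none"        # hyper | hypo | none
    diff_m6a_p: float = 1.0
    diff_m6a_log2fc: float = 0.0
    expressed: bool = False
    de_direction: str = "ns"
    de_log2fc: float = 0.0
    concurrent: bool = False
    prognostic_os: str = "not significant"
    cox_beta: float = 0.0
    genetic_confound: bool = False
    parent_correlation: str = "No"
    shared_mirna_count: int = 0
    rank_score: float = float("nan")
    passed: bool = False


def filter_cascade(diff_peaks, de_results, matrix, cox_table,
                   genetic_summaries=None, correlations=None,
                   sponge_counts: Optional[dict] = None,
                   subtypes: Optional[dict] = None,
                   pseudogene_ids: Optional[set] = None,
                   thresholds: Optional[CascadeThresholds] = None) -> dict:
    """Run the ordered filters; returns {"reports": [CandidateReport...],
    "survivors": {stage: [ids]}, "skipped_filters": [...]}.

    A missing input layer (None) skips the corresponding filter and flags
    it; survivors after each filter are a subset of the previous stage.
    """
    th = thresholds or CascadeThresholds()
    from .integrate import normalize_cpm

    universe = set(pseudogene_ids) if pseudogene_ids is not None else None
    skipped = []

    # stage 1: differential m6A
    best_diff = {}
    for d in diff_peaks:
        if universe is not None and d.gene_id not in universe:
            continue
        cur = best_diff.get(d.gene_id)
        if cur is None or d.p_value < cur.p_value:
            best_diff[d.gene_id] = d
    reports = {}
    for gene_id, d in best_diff.items():
        r = CandidateReport(gene_id, (subtypes or {}).get(gene_id, ""))
        r.diff_m6a_p = d.p_value
        r.diff_m6a_log2fc = d.diff_log2fc
        r.diff_m6a = d.direction if d.p_value < th.diff_m6a_p else "none"
        reports[gene_id] = r
    survivors = {"diff_m6a": sorted(
        g for g, r in reports.items() if r.diff_m6a != "none"
    )}
    alive = set(survivors["diff_m6a"])

    # stage 2: expressed ("stabilized" RNA)
    if matrix is not None:
        cpm = normalize_cpm(matrix.counts)
        for cond in ("tumour", "normal"):
            cols = matrix.samples_of(cond)
            frac = (cpm[cols] >= th.expressed_cpm).mean(axis=1)
            for g in list(alive):
                if g in frac.index and frac[g] >= th.expressed_sample_fraction:
                    reports[g].expressed = True
        alive = {g for g in alive if reports[g].expressed}
    else:
        skipped.append("expressed")
        for g in alive:
            reports[g].expressed = True
    survivors["expressed"] = sorted(alive)

    # stage 3: concurrent differential expression, opposite sign to m6A
    if de_results is not None:
        de_by_gene = {r.gene_id: r for r in de_results}
        for g in list(alive):
            de = de_by_gene.get(g)
            if de is None:
                continue
            reports[g].de_direction = de.direction
            reports[g].de_log2fc = de.log2fc
            if de.direction == "ns":
                continue
            if not th.directional:
                reports[g].concurrent = True
            elif (reports[g].diff_m6a == "hypo" and de.direction == "up") or (
                    reports[g].diff_m6a == "hyper" and de.direction == "down"):
                reports[g].concurrent = True
        alive = {g for g in alive if reports[g].concurrent}
    else:
        skipped.append("concurrent_de")
    survivors["concurrent_de"] = sorted(alive)

    # stage 4: prognostic, direction-consistent
    if cox_table is not None:
        cox = cox_table.set_index("gene_id")
        for g in list(alive):
            if g not in cox.index:
                continue
            row = cox.loc[g]
            reports[g].prognostic_os = row["classification"]
            reports[g].cox_beta = float(row["beta"]) if np.isfinite(row["beta"]) else 0.0
        def consistent(r):
            return (r.de_direction == "up" and r.prognostic_os == "risk") or (
                r.de_direction == "down" and r.prognostic_os == "protective")
        alive = {g for g in alive if consistent(reports[g])}
    else:
        skipped.append("prognostic")
    survivors["prognostic"] = sorted(alive)

    # stage 5: genetic confound exclusion
    if genetic_summaries is not None:
        by_gene = {s.gene_id: s for s in genetic_summaries}
        for g in list(alive):
            s = by_gene.get(g)
            if s is not None and (
                s.mutation_frequency >= th.mutation_frequency_max
                or s.cnv_frequency >= th.cnv_frequency_max
            ):
                reports[g].genetic_confound = True
        alive = {g for g in alive if not reports[g].genetic_confound}
    else:
        skipped.append("genetic")
    survivors["genetic"] = sorted(alive)

    # stage 6: optional ceRNA evidence
    if correlations is not None:
        corr_by_pg = {c.pseudogene_id: c.sign_class for c in correlations}
        for g, r in reports.items():
            r.parent_correlation = corr_by_pg.get(g, "No")
    if sponge_counts is not None:
        for g, r in reports.items():
            r.shared_mirna_count = int(sponge_counts.get(g, 0))
    if th.require_cerna:
        if correlations is None or sponge_counts is None:
            skipped.append("cerna")
        else:
            alive = {
                g for g in alive
                if reports[g].shared_mirna_count >= 1
                and reports[g].parent_correlation == "Positive"
            }
    survivors["cerna"] = sorted(alive)

    for g in alive:
        reports[g].passed = True
    return {
        "reports": list(reports.values()),
        "survivors": survivors,
        "skipped_filters": skipped,
    }


def rank_candidates(reports: list) -> list:
    """Rank surviving candidates by summed standardized effect magnitudes.

    rank_score = z(|diff-m6A log2FC|) + z(|expression log2FC|) +
    z(|Cox beta|) over survivors (z-scoring the magnitudes keeps the score
    monotone in each effect size); ties broken by smaller differential-m6A
    p, then lexicographic id.
    """
    survivors = [r for r in reports if r.passed]
    if not survivors:
        return []

    def zscores(values):
        v = np.abs(np.asarray(values, dtype=float))
        sd = v.std(ddof=0)
        return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd

    z_m6a = zscores([r.diff_m6a_log2fc for r in survivors])
    z_de = zscores([r.de_log2fc for r in survivors])
    z_cox = zscores([r.cox_beta for r in survivors])
    for r, a, b, c in zip(survivors, z_m6a, z_de, z_cox):
        r.rank_score = float(a + b + c)
    survivors.sort(key=lambda r: (-r.rank_score, r.diff_m6a_p, r.pseudogene_id))
    return survivors


def reports_to_frame(reports: list) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in reports])


# ---------------------------------------------------------------------------
# end-to-end pipeline

def run_pipeline(config=None, outdir: Optional[str] = None,
                 thresholds: Optional[CascadeThresholds] = None) -> dict:
    """Simulate a cohort and run every analysis stage.

    Returns a bundle with all intermediate tables; when ``outdir`` is given,
    writes the standard TSV/BED outputs plus a JSON run log (seed, stage
    counts) whose bytes are identical across reruns with the same config.
    """
    from . import annotate_peaks as ap
    from . import cerna as ce
    from . import integrate as ig
    from . import merip as mp
    from . import motifs as mo
    from . import survival as sv
    from . import synthetic as syn

    config = config or syn.SimConfig()
    catalog, sequences, truth = syn.simulate_genome_annotation(config)
    mirnas, sequences = syn.simulate_mirnas(config, catalog, sequences, truth)
    wc = syn.simulate_merip(catalog, config, truth)

    wc_t = wc.subset_condition("tumour")
    wc_n = wc.subset_condition("normal")
    peaks_t = mp.call_peaks(wc_t, "tumour", step=config.step)
    peaks_n = mp.call_peaks(wc_n, "normal", step=config.step)
    union = mp.union_peaks(peaks_t, peaks_n)
    diff = mp.diff_methylation(wc_t, wc_n, union)
    m6a_levels = mp.gene_m6a_level(wc, peaks_t + peaks_n, condition="tumour")

    subtypes = {g: rec.subtype for g, rec in catalog.pseudogenes.items()}
    annotated = ap.annotate_peaks(peaks_t + peaks_n, catalog, subtypes=subtypes)
    region_dist = ap.region_distribution(annotated, by=["condition"])
    chrom_dist = ap.chromosome_distribution(peaks_t + peaks_n)

    peak_seqs = [
        syn.transcript_sequence(catalog.model(p.gene_id), sequences)
        [p.tx_start:p.tx_end]
        for p in peaks_t
    ]
    controls = mo.shuffle_controls(peak_seqs, seed=config.seed + 1)
    motif_results = mo.find_motifs(peak_seqs, controls)

    matrix = syn.simulate_expression(catalog, config, truth)
    de = ig.differential_expression(matrix)
    correlations = ig.spearman_pairs(matrix, catalog.pairs)
    tristile = ig.tristile_integration(m6a_levels, matrix)
    strata = ig.correlation_by_m6a_strata(correlations, m6a_levels, subtypes)

    surv_table = syn.simulate_survival(matrix, config, truth)
    logc = ig.log_cpm(matrix.counts[matrix.samples_of("tumour")])
    pg_ids = set(catalog.pseudogenes)
    cox_table = sv.cox_screen(logc.loc[sorted(pg_ids)], surv_table)

    mut, cnv = syn.simulate_genetics(catalog, config, truth)
    genetics = ig.genetic_summary(mut, cnv, matrix)

    mirna_objs = [ce.MiRNA(k, v) for k, v in mirnas.items()]
    sponge_counts = {}
    for pg_id, parent in catalog.pairs:
        pg_seq = syn.transcript_sequence(catalog.model(pg_id), sequences)
        pa_seq = syn.transcript_sequence(catalog.model(parent), sequences)
        res = ce.shared_mirnas(pg_seq, pa_seq, mirna_objs)
        sponge_counts[pg_id] = res["venn"]["shared"]

    cascade = filter_cascade(
        diff, de, matrix, cox_table, genetics, correlations,
        sponge_counts, subtypes, pseudogene_ids=pg_ids,
        thresholds=thresholds,
    )
    ranked = rank_candidates(cascade["reports"])

    bundle = {
        "config": config,
        "catalog": catalog,
        "truth": truth,
        "window_counts": wc,
        "peaks_tumour": peaks_t,
        "peaks_normal": peaks_n,
        "diff_peaks": diff,
        "m6a_levels": m6a_levels,
        "region_distribution": region_dist,
        "chromosome_distribution": chrom_dist,
        "motifs": motif_results,
        "expression": matrix,
        "de": de,
        "correlations": correlations,
        "tristile": tristile,
        "strata": strata,
        "survival": surv_table,
        "cox": cox_table,
        "genetics": genetics,
        "sponge_counts": sponge_counts,
        "cascade": cascade,
        "ranked": ranked,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle, outdir: Path) -> None:
    from . import annotations as an
    from . import integrate as ig
    from . import merip as mp
    from . import motifs as mo
    from . import synthetic as syn

    outdir.mkdir(parents=True, exist_ok=True)
    an.write_gtf(bundle["catalog"], str(outdir / "annotation.gtf"))
    an.write_pair_table(bundle["catalog"], str(outdir / "pairs.tsv"))
    bundle["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    mp.write_peaks_bed(bundle["peaks_tumour"] + bundle["peaks_normal"],
                       str(outdir / "peaks.bed"))
    mp.diff_peaks_to_frame(bundle["diff_peaks"]).to_csv(
        outdir / "diff_peaks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g.gene_id, "level": g.level, "tertile": g.tertile,
          "m6a_positive": g.m6a_positive} for g in bundle["m6a_levels"]]
    ).to_csv(outdir / "m6a_levels.tsv", sep="\t", index=False)
    bundle["region_distribution"].to_csv(
        outdir / "region_distribution.tsv", sep="\t", index=False)
    bundle["chromosome_distribution"].to_csv(
        outdir / "chromosome_distribution.tsv", sep="\t", index=False)
    mo.motifs_to_frame(bundle["motifs"]).to_csv(
        outdir / "motifs.tsv", sep="\t", index=False)
    ig.de_to_frame(bundle["de"]).to_csv(outdir / "de.tsv", sep="\t", index=False)
    ig.correlations_to_frame(bundle["correlations"]).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False)
    bundle["tristile"]["cdf"].to_csv(outdir / "tristile_cdf.tsv", sep="\t", index=False)
    bundle["survival"].to_csv(outdir / "survival.tsv", sep="\t", index=False)
    bundle["cox"].to_csv(outdir / "cox.tsv", sep="\t", index=False)
    ig.genetics_to_frame(bundle["genetics"]).to_csv(
        outdir / "genetics.tsv", sep="\t", index=False)
    reports_to_frame(bundle["cascade"]["reports"]).to_csv(
        outdir / "candidate_report.tsv", sep="\t", index=False)
    reports_to_frame(bundle["ranked"]).to_csv(
        outdir / "ranked_candidates.tsv", sep="\t", index=False)
    log = {
        "seed": bundle["config"].seed,
        "config": syn.config_to_dict(bundle["config"]),
        "n_genes": int(len(bundle["truth"])),
        "n_peaks_tumour": len(bundle["peaks_tumour"]),
        "n_peaks_normal": len(bundle["peaks_normal"]),
        "n_diff_peaks": len(bundle["diff_peaks"]),
        "survivors": {k: len(v) for k, v in bundle["cascade"]["survivors"].items()},
        "skipped_filters": bundle["cascade"]["skipped_filters"],
        "top_candidate": (bundle["ranked"][0].pseudogene_id
                          if bundle["ranked"] else None),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
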