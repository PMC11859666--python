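"""Synthetic multi-omics generator.

Emulates the statistical structure of the real study design — MeRIP-seq
IP/input window counts over tumour and normal tissue, bulk expression
counts for tumour and normal cohorts, survival outcomes tied to expression,
and mutation/CNV matrices — over a randomly generated annotation with
pseudogene subtypes, parent-gene pairing and a planted m6A motif at
methylation sites.

Everything is driven by one ``SimConfig`` whose defaults are the study
conditions; a single master seed spawns a named substream per component so
adding one generator never perturbs another.  The planted truth (which
genes are methylated, hyper/hypo, differentially expressed, prognostic) is
emitted as a table so downstream recovery tests are self-contained.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .annotations import (
    Catalog,
    GenomicInterval,
    PseudogeneRecord,
    TranscriptModel,
)
from .integrate import ExpressionMatrix
from .merip import WindowCounts, tile_length

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the simulated study conditions."""

    n_genes: int = 200
    pseudogene_fraction: float = 0.5
    # processed pseudogenes dominate the genome (~72%)
    subtype_proportions: dict = field(
        default_factory=lambda: {
            "processed": 0.72, "unprocessed": 0.20,
            "unitary": 0.05, "polymorphic": 0.03,
        }
    )
    # expression cohort sizes (scaled-down tumour cohort vs normal controls)
    n_tumour: int = 50
    n_normal: int = 30
    # MeRIP design: replicate IP/input library pairs per condition
    merip_tumour_reps: int = 6
    merip_normal_reps: int = 7
    window_size: int = 50
    step: int = 25
    mean_depth_per_window: float = 30.0
    nb_dispersion: float = 0.1
    peak_enrichment_fold: float = 4.0
    fraction_methylated: float = 0.3
    fraction_hyper: float = 0.15  # of methylated genes: tumour-specific m6A
    fraction_hypo: float = 0.15   # of methylated genes: normal-specific m6A
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    cerna_coupling_rho: float = 0.6
    # correlation attenuation with m6A, applied to processed pseudogenes
    cerna_m6a_attenuation: float = 0.8
    m6a_expression_gamma: float = 0.3  # expression mean ~ exp(-gamma * m6A level)
    survival_beta: float = float(np.log(2.0))  # log-HR per SD of risk-gene expression
    censor_fraction: float = 0.2
    mutation_rate: float = 0.005
    cnv_rate: float = 0.03
    planted_motif: str = "GGACU"
    plant_candidate: bool = True
    # gene architecture
    min_exons: int = 1
    max_exons: int = 4
    exon_length_range: tuple = (150, 400)
    intron_length_range: tuple = (100, 400)
    intergenic_gap: int = 500
    n_chromosomes: int = 6
    # nuisance scales
    base_log_mean: float = float(np.log(100.0))
    base_log_sd: float = 0.7
    sample_effect_sd: float = 0.8
    baseline_hazard: float = 0.1
    seed: int = 0

    def __post_init__(self):
        fracs = [
            self.pseudogene_fraction, self.fraction_methylated,
            self.fraction_hyper, self.fraction_hypo, self.de_fraction,
            self.censor_fraction, self.mutation_rate, self.cnv_rate,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.peak_enrichment_fold <= 0 or self.nb_dispersion <= 0:
            raise ValueError("folds and dispersion must be positive")
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable across runs and across component additions."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """NB(mean, phi) with variance mu + phi mu^2 via gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# annotation + sequence

def simulate_genome_annotation(config: SimConfig):
    """Random gene models, pseudogene layer, chromosome sequences and the
    planted truth table.

    Returns (catalog, sequences, truth) where ``sequences`` maps chromosome
    name -> DNA string and ``truth`` is a per-gene DataFrame.  Methylated
    genes carry the planted motif (DNA alphabet) at the centre of each
    designated methylation window; the motif is written strand-aware so the
    transcript reads it 5'->3'.
    """
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = _rng(config.seed, "annotation")

    n_pg = int(round(config.n_genes * config.pseudogene_fraction))
    n_coding = config.n_genes - n_pg
    subtype_names = list(config.subtype_proportions)
    subtype_p = np.array([config.subtype_proportions[s] for s in subtype_names])

    # counts per subtype: largest-remainder rounding so proportions are exact
    raw = subtype_p * n_pg
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_pg - counts.sum()]:
        counts[i] += 1

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: config.intergenic_gap for c in chrom_names}
    seqs = {c: [rng.choice(list("ACGT"), size=config.intergenic_gap).tolist()]
            for c in chrom_names}

    catalog = Catalog()
    truth_rows = []
    gene_specs = [("gene", None)] * n_coding
    for name, k in zip(subtype_names, counts):
        gene_specs += [("pseudogene", name)] * int(k)
    order = rng.permutation(len(gene_specs))
    gene_specs = [gene_specs[i] for i in order]

    methylated = rng.random(config.n_genes) < config.fraction_methylated
    meth_idx = np.flatnonzero(methylated)
    n_meth = len(meth_idx)
    n_hyper = int(round(n_meth * config.fraction_hyper))
    n_hypo = int(round(n_meth * config.fraction_hypo))
    shuffled = rng.permutation(meth_idx)
    hyper_set = set(shuffled[:n_hyper].tolist())
    hypo_set = set(shuffled[n_hyper: n_hyper + n_hypo].tolist())

    de = rng.random(config.n_genes) < config.de_fraction
    de_sign = rng.choice([-1, 1], size=config.n_genes)

    motif_dna = config.planted_motif.upper().replace("U", "T")

    for i, (kind, subtype) in enumerate(gene_specs):
        gene_id = f"PG{i:04d}" if kind == "pseudogene" else f"G{i:04d}"
        chrom = chrom_names[i % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 1 if subtype == "processed" else int(
            rng.integers(config.min_exons, config.max_exons + 1)
        )
        pos = cursors[chrom]
        exons = []
        for e in range(n_exons):
            elen = int(rng.integers(*config.exon_length_range))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            seqs[chrom].append(rng.choice(list("ACGT"), size=elen).tolist())
            pos += elen
            if e < n_exons - 1:
                ilen = int(rng.integers(*config.intron_length_range))
                seqs[chrom].append(rng.choice(list("ACGT"), size=ilen).tolist())
                pos += ilen
        gap = config.intergenic_gap
        seqs[chrom].append(rng.choice(list("ACGT"), size=gap).tolist())
        cursors[chrom] = pos + gap
        model = TranscriptModel(gene_id, f"{gene_id}.t1", "simulated", exons)

        is_meth = bool(methylated[i])
        in_hyper = i in hyper_set
        in_hypo = i in hypo_set
        meth_tumour = is_meth and not in_hypo
        meth_normal = is_meth and not in_hyper
        planted_windows = ()
        if is_meth:
            tiles = tile_length(model.exonic_length, config.window_size, config.step)
            # non-overlapping candidate windows so sites do not collide
            candidates = [w for w in range(len(tiles))
                          if tiles[w][0] % config.window_size == 0]
            k_sites = min(int(rng.integers(1, 3)), len(candidates))
            planted_windows = tuple(
                sorted(rng.choice(candidates, size=k_sites, replace=False).tolist())
            )
        row = {
            "gene_id": gene_id,
            "kind": kind,
            "subtype": subtype or "",
            "chrom": chrom,
            "strand": strand,
            "exonic_length": model.exonic_length,
            "methylated": is_meth,
            "meth_tumour": meth_tumour,
            "meth_normal": meth_normal,
            "m6a_group": ("hyper" if in_hyper else
                          "hypo" if in_hypo else
                          "stable" if is_meth else "none"),
            "planted_windows": ";".join(str(w) for w in planted_windows),
            "de_status": "ns",
            "true_log2fc": 0.0,
            "is_risk_gene": False,
            "is_candidate": False,
            "parent_gene_id": "",
        }
        if de[i]:
            row["de_status"] = "up" if de_sign[i] > 0 else "down"
            row["true_log2fc"] = float(de_sign[i] * config.de_log2fc)
        if kind == "pseudogene":
            catalog.pseudogenes[gene_id] = PseudogeneRecord(gene_id, subtype, model)
        else:
            catalog.genes[gene_id] = model
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows).set_index("gene_id", drop=False)

    # parent pairing: each pseudogene paired with a random coding gene
    coding_ids = list(catalog.genes)
    pg_ids = list(catalog.pseudogenes)
    if coding_ids:
        # unique parents when possible so each pair's latent coupling is
        # independent of every other pair's
        if len(coding_ids) >= len(pg_ids):
            parents = rng.choice(coding_ids, size=len(pg_ids), replace=False)
        else:
            parents = rng.choice(coding_ids, size=len(pg_ids), replace=True)
        for pg_id, parent in zip(pg_ids, parents):
            rec = catalog.pseudogenes[pg_id]
            rec.parent_gene_id, rec.unpaired = str(parent), False
            catalog.pairs.append((pg_id, str(parent)))
            truth.loc[pg_id, "parent_gene_id"] = str(parent)
        catalog.pair_summary = {
            "n": len(pg_ids), "paired": len(catalog.pairs),
            "unique_parents": len({p for _, p in catalog.pairs}), "skipped": 0,
        }

    # designate exactly one strong candidate: processed pseudogene, hypo-m6A,
    # up-regulated, prognostic risk, genetically unaltered
    if config.plant_candidate:
        processed = [g for g in pg_ids
                     if catalog.pseudogenes[g].subtype == "processed"
                     and truth.loc[g, "parent_gene_id"] != ""]
        if not processed:
            raise ValueError("no processed pseudogene available for candidate")
        cand = sorted(processed)[int(rng.integers(len(processed)))]
        model = catalog.pseudogenes[cand].model
        tiles = tile_length(model.exonic_length, config.window_size, config.step)
        candidates = [w for w in range(len(tiles))
                      if tiles[w][0] % config.window_size == 0]
        truth.loc[cand, ["methylated", "meth_tumour", "meth_normal"]] = (
            True, False, True
        )
        truth.loc[cand, "m6a_group"] = "hypo"
        truth.loc[cand, "planted_windows"] = ";".join(
            str(w) for w in candidates[:2]
        )
        truth.loc[cand, "de_status"] = "up"
        truth.loc[cand, "true_log2fc"] = float(config.de_log2fc)
        truth.loc[cand, "is_risk_gene"] = True
        truth.loc[cand, "is_candidate"] = True
        # other diff-m6A genes must not mimic the full candidate profile:
        # decouple their expression change from the m6A direction
        for g in truth.index[(truth["m6a_group"].isin(["hyper", "hypo"]))
                             & (~truth["is_candidate"])]:
            if truth.loc[g, "m6a_group"] == "hypo" and truth.loc[g, "de_status"] == "up":
                truth.loc[g, "de_status"] = "ns"
                truth.loc[g, "true_log2fc"] = 0.0
            if truth.loc[g, "m6a_group"] == "hyper" and truth.loc[g, "de_status"] == "down":
                truth.loc[g, "de_status"] = "ns"
                truth.loc[g, "true_log2fc"] = 0.0

    # materialize sequences and plant the motif at methylation sites
    sequences = {c: list("".join("".join(part) for part in parts))
                 for c, parts in seqs.items()}
    for gene_id, row in truth.iterrows():
        if not row["planted_windows"]:
            continue
        model = catalog.model(gene_id)
        tiles = tile_length(model.exonic_length, config.window_size, config.step)
        for w in (int(x) for x in row["planted_windows"].split(";")):
            s, e = tiles[w]
            centre = (s + e) // 2 - len(motif_dna) // 2
            for k, base in enumerate(motif_dna):
                tpos = centre + k
                gpos = model.transcript_to_genomic(tpos)
                sequences[model.chrom][gpos] = (
                    base if model.strand == "+" else base.translate(COMPLEMENT)
                )
    sequences = {c: "".join(v) for c, v in sequences.items()}
    return catalog, sequences, truth


def write_fasta(sequences: dict, path: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sorted(sequences.items())]
    SeqIO.write(records, path, "fasta")


def transcript_sequence(model: TranscriptModel, sequences: dict) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on -)."""
    s = "".join(sequences[model.chrom][e.start:e.end] for e in model.exons)
    return revcomp(s) if model.strand == "-" else s


# ---------------------------------------------------------------------------
# MeRIP window counts

def simulate_merip(catalog: Catalog, config: SimConfig,
                   truth: pd.DataFrame) -> WindowCounts:
    """IP/input NB window counts for both conditions.

    Input counts follow NB with a gene-level mean; IP counts at planted
    methylation windows are inflated by ``peak_enrichment_fold`` in the
    conditions where the gene is methylated.
    """
    rng = _rng(config.seed, "merip")
    rows = []
    gene_factor = {}
    for gene_id in catalog.all_ids():
        model = catalog.model(gene_id)
        gene_factor[gene_id] = float(
            np.exp(rng.normal(0.0, 0.35))
        )
        for w, (s, e) in enumerate(
            tile_length(model.exonic_length, config.window_size, config.step)
        ):
            gs = model.transcript_to_genomic(s)
            ge = model.transcript_to_genomic(e - 1)
            rows.append((gene_id, w, model.chrom, min(gs, ge), max(gs, ge) + 1,
                         model.strand, s, e))
    windows = pd.DataFrame(
        rows, columns=["gene_id", "window_index", "chrom", "start", "end",
                       "strand", "tx_start", "tx_end"])

    planted = {}
    for gene_id, row in truth.iterrows():
        if row["planted_windows"]:
            planted[gene_id] = {int(x) for x in row["planted_windows"].split(";")}

    sample_rows, ip_cols, input_cols = [], {}, {}
    base_mu = np.array(
        [config.mean_depth_per_window * gene_factor[g] for g in windows["gene_id"]]
    )
    # per-window methylation fold masks per condition
    fold_mask = {}
    for cond, flag in (("tumour", "meth_tumour"), ("normal", "meth_normal")):
        mask = np.ones(len(windows))
        for i, (g, w) in enumerate(zip(windows["gene_id"], windows["window_index"])):
            if truth.loc[g, flag] and w in planted.get(g, ()):  # planted site
                mask[i] = config.peak_enrichment_fold
        fold_mask[cond] = mask
    reps = {"tumour": config.merip_tumour_reps, "normal": config.merip_normal_reps}
    shape = 1.0 / config.nb_dispersion
    for cond in ("tumour", "normal"):
        for r in range(reps[cond]):
            sid = f"{cond[0].upper()}{r + 1}"
            sample_rows.append({"sample_id": sid, "condition": cond})
            # paired-aliquot model: the IP library and its matched input
            # share the window's latent biological abundance (same RNA
            # pool); enrichment acts multiplicatively on the IP rate.
            # Marginally both are NB(mu, phi).
            lam = rng.gamma(shape, base_mu * config.nb_dispersion)
            input_cols[sid] = rng.poisson(lam)
            ip_cols[sid] = rng.poisson(lam * fold_mask[cond])
    samples = pd.DataFrame(sample_rows)
    return WindowCounts(
        windows,
        pd.DataFrame(ip_cols, index=windows.index),
        pd.DataFrame(input_cols, index=windows.index),
        samples,
    )


# ---------------------------------------------------------------------------
# expression

def planted_m6a_level(config: SimConfig, truth: pd.DataFrame,
                      condition: str = "tumour") -> pd.Series:
    """The generator's own per-gene m6A level (log2 enrichment at planted
    sites, 0 for unmethylated genes) in one condition."""
    flag = "meth_tumour" if condition == "tumour" else "meth_normal"
    level = np.where(truth[flag], np.log2(config.peak_enrichment_fold), 0.0)
    return pd.Series(level, index=truth.index)


def simulate_expression(catalog: Catalog, config: SimConfig,
                        truth: pd.DataFrame,
                        m6a_levels: Optional[pd.Series] = None) -> ExpressionMatrix:
    """NB expression counts for tumour and normal cohorts.

    Gene means carry (i) the planted DE log2 fold changes, (ii) the
    m6A-expression coupling exp(-gamma * level) in each condition, and
    (iii) pseudogene-parent coupling through a shared per-sample Gaussian
    latent on the log-mean scale (coupling rho, attenuated with m6A level
    for processed pseudogenes).
    """
    rng = _rng(config.seed, "expression")
    genes = list(truth.index)
    n_genes = len(genes)
    n_t, n_n = config.n_tumour, config.n_normal
    sample_ids = [f"TU{i + 1:03d}" for i in range(n_t)] + [
        f"NO{i + 1:03d}" for i in range(n_n)]
    conditions = pd.Series(
        ["tumour"] * n_t + ["normal"] * n_n, index=sample_ids, name="condition")

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=n_genes)
    level_t = (m6a_levels if m6a_levels is not None
               else planted_m6a_level(config, truth, "tumour"))
    level_n = planted_m6a_level(config, truth, "normal")
    gamma = config.m6a_expression_gamma

    log_mu = np.zeros((n_genes, n_t + n_n))
    for gi, g in enumerate(genes):
        lfc = truth.loc[g, "true_log2fc"] * np.log(2.0)
        mu_t = base[gi] + lfc - gamma * float(level_t[g])
        mu_n = base[gi] - gamma * float(level_n[g])
        log_mu[gi, :n_t] = mu_t
        log_mu[gi, n_t:] = mu_n

    # per-sample latent effects: shared within a pair at rho_eff
    sigma = config.sample_effect_sd
    latent = np.zeros((n_genes, n_t + n_n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    paired_pg = {pg: parent for pg, parent in catalog.pairs}
    max_level = max(float(level_t.max()), 1e-9)
    own_z = rng.normal(size=(n_genes, n_t + n_n))
    for pg, parent in paired_pg.items():
        if pg not in gene_pos or parent not in gene_pos:
            continue
        rho = config.cerna_coupling_rho
        if catalog.pseudogenes[pg].subtype == "processed":
            atten = config.cerna_m6a_attenuation * float(level_t[pg]) / max_level
            rho = rho * max(0.0, 1.0 - atten)
        z_pg = own_z[gene_pos[pg]]
        eps = rng.normal(size=n_t + n_n)
        own_z[gene_pos[parent]] = rho * z_pg + np.sqrt(max(0.0, 1 - rho**2)) * eps
    latent = sigma * own_z

    mu = np.exp(log_mu + latent)
    counts = _nb(rng, mu, config.nb_dispersion)
    frame = pd.DataFrame(counts, index=genes, columns=sample_ids)
    return ExpressionMatrix(frame, conditions)


# ---------------------------------------------------------------------------
# survival

def simulate_survival(matrix: ExpressionMatrix, config: SimConfig,
                      truth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample survival table for the tumour cohort.

    Event times are exponential with hazard lambda0 * exp(beta * z) where z
    is the standardized mean log2(CPM+1) of the designated risk genes;
    censoring is an independent exponential with rate tuned to the
    configured censoring fraction.
    """
    from .integrate import log_cpm

    rng = _rng(config.seed, "survival")
    cols = matrix.samples_of("tumour")
    logc = log_cpm(matrix.counts[cols])
    risk_genes = list(truth.index[truth["is_risk_gene"]])
    if risk_genes:
        score = logc.loc[risk_genes].mean(axis=0)
        sd = score.std(ddof=0)
        z = (score - score.mean()) / (sd if sd > 0 else 1.0)
    else:
        z = pd.Series(0.0, index=cols)
    lam = config.baseline_hazard * np.exp(config.survival_beta * z.to_numpy())
    event_t = rng.exponential(1.0 / lam)
    cf = config.censor_fraction
    if cf > 0:
        c_rate = config.baseline_hazard * cf / (1.0 - cf)
        censor_t = rng.exponential(1.0 / c_rate, size=len(cols))
    else:
        censor_t = np.full(len(cols), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame(
        {"sample_id": cols, "time": time, "event": event}
    )


# ---------------------------------------------------------------------------
# genetics

def simulate_genetics(catalog: Catalog, config: SimConfig, truth: pd.DataFrame,
                      sample_ids: Optional[list] = None):
    """Bernoulli mutation calls and integer CNV states in {-2..2} for the
    tumour cohort; the planted candidate is kept genetically clean."""
    rng = _rng(config.seed, "genetics")
    if sample_ids is None:
        sample_ids = [f"TU{i + 1:03d}" for i in range(config.n_tumour)]
    genes = list(truth.index)
    n, m = len(genes), len(sample_ids)
    mut = (rng.random((n, m)) < config.mutation_rate).astype(int)
    has_cnv = rng.random((n, m)) < config.cnv_rate
    states = rng.choice([-2, -1, 1, 2], size=(n, m))
    cnv = np.where(has_cnv, states, 0)
    cand = truth.index[truth["is_candidate"]]
    for g in cand:
        gi = genes.index(g)
        mut[gi, :] = 0
        cnv[gi, :] = 0
    mut_df = pd.DataFrame(mut, index=genes, columns=sample_ids)
    cnv_df = pd.DataFrame(cnv, index=genes, columns=sample_ids)
    return mut_df, cnv_df


# ---------------------------------------------------------------------------
# miRNA layer (for the ceRNA stage of the pipeline)

def simulate_mirnas(config: SimConfig, catalog: Catalog, sequences: dict,
                    truth: pd.DataFrame, n_mirnas: int = 10,
                    length: int = 22):
    """Random miRNA set; the first miRNA gets seed-match sites planted into
    the candidate pseudogene and its parent so the shared-sponge stage has a
    recoverable signal."""
    rng = _rng(config.seed, "mirna")
    bases = "ACGU"
    mirnas = {}
    for i in range(n_mirnas):
        mirnas[f"mir-{i + 1:03d}"] = "".join(
            rng.choice(list(bases), size=length).tolist()
        )
    seqs = dict(sequences)
    cand = list(truth.index[truth["is_candidate"]])
    if cand:
        mir = mirnas["mir-001"]
        seed_dna = mir[1:7].replace("U", "T")
        site = revcomp(seed_dna)  # transcript-sense 6mer site
        for gene_id in [cand[0], truth.loc[cand[0], "parent_gene_id"]]:
            if not gene_id:
                continue
            model = catalog.model(gene_id)
            tpos = model.exonic_length - 30  # near the transcript 3' end
            chrom_seq = list(seqs[model.chrom])
            for k, base in enumerate(site):
                gpos = model.transcript_to_genomic(tpos + k)
                chrom_seq[gpos] = (base if model.strand == "+"
                                   else base.translate(COMPLEMENT))
            seqs[model.chrom] = "".join(chrom_seq)
    return mirnas, seqs


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["exon_length_range"] = list(d["exon_length_range"])
    d["intron_length_range"] = list(d["intron_length_range"])
    return d
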