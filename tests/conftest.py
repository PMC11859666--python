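import numpy as np
import pandas as pd
import pytest

from pseudom6a.annotations import Catalog, GenomicInterval, TranscriptModel
from pseudom6a.synthetic import SimConfig, simulate_genome_annotation


@pytest.fixture
def toy_catalog():
    """Two genes on chr1: a two-exon coding gene with CDS/UTRs and a
    single-exon (processed-pseudogene-like) gene on the minus strand."""
    from pseudom6a.annotations import PseudogeneRecord

    coding = TranscriptModel(
        "GENE1", "GENE1.t1", "protein_coding",
        exons=[GenomicInterval("chr1", 100, 300, "+"),
               GenomicInterval("chr1", 400, 700, "+")],
        cds=[GenomicInterval("chr1", 150, 300, "+"),
             GenomicInterval("chr1", 400, 600, "+")],
    )
    pg_model = TranscriptModel(
        "PGX", "PGX.t1", "processed_pseudogene",
        exons=[GenomicInterval("chr1", 2000, 2400, "-")],
    )
    cat = Catalog()
    cat.genes["GENE1"] = coding
    cat.pseudogenes["PGX"] = PseudogeneRecord("PGX", "processed", pg_model)
    return cat


@pytest.fixture(scope="session")
def small_sim():
    """One shared 120-gene simulated cohort (annotation + truth only)."""
    cfg = SimConfig(n_genes=120, seed=7)
    catalog, sequences, truth = simulate_genome_annotation(cfg)
    return cfg, catalog, sequences, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
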