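"""Genomic data model: gene/transcript structures, pseudogene subtypes and
parent-gene pairing.

All internal coordinates are 0-based half-open on the forward strand of the
reference; GTF input/output converts at the boundary (GTF is 1-based,
inclusive).  Region labels (5'UTR vs 3'UTR, TSS vs TTS) are strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pandas as pd

PSEUDOGENE_SUBTYPES = ("processed", "unprocessed", "unitary", "polymorphic")

#: region vocabulary used by peak annotation
REGION_LABELS = ("3'UTR", "5'UTR", "exon", "TSS", "TTS", "intron", "intergenic")


class GtfParseError(ValueError):
    """Raised for a structurally invalid GTF line; carries the line number."""


class CatalogValidationError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """One transcript per gene: ordered disjoint exons, optional CDS.

    UTRs, TSS/TTS and introns are derived, never stored.
    """

    gene_id: str
    transcript_id: str
    biotype: str
    exons: list  # of GenomicInterval, sorted, disjoint
    cds: Optional[list] = None

    def __post_init__(self):
        if not self.exons:
            raise CatalogValidationError(f"{self.gene_id}: no exons")
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise CatalogValidationError(
                    f"{self.gene_id}: overlapping exons [{a.start},{a.end}) "
                    f"and [{b.start},{b.end})"
                )
        self.exons = ex
        if self.cds:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            for c in self.cds:
                if not any(e.start <= c.start and c.end <= e.end for e in ex):
                    raise CatalogValidationError(
                        f"{self.gene_id}: CDS [{c.start},{c.end}) outside exons"
                    )

    # -- derived structure ------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware genomic position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def _utrs(self) -> tuple:
        """(utr5, utr3) interval lists; empty when there is no CDS."""
        if not self.cds:
            return [], []
        cds_start = self.cds[0].start
        cds_end = self.cds[-1].end
        before, after = [], []
        for e in self.exons:
            if e.start < cds_start:
                before.append(
                    GenomicInterval(self.chrom, e.start, min(e.end, cds_start), self.strand)
                )
            if e.end > cds_end:
                after.append(
                    GenomicInterval(self.chrom, max(e.start, cds_end), e.end, self.strand)
                )
        return (before, after) if self.strand == "+" else (after, before)

    @property
    def utr5(self) -> list:
        return self._utrs()[0]

    @property
    def utr3(self) -> list:
        return self._utrs()[1]

    # -- coordinate projection --------------------------------------------
    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position inside an exon to the 5'->3' transcript
        coordinate; None if the position is intronic or outside the span."""
        offset = 0
        for e in self.exons:
            if e.start <= pos < e.end:
                t = offset + (pos - e.start)
                if self.strand == "-":
                    t = self.exonic_length - 1 - t
                return t
            offset += len(e)
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.exonic_length:
            raise ValueError(f"transcript position {tpos} out of range")
        if self.strand == "-":
            tpos = self.exonic_length - 1 - tpos
        for e in self.exons:
            if tpos < len(e):
                return e.start + tpos
            tpos -= len(e)
        raise AssertionError("unreachable")


@dataclass
class PseudogeneRecord:
    pseudogene_id: str
    subtype: str
    model: TranscriptModel
    parent_gene_id: Optional[str] = None
    unpaired: bool = True

    def __post_init__(self):
        if self.subtype not in PSEUDOGENE_SUBTYPES:
            raise ValueError(
                f"subtype must be one of {PSEUDOGENE_SUBTYPES}, got {self.subtype!r}"
            )


@dataclass
class Catalog:
    """All gene models plus the pseudogene layer and parent pairing."""

    genes: dict = field(default_factory=dict)        # gene_id -> TranscriptModel
    pseudogenes: dict = field(default_factory=dict)  # id -> PseudogeneRecord
    pairs: list = field(default_factory=list)        # (pseudogene_id, parent_gene_id)
    pair_summary: dict = field(default_factory=dict)

    def model(self, gene_id: str) -> TranscriptModel:
        if gene_id in self.genes:
            return self.genes[gene_id]
        return self.pseudogenes[gene_id].model

    def all_ids(self) -> list:
        return list(self.genes) + list(self.pseudogenes)

    def validate_pairs(self) -> None:
        seen = set()
        for pg, parent in self.pairs:
            if pg not in self.pseudogenes:
                raise CatalogValidationError(f"pair references unknown pseudogene {pg}")
            if parent not in self.genes:
                raise CatalogValidationError(f"pair references unknown parent {parent}")
            if (pg, parent) in seen:
                raise CatalogValidationError(f"duplicate pair ({pg}, {parent})")
            seen.add((pg, parent))


# ---------------------------------------------------------------------------
# biotype mapping

def classify_biotype(biotype: str) -> Optional[str]:
    """Map an annotation biotype onto the four pseudogene subtypes.

    Returns None for biotypes that are not pseudogenes (they are kept as
    ordinary genes in the catalog).
    """
    b = biotype.lower()
    if "pseudogene" not in b:
        return None
    for subtype in ("unprocessed", "processed", "unitary", "polymorphic"):
        if subtype in b:
            return subtype
    return None  # bare/unclassified "pseudogene" -> treated as ordinary gene


# ---------------------------------------------------------------------------
# GTF I/O

def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid 1-based interval {start}-{end}"
                )


def read_gtf(path: str) -> Catalog:
    """Read a GTF file into a Catalog (coordinates converted to 0-based
    half-open).  Pseudogene biotypes are mapped onto the four subtypes;
    anything else is recorded as a non-pseudogene gene."""
    _validate_gtf_lines(path)
    with open(path) as fh:
        if not any(ln.strip() and not ln.startswith("#") for ln in fh):
            return Catalog()

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    catalog = Catalog()
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.attributes["gene_id"][0]
        biotype = (
            gene.attributes.get("gene_biotype") or gene.attributes.get("gene_type") or ["protein_coding"]
        )[0]
        transcripts = list(db.children(gene, featuretype="transcript"))
        if not transcripts:
            continue
        # single-model policy: one transcript per gene, first encountered
        tx = transcripts[0]
        tx_id = tx.attributes["transcript_id"][0]
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(tx, featuretype="exon", order_by="start")
        ]
        cds = [
            GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
            for c in db.children(tx, featuretype="CDS", order_by="start")
        ] or None
        for e in exons:
            if e.start < tx.start - 1 or e.end > tx.end:
                raise CatalogValidationError(
                    f"{gene_id}: exon [{e.start},{e.end}) outside transcript span "
                    f"[{tx.start - 1},{tx.end})"
                )
        model = TranscriptModel(gene_id, tx_id, biotype, exons, cds)
        subtype = classify_biotype(biotype)
        if subtype is None:
            catalog.genes[gene_id] = model
        else:
            catalog.pseudogenes[gene_id] = PseudogeneRecord(gene_id, subtype, model)
    return catalog


def write_gtf(catalog: Catalog, path: str) -> None:
    """Write a Catalog back to GTF (1-based inclusive)."""

    def rows(model: TranscriptModel, biotype: str):
        attrs = f'gene_id "{model.gene_id}"; gene_biotype "{biotype}";'
        tattrs = (
            f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}"; '
            f'gene_biotype "{biotype}";'
        )
        yield (model.chrom, "gene", model.start + 1, model.end, model.strand, attrs)
        yield (model.chrom, "transcript", model.start + 1, model.end, model.strand, tattrs)
        for e in model.exons:
            yield (e.chrom, "exon", e.start + 1, e.end, e.strand, tattrs)
        for c in model.cds or []:
            yield (c.chrom, "CDS", c.start + 1, c.end, c.strand, tattrs)

    biotype_of = {s: f"{s}_pseudogene" for s in PSEUDOGENE_SUBTYPES}
    with open(path, "w") as fh:
        entries = [(gid, m, m.biotype) for gid, m in catalog.genes.items()]
        entries += [
            (gid, rec.model, biotype_of[rec.subtype])
            for gid, rec in catalog.pseudogenes.items()
        ]
        entries.sort(key=lambda t: (t[1].chrom, t[1].start, t[0]))
        for _, model, biotype in entries:
            for chrom, feat, start, end, strand, attrs in rows(model, biotype):
                fh.write(
                    f"{chrom}\tpseudom6a\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )


def write_bed6(intervals: Iterable, names: Iterable, scores: Iterable, path: str,
               extra_columns: Optional[pd.DataFrame] = None) -> None:
    """BED6 (+ optional extra columns) writer; BED stays 0-based half-open."""
    rows = []
    for iv, name, score in zip(intervals, names, scores):
        rows.append([iv.chrom, iv.start, iv.end, name, score, iv.strand])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if extra_columns is not None:
        df = pd.concat([df, extra_columns.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# parent pairing

def read_pair_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pseudogene_id", "parent_gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    return df


def pair_parents(catalog: Catalog, mapping: pd.DataFrame) -> Catalog:
    """Attach parent-gene assignments from a pseudogene_id -> parent_gene_id
    table.  Pairs whose parent is absent from the catalog are skipped with a
    warning.  The summary (n pseudogenes, n paired, n unique parents, n
    skipped) lands in ``catalog.pair_summary``."""
    catalog.pairs = []
    skipped = 0
    table = dict(zip(mapping["pseudogene_id"], mapping["parent_gene_id"]))
    for pg_id, rec in catalog.pseudogenes.items():
        parent = table.get(pg_id)
        if parent is None:
            rec.parent_gene_id, rec.unpaired = None, True
            continue
        if parent not in catalog.genes:
            warnings.warn(
                f"parent {parent} of {pg_id} not in catalog; pair skipped",
                stacklevel=2,
            )
            skipped += 1
            rec.parent_gene_id, rec.unpaired = None, True
            continue
        rec.parent_gene_id, rec.unpaired = parent, False
        catalog.pairs.append((pg_id, parent))
    catalog.pair_summary = {
        "n": len(catalog.pseudogenes),
        "paired": len(catalog.pairs),
        "unique_parents": len({p for _, p in catalog.pairs}),
        "skipped": skipped,
    }
    catalog.validate_pairs()
    return catalog


def write_pair_table(catalog: Catalog, path: str) -> None:
    pd.DataFrame(catalog.pairs, columns=["pseudogene_id", "parent_gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# region derivation

def derive_regions(model: TranscriptModel, flank: int = 1000) -> list:
    """Labeled (GenomicInterval, label) regions for one gene model.

    Labels cover exon / intron / 5'UTR / 3'UTR plus TSS and TTS windows of
    ``flank`` nt on each side of the start/end site.  Regions may overlap;
    precedence is applied by the peak annotator, not here.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    regions = []
    utr5, utr3 = model._utrs()
    for iv in utr5:
        regions.append((iv, "5'UTR"))
    for iv in utr3:
        regions.append((iv, "3'UTR"))
    for e in model.exons:
        regions.append((e, "exon"))
    for i in model.introns:
        regions.append((i, "intron"))
    for site, label in ((model.tss, "TSS"), (model.tts, "TTS")):
        lo = max(0, site - flank)
        hi = site + flank + 1
        regions.append((GenomicInterval(model.chrom, lo, hi, model.strand), label))
    return regions
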