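"""Peak-to-region annotation with precedence, and distribution summaries.

A peak gets exactly one region label, decided by its midpoint: all regions
of all gene models containing the midpoint are collected and the label
highest in the precedence order wins; a midpoint inside no model is
intergenic.  The default precedence (3'UTR > 5'UTR > exon > TSS > TTS >
intron > intergenic) is configurable.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .annotations import Catalog, derive_regions

DEFAULT_PRECEDENCE = ("3'UTR", "5'UTR", "exon", "TSS", "TTS", "intron", "intergenic")


def _position_labels(catalog: Catalog, chrom: str, pos: int,
                     flank: int) -> set:
    labels = set()
    for gene_id in catalog.all_ids():
        model = catalog.model(gene_id)
        if model.chrom != chrom:
            continue
        if not (model.start - flank <= pos < model.end + flank):
            continue
        for iv, label in derive_regions(model, flank):
            if iv.contains(chrom, pos):
                labels.add(label)
    return labels


def annotate_peak(peak, catalog: Catalog,
                  precedence: tuple = DEFAULT_PRECEDENCE,
                  flank: int = 1000) -> str:
    """Single region label for a peak, by midpoint and precedence."""
    mid = peak.interval.midpoint
    labels = _position_labels(catalog, peak.interval.chrom, mid, flank)
    for label in precedence:
        if label in labels:
            return label
    return "intergenic"


def annotate_peaks(peaks: list, catalog: Catalog,
                   precedence: tuple = DEFAULT_PRECEDENCE,
                   flank: int = 1000,
                   subtypes: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "gene_id": p.gene_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "strand": p.interval.strand,
                "condition": getattr(p, "condition", ""),
                "subtype": (subtypes or {}).get(p.gene_id, ""),
                "region": annotate_peak(p, catalog, precedence, flank),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "condition", "subtype", "region"])


def region_distribution(annotated: pd.DataFrame,
                        by: Optional[list] = None) -> pd.DataFrame:
    """Per-group region proportions (summing to 1 within each group).

    ``by`` may name grouping columns (e.g. ["condition"] or
    ["condition", "subtype"]); empty groups are omitted with a warning.
    """
    import warnings

    if annotated.empty:
        warnings.warn("no annotated peaks; empty distribution", stacklevel=2)
        return pd.DataFrame(columns=list(by or []) + ["region", "proportion"])
    if by:
        out = []
        for keys, sub in annotated.groupby(by):
            if sub.empty:
                continue
            props = sub["region"].value_counts(normalize=True)
            keys = keys if isinstance(keys, tuple) else (keys,)
            for region, prop in props.items():
                out.append(dict(zip(by, keys)) | {"region": region,
                                                  "proportion": float(prop)})
        return pd.DataFrame(out)
    props = annotated["region"].value_counts(normalize=True)
    return pd.DataFrame(
        {"region": props.index, "proportion": props.to_numpy()}
    )


def chromosome_distribution(peaks: list) -> pd.DataFrame:
    """Peak counts per chromosome (sums to the number of peaks)."""
    counts = {}
    for p in peaks:
        counts[p.interval.chrom] = counts.get(p.interval.chrom, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["chrom", "n_peaks"]
    )


def metagene_profile(peaks: list, catalog: Catalog,
                     bins_per_region: int = 30) -> pd.DataFrame:
    """Positional density of peak midpoints over a 5'UTR / exon-body / 3'UTR
    metagene, each segment scaled to ``bins_per_region`` bins.

    Midpoints are projected into transcript coordinates of the peak's gene.
    Transcripts lacking annotated UTRs contribute only to the middle (exon
    body) segment.  The density sums to 1 over all bins; an empty peak set
    yields an all-zero profile.
    """
    n_bins = 3 * bins_per_region
    hist = np.zeros(n_bins)
    for p in peaks:
        try:
            model = catalog.model(p.gene_id)
        except KeyError:
            continue
        mid = p.interval.midpoint
        tpos = model.genomic_to_transcript(mid)
        if tpos is None:
            # midpoint fell in an intron of a merged span; use span centre
            tpos = min(
                model.exonic_length - 1,
                max(0, (p.tx_start + p.tx_end) // 2
                    if getattr(p, "tx_end", 0) else 0),
            )
        L = model.exonic_length
        u5 = sum(len(iv) for iv in model.utr5)
        u3 = sum(len(iv) for iv in model.utr3)
        body = L - u5 - u3
        if u5 and tpos < u5:
            seg, frac = 0, tpos / u5
        elif u3 and tpos >= L - u3:
            seg, frac = 2, (tpos - (L - u3)) / u3
        else:
            seg, frac = 1, (tpos - u5) / max(body, 1)
        b = seg * bins_per_region + min(
            bins_per_region - 1, int(frac * bins_per_region)
        )
        hist[b] += 1
    total = hist.sum()
    density = hist / total if total > 0 else hist
    segments = (["5'UTR"] * bins_per_region + ["exon"] * bins_per_region
                + ["3'UTR"] * bins_per_region)
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "segment": segments, "density": density,
         "empty": total == 0}
    )
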