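"""Overlap of catalog trait-associated SNPs with differential loci.

Catalog associations are first filtered to nominal p-values strictly
below 1e-5; each surviving SNP (a 1 bp point) is then tested for
containment in induced and suppressed broad domains, yielding one hit
per (SNP, trait, locus) triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .differential import STATUS_INDUCED, STATUS_SUPPRESSED, BroadDomain
from .genomic_io import GenomicInterval, VariantRecord

__all__ = [
    "CATALOG_P_THRESHOLD",
    "OverlapHit",
    "filter_catalog",
    "overlap_variants",
    "overlap_table",
]

CATALOG_P_THRESHOLD = 1e-5


@dataclass(frozen=True)
class OverlapHit:
    snp_id: str
    trait: str
    locus: GenomicInterval
    locus_status: str
    catalog_p: float
    source_ref: str = ""


def filter_catalog(
    variants: Sequence[VariantRecord],
    p_threshold: float = CATALOG_P_THRESHOLD,
) -> list[VariantRecord]:
    """Keep associations with p strictly below the threshold.

    Duplicate (snp_id, trait) pairs collapse to the smallest p-value.
    The inequality is strict: p exactly at the threshold is removed.
    """
    best: dict[tuple[str, str], VariantRecord] = {}
    order: list[tuple[str, str]] = []
    for v in variants:
        if not v.p_value < p_threshold:
            continue
        key = (v.snp_id, v.trait)
        if key not in best:
            best[key] = v
            order.append(key)
        elif v.p_value < best[key].p_value:
            best[key] = v
    return [best[k] for k in order]


def overlap_variants(
    variants: Sequence[VariantRecord],
    domains: Sequence[BroadDomain],
) -> list[OverlapHit]:
    """Point-in-interval test of each variant against differential domains.

    Only induced and suppressed domains are scanned; the hit records the
    domain's status so the two sets stay distinguishable. Output is
    sorted by (chromosome, position, trait, locus).
    """
    differential = [
        d for d in domains if d.status in (STATUS_INDUCED, STATUS_SUPPRESSED)
    ]
    by_chrom: dict[str, list[BroadDomain]] = {}
    for d in differential:
        by_chrom.setdefault(d.interval.chrom, []).append(d)
    for doms in by_chrom.values():
        doms.sort(key=lambda d: d.interval.start)
    hits: list[OverlapHit] = []
    for v in variants:
        for d in by_chrom.get(v.chrom, ()):
            if d.interval.start <= v.position < d.interval.end:
                hits.append(
                    OverlapHit(
                        snp_id=v.snp_id,
                        trait=v.trait,
                        locus=d.interval,
                        locus_status=d.status,
                        catalog_p=v.p_value,
                        source_ref=v.source_ref,
                    )
                )
    hits.sort(
        key=lambda h: (h.locus.chrom, h.locus.start, h.snp_id, h.trait)
    )
    return hits


def overlap_table(hits: Sequence[OverlapHit]) -> pd.DataFrame:
    """Report table: trait, SNP, region, locus status, catalog p, reference."""
    rows = [
        (
            h.trait,
            h.snp_id,
            f"{h.locus.chrom}:{h.locus.start}-{h.locus.end}",
            h.locus_status,
            h.catalog_p,
            h.source_ref,
        )
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["trait", "snp_id", "region", "locus_status", "catalog_p", "source_ref"],
    )
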