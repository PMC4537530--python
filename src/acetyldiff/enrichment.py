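"""GREAT-style regulatory domains, locus->gene association, term enrichment.

Each gene gets a basal regulatory domain covering 5 kb on its 5' side
and 1 kb on its 3' side of the TSS; the domain is then extended in both
directions up to the nearest other gene's basal-domain boundary, capped
at 100 kb from the TSS and clipped at chromosome ends. A differential
locus is associated with every gene whose (extended) regulatory domain
it overlaps by >= 1 bp. Term over-representation in the associated gene
set is tested with the upper-tail hypergeometric distribution against
the universe of all annotated genes, with Benjamini-Hochberg FDR applied
separately within each ontology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import GeneRecord, GenomicInterval, TermAnnotation

__all__ = [
    "RegulatoryDomain",
    "EnrichmentResult",
    "AssociationResult",
    "build_domains",
    "associate_loci",
    "hypergeom_enrich",
    "report_enrichment",
    "BASAL_UPSTREAM",
    "BASAL_DOWNSTREAM",
    "MAX_EXTENSION",
]

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 100_000


@dataclass(frozen=True)
class RegulatoryDomain:
    """Per-gene basal + extended regulatory span (half-open)."""

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


def _basal_span(gene: GeneRecord, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        lo, hi = gene.tss - BASAL_UPSTREAM, gene.tss + BASAL_DOWNSTREAM
    else:
        lo, hi = gene.tss - BASAL_DOWNSTREAM, gene.tss + BASAL_UPSTREAM
    return max(0, lo), min(chrom_len, hi)


def build_domains(
    genes: Sequence[GeneRecord],
    chrom_sizes: Mapping[str, int],
) -> list[RegulatoryDomain]:
    """Construct regulatory domains for all genes.

    Per direction the extension runs from the basal edge outward to the
    nearest of (a) another gene's basal-domain boundary, (b) the point
    100 kb from the TSS, (c) the chromosome end. A neighbouring basal
    domain that already overlaps the gene's own basal start/end blocks
    extension entirely on that side (the extension beyond the basal
    never overlaps another basal domain).
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        if g.tss >= chrom_sizes[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside chromosome "
                f"{g.chrom} (length {chrom_sizes[g.chrom]})"
            )
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        L = int(chrom_sizes[chrom])
        basal = [_basal_span(g, L) for g in chrom_genes]
        for i, g in enumerate(chrom_genes):
            b_lo, b_hi = basal[i]
            cap_lo = max(0, g.tss - MAX_EXTENSION)
            cap_hi = min(L, g.tss + MAX_EXTENSION)
            left = cap_lo
            right = cap_hi
            for j, (o_lo, o_hi) in enumerate(basal):
                if j == i:
                    continue
                if o_lo <= b_lo:
                    left = max(left, min(o_hi, b_lo))
                if o_hi >= b_hi:
                    right = min(right, max(o_lo, b_hi))
            left = min(left, b_lo)
            right = max(right, b_hi)
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    basal=GenomicInterval(chrom, b_lo, b_hi),
                    extended=GenomicInterval(chrom, left, right),
                )
            )
    domains.sort(key=lambda d: (d.extended.chrom, d.extended.start, d.gene_id))
    return domains


@dataclass
class AssociationResult:
    """Locus <-> gene associations by regulatory-domain overlap.

    ``locus_genes`` is aligned with the input locus list (empty list for
    a locus overlapping no domain); ``gene_loci`` maps gene_id to locus
    indices; ``overlap_bp`` maps (locus index, gene_id) to overlap width.
    """

    loci: list[GenomicInterval]
    locus_genes: list[list[str]]
    gene_loci: dict[str, list[int]]
    overlap_bp: dict[tuple[int, str], int]

    @property
    def selected_genes(self) -> set[str]:
        return {g for g, loci in self.gene_loci.items() if loci}


def associate_loci(
    loci: Sequence[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
) -> AssociationResult:
    """Associate each locus with all genes whose extended domain it overlaps."""
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.extended.chrom, IntervalTree()).addi(
            d.extended.start, d.extended.end, d
        )
    locus_genes: list[list[str]] = []
    gene_loci: dict[str, list[int]] = {}
    overlap_bp: dict[tuple[int, str], int] = {}
    for idx, locus in enumerate(loci):
        hits = trees.get(locus.chrom, IntervalTree()).overlap(locus.start, locus.end)
        gene_ids = sorted(h.data.gene_id for h in hits)
        locus_genes.append(gene_ids)
        for h in hits:
            d: RegulatoryDomain = h.data
            gene_loci.setdefault(d.gene_id, []).append(idx)
            overlap_bp[(idx, d.gene_id)] = min(locus.end, d.extended.end) - max(
                locus.start, d.extended.start
            )
    return AssociationResult(list(loci), locus_genes, gene_loci, overlap_bp)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    ontology: str
    K: int  # annotated genes in universe
    N: int  # universe size
    n: int  # selected genes
    k: int  # annotated among selected
    p_value: float
    fold_enrichment: float
    fdr: float


def hypergeom_enrich(
    selected_genes: Iterable[str],
    term_table: Sequence[TermAnnotation],
    universe: Iterable[str],
    alpha_fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment with BH FDR per ontology.

    For a term annotating K of the N universe genes, with n selected
    genes of which k are annotated: p = P(X >= k), X ~ Hypergeom(N, K, n).
    Results are sorted by (fdr, p, term_id); ``alpha_fdr`` is not applied
    here (callers flag significance), it is kept for signature clarity.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    selected = set(selected_genes) & universe_set
    if not selected:
        raise ValueError("empty selected gene set (after restricting to universe)")
    N, n = len(universe_set), len(selected)
    terms: dict[tuple[str, str], dict] = {}
    for t in term_table:
        if t.gene_id not in universe_set:
            continue
        key = (t.ontology, t.term_id)
        entry = terms.setdefault(
            key, {"name": t.term_name, "genes": set()}
        )
        entry["genes"].add(t.gene_id)
    results: list[EnrichmentResult] = []
    by_ontology: dict[str, list[int]] = {}
    for (ontology, term_id), entry in sorted(terms.items()):
        K = len(entry["genes"])
        k = len(entry["genes"] & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        fold = (k / n) / (K / N) if K > 0 else float("nan")
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=entry["name"],
                ontology=ontology,
                K=K,
                N=N,
                n=n,
                k=k,
                p_value=p,
                fold_enrichment=fold,
                fdr=float("nan"),
            )
        )
        by_ontology.setdefault(ontology, []).append(len(results) - 1)
    # BH within each ontology (panels are tested separately)
    for ontology, idxs in by_ontology.items():
        pvals = np.array([results[i].p_value for i in idxs])
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for i, f in zip(idxs, fdrs):
            r = results[i]
            results[i] = EnrichmentResult(
                r.term_id, r.term_name, r.ontology, r.K, r.N, r.n, r.k,
                r.p_value, r.fold_enrichment, float(f),
            )
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return results


def report_enrichment(
    results: Sequence[EnrichmentResult],
    alpha_fdr: float = 0.05,
    plot_path=None,
) -> pd.DataFrame:
    """Ranked enrichment table (one row per term) with a significance flag.

    Ordering key is (fdr, p_value, term_id). With ``plot_path`` a bubble
    plot is exported (circle size ~ k, transparency ~ fold enrichment,
    one panel per ontology, cutoff line at alpha_fdr).
    """
    ordered = sorted(results, key=lambda r: (r.fdr, r.p_value, r.term_id))
    df = pd.DataFrame(
        [
            (
                r.ontology, r.term_id, r.term_name, r.N, r.K, r.n, r.k,
                r.p_value, r.fold_enrichment, r.fdr, r.fdr <= alpha_fdr,
            )
            for r in ordered
        ],
        columns=[
            "ontology", "term_id", "term_name", "universe_N", "annotated_K",
            "selected_n", "overlap_k", "p_value", "fold_enrichment", "fdr",
            "significant",
        ],
    )
    if plot_path is not None and len(df):
        _bubble_plot(df, alpha_fdr, plot_path)
    return df


def _bubble_plot(df: pd.DataFrame, alpha_fdr: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ontologies = sorted(df["ontology"].unique())
    fig, axes = plt.subplots(
        1, len(ontologies), figsize=(5 * len(ontologies), 4), squeeze=False
    )
    for ax, onto in zip(axes[0], ontologies):
        sub = df[df["ontology"] == onto].head(15)[::-1]
        y = np.arange(len(sub))
        x = -np.log10(np.maximum(sub["fdr"].to_numpy(float), 1e-300))
        fold = sub["fold_enrichment"].to_numpy(float)
        fmax = np.nanmax(fold) if len(fold) else 1.0
        alpha = np.clip(fold / max(fmax, 1e-9), 0.15, 1.0)
        sizes = 30 + 20 * sub["overlap_k"].to_numpy(float)
        for yi, xi, ai, si in zip(y, x, alpha, sizes):
            ax.scatter(xi, yi, s=si, alpha=float(ai), color="navy")
        ax.axvline(-np.log10(alpha_fdr), color="red", lw=1)
        ax.set_yticks(y)
        ax.set_yticklabels(sub["term_name"], fontsize=7)
        ax.set_xlabel("-log10 FDR")
        ax.set_title(onto)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
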