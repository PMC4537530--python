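"""In-memory end-to-end execution of the analysis on a synthetic cohort,
with scoring helpers against the planted ground truth.

This is the programmatic counterpart of the file-based pipeline: it
generates reads, deduplicates, calls peaks, merges and classifies
domains, computes aggregate profiles, runs enrichment and GWAS overlap,
and exposes recovery metrics used by the validation suite and the
analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .differential import (
    STATUS_INDUCED,
    STATUS_SUPPRESSED,
    STATUS_SHARED,
    BroadDomain,
    DifferentialRule,
    classify_domains,
    merge_domains,
)
from .enrichment import (
    EnrichmentResult,
    associate_loci,
    build_domains,
    hypergeom_enrich,
)
from .genomic_io import GenomicInterval
from .gwas import OverlapHit, filter_catalog, overlap_variants
from .peaks import CallerConfig, Peak, ReadSet, call_peaks, deduplicate
from .profiles import AggregateProfile, ProfileConfig, compute_profile, group_profile
from .synthetic import SyntheticCohort, SyntheticDesign

__all__ = ["StudyResult", "run_synthetic_study", "central_gap"]

CENTRAL_BINS = slice(180, 221)  # +/- 20 bins around the center of 400


@dataclass
class StudyResult:
    """All stage outputs of one synthetic end-to-end run."""

    design: SyntheticDesign
    cohort: SyntheticCohort
    reads: dict[str, dict[str, ReadSet]]
    peaks: dict[str, list[Peak]]
    domains: list[BroadDomain]
    tss_profiles: dict[str, AggregateProfile]  # per group
    enhancer_profiles: dict[str, AggregateProfile]
    enrichment: list[EnrichmentResult]
    gwas_hits: list[OverlapHit]

    # ---- scoring against planted truth ----

    def planted_recovery(self) -> dict[str, float]:
        """Per-subject fraction of active planted peaks overlapping a called peak."""
        out = {}
        for subj in self.cohort.subjects:
            group = self.cohort.subject_groups[subj]
            active = self.cohort._active_peaks(group)
            called = self.peaks[subj]
            hit = sum(
                any(p.interval.overlaps(t) for p in called) for t in active
            )
            out[subj] = hit / len(active) if active else float("nan")
        return out

    def _domains_with_status(self, status: str) -> list[GenomicInterval]:
        return [d.interval for d in self.domains if d.status == status]

    def class_recovery(self) -> dict[str, float]:
        """Fractions of planted peaks recovered with the right status.

        induced/suppressed: planted peak overlaps >= 1 domain of the
        matching status; shared_misclassified: planted shared peak
        overlaps an induced or suppressed domain.
        """
        truth = self.cohort.truth
        out = {}
        for cls, status in (("induced", STATUS_INDUCED), ("suppressed", STATUS_SUPPRESSED)):
            planted = truth.peaks_of_class(cls)
            doms = self._domains_with_status(status)
            if planted:
                out[cls] = sum(
                    any(dm.overlaps(t) for dm in doms) for t in planted
                ) / len(planted)
            else:
                out[cls] = float("nan")
        shared = truth.peaks_of_class("shared")
        diff = self._domains_with_status(STATUS_INDUCED) + self._domains_with_status(
            STATUS_SUPPRESSED
        )
        out["shared_misclassified"] = (
            sum(any(dm.overlaps(t) for dm in diff) for t in shared) / len(shared)
            if shared
            else float("nan")
        )
        return out

    def n_status(self, status: str) -> int:
        return sum(1 for d in self.domains if d.status == status)

    def pathway_rank_of_planted(self) -> Optional[int]:
        """1-based FDR rank of the planted term among pathway terms."""
        onto, term_id = self.cohort.truth.planted_term
        ranked = [r for r in self.enrichment if r.ontology == onto]
        for i, r in enumerate(ranked, start=1):
            if r.term_id == term_id:
                return i
        return None


def central_gap(profiles: dict[str, AggregateProfile]) -> float:
    """Mean high-minus-low log-ratio over the central +/- 20 bins."""
    return float(
        np.mean(profiles["high"].values[CENTRAL_BINS] - profiles["low"].values[CENTRAL_BINS])
    )


def run_synthetic_study(
    design: SyntheticDesign,
    caller: CallerConfig = CallerConfig(),
    profile_cfg: ProfileConfig = ProfileConfig(),
    rule: DifferentialRule = DifferentialRule(),
    alpha_fdr: float = 0.05,
) -> StudyResult:
    """Generate a cohort and run every analysis stage in memory."""
    cohort = SyntheticCohort(design)
    chrom_sizes = design.chrom_sizes
    reads = {
        s: {r: deduplicate(cohort.generate_reads(s, r)) for r in ("chip", "input")}
        for s in cohort.subjects
    }
    peaks = {
        s: call_peaks(reads[s]["chip"], reads[s]["input"], caller, chrom_sizes)
        for s in cohort.subjects
    }
    domains = classify_domains(merge_domains(peaks), cohort.subject_groups, rule)

    def group_profiles(anchors):
        per_subject = [
            compute_profile(
                reads[s]["chip"], reads[s]["input"], anchors, profile_cfg,
                chrom_sizes, label=s,
            )
            for s in cohort.subjects
        ]
        return group_profile(per_subject, cohort.subject_groups)

    tss_profiles = group_profiles(cohort.truth.genes)
    enhancer_profiles = (
        group_profiles(cohort.truth.enhancers) if cohort.truth.enhancers else {}
    )

    loci = [
        d.interval for d in domains if d.status in (STATUS_INDUCED, STATUS_SUPPRESSED)
    ]
    enrichment: list[EnrichmentResult] = []
    if loci:
        reg = build_domains(cohort.truth.genes, chrom_sizes)
        selected = associate_loci(loci, reg).selected_genes
        if selected:
            enrichment = hypergeom_enrich(
                selected, cohort.truth.terms,
                [g.gene_id for g in cohort.truth.genes], alpha_fdr,
            )
    hits = overlap_variants(filter_catalog(cohort.truth.variants), domains)
    return StudyResult(
        design=design,
        cohort=cohort,
        reads=reads,
        peaks=peaks,
        domains=domains,
        tss_profiles=tss_profiles,
        enhancer_profiles=enhancer_profiles,
        enrichment=enrichment,
        gwas_hits=hits,
    )
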