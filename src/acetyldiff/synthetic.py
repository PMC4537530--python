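"""Synthetic ChIP-seq cohort generator with planted ground truth.

The generator emulates a two-group exposure design (``high`` vs ``low``,
two subjects each by default): a small multi-chromosome genome carries
planted H3K27ac peaks of three classes — ``shared`` (active in every
subject), ``induced`` (active only in high-exposure subjects) and
``suppressed`` (active only in low-exposure subjects) — plus gene and
enhancer annotations, a two-ontology gene->term table with one pathway
term deliberately enriched among induced-peak-proximal genes, and a
GWAS-catalog-style variant table containing known-overlapping SNPs and
planted negative controls.

Reads are emitted directly as aligned 101 bp single-end intervals drawn
from an inhomogeneous Poisson process: the input sample is uniform at
``background_rate`` reads/bp; the ChIP sample multiplies the background
by ``peak_fold`` inside peaks active for the subject's group and by the
group's global fold (``global_tss_fold_high``/``_low``) within +/- 1 kb
of every TSS and every enhancer center, so the high group shows a mild
genome-wide promoter/enhancer elevation on top of its extra peaks.
Duplicate read positions are allowed so deduplication has work to do.

All randomness flows from ``design.seed`` through per-(subject, role)
``numpy`` seed sequences; identical (design, seed) gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    GeneRecord,
    GenomicInterval,
    TermAnnotation,
    VariantRecord,
    write_bed,
    write_gene_table,
    write_term_table,
    write_variant_table,
)
from .peaks import ReadSet

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "Annotations",
    "SyntheticCohort",
    "GenomeTooSmallError",
    "generate_reads",
    "generate_annotations",
    "write_cohort",
]

# Layout geometry (bp). Differential slots are wide enough that each
# planted differential peak and its proximal gene sit > 100 kb (the
# regulatory-domain cap) from the neighbouring slot's features; shared
# slots are denser since shared peaks never drive gene selection.
DIFF_SLOT = 185_000
SHARED_SLOT = 65_000
EDGE_RESERVE = 150_000  # start of chrom 1 reserved for the chromosome-edge gene
CHROM_MARGIN = 10_000
SPECIAL_TAIL = 550_000  # isolated gene + close pair + end margin
PEAK_BOOST_HALF = 1_000  # half-width of TSS / enhancer global-fold zones


class GenomeTooSmallError(ValueError):
    """Genome cannot host the requested peaks/genes; message states the minimum."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Study-design parameters for the synthetic cohort.

    Defaults are the package's standard desk-scale conditions: 2 exposure
    groups x 2 subjects, 101 bp single-end reads, background 0.01
    reads/bp, 8-fold ChIP enrichment inside peaks, global promoter/
    enhancer folds 2.0 (high) vs 1.5 (low), and 60/20/5 planted
    shared/induced/suppressed peaks of 1 kb, mirroring the asymmetry in
    which exposure mostly gains rather than loses acetylation.
    """

    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
    )
    n_subjects_per_group: int = 2
    read_length: int = 101
    background_rate: float = 0.01
    peak_fold: float = 8.0
    global_tss_fold_high: float = 2.0
    global_tss_fold_low: float = 1.5
    n_shared_peaks: int = 60
    n_induced_peaks: int = 20
    n_suppressed_peaks: int = 5
    peak_width: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        for name in ("peak_fold", "global_tss_fold_high", "global_tss_fold_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.peak_width <= 0 or self.read_length <= 0:
            raise ValueError("peak_width and read_length must be positive")
        for name in ("n_shared_peaks", "n_induced_peaks", "n_suppressed_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.genome:
            raise ValueError("genome must contain at least one chromosome")
        object.__setattr__(self, "genome", tuple((c, int(l)) for c, l in self.genome))

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)

    @property
    def subjects(self) -> list[str]:
        return [f"high_{i+1}" for i in range(self.n_subjects_per_group)] + [
            f"low_{i+1}" for i in range(self.n_subjects_per_group)
        ]

    @property
    def subject_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.subjects}


@dataclass
class GroundTruth:
    """Planted features, recoverable by coordinates."""

    peaks: list[tuple[GenomicInterval, str]]  # (span, class) class in shared/induced/suppressed
    genes: list[GeneRecord]
    enhancers: list[GenomicInterval]
    terms: list[TermAnnotation]
    variants: list[VariantRecord]
    planted_term: tuple[str, str]  # (ontology, term_id)
    induced_proximal_genes: list[str]
    suppressed_proximal_genes: list[str]
    expected_hit_snps: dict[str, str]  # snp_id -> expected locus status
    negative_snps: list[str]

    def peaks_of_class(self, label: str) -> list[GenomicInterval]:
        return [iv for iv, c in self.peaks if c == label]


@dataclass
class Annotations:
    genes: list[GeneRecord]
    enhancers: list[GenomicInterval]
    terms: list[TermAnnotation]
    variants: list[VariantRecord]
    truth: GroundTruth


def _required_length(design: SyntheticDesign) -> int:
    n_diff = design.n_induced_peaks + design.n_suppressed_peaks
    return (
        EDGE_RESERVE
        + n_diff * DIFF_SLOT
        + design.n_shared_peaks * SHARED_SLOT
        + SPECIAL_TAIL
    )


def generate_annotations(design: SyntheticDesign) -> Annotations:
    """Place peaks, genes, enhancers, terms and variants deterministically.

    Gene spacing exercises every regulatory-domain branch by
    construction: each differential peak gets one proximal gene ~3 kb
    away (alternating strands), background genes interleave with shared
    peaks, a chromosome-edge gene sits at TSS 2 kb, one close pair has
    basal domains 30 kb apart and one isolated gene is > 200 kb from any
    neighbour.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0,)))
    chroms = list(design.genome)
    n_diff = design.n_induced_peaks + design.n_suppressed_peaks

    # --- slot placement across chromosomes ---
    slots_diff: list[tuple[str, int]] = []
    slots_shared: list[tuple[str, int]] = []
    ci = 0
    cursor = EDGE_RESERVE if chroms else 0
    def advance(slot: int) -> Optional[tuple[str, int]]:
        nonlocal ci, cursor
        while ci < len(chroms):
            chrom, L = chroms[ci]
            if cursor + slot <= L - CHROM_MARGIN:
                pos = cursor
                cursor += slot
                return chrom, pos
            ci += 1
            cursor = CHROM_MARGIN
        return None

    for _ in range(n_diff):
        s = advance(DIFF_SLOT)
        if s is None:
            raise GenomeTooSmallError(
                f"genome too small for requested features: need total length "
                f">= {_required_length(design)} bp"
            )
        slots_diff.append(s)
    for _ in range(design.n_shared_peaks):
        s = advance(SHARED_SLOT)
        if s is None:
            raise GenomeTooSmallError(
                f"genome too small for requested features: need total length "
                f">= {_required_length(design)} bp"
            )
        slots_shared.append(s)

    # --- differential peaks + proximal genes ---
    classes = ["induced"] * design.n_induced_peaks + [
        "suppressed"
    ] * design.n_suppressed_peaks
    classes = [classes[i] for i in rng.permutation(n_diff)] if n_diff else []
    peaks: list[tuple[GenomicInterval, str]] = []
    genes: list[GeneRecord] = []
    induced_proximal: list[str] = []
    suppressed_proximal: list[str] = []
    for i, ((chrom, slot0), cls) in enumerate(zip(slots_diff, classes)):
        start = slot0 + 90_000 + int(rng.integers(0, 20_000))
        peak = GenomicInterval(chrom, start, start + design.peak_width)
        peaks.append((peak, cls))
        strand = "+" if i % 2 == 0 else "-"
        gid = f"G_{cls.upper()[:3]}_{i:03d}"
        genes.append(GeneRecord(gid, chrom, strand, peak.end + 3_000))
        (induced_proximal if cls == "induced" else suppressed_proximal).append(gid)

    # --- shared peaks, enhancers, background genes ---
    enhancers: list[GenomicInterval] = []
    for j, (chrom, slot0) in enumerate(slots_shared):
        start = slot0 + 30_000 + int(rng.integers(0, 4_000))
        peak = GenomicInterval(chrom, start, start + design.peak_width)
        peaks.append((peak, "shared"))
        if j % 2 == 0:
            c = (peak.start + peak.end) // 2
            enhancers.append(GenomicInterval(chrom, c - 100, c + 100))
        if j % 2 == 1:
            genes.append(
                GeneRecord(
                    f"G_BG_{j:03d}", chrom, "+" if j % 4 == 1 else "-", slot0 + 52_000
                )
            )

    # --- special-layout genes (edge, isolated, close pair) ---
    edge_chrom, edge_len = chroms[0]
    if edge_len >= EDGE_RESERVE:
        genes.append(GeneRecord("G_EDGE", edge_chrom, "+", 2_000))
    placed_tail = False
    while ci < len(chroms):
        chrom, L = chroms[ci]
        if cursor + SPECIAL_TAIL <= L:
            genes.append(GeneRecord("G_ISOLATED", chrom, "+", cursor + 205_000))
            genes.append(GeneRecord("G_PAIR_A", chrom, "+", cursor + 410_000))
            genes.append(GeneRecord("G_PAIR_B", chrom, "-", cursor + 440_000))
            placed_tail = True
            break
        ci += 1
        cursor = CHROM_MARGIN
    if not placed_tail:
        raise GenomeTooSmallError(
            f"genome too small for requested features: need total length "
            f">= {_required_length(design)} bp"
        )

    # --- term table ---
    terms: list[TermAnnotation] = []
    planted = ("pathway", "PW:9001")
    all_gene_ids = [g.gene_id for g in genes]
    bg_ids = [g for g in all_gene_ids if g.startswith(("G_BG", "G_PAIR", "G_ISO", "G_EDGE"))]
    if induced_proximal:
        n_pl = max(1, math.ceil(0.85 * len(induced_proximal)))
        planted_genes = [
            str(g) for g in rng.choice(induced_proximal, size=n_pl, replace=False)
        ]
        planted_genes += [
            str(g) for g in rng.choice(bg_ids, size=min(2, len(bg_ids)), replace=False)
        ]
        for gid in planted_genes:
            terms.append(
                TermAnnotation(
                    gid, "pathway", planted[1], "inflammatory response pathway"
                )
            )
    decoy_names = [
        "lipid transport pathway", "axon guidance pathway",
        "glycolysis pathway", "DNA repair pathway",
        "cell adhesion pathway", "ion channel pathway",
        "circadian clock pathway",
    ]
    for t, name in enumerate(decoy_names):
        size = min(5, len(all_gene_ids))
        for gid in rng.choice(all_gene_ids, size=size, replace=False):
            terms.append(TermAnnotation(str(gid), "pathway", f"PW:{9100+t}", name))
    bp_names = [
        "response to stimulus", "cell activation", "chromatin organization",
        "vesicle transport", "protein folding", "RNA splicing",
        "apoptotic process", "cell cycle", "metabolic process",
        "signal transduction", "development", "transport",
    ]
    for t, name in enumerate(bp_names):
        size = min(6, len(all_gene_ids))
        for gid in rng.choice(all_gene_ids, size=size, replace=False):
            terms.append(
                TermAnnotation(str(gid), "biological_process", f"BP:{100+t}", name)
            )
    case_ids = induced_proximal + suppressed_proximal
    if case_ids:
        for gid in rng.choice(
            case_ids, size=min(10, len(case_ids)), replace=False
        ):
            terms.append(
                TermAnnotation(str(gid), "biological_process", "BP:900", "leukocyte activation")
            )
    # drop duplicate (gene, ontology, term) triples from random draws
    seen = set()
    uniq_terms = []
    for t in terms:
        key = (t.gene_id, t.ontology, t.term_id)
        if key not in seen:
            seen.add(key)
            uniq_terms.append(t)
    terms = uniq_terms

    # --- variant table ---
    variants: list[VariantRecord] = []
    expected_hits: dict[str, str] = {}
    negatives: list[str] = []
    induced_pk = [iv for iv, c in peaks if c == "induced"]
    suppressed_pk = [iv for iv, c in peaks if c == "suppressed"]
    shared_pk = [iv for iv, c in peaks if c == "shared"]
    hit_traits = [
        ("Inflammatory bowel disease", 1e-6),
        ("Alzheimer's disease", 5e-7),
        ("Red blood cell traits", 1e-8),
        ("Fibrinogen", 1e-12),
    ]
    for i, pk in enumerate(induced_pk[:4]):
        trait, p = hit_traits[i]
        sid = f"rs_ind_{i}"
        variants.append(
            VariantRecord(sid, pk.chrom, (pk.start + pk.end) // 2, trait, p, f"2000{i}")
        )
        expected_hits[sid] = "induced"
    if induced_pk:
        variants.append(
            VariantRecord(
                "rs_weak", induced_pk[0].chrom, (induced_pk[0].start + induced_pk[0].end) // 2 + 10,
                "Weak association trait", 1e-3, "20010",
            )
        )
        negatives.append("rs_weak")
        variants.append(
            VariantRecord(
                "rs_boundary", induced_pk[0].chrom,
                (induced_pk[0].start + induced_pk[0].end) // 2 + 20,
                "Boundary trait", 1.0e-5, "20011",
            )
        )
        negatives.append("rs_boundary")
    if suppressed_pk:
        sid = "rs_sup_0"
        pk = suppressed_pk[0]
        variants.append(
            VariantRecord(sid, pk.chrom, (pk.start + pk.end) // 2, "Metabolic traits", 1e-7, "20020")
        )
        expected_hits[sid] = "suppressed"
    if shared_pk:
        pk = shared_pk[0]
        variants.append(
            VariantRecord(
                "rs_shared", pk.chrom, (pk.start + pk.end) // 2,
                "Ubiquitous trait", 1e-9, "20030",
            )
        )
        negatives.append("rs_shared")
    # intergenic, catalog-significant but outside every planted peak
    variants.append(
        VariantRecord("rs_far_1", edge_chrom, 60_000, "Height", 1e-8, "20040")
    )
    variants.append(
        VariantRecord("rs_far_2", edge_chrom, 120_000, "BMI", 1e-7, "20041")
    )
    negatives += ["rs_far_1", "rs_far_2"]
    variants.append(
        VariantRecord("rs_null", edge_chrom, 80_000, "Null trait", 0.5, "20042")
    )
    negatives.append("rs_null")

    truth = GroundTruth(
        peaks=peaks,
        genes=genes,
        enhancers=enhancers,
        terms=terms,
        variants=variants,
        planted_term=planted,
        induced_proximal_genes=induced_proximal,
        suppressed_proximal_genes=suppressed_proximal,
        expected_hit_snps=expected_hits,
        negative_snps=negatives,
    )
    return Annotations(genes, enhancers, terms, variants, truth)


class SyntheticCohort:
    """A fully specified synthetic study: design + placed annotations.

    Provides per-(subject, role) read generation and exposes the exact
    piecewise-constant rate functions for rate-level testing.
    """

    def __init__(self, design: SyntheticDesign):
        self.design = design
        self.annotations = generate_annotations(design)
        self.truth = self.annotations.truth
        self.subjects = design.subjects
        self.subject_groups = design.subject_groups

    def _active_peaks(self, group: str) -> list[GenomicInterval]:
        keep = {"shared", "induced" if group == "high" else "suppressed"}
        return [iv for iv, c in self.truth.peaks if c in keep]

    def rate_segments(self, subject: str, role: str) -> dict[str, list[tuple[int, int, float]]]:
        """Piecewise-constant read-start rate (reads/bp) per chromosome."""
        if subject not in self.subject_groups:
            raise ValueError(f"unknown subject {subject!r}")
        if role not in ("chip", "input"):
            raise ValueError(f"unknown sample role {role!r}")
        design = self.design
        out: dict[str, list[tuple[int, int, float]]] = {}
        group = self.subject_groups[subject]
        fold = (
            design.global_tss_fold_high if group == "high" else design.global_tss_fold_low
        )
        for chrom, L in design.genome:
            if role == "input":
                out[chrom] = [(0, L, design.background_rate)]
                continue
            # events: (pos, kind, delta); kind 0 = peak fold, 1 = global fold
            events: list[tuple[int, int, int]] = []
            for iv in self._active_peaks(group):
                if iv.chrom == chrom:
                    events.append((iv.start, 0, 1))
                    events.append((iv.end, 0, -1))
            zone_centers = [g.tss for g in self.truth.genes if g.chrom == chrom]
            zone_centers += [
                (e.start + e.end) // 2
                for e in self.truth.enhancers
                if e.chrom == chrom
            ]
            for c in zone_centers:
                events.append((max(0, c - PEAK_BOOST_HALF), 1, 1))
                events.append((min(L, c + PEAK_BOOST_HALF), 1, -1))
            events.sort()
            segments: list[tuple[int, int, float]] = []
            pos = 0
            n_peak = n_boost = 0
            k = 0
            while k <= len(events):
                nxt = events[k][0] if k < len(events) else L
                if nxt > pos:
                    rate = (
                        design.background_rate
                        * design.peak_fold**n_peak
                        * fold**n_boost
                    )
                    segments.append((pos, min(nxt, L), rate))
                    pos = min(nxt, L)
                if k == len(events):
                    break
                _, kind, delta = events[k]
                if kind == 0:
                    n_peak += delta
                else:
                    n_boost += delta
                k += 1
            # coalesce adjacent segments with identical rates
            merged: list[tuple[int, int, float]] = []
            for s, e, r in segments:
                if e <= s:
                    continue
                if merged and merged[-1][2] == r and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e, r)
                else:
                    merged.append((s, e, r))
            out[chrom] = merged
        return out

    def generate_reads(self, subject: str, role: str) -> ReadSet:
        """Draw one sample's reads from the subject's rate function.

        Read starts follow an inhomogeneous Poisson process; reads have
        fixed length (clipped at the chromosome end) and uniform random
        strand. Output is coordinate-sorted. Deterministic per
        (design.seed, subject, role).
        """
        segments = self.rate_segments(subject, role)
        si = self.subjects.index(subject)
        ri = 0 if role == "chip" else 1
        rng = np.random.default_rng(
            np.random.SeedSequence(self.design.seed, spawn_key=(1 + si, ri))
        )
        frames = []
        for chrom, L in self.design.genome:
            starts_parts = []
            for s, e, rate in segments[chrom]:
                n = rng.poisson(rate * (e - s))
                if n:
                    starts_parts.append(rng.integers(s, e, size=n, dtype=np.int64))
            if starts_parts:
                starts = np.concatenate(starts_parts)
            else:
                starts = np.empty(0, dtype=np.int64)
            strands = rng.integers(0, 2, size=starts.size)
            order = np.argsort(starts, kind="stable")
            starts = starts[order]
            strands = strands[order]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": np.minimum(starts + self.design.read_length, L),
                        "strand": np.where(strands == 0, "+", "-"),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        return ReadSet(
            sample_id=f"{subject}_{role}", subject_id=subject, role=role, df=df
        )


def generate_reads(design: SyntheticDesign, subject: str, sample: str) -> ReadSet:
    """Convenience wrapper: build the cohort and draw one sample."""
    return SyntheticCohort(design).generate_reads(subject, sample)


def write_cohort(design: SyntheticDesign, outdir) -> Path:
    """Write a complete simulated study to ``outdir``.

    Emits per-sample read BEDs, gene/enhancer/term/variant tables, the
    planted-truth peak table, and a ``run.yaml`` runnable by the
    pipeline. Returns the path to ``run.yaml``.
    """
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    cohort = SyntheticCohort(design)
    subjects_cfg = {}
    for subject in cohort.subjects:
        entry = {"group": cohort.subject_groups[subject]}
        for role in ("chip", "input"):
            rs = cohort.generate_reads(subject, role)
            path = outdir / "reads" / f"{subject}_{role}.bed"
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                for i, r in enumerate(rs.df.itertuples(index=False)):
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")
            entry[role] = str(path)
        subjects_cfg[subject] = entry
    write_gene_table(cohort.truth.genes, outdir / "genes.tsv")
    write_bed(cohort.truth.enhancers, outdir / "enhancers.bed", columns=3)
    write_term_table(cohort.truth.terms, outdir / "terms.tsv")
    write_variant_table(cohort.truth.variants, outdir / "variants.tsv")
    truth_df = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, c) for iv, c in cohort.truth.peaks],
        columns=["chrom", "start", "end", "class"],
    )
    truth_df.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False, lineterminator="\n")
    cfg = {
        "genome": {c: l for c, l in design.genome},
        "subjects": subjects_cfg,
        "genes": str(outdir / "genes.tsv"),
        "enhancers": str(outdir / "enhancers.bed"),
        "terms": str(outdir / "terms.tsv"),
        "variants": str(outdir / "variants.tsv"),
        "seed": design.seed,
    }
    with open(outdir / "run.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir / "run.yaml"
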