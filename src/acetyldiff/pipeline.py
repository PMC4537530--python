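"""End-to-end orchestration: dedup -> peaks -> domains -> profiles ->
enrichment -> GWAS overlap, from one configuration.

Every stage writes its outputs under the run's output directory and a
run log records parameters, seed and per-stage counts. The pipeline is
deterministic given identical configuration and inputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .differential import (
    STATUS_INDUCED,
    STATUS_SUPPRESSED,
    BroadDomain,
    DifferentialRule,
    classify_domains,
    differential_summary,
    merge_domains,
)
from .enrichment import (
    associate_loci,
    build_domains,
    hypergeom_enrich,
    report_enrichment,
)
from .genomic_io import (
    BedRecord,
    read_bed,
    read_gene_table,
    read_term_table,
    read_variant_table,
    write_bed,
)
from .gwas import filter_catalog, overlap_table, overlap_variants
from .peaks import CallerConfig, call_peaks, deduplicate, peak_count_summary, read_reads_bed, write_peaks_bed
from .profiles import ProfileConfig, compute_profile, group_profile, profile_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("acetyldiff")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``subjects`` maps subject id -> {"group": ..., "chip": path,
    "input": path}; exactly the two roles chip+input are required per
    subject and every subject must belong to exactly one of the two
    exposure groups.
    """

    genome: Mapping[str, int]
    subjects: Mapping[str, Mapping[str, str]]
    genes: str
    enhancers: str
    terms: str
    variants: str
    outdir: str = "out"
    seed: int = 0
    caller: CallerConfig = field(default_factory=CallerConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    rule: DifferentialRule = field(default_factory=DifferentialRule)
    alpha_fdr: float = 0.05
    gwas_p_threshold: float = 1e-5
    high_group: str = "high"
    low_group: str = "low"

    def validate(self) -> None:
        if not (0 < self.alpha_fdr < 1) or not (0 < self.gwas_p_threshold < 1):
            raise ValueError("alpha_fdr and gwas_p_threshold must lie in (0, 1)")
        groups = set()
        for subj, entry in self.subjects.items():
            if "group" not in entry:
                raise ValueError(f"subject {subj!r} has no group assignment")
            groups.add(entry["group"])
            for role in ("chip", "input"):
                if role not in entry:
                    raise ValueError(
                        f"subject {subj!r} is missing its {role!r} sample"
                    )
        if groups != {self.high_group, self.low_group}:
            raise ValueError(
                f"subject groups {sorted(groups)} must be exactly "
                f"{{{self.high_group!r}, {self.low_group!r}}}"
            )

    @property
    def subject_groups(self) -> dict[str, str]:
        return {s: e["group"] for s, e in self.subjects.items()}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for key in (
            "genome", "subjects", "genes", "enhancers", "terms", "variants",
            "outdir", "seed", "alpha_fdr", "gwas_p_threshold",
            "high_group", "low_group",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "caller" in raw:
            kwargs["caller"] = CallerConfig(**{
                k: tuple(v) if k == "local_scales" else v
                for k, v in raw["caller"].items()
            })
        if "profile" in raw:
            kwargs["profile"] = ProfileConfig(**raw["profile"])
        if "rule" in raw:
            kwargs["rule"] = DifferentialRule(mode=raw["rule"])
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; return the output manifest (also written as JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "outputs": {}, "counts": {}}
    logger.info(
        "run start: version=%s seed=%d subjects=%s caller=%s rule=%s",
        __version__, cfg.seed, sorted(cfg.subjects), cfg.caller, cfg.rule.mode,
    )
    try:
        _run_stages(cfg, outdir, manifest)
        manifest["status"] = "complete"
    except PipelineError as exc:
        manifest["status"] = f"failed at {exc.stage}"
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.error("%s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stages(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    chrom_sizes = {c: int(l) for c, l in cfg.genome.items()}
    subjects = sorted(cfg.subjects)
    groups = cfg.subject_groups

    # stage 1-2: load + deduplicate reads
    @_stage("deduplicate")
    def load_reads():
        out = {}
        for subj in subjects:
            out[subj] = {}
            for role in ("chip", "input"):
                path = cfg.subjects[subj][role]
                if not Path(path).exists():
                    raise FileNotFoundError(
                        f"subject {subj!r} {role} sample file not found: {path}"
                    )
                rs = read_reads_bed(path, f"{subj}_{role}", subj, role)
                out[subj][role] = deduplicate(rs)
        return out

    reads = load_reads()
    for subj in subjects:
        for role in ("chip", "input"):
            manifest["counts"][f"dedup_reads_{subj}_{role}"] = reads[subj][role].depth
    logger.info("deduplication done")

    # stage 3: peak calling per subject
    @_stage("callpeaks")
    def call_all():
        peaks = {}
        for subj in subjects:
            peaks[subj] = call_peaks(
                reads[subj]["chip"], reads[subj]["input"], cfg.caller, chrom_sizes
            )
            path = outdir / f"peaks_{subj}.bed"
            write_peaks_bed(peaks[subj], path)
            manifest["outputs"][f"peaks_{subj}"] = str(path)
            manifest["counts"][f"peaks_{subj}"] = len(peaks[subj])
        return peaks

    peaks = call_all()
    summary = peak_count_summary(peaks)
    summary.to_csv(outdir / "peak_counts.tsv", sep="\t", index=False, lineterminator="\n")
    manifest["outputs"]["peak_counts"] = str(outdir / "peak_counts.tsv")
    logger.info("peak calling done: %s", dict(zip(summary.subject_id, summary.n_peaks)))

    # stage 4: merge + classify
    @_stage("differential")
    def differential():
        domains = merge_domains(peaks)
        classified = classify_domains(
            domains, groups, cfg.rule, cfg.high_group, cfg.low_group
        )
        recs = [
            BedRecord(d.interval, name=d.status, score=len(d.contributing))
            for d in classified
        ]
        write_bed(recs, outdir / "domains_all.bed", columns=6)
        for status, fname in (
            (STATUS_INDUCED, "induced.bed"),
            (STATUS_SUPPRESSED, "suppressed.bed"),
        ):
            write_bed(
                [d.interval for d in classified if d.status == status],
                outdir / fname,
                columns=3,
            )
            manifest["outputs"][fname.split(".")[0]] = str(outdir / fname)
        differential_summary(classified).to_csv(
            outdir / "differential_summary.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        return classified

    classified = differential()
    n_ind = sum(1 for d in classified if d.status == STATUS_INDUCED)
    n_sup = sum(1 for d in classified if d.status == STATUS_SUPPRESSED)
    manifest["counts"]["domains"] = len(classified)
    manifest["counts"]["induced"] = n_ind
    manifest["counts"]["suppressed"] = n_sup
    logger.info("differential: %d domains (%d induced, %d suppressed)",
                len(classified), n_ind, n_sup)

    # stage 5: aggregate profiles
    @_stage("profile")
    def profiles_stage():
        genes = read_gene_table(cfg.genes)
        enhancers = read_bed(cfg.enhancers).intervals
        for anchors, tag in ((genes, "tss"), (enhancers, "enhancer")):
            if not anchors:
                continue
            per_subject = [
                compute_profile(
                    reads[s]["chip"], reads[s]["input"], anchors, cfg.profile,
                    chrom_sizes, label=s,
                )
                for s in subjects
            ]
            by_group = group_profile(per_subject, groups)
            for label, prof in list(by_group.items()) + [
                (p.label, p) for p in per_subject
            ]:
                path = outdir / f"profile_{tag}_{label}.tsv"
                profile_table(prof).to_csv(
                    path, sep="\t", index=False, lineterminator="\n"
                )
                manifest["outputs"][f"profile_{tag}_{label}"] = str(path)
        return True

    profiles_stage()
    logger.info("profiles done")

    # stage 6: regulatory domains + enrichment
    @_stage("enrich")
    def enrich():
        genes = read_gene_table(cfg.genes)
        terms = read_term_table(cfg.terms)
        reg_domains = build_domains(genes, chrom_sizes)
        write_bed(
            [BedRecord(d.extended, name=d.gene_id) for d in reg_domains],
            outdir / "regulatory_domains.bed",
            columns=6,
        )
        diff_loci = [
            d.interval
            for d in classified
            if d.status in (STATUS_INDUCED, STATUS_SUPPRESSED)
        ]
        assoc_rows = []
        results_df = pd.DataFrame()
        if diff_loci:
            assoc = associate_loci(diff_loci, reg_domains)
            for idx, gene_ids in enumerate(assoc.locus_genes):
                locus = assoc.loci[idx]
                for gid in gene_ids:
                    assoc_rows.append(
                        (
                            f"{locus.chrom}:{locus.start}-{locus.end}",
                            gid,
                            assoc.overlap_bp[(idx, gid)],
                        )
                    )
            selected = assoc.selected_genes
            universe = [g.gene_id for g in genes]
            if selected:
                results = hypergeom_enrich(selected, terms, universe, cfg.alpha_fdr)
                results_df = report_enrichment(results, cfg.alpha_fdr)
        pd.DataFrame(
            assoc_rows, columns=["locus", "gene_id", "overlap_bp"]
        ).to_csv(outdir / "associations.tsv", sep="\t", index=False, lineterminator="\n")
        for onto in sorted(results_df["ontology"].unique()) if len(results_df) else []:
            path = outdir / f"enrichment_{onto}.tsv"
            results_df[results_df["ontology"] == onto].to_csv(
                path, sep="\t", index=False, lineterminator="\n"
            )
            manifest["outputs"][f"enrichment_{onto}"] = str(path)
        return results_df

    results_df = enrich()
    manifest["counts"]["enriched_terms"] = (
        int(results_df["significant"].sum()) if len(results_df) else 0
    )
    logger.info("enrichment done: %d significant terms", manifest["counts"]["enriched_terms"])

    # stage 7: GWAS overlap
    @_stage("gwas")
    def gwas_stage():
        variants = read_variant_table(cfg.variants)
        filtered = filter_catalog(variants, cfg.gwas_p_threshold)
        hits = overlap_variants(filtered, classified)
        table = overlap_table(hits)
        path = outdir / "gwas_overlap.tsv"
        table.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest["outputs"]["gwas_overlap"] = str(path)
        manifest["counts"]["gwas_catalog_filtered"] = len(filtered)
        manifest["counts"]["gwas_hits"] = len(hits)
        return hits

    hits = gwas_stage()
    logger.info("gwas overlap done: %d hits", len(hits))
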