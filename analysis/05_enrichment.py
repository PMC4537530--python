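"""Associate differential loci with genes via basal+extended regulatory
domains (5 kb upstream / 1 kb downstream, extended to the nearest
neighbouring basal domain, at most 100 kb from the TSS) and test term
over-representation with the hypergeometric test at 5% FDR per
ontology.

Writes per-ontology enrichment tables to results/ and a bubble plot to
scratch/figures/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from _common import FIG_DIR, RESULTS, RUN_DIR, ensure_dirs, load_run_config

from acetyldiff.enrichment import (
    associate_loci,
    build_domains,
    hypergeom_enrich,
    report_enrichment,
)
from acetyldiff.genomic_io import read_bed, read_gene_table, read_term_table


def main():
    ensure_dirs()
    cfg = load_run_config()
    chrom_sizes = {c: int(l) for c, l in cfg["genome"].items()}
    genes = read_gene_table(cfg["genes"])
    terms = read_term_table(cfg["terms"])
    loci = (
        read_bed(RUN_DIR / "induced.bed").intervals
        + read_bed(RUN_DIR / "suppressed.bed").intervals
    )
    domains = build_domains(genes, chrom_sizes)
    assoc = associate_loci(loci, domains)
    results = hypergeom_enrich(
        assoc.selected_genes, terms, [g.gene_id for g in genes], alpha_fdr=0.05
    )
    df = report_enrichment(results, alpha_fdr=0.05, plot_path=FIG_DIR / "enrichment.png")
    for onto in sorted(df["ontology"].unique()):
        df[df["ontology"] == onto].to_csv(
            RESULTS / f"05_enrichment_{onto}.tsv", sep="\t", index=False
        )
    print(
        f"found: {len(assoc.selected_genes)} genes associated with "
        f"{len(loci)} differential loci; "
        f"{int(df['significant'].sum())} terms significant at 5% FDR."
    )
    top = df[df["significant"]].groupby("ontology").head(3)
    print(top[["ontology", "term_id", "term_name", "overlap_k", "fdr"]].to_string(index=False))


if __name__ == "__main__":
    main()
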