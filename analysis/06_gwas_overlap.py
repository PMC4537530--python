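"""Overlap catalog trait-associated SNPs (nominal p < 1e-5, strict) with
the induced and suppressed loci.

Writes the hit table to results/06_gwas_overlap.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, RUN_DIR, ensure_dirs, load_run_config

from acetyldiff.differential import BroadDomain
from acetyldiff.genomic_io import read_bed, read_variant_table
from acetyldiff.gwas import filter_catalog, overlap_table, overlap_variants


def main():
    ensure_dirs()
    cfg = load_run_config()
    domains = []
    for status in ("induced", "suppressed"):
        for iv in read_bed(RUN_DIR / f"{status}.bed").intervals:
            domains.append(BroadDomain(iv, {}, {}, status))
    variants = read_variant_table(cfg["variants"])
    filtered = filter_catalog(variants)
    hits = overlap_variants(filtered, domains)
    table = overlap_table(hits)
    table.to_csv(RESULTS / "06_gwas_overlap.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        f"found: {len(filtered)}/{len(variants)} catalog associations pass the "
        f"p < 1e-5 filter; {len(hits)} overlap a differential locus "
        f"({sum(h.locus_status == 'induced' for h in hits)} induced, "
        f"{sum(h.locus_status == 'suppressed' for h in hits)} suppressed)."
    )


if __name__ == "__main__":
    main()
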