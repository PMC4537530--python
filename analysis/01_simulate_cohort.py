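"""Simulate the study cohort: 2 exposure groups x 2 subjects, ChIP +
matched input reads per subject, with planted shared/induced/suppressed
peaks, gene/enhancer annotations, a two-ontology term table and a
GWAS-catalog-style variant table.

Writes the cohort under scratch/sim/ and a design/truth summary to
results/01_truth_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd
from _common import RESULTS, SIM_DIR, STUDY_SEED, ensure_dirs

from acetyldiff.synthetic import SyntheticDesign, write_cohort


def main():
    ensure_dirs()
    design = SyntheticDesign(seed=STUDY_SEED)
    run_yaml = write_cohort(design, SIM_DIR)
    truth = pd.read_csv(SIM_DIR / "truth_peaks.tsv", sep="\t")
    genes = pd.read_csv(SIM_DIR / "genes.tsv", sep="\t")
    variants = pd.read_csv(SIM_DIR / "variants.tsv", sep="\t")
    summary = pd.DataFrame(
        {
            "quantity": [
                "genome_bp",
                "subjects",
                "planted_shared_peaks",
                "planted_induced_peaks",
                "planted_suppressed_peaks",
                "genes",
                "catalog_variants",
            ],
            "value": [
                sum(l for _, l in design.genome),
                len(design.subjects),
                int((truth["class"] == "shared").sum()),
                int((truth["class"] == "induced").sum()),
                int((truth["class"] == "suppressed").sum()),
                len(genes),
                len(variants),
            ],
        }
    )
    summary.to_csv(RESULTS / "01_truth_summary.tsv", sep="\t", index=False)
    print(f"cohort simulated under {SIM_DIR} (config: {run_yaml})")
    print(summary.to_string(index=False))
    print(
        "found: high-exposure subjects carry "
        f"{int((truth['class'] != 'suppressed').sum())} active planted peaks, "
        f"low-exposure subjects {int((truth['class'] != 'induced').sum())}; the "
        "asymmetry (more induced than suppressed) mirrors an exposure that "
        "mostly gains acetylation."
    )


if __name__ == "__main__":
    main()
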