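# acetyldiff

Differential H3K27ac ChIP-seq analysis between exposure groups, as a
tested, reusable pipeline over interval-level data.

## The problem

Histone H3 lysine-27 acetylation (H3K27ac) marks active promoters and
enhancers. Comparing genome-wide H3K27ac profiles between small groups
of individuals with different environmental exposure (e.g. high vs low
particulate-matter exposure) asks four questions:

1. Where is the mark enriched in each individual? (ChIP-seq peak calling
   against a matched input sample.)
2. Which regions differ between the groups? (Cross-individual peak
   merging into broad domains; presence/absence classification into
   *induced* — detected only in the high-exposure group — and
   *suppressed* — detected only in the low-exposure group.)
3. Does the mark shift globally at regulatory elements? (Aggregate,
   input-normalised log-ratio profiles in ±10 kb windows around TSSs and
   enhancer centers, 400 × 50 bp bins.)
4. What do the differential regions do? (GREAT-style regulatory-domain
   gene association with hypergeometric term enrichment at 5 % FDR, and
   overlap with GWAS-catalog trait-associated SNPs at nominal p < 10⁻⁵.)

`acetyldiff` implements all four stages plus a synthetic-cohort
generator with planted ground truth, so the whole chain is validated end
to end: every planted signal class is recoverable by coordinates and
every stage's output can be scored against what was planted.

## The core statistics

**Peak calling.** Reads are deduplicated to one per (chromosome, start,
strand). Sliding windows (300 bp, step 100 bp) are tested against a
local Poisson background estimated from the matched input:

    λ_local = w · max(rate_genome, rate_1kb, rate_5kb, rate_10kb) · d_chip/d_input

where the rates are input read-start densities around the window and
the depth ratio corrects for library size. A window is significant when
its ChIP read-start count k satisfies k ≥ 5 and P(X ≥ k | λ_local) < 10⁻⁵
(upper-tail Poisson); significant windows within 200 bp merge into one
peak.

**Differential loci.** Peaks from all subjects merge transitively by
≥ 1 bp overlap into broad domains. Under the default `any-vs-none` rule
a domain is induced iff ≥ 1 high-exposure subject contributes and no
low-exposure subject does (suppressed: the converse; `all-vs-none` is
available as a stricter option).

**Profiles.** Per 50 bp bin b pooled over anchors,
D(b) = count(b)/(n_anchors · bin_size · depth) and
value(b) = log₂((D_chip + ε)/(D_input + ε)) with a symmetric
pseudocount ε; minus-strand TSS windows are flipped so bins run 5′→3′.

**Enrichment.** Each gene gets a basal regulatory domain (5 kb upstream
to 1 kb downstream of the TSS) extended to the nearest neighbouring
basal domain, at most 100 kb from the TSS. A differential locus is
associated with every gene whose domain it overlaps. For a term
annotating K of N universe genes, with k of the n selected genes
annotated, p = P(X ≥ k), X ~ Hypergeom(N, K, n), with Benjamini–Hochberg
FDR within each ontology.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
default synthetic cohort (10 Mb genome, 2×2 subjects, 60 shared + 20
induced + 5 suppressed planted 1 kb peaks, 8-fold in-peak enrichment
over a 0.01 reads/bp background, global promoter/enhancer folds 2.0 vs
1.5):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_peaks.py
...
python analysis/06_gwas_overlap.py
```

Output (seed 1):

```
subject_id  n_peaks group
    high_1       80  high
    high_2       83  high
     low_1       65   low
     low_2       66   low
found: mean peak count 81.5 in the high-exposure group vs 65.5 in the low-exposure group

found: 23 induced vs 6 suppressed loci (89 broad domains total)
found: tss profile central (+/-20 bin) high-minus-low gap = +0.00065 log2 units
found: enhancer profile central (+/-20 bin) high-minus-low gap = +0.00221 log2 units

          ontology term_id                     term_name  overlap_k      fdr
           pathway PW:9001 inflammatory response pathway         17 0.000025
biological_process  BP:900          leukocyte activation         10 0.001746

found: 8/11 catalog associations pass the p < 1e-5 filter; 5 overlap a
differential locus (4 induced, 1 suppressed).
```

Reading these numbers: all 20 planted induced and all 5 planted
suppressed peaks are recovered with the right label (the extra
induced/suppressed domains come from the high group's global
promoter/enhancer elevation, which genuinely creates group-specific
peaks); the high-exposure group has more peaks and higher central
profile values at both promoters and enhancers; the planted
"inflammatory response pathway" term ranks first in its ontology; and
exactly the planted catalog-significant in-peak SNPs are reported, while
the planted sub-threshold (p = 10⁻³) and boundary (p = 10⁻⁵ exactly,
excluded by the strict inequality) negative controls are not.

The same stages are exposed as a CLI (`acetyldiff simulate`,
`callpeaks`, `differential`, `profile`, `enrich`, `gwas`, `run`) for use
on files, e.g.:

```bash
acetyldiff simulate --outdir sim/ --seed 17
acetyldiff run --config sim/run.yaml --outdir out/
```

## Layout

```
src/acetyldiff/     library: genomic_io, peaks, differential, profiles,
                    enrichment, gwas, synthetic, study, pipeline, cli
analysis/           numbered narrative drivers (write tables to results/)
tests/              pytest suite incl. end-to-end validation
scripts/            acceptance.py
docs/methods.md     model, parameters, design choices, limitations
```
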