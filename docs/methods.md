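# Methods

## Scope and data model

`acetyldiff` analyses single-end ChIP-seq data that has already been
aligned: its inputs are read *intervals* (BED), not FASTQ. All internal
coordinates are 0-based half-open; the only 1-based convention is the
variant table's file format, converted at read time. Chromosome names
match by exact string equality (an explicit normalisation helper exists;
nothing is aliased silently), and malformed input lines are fatal with a
line number rather than skipped — a deterministic pipeline is worth more
than a permissive parser.

## Peak calling

The caller is a fixed-width sliding-window local-Poisson test of the
ChIP sample against its matched input. It keeps the core idea of
model-based callers — a dynamic local background — while dropping
everything that is not needed for interval-level data (fragment-shift
model building, duplicate-rate estimation beyond full deduplication,
broad/narrow distinctions).

Parameters (all in `CallerConfig`):

| parameter    | default          | meaning |
|--------------|------------------|---------|
| window       | 300 bp           | test window width |
| step         | 100 bp           | window stride |
| p_threshold  | 1e-5             | upper-tail Poisson significance cutoff |
| local_scales | 1, 5, 10 kb      | spans for local input-rate estimation |
| merge_gap    | 200 bp           | max separation at which significant windows merge |
| min_count    | 5 reads          | floor on the window ChIP count |

Window coverage counts read **start** positions, so every read belongs
to exactly one 100 bp accounting stripe and boundary double-counting
cannot occur. The local rate is the maximum of the genome-wide input
rate and the input rate in each local scale centred on the window
(clipped at chromosome ends, with rates computed over the clipped
span); taking the maximum makes the test conservative where the input
is locally dense. Unequal library sizes are handled by scaling the
input-derived expectation by `chip_depth / input_depth`. Windows at
chromosome ends are clipped and their expectation scales with the
clipped width. Merged peaks carry the minimum member-window p-value and
counts/expectation recomputed on the merged span.

Because the Poisson count is discrete, the realized per-window
false-positive rate on null data is the tail mass just *below* the
threshold (about 3×10⁻⁶ at λ = 3 for the 10⁻⁵ cutoff), not the nominal
10⁻⁵; the calibration test therefore treats the nominal rate as an
upper bound and checks the observed significant-window count against
the Poisson band it implies.

## Differential loci

Peaks from all subjects merge by transitive single-linkage with ≥ 1 bp
overlap (book-ended half-open intervals do not merge). Classification
is presence/absence between the two exposure groups. "Detected in one
group" is ambiguous with small groups, so both readings are
implemented:

* `any-vs-none` (default): one subject's peak establishes group
  presence. With two subjects per group this is the natural reading of
  "detected in a group's merged peak set".
* `all-vs-none`: every subject of the group must contribute; domains
  satisfying neither rule in a group are labelled
  `group-specific-partial`.

No quantitative (count-based) differential test is attempted: the
contract is presence/absence, and "missing" means "no called peak",
not "signal below some secondary threshold".

## Aggregate profiles

A ±10 kb window around each anchor is split into 400 × 50 bp bins.
Counts are pooled across anchors *before* the log ("log of ratio of
averages") because the per-anchor log is unstable at zero-count bins.
Per bin, the density D = pooled count / (n_anchors · bin_size · depth)
is computed for ChIP and input, and the profile value is
log₂((D_chip + ε)/(D_input + ε)) with pseudocount ε = 10⁻⁴ reads/bp on
both sides, which keeps the ChIP≡input identity case at exactly zero
and every bin finite. Minus-strand TSS windows are reversed so bins run
5′→3′; enhancer centers are unstranded. Anchors whose window would
cross a chromosome boundary are dropped and counted. Group curves are
per-bin arithmetic means of the subjects' normalised profiles (pooling
reads per group before normalisation would weight subjects by depth;
per-subject-then-mean weights them equally).

Two numerical consequences of this definition are worth stating. First,
dividing by total depth makes D of order 10⁻⁷ for desk-scale libraries,
so the default pseudocount dominates both densities and compresses the
log-ratio scale to ~10⁻²–10⁻³; orderings, shapes, symmetries and the
identity-zero property are unaffected, and the pseudocount is
configurable if absolute magnitudes matter. Second, with two subjects
per group, ~60 TSS anchors and a 0.01 reads/bp background, per-bin shot
noise in the high-minus-low difference (sd ≈ 0.45 of the uncompressed
log-ratio) exceeds the expected gap (log₂(2.0/1.5) ≈ 0.42), so the
groupwise elevation is assessed on the mean over the central ±20 bins
(where the noise averages down ~6-fold and the separation is ≈ 5–6
standard errors), not bin-by-bin.

## Regulatory domains and enrichment

Each gene's basal domain covers 5 kb on its 5′ side and 1 kb on its 3′
side of the TSS (half-open, clipped at chromosome bounds). Extension
runs per direction from the basal edge to the nearest of: another
gene's basal boundary, the point 100 kb from the TSS, or the chromosome
end. The 100 kb cap is measured from the TSS (the gene's reference
point), not the basal edge. A neighbouring basal domain already
overlapping the gene's basal blocks extension entirely on that side, so
the extension region (extended minus basal) never overlaps any other
basal domain — an invariant the tests check on 10⁴ random gene layouts.

A differential locus associates with every gene whose extended domain
it overlaps by ≥ 1 bp; a gene counts once no matter how many loci
support it. The enrichment universe is all genes in the provided
annotation table — the only well-defined set available — and the test
is the upper-tail hypergeometric p = P(X ≥ k) for X ~ Hypergeom(N, K, n),
with fold enrichment (k/n)/(K/N). Benjamini–Hochberg FDR is applied
separately within each ontology (the two panels are separate families).
Only the gene-based hypergeometric test is implemented; the
region-based binomial test some tools add, ontology-graph propagation
and evidence-code filtering are deliberately out of scope (terms are
flat labels).

## GWAS overlap

Catalog associations are filtered to nominal p strictly below 10⁻⁵
(p = 10⁻⁵ exactly is excluded), duplicates collapse to the smallest
p-value per (SNP, trait), and each SNP is a 1 bp point tested for
containment in induced and suppressed domains — no LD expansion or
proxy lookup. One hit is emitted per (SNP, trait, locus) triple with
the locus status carried along, since whether only induced loci or all
differential loci should be scanned is a reporting choice; both are
labelled.

## Synthetic cohort

The generator emulates the study conditions the analysis assumes: two
exposure groups × two subjects, 101 bp single-end reads, and a
10 Mb two-chromosome genome carrying 60 shared, 20 induced and 5
suppressed planted 1 kb peaks (more induced than suppressed, matching
an exposure that mostly gains acetylation). Read starts follow an
inhomogeneous Poisson process: input is uniform at 0.01 reads/bp
(~10⁵ reads per sample — deliberately desk-scale, roughly 20–50× below
real library depths, chosen so the full multi-seed suite runs in
seconds per cohort); ChIP multiplies the background by 8 inside peaks
active for the subject's group and by the group's global fold (2.0
high / 1.5 low) within ±1 kb of every TSS and enhancer center, so the
high group shows a mild genome-wide promoter/enhancer elevation on top
of its extra peaks. Folds stack multiplicatively where zones overlap
(enhancer centers sit inside half the shared peaks, giving those peaks
16× vs 12× — the source of the groupwise enhancer-profile gap).
Duplicate read positions are allowed so deduplication has real work;
strand is uniform random; all randomness flows from one seed through
per-(subject, sample) seed sequences, so identical designs reproduce
byte-identical cohorts.

Placement is deliberate rather than uniform, because regulatory domains
reach 100 kb and a uniform layout on a desk-scale genome would associate
nearly every gene with some differential locus: differential peaks
occupy 185 kb slots with one proximal gene each (~3 kb away, alternating
strands), shared peaks occupy 65 kb slots interleaved with background
genes ≥ 17 kb away, and the layout always includes a chromosome-edge
gene (TSS at 2 kb), a close pair (basal domains 30 kb apart) and an
isolated gene (> 200 kb from any neighbour) to exercise every
domain-construction branch. The term table plants one pathway term on
85 % of the induced-proximal genes (plus two background genes); the
variant table plants catalog-significant SNPs inside induced and
suppressed peaks, a sub-threshold SNP (p = 10⁻³) and an exact-boundary
SNP (p = 10⁻⁵) inside an induced peak, a significant SNP inside a
shared peak, and intergenic significant SNPs — each a positive or
negative control for one filtering or overlap rule.

What the generator does **not** model: sequencing error, mappability
bias, fragment-size effects, GC bias, diploid genomes, biological
replicate variability beyond Poisson sampling, and peak-width
heterogeneity. Passing tests therefore demonstrate that the pipeline's
logic and statistics are correct under its own model assumptions — not
that the caller is competitive with production callers on real data.

## Determinism and numerics

The analysis stages contain no randomness; the pipeline re-run on
identical inputs is byte-identical. Poisson and hypergeometric tails
come from scipy and are cross-checked in the tests against independent
brute-force oracles (term-by-term summation; exact integer
enumeration) to 10⁻⁹/10⁻¹⁰ relative error. Enrichment ordering breaks
ties deterministically by (FDR, p, term id). Degenerate inputs fail
loudly: zero-depth input samples, empty gene universes, empty
selections, all-dropped anchors, unmapped subjects and too-small
genomes all raise errors naming the offending entity.

## Known limitations

* Presence/absence differential calling cannot distinguish "absent"
  from "just under threshold"; with two subjects per group no
  statistical test of group difference is attempted.
* The caller has no fragment-shift model, so peak boundaries are
  window-resolution (±100 bp) approximations.
* The profile depth-normalisation/pseudocount interaction compresses
  absolute log-ratio magnitudes at low depth (see above).
* Enrichment treats terms as flat labels; nested ontology terms are
  tested as if independent, which BH within ontology only partially
  addresses.
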