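import numpy as np
import pandas as pd
import pytest

from acetyldiff.synthetic import (
    GenomeTooSmallError,
    SyntheticCohort,
    SyntheticDesign,
    generate_annotations,
    generate_reads,
)

NULL_DESIGN = dict(
    genome=(("chr1", 1_000_000),),
    n_shared_peaks=0,
    n_induced_peaks=0,
    n_suppressed_peaks=0,
    global_tss_fold_high=1.0,
    global_tss_fold_low=1.0,
)


class TestRates:
    def test_null_design_chip_rate_equals_input_rate(self):
        cohort = SyntheticCohort(SyntheticDesign(seed=0, **NULL_DESIGN))
        chip = cohort.rate_segments("high_1", "chip")
        inp = cohort.rate_segments("high_1", "input")
        for chrom in chip:
            # with no peaks and unit folds the piecewise rates collapse to
            # a single background segment in both samples
            assert {(s, e, r) for s, e, r in chip[chrom]} == {
                (s, e, r) for s, e, r in inp[chrom]
            }

    def test_peak_fold_applied_only_to_active_classes(self):
        cohort = SyntheticCohort(SyntheticDesign(seed=1))
        d = cohort.design

        def rate_at(segments, chrom, pos):
            for s, e, r in segments[chrom]:
                if s <= pos < e:
                    return r
            raise AssertionError("position not covered")

        hi = cohort.rate_segments("high_1", "chip")
        lo = cohort.rate_segments("low_1", "chip")
        for iv in cohort.truth.peaks_of_class("induced"):
            mid = (iv.start + iv.end) // 2
            assert rate_at(hi, iv.chrom, mid) == pytest.approx(
                d.background_rate * d.peak_fold
            )
            assert rate_at(lo, iv.chrom, mid) == pytest.approx(d.background_rate)
        # class separation: suppressed regions show no enrichment in any
        # high-group subject
        for subj in ("high_1", "high_2"):
            segs = cohort.rate_segments(subj, "chip")
            for iv in cohort.truth.peaks_of_class("suppressed"):
                mid = (iv.start + iv.end) // 2
                assert rate_at(segs, iv.chrom, mid) == pytest.approx(
                    d.background_rate
                )

    def test_global_fold_elevates_tss_and_enhancer_zones_per_group(self):
        cohort = SyntheticCohort(SyntheticDesign(seed=1))
        d = cohort.design

        def rate_at(segments, chrom, pos):
            for s, e, r in segments[chrom]:
                if s <= pos < e:
                    return r
            raise AssertionError

        gene = cohort.truth.genes[0]
        hi = rate_at(cohort.rate_segments("high_1", "chip"), gene.chrom, gene.tss)
        lo = rate_at(cohort.rate_segments("low_1", "chip"), gene.chrom, gene.tss)
        assert hi == pytest.approx(d.background_rate * d.global_tss_fold_high)
        assert lo == pytest.approx(d.background_rate * d.global_tss_fold_low)
        enh = cohort.truth.enhancers[0]
        c = (enh.start + enh.end) // 2
        hi_e = rate_at(cohort.rate_segments("high_1", "chip"), enh.chrom, c)
        # enhancer centers sit inside shared peaks: folds stack
        assert hi_e == pytest.approx(
            d.background_rate * d.peak_fold * d.global_tss_fold_high
        )

    def test_unknown_subject_error_names_subject(self):
        cohort = SyntheticCohort(SyntheticDesign(seed=0, **NULL_DESIGN))
        with pytest.raises(ValueError, match="nobody"):
            cohort.generate_reads("nobody", "chip")


class TestReads:
    def test_input_read_count_matches_poisson_expectation(self):
        # 0.01 reads/bp on a 1 Mb genome: expectation 10,000 per input sample
        counts = []
        for seed in range(20):
            rs = generate_reads(
                SyntheticDesign(seed=seed, **NULL_DESIGN), "low_1", "input"
            )
            counts.append(rs.depth)
            assert abs(rs.depth - 10_000) < 4 * np.sqrt(10_000)
        assert abs(np.mean(counts) - 10_000) < 4 * np.sqrt(10_000 / 20)
        # Poisson variance: sample variance within a factor ~3 of the mean
        assert 10_000 / 3 < np.var(counts, ddof=1) < 10_000 * 3

    def test_same_seed_same_design_identical_reads(self):
        d = SyntheticDesign(seed=11, **NULL_DESIGN)
        a = generate_reads(d, "high_1", "chip")
        b = generate_reads(d, "high_1", "chip")
        pd.testing.assert_frame_equal(a.df, b.df)
        c = generate_reads(SyntheticDesign(seed=12, **NULL_DESIGN), "high_1", "chip")
        assert not a.df.equals(c.df)

    def test_reads_sorted_fixed_length_with_duplicates(self):
        d = SyntheticDesign(seed=2)
        rs = generate_reads(d, "high_1", "chip")
        for chrom, grp in rs.df.groupby("chrom"):
            assert grp["start"].is_monotonic_increasing
        interior = rs.df[rs.df["end"] - rs.df["start"] == d.read_length]
        assert len(interior) > 0.99 * len(rs.df)  # only chromosome-end reads clip
        # duplicates are deliberately allowed so deduplication has work to do
        assert rs.df.duplicated(subset=["chrom", "start", "strand"]).any()

    def test_in_peak_density_converges_to_peak_fold(self):
        # empirical enrichment inside induced peaks (the class with no
        # stacked promoter/enhancer zones) vs background, 20 seeds
        ratios = []
        for seed in range(20):
            d = SyntheticDesign(seed=seed)
            cohort = SyntheticCohort(d)
            rs = cohort.generate_reads("high_1", "chip")
            active = cohort.truth.peaks_of_class("induced")
            peak_bp = sum(len(iv) for iv in active)
            in_peak = 0
            for iv in active:
                sub = rs.df[rs.df["chrom"] == iv.chrom]
                in_peak += int(
                    ((sub["start"] >= iv.start) & (sub["start"] < iv.end)).sum()
                )
            ratios.append((in_peak / peak_bp) / d.background_rate)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - SyntheticDesign().peak_fold) < 3 * se + 0.05


class TestAnnotations:
    def test_planted_peak_counts_conserved(self):
        ann = generate_annotations(SyntheticDesign(seed=3, n_induced_peaks=20))
        assert len(ann.truth.peaks_of_class("induced")) == 20
        assert len(ann.truth.peaks_of_class("suppressed")) == 5
        assert len(ann.truth.peaks_of_class("shared")) == 60

    def test_peaks_disjoint_and_inside_genome(self):
        d = SyntheticDesign(seed=4)
        ann = generate_annotations(d)
        sizes = d.chrom_sizes
        ivs = sorted(
            (iv.chrom, iv.start, iv.end) for iv, _ in ann.truth.peaks
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            assert c1 != c2 or e1 <= s2
        for c, s, e in ivs:
            assert 0 <= s < e <= sizes[c]

    def test_negative_control_snp_inside_induced_peak(self):
        ann = generate_annotations(SyntheticDesign(seed=5))
        weak = [v for v in ann.variants if v.p_value == 1e-3]
        assert weak, "a sub-threshold catalog SNP must be planted"
        induced = ann.truth.peaks_of_class("induced")
        assert any(
            iv.contains_point(v.chrom, v.position) for v in weak for iv in induced
        )

    def test_gene_layout_exercises_domain_branches(self):
        ann = generate_annotations(SyntheticDesign(seed=6))
        by_id = {g.gene_id: g for g in ann.genes}
        pair_a, pair_b = by_id["G_PAIR_A"], by_id["G_PAIR_B"]
        assert pair_a.chrom == pair_b.chrom
        assert abs(pair_b.tss - pair_a.tss) < 100_000  # basal domains < 100 kb apart
        iso = by_id["G_ISOLATED"]
        others = [
            g for g in ann.genes
            if g.chrom == iso.chrom and g.gene_id != "G_ISOLATED"
        ]
        assert min(abs(g.tss - iso.tss) for g in others) > 200_000
        assert by_id["G_EDGE"].tss == 2_000  # basal/extension clipped at 0

    def test_planted_term_covers_most_induced_proximal_genes(self):
        ann = generate_annotations(SyntheticDesign(seed=7))
        onto, term_id = ann.truth.planted_term
        annotated = {
            t.gene_id for t in ann.terms
            if t.ontology == onto and t.term_id == term_id
        }
        prox = set(ann.truth.induced_proximal_genes)
        assert len(annotated & prox) >= 0.8 * len(prox)

    def test_genome_too_small_reports_minimum(self):
        with pytest.raises(GenomeTooSmallError, match=r"\d+ bp"):
            generate_annotations(
                SyntheticDesign(genome=(("chr1", 200_000),), seed=0)
            )

    @pytest.mark.parametrize(
        "field,value",
        [
            ("background_rate", 0.0),
            ("peak_fold", -1.0),
            ("n_subjects_per_group", 0),
            ("n_induced_peaks", -3),
        ],
    )
    def test_invalid_design_rejected(self, field, value):
        with pytest.raises(ValueError):
            SyntheticDesign(**{field: value})
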