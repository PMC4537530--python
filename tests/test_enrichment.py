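import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from _oracles import hypergeom_upper_tail
from acetyldiff.enrichment import (
    associate_loci,
    build_domains,
    hypergeom_enrich,
    report_enrichment,
)
from acetyldiff.genomic_io import GeneRecord, GenomicInterval, TermAnnotation

SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


class TestBuildDomains:
    def test_isolated_plus_strand_gene(self):
        (d,) = build_domains([GeneRecord("g", "chr1", "+", 500_000)], SIZES)
        assert (d.basal.start, d.basal.end) == (495_000, 501_000)
        assert (d.extended.start, d.extended.end) == (400_000, 600_000)

    def test_minus_strand_basal_orientation(self):
        (d,) = build_domains([GeneRecord("g", "chr1", "-", 500_000)], SIZES)
        # 5 kb upstream lies at higher coordinates on the minus strand
        assert (d.basal.start, d.basal.end) == (499_000, 505_000)

    def test_two_neighbouring_genes_stop_at_each_others_basal(self):
        genes = [
            GeneRecord("A", "chr1", "+", 100_000),
            GeneRecord("B", "chr1", "+", 150_000),
        ]
        domains = {d.gene_id: d for d in build_domains(genes, SIZES)}
        assert domains["A"].extended.end == 145_000  # B's basal start
        assert domains["B"].extended.start == 101_000  # A's basal end
        assert domains["A"].extended.start == 0  # 100 kb cap clipped at chrom 0
        assert domains["B"].extended.end == 250_000

    def test_chromosome_edge_clipping(self):
        (d,) = build_domains([GeneRecord("g", "chr1", "+", 2_000)], SIZES)
        assert d.basal.start == 0  # 5 kb upstream clipped at coordinate 0
        assert d.extended.start == 0
        assert d.extended.end == 102_000

    def test_tss_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_domains([GeneRecord("g", "chr1", "+", 2_000_000)], SIZES)

    def test_random_layouts_satisfy_domain_invariants(self):
        # 10^4 genes across random layouts; every domain obeys:
        # basal within extended; extended within 100 kb of the TSS and the
        # chromosome; the extension never overlaps another gene's basal
        rng = np.random.default_rng(2024)
        total = 0
        while total < 10_000:
            n = int(rng.integers(2, 60))
            L = int(rng.integers(200_000, 2_000_000))
            genes = [
                GeneRecord(
                    f"g{i}", "chr1",
                    "+" if rng.integers(2) else "-",
                    int(rng.integers(0, L)),
                )
                for i in range(n)
            ]
            # one TSS per gene id is required, duplicates of position are fine
            domains = build_domains(genes, {"chr1": L})
            basal_by_id = {d.gene_id: d.basal for d in domains}
            gene_by_id = {g.gene_id: g for g in genes}
            for d in domains:
                g = gene_by_id[d.gene_id]
                assert d.extended.start <= d.basal.start < d.basal.end <= d.extended.end
                assert d.extended.start >= max(0, g.tss - 100_000)
                assert d.extended.end <= min(L, g.tss + 100_000)
                # the extension (extended minus basal) never overlaps
                # another gene's basal domain
                for other_id, ob in basal_by_id.items():
                    if other_id == d.gene_id:
                        continue
                    left = (d.extended.start, d.basal.start)
                    right = (d.basal.end, d.extended.end)
                    for lo, hi in (left, right):
                        if lo < hi:
                            assert not (ob.start < hi and lo < ob.end), (
                                f"extension [{lo},{hi}) of {d.gene_id} overlaps "
                                f"basal of {other_id}"
                            )
            total += n


class TestAssociate:
    GENES = [GeneRecord("g", "chr1", "+", 500_000)]

    def test_locus_in_basal_is_associated(self):
        domains = build_domains(self.GENES, SIZES)
        assoc = associate_loci([GenomicInterval("chr1", 496_000, 497_000)], domains)
        assert assoc.locus_genes == [["g"]]
        assert assoc.selected_genes == {"g"}

    def test_locus_spanning_two_domains_hits_both(self):
        genes = [
            GeneRecord("A", "chr1", "+", 100_000),
            GeneRecord("B", "chr1", "+", 150_000),
        ]
        domains = build_domains(genes, SIZES)
        assoc = associate_loci([GenomicInterval("chr1", 140_000, 148_000)], domains)
        assert assoc.locus_genes == [["A", "B"]]

    def test_geneless_chromosome_locus_retained_with_empty_list(self):
        domains = build_domains(self.GENES, SIZES)
        assoc = associate_loci([GenomicInterval("chr2", 10, 20)], domains)
        assert assoc.locus_genes == [[]]
        assert assoc.selected_genes == set()

    @given(
        start=st.integers(0, 900_000),
        width=st.integers(1, 20_000),
        grow=st.integers(0, 30_000),
    )
    def test_association_monotone_under_locus_growth(self, start, width, grow):
        genes = [
            GeneRecord("A", "chr1", "+", 100_000),
            GeneRecord("B", "chr1", "-", 150_000),
            GeneRecord("C", "chr1", "+", 700_000),
        ]
        domains = build_domains(genes, SIZES)
        small = GenomicInterval("chr1", start, start + width)
        big = GenomicInterval(
            "chr1", max(0, start - grow), min(1_000_000, start + width + grow)
        )
        small_genes = set(associate_loci([small], domains).locus_genes[0])
        big_genes = set(associate_loci([big], domains).locus_genes[0])
        assert small_genes <= big_genes


class TestHypergeom:
    def test_textbook_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        terms = [TermAnnotation(f"g{i}", "pathway", "T", "t") for i in range(5)]
        universe = [f"g{i}" for i in range(10)]
        (res,) = hypergeom_enrich(["g0", "g1", "g2", "g3"], terms, universe)
        assert res.k == 4 and res.K == 5 and res.n == 4 and res.N == 10
        assert res.p_value == pytest.approx(5 / 210, rel=1e-12)
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(4, 10, 5, 4), rel=1e-12
        )
        assert res.fold_enrichment == pytest.approx((4 / 4) / (5 / 10))

    def test_zero_overlap_gives_p_one(self):
        terms = [TermAnnotation("g9", "pathway", "T", "t")]
        universe = [f"g{i}" for i in range(10)]
        (res,) = hypergeom_enrich(["g0", "g1"], terms, universe)
        assert res.k == 0 and res.p_value == 1.0

    def test_saturated_term_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        terms = [TermAnnotation(g, "pathway", "T", "t") for g in universe]
        (res,) = hypergeom_enrich(["g0", "g1", "g2"], terms, universe)
        assert res.k == res.n and res.K == res.N
        assert res.p_value == 1.0

    def test_matches_exact_oracle_on_sampled_configurations(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            N = int(rng.integers(2, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            expected = hypergeom_upper_tail(k, N, K, n)
            got = float(stats.hypergeom.sf(k - 1, N, K, n))
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    def test_fdr_computed_within_each_ontology(self):
        universe = [f"g{i}" for i in range(40)]
        selected = universe[:10]
        terms = (
            # pathway panel: one strong term among three
            [TermAnnotation(g, "pathway", "P1", "p1") for g in universe[:10]]
            + [TermAnnotation(g, "pathway", "P2", "p2") for g in universe[20:25]]
            + [TermAnnotation(g, "pathway", "P3", "p3") for g in universe[30:35]]
            # process panel: a single term, so its FDR equals its p-value
            + [TermAnnotation(g, "biological_process", "B1", "b1") for g in universe[:10]]
        )
        results = hypergeom_enrich(selected, terms, universe)
        by_id = {r.term_id: r for r in results}
        assert by_id["B1"].fdr == pytest.approx(by_id["B1"].p_value)
        # same p, but the pathway panel divides by 3 terms under BH
        assert by_id["P1"].p_value == pytest.approx(by_id["B1"].p_value)
        assert by_id["P1"].fdr >= by_id["B1"].fdr

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["g0"], [], [])
        with pytest.raises(ValueError):
            hypergeom_enrich([], [], ["g0"])


class TestReport:
    def test_ordering_key_and_significance_flag(self):
        universe = [f"g{i}" for i in range(30)]
        terms = (
            [TermAnnotation(g, "pathway", "T_STRONG", "strong") for g in universe[:8]]
            + [TermAnnotation(g, "pathway", "T_A", "null a") for g in universe[10:14]]
            + [TermAnnotation(g, "pathway", "T_B", "null b") for g in universe[14:18]]
        )
        results = hypergeom_enrich(universe[:8], terms, universe)
        df = report_enrichment(results, alpha_fdr=0.05)
        keys = list(zip(df["fdr"], df["p_value"], df["term_id"]))
        assert keys == sorted(keys)
        assert df.iloc[0]["term_id"] == "T_STRONG"
        assert bool(df.iloc[0]["significant"])
        # ties between the two null terms break deterministically by term_id
        nulls = df[df["term_id"].isin(["T_A", "T_B"])]
        assert list(nulls["term_id"]) == sorted(nulls["term_id"])

    def test_empty_significant_set_still_reported(self):
        universe = [f"g{i}" for i in range(30)]
        terms = [TermAnnotation(g, "pathway", "T", "t") for g in universe[15:20]]
        results = hypergeom_enrich(universe[:3], terms, universe)
        df = report_enrichment(results, alpha_fdr=0.05)
        assert len(df) == 1 and not df["significant"].any()
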