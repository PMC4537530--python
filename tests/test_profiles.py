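import numpy as np
import pytest

from acetyldiff.genomic_io import GeneRecord, GenomicInterval
from acetyldiff.peaks import ReadSet
from acetyldiff.profiles import (
    AggregateProfile,
    ProfileConfig,
    compute_profile,
    group_profile,
    profile_table,
)
from acetyldiff.synthetic import SyntheticCohort, SyntheticDesign

SIZES = {"chr1": 1_000_000}


def _uniform_reads(n, subject, role, length=100, chrom="chr1", span=1_000_000, seed=0):
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, span - length, size=n))
    ivs = [GenomicInterval(chrom, int(s), int(s) + length, "+") for s in starts]
    return ReadSet.from_intervals(ivs, f"{subject}_{role}", subject, role)


class TestComputeProfile:
    def test_identical_samples_give_exact_zero(self):
        rs = _uniform_reads(5000, "s1", "chip")
        anchors = [GeneRecord("g1", "chr1", "+", 500_000)]
        prof = compute_profile(rs, rs, anchors, ProfileConfig(), SIZES)
        assert np.all(prof.values == 0.0)

    def test_null_generated_pair_stays_small(self):
        # chip and input drawn from the same rate (default synthetic depths)
        d = SyntheticDesign(
            genome=(("chr1", 1_000_000),),
            n_shared_peaks=0, n_induced_peaks=0, n_suppressed_peaks=0,
            global_tss_fold_high=1.0, global_tss_fold_low=1.0, seed=21,
        )
        c = SyntheticCohort(d)
        chip = c.generate_reads("high_1", "chip")
        inp = c.generate_reads("high_1", "input")
        anchors = [g for g in c.truth.genes if g.chrom == "chr1"]
        prof = compute_profile(chip, inp, anchors, ProfileConfig(), d.chrom_sizes)
        assert np.max(np.abs(prof.values)) < 0.1

    def test_single_central_read_lands_in_bin_200(self):
        anchor = GeneRecord("g1", "chr1", "+", 500_000)
        chip = ReadSet.from_intervals(
            [GenomicInterval("chr1", 500_000, 500_100, "+")], "c", "s1", "chip"
        )
        inp = _uniform_reads(20_000, "s1", "input")
        prof = compute_profile(chip, inp, [anchor], ProfileConfig(), SIZES)
        assert prof.chip_counts.sum() == 1
        assert int(np.argmax(prof.chip_counts)) == 200

    def test_minus_strand_downstream_reads_appear_left_of_center(self):
        # for a minus-strand TSS, genomically-rightward reads are 5' of the
        # TSS... reads *left* in genome coordinates are downstream (3'), so
        # signal downstream in genome coordinates shows up left of center
        # after the 5'->3' flip
        anchor = GeneRecord("g1", "chr1", "-", 500_000)
        downstream = [  # genome coordinates right of the TSS
            GenomicInterval("chr1", 500_000 + off, 500_100 + off, "+")
            for off in range(100, 5000, 100)
        ]
        chip = ReadSet.from_intervals(downstream, "c", "s1", "chip")
        inp = _uniform_reads(20_000, "s1", "input")
        prof = compute_profile(chip, inp, [anchor], ProfileConfig(), SIZES)
        left, right = prof.chip_counts[:200].sum(), prof.chip_counts[200:].sum()
        assert left == len(downstream) and right == 0

    def test_mirror_symmetry_exact_under_strand_reversal(self):
        d = SyntheticDesign(seed=22)
        c = SyntheticCohort(d)
        chip = c.generate_reads("high_1", "chip")
        inp = c.generate_reads("high_1", "input")
        genes = c.truth.genes
        flipped = [
            GeneRecord(g.gene_id, g.chrom, "-" if g.strand == "+" else "+", g.tss)
            for g in genes
        ]
        a = compute_profile(chip, inp, genes, ProfileConfig(), d.chrom_sizes)
        b = compute_profile(chip, inp, flipped, ProfileConfig(), d.chrom_sizes)
        assert np.array_equal(a.values, b.values[::-1])

    def test_depth_invariance_under_read_duplication(self):
        import pandas as pd

        d = SyntheticDesign(seed=23)
        c = SyntheticCohort(d)
        chip = c.generate_reads("high_1", "chip")
        inp = c.generate_reads("high_1", "input")
        chip2 = ReadSet(
            "c2", "high_1", "chip",
            pd.concat([chip.df, chip.df], ignore_index=True),
        )
        inp2 = ReadSet(
            "i2", "high_1", "input",
            pd.concat([inp.df, inp.df], ignore_index=True),
        )
        cfg = ProfileConfig()
        a = compute_profile(chip, inp, c.truth.genes, cfg, d.chrom_sizes)
        b = compute_profile(chip2, inp2, c.truth.genes, cfg, d.chrom_sizes)
        assert np.array_equal(a.values, b.values)

    def test_bin_count_conservation(self):
        d = SyntheticDesign(seed=24)
        c = SyntheticCohort(d)
        chip = c.generate_reads("high_1", "chip")
        cfg = ProfileConfig()
        anchors = [g for g in c.truth.genes]
        prof = compute_profile(
            chip, c.generate_reads("high_1", "input"), anchors, cfg, d.chrom_sizes
        )
        kept_windows = 0
        for g in anchors:
            if g.tss - cfg.flank < 0 or g.tss + cfg.flank > d.chrom_sizes[g.chrom]:
                continue
            sub = chip.df[chip.df["chrom"] == g.chrom]
            kept_windows += int(
                (
                    (sub["start"] >= g.tss - cfg.flank)
                    & (sub["start"] < g.tss + cfg.flank)
                ).sum()
            )
        assert prof.chip_counts.sum() == kept_windows

    def test_edge_anchors_dropped_and_counted(self):
        anchors = [
            GeneRecord("edge", "chr1", "+", 2_000),  # window crosses 0
            GeneRecord("ok", "chr1", "+", 500_000),
        ]
        chip = _uniform_reads(1000, "s1", "chip")
        inp = _uniform_reads(1000, "s1", "input", seed=1)
        prof = compute_profile(chip, inp, anchors, ProfileConfig(), SIZES)
        assert prof.n_anchors == 1 and prof.n_dropped == 1
        with pytest.raises(ValueError, match="dropped"):
            compute_profile(
                chip, inp, [anchors[0]], ProfileConfig(), SIZES
            )

    def test_config_geometry_enforced(self):
        with pytest.raises(ValueError):
            ProfileConfig(flank=10_000, n_bins=100, bin_size=50)


class TestGroupProfile:
    def _profile(self, label, values):
        return AggregateProfile(
            anchor_type="tss", label=label, values=np.asarray(values, float),
            n_anchors=1, config=ProfileConfig(flank=50, n_bins=2, bin_size=50),
        )

    def test_identical_subjects_mean_is_identity(self):
        p = self._profile("s1", [1.0, -0.5])
        q = self._profile("s2", [1.0, -0.5])
        out = group_profile([p, q], {"s1": "high", "s2": "high"})
        assert np.array_equal(out["high"].values, p.values)

    def test_opposite_values_average_to_zero(self):
        p = self._profile("s1", [1.0, 1.0])
        q = self._profile("s2", [-1.0, -1.0])
        out = group_profile([p, q], {"s1": "high", "s2": "high"})
        assert np.array_equal(out["high"].values, [0.0, 0.0])

    def test_mixed_configs_rejected(self):
        p = self._profile("s1", [1.0, 0.0])
        q = AggregateProfile(
            anchor_type="tss", label="s2", values=np.zeros(4), n_anchors=1,
            config=ProfileConfig(flank=100, n_bins=4, bin_size=50),
        )
        with pytest.raises(ValueError):
            group_profile([p, q], {"s1": "high", "s2": "high"})

    def test_profile_table_layout(self):
        p = self._profile("s1", [0.25, 0.5])
        df = profile_table(p)
        assert list(df.columns) == ["bin_index", "offset_bp_from_anchor", "value"]
        assert list(df["offset_bp_from_anchor"]) == [-50, 0]
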