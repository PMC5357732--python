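"""Locus and boundary meta-profiles: binning, mirroring, ChIP/input ratios."""

import numpy as np
import pytest

from scnbound.genome import Segment, SegmentedGenome
from scnbound.profiles import ChipPair, chip_ratio, locus_profile, meta_profile
from scnbound.reads import AlignedRead, Library
from scnbound.simulate import SimConfig, make_genome, simulate_scnrna

from conftest import make_library, make_reads, reads_at_anchors


def naive_meta_counts(lib, genome, ies_type, bin_size, window, anchor_mode):
    """Independent oracle: per-read, per-boundary interval membership."""
    n_bins = 2 * window // bin_size
    sense = np.zeros(n_bins)
    anti = np.zeros(n_bins)
    use = [w for w in genome.boundaries(window)
           if w.eligible and w.ies_type == ies_type]
    for w in use:
        for rec in lib.reads.itertuples(index=False):
            if rec.chrom != w.chrom:
                continue
            a = AlignedRead(rec.chrom, rec.start, rec.end, rec.strand).anchor(
                anchor_mode
            )
            in_win = (w.outside[0] <= a < w.outside[1]) or (
                w.inside[0] <= a < w.inside[1]
            )
            if not in_win:
                continue
            if w.side == "left":
                off = a - w.boundary
                is_sense = rec.strand == "+"
            else:
                off = (w.boundary - 1) - a
                is_sense = rec.strand == "-"
            b = (off + window) // bin_size
            if is_sense:
                sense[b] += 1
            else:
                anti[b] += 1
    return sense, anti, len(use)


class TestLocusProfile:
    def test_single_read_lands_in_its_bin(self):
        lib = make_library(reads_at_anchors("chr1", [150]), scnrna_filter=True)
        p = locus_profile(lib, "chr1", 0, 1000, bin_size=100)
        expect = np.zeros(10)
        expect[1] = 1e6  # one read, RPM of a 1-read library
        np.testing.assert_allclose(p.sense, expect)
        np.testing.assert_allclose(p.antisense, np.zeros(10))

    def test_anchor_on_bin_edge_goes_to_upper_bin(self):
        lib = make_library(reads_at_anchors("chr1", [200]), scnrna_filter=True)
        p = locus_profile(lib, "chr1", 0, 1000, bin_size=100,
                          value_kind="raw_count")
        assert p.sense[2] == 1 and p.sense[1] == 0

    def test_uniform_coverage_within_binomial_tolerance(self):
        rng = np.random.default_rng(42)
        n = 10_000
        anchors = rng.integers(0, 2000, size=n)
        lib = make_library(reads_at_anchors("chr1", anchors),
                           scnrna_filter=True)
        p = locus_profile(lib, "chr1", 0, 2000, bin_size=100,
                          value_kind="raw_count")
        n_bins = 20
        mean = n / n_bins
        sd = np.sqrt(n * (1 / n_bins) * (1 - 1 / n_bins))
        assert np.all(np.abs(p.sense - mean) < 3 * sd + 1)

    def test_region_outside_genome_errors(self, toy_genome):
        lib = make_library(reads_at_anchors("chr1", [10]), scnrna_filter=True)
        with pytest.raises(ValueError, match="outside"):
            locus_profile(lib, "chr1", 0, 20_000, genome=toy_genome)

    def test_strands_split(self):
        recs = reads_at_anchors("chr1", [50], "+") + reads_at_anchors(
            "chr1", [50], "-"
        )
        lib = make_library(recs, scnrna_filter=True)
        p = locus_profile(lib, "chr1", 0, 100, bin_size=100,
                          value_kind="raw_count")
        assert p.sense[0] == 1 and p.antisense[0] == 1


class TestMetaProfile:
    def test_mirrored_right_boundary_hand_trace(self, toy_genome):
        # + read 5'-anchored at 3100, IES_A [1000,3000): only the right
        # boundary sees it, at offset (3000-1)-3100 = -101 (outside),
        # strand flipped to antisense after mirroring.
        lib = make_library(reads_at_anchors("chr1", [3100], "+"),
                           scnrna_filter=True)
        p = meta_profile(lib, toy_genome, "A", bin_size=10, window=500,
                         anchor_mode="five_prime", value_kind="raw_count")
        expect_bin = (-101 + 500) // 10  # 39, covering offsets -110..-101
        assert p.antisense[expect_bin] == 1
        assert p.antisense.sum() == 1 and p.sense.sum() == 0
        assert p.offsets()[expect_bin] == -110

    def test_reads_confined_inside_leave_outside_bins_empty(self, toy_genome):
        anchors = [1200, 1800, 2500, 2900]
        lib = make_library(reads_at_anchors("chr1", anchors),
                           scnrna_filter=True)
        p = meta_profile(lib, toy_genome, "A", value_kind="raw_count",
                         anchor_mode="five_prime")
        outside = p.offsets() < 0
        assert p.total()[outside].sum() == 0
        assert p.total().sum() > 0

    def test_no_eligible_boundaries_errors(self):
        segs = [
            Segment("chr1", 0, 1000, "MDS"),
            Segment("chr1", 1000, 1200, "IES_A", "tiny"),
            Segment("chr1", 1200, 3000, "MDS"),
        ]
        g = SegmentedGenome({"chr1": 3000}, segs)
        lib = make_library(reads_at_anchors("chr1", [1100]),
                           scnrna_filter=True)
        with pytest.raises(ValueError, match="type-A"):
            meta_profile(lib, g, "A")

    def test_oracle_equivalence_on_small_genome(self):
        cfg = SimConfig(seed=7, n_chrom=1, chrom_length=80_000, n_ies_A=4,
                        n_ies_B=3, n_reads=3000, ies_length_range=(800, 2500),
                        mds_length_range=(1500, 4000))
        g = make_genome(cfg)
        lib = simulate_scnrna(cfg, g)
        for ies_type in ("A", "B"):
            p = meta_profile(lib, g, ies_type, value_kind="raw_count",
                             anchor_mode="nt13")
            sense, anti, n_b = naive_meta_counts(lib, g, ies_type, 10, 500,
                                                 "nt13")
            np.testing.assert_array_equal(p.sense, sense)
            np.testing.assert_array_equal(p.antisense, anti)
            assert p.n_boundaries == n_b

    def test_conservation_of_anchor_counts(self, toy_genome):
        rng = np.random.default_rng(3)
        anchors = rng.integers(0, 10_000, size=2000)
        strands = np.where(rng.random(2000) < 0.5, "+", "-")
        recs = []
        for a, s in zip(anchors, strands):
            recs += reads_at_anchors("chr1", [a], s)
        lib = make_library(recs, scnrna_filter=True)
        p = meta_profile(lib, toy_genome, "A", value_kind="raw_count",
                         anchor_mode="five_prime")
        wins = [w for w in toy_genome.boundaries(500)
                if w.eligible and w.ies_type == "A"]
        expected = sum(
            int(np.sum((anchors >= lo) & (anchors < hi)))
            for w in wins for lo, hi in (w.outside, w.inside)
        )
        assert p.total().sum() == expected

    def test_symmetric_coverage_gives_symmetric_profile(self, toy_genome):
        # equal counts at +/-d around each boundary of the type-A IES
        recs = []
        for b in (1000, 3000):
            for d in (5, 105, 255, 495):
                recs += reads_at_anchors("chr1", [b + d, b - 1 - d], "+")
        lib = make_library(recs, scnrna_filter=True)
        p = meta_profile(lib, toy_genome, "A", value_kind="raw_count",
                         anchor_mode="five_prime")
        np.testing.assert_array_equal(p.total(), p.total()[::-1])


class TestChipRatio:
    def _pair(self, chip_recs, input_recs):
        return ChipPair(
            chip=make_library(chip_recs, name="chip"),
            input=make_library(input_recs, name="input"),
        )

    def test_ratio_of_rpm(self):
        # 2 chip reads vs 1 input read in bin 0, equal library sizes:
        # chip RPM 4.0-like ratio = 2.0 after size normalization
        chip = reads_at_anchors("chr1", [10, 20], "+") + reads_at_anchors(
            "chr1", [900, 910], "+"
        )
        inp = reads_at_anchors("chr1", [30], "+") + reads_at_anchors(
            "chr1", [920, 930, 940], "+"
        )
        pair = self._pair(chip, inp)
        p = chip_ratio(pair, mode="locus", chrom="chr1", start=0, end=1000,
                       bin_size=500, anchor_mode="five_prime")
        assert p.sense[0] == pytest.approx(2.0)

    def test_zero_input_bin_is_masked_not_zero_or_inf(self):
        chip = reads_at_anchors("chr1", [10], "+")
        inp = reads_at_anchors("chr1", [600], "+")
        pair = self._pair(chip, inp)
        p = chip_ratio(pair, mode="locus", chrom="chr1", start=0, end=1000,
                       bin_size=500, anchor_mode="five_prime")
        assert p.mask[0] and not p.mask[1]
        assert np.isnan(p.sense[0])
        assert p.sense[1] == 0.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            self._pair([], reads_at_anchors("chr1", [0]))


class TestMirrorInvariance:
    @staticmethod
    def reflect(genome, reads):
        """Reflect every chromosome (and its reads) end-for-end."""
        segs = []
        for chrom, ss in genome.segments.items():
            L = genome.chrom_lengths[chrom]
            for s in ss:
                segs.append(Segment(chrom, L - s.end, L - s.start, s.label,
                                    s.ies_id))
        g2 = SegmentedGenome(dict(genome.chrom_lengths), segs)
        df = reads.copy()
        lengths = {c: genome.chrom_lengths[c] for c in df["chrom"].unique()}
        L = df["chrom"].map(lengths)
        start, end = df["start"].copy(), df["end"].copy()
        df["start"] = L - end
        df["end"] = L - start
        df["strand"] = np.where(df["strand"] == "+", "-", "+")
        return g2, df

    def test_reflection_preserves_meta_profile(self):
        cfg = SimConfig(seed=19, n_chrom=2, chrom_length=100_000, n_ies_A=5,
                        n_ies_B=4, n_reads=5000)
        g = make_genome(cfg)
        lib = simulate_scnrna(cfg, g)
        g2, reads2 = self.reflect(g, lib.reads)
        lib2 = Library.from_reads(reads2, scnrna_filter=True)
        for mode in ("five_prime", "nt13"):
            p1 = meta_profile(lib, g, "A", anchor_mode=mode,
                              value_kind="raw_count")
            p2 = meta_profile(lib2, g2, "A", anchor_mode=mode,
                              value_kind="raw_count")
            np.testing.assert_array_equal(p1.sense, p2.sense)
            np.testing.assert_array_equal(p1.antisense, p2.antisense)

    def test_double_reflection_is_identity(self, toy_genome):
        lib = make_library(
            reads_at_anchors("chr1", [1100, 2950, 3100], "+")
            + reads_at_anchors("chr1", [900, 1400], "-"),
            scnrna_filter=True,
        )
        g2, r2 = self.reflect(toy_genome, lib.reads)
        g3, r3 = self.reflect(g2, r2)
        assert g3.all_segments() == toy_genome.all_segments()
        np.testing.assert_array_equal(
            r3.sort_values("start")[["start", "end"]].to_numpy(),
            lib.reads.sort_values("start")[["start", "end"]].to_numpy(),
        )
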