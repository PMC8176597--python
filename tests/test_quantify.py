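import numpy as np
import pandas as pd
import pytest

from tetrace.annotations_io import FragmentAlignment, GenomicInterval, TEFeature
from tetrace.quantify import (
    LibraryStats,
    average_replicates,
    count_fractional,
    coverage_fpkm,
    fpkm_from_counts,
    genome_coverage,
)

from .oracles import brute_force_fractional_counts, brute_force_pileup


def te(fid, start, end, chrom="chr1"):
    return TEFeature(fid, fid, "LTR/ERV", GenomicInterval(chrom, start, end))


def frag(fid, hits, n_hits=None):
    blocks = [[GenomicInterval(c, s, e) for c, s, e in hit] for hit in hits]
    return FragmentAlignment(fid, blocks, n_hits or len(hits))


class TestCountFractional:
    def test_double_overlap_splits_evenly(self):
        """One unique fragment overlapping two features by >=30 nt gives each 0.5."""
        feats = [te("A", 0, 150), te("B", 120, 300)]
        f = frag("f1", [[("chr1", 100, 200)]])
        counts = count_fractional([f], feats)
        assert counts["A"] == pytest.approx(0.5)
        assert counts["B"] == pytest.approx(0.5)

    def test_multihit_splits_across_hits(self):
        """A 2-hit fragment whose second hit overlaps nothing contributes 0.5."""
        feats = [te("A", 0, 200)]
        f = frag("f1", [[("chr1", 50, 150)], [("chr1", 5000, 5100)]], n_hits=2)
        counts = count_fractional([f], feats)
        assert counts["A"] == pytest.approx(0.5)

    def test_below_min_overlap_contributes_zero(self):
        feats = [te("A", 0, 129)]
        f = frag("f1", [[("chr1", 100, 200)]])  # 29 nt inside A
        assert count_fractional([f], feats)["A"] == 0.0

    def test_mate_overlap_bases_counted_once(self):
        """Two mates overlapping the same 25 nt of a feature must not reach a
        30 nt threshold by double-counting."""
        feats = [te("A", 0, 125)]
        f = frag("f1", [[("chr1", 100, 200), ("chr1", 100, 200)]])
        assert count_fractional([f], feats)["A"] == 0.0

    def test_conservation_upper_bound(self):
        """A fragment's total contribution across features never exceeds 1 and
        equals 1 when every hit overlaps a feature."""
        feats = [te("A", 0, 200), te("B", 150, 400), te("C", 1000, 1300)]
        f = frag("f1", [[("chr1", 100, 200)], [("chr1", 1050, 1150)]], n_hits=2)
        counts = count_fractional([f], feats)
        assert counts.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("instance_seed", range(50))
    def test_matches_brute_force_oracle(self, instance_seed):
        """Exact agreement with a per-base all-pairs enumeration oracle on
        random instances (<=100 fragments x <=20 features)."""
        rng = np.random.default_rng(instance_seed)
        n_feat = rng.integers(1, 21)
        raw_feats = []
        for i in range(n_feat):
            s = int(rng.integers(0, 2000))
            raw_feats.append((f"F{i}", "chr1", s, s + int(rng.integers(40, 400))))
        feats = [te(fid, s, e) for fid, _, s, e in raw_feats]
        raw_frags = []
        for j in range(int(rng.integers(1, 101))):
            n_hits = int(rng.integers(1, 4))
            hits = []
            for _ in range(n_hits):
                s = int(rng.integers(0, 2200))
                blocks = [("chr1", s, s + 100)]
                if rng.random() < 0.5:  # paired, mates may overlap
                    s2 = s + int(rng.integers(50, 150))
                    blocks.append(("chr1", s2, s2 + 100))
                hits.append(blocks)
            raw_frags.append((n_hits, hits))
        expected = brute_force_fractional_counts(raw_frags, raw_feats)
        frags = [
            frag(f"f{j}", hits, n_hits) for j, (n_hits, hits) in enumerate(raw_frags)
        ]
        got = count_fractional(frags, feats)
        for fid, _, _, _ in raw_feats:
            assert got[fid] == pytest.approx(expected[fid], abs=1e-12)


class TestFpkmFromCounts:
    def test_direct_arithmetic(self):
        """count 10 over a 1 kb feature in a 1 M-fragment library is 10 FPKM."""
        feats = [te("A", 0, 1000)]
        counts = pd.Series({"A": 10.0})
        st = LibraryStats("lib", 1_000_000)
        assert fpkm_from_counts(counts, feats, st)["A"] == pytest.approx(10.0)

    def test_zero_count_and_linearity(self):
        feats = [te("A", 0, 1000)]
        counts = pd.DataFrame({"l1": {"A": 8.0}, "l2": {"A": 8.0}})
        stats = {"l1": LibraryStats("l1", 10**6), "l2": LibraryStats("l2", 2 * 10**6)}
        out = fpkm_from_counts(counts, feats, stats)
        assert out.loc["A", "l1"] == pytest.approx(2 * out.loc["A", "l2"])
        assert fpkm_from_counts(pd.Series({"A": 0.0}), feats, stats["l1"])["A"] == 0

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            LibraryStats("lib", 0)


class TestGenomeCoverage:
    def test_stacked_fragments(self):
        f1 = frag("a", [[("chr1", 100, 200)]])
        f2 = frag("b", [[("chr1", 100, 200)]])
        track = genome_coverage([f1, f2])
        assert track.region_sum(GenomicInterval("chr1", 100, 200)) == 200
        assert track.region_sum(GenomicInterval("chr1", 200, 300)) == 0
        assert track.total() == 200  # mass = summed block lengths

    def test_empty_alignments(self):
        assert genome_coverage([]).total() == 0

    def test_matches_naive_pileup_and_mass_balance(self):
        """Random alignments: depth equals the per-base pileup oracle and the
        track mass equals the summed block lengths."""
        rng = np.random.default_rng(7)
        raw_frags = []
        for _ in range(60):
            hits = []
            for _ in range(int(rng.integers(1, 3))):
                s = int(rng.integers(0, 900))
                hits.append([("chr1", s, s + 100)])
            raw_frags.append((len(hits), hits))
        frags = [frag(f"f{i}", h, n) for i, (n, h) in enumerate(raw_frags)]
        track = genome_coverage(frags, {"chr1": 1000})
        oracle = brute_force_pileup(raw_frags, {"chr1": 1000})
        assert track.depth["chr1"].tolist() == oracle["chr1"]
        total_block = sum(e - s for _, h in raw_frags for hit in h for _, s, e in hit)
        assert track.total() == total_block


class TestCoverageFpkm:
    def test_methods_formula(self):
        """5 fully contained 100 nt reads in a 500 nt element at library size
        10^6: C=500, FPKM = 500e9 / (100 * 500 * 1e6) = 10."""
        ltr = GenomicInterval("chr1", 1000, 1500)
        frags = [frag(f"f{i}", [[("chr1", 1000 + 50 * i, 1100 + 50 * i)]]) for i in range(5)]
        track = genome_coverage(frags)
        st = LibraryStats("lib", 1_000_000, read_length=100)
        assert coverage_fpkm(track, ltr, st) == pytest.approx(10.0)

    def test_zero_coverage(self):
        track = genome_coverage([])
        assert coverage_fpkm(track, GenomicInterval("chr1", 0, 500), LibraryStats("l", 10)) == 0

    def test_identity_with_count_fpkm_for_contained_unique_reads(self):
        """For unique-mapping fragments fully inside the element the two FPKM
        definitions coincide exactly (C = count x read length)."""
        rng = np.random.default_rng(3)
        ltr = te("L", 5000, 5800)
        frags = []
        for i in range(137):
            s = int(rng.integers(5000, 5800 - 200 + 1))
            frags.append(frag(f"f{i}", [[("chr1", s, s + 100), ("chr1", s + 100, s + 200)]]))
        st = LibraryStats("lib", 314_159, read_length=200)  # 200 aligned nt per fragment
        cov = coverage_fpkm(genome_coverage(frags), ltr.interval, st)
        cnt = fpkm_from_counts(count_fractional(frags, [ltr]), [ltr], st)["L"]
        assert cov == pytest.approx(cnt, rel=1e-12)


class TestAverageReplicates:
    def test_mean_and_idempotence(self):
        expr = pd.DataFrame({"t1_r1": {"A": 4.0}, "t1_r2": {"A": 6.0}, "t2_r1": {"A": 1.0}})
        design = {"t1_r1": "t1", "t1_r2": "t1", "t2_r1": "t2"}
        avg = average_replicates(expr, design)
        assert avg.loc["A", "t1"] == 5.0
        assert avg.loc["A", "t2"] == 1.0  # single replicate is identity
        again = average_replicates(avg, {"t1": "t1", "t2": "t2"})
        pd.testing.assert_frame_equal(avg, again)

    def test_unmapped_library_rejected(self):
        expr = pd.DataFrame({"t1_r1": {"A": 4.0}})
        with pytest.raises(ValueError):
            average_replicates(expr, {})
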