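import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetrace.annotations_io import GeneFeature, GenomicInterval, TEFeature
from tetrace.filtering import (
    FilterConfig,
    classify_proximity,
    exclude_gene_overlaps,
    filter_dynamic,
)


def gene(gid, start, end, strand="+", biotype="coding"):
    return GeneFeature(gid, gid, biotype, GenomicInterval("chr1", start, end, strand))


def ltr(fid, start, end):
    return TEFeature(fid, fid, "LTR/ERV", GenomicInterval("chr1", start, end))


class TestFilterDynamic:
    def test_constant_and_zero_profiles_excluded(self):
        expr = pd.DataFrame(
            {
                f"t{i}": {"const": 50.0, "zero": 0.0, "dyn": v}
                for i, v in enumerate([1, 80, 80, 1, 1, 1, 1])
            }
        )
        kept = filter_dynamic(expr, FilterConfig(min_fpkm=20, min_sd=20))
        assert kept == ["dyn"]

    def test_comparator_boundary(self):
        """'at least' keeps a feature sitting exactly on the threshold,
        'more than' drops it."""
        expr = pd.DataFrame([[5.0, 0.0, 0.0]], index=["x"], columns=list("abc"))
        sd = expr.loc["x"].std()  # ~2.887
        at_least = FilterConfig(min_fpkm=5, min_sd=float(sd), comparator=">=")
        more_than = FilterConfig(min_fpkm=5, min_sd=float(sd), comparator=">")
        assert filter_dynamic(expr, at_least) == ["x"]
        assert filter_dynamic(expr, more_than) == []

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            filter_dynamic(pd.DataFrame({"only": {"a": 1.0}}), FilterConfig(1, 1))

    @settings(deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.lists(st.floats(0, 100), min_size=7, max_size=7), min_size=1, max_size=12
        ),
        lo=st.floats(0, 30),
        hi=st.floats(0, 30),
    )
    def test_monotone_in_thresholds(self, data, lo, hi):
        """Raising either threshold never adds a feature to the kept set."""
        expr = pd.DataFrame(data, index=[f"f{i}" for i in range(len(data))])
        lo_fpkm, hi_fpkm = sorted((lo, hi))
        base = set(filter_dynamic(expr, FilterConfig(lo_fpkm, lo_fpkm)))
        tighter = set(filter_dynamic(expr, FilterConfig(hi_fpkm, hi_fpkm)))
        assert tighter <= base


class TestExcludeGeneOverlaps:
    def test_contained_te_excluded_abutting_kept(self):
        genes = [gene("g", 1000, 2000)]
        inside = ltr("inside", 1200, 1400)
        abutting = ltr("abutting", 2000, 2300)  # half-open adjacency: 0 shared bases
        noncoding_hit = ltr("nc_hit", 100, 300)
        genes.append(gene("nc", 150, 250, biotype="noncoding"))
        kept = exclude_gene_overlaps([inside, abutting, noncoding_hit], genes)
        assert kept == ["abutting", "nc_hit"]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        genes = [
            gene(f"g{i}", s, s + int(rng.integers(100, 1000)))
            for i, s in enumerate(rng.integers(0, 20_000, size=15))
        ]
        tes = [
            ltr(f"t{i}", s, s + int(rng.integers(50, 600)))
            for i, s in enumerate(rng.integers(0, 20_000, size=40))
        ]
        expected = [
            t.te_id
            for t in tes
            if all(t.interval.overlap_len(g.interval) == 0 for g in genes)
        ]
        assert exclude_gene_overlaps(tes, genes) == expected


class TestClassifyProximity:
    def test_distance_boundary(self):
        """Gap 4999 is near-gene (strict < 5000); gap 5000 is solo."""
        genes = [gene("g", 100_000, 102_000)]
        near = ltr("near", 102_000 + 4999, 102_000 + 4999 + 500)
        solo = ltr("solo", 102_000 + 5000, 102_000 + 5000 + 500)
        calls = {c.ltr_id: c for c in classify_proximity([near, solo], genes)}
        assert calls["near"].status == "near-gene"
        assert calls["near"].distance == 4999
        assert calls["solo"].status == "solo"

    def test_overlap_and_no_gene_chromosome(self):
        genes = [gene("g", 1000, 2000)]
        over = ltr("over", 1500, 1900)
        lonely = TEFeature("lonely", "lonely", "LTR/ERV", GenomicInterval("chr2", 0, 500))
        calls = {c.ltr_id: c for c in classify_proximity([over, lonely], genes)}
        assert calls["over"].status == "overlapping-gene"
        assert calls["over"].distance == 0
        assert calls["lonely"].status == "solo"
        assert math.isinf(calls["lonely"].distance)

    def test_upstream_of_minus_strand_gene(self):
        """An LTR 3 kb 5' of a minus-strand gene lies beyond its TSS (the
        gene's end), so the flag is set."""
        genes = [gene("g", 10_000, 12_000, strand="-")]
        upstream = ltr("up", 15_000, 15_500)  # 3 kb past the gene end = 5' side
        downstream = ltr("down", 6_500, 7_000)
        calls = {c.ltr_id: c for c in classify_proximity([upstream, downstream], genes)}
        assert calls["up"].status == "near-gene" and calls["up"].upstream_flag
        assert not calls["down"].upstream_flag

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        genes = [gene(f"g{i}", s, s + 2000) for i, s in enumerate(range(0, 50_000, 10_000))]
        ltrs = [
            ltr(f"l{i}", int(s), int(s) + 400)
            for i, s in enumerate(rng.integers(0, 80_000, size=30))
        ]
        calls = classify_proximity(ltrs, genes)
        assert len(calls) == len(ltrs)
        assert all(c.status in ("overlapping-gene", "near-gene", "solo") for c in calls)
        for c in calls:
            if c.status == "near-gene":
                assert 0 < c.distance < 5000
            elif c.status == "solo":
                assert c.distance >= 5000
            else:
                assert c.distance == 0


class TestCascadeOnSyntheticData:
    def test_recovers_planted_dynamic_ltrs(self, pipeline_result):
        """Under the default noise model the LTR cascade keeps >=95% of the
        planted dynamic LTR-class features and no planted constant ones."""
        m = pipeline_result.metrics
        assert m["filter_recall"] >= 0.95
        assert m["constant_kept"] == 0

    def test_deterministic_mode_recovers_exactly(self, deterministic_study, tmp_path):
        from tetrace.annotations_io import read_gtf, read_repeatmasker_out
        from tetrace.pipeline import run_filter, run_quantify

        study = deterministic_study
        tes = read_repeatmasker_out(study.te_out)
        genes = read_gtf(study.gene_gtf)
        manifest = pd.read_csv(study.library_manifest, sep="\t")
        quant = run_quantify(study.sam_files, tes, genes, manifest)
        filt = run_filter(quant, tes, genes)
        truth = study.truth
        ltr_classes = {"solo_ltr", "erv_ltr", "erv_int"}
        planted = truth.dynamic_ids(ltr_classes)
        assert set(filt.kept_ltrs) == planted
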