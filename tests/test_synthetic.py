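import filecmp

import pandas as pd
import pytest

from tetrace.annotations_io import read_alignments, read_gtf, read_repeatmasker_out
from tetrace.quantify import count_fractional, fpkm_from_counts
from tetrace.synthetic import (
    DYNAMIC_PROGRAMS,
    SimulationConfig,
    simulate,
    truth_report,
)


def small_cfg(**kw):
    """A reduced census for fast structural tests."""
    defaults = dict(
        seed=7,
        n_genes=10,
        n_solo_ltrs=8,
        n_ervs=2,
        n_lines_sines=4,
        n_tfs=8,
        n_near_gene_ltrs=2,
        library_size=300_000,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulate:
    def test_same_seed_byte_identical(self, tmp_path):
        a = simulate(small_cfg(), tmp_path / "a")
        b = simulate(small_cfg(), tmp_path / "b")
        for name in ["genes.gtf", "repeats.out", "go_map.tsv", "libraries.tsv", "tp1_r1.sam"]:
            assert filecmp.cmp(a.outdir / name, b.outdir / name, shallow=False), name

    def test_emitted_files_parse_and_match_truth(self, tmp_path):
        study = simulate(small_cfg(), tmp_path)
        tes = read_repeatmasker_out(study.te_out)
        genes = read_gtf(study.gene_gtf)
        assert {t.te_id for t in tes} | {g.gene_id for g in genes} == set(
            study.truth.program
        )
        by_id = {t.te_id: t.interval for t in tes}
        by_id.update({g.gene_id: g.interval for g in genes})
        for t in study.tes:
            assert by_id[t.te_id] == t.interval

    def test_no_multimappers_when_fraction_zero(self, tmp_path):
        study = simulate(small_cfg(multimap_fraction=0.0), tmp_path)
        frags = list(read_alignments(study.sam_files["tp2_r1"]))
        assert frags
        assert all(f.n_hits == 1 for f in frags)

    def test_multimappers_are_erv_ltr_structural(self, tmp_path):
        study = simulate(small_cfg(), tmp_path)
        partners = study.truth.multimap_partners
        frags = list(read_alignments(study.sam_files["tp2_r1"]))
        multi = [f for f in frags if f.n_hits == 2]
        assert multi, "transient timepoint should emit ERV multi-mappers"
        ltr_ivs = {
            fid: next(t.interval for t in study.tes if t.te_id == fid)
            for fid in partners
        }
        for f in multi:
            src = f.fragment_id.split(":")[1]
            assert src in partners
            # second hit falls inside the homologous partner copy
            piv = ltr_ivs[partners[src]]
            blocks = f.hits[1]
            assert all(piv.start <= b.start and b.end <= piv.end for b in blocks)

    def test_fragment_longer_than_feature_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="fragment length"):
            simulate(small_cfg(sine_length=150), tmp_path)

    def test_deterministic_mode_recovers_true_fpkm(self, deterministic_study):
        """Zero-noise counts pushed through counting + FPKM reproduce the
        planted trajectories for unique-mapping features, up to the
        one-fragment rounding granularity."""
        study = deterministic_study
        cfg = study.config
        tes = read_repeatmasker_out(study.te_out)
        genes = read_gtf(study.gene_gtf)
        solo = [t for t in tes if t.te_id.startswith("SoloLTR")]
        from tetrace.quantify import LibraryStats

        lib = "tp2_r1"
        frags = list(read_alignments(study.sam_files[lib]))
        counts = count_fractional(frags, solo)
        st = LibraryStats(lib, cfg.library_size, cfg.read_length)
        fpkm = fpkm_from_counts(counts, solo, st)
        for t in solo:
            true = study.truth.true_fpkm.loc[t.te_id, "tp2"]
            granularity = 1e9 / (t.interval.length * cfg.library_size)
            assert fpkm[t.te_id] == pytest.approx(true, abs=0.51 * granularity)


class TestTruthReport:
    def test_perfect_outputs_score_one(self, tmp_path):
        study = simulate(small_cfg(), tmp_path)
        truth = study.truth
        planted = truth.dynamic_ids()
        metrics = truth_report(truth, kept_ids=planted)
        assert metrics["filter_recall"] == 1.0
        assert metrics["filter_precision"] == 1.0
        assert metrics["constant_kept"] == 0.0
        program_codes = {p: i for i, p in enumerate(sorted(set(truth.program.values())))}
        perfect = pd.Series(
            {fid: program_codes[truth.program[fid]] for fid in truth.program}
        )
        assert truth_report(truth, assignment=perfect)["cluster_purity"] == 1.0

    def test_random_assignment_purity_near_max_class_share(self, tmp_path):
        """Random labels over 3 balanced planted groups give purity near the
        max-class share (1/3, plus small-sample inflation)."""
        import numpy as np

        study = simulate(small_cfg(n_solo_ltrs=30, n_near_gene_ltrs=0), tmp_path)
        truth = study.truth
        ids = [f for f, c in truth.feature_class.items() if c == "solo_ltr"]
        programs = pd.Series({f: truth.program[f] for f in ids})
        balanced = [
            f for prog in DYNAMIC_PROGRAMS for f in programs.index[programs == prog][:6]
        ]
        rng = np.random.default_rng(0)
        purities = []
        for _ in range(200):
            rand = pd.Series(rng.integers(0, 3, size=len(balanced)), index=balanced)
            purities.append(truth_report(truth, assignment=rand)["cluster_purity"])
        assert 1 / 3 < np.mean(purities) < 0.55

    def test_unknown_ids_rejected(self, tmp_path):
        study = simulate(small_cfg(), tmp_path)
        with pytest.raises(ValueError):
            truth_report(study.truth, kept_ids={"who"})

    def test_shuffled_tf_profiles_lose_top_rank(self, tmp_path):
        """Negative control: if the reported top cluster excludes the planted
        activators the recovery metric drops to zero."""
        study = simulate(small_cfg(), tmp_path)
        metrics = truth_report(study.truth, top_tf_cluster=["TFC1", "TFC2"])
        assert metrics["activator_tfs_in_top_cluster"] == 0.0
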