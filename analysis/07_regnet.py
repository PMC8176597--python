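"""Regulatory inference: filter motif-derived TF candidates for dynamic
expression, correlate them with the transiently activated LTR clusters over
the 7 timepoint averages, and bicluster the correlation matrix."""

from common import SEED, STUDY_DIR, RESULTS, outdir
from tetrace.pipeline import (
    load_clusters,
    load_filter,
    load_quantify,
    load_study_inputs,
    run_regnet,
)
from tetrace.regnet import significance_boundary
from tetrace.synthetic import GroundTruth, truth_report


def main() -> None:
    tes, genes, _, _ = load_study_inputs(STUDY_DIR)
    quant = load_quantify(STUDY_DIR, RESULTS / "quant")
    clusters = load_clusters(RESULTS / "cluster", seed=SEED)
    filt = load_filter(RESULTS / "filter")
    tf_candidates = (STUDY_DIR / "tf_candidates.txt").read_text().split()
    res = run_regnet(quant, clusters, tf_candidates, genes, tes, filt, outdir("regnet"))

    print(f"{len(res.kept_tfs)} of {len(tf_candidates)} TF candidates pass the 5/5 filter")
    print(f"{len(res.transient_ltrs)} LTRs in the transient clusters")
    boundary = significance_boundary(7, 0.05)
    n_sig = int((res.corr.p < 0.05).sum().sum())
    print(f"two-sided 5% boundary at n=7: r = {boundary:.4f}; "
          f"{n_sig}/{res.corr.p.size} TF-LTR pairs significant at 5%")
    print(f"top bicluster row group: {', '.join(res.top_cluster)}")

    truth = GroundTruth.load(STUDY_DIR)
    m = truth_report(truth, top_tf_cluster=res.top_cluster)
    print(f"planted activators recovered in top cluster: "
          f"{m['activator_tfs_in_top_cluster']:.2f}")


if __name__ == "__main__":
    main()
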