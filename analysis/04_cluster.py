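"""Cluster the kept features' replicate-averaged temporal profiles with a
self-organizing map, per feature class (genes / TEs / LTRs)."""

import pandas as pd

from common import SEED, STUDY_DIR, RESULTS, outdir
from tetrace.pipeline import load_filter, load_quantify, run_cluster
from tetrace.synthetic import GroundTruth, truth_report


def main() -> None:
    quant = load_quantify(STUDY_DIR, RESULTS / "quant")
    filt = load_filter(RESULTS / "filter")
    clusters = run_cluster(quant, filt, seed=SEED, outdir=outdir("cluster"))
    truth = GroundTruth.load(STUDY_DIR)
    for cls in ("genes", "tes", "ltrs"):
        som = clusters.som[cls]
        sizes = som.assignment.value_counts().sort_index()
        purity = truth_report(truth, assignment=som.assignment)["cluster_purity"]
        print(f"{cls}: grid {som.grid_shape}, cluster sizes "
              f"{sizes.to_dict()}, purity vs planted programs {purity:.3f}")


if __name__ == "__main__":
    main()
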