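"""Genomic context of the kept LTR elements: overlapping a gene, near a
gene (< 5 kb) or solo; near-gene LTRs are correlated with their neighbour
gene's temporal profile."""

import pandas as pd

from common import STUDY_DIR, RESULTS, outdir
from tetrace.filtering import classify_proximity, proximity_table
from tetrace.pipeline import load_filter, load_quantify, load_study_inputs
from tetrace.regnet import correlate_pairs


def main() -> None:
    tes, genes, _, _ = load_study_inputs(STUDY_DIR)
    filt = load_filter(RESULTS / "filter")
    quant = load_quantify(STUDY_DIR, RESULTS / "quant")
    by_id = {t.te_id: t for t in tes}
    calls = classify_proximity([by_id[i] for i in filt.kept_ltrs], genes)
    out = outdir("context")
    proximity_table(calls).to_csv(out / "ltr_context.tsv", sep="\t")
    status = pd.Series([c.status for c in calls]).value_counts()
    print("LTR genomic context:")
    print(status.to_string())

    pairs = [(c.ltr_id, c.nearest_gene_id) for c in calls if c.status == "near-gene"]
    near = correlate_pairs(quant.averaged("ltr"), quant.averaged("gene"), pairs)
    near.to_csv(out / "near_gene_correlation.tsv", sep="\t")
    if len(near):
        print(f"near-gene LTR/neighbour correlations: median r = {near['r'].median():.3f}")


if __name__ == "__main__":
    main()
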