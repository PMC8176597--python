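"""Quantify expression: fractional fragment counts over TEs and genes,
count-based FPKM for both, and per-base-coverage FPKM for LTR elements
(the sensitive quantification short LTRs need)."""

from common import STUDY_DIR, outdir
from tetrace.pipeline import load_study_inputs, run_quantify


def main() -> None:
    tes, genes, manifest, sams = load_study_inputs(STUDY_DIR)
    quant = run_quantify(sams, tes, genes, manifest, outdir("quant"))
    ltr_avg = quant.averaged("ltr")
    print(f"quantified {len(quant.te_counts)} TEs and {len(quant.gene_fpkm)} genes "
          f"across {quant.te_counts.shape[1]} libraries")
    print("coverage-FPKM of LTR elements, timepoint averages (head):")
    print(ltr_avg.head().round(2).to_string())


if __name__ == "__main__":
    main()
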