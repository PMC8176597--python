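"""Generate the toy reprogramming study: 7 timepoints x 2 replicates of
2x100 nt pairs over a 1 Mb genome carrying genes, solo LTRs, full ERVs,
LINEs/SINEs and TF genes with planted temporal programs."""

import pandas as pd

from common import SEED, STUDY_DIR
from tetrace.synthetic import SimulationConfig, simulate


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    study = simulate(cfg, STUDY_DIR)
    manifest = pd.read_csv(study.library_manifest, sep="\t")
    programs = pd.Series(study.truth.program).value_counts()
    print(f"study written to {study.outdir}")
    print(f"{len(study.genes)} genes, {len(study.tes)} TE copies, "
          f"{len(manifest)} libraries "
          f"(~{manifest['aligned_fragments'].mean():,.0f} aligned fragments each)")
    print("planted programs:")
    print(programs.to_string())


if __name__ == "__main__":
    main()
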