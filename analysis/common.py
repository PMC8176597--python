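"""Shared paths and defaults for the numbered analysis scripts.

The simulated study (large SAM files) lives under scratch/; every table a
reader would inspect goes under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = ROOT / "scratch" / "analysis" / "study"
RESULTS = ROOT / "results"
SEED = 0


def outdir(stage: str) -> Path:
    d = RESULTS / stage
    d.mkdir(parents=True, exist_ok=True)
    return d
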