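"""Expression/variability filter cascades and LTR genomic-context calls.

The study's cascades all share one predicate — a feature must reach a
minimum expression somewhere in the course and vary enough across it — with
stage-specific thresholds: 20/20 FPKM for genes on the 7 timepoint
averages, 5/5 for TEs, 5/5 for the coverage-quantified LTRs and 5/5 for TF
candidates.  Features overlapping coding genes are then excluded, and
surviving LTRs are classified by proximity to the nearest gene (within 5 kb
= near-gene, otherwise solo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations_io import GeneFeature, GenomicInterval
from .quantify import build_feature_index


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for one stage of the dynamic-feature filter.

    ``comparator`` applies to both conditions: ">=" keeps features at the
    threshold, ">" requires strict excess.  ``ddof`` selects sample (1) or
    population (0) standard deviation.
    """

    min_fpkm: float
    min_sd: float
    scope: str = "per-timepoint-average"  # or "per-library"
    comparator: str = ">="
    ddof: int = 1

    def __post_init__(self) -> None:
        if self.min_fpkm < 0 or self.min_sd < 0:
            raise ValueError("thresholds must be >= 0")
        if self.comparator not in (">=", ">"):
            raise ValueError("comparator must be '>=' or '>'")


# stage presets; the TE stage has two published variants that disagree
GENE_FILTER = FilterConfig(min_fpkm=20, min_sd=20)
TE_FILTER_RESULTS = FilterConfig(min_fpkm=5, min_sd=5, scope="per-library")
TE_FILTER_METHODS = FilterConfig(min_fpkm=10, min_sd=5, comparator=">")
LTR_FILTER = FilterConfig(min_fpkm=5, min_sd=5)
TF_FILTER = FilterConfig(min_fpkm=5, min_sd=5)


def filter_dynamic(expr: pd.DataFrame, cfg: FilterConfig) -> list[str]:
    """Feature ids whose profile peaks above ``min_fpkm`` and whose sd
    across columns exceeds ``min_sd``."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 columns to compute a standard deviation")
    peak = expr.max(axis=1)
    sd = expr.std(axis=1, ddof=cfg.ddof)
    if cfg.comparator == ">=":
        keep = (peak >= cfg.min_fpkm) & (sd >= cfg.min_sd)
    else:
        keep = (peak > cfg.min_fpkm) & (sd > cfg.min_sd)
    return list(expr.index[keep])


def exclude_gene_overlaps(
    features: Sequence, genes: Sequence[GeneFeature]
) -> list[str]:
    """Ids of features sharing no base with any coding gene body."""
    trees = build_feature_index([g for g in genes if g.biotype == "coding"])
    kept = []
    for f in features:
        iv = f.interval
        tree = trees.get(iv.chrom)
        if tree is None or not tree.overlap(iv.start, iv.end):
            fid = getattr(f, "te_id", None) or getattr(f, "gene_id")
            kept.append(fid)
    return kept


@dataclass(frozen=True)
class ProximityCall:
    """Genomic context of one LTR relative to the nearest gene."""

    ltr_id: str
    status: str  # overlapping-gene | near-gene | solo
    nearest_gene_id: str | None
    distance: float  # nt gap; 0 = overlap; inf = no gene on the chromosome
    upstream_flag: bool


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap in nt; 0 when the intervals overlap or abut."""
    if a.overlap_len(b) > 0:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def classify_proximity(
    ltrs: Sequence,
    genes: Sequence[GeneFeature],
    max_dist: int = 5000,
) -> list[ProximityCall]:
    """Partition LTRs into overlapping-gene / near-gene (< max_dist) / solo.

    ``upstream_flag`` is true when the LTR lies 5' of the nearest gene's TSS
    on that gene's strand.
    """
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    calls = []
    for ltr in ltrs:
        iv = ltr.interval
        ltr_id = getattr(ltr, "te_id", None) or getattr(ltr, "gene_id")
        cands = by_chrom.get(iv.chrom, [])
        if not cands:
            calls.append(ProximityCall(ltr_id, "solo", None, math.inf, False))
            continue
        best = min(cands, key=lambda g: (_gap(iv, g.interval), g.gene_id))
        d = _gap(iv, best.interval)
        if iv.overlap_len(best.interval) > 0:
            status = "overlapping-gene"
        elif d < max_dist:
            status = "near-gene"
        else:
            status = "solo"
        if best.interval.strand == "-":
            upstream = iv.start >= best.tss
        else:
            upstream = iv.end <= best.tss
        calls.append(ProximityCall(ltr_id, status, best.gene_id, float(d), bool(upstream)))
    return calls


def proximity_table(calls: Sequence[ProximityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ltr_id": [c.ltr_id for c in calls],
            "status": [c.status for c in calls],
            "nearest_gene_id": [c.nearest_gene_id for c in calls],
            "distance": [c.distance for c in calls],
            "upstream_flag": [c.upstream_flag for c in calls],
        }
    ).set_index("ltr_id")
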