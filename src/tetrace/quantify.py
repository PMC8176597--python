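"""Fractional-overlap counting and the two FPKM statistics.

Two FPKM variants are computed.  The count-based variant divides a
fractional fragment count by feature length (kb) and library size
(millions).  The coverage-based variant, used for short LTRs that
fragment-level counting detects poorly, sums per-base read depth C over the
element and normalizes by read length as well:

    FPKM_cov = C * 1e9 / (L_read * L_LTR * total_fragments)

For unique-mapping reads fully contained in the element the two are
identical, because C = count * L_read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotations_io import FragmentAlignment, GenomicInterval, TEFeature

FPKM_SCALE = 1e9  # 1e3 (per kb) * 1e6 (per million fragments)


@dataclass(frozen=True)
class LibraryStats:
    """Per-library normalization constants."""

    library_id: str
    total_fragments: int
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.total_fragments <= 0:
            raise ValueError("total_fragments must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")


def build_feature_index(features: Sequence) -> dict[str, IntervalTree]:
    """chrom -> IntervalTree of features (data = feature object)."""
    trees: dict[str, IntervalTree] = {}
    for f in features:
        iv = f.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, f)
    return trees


def _feature_id(f) -> str:
    return f.te_id if isinstance(f, TEFeature) else f.gene_id


def _union_blocks(blocks: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Merge a hit's blocks per chrom so overlapping mate bases count once."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        per_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def count_fractional(
    alignments: Iterable[FragmentAlignment],
    features: Sequence,
    min_overlap: int = 30,
) -> pd.Series:
    """Fractional fragment counts over ``features`` for one library.

    For each hit of a fragment, the set S of features overlapped by at
    least ``min_overlap`` aligned bases (both mates, overlapping mate bases
    counted once) receives 1/(n_hits * |S|) each.  A fragment therefore
    contributes at most 1 in total across all features.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = build_feature_index(features)
    ids = [_feature_id(f) for f in features]
    counts = dict.fromkeys(ids, 0.0)
    for frag in alignments:
        for hit in frag.hits:
            merged = _union_blocks(hit)
            per_feature: dict[str, int] = {}
            for chrom, blocks in merged.items():
                tree = trees.get(chrom)
                if tree is None:
                    continue
                for s, e in blocks:
                    for node in tree.overlap(s, e):
                        f = node.data
                        ov = min(e, node.end) - max(s, node.begin)
                        if ov > 0:
                            fid = _feature_id(f)
                            per_feature[fid] = per_feature.get(fid, 0) + ov
            hit_set = [fid for fid, ov in per_feature.items() if ov >= min_overlap]
            if hit_set:
                w = 1.0 / (frag.n_hits * len(hit_set))
                for fid in hit_set:
                    counts[fid] += w
    return pd.Series(counts, name="count")


def fpkm_from_counts(
    counts: pd.DataFrame | pd.Series,
    features: Sequence,
    stats: Mapping[str, LibraryStats] | LibraryStats,
) -> pd.DataFrame | pd.Series:
    """Count-based FPKM: count * 1e9 / (length * total_fragments)."""
    lengths = pd.Series({_feature_id(f): f.interval.length for f in features})
    if isinstance(counts, pd.Series):
        st = stats if isinstance(stats, LibraryStats) else next(iter(stats.values()))
        return counts * FPKM_SCALE / (lengths.reindex(counts.index) * st.total_fragments)
    out = {}
    for lib in counts.columns:
        st = stats[lib]
        out[lib] = counts[lib] * FPKM_SCALE / (lengths.reindex(counts.index) * st.total_fragments)
    return pd.DataFrame(out)


class CoverageTrack:
    """Per-base read depth, one integer vector per reference sequence."""

    def __init__(self, chrom_sizes: Mapping[str, int] | None = None):
        self.depth: dict[str, np.ndarray] = {}
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                self.depth[chrom] = np.zeros(size, dtype=np.int64)

    def _ensure(self, chrom: str, end: int) -> np.ndarray:
        arr = self.depth.get(chrom)
        if arr is None or len(arr) < end:
            new = np.zeros(max(end, 1), dtype=np.int64)
            if arr is not None:
                new[: len(arr)] = arr
            self.depth[chrom] = new
        return self.depth[chrom]

    def add_block(self, chrom: str, start: int, end: int) -> None:
        arr = self._ensure(chrom, end)
        arr[start:end] += 1

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))

    def region_sum(self, iv: GenomicInterval) -> int:
        arr = self.depth.get(iv.chrom)
        if arr is None:
            return 0
        return int(arr[iv.start : min(iv.end, len(arr))].sum())

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.depth):
                arr = self.depth[chrom]
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    if arr[s]:
                        fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def genome_coverage(
    alignments: Iterable[FragmentAlignment],
    chrom_sizes: Mapping[str, int] | None = None,
    unique_only: bool = False,
) -> CoverageTrack:
    """Per-base depth including every reported hit of every fragment.

    Mirrors ``bedtools genomecov`` on a BAM: every alignment record's blocks
    pile up, multi-mapper hits included (``unique_only`` restricts to
    fragments with a single hit).
    """
    track = CoverageTrack(chrom_sizes)
    for frag in alignments:
        if unique_only and frag.n_hits > 1:
            continue
        for hit in frag.hits:
            for b in hit:
                track.add_block(b.chrom, b.start, b.end)
    return track


def coverage_fpkm(
    track: CoverageTrack, ltr: GenomicInterval, stats: LibraryStats
) -> float:
    """Coverage-based FPKM of one element.

    C (the summed depth over the element) counts each covering read once per
    covered base, so dividing by read length recovers fragment units.
    """
    c = track.region_sum(ltr)
    return c * FPKM_SCALE / (stats.read_length * ltr.length * stats.total_fragments)


def average_replicates(
    expr: pd.DataFrame, design: Mapping[str, str]
) -> pd.DataFrame:
    """Average replicate library columns into one column per timepoint."""
    missing = [lib for lib in expr.columns if lib not in design]
    if missing:
        raise ValueError(f"libraries not in design map: {missing}")
    groups: dict[str, list[str]] = {}
    for lib in expr.columns:
        groups.setdefault(design[lib], []).append(lib)
    timepoints = sorted(set(design.values()))
    empty = [tp for tp in timepoints if tp not in groups]
    if empty:
        raise ValueError(f"timepoints with zero libraries: {empty}")
    out = {tp: expr[groups[tp]].mean(axis=1) for tp in timepoints}
    return pd.DataFrame(out)[timepoints]
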