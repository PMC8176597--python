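"""Annotation and alignment I/O with one internal coordinate convention.

Everything inside the package is 0-based half-open; conversion to and from
1-based inclusive conventions (RepeatMasker ``.out``, GTF) happens only in
the readers and writers defined here.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

log = logging.getLogger(__name__)

REPEAT_CLASSES = frozenset(
    {
        "LTR/ERV",
        "LINE",
        "SINE",
        "DNA",
        "Low_complexity",
        "Satellite",
        "Simple_repeat",
        "Other",
    }
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TEFeature:
    """One RepeatMasker repeat copy."""

    te_id: str
    repeat_name: str
    repeat_class: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat_class {self.repeat_class!r}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene-body span; ``tss`` follows from the strand."""

    gene_id: str
    gene_name: str
    biotype: str  # coding | noncoding | other
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1


@dataclass
class FragmentAlignment:
    """All reported alignments of one sequenced fragment.

    ``hits`` is a list of alignment hits; each hit is a list of aligned
    blocks (GenomicInterval).  A proper pair contributes the blocks of both
    mates to one hit.  ``n_hits`` is the reported multiplicity (NH tag when
    present).
    """

    fragment_id: str
    hits: list[list[GenomicInterval]] = field(default_factory=list)
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")


def _map_repeat_class(raw: str) -> str:
    """Collapse a RepeatMasker class/family string onto the closed vocabulary."""
    top = raw.split("/")[0]
    if top == "LTR":
        return "LTR/ERV"
    if top in ("LINE", "SINE", "DNA", "Low_complexity", "Satellite", "Simple_repeat"):
        return top
    return "Other"


def read_repeatmasker_out(path: str | Path) -> list[TEFeature]:
    """Parse a RepeatMasker ``.out`` file into TEFeatures.

    The format carries 3 header lines and 1-based inclusive coordinates;
    strand ``C`` denotes the minus strand.  When a repeat name recurs, the
    te_id is disambiguated with ``chrom:start``.
    """
    feats: list[TEFeature] = []
    seen: dict[str, int] = defaultdict(int)
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        try:
            chrom = parts[4]
            begin = int(parts[5])
            end = int(parts[6])
            strand = "-" if parts[8] == "C" else "+"
            repeat_name = parts[9]
            repeat_class = _map_repeat_class(parts[10])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed RepeatMasker row at line {lineno}: {exc}") from exc
        interval = GenomicInterval(chrom, begin - 1, end, strand)
        seen[repeat_name] += 1
        te_id = repeat_name if seen[repeat_name] == 1 else f"{repeat_name}_{chrom}:{interval.start}"
        feats.append(TEFeature(te_id, repeat_name, repeat_class, interval))
    # second pass: if a name recurred, its first copy also needs the suffix
    dup_names = {n for n, c in seen.items() if c > 1}
    if dup_names:
        out = []
        for f in feats:
            if f.repeat_name in dup_names and f.te_id == f.repeat_name:
                out.append(
                    TEFeature(
                        f"{f.repeat_name}_{f.interval.chrom}:{f.interval.start}",
                        f.repeat_name,
                        f.repeat_class,
                        f.interval,
                    )
                )
            else:
                out.append(f)
        feats = out
    return feats


def write_repeatmasker_out(feats: Iterable[TEFeature], path: str | Path) -> None:
    """Emit a minimal RepeatMasker-style ``.out`` (synthetic data, round-trips)."""
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query      position in query           matching       repeat\n")
        fh.write("score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family\n")
        fh.write("\n")
        for f in feats:
            strand = "C" if f.interval.strand == "-" else "+"
            cls = "LTR/ERV1" if f.repeat_class == "LTR/ERV" else f.repeat_class
            fh.write(
                f"  225   1.0  0.0  0.0  {f.interval.chrom} {f.interval.start + 1} "
                f"{f.interval.end} (0) {strand} {f.repeat_name} {cls} 1 100 (0) 1\n"
            )


def read_gtf(path: str | Path) -> list[GeneFeature]:
    """Read gene features from a GTF; one GeneFeature per gene_id.

    The span of a gene is the union (min start, max end) of all its records.
    """
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GTF row at line {lineno}")
            chrom, _, _, start, end, _, strand, _, attrs = cols[:9]
            attr = _parse_gtf_attrs(attrs)
            if "gene_id" not in attr:
                raise ValueError(f"GTF record without gene_id at line {lineno}")
            gid = attr["gene_id"]
            rec = spans.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand if strand in "+-" else ".",
                    "gene_name": attr.get("gene_name", gid),
                    "biotype": attr.get("gene_biotype", "other"),
                },
            )
            rec["start"] = min(rec["start"], int(start) - 1)
            rec["end"] = max(rec["end"], int(end))
    return [
        GeneFeature(
            gid,
            rec["gene_name"],
            rec["biotype"],
            GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"]),
        )
        for gid, rec in spans.items()
    ]


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_gtf(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\ttetrace\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '+'}\t.\t{attrs}\n"
            )


def write_bed(features: Iterable[TEFeature | GeneFeature], path: str | Path) -> None:
    """Write any feature list as BED6 (native 0-based half-open)."""
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            name = f.te_id if isinstance(f, TEFeature) else f.gene_id
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read BED6 as (name, interval) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else f"{chrom}:{start}-{end}"
            strand = cols[5].strip() if len(cols) > 5 else "."
            out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out


def _blocks_of(rec: pysam.AlignedSegment) -> list[GenomicInterval]:
    return [
        GenomicInterval(rec.reference_name, s, e)
        for s, e in rec.get_blocks()
        if e > s
    ]


def read_alignments(path: str | Path) -> Iterator[FragmentAlignment]:
    """Yield one FragmentAlignment per sequenced fragment from SAM/BAM.

    The counting unit is the fragment: the two mates of a proper pair are
    merged into one hit.  Multi-mapper multiplicity comes from the NH tag
    when present, otherwise from the number of records sharing the query
    name.  Unmapped records are skipped (count logged).
    """
    # group records by query name (works on unsorted input; whole file held
    # in memory — fine at the scales this package targets)
    by_name: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    n_unmapped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            by_name[rec.query_name].append(rec)
    if n_unmapped:
        log.info("skipped %d unmapped records in %s", n_unmapped, path)

    for name, recs in by_name.items():
        # one hit = all records of one alignment instance; paired records of
        # the same instance share the HI tag when present, else pair primary
        # with primary and secondaries positionally
        hits: dict[int, list[GenomicInterval]] = defaultdict(list)
        nh = None
        per_mate_index: dict[tuple, int] = defaultdict(int)
        for rec in recs:
            if rec.has_tag("NH"):
                nh = max(nh or 0, rec.get_tag("NH"))
            if rec.has_tag("HI"):
                hit_idx = int(rec.get_tag("HI"))
            else:
                mate_key = (rec.is_read2,)
                hit_idx = per_mate_index[mate_key]
                per_mate_index[mate_key] += 1
            hits[hit_idx].extend(_blocks_of(rec))
        n_hits = nh if nh is not None else len(hits)
        yield FragmentAlignment(name, [hits[k] for k in sorted(hits)], max(n_hits, 1))


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
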