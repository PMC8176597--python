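"""Self-contained toy reprogramming study with known ground truth.

Emulates the statistical design of the real study — 7 timepoints x 2
replicates of paired-end 2x100 nt fragments over a genome carrying coding
genes, solo LTRs, full LTR-internal-LTR ERVs, LINEs/SINEs and TF genes —
with four planted temporal programs:

* ``transient``     — activated at timepoints 2-3, near zero afterwards
                      (the ERV/LTR signature of interest)
* ``gradual_up``    — monotone increase across the course
* ``gradual_down``  — monotone decrease
* ``constant``      — expressed but flat (must fail the sd filters)
* ``low``           — background expression (must fail the peak filters)

Per library, a feature's expected fragment count is
``FPKM * length(kb) * library_size(millions)``; realized counts are
negative binomial (or exact rounding in deterministic mode), fragments are
placed uniformly inside the feature, and a fraction of ERV-LTR fragments
multi-map across the element's two homologous LTR copies.  A planted GO
term covers most transient genes, and planted activator TFs share the
transient program so they correlate with the transient LTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotations_io import (
    GeneFeature,
    GenomicInterval,
    TEFeature,
    write_gtf,
    write_repeatmasker_out,
)

DYNAMIC_PROGRAMS = ("transient", "gradual_up", "gradual_down")

# FPKM trajectories over the 7 timepoints, per feature class and program
GENE_TRAJECTORIES = {
    "transient": [1, 80, 80, 1, 1, 1, 1],
    "gradual_up": list(np.linspace(5, 100, 7)),
    "gradual_down": list(np.linspace(100, 5, 7)),
    "constant": [50] * 7,
    "low": [2] * 7,
}
TE_TRAJECTORIES = {
    "transient": [0.5, 30, 30, 0.5, 0.5, 0.5, 0.5],
    "gradual_up": list(np.linspace(1, 25, 7)),
    "gradual_down": list(np.linspace(25, 1, 7)),
    "constant": [10] * 7,
    "low": [0.5] * 7,
}
TF_TRAJECTORIES = {
    "transient": [2, 60, 60, 2, 2, 2, 2],
    "gradual_up": list(np.linspace(5, 50, 7)),
    "gradual_down": list(np.linspace(50, 5, 7)),
    "constant": [20] * 7,
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the toy simulation.

    The defaults define the study conditions: 7 timepoints x 2 replicates,
    2x100 nt pairs, 2 million fragments per library (a scaled-down bulk
    library that keeps count granularity well below the filter thresholds),
    negative-binomial count noise with dispersion 100 (replicate CV ~10%,
    i.e. highly reproducible replicates), and 30% structural multi-mapping
    between the two LTR copies of each ERV.
    """

    seed: int = 0
    n_timepoints: int = 7
    n_replicates: int = 2
    read_length: int = 100
    fragment_length: int = 200
    paired: bool = True
    library_size: int = 2_000_000
    genome_size: int = 1_000_000
    n_genes: int = 60
    n_solo_ltrs: int = 40
    n_ervs: int = 10
    n_lines_sines: int = 20
    n_tfs: int = 8
    n_near_gene_ltrs: int = 6
    dispersion: float | None = 100.0  # None => deterministic counts
    multimap_fraction: float = 0.3
    gene_length: int = 2000
    solo_ltr_length: int = 800
    erv_ltr_length: int = 600
    erv_internal_length: int = 3000
    line_length: int = 1500
    sine_length: int = 300

    def __post_init__(self) -> None:
        if not 0 <= self.multimap_fraction <= 1:
            raise ValueError("multimap_fraction must be in [0, 1]")
        for name in ("n_genes", "n_solo_ltrs", "n_ervs", "n_lines_sines", "n_tfs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def timepoints(self) -> list[str]:
        return [f"tp{i + 1}" for i in range(self.n_timepoints)]

    @property
    def libraries(self) -> list[str]:
        return [
            f"{tp}_r{r + 1}"
            for tp in self.timepoints
            for r in range(self.n_replicates)
        ]

    @property
    def design(self) -> dict[str, str]:
        return {lib: lib.rsplit("_", 1)[0] for lib in self.libraries}


@dataclass
class GroundTruth:
    """Planted labels the pipeline outputs are scored against."""

    program: dict[str, str]  # feature id -> program label
    true_fpkm: pd.DataFrame  # feature x timepoint planted trajectories
    feature_class: dict[str, str]  # gene | tf | solo_ltr | erv_ltr | erv_int | line | sine
    enriched_term: str
    enriched_cluster: set[str]  # gene ids of the cluster the term is planted in
    activator_tfs: list[str]
    near_gene_pairs: list[tuple[str, str]]  # (ltr_id, gene_id)
    multimap_partners: dict[str, str]  # erv ltr id -> homologous partner ltr id

    def dynamic_ids(self, classes: set[str] | None = None) -> set[str]:
        return {
            fid
            for fid, prog in self.program.items()
            if prog in DYNAMIC_PROGRAMS
            and (classes is None or self.feature_class[fid] in classes)
        }

    def constant_ids(self, classes: set[str] | None = None) -> set[str]:
        return {
            fid
            for fid, prog in self.program.items()
            if prog == "constant"
            and (classes is None or self.feature_class[fid] in classes)
        }

    def save(self, outdir: Path) -> None:
        """Persist as text artifacts (feature table + metadata JSON)."""
        import json

        outdir = Path(outdir)
        table = pd.DataFrame(
            {
                "feature_class": pd.Series(self.feature_class),
                "program": pd.Series(self.program),
            }
        )
        table.join(self.true_fpkm).to_csv(
            outdir / "truth_features.tsv", sep="\t", index_label="feature_id"
        )
        meta = {
            "enriched_term": self.enriched_term,
            "enriched_cluster": sorted(self.enriched_cluster),
            "activator_tfs": self.activator_tfs,
            "near_gene_pairs": self.near_gene_pairs,
            "multimap_partners": self.multimap_partners,
        }
        (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir: Path) -> "GroundTruth":
        import json

        outdir = Path(outdir)
        table = pd.read_csv(outdir / "truth_features.tsv", sep="\t", index_col=0)
        meta = json.loads((outdir / "truth_meta.json").read_text())
        tp_cols = [c for c in table.columns if c.startswith("tp")]
        return cls(
            program=table["program"].to_dict(),
            true_fpkm=table[tp_cols],
            feature_class=table["feature_class"].to_dict(),
            enriched_term=meta["enriched_term"],
            enriched_cluster=set(meta["enriched_cluster"]),
            activator_tfs=meta["activator_tfs"],
            near_gene_pairs=[tuple(p) for p in meta["near_gene_pairs"]],
            multimap_partners=meta["multimap_partners"],
        )


@dataclass
class SimulatedStudy:
    """Paths of every emitted artifact plus the ground truth."""

    outdir: Path
    genome_fasta: Path
    te_out: Path
    gene_gtf: Path
    sam_files: dict[str, Path]  # library id -> SAM
    go_tsv: Path
    tf_list: Path
    library_manifest: Path
    config: SimulationConfig
    truth: GroundTruth
    genes: list[GeneFeature] = field(default_factory=list)
    tes: list[TEFeature] = field(default_factory=list)


def _round_robin(labels: list[str], n: int) -> list[str]:
    return [labels[i % len(labels)] for i in range(n)]


def _lay_out_features(cfg: SimulationConfig):
    """Place genes (with planted near-gene LTRs) then a TE block on chr1.

    Genes sit 1 kb apart; the TE block starts 10 kb after the last gene so
    its LTRs are unambiguously solo (>= 5 kb from any gene body).
    """
    genes: list[GeneFeature] = []
    tes: list[TEFeature] = []
    program: dict[str, str] = {}
    fclass: dict[str, str] = {}
    near_pairs: list[tuple[str, str]] = []
    partners: dict[str, str] = {}

    gene_programs = _round_robin(
        ["transient", "gradual_up", "gradual_down", "constant", "low"], cfg.n_genes
    )
    cursor = 1000
    strands = ["+", "-"]
    transient_gene_ids = []
    near_ltr_budget = cfg.n_near_gene_ltrs
    near_ltr_idx = 0
    for i in range(cfg.n_genes):
        gid = f"gene{i:03d}"
        strand = strands[i % 2]
        iv = GenomicInterval("chr1", cursor, cursor + cfg.gene_length, strand)
        genes.append(GeneFeature(gid, gid.upper(), "coding", iv))
        program[gid] = gene_programs[i]
        fclass[gid] = "gene"
        if gene_programs[i] == "transient":
            transient_gene_ids.append(gid)
        cursor = iv.end + 1000
        # a planted transient LTR 2 kb downstream of a transient gene
        if gene_programs[i] == "transient" and near_ltr_budget > 0:
            lid = f"NearLTR_{near_ltr_idx}"
            ltr_iv = GenomicInterval("chr1", iv.end + 2000, iv.end + 2000 + cfg.solo_ltr_length, "+")
            tes.append(TEFeature(lid, lid, "LTR/ERV", ltr_iv))
            program[lid] = "transient"
            fclass[lid] = "solo_ltr"
            near_pairs.append((lid, gid))
            near_ltr_budget -= 1
            near_ltr_idx += 1
            cursor = ltr_iv.end + 6000
    # TF genes at the end of the gene block
    tf_programs = _round_robin(
        ["transient", "transient", "transient", "gradual_up", "gradual_up",
         "gradual_down", "constant", "constant"],
        cfg.n_tfs,
    )
    tf_names = ["KLF4L", "ETV5L", "ELK1L", "TFUP1", "TFUP2", "TFDN1", "TFC1", "TFC2"]
    activators = []
    for i in range(cfg.n_tfs):
        tid = tf_names[i] if i < len(tf_names) else f"tf{i:02d}"
        iv = GenomicInterval("chr1", cursor, cursor + cfg.gene_length, strands[i % 2])
        genes.append(GeneFeature(tid, tid, "coding", iv))
        program[tid] = tf_programs[i]
        fclass[tid] = "tf"
        if tf_programs[i] == "transient":
            activators.append(tid)
        cursor = iv.end + 1000

    cursor += 10_000  # TE block: everything below is solo relative to genes
    solo_programs = _round_robin(
        ["transient", "transient", "gradual_up", "gradual_down", "constant"],
        cfg.n_solo_ltrs - cfg.n_near_gene_ltrs,
    )
    for i, prog in enumerate(solo_programs):
        lid = f"SoloLTR_{i}"
        iv = GenomicInterval("chr1", cursor, cursor + cfg.solo_ltr_length, "+")
        tes.append(TEFeature(lid, lid, "LTR/ERV", iv))
        program[lid] = prog
        fclass[lid] = "solo_ltr"
        cursor = iv.end + 500
    for i in range(cfg.n_ervs):
        # full ERV: LTR5 - internal - LTR3, all transient, LTRs homologous
        l5 = f"MacERV_LTR_{i}a"
        intern = f"MacERV_int_{i}"
        l3 = f"MacERV_LTR_{i}b"
        iv5 = GenomicInterval("chr1", cursor, cursor + cfg.erv_ltr_length, "+")
        ivi = GenomicInterval("chr1", iv5.end, iv5.end + cfg.erv_internal_length, "+")
        iv3 = GenomicInterval("chr1", ivi.end, ivi.end + cfg.erv_ltr_length, "+")
        tes.append(TEFeature(l5, l5, "LTR/ERV", iv5))
        tes.append(TEFeature(intern, intern, "LTR/ERV", ivi))
        tes.append(TEFeature(l3, l3, "LTR/ERV", iv3))
        for fid in (l5, intern, l3):
            program[fid] = "transient"
        fclass[l5] = fclass[l3] = "erv_ltr"
        fclass[intern] = "erv_int"
        partners[l5] = l3
        partners[l3] = l5
        cursor = iv3.end + 500
    ls_programs = _round_robin(
        ["gradual_up", "gradual_down", "constant", "constant"], cfg.n_lines_sines
    )
    for i, prog in enumerate(ls_programs):
        is_line = i % 2 == 0
        name = f"{'L1Mac' if is_line else 'AluMac'}_{i}"
        length = cfg.line_length if is_line else cfg.sine_length
        iv = GenomicInterval("chr1", cursor, cursor + length, "+")
        tes.append(TEFeature(name, name, "LINE" if is_line else "SINE", iv))
        program[name] = prog
        fclass[name] = "line" if is_line else "sine"
        cursor = iv.end + 500

    if cursor > cfg.genome_size:
        raise ValueError(
            f"feature layout ({cursor} nt) exceeds genome_size {cfg.genome_size}"
        )
    return genes, tes, program, fclass, near_pairs, partners, activators


def _trajectory(fid: str, fclass: str, prog: str) -> list[float]:
    if fclass in ("gene",):
        return GENE_TRAJECTORIES[prog]
    if fclass == "tf":
        return TF_TRAJECTORIES[prog]
    return TE_TRAJECTORIES[prog]


def _draw_count(rng: np.random.Generator, mu: float, dispersion: float | None) -> int:
    if mu <= 0:
        return 0
    if dispersion is None:
        return int(round(mu))
    p = dispersion / (dispersion + mu)
    return int(rng.negative_binomial(dispersion, p))


def _emit_pair(
    sam: pysam.AlignmentFile,
    name: str,
    chrom_id: int,
    s: int,
    read_len: int,
    frag_len: int,
    nh: int,
    hit_index: int,
    secondary: bool,
) -> None:
    flags1 = 0x1 | 0x2 | 0x40 | 0x20
    flags2 = 0x1 | 0x2 | 0x80 | 0x10
    if secondary:
        flags1 |= 0x100
        flags2 |= 0x100
    mate2_start = s + frag_len - read_len
    for flags, pos, mpos, tlen in (
        (flags1, s, mate2_start, frag_len),
        (flags2, mate2_start, s, -frag_len),
    ):
        rec = pysam.AlignedSegment(sam.header)
        rec.query_name = name
        rec.flag = flags
        rec.reference_id = chrom_id
        rec.reference_start = pos
        rec.mapping_quality = 1 if nh > 1 else 60
        rec.cigarstring = f"{read_len}M"
        rec.next_reference_id = chrom_id
        rec.next_reference_start = mpos
        rec.template_length = tlen
        rec.query_sequence = None
        rec.set_tag("NH", nh)
        rec.set_tag("HI", hit_index)
        sam.write(rec)


def simulate(cfg: SimulationConfig, outdir: str | Path) -> SimulatedStudy:
    """Generate the full toy study into ``outdir``; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes, tes, program, fclass, near_pairs, partners, activators = _lay_out_features(cfg)
    feature_by_id: dict[str, GenomicInterval] = {}
    for g in genes:
        feature_by_id[g.gene_id] = g.interval
    for t in tes:
        feature_by_id[t.te_id] = t.interval
    for fid, iv in feature_by_id.items():
        if iv.length < cfg.fragment_length:
            raise ValueError(f"fragment length exceeds feature {fid} ({iv.length} nt)")

    true_fpkm = pd.DataFrame(
        {fid: _trajectory(fid, fclass[fid], program[fid]) for fid in feature_by_id},
        index=cfg.timepoints,
    ).T

    # --- annotations & genome ---------------------------------------------
    gene_gtf = outdir / "genes.gtf"
    write_gtf(genes, gene_gtf)
    te_out = outdir / "repeats.out"
    write_repeatmasker_out(tes, te_out)
    genome_fasta = outdir / "genome.fa"
    _write_genome(genome_fasta, cfg.genome_size, rng)

    # --- reads -------------------------------------------------------------
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": "chr1", "LN": cfg.genome_size}]}
    sam_files: dict[str, Path] = {}
    manifest_rows = []
    for lib in cfg.libraries:
        tp = cfg.design[lib]
        path = outdir / f"{lib}.sam"
        sam_files[lib] = path
        n_frag = 0
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for fid, iv in feature_by_id.items():
                fpkm = true_fpkm.loc[fid, tp]
                mu = fpkm * (iv.length / 1000) * (cfg.library_size / 1e6)
                count = _draw_count(rng, mu, cfg.dispersion)
                if count == 0:
                    continue
                partner = partners.get(fid)
                n_multi = (
                    int(round(cfg.multimap_fraction * count)) if partner else 0
                )
                piv = feature_by_id[partner] if partner else None
                starts = rng.integers(
                    iv.start, iv.end - cfg.fragment_length + 1, size=count
                )
                for j, s in enumerate(starts):
                    name = f"{lib}:{fid}:{j}"
                    n_frag += 1
                    if j < n_multi:
                        offset = int(s) - iv.start
                        _emit_pair(sam, name, 0, int(s), cfg.read_length,
                                   cfg.fragment_length, 2, 0, False)
                        _emit_pair(sam, name, 0, piv.start + offset,
                                   cfg.read_length, cfg.fragment_length, 2, 1, True)
                    else:
                        _emit_pair(sam, name, 0, int(s), cfg.read_length,
                                   cfg.fragment_length, 1, 0, False)
        manifest_rows.append(
            {
                "library_id": lib,
                "timepoint": tp,
                "total_fragments": cfg.library_size,
                "aligned_fragments": n_frag,
                "read_length": cfg.read_length,
                "paired": cfg.paired,
            }
        )
    manifest = outdir / "libraries.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)

    # --- GO map & TF candidates -------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    transient_genes = {g for g in gene_ids if program[g] == "transient" and fclass[g] == "gene"}
    go_tsv = outdir / "go_map.tsv"
    enriched_term = "GO:9000001"
    _write_go_map(go_tsv, gene_ids, transient_genes, enriched_term, rng)
    tf_list = outdir / "tf_candidates.txt"
    tf_ids = [g.gene_id for g in genes if fclass[g.gene_id] == "tf"]
    tf_list.write_text("\n".join(tf_ids) + "\n")

    _write_config(outdir / "config.txt", cfg)

    truth = GroundTruth(
        program=program,
        true_fpkm=true_fpkm,
        feature_class=fclass,
        enriched_term=enriched_term,
        enriched_cluster=transient_genes,
        activator_tfs=activators,
        near_gene_pairs=near_pairs,
        multimap_partners=partners,
    )
    truth.save(outdir)
    return SimulatedStudy(
        outdir, genome_fasta, te_out, gene_gtf, sam_files, go_tsv, tf_list,
        manifest, cfg, truth, genes, tes,
    )


def _write_genome(path: Path, size: int, rng: np.random.Generator) -> None:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=size)
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        raw = seq.tobytes().decode()
        for i in range(0, size, 80):
            fh.write(raw[i : i + 80] + "\n")


def _write_go_map(
    path: Path,
    gene_ids: list[str],
    planted_cluster: set[str],
    term: str,
    rng: np.random.Generator,
) -> None:
    """Planted term covers 80% of the transient cluster and 10% of the rest;
    15 decoy terms annotate random gene octets."""
    rows = []
    cluster = sorted(planted_cluster)
    others = sorted(set(gene_ids) - planted_cluster)
    n_in = max(1, int(round(0.8 * len(cluster))))
    n_out = max(1, int(round(0.1 * len(others))))
    for g in cluster[:n_in]:
        rows.append((g, term))
    for g in rng.choice(others, size=min(n_out, len(others)), replace=False):
        rows.append((str(g), term))
    for d in range(15):
        decoy = f"GO:8{d:06d}"
        for g in rng.choice(gene_ids, size=min(8, len(gene_ids)), replace=False):
            rows.append((str(g), decoy))
    # every gene annotated at least once so the background is the full set
    annotated = {g for g, _ in rows}
    for g in gene_ids:
        if g not in annotated:
            rows.append((g, "GO:0000000"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _write_config(path: Path, cfg: SimulationConfig) -> None:
    with open(path, "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"{key}\t{val}\n")


def truth_report(
    truth: GroundTruth,
    kept_ids: set[str] | None = None,
    dynamic_universe: set[str] | None = None,
    assignment: pd.Series | None = None,
    enrichment_rows=None,
    top_tf_cluster: list[str] | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the planted labels.

    Any subset of outputs may be supplied; only the matching metrics are
    returned.  ``kept_ids`` is scored against the planted dynamic features
    inside ``dynamic_universe`` (default: all features).
    """
    metrics: dict[str, float] = {}
    if kept_ids is not None:
        universe = dynamic_universe or set(truth.program)
        stray = kept_ids - set(truth.program)
        if stray:
            raise ValueError(f"unknown feature ids in kept set: {sorted(stray)[:5]}")
        planted = truth.dynamic_ids() & universe
        constant = truth.constant_ids() & universe
        metrics["filter_recall"] = (
            len(kept_ids & planted) / len(planted) if planted else 1.0
        )
        metrics["filter_precision"] = (
            len(kept_ids & planted) / len(kept_ids) if kept_ids else 1.0
        )
        metrics["constant_kept"] = float(len(kept_ids & constant))
    if assignment is not None:
        from .som_clustering import cluster_purity

        stray = set(assignment.index) - set(truth.program)
        if stray:
            raise ValueError(f"unknown feature ids in assignment: {sorted(stray)[:5]}")
        labels = pd.Series({fid: truth.program[fid] for fid in assignment.index})
        metrics["cluster_purity"] = cluster_purity(assignment, labels)
    if enrichment_rows is not None:
        sig = {r.term_id for r in enrichment_rows if r.significant}
        metrics["planted_term_recovered"] = float(truth.enriched_term in sig)
    if top_tf_cluster is not None:
        hit = set(truth.activator_tfs) & set(top_tf_cluster)
        metrics["activator_tfs_in_top_cluster"] = (
            len(hit) / len(truth.activator_tfs) if truth.activator_tfs else 1.0
        )
    return metrics
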