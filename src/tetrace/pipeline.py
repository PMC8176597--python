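"""Stage orchestration: simulate -> quantify -> filter -> cluster ->
enrich -> context -> regnet, with TSV artifacts per stage.

Each ``run_*`` function is a pure driver over the library modules; the CLI
and the numbered analysis scripts both call these, so every number in the
outputs comes from the same code path.  All stages write their tables under
``outdir`` and the seed of every stochastic stage is derived from one
master seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations_io import (
    GeneFeature,
    TEFeature,
    read_alignments,
    read_gtf,
    read_repeatmasker_out,
    write_tsv_matrix,
)
from .enrichment import AnnotationMap, enrich, enrichment_table
from .filtering import (
    GENE_FILTER,
    LTR_FILTER,
    TE_FILTER_RESULTS,
    classify_proximity,
    exclude_gene_overlaps,
    filter_dynamic,
    proximity_table,
)
from .quantify import (
    LibraryStats,
    average_replicates,
    count_fractional,
    coverage_fpkm,
    fpkm_from_counts,
    genome_coverage,
)
from .regnet import bicluster, correlate, correlate_pairs, filter_tfs, top_row_cluster
from .som_clustering import (
    DEFAULT_GRIDS,
    SOMResult,
    choose_grid,
    cluster_summary,
    normalize_profiles,
    train_som,
)
from .synthetic import SimulatedStudy, SimulationConfig, simulate

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % 2**31
    )


@dataclass
class QuantifyResult:
    te_counts: pd.DataFrame  # TE x library fractional counts
    te_fpkm: pd.DataFrame  # count-based
    gene_fpkm: pd.DataFrame
    ltr_cov_fpkm: pd.DataFrame  # coverage-based, LTR-class TEs only
    stats: dict[str, LibraryStats]
    design: dict[str, str]

    def averaged(self, which: str) -> pd.DataFrame:
        mat = {"te": self.te_fpkm, "gene": self.gene_fpkm, "ltr": self.ltr_cov_fpkm}[which]
        return average_replicates(mat, self.design)


def run_quantify(
    sam_files: dict[str, Path],
    tes: list[TEFeature],
    genes: list[GeneFeature],
    manifest: pd.DataFrame,
    outdir: Path | None = None,
    min_overlap: int = 30,
) -> QuantifyResult:
    """Count fragments and compute the three expression matrices."""
    stats = {
        row.library_id: LibraryStats(row.library_id, int(row.total_fragments), int(row.read_length))
        for row in manifest.itertuples()
    }
    # coverage depth is per read, so its normalization must count reads:
    # a paired library has two reads per fragment
    paired = dict(
        zip(manifest["library_id"], manifest.get("paired", pd.Series(False, index=manifest.index)))
    )
    read_stats = {
        lib: LibraryStats(
            lib, st.total_fragments * (2 if paired.get(lib) else 1), st.read_length
        )
        for lib, st in stats.items()
    }
    design = dict(zip(manifest["library_id"], manifest["timepoint"]))
    ltrs = [t for t in tes if t.repeat_class == "LTR/ERV"]
    te_counts, gene_counts, cov_cols = {}, {}, {}
    for lib, path in sam_files.items():
        frags = list(read_alignments(path))
        te_counts[lib] = count_fractional(frags, tes, min_overlap)
        gene_counts[lib] = count_fractional(frags, genes, min_overlap)
        track = genome_coverage(frags)
        cov_cols[lib] = pd.Series(
            {t.te_id: coverage_fpkm(track, t.interval, read_stats[lib]) for t in ltrs}
        )
    te_count_mat = pd.DataFrame(te_counts)
    gene_count_mat = pd.DataFrame(gene_counts)
    result = QuantifyResult(
        te_counts=te_count_mat,
        te_fpkm=fpkm_from_counts(te_count_mat, tes, stats),
        gene_fpkm=fpkm_from_counts(gene_count_mat, genes, stats),
        ltr_cov_fpkm=pd.DataFrame(cov_cols),
        stats=stats,
        design=design,
    )
    if outdir is not None:
        write_tsv_matrix(result.te_counts, outdir / "te_counts.tsv")
        write_tsv_matrix(result.te_fpkm, outdir / "te_fpkm.tsv")
        write_tsv_matrix(result.gene_fpkm, outdir / "gene_fpkm.tsv")
        write_tsv_matrix(result.ltr_cov_fpkm, outdir / "ltr_coverage_fpkm.tsv")
    return result


def load_study_inputs(study_dir: Path):
    """(tes, genes, manifest, sam_files) from a simulated study directory."""
    study_dir = Path(study_dir)
    for name in ("repeats.out", "genes.gtf", "libraries.tsv"):
        if not (study_dir / name).exists():
            raise FileNotFoundError(study_dir / name)
    tes = read_repeatmasker_out(study_dir / "repeats.out")
    genes = read_gtf(study_dir / "genes.gtf")
    manifest = pd.read_csv(study_dir / "libraries.tsv", sep="\t")
    sams = {
        row.library_id: study_dir / f"{row.library_id}.sam"
        for row in manifest.itertuples()
    }
    missing = [str(p) for p in sams.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing alignment files: {missing}")
    return tes, genes, manifest, sams


def load_quantify(study_dir: Path, quant_dir: Path) -> "QuantifyResult":
    """Rebuild a QuantifyResult from a quantify stage's TSV artifacts."""
    from .annotations_io import read_tsv_matrix

    study_dir, quant_dir = Path(study_dir), Path(quant_dir)
    manifest = pd.read_csv(study_dir / "libraries.tsv", sep="\t")
    stats = {
        r.library_id: LibraryStats(r.library_id, int(r.total_fragments), int(r.read_length))
        for r in manifest.itertuples()
    }
    return QuantifyResult(
        te_counts=read_tsv_matrix(quant_dir / "te_counts.tsv"),
        te_fpkm=read_tsv_matrix(quant_dir / "te_fpkm.tsv"),
        gene_fpkm=read_tsv_matrix(quant_dir / "gene_fpkm.tsv"),
        ltr_cov_fpkm=read_tsv_matrix(quant_dir / "ltr_coverage_fpkm.tsv"),
        stats=stats,
        design=dict(zip(manifest["library_id"], manifest["timepoint"])),
    )


def load_filter(filter_dir: Path) -> "FilterResult":
    def ids(name):
        return [l for l in (Path(filter_dir) / f"{name}.txt").read_text().splitlines() if l]

    return FilterResult(ids("kept_genes"), ids("kept_tes"), ids("kept_ltrs"))


def load_clusters(cluster_dir: Path, seed: int = 0) -> "ClusterResult":
    from .annotations_io import read_tsv_matrix

    cluster_dir = Path(cluster_dir)
    soms, profs, sums = {}, {}, {}
    for cls, prefix in CLASS_PREFIX.items():
        assign = pd.read_csv(cluster_dir / f"som_{cls}_assignment.tsv", sep="\t", index_col=0)
        protos = read_tsv_matrix(cluster_dir / f"som_{cls}_prototypes.tsv")
        grid = DEFAULT_GRIDS[cls]
        if grid[0] * grid[1] != len(protos):
            grid = (1, len(protos))
        nodes = assign["node"].str.lstrip(prefix).astype(int)
        soms[cls] = SOMResult(grid, protos.to_numpy(), nodes, seed)
        sums[cls] = pd.read_csv(cluster_dir / f"som_{cls}_summary.tsv", sep="\t", index_col=0)
    return ClusterResult(soms, profs, sums)


@dataclass
class FilterResult:
    kept_genes: list[str]
    kept_tes: list[str]
    kept_ltrs: list[str]


def run_filter(
    quant: QuantifyResult,
    tes: list[TEFeature],
    genes: list[GeneFeature],
    outdir: Path | None = None,
) -> FilterResult:
    """The three filter cascades: genes 20/20, TEs 5/5, LTRs 5/5 (coverage).

    TE and LTR survivors overlapping coding gene bodies are excluded.
    """
    gene_avg = quant.averaged("gene")
    kept_genes = filter_dynamic(gene_avg, GENE_FILTER)

    te_by_id = {t.te_id: t for t in tes}
    kept_te_expr = set(filter_dynamic(quant.te_fpkm, TE_FILTER_RESULTS))
    no_overlap = set(exclude_gene_overlaps([te_by_id[i] for i in kept_te_expr], genes))
    kept_tes = [i for i in quant.te_fpkm.index if i in no_overlap]

    ltr_avg = quant.averaged("ltr")
    kept_ltr_expr = set(filter_dynamic(ltr_avg, LTR_FILTER))
    ltr_no_overlap = set(
        exclude_gene_overlaps([te_by_id[i] for i in kept_ltr_expr], genes)
    )
    kept_ltrs = [i for i in ltr_avg.index if i in ltr_no_overlap]

    if outdir is not None:
        for name, ids in (
            ("kept_genes", kept_genes),
            ("kept_tes", kept_tes),
            ("kept_ltrs", kept_ltrs),
        ):
            (outdir / f"{name}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
    return FilterResult(kept_genes, kept_tes, kept_ltrs)


@dataclass
class ClusterResult:
    som: dict[str, SOMResult]  # class -> result
    profiles: dict[str, pd.DataFrame]
    summaries: dict[str, pd.DataFrame]


CLASS_PREFIX = {"genes": "G", "tes": "T", "ltrs": "L"}


def run_cluster(
    quant: QuantifyResult,
    filt: FilterResult,
    seed: int,
    outdir: Path | None = None,
    grids: dict[str, tuple[int, int]] | None = None,
    iterations: int = 20_000,
) -> ClusterResult:
    """SOM-cluster each kept feature class on its replicate-averaged profiles."""
    grids = grids or DEFAULT_GRIDS
    sources = {
        "genes": quant.averaged("gene").loc[filt.kept_genes],
        "tes": quant.averaged("te").loc[filt.kept_tes],
        "ltrs": quant.averaged("ltr").loc[filt.kept_ltrs],
    }
    soms, profs, sums = {}, {}, {}
    for cls, expr in sources.items():
        prof = normalize_profiles(expr)
        grid = choose_grid(len(prof), grids[cls])
        if grid != grids[cls]:
            log.info("%s: %d profiles, shrinking grid %s -> %s", cls, len(prof), grids[cls], grid)
        res = train_som(
            prof, grid, iterations=iterations, seed=stage_seed(seed, f"som-{cls}")
        )
        soms[cls], profs[cls] = res, prof
        sums[cls] = cluster_summary(res, prof)
        if outdir is not None:
            labels = res.labels(CLASS_PREFIX[cls])
            labels.rename("node").to_frame().to_csv(
                outdir / f"som_{cls}_assignment.tsv", sep="\t", index_label="feature_id"
            )
            sums[cls].to_csv(outdir / f"som_{cls}_summary.tsv", sep="\t")
            pd.DataFrame(res.prototypes, columns=expr.columns).to_csv(
                outdir / f"som_{cls}_prototypes.tsv", sep="\t", index_label="node"
            )
    return ClusterResult(soms, profs, sums)


def run_enrich(
    clusters: ClusterResult,
    go_tsv: Path,
    quantified_genes: set[str],
    alpha: float = 0.05,
    outdir: Path | None = None,
) -> dict[str, list]:
    """Per gene-cluster GO over-representation against the annotated and
    quantified background."""
    annot = AnnotationMap.from_tsv(go_tsv)
    annot.background &= quantified_genes
    annot.term_genes = {t: g & annot.background for t, g in annot.term_genes.items()}
    res = clusters.som["genes"]
    out = {}
    for node in range(res.grid_shape[0] * res.grid_shape[1]):
        members = set(res.assignment.index[res.assignment == node]) & annot.background
        if not members:
            continue
        rows = enrich(members, annot, alpha)
        label = res.node_label(node, "G")
        out[label] = rows
        if outdir is not None and rows:
            enrichment_table(rows).to_csv(outdir / f"enrichment_{label}.tsv", sep="\t")
    return out


def transient_nodes(som: SOMResult, peak_timepoints: tuple[int, ...] = (1, 2)) -> list[int]:
    """Nodes showing the transient-activation signature on normalized
    profiles: below-average before activation, peak at the 2nd/3rd
    timepoint, and silenced (below average) at every later timepoint."""
    picked = []
    for node in range(som.prototypes.shape[0]):
        proto = som.prototypes[node]
        if not (som.assignment == node).any():
            continue
        if (
            int(np.argmax(proto)) in peak_timepoints
            and proto[0] < 0
            and proto[max(peak_timepoints) + 1 :].max() < 0
        ):
            picked.append(node)
    return picked


@dataclass
class RegnetResult:
    kept_tfs: list[str]
    transient_ltrs: list[str]
    corr: object
    order: object
    top_cluster: list[str]
    near_gene_corr: pd.DataFrame


def run_regnet(
    quant: QuantifyResult,
    clusters: ClusterResult,
    tf_candidates: list[str],
    genes: list[GeneFeature],
    tes: list[TEFeature],
    filt: FilterResult,
    outdir: Path | None = None,
) -> RegnetResult:
    """TF filtering, TF x transient-LTR correlation, biclustering, and
    neighbour-gene correlation for near-gene LTRs."""
    gene_avg = quant.averaged("gene")
    kept_tfs = filter_tfs(gene_avg, tf_candidates)

    ltr_som = clusters.som["ltrs"]
    nodes = set(transient_nodes(ltr_som))
    transient_ltrs = [
        fid for fid, node in ltr_som.assignment.items() if node in nodes
    ]
    ltr_avg = quant.averaged("ltr").loc[transient_ltrs]
    corr = correlate(gene_avg.loc[kept_tfs], ltr_avg)
    order = bicluster(corr)
    top = top_row_cluster(order, corr)

    te_by_id = {t.te_id: t for t in tes}
    calls = classify_proximity([te_by_id[i] for i in filt.kept_ltrs], genes)
    pairs = [(c.ltr_id, c.nearest_gene_id) for c in calls if c.status == "near-gene"]
    near_corr = correlate_pairs(quant.averaged("ltr"), gene_avg, pairs)

    if outdir is not None:
        write_tsv_matrix(corr.r, outdir / "tf_ltr_r.tsv", index_label="tf_id")
        write_tsv_matrix(corr.p, outdir / "tf_ltr_p.tsv", index_label="tf_id")
        (outdir / "bicluster_rows.txt").write_text("\n".join(order.row_order) + "\n")
        (outdir / "bicluster_cols.txt").write_text("\n".join(order.col_order) + "\n")
        proximity_table(calls).to_csv(outdir / "ltr_context.tsv", sep="\t")
        near_corr.to_csv(outdir / "near_gene_correlation.tsv", sep="\t")
    return RegnetResult(kept_tfs, transient_ltrs, corr, order, top, near_corr)


@dataclass
class PipelineResult:
    study: SimulatedStudy
    quant: QuantifyResult
    filt: FilterResult
    clusters: ClusterResult
    enrichments: dict[str, list]
    regnet: RegnetResult
    metrics: dict[str, float] = field(default_factory=dict)


def run_all(
    cfg: SimulationConfig,
    outdir: str | Path,
    som_iterations: int = 20_000,
) -> PipelineResult:
    """One-shot end-to-end run on a fresh simulation; writes all artifacts
    plus a run manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    study = simulate(cfg, sim_dir)
    # re-read the annotations through the format boundary, as a real run would
    tes = read_repeatmasker_out(study.te_out)
    genes = read_gtf(study.gene_gtf)
    manifest = pd.read_csv(study.library_manifest, sep="\t")
    quant = run_quantify(study.sam_files, tes, genes, manifest, outdir)
    filt = run_filter(quant, tes, genes, outdir)
    clusters = run_cluster(quant, filt, seed=cfg.seed, outdir=outdir, iterations=som_iterations)
    enr = run_enrich(clusters, study.go_tsv, set(quant.gene_fpkm.index), outdir=outdir)
    tf_candidates = study.tf_list.read_text().split()
    reg = run_regnet(quant, clusters, tf_candidates, genes, tes, filt, outdir)

    from .synthetic import truth_report

    truth = study.truth
    metrics = {}
    metrics.update(
        truth_report(
            truth,
            kept_ids=set(filt.kept_ltrs),
            dynamic_universe={
                fid for fid, c in truth.feature_class.items()
                if c in ("solo_ltr", "erv_ltr", "erv_int")
            },
        )
    )
    all_enr = [r for rows in enr.values() for r in rows]
    metrics.update(
        truth_report(
            truth,
            assignment=clusters.som["ltrs"].assignment,
            enrichment_rows=all_enr,
            top_tf_cluster=reg.top_cluster,
        )
    )
    manifest_obj = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: str(v) for k, v in vars(cfg).items()},
        "som_iterations": som_iterations,
        "metrics": metrics,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest_obj, indent=2))
    return PipelineResult(study, quant, filt, clusters, enr, reg, metrics)
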