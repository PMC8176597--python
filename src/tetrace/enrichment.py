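"""GO-term over-representation by hypergeometric test with BH correction.

Works on a flat gene-to-term map (no GO-graph ancestor propagation; supply
a pre-propagated map if that is wanted).  For a cluster of n genes from a
background of N, a term annotating K background genes and k cluster genes
is scored with the one-sided upper tail P(X >= k), X ~ Hypergeom(N, K, n),
and the p-values are Benjamini-Hochberg adjusted across all tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnnotationMap:
    """term -> gene sets over a background universe."""

    term_genes: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set().union(*self.term_genes.values()) if self.term_genes else set()
        stray = set().union(*self.term_genes.values()) - self.background if self.term_genes else set()
        if stray:
            raise ValueError(f"annotated genes outside background: {sorted(stray)[:5]}...")

    @classmethod
    def from_tsv(cls, path: str | Path, names_path: str | Path | None = None,
                 background: set[str] | None = None) -> "AnnotationMap":
        """Load a two-column (gene_id, term_id) TSV; optional term-name TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
        term_genes: dict[str, set[str]] = {}
        for term, grp in df.groupby("term_id"):
            term_genes[str(term)] = set(grp["gene_id"].astype(str))
        names = {}
        if names_path is not None:
            nd = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "name"])
            names = dict(zip(nd["term_id"].astype(str), nd["name"]))
        if background is not None:
            term_genes = {t: g & background for t, g in term_genes.items()}
        return cls(term_genes, names, background or set())


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def enrich(cluster: set[str], annot: AnnotationMap, alpha: float = 0.05) -> list[EnrichmentRow]:
    """Over-representation of every term hitting the cluster (k >= 1).

    Rows come back sorted by adjusted p (ties by term id); ``significant``
    marks p_adj < alpha.
    """
    stray = cluster - annot.background
    if stray:
        raise ValueError(f"cluster genes absent from background: {sorted(stray)}")
    N = len(annot.background)
    n = len(cluster)
    rows = []
    for term, genes in sorted(annot.term_genes.items()):
        K = len(genes)
        k = len(cluster & genes)
        if k < 1:
            continue
        rows.append((term, k, K, hypergeom_upper(k, K, n, N)))
    padj = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentRow(term, annot.term_names.get(term, term), k, n, K, N, p, float(pa), bool(pa < alpha))
        for (term, k, K, p), pa in zip(rows, padj)
    ]
    out.sort(key=lambda r: (r.p_adj, r.term_id))
    return out


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "name": [r.name for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "K": [r.K for r in rows],
            "N": [r.N for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "significant": [r.significant for r in rows],
        }
    ).set_index("term_id")
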