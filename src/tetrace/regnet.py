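"""TF-to-LTR regulatory inference from temporal co-expression.

Candidate TFs (from an upstream motif scan) are filtered for expression and
variability, then correlated with each LTR's profile over the 7 timepoint
averages (Pearson; two-sided p from the t transform with n-2 = 5 degrees of
freedom).  The r matrix is clustered hierarchically in both directions so
co-acting TFs and co-regulated LTRs group together, as in a clustered
heatmap.  With n = 7 the two-sided 5% significance boundary sits at
|r| ~ 0.7545.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .filtering import TF_FILTER, FilterConfig, filter_dynamic

log = logging.getLogger(__name__)


def filter_tfs(
    expr: pd.DataFrame,
    candidates: list[str],
    cfg: FilterConfig = TF_FILTER,
) -> list[str]:
    """Candidates passing the dynamic-expression filter (>=5 FPKM peak,
    sd >= 5 by default); absent candidates are logged and dropped."""
    present = [c for c in candidates if c in expr.index]
    missing = sorted(set(candidates) - set(present))
    if missing:
        log.warning("TF candidates absent from expression matrix: %s", missing)
    if not present:
        return []
    kept = set(filter_dynamic(expr.loc[present], cfg))
    return [c for c in present if c in kept]


@dataclass
class CorrelationResult:
    r: pd.DataFrame  # TFs x LTRs
    p: pd.DataFrame
    n_points: int
    flagged: list[tuple[str, str]]  # zero-variance pairs, r undefined


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return r, float(2 * stats.t.sf(abs(t), df=n - 2))


def correlate(tf_expr: pd.DataFrame, ltr_expr: pd.DataFrame) -> CorrelationResult:
    """Pearson r and two-sided p for every TF x LTR pair of profiles."""
    if list(tf_expr.columns) != list(ltr_expr.columns):
        raise ValueError("TF and LTR matrices must share the same timepoint columns")
    n = tf_expr.shape[1]
    r = pd.DataFrame(np.nan, index=tf_expr.index, columns=ltr_expr.index)
    p = pd.DataFrame(np.nan, index=tf_expr.index, columns=ltr_expr.index)
    flagged = []
    tf_vals = tf_expr.to_numpy(dtype=float)
    ltr_vals = ltr_expr.to_numpy(dtype=float)
    for i, tf in enumerate(tf_expr.index):
        for j, ltr in enumerate(ltr_expr.index):
            x, y = tf_vals[i], ltr_vals[j]
            if x.std() == 0 or y.std() == 0:
                flagged.append((tf, ltr))
                continue
            r.iloc[i, j], p.iloc[i, j] = _pearson_with_p(x, y)
    return CorrelationResult(r, p, n, flagged)


def significance_boundary(n: int = 7, alpha: float = 0.05) -> float:
    """Smallest |r| two-sided significant at ``alpha`` for sample size n."""
    t_crit = stats.t.isf(alpha / 2, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def correlate_pairs(
    ltr_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Pearson r (and p) for listed (LTR, neighbour gene) profile pairs."""
    rows = []
    for ltr, gene in pairs:
        x = ltr_expr.loc[ltr].to_numpy(dtype=float)
        y = gene_expr.loc[gene].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append((ltr, gene, np.nan, np.nan))
            continue
        r, p = _pearson_with_p(x, y)
        rows.append((ltr, gene, r, p))
    return pd.DataFrame(rows, columns=["ltr_id", "gene_id", "r", "p"]).set_index("ltr_id")


@dataclass
class BiclusterOrder:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def bicluster(corr: CorrelationResult) -> BiclusterOrder:
    """Average-linkage hierarchical clustering of the r matrix, both ways.

    Undefined pairs are imputed as r = 0 (with a warning) so the matrix is
    complete; fewer than 2 rows or columns yields the trivial order.
    """
    r = corr.r.copy()
    if corr.flagged:
        log.warning("imputing r=0 for %d undefined pairs", len(corr.flagged))
        r = r.fillna(0.0)
    rows = list(r.index)
    cols = list(r.columns)
    row_link = col_link = None
    row_order, col_order = rows, cols
    if len(rows) >= 2:
        row_link = linkage(r.to_numpy(), method="average", metric="euclidean")
        row_order = [rows[i] for i in leaves_list(row_link)]
    if len(cols) >= 2:
        col_link = linkage(r.to_numpy().T, method="average", metric="euclidean")
        col_order = [cols[i] for i in leaves_list(col_link)]
    return BiclusterOrder(row_order, col_order, row_link, col_link)


def top_row_cluster(order: BiclusterOrder, corr: CorrelationResult) -> list[str]:
    """TF ids in the root-split branch with the higher mean r.

    Splits the row dendrogram at its root into two TF groups and returns the
    one more positively correlated with the LTR set on average.
    """
    from scipy.cluster.hierarchy import fcluster

    if order.row_linkage is None:
        return order.row_order
    labels = fcluster(order.row_linkage, t=2, criterion="maxclust")
    rows = list(corr.r.index)
    groups = {lab: [rows[i] for i in range(len(rows)) if labels[i] == lab] for lab in set(labels)}
    mean_r = {lab: corr.r.loc[g].mean().mean() for lab, g in groups.items()}
    return groups[max(mean_r, key=mean_r.get)]
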