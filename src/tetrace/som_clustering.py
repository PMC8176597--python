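"""Self-organizing-map clustering of temporal expression profiles.

Profiles are row z-normalized and clustered on a small rectangular grid
with an online SOM: prototypes start as randomly chosen data rows, and each
training step pulls the best-matching node and its grid neighbours toward
one randomly presented profile.  The learning rate decays linearly from
0.1 to 0.005 and the Gaussian neighbourhood radius from max(grid dims)/2 to
0.5 over the run.  Default grids follow the cluster counts used for the
three feature classes in this analysis: 4x4 for genes, 2x3 for TEs, 1x5
for LTRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_GRIDS = {"genes": (4, 4), "tes": (2, 3), "ltrs": (1, 5)}


def choose_grid(
    n_features: int, base_grid: tuple[int, int], min_per_node: int = 10
) -> tuple[int, int]:
    """Shrink ``base_grid`` when the data cannot populate it.

    The class grids above suit study-scale feature sets (hundreds to
    thousands of profiles); a map with far more nodes than ~n/10 shreds
    coherent temporal programs across near-empty nodes.  When the feature
    set is too small, fall back to a 1-row map with about one node per
    ``min_per_node`` profiles (never fewer than 2).
    """
    rows, cols = base_grid
    if rows * cols * min_per_node <= n_features:
        return base_grid
    return (1, max(2, n_features // min_per_node))


def normalize_profiles(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population variance); constant rows become zeros."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 timepoints")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        log.warning("%d constant profiles mapped to all-zero vectors", int(flat.sum()))
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


@dataclass
class SOMResult:
    grid_shape: tuple[int, int]
    prototypes: np.ndarray  # (rows*cols, n_timepoints)
    assignment: pd.Series  # feature id -> node index (row-major)
    seed: int

    def node_label(self, node: int, prefix: str = "C") -> str:
        return f"{prefix}{node}"

    def labels(self, prefix: str = "C") -> pd.Series:
        return self.assignment.map(lambda n: f"{prefix}{n}")


def _assign(data: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    d2 = ((data[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def train_som(
    profiles: pd.DataFrame,
    grid_shape: tuple[int, int] = (2, 3),
    iterations: int = 20_000,
    seed: int = 0,
    alpha: tuple[float, float] = (0.1, 0.005),
    order_seed: int | None = None,
    n_init: int = 5,
) -> SOMResult:
    """Train an online SOM on normalized profiles; deterministic given seed.

    Online SOMs can converge to a poor map (e.g. an empty node while two
    temporal programs share a prototype), so ``n_init`` independent runs are
    trained from different seeded initializations and the map with the
    lowest quantization error is kept.  ``order_seed`` reseeds only the
    presentation order (used to test that the clustering is invariant to
    the order features are stored in).
    """
    if n_init > 1:
        best = None
        best_qe = np.inf
        for sub in np.random.SeedSequence(seed).generate_state(n_init):
            res = train_som(
                profiles, grid_shape, iterations, int(sub % 2**31), alpha,
                order_seed, n_init=1,
            )
            qe = quantization_error(profiles, res)
            if qe < best_qe:
                best, best_qe = res, qe
        return SOMResult(best.grid_shape, best.prototypes, best.assignment, seed)
    rows, cols = grid_shape
    n_nodes = rows * cols
    # train on rows sorted by feature id so the result is invariant to the
    # order features happen to be stored in
    ordered = profiles.sort_index(kind="stable")
    data = ordered.to_numpy(dtype=float)
    n, dim = data.shape
    if n_nodes < 1 or iterations < 1:
        raise ValueError("grid nodes and iterations must be >= 1")
    if n_nodes > n:
        raise ValueError(f"more nodes ({n_nodes}) than features ({n})")

    rng = np.random.default_rng(seed)
    prototypes = data[rng.choice(n, size=n_nodes, replace=False)].copy()
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)

    order_rng = np.random.default_rng(order_seed) if order_seed is not None else rng
    a0, a1 = alpha
    r0, r1 = max(rows, cols) / 2.0, 0.5
    for t in range(iterations):
        frac = t / max(iterations - 1, 1)
        lr = a0 + (a1 - a0) * frac
        radius = r0 + (r1 - r0) * frac
        x = data[order_rng.integers(n)]
        bmu = int(((prototypes - x) ** 2).sum(axis=1).argmin())
        grid_d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
        h = np.exp(-grid_d2 / (2 * radius**2))
        prototypes += lr * h[:, None] * (x - prototypes)

    assignment = pd.Series(
        _assign(profiles.to_numpy(dtype=float), prototypes), index=profiles.index
    )
    return SOMResult((rows, cols), prototypes, assignment, seed)


def quantization_error(profiles: pd.DataFrame, result: SOMResult) -> float:
    """Mean Euclidean distance of each profile to its prototype."""
    data = profiles.to_numpy(dtype=float)
    protos = result.prototypes[result.assignment.to_numpy()]
    return float(np.linalg.norm(data - protos, axis=1).mean())


def cluster_summary(result: SOMResult, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per node: member count, per-timepoint mean and sd curves.

    Empty nodes get n=0 with NaN curves (flagged, not dropped).
    """
    n_nodes = result.grid_shape[0] * result.grid_shape[1]
    rows = []
    for node in range(n_nodes):
        members = result.assignment.index[result.assignment == node]
        sub = profiles.loc[members]
        row: dict = {"node": node, "n": len(members)}
        for j, tp in enumerate(profiles.columns):
            if len(members):
                row[f"mean_{tp}"] = float(sub.iloc[:, j].mean())
                row[f"sd_{tp}"] = float(sub.iloc[:, j].std(ddof=0))
            else:
                row[f"mean_{tp}"] = np.nan
                row[f"sd_{tp}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")


def cluster_purity(assignment: pd.Series, truth: pd.Series) -> float:
    """Fraction of features whose node's majority truth label matches theirs."""
    truth = truth.reindex(assignment.index)
    correct = 0
    for node in assignment.unique():
        labels = truth[assignment == node]
        correct += labels.value_counts().iloc[0] if len(labels) else 0
    return correct / len(assignment)
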