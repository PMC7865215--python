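"""Spot-module detection and gene-set enrichment on portraits.

Spot modules are the connected red (up) or blue (down) areas of a
portrait: cells beyond a quantile threshold of the portrait's non-empty
values, grouped by 8-connectivity, kept when large enough. A spot's gene
module is the union of genes assigned to its cells.

Functional scoring of spot gene modules uses the one-sided Fisher exact
test against a gene-set collection (GMT), and set-level regulation per
sample group uses the Gene Set Z-score: the summed per-gene scores of a
set standardised against the expectation and hypergeometric
(sampling-without-replacement) variance of an equally sized random set,
with a small additive variance stabiliser for near-degenerate sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .data_core import GROUPS, DataError, ExpressionLayer, MultiLayerDataset
from .portraits import Portrait, metagene_expression
from .som import TrainedSOM

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SpotModule:
    cells: set[tuple[int, int]]
    member_genes: set[str]
    polarity: str                 # "up" | "down"
    peak_value: float
    source_portrait: str

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [n for n, g in self.sets.items() if not g]
        if empty:
            raise DataError(f"empty gene set(s): {empty[:3]}")


@dataclass
class GSZConfig:
    lambda_stabilizer: float = 0.1
    gene_score: str = "centered_expression"

    def __post_init__(self) -> None:
        if self.lambda_stabilizer < 0:
            raise DataError("lambda_stabilizer must be >= 0")


@dataclass
class GSZResult:
    matrix: pd.DataFrame           # sets x groups z-scores
    row_order: list[int]
    row_linkage: np.ndarray | None
    dropped_sets: list[str] = field(default_factory=list)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set collection (name, description, genes...)."""
    from gseapy.parser import read_gmt as _read

    sets = _read(str(path))
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection({k: list(v) for k, v in sets.items()}, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def detect_spots(
    p: Portrait,
    som: TrainedSOM,
    quantile: float = 0.98,
    min_cells: int = 3,
    polarity: str = "up",
) -> list[SpotModule]:
    """Quantile-threshold + 8-connected-component spot detection.

    For ``polarity="up"`` the threshold is the given quantile of the
    portrait's non-empty values and cells strictly above it are candidate
    spot cells; for ``"down"`` the (1 - quantile) quantile with cells
    strictly below. Components with fewer than ``min_cells`` cells are
    discarded. Spots are returned strongest peak first.
    """
    if polarity not in ("up", "down"):
        raise DataError(f"polarity must be 'up' or 'down', got {polarity!r}")
    vals = p.nonempty_values()
    if vals.size == 0:
        return []
    if polarity == "up":
        thr = np.quantile(vals, quantile)
        mask = np.where(np.isfinite(p.grid), p.grid > thr, False)
    else:
        thr = np.quantile(vals, 1.0 - quantile)
        mask = np.where(np.isfinite(p.grid), p.grid < thr, False)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    cols = som.config.grid_cols
    spots = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        if rr.size < min_cells:
            continue
        units = rr * cols + cc
        members = {
            som.gene_ids[g] for g in np.flatnonzero(np.isin(som.bmu, units))
        }
        if not members:
            continue
        cell_vals = p.grid[rr, cc]
        peak = float(np.max(cell_vals) if polarity == "up" else np.min(cell_vals))
        spots.append(
            SpotModule(set(zip(rr.tolist(), cc.tolist())), members, polarity,
                       peak, p.subject)
        )
    spots.sort(key=lambda s: abs(s.peak_value), reverse=True)
    logger.info("detected %d %s-spot(s) on %r", len(spots), polarity, p.subject)
    return spots


def fisher_enrichment(
    spot_genes: set, gene_set: set, universe_size: int
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of a spot against a set.

    Returns ``(odds_ratio, p)`` from the 2x2 table in-spot/not x
    in-set/not; ``odds_ratio > 1`` indicates over-representation.
    """
    spot_genes, gene_set = set(spot_genes), set(gene_set)
    if not spot_genes or not gene_set:
        raise DataError("spot and gene set must be non-empty")
    if universe_size < len(spot_genes | gene_set):
        raise DataError("universe smaller than spot/set union")
    a = len(spot_genes & gene_set)
    b = len(spot_genes) - a
    c = len(gene_set) - a
    d = universe_size - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def gsz_score(gene_scores, in_set, cfg: GSZConfig | None = None) -> float:
    """Gene Set Z-score of one set against a per-gene score vector.

    ``in_set`` is a boolean mask (length N) or an index array of set
    members. With S the summed member scores, m the set size and the N
    scores treated as the sampling population:

        E = m * mean(scores)
        V = m * (N - m) / (N - 1) * var(scores)      (population variance)
        z = (S - E) / sqrt(V + lambda)

    i.e. S is standardised against drawing m scores without replacement.
    """
    cfg = cfg or GSZConfig()
    scores = np.asarray(gene_scores, float)
    if not np.all(np.isfinite(scores)):
        raise DataError("gene scores must be finite")
    N = scores.size
    in_set = np.asarray(in_set)
    if in_set.dtype == bool:
        if in_set.size != N:
            raise DataError("boolean set mask length must equal score length")
        mask = in_set
    else:
        mask = np.zeros(N, bool)
        mask[in_set] = True
    m = int(mask.sum())
    if not 1 <= m <= N:
        raise DataError(f"set size {m} outside [1, {N}]")
    lam = cfg.lambda_stabilizer
    if m == N and lam == 0:
        raise DataError("set equals the universe and lambda is 0: zero variance")
    S = scores[mask].sum()
    E = m * scores.mean()
    V = 0.0 if N == 1 else m * (N - m) / (N - 1) * scores.var(ddof=0)
    denom = np.sqrt(V + lam)
    if denom == 0:
        # constant scores: S = E exactly, define z = 0
        if S == E:
            return 0.0
        raise DataError("zero variance with non-zero enrichment")
    return float((S - E) / denom)


def gsz_matrix(
    ds: MultiLayerDataset | ExpressionLayer,
    som: TrainedSOM,
    collection: GeneSetCollection,
    groups=GROUPS,
    cfg: GSZConfig | None = None,
) -> GSZResult:
    """Set x group matrix of Gene Set Z-scores, rows clustered.

    The per-gene score of a group is its group-mean centred expression.
    Accepts a single layer (columns = groups) or a multi-layer dataset
    (columns = "layer:group"). Sets with no overlap with the trained gene
    universe are dropped with a warning.
    """
    cfg = cfg or GSZConfig()
    layers = ds.layers if isinstance(ds, MultiLayerDataset) else [ds]
    gene_pos = {g: i for i, g in enumerate(som.gene_ids)}

    columns, scores_cols = [], []
    for lay in layers:
        if lay.gene_ids != som.gene_ids:
            raise DataError("layer gene universe does not match the trained map")
        for grp in groups:
            idx = lay.group_indices(grp)
            if idx.size == 0:
                continue
            name = grp if len(layers) == 1 else f"{lay.layer_name}:{grp}"
            columns.append(name)
            scores_cols.append(lay.values[:, idx].mean(axis=1))
    if not columns:
        raise DataError("no non-empty groups")
    score_mat = np.column_stack(scores_cols)

    rows, names, dropped = [], [], []
    for set_name, genes in collection.sets.items():
        members = np.array([gene_pos[g] for g in genes if g in gene_pos], int)
        if members.size == 0:
            dropped.append(set_name)
            continue
        mask = np.zeros(len(som.gene_ids), bool)
        mask[members] = True
        rows.append([gsz_score(score_mat[:, j], mask, cfg) for j in range(len(columns))])
        names.append(set_name)
    if dropped:
        logger.warning("dropped %d set(s) with no universe overlap", len(dropped))
    if not rows:
        raise DataError("no gene set overlaps the trained gene universe")
    mat = pd.DataFrame(rows, index=names, columns=columns)
    if len(rows) >= 3:
        link = average(pdist(mat.to_numpy(), metric="euclidean"))
        order = list(leaves_list(link))
    else:
        link, order = None, list(range(len(rows)))
    return GSZResult(mat, order, link, dropped)


def upregulated_overlap(
    z: pd.DataFrame, z_cutoff: float = 2.0
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Pairwise overlap counts of gene sets upregulated per group column.

    Returns the symmetric counts matrix (diagonal = each group's own
    count) and the passing set names per column.
    """
    if z.shape[1] < 2:
        raise DataError("need at least two result columns")
    passing = {col: set(z.index[z[col] >= z_cutoff]) for col in z.columns}
    counts = pd.DataFrame(
        [[len(passing[a] & passing[b]) for b in z.columns] for a in z.columns],
        index=z.columns, columns=z.columns, dtype=int,
    )
    return counts, passing
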