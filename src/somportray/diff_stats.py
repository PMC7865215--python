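"""Per-gene differential expression between mutation groups.

Each pairwise comparison runs a Welch unequal-variance t-test per gene on
the centred log10 expression values, adjusts p-values with the
Benjamini-Hochberg step-up procedure, counts deregulated genes at the FDR
thresholds of interest, and annotates the comparison with stars following
the convention: "**" for more than 1000 genes at FDR < 0.05, "*" for more
than 100, "" otherwise. logFC is the difference of group means on the log10
scale. One-way ANOVA across all five groups and a z-scored, hierarchically
clustered gene-panel heatmap (e.g. the PARP family panel) support
per-gene-family views.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .data_core import GROUPS, DataError, ExpressionLayer

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1000, "**"), (100, "*"))  # counts at FDR < 0.05


@dataclass
class DifferentialResult:
    comparison: tuple[str, str, str]          # (groupA, groupB, layer)
    table: pd.DataFrame                       # gene_id, logFC, t, p, fdr
    counts_at: dict[float, int]
    stars: str
    top_genes: pd.DataFrame                   # strongest up/down by logFC


@dataclass
class AnovaResult:
    gene_id: str
    group_means: dict[str, float]
    F: float
    p: float


@dataclass
class PanelHeatmap:
    matrix: pd.DataFrame                      # z-scored genes x groups
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)


def welch_test(x, y) -> tuple[float, float]:
    """Welch t-test with Satterthwaite df; two-sided p.

    Degenerate case: zero variance in both groups with equal means yields
    (t, p) = (0, 1); unequal means with zero variance yields (inf, 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise DataError("welch_test needs at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_de(
    layer: ExpressionLayer,
    group_a: str,
    group_b: str,
    thresholds: tuple[float, ...] = (0.05, 0.01),
    n_top: int = 4,
) -> DifferentialResult:
    """Genome-wide Welch + BH between two mutation groups of one layer."""
    ia, ib = layer.group_indices(group_a), layer.group_indices(group_b)
    if ia.size < 2 or ib.size < 2:
        raise DataError(
            f"groups need >=2 samples ({group_a}: {ia.size}, {group_b}: {ib.size})"
        )
    A, B = layer.values[:, ia], layer.values[:, ib]
    with warnings.catch_warnings():
        # near-constant genes trip scipy's catastrophic-cancellation warning;
        # their degenerate statistics are redefined explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    logfc = A.mean(axis=1) - B.mean(axis=1)
    # genes constant in both groups: define t=0, p=1 when means agree
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = degenerate & (logfc == 0)
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        diff = degenerate & (logfc != 0)
        t = np.where(diff, np.sign(logfc) * np.inf, t)
        p = np.where(diff, 0.0, p)
    fdr = bh_fdr(p)
    table = pd.DataFrame(
        {"gene_id": layer.gene_ids, "logFC": logfc, "t": t, "p": p, "fdr": fdr}
    )
    counts_at = {thr: int(np.sum(fdr < thr)) for thr in sorted(thresholds, reverse=True)}
    n05 = int(np.sum(fdr < 0.05))
    stars = next((s for thr, s in STAR_THRESHOLDS if n05 > thr), "")
    by_fc = table.sort_values("logFC", ascending=False)
    top = pd.concat([by_fc.head(n_top), by_fc.tail(n_top)])
    top = top.assign(
        direction=["up"] * n_top + ["down"] * n_top,
        significance=[_gene_stars(f) for f in top["fdr"]],
    )
    logger.info(
        "%s vs %s (%s): %d genes at FDR<0.05 %s",
        group_a, group_b, layer.layer_name, n05, stars,
    )
    return DifferentialResult(
        (group_a, group_b, layer.layer_name), table, counts_at, stars, top
    )


def _gene_stars(fdr: float) -> str:
    if fdr <= 0.01:
        return "**"
    if fdr <= 0.05:
        return "*"
    return ""


def one_way_anova(layer: ExpressionLayer, gene_id: str, groups=GROUPS) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of a gene across groups."""
    if gene_id not in layer.gene_ids:
        raise DataError(f"gene {gene_id!r} not in layer {layer.layer_name!r}")
    row = layer.values[layer.gene_ids.index(gene_id)]
    samples, means = [], {}
    for g in groups:
        idx = layer.group_indices(g)
        if idx.size:
            means[g] = float(row[idx].mean())
        if idx.size >= 2:
            samples.append(row[idx])
    if len(samples) < 2:
        raise DataError("one-way ANOVA needs >=2 groups with >=2 samples each")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*samples)
    return AnovaResult(gene_id, means, float(F), float(p))


def panel_heatmap(
    layer: ExpressionLayer, gene_panel, groups=GROUPS
) -> PanelHeatmap:
    """Group-mean matrix of a gene panel, row z-scored and clustered.

    Hierarchical clustering uses average linkage on Euclidean distances for
    both rows (genes) and columns (groups). Panel genes absent from the
    layer are dropped with a warning.
    """
    present = [g for g in gene_panel if g in layer.gene_ids]
    dropped = [g for g in gene_panel if g not in layer.gene_ids]
    if dropped:
        logger.warning("panel: dropped %d missing genes: %s", len(dropped), dropped)
    if len(present) < 2:
        raise DataError("need at least 2 panel genes present in the layer")
    used = [g for g in groups if layer.group_indices(g).size > 0]
    if len(used) < 2:
        raise DataError("need at least 2 non-empty groups")
    gi = [layer.gene_ids.index(g) for g in present]
    M = np.column_stack(
        [layer.values[np.ix_(gi, layer.group_indices(g))].mean(axis=1) for g in used]
    )
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    row_link = average(pdist(Z, metric="euclidean"))
    col_link = average(pdist(Z.T, metric="euclidean"))
    return PanelHeatmap(
        pd.DataFrame(Z, index=present, columns=used),
        list(leaves_list(row_link)),
        list(leaves_list(col_link)),
        row_link,
        col_link,
        dropped,
    )
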