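"""Expression portraits: per-sample, group-mean and difference grids.

A portrait arranges a sample's metagene expression values on the SOM grid.
A metagene's value in a sample is the mean expression of its member genes
in that sample (the cluster-mean reading of a metagene profile), so the
group-mean portrait equals, cell by cell, the mean of its members' sample
portraits. Difference portraits subtract two portraits to expose
group-specific up-/down-regulation. Units that received no genes during
training are flagged empty (NaN) and rendered neutral grey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from PIL import Image

from .data_core import DataError, ExpressionLayer, write_values, read_values
from .som import TrainedSOM

logger = logging.getLogger(__name__)

#: blue (minimum) -> white -> maroon (maximum), the portrayal palette
PORTRAIT_CMAP = LinearSegmentedColormap.from_list(
    "portrait", ["#00008B", "#FFFFFF", "#800000"]
)


@dataclass
class Portrait:
    grid: np.ndarray          # grid_rows x grid_cols, NaN = empty unit
    subject: str              # sample id | group label | "A minus B"
    layer_name: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def nonempty_values(self) -> np.ndarray:
        return self.grid[np.isfinite(self.grid)]


@dataclass
class SignatureProjection:
    signature_name: str
    hits: list[tuple[str, int, int]]   # (gene_id, row, col)
    misses: list[str]


def metagene_expression(som: TrainedSOM, layer: ExpressionLayer) -> np.ndarray:
    """K x n_samples matrix of per-unit mean member-gene expression.

    Empty units are NaN for every sample: emptiness is a property of the
    trained map, not of any particular sample.
    """
    if layer.gene_ids != som.gene_ids:
        raise DataError("layer gene universe does not match the trained map")
    K = som.n_units
    sums = np.zeros((K, layer.n_samples))
    np.add.at(sums, som.bmu, layer.values)
    counts = np.bincount(som.bmu, minlength=K).astype(float)
    with np.errstate(invalid="ignore"):
        out = sums / counts[:, None]
    out[counts == 0, :] = np.nan
    return out


def _to_grid(som: TrainedSOM, per_unit: np.ndarray) -> np.ndarray:
    return per_unit.reshape(som.config.grid_rows, som.config.grid_cols)


def sample_portrait(som: TrainedSOM, layer: ExpressionLayer, sample_id: str) -> Portrait:
    if sample_id not in layer.sample_ids:
        raise DataError(f"unknown sample {sample_id!r} in layer {layer.layer_name!r}")
    j = layer.sample_ids.index(sample_id)
    per_unit = metagene_expression(som, layer)[:, j]
    return Portrait(_to_grid(som, per_unit), sample_id, layer.layer_name)


def group_mean_portrait(som: TrainedSOM, layer: ExpressionLayer, group: str) -> Portrait:
    idx = layer.group_indices(group)
    if idx.size == 0:
        raise DataError(f"group {group!r} has no samples in layer {layer.layer_name!r}")
    per_unit = metagene_expression(som, layer)[:, idx].mean(axis=1)
    return Portrait(_to_grid(som, per_unit), group, layer.layer_name)


def difference_portrait(a: Portrait, b: Portrait) -> Portrait:
    if a.shape != b.shape:
        raise DataError(f"portrait shapes differ: {a.shape} vs {b.shape}")
    if a.layer_name != b.layer_name:
        raise DataError("difference portraits require the same layer")
    return Portrait(a.grid - b.grid, f"{a.subject} minus {b.subject}", a.layer_name)


def render_portrait(
    p: Portrait,
    path,
    scale: int = 10,
    symmetric: bool | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Write the portrait as a PNG plus a sidecar TSV of the numeric grid.

    Colours run blue -> white -> maroon from minimum to maximum. Difference
    portraits (detected by " minus " in the subject, or ``symmetric=True``)
    centre white at zero. Empty units are grey and excluded from the scale.
    ``vmin``/``vmax`` override the per-portrait limits to share one scale
    across several portraits. The image is ``scale`` pixels per grid cell.
    """
    path = Path(path)
    grid = p.grid
    vals = p.nonempty_values()
    if vals.size == 0:
        raise DataError("portrait has no non-empty cells")
    if symmetric is None:
        symmetric = " minus " in p.subject
    lo = np.min(vals) if vmin is None else vmin
    hi = np.max(vals) if vmax is None else vmax
    if symmetric:
        m = max(abs(lo), abs(hi), 1e-300)
        lo, hi = -m, m
    if hi <= lo:  # constant portrait: map everything to the midpoint
        norm = np.full_like(grid, 0.5)
    else:
        norm = (grid - lo) / (hi - lo)
    rgba = PORTRAIT_CMAP(np.clip(np.nan_to_num(norm, nan=0.5), 0, 1))
    rgb = (rgba[:, :, :3] * 255).astype(np.uint8)
    rgb[~np.isfinite(grid)] = (128, 128, 128)
    big = np.kron(rgb, np.ones((scale, scale, 1), dtype=np.uint8))
    Image.fromarray(big).save(path)
    write_values(
        [str(r) for r in range(grid.shape[0])],
        [str(c) for c in range(grid.shape[1])],
        grid,
        path.with_suffix(".tsv"),
    )
    logger.info("rendered portrait %r to %s", p.subject, path)


def read_portrait_grid(path) -> np.ndarray:
    """Read back a sidecar TSV grid written by `render_portrait`."""
    _, _, values = read_values(path)
    return values


def project_signature(som: TrainedSOM, gene_list, name: str) -> SignatureProjection:
    """Map a signature gene list onto grid coordinates of assigned metagenes."""
    gene_list = list(gene_list)
    if not gene_list:
        raise DataError("empty signature gene list")
    assignment = som.gene_assignment
    hits, misses = [], []
    for g in gene_list:
        if g in assignment:
            r, c = som.coords(assignment[g])
            hits.append((g, r, c))
        else:
            misses.append(g)
    if misses:
        logger.warning(
            "signature %r: %d of %d genes not in the trained universe",
            name, len(misses), len(gene_list),
        )
    return SignatureProjection(name, hits, misses)


def read_signature(path) -> list[str]:
    """Read a signature list: one gene ID per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes
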