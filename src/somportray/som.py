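"""Multi-layer batch self-organizing map over gene expression profiles.

Genes are clustered onto a rectangular grid of *metagenes* (default 45x45 =
2025 units) by minimal Euclidean distance between each gene's profile —
the concatenation of its centred per-layer expression vectors — and the
unit's codebook vector. Training one map on the joint profile space makes
every layer share a single gene-to-unit assignment, so a gene occupies the
same grid position in every cohort and portraits are directly comparable
across layers.

The batch variant is used: each epoch all genes are assigned to their
best-matching unit (BMU) and every codebook row is recomputed as the
Gaussian-neighbourhood-weighted mean of the gene profiles, with the
neighbourhood radius decaying linearly between epochs. Batch updates make
training deterministic for a given seed and initialisation mode. As the
radius vanishes the update degenerates to Lloyd's k-means iteration, which
provides an independent correctness oracle (`kmeans_limit_check`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .data_core import DataError, MultiLayerDataset, write_values, read_values

logger = logging.getLogger(__name__)


@dataclass
class SOMConfig:
    grid_rows: int = 45
    grid_cols: int = 45
    epochs: int = 100
    initial_radius: float | None = None  # defaults to max(rows, cols) / 2
    final_radius: float = 0.5
    init: str = "pca"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DataError("grid dimensions must be positive")
        if self.epochs < 1:
            raise DataError("epochs must be positive")
        if self.initial_radius is None:
            self.initial_radius = max(self.grid_rows, self.grid_cols) / 2.0
        if not (self.initial_radius >= self.final_radius > 0):
            raise DataError("need initial_radius >= final_radius > 0")
        if self.init not in ("pca", "random"):
            raise DataError(f"unknown init mode {self.init!r}")

    @property
    def n_units(self) -> int:
        """Number of metagene units K = grid_rows * grid_cols."""
        return self.grid_rows * self.grid_cols


@dataclass
class MetageneProfile:
    """Mean profile of a metagene's member genes; NaN-filled when empty."""

    values: np.ndarray
    empty: bool


@dataclass
class TrainedSOM:
    """A trained map: codebook, per-layer column slices, gene assignment.

    Grid convention: unit index k maps to 0-based row-major coordinates
    ``(row, col) = (k // grid_cols, k % grid_cols)``.
    """

    config: SOMConfig
    codebook: np.ndarray            # K x D
    layer_slices: dict[str, tuple[int, int]]
    gene_ids: list[str]
    bmu: np.ndarray                 # per-gene unit index, len N

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.codebook)):
            raise DataError("codebook contains non-finite entries")
        if len(self.bmu) != len(self.gene_ids):
            raise DataError("assignment length mismatch")

    @property
    def n_units(self) -> int:
        return self.config.n_units

    @property
    def gene_assignment(self) -> dict[str, int]:
        return {g: int(k) for g, k in zip(self.gene_ids, self.bmu)}

    def coords(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_units:
            raise IndexError(f"metagene index {k} out of range")
        return k // self.config.grid_cols, k % self.config.grid_cols

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.bmu, minlength=self.n_units)

    def grid_coordinates(self) -> np.ndarray:
        """K x 2 array of (row, col) per unit."""
        rows, cols = self.config.grid_rows, self.config.grid_cols
        rr, cc = np.divmod(np.arange(rows * cols), cols)
        return np.column_stack([rr, cc]).astype(float)


def concatenate_profiles(ds: MultiLayerDataset) -> np.ndarray:
    """Stack each gene's centred per-layer profiles side by side (N x D)."""
    return np.hstack([lay.values for lay in ds.layers])


def _layer_slices(ds: MultiLayerDataset) -> dict[str, tuple[int, int]]:
    slices, start = {}, 0
    for lay in ds.layers:
        slices[lay.layer_name] = (start, start + lay.n_samples)
        start += lay.n_samples
    return slices


def _grid_sqdist(rows: int, cols: int) -> np.ndarray:
    xy = np.column_stack(np.divmod(np.arange(rows * cols), cols)).astype(float)
    d = xy[:, None, :] - xy[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _init_codebook(X: np.ndarray, cfg: SOMConfig) -> np.ndarray:
    K, D = cfg.n_units, X.shape[1]
    if cfg.init == "random":
        rng = np.random.default_rng(cfg.seed)
        replace_ = X.shape[0] < K
        idx = rng.choice(X.shape[0], size=K, replace=replace_)
        return X[idx].astype(float).copy()
    # PCA init: span the grid with the first two principal axes, scaled by
    # the standard deviation of the data projected on each axis.
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD; axes beyond the data rank contribute nothing
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    book = np.tile(mean, (K, 1))
    n = max(X.shape[0] - 1, 1)
    rr, cc = np.divmod(np.arange(K), cfg.grid_cols)
    for axis, (coord, extent) in enumerate(
        [(rr, cfg.grid_rows), (cc, cfg.grid_cols)]
    ):
        if axis >= vt.shape[0] or s[axis] <= 0 or extent < 2:
            continue
        scale = 2.0 * s[axis] / np.sqrt(n)  # +/- 2 sd across the grid span
        pos = (coord / (extent - 1) - 0.5) * scale
        book += pos[:, None] * vt[axis][None, :]
    return book


def _assign(X: np.ndarray, book: np.ndarray) -> np.ndarray:
    # squared Euclidean distances; argmin breaks ties at the lowest index
    d = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ book.T
        + np.einsum("ij,ij->i", book, book)[None, :]
    )
    return np.argmin(d, axis=1)


def train_som(ds: MultiLayerDataset, cfg: SOMConfig | None = None) -> TrainedSOM:
    """Batch-train the shared map on the concatenated cross-layer profiles."""
    cfg = cfg or SOMConfig()
    X = concatenate_profiles(ds)
    if not np.all(np.isfinite(X)):
        raise DataError("expression values contain non-finite entries")
    N, D = X.shape
    if N < 1 or D < 1:
        raise DataError("need at least one gene and one sample")
    K = cfg.n_units
    book = _init_codebook(X, cfg)
    gridsq = _grid_sqdist(cfg.grid_rows, cfg.grid_cols)

    for epoch in range(cfg.epochs):
        frac = epoch / (cfg.epochs - 1) if cfg.epochs > 1 else 1.0
        sigma = cfg.initial_radius + frac * (cfg.final_radius - cfg.initial_radius)
        bmu = _assign(X, book)
        sums = np.zeros((K, D))
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=K).astype(float)
        H = np.exp(-gridsq / (2.0 * sigma * sigma))
        num = H @ sums
        den = H @ counts
        nonzero = den > 1e-300
        book = np.where(nonzero[:, None], num / np.where(nonzero, den, 1.0)[:, None], book)
    bmu = _assign(X, book)
    logger.info(
        "trained %dx%d SOM on %d genes, D=%d (%d epochs)",
        cfg.grid_rows, cfg.grid_cols, N, D, cfg.epochs,
    )
    return TrainedSOM(cfg, book, _layer_slices(ds), list(ds.gene_ids), bmu)


def metagene_profile(som: TrainedSOM, ds: MultiLayerDataset, k: int) -> MetageneProfile:
    """Mean concatenated profile over the metagene's member genes."""
    if not 0 <= k < som.n_units:
        raise IndexError(f"metagene index {k} out of range [0, {som.n_units})")
    X = concatenate_profiles(ds)
    members = np.flatnonzero(som.bmu == k)
    if members.size == 0:
        return MetageneProfile(np.full(X.shape[1], np.nan), empty=True)
    return MetageneProfile(X[members].mean(axis=0), empty=False)


def kmeans_limit_check(ds: MultiLayerDataset, cfg: SOMConfig) -> bool:
    """Verify the k-means limit: with a vanishing neighbourhood the trained
    assignment is a Lloyd fixed point of nearest-centroid reassignment.

    Intended for small instances (<=100 genes, K <= 9) with
    ``final_radius`` close to zero.
    """
    som = train_som(ds, cfg)
    X = concatenate_profiles(ds)
    occupied = np.unique(som.bmu)
    centroids = np.vstack([X[som.bmu == u].mean(axis=0) for u in occupied])
    nearest = _assign(X, centroids)
    return bool(np.array_equal(occupied[nearest], som.bmu))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_som(som: TrainedSOM, out_dir) -> None:
    """Write codebook.tsv, assignment.tsv and config.yaml to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [
        f"{name}:{i}"
        for name, (a, b) in som.layer_slices.items()
        for i in range(b - a)
    ]
    write_values([str(k) for k in range(som.n_units)], cols, som.codebook,
                 out / "codebook.tsv")
    rows = som.bmu // som.config.grid_cols
    cc = som.bmu % som.config.grid_cols
    import pandas as pd

    pd.DataFrame(
        {"gene_id": som.gene_ids, "metagene_index": som.bmu, "row": rows, "col": cc}
    ).to_csv(out / "assignment.tsv", sep="\t", index=False)
    cfg = {
        "grid_rows": som.config.grid_rows,
        "grid_cols": som.config.grid_cols,
        "epochs": som.config.epochs,
        "initial_radius": float(som.config.initial_radius),
        "final_radius": float(som.config.final_radius),
        "init": som.config.init,
        "seed": som.config.seed,
        "coordinate_convention": "0-based, row-major, (row, col)",
        "layer_slices": {k: list(v) for k, v in som.layer_slices.items()},
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_som(in_dir) -> TrainedSOM:
    import pandas as pd

    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    slices = {k: tuple(v) for k, v in raw.pop("layer_slices").items()}
    raw.pop("coordinate_convention", None)
    cfg = SOMConfig(**raw)
    _, _, book = read_values(src / "codebook.tsv")
    asg = pd.read_csv(src / "assignment.tsv", sep="\t")
    return TrainedSOM(
        cfg, book, slices, [str(g) for g in asg["gene_id"]],
        asg["metagene_index"].to_numpy(int),
    )
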