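"""Core data containers and preprocessing for cohort expression matrices.

The pipeline operates on raw RNA-seq count matrices (genes x samples), one
per cohort "layer" (e.g. an ovarian and a breast cancer cohort), together
with per-sample annotations carrying a BRCA mutation-group label and
arbitrary clinical phenotype columns.

Preprocessing follows the standard portrayal chain: drop genes with zero
counts in every sample, log10-transform (with a pseudocount), and centre
each gene against its mean expression so that portraits show deviation from
the gene's own baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five mutation-stratified sample groups.
GROUPS = ("gBRCA1", "sBRCA1", "gBRCA2", "sBRCA2", "noBRCA")


class DataError(ValueError):
    """Raised for malformed or degenerate input data."""


@dataclass
class RawCountMatrix:
    """A genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise DataError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise DataError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Annotation of a single sample: mutation group plus phenotype values.

    ``phenotypes`` maps a phenotype name to a numeric or categorical value;
    missing values are ``None`` (or NaN for numeric columns).
    """

    sample_id: str
    group: str
    phenotypes: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )


@dataclass
class ExpressionLayer:
    """One cohort's preprocessed (log10, gene-centred) expression matrix.

    ``annotations`` is a DataFrame indexed by sample id with a mandatory
    ``group`` column; remaining columns are phenotypes.
    """

    layer_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("value matrix shape mismatch")
        missing = [s for s in self.sample_ids if s not in self.annotations.index]
        if missing:
            raise DataError(
                f"layer {self.layer_name!r}: {len(missing)} samples lack "
                f"annotations (first: {missing[0]!r})"
            )
        bad = set(self.annotations["group"]) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group label(s): {sorted(bad)}")
        # keep annotation rows aligned with the sample order
        self.annotations = self.annotations.loc[self.sample_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> np.ndarray:
        """Group label per sample, in sample order."""
        return self.annotations["group"].to_numpy()

    def group_indices(self, label: str) -> np.ndarray:
        if label not in GROUPS:
            raise DataError(f"unknown group {label!r}")
        return np.flatnonzero(self.groups == label)

    def annotation(self, sample_id: str) -> SampleAnnotation:
        row = self.annotations.loc[sample_id]
        phen = {k: v for k, v in row.items() if k != "group"}
        return SampleAnnotation(sample_id, row["group"], phen)


@dataclass
class MultiLayerDataset:
    """Ordered layers sharing one identically ordered gene universe."""

    layers: list[ExpressionLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise DataError("dataset needs at least one layer")
        ref = self.layers[0].gene_ids
        for lay in self.layers[1:]:
            if lay.gene_ids != ref:
                raise DataError(
                    f"layer {lay.layer_name!r} gene universe differs from "
                    f"layer {self.layers[0].layer_name!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.layers[0].gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def layer_names(self) -> list[str]:
        return [lay.layer_name for lay in self.layers]

    def layer(self, name: str) -> ExpressionLayer:
        for lay in self.layers:
            if lay.layer_name == name:
                return lay
        raise KeyError(name)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {what} ID {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path, format: str = "tsv") -> RawCountMatrix:
    """Read a TSV count matrix: first column gene IDs, header sample IDs."""
    if format != "tsv":
        raise DataError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise DataError(f"{path}: no genes in data section")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate first non-numeric cell for the error message
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy() & df.notna().to_numpy())
        if len(bad):
            r, c = bad[0]
            raise DataError(
                f"{path}: non-numeric count at gene {gene_ids[r]!r}, "
                f"sample {sample_ids[c]!r}"
            )
        values = coerced.to_numpy()
    m = RawCountMatrix(gene_ids, sample_ids, values)
    logger.info("read %d genes x %d samples from %s", m.n_genes, m.n_samples, path)
    return m


def write_count_matrix(m: RawCountMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    logger.info("wrote %d genes x %d samples to %s", m.n_genes, m.n_samples, path)


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns: sample_id, group, phenotypes...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise DataError(f"{path}: missing mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise DataError(f"{path}: unknown group label(s) {sorted(bad)}")
    df = df.set_index("sample_id")
    logger.info("read annotations for %d samples from %s", len(df), path)
    return df


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def write_values(gene_ids, sample_ids, values, path) -> None:
    """Write a real-valued matrix as TSV at 12 significant digits."""
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


def read_values(path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(float)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_zero_genes(m: RawCountMatrix) -> RawCountMatrix:
    """Drop genes whose counts are zero in every sample (order preserved)."""
    keep = np.flatnonzero(m.counts.sum(axis=1) > 0)
    if keep.size == 0:
        raise DataError("empty matrix after filtering all-zero genes")
    if keep.size == m.n_genes:
        return m
    logger.info("filtered %d all-zero genes of %d", m.n_genes - keep.size, m.n_genes)
    return RawCountMatrix(
        [m.gene_ids[i] for i in keep], list(m.sample_ids), m.counts[keep]
    )


def log_centralize(
    m: RawCountMatrix, pseudocount: float = 1.0, center: str = "gene"
) -> np.ndarray:
    """log10(count + pseudocount), centred per gene across the layer's samples.

    ``center="gene"`` subtracts each gene's mean across samples (default);
    ``center="global"`` subtracts the single grand mean of the log matrix.
    """
    if pseudocount <= 0:
        raise DataError("pseudocount must be positive")
    logged = np.log10(m.counts.astype(float) + pseudocount)
    if center == "gene":
        return logged - logged.mean(axis=1, keepdims=True)
    if center == "global":
        return logged - logged.mean()
    raise DataError(f"unknown centering mode {center!r}")


def make_layer(
    name: str,
    m: RawCountMatrix,
    annotations: pd.DataFrame,
    pseudocount: float = 1.0,
    center: str = "gene",
) -> ExpressionLayer:
    """Full preprocessing chain: zero-filter, log10, centre, attach annotations."""
    filtered = filter_zero_genes(m)
    values = log_centralize(filtered, pseudocount=pseudocount, center=center)
    return ExpressionLayer(
        name, list(filtered.gene_ids), list(filtered.sample_ids), values, annotations
    )


def build_multilayer(layers: Iterable[ExpressionLayer]) -> MultiLayerDataset:
    """Intersect gene universes and reorder every layer to the common order.

    Genes absent from any layer are dropped (count logged). The common
    order follows the first layer.
    """
    layers = list(layers)
    if not layers:
        raise DataError("no layers given")
    common = set(layers[0].gene_ids)
    for lay in layers[1:]:
        common &= set(lay.gene_ids)
    if not common:
        raise DataError("gene universes have empty intersection")
    order = [g for g in layers[0].gene_ids if g in common]
    total = sum(lay.n_genes for lay in layers)
    dropped = total - len(order) * len(layers)
    if dropped:
        logger.info("dropped %d gene rows absent from some layer", dropped)
    out = []
    for lay in layers:
        if lay.gene_ids == order:
            out.append(lay)
            continue
        pos = {g: i for i, g in enumerate(lay.gene_ids)}
        idx = np.array([pos[g] for g in order])
        out.append(
            ExpressionLayer(
                lay.layer_name, order, list(lay.sample_ids),
                lay.values[idx], lay.annotations,
            )
        )
    return MultiLayerDataset(out)
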