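"""Phenotype maps: per-metagene regression of clinical variables.

For each metagene the phenotype is regressed on that unit's expression
across samples — ordinary least squares for numeric phenotypes, an
L2-penalised logistic regression for (one-vs-rest binarised) categorical
phenotypes — and the coefficient is placed at the unit's grid cell. The
resulting map is compared with expression portraits by Pearson
correlation over the non-empty cells: overlap of high-coefficient and
high-expression regions marks gene clusters associated with the
phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_core import DataError, ExpressionLayer
from .portraits import Portrait, metagene_expression
from .som import TrainedSOM

logger = logging.getLogger(__name__)


@dataclass
class EncodedPhenotype:
    name: str
    kind: str                  # "numeric" | "categorical"
    values: np.ndarray         # float (numeric) or 0/1 indicator (categorical)
    mask: np.ndarray           # True where the phenotype is observed
    level: str | None = None   # binarised level for categorical phenotypes

    @property
    def n_samples_used(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhenotypeMap:
    grid: np.ndarray
    phenotype_name: str
    phenotype_kind: str
    n_samples_used: int

    def nonempty_values(self) -> np.ndarray:
        return self.grid[np.isfinite(self.grid)]


def phenotype_levels(annotations: pd.DataFrame, name: str) -> list[str]:
    col = _column(annotations, name)
    return sorted({str(v) for v in col.dropna().unique()})


def _column(annotations: pd.DataFrame, name: str) -> pd.Series:
    if name not in annotations.columns:
        raise DataError(f"phenotype column {name!r} not found")
    if name == "group":
        raise DataError("'group' is the stratification label, not a phenotype")
    return annotations[name]


def encode_phenotype(
    annotations: pd.DataFrame, name: str, level: str | None = None
) -> EncodedPhenotype:
    """Encode a phenotype column for regression.

    Numeric columns pass through; categorical columns are one-vs-rest
    binarised at ``level`` (each level yields its own map). Missing values
    (empty cells / NaN) are masked out and counted.
    """
    col = _column(annotations, name)
    numeric = pd.to_numeric(col, errors="coerce")
    observed = col.notna() & (col.astype(str).str.strip() != "")
    if observed.sum() == 0:
        raise DataError(f"phenotype {name!r} is entirely missing")
    is_numeric = numeric[observed].notna().all()
    if is_numeric:
        if level is not None:
            raise DataError(f"numeric phenotype {name!r} takes no level")
        return EncodedPhenotype(
            name, "numeric", numeric.to_numpy(float), observed.to_numpy()
        )
    levels = phenotype_levels(annotations, name)
    if len(levels) < 2:
        raise DataError(f"categorical phenotype {name!r} has a single level")
    if level is None:
        raise DataError(
            f"categorical phenotype {name!r} needs a level; available: {levels}"
        )
    if level not in levels:
        raise DataError(f"level {level!r} not among {levels}")
    indicator = (col.astype(str) == level).astype(float).to_numpy()
    return EncodedPhenotype(name, "categorical", indicator, observed.to_numpy(), level)


def phenotype_map(
    som: TrainedSOM,
    layer: ExpressionLayer,
    encoded: EncodedPhenotype,
    penalty: float = 1.0,
    min_samples: int = 8,
    direction: str = "expression",
) -> PhenotypeMap:
    """Regression-coefficient grid for one (encoded) phenotype.

    Per metagene k, numeric phenotypes give the OLS slope of the simple
    regression between the phenotype and metagene_k expression across
    samples. ``direction="expression"`` (default) takes metagene
    expression as the response (slope = cov(x_k, y) / var(y)): units
    unrelated to the phenotype then get near-zero coefficients regardless
    of their expression variance, which keeps maps stable. With
    ``direction="phenotype"`` the phenotype is the response
    (slope = cov / var(x_k)); note that low-variance units then produce
    noisy coefficients. Categorical phenotypes always use a logistic
    regression of the level indicator on metagene expression, with an L2
    penalty (strength ``penalty``) so the coefficient stays finite under
    perfect separation. Empty metagenes are NaN; constant predictors get
    coefficient 0.
    """
    if direction not in ("expression", "phenotype"):
        raise DataError(f"unknown regression direction {direction!r}")
    if len(encoded.values) != layer.n_samples:
        raise DataError("phenotype vector length does not match the layer")
    mask = encoded.mask & np.isfinite(encoded.values)
    n_used = int(mask.sum())
    if n_used < min_samples:
        raise DataError(f"only {n_used} usable samples (< {min_samples})")
    y = encoded.values[mask]
    M = metagene_expression(som, layer)[:, mask]   # K x n_used
    K = M.shape[0]
    coef = np.full(K, np.nan)
    nonempty = np.isfinite(M[:, 0])
    if encoded.kind == "numeric":
        X = M[nonempty]
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        num = xc @ yc
        if direction == "expression":
            denom = np.full(X.shape[0], float(yc @ yc))
        else:
            denom = np.einsum("ij,ij->i", xc, xc)
        coef[nonempty] = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        if len(np.unique(y)) < 2:
            raise DataError("indicator has a single class among usable samples")
        model = LogisticRegression(C=1.0 / penalty, solver="lbfgs")  # l2 default
        for k in np.flatnonzero(nonempty):
            x = M[k]
            if np.ptp(x) == 0:
                coef[k] = 0.0
                continue
            model.fit(x[:, None], y)
            coef[k] = model.coef_[0, 0]
    name = encoded.name if encoded.level is None else f"{encoded.name}={encoded.level}"
    return PhenotypeMap(
        coef.reshape(som.config.grid_rows, som.config.grid_cols),
        name, encoded.kind, n_used,
    )


def map_correlation(phen: PhenotypeMap, port: Portrait) -> float:
    """Pearson correlation between a phenotype map and a portrait.

    Computed over cells that are non-empty in both grids. Returns NaN (the
    undefined-correlation flag) when either grid is constant there.
    """
    if phen.grid.shape != port.grid.shape:
        raise DataError("grids have different shapes")
    mask = np.isfinite(phen.grid) & np.isfinite(port.grid)
    if mask.sum() < 3:
        raise DataError("need at least 3 paired non-empty cells")
    a, b = phen.grid[mask], port.grid[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant map in correlation; returning NaN")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
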