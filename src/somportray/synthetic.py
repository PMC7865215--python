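"""Synthetic mutation-stratified RNA-seq cohorts with planted structure.

The generator emulates the study design the pipeline targets: two cohort
layers (ovarian- and breast-like) sharing one gene universe, samples
stratified into the five BRCA mutation groups at the observed cohort
proportions (OV: 19/14/16/8/281; BRCA: 12/28/15/26/613), planted
co-expressed gene modules that are shifted up or down in specific groups,
negative-binomial count noise, and clinical phenotype variables coupled to
the planted modules.

Per gene g and sample s the count is drawn as

    count ~ NB(mean = 10 ** (mu_g + delta_gs), dispersion = phi)

with ``mu_g`` uniform on ``base_log_mean_range`` and ``delta_gs`` the sum
of the module's group effect (a log10 shift, applied when s belongs to the
module's target group and layer) and a shared per-sample latent factor
that induces within-module co-expression — the structure SOM locality is
supposed to find. Numeric phenotypes are linear in the coupled module's
latent factor plus Gaussian noise; categorical phenotypes threshold the
same construct at its median. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_core import (
    GROUPS,
    DataError,
    MultiLayerDataset,
    RawCountMatrix,
    build_multilayer,
    make_layer,
)

logger = logging.getLogger(__name__)

#: Observed cohort composition: samples per mutation group and layer.
DEFAULT_GROUP_SIZES: dict[str, dict[str, int]] = {
    "OV": {"gBRCA1": 19, "sBRCA1": 14, "gBRCA2": 16, "sBRCA2": 8, "noBRCA": 281},
    "BRCA": {"gBRCA1": 12, "sBRCA1": 28, "gBRCA2": 15, "sBRCA2": 26, "noBRCA": 613},
}


@dataclass
class ModuleSpec:
    module_id: str
    n_genes: int
    target_group: str
    effect: float                       # log10 shift in the target group
    target_layers: tuple[str, ...] | None = None   # None = all layers

    def __post_init__(self) -> None:
        if self.target_group not in GROUPS:
            raise DataError(f"unknown target group {self.target_group!r}")
        if not np.isfinite(self.effect):
            raise DataError("module effect must be finite")


@dataclass
class PhenotypeSpec:
    name: str
    kind: str                           # "numeric" | "categorical"
    coupled_module: str
    coupling_strength: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise DataError(f"unknown phenotype kind {self.kind!r}")


@dataclass
class SyntheticConfig:
    n_genes: int = 3000
    group_sizes: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_SIZES.items()}
    )
    modules: list[ModuleSpec] = field(default_factory=list)
    nb_dispersion: float = 0.2
    base_log_mean_range: tuple[float, float] = (1.0, 3.0)
    module_factor_sd: float = 0.4
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise DataError("nb_dispersion must be positive")
        total_module_genes = sum(m.n_genes for m in self.modules)
        if total_module_genes > self.n_genes:
            raise DataError(
                f"{total_module_genes} module genes exceed n_genes={self.n_genes}"
            )
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate module ids")
        for layer, sizes in self.group_sizes.items():
            for grp, n in sizes.items():
                if grp not in GROUPS:
                    raise DataError(f"unknown group {grp!r} in layer {layer!r}")
                if n <= 0:
                    raise DataError(f"group size must be positive ({layer}/{grp})")


@dataclass
class SyntheticTruth:
    module_membership: dict[str, str | None]        # gene -> module_id or None
    modules: list[ModuleSpec]
    phenotypes: list[PhenotypeSpec]
    latent_factors: dict[str, dict[str, np.ndarray]]  # layer -> module -> per-sample

    def module_genes(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_id]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[dict[str, RawCountMatrix], dict[str, pd.DataFrame], SyntheticTruth]:
    """Draw raw count matrices, annotations and the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.base_log_mean_range
    mu = rng.uniform(lo, hi, size=cfg.n_genes)

    # assign module genes: a random disjoint block per module
    membership: dict[str, str | None] = {g: None for g in gene_ids}
    pool = rng.permutation(cfg.n_genes)
    offset = 0
    module_rows: dict[str, np.ndarray] = {}
    for mod in cfg.modules:
        rows = np.sort(pool[offset:offset + mod.n_genes])
        offset += mod.n_genes
        module_rows[mod.module_id] = rows
        for r in rows:
            membership[gene_ids[r]] = mod.module_id

    matrices: dict[str, RawCountMatrix] = {}
    annotations: dict[str, pd.DataFrame] = {}
    factors: dict[str, dict[str, np.ndarray]] = {}
    for layer_name, sizes in cfg.group_sizes.items():
        groups = [g for g in GROUPS if g in sizes]
        labels = np.repeat(groups, [sizes[g] for g in groups])
        n_samples = labels.size
        sample_ids = [f"{layer_name}_S{i:04d}" for i in range(n_samples)]

        delta = np.zeros((cfg.n_genes, n_samples))
        factors[layer_name] = {}
        for mod in cfg.modules:
            f = rng.normal(0.0, cfg.module_factor_sd, size=n_samples)
            factors[layer_name][mod.module_id] = f
            rows = module_rows[mod.module_id]
            delta[rows, :] += f[None, :]
            if mod.target_layers is None or layer_name in mod.target_layers:
                hit = labels == mod.target_group
                delta[np.ix_(rows, np.flatnonzero(hit))] += mod.effect

        mean = np.power(10.0, mu[:, None] + delta)
        counts = _nb_counts(rng, mean, cfg.nb_dispersion)
        matrices[layer_name] = RawCountMatrix(gene_ids, sample_ids, counts)

        ann = pd.DataFrame({"group": labels}, index=pd.Index(sample_ids, name="sample_id"))
        for ph in cfg.phenotypes:
            if ph.coupled_module not in factors[layer_name]:
                raise DataError(f"phenotype {ph.name!r} couples unknown module")
            base = ph.coupling_strength * factors[layer_name][ph.coupled_module]
            noisy = base + rng.normal(0.0, ph.noise_sd, size=n_samples)
            if ph.kind == "numeric":
                ann[ph.name] = noisy
            else:
                ann[ph.name] = np.where(noisy > np.median(noisy), "high", "low")
        annotations[layer_name] = ann
        logger.info(
            "layer %s: %d genes x %d samples (%s)",
            layer_name, cfg.n_genes, n_samples,
            ", ".join(f"{g}={sizes[g]}" for g in groups),
        )

    truth = SyntheticTruth(membership, list(cfg.modules), list(cfg.phenotypes), factors)
    return matrices, annotations, truth


def to_dataset(
    matrices: dict[str, RawCountMatrix],
    annotations: dict[str, pd.DataFrame],
    pseudocount: float = 1.0,
) -> MultiLayerDataset:
    """Preprocess generated matrices into a joint multi-layer dataset."""
    layers = [
        make_layer(name, matrices[name], annotations[name], pseudocount=pseudocount)
        for name in matrices
    ]
    return build_multilayer(layers)


def small_fixture_config(seed: int = 7) -> SyntheticConfig:
    """Configuration of the bundled tiny study: 200 genes, 2 layers,
    20 samples per layer, two 30-gene modules at effect 1.0 log10 and a
    numeric plus a categorical phenotype coupled to them."""
    return SyntheticConfig(
        n_genes=200,
        group_sizes={
            "L1": {"gBRCA1": 4, "sBRCA1": 3, "gBRCA2": 3, "sBRCA2": 2, "noBRCA": 8},
            "L2": {"gBRCA1": 4, "sBRCA1": 3, "gBRCA2": 3, "sBRCA2": 2, "noBRCA": 8},
        },
        modules=[
            ModuleSpec("M1", 30, "gBRCA1", 1.0),
            ModuleSpec("M2", 30, "gBRCA2", 1.0),
        ],
        phenotypes=[
            PhenotypeSpec("aneuploidy_score", "numeric", "M1", 2.0, 0.5),
            PhenotypeSpec("stage", "categorical", "M2", 2.0, 0.5),
        ],
        seed=seed,
    )


def small_fixture(seed: int = 7):
    """Deterministic tiny dataset for fast tests: raw matrices,
    annotations and planted truth (see `small_fixture_config`)."""
    return generate_dataset(small_fixture_config(seed))
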