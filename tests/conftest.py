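import numpy as np
import pandas as pd
import pytest

from somportray import (
    ExpressionLayer,
    MultiLayerDataset,
    SOMConfig,
    small_fixture,
    to_dataset,
    train_som,
)

#: analysis settings for the bundled 9x9 small-grid study
SMALL_GRID = dict(grid_rows=9, grid_cols=9, epochs=60)
SPOT_QUANTILE = 0.85  # planted modules cover ~15% of the gene universe


def make_layer_from_values(values, groups=None, name="L", phenotypes=None):
    """Wrap a raw value matrix (already centred or not) into a layer."""
    values = np.asarray(values, float)
    n, d = values.shape
    genes = [f"g{i}" for i in range(n)]
    samples = [f"s{j}" for j in range(d)]
    groups = list(groups) if groups is not None else ["noBRCA"] * d
    ann = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample_id"))
    if phenotypes:
        for k, v in phenotypes.items():
            ann[k] = v
    return ExpressionLayer(name, genes, samples, values, ann)


def make_dataset_from_values(values, **kw):
    return MultiLayerDataset([make_layer_from_values(values, **kw)])


@pytest.fixture(scope="session")
def fixture_bundle():
    """The bundled tiny study plus a trained 9x9 map (seed 7)."""
    mats, anns, truth = small_fixture(seed=7)
    ds = to_dataset(mats, anns)
    som = train_som(ds, SOMConfig(**SMALL_GRID, seed=7))
    return mats, anns, truth, ds, som
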