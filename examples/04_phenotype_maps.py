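"""Phenotype maps and their correlation with expression portraits.

The fixture's numeric 'aneuploidy_score' is coupled to the planted
gBRCA1 module, so its regression-coefficient map should overlap the
gBRCA1 portrait's up-spot: a strong positive Pearson correlation.
"""

from somportray import (
    GROUPS,
    SOMConfig,
    encode_phenotype,
    group_mean_portrait,
    map_correlation,
    phenotype_map,
    small_fixture,
    to_dataset,
    train_som,
)

mats, anns, truth = small_fixture(seed=7)
ds = to_dataset(mats, anns)
som = train_som(ds, SOMConfig(grid_rows=9, grid_cols=9, epochs=60, seed=7))
layer = ds.layers[0]

enc = encode_phenotype(layer.annotations, "aneuploidy_score")
pmap = phenotype_map(som, layer, enc)
print(f"phenotype map {pmap.phenotype_name!r} from {pmap.n_samples_used} samples")

print("correlation of the map with each group portrait "
      "(high r = the phenotype tracks that group's expression program):")
for g in GROUPS:
    r = map_correlation(pmap, group_mean_portrait(som, layer, g))
    marker = "  <- coupled module's target group" if g == "gBRCA1" else ""
    print(f"  {g:8s} r = {r:+.2f}{marker}")

# categorical phenotypes are binarised per level
enc2 = encode_phenotype(layer.annotations, "stage", level="high")
pmap2 = phenotype_map(som, layer, enc2)
r = map_correlation(pmap2, group_mean_portrait(som, layer, "gBRCA2"))
print(f"\nlogistic map {pmap2.phenotype_name!r} vs gBRCA2 portrait: r = {r:+.2f}")
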