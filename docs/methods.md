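# Methods

## Model and procedure

`somportray` reduces one or more cohort expression matrices to a shared
rectangular grid of metagenes and reads all downstream analyses off that
grid. The chain is:

1. **Preprocessing** (`data_core`). Genes with zero counts in every sample
   of a layer are removed; remaining counts are log10-transformed with a
   pseudocount and centred per gene across the layer's samples. Centring
   per gene (rather than subtracting a single grand mean) is what makes a
   portrait cell read as "above/below this gene set's own baseline", which
   is the contrast the portraits are meant to show; the single-scalar
   alternative is available via `center="global"`. The pseudocount defaults
   to 1 so that zero counts map to 0 before centring. When several layers
   are joined, gene universes are intersected (exact string match, no
   identifier translation) and every layer is reordered to the common
   order.

2. **Multi-layer SOM** (`som`). Each gene's centred per-layer profiles are
   concatenated, and a single batch SOM is trained on the joint vectors.
   Because one assignment is trained on the concatenation, every layer
   shares it, and a gene sits at the same grid coordinate in every cohort
   by construction. Batch training (assign all genes to their best-matching
   unit, then recompute every codebook row as the neighbourhood-weighted
   mean) was chosen over online training because it is deterministic given
   the seed and initialisation, at identical clustering quality for this
   use. The neighbourhood is Gaussian, `exp(−d²/2σ²)` on grid coordinates,
   with σ decayed linearly from `initial_radius` (default half the larger
   grid side) to `final_radius` (default 0.5) over the epochs (default
   100). Initialisation is PCA by default — codebook rows span ±2 SD of
   the data along the first two principal axes, mapped to grid rows and
   columns — which is deterministic without randomness; `init="random"`
   samples genes as initial codebook rows using the seed. Best-matching-
   unit ties break to the lowest unit index. Units whose neighbourhood
   receives no mass keep their previous codebook row. Layers are not
   re-weighted: each contributes to the Euclidean distance in proportion
   to its sample count, so a larger cohort influences the map more — the
   natural reading of joint training, exposed rather than hidden.

   As σ → 0 the batch update degenerates to Lloyd's k-means iteration;
   `kmeans_limit_check` trains with a near-zero final radius and verifies
   that the final assignment is a fixed point of nearest-centroid
   reassignment. This is the engine's independent correctness oracle and
   part of the acceptance suite (10/10 small random instances).

3. **Portraits** (`portraits`). A metagene's value in a sample is the mean
   centred expression of its member genes in that sample — the
   cluster-mean reading of a metagene profile — rather than the codebook
   entry; group portraits are therefore exactly the cell-wise mean of
   their members' sample portraits (asserted to 1e-9), and difference
   portraits are exactly antisymmetric. Units left empty by training are
   NaN for every sample (emptiness is a property of the map), rendered
   neutral grey and excluded from colour scaling. Group portraits scale
   per portrait min/max; difference portraits centre white at zero. A
   shared scale across portraits is available via `vmin`/`vmax`.

4. **Spot modules and enrichment** (`spots`). Spot detection thresholds
   the portrait at a quantile of its non-empty values (strict inequality,
   so a constant portrait yields nothing), groups passing cells by
   8-connectivity, and keeps components with at least `min_cells` cells.
   The defaults (quantile 0.98, min 3 cells) suit a 45×45 grid where a
   spot of interest covers ~1–2% of the 2025 units. Fisher enrichment is
   the one-sided hypergeometric tail of the 2×2 spot × set table. The
   Gene Set Z-score is instantiated as the random-set statistic: with S
   the summed per-gene scores of a set of size m among N genes,
   E = m·mean, V = m(N−m)/(N−1)·var (population variance, i.e. drawing m
   scores without replacement), z = (S−E)/√(V+λ). λ (default 0.1)
   stabilises near-degenerate sets; constant score vectors define z = 0.
   This is a declared instantiation of the set-Z family of statistics,
   not a transcription of any particular implementation.

5. **Differential statistics** (`diff_stats`). The per-gene two-group test
   is Welch's unequal-variance t on the centred log10 values with
   Benjamini–Hochberg adjustment — chosen as a robust default that needs
   no count-model fitting; variance-moderated and negative-binomial GLM
   tests are deliberately out of scope. logFC is the difference of group
   means on the log10 scale. Genes constant in both groups get (t, p) =
   (0, 1) when means agree. Deregulated-gene counts are annotated `*`
   (>100) or `**` (>1000 genes at FDR < 0.05). Gene panels use classical
   one-way ANOVA, and panel heatmaps z-score rows (ddof = 1) and cluster
   rows and columns with average linkage on Euclidean distances.

6. **Phenotype maps** (`phenotypes`). Per metagene, a simple regression
   links the unit's expression across samples to one clinical variable,
   and the coefficient is placed at the unit's cell. For numeric
   phenotypes the default regresses **metagene expression on the
   phenotype** (slope = cov/var(phenotype)). The opposite direction —
   phenotype as response, slope = cov/var(expression) — is available as
   `direction="phenotype"` but is not the default because units with tiny
   expression variance then carry slopes with enormous sampling noise,
   and the map degenerates into that noise (measured r ≈ 0.14 against the
   target portrait on the validation fixture, versus ≈ 0.87 for the
   default). Categorical phenotypes are one-vs-rest binarised per level
   (one map per level) and fitted with logistic regression of the
   indicator on expression with an L2 penalty (default strength 1.0),
   which keeps coefficients finite under the perfect separation that
   small mutation groups readily produce and simultaneously suppresses
   the low-variance instability. Maps and portraits are compared by
   Pearson correlation over cells non-empty in both; a constant grid
   yields NaN rather than an error. Samples with missing phenotype values
   are excluded and counted; at least 8 usable samples are required.

## Synthetic cohorts (`synthetic`)

The generator emulates the study design: two layers sharing a gene
universe, samples in the five groups gBRCA1/sBRCA1/gBRCA2/sBRCA2/noBRCA at
the observed cohort composition (OV 19/14/16/8/281 = 338; BRCA
12/28/15/26/613 = 694, the defaults), planted co-expressed modules, and
phenotypes coupled to them. Counts are Gamma–Poisson (negative binomial,
Var = μ + φμ², dispersion φ default 0.2 — typical bulk RNA-seq
overdispersion) around 10^(μ_g + δ_gs) with μ_g uniform on (1, 3), i.e.
baseline means of 10–1000 counts. δ adds the module's group effect (a
log10 shift) plus a per-sample latent factor (SD 0.4) shared by the
module's genes — co-expression the SOM can discover, not just mean
shifts. Numeric phenotypes are linear in the coupled module's factor plus
Gaussian noise; categorical ones threshold the same construct at its
median. Everything derives from one seed.

What the generator does **not** emulate: real gene–gene correlation
beyond the planted modules, library-size variation, batch effects, and
identifier complexities. Passing tests therefore demonstrate that the
machinery recovers structure of the planted kind at realistic noise
levels — not performance on real TCGA data.

## Validation-study sizes and settings

The bundled fixture (`small_fixture`) is 200 genes × 2 layers × 20
samples per layer with two 30-gene modules at effect 1.0 log10, analysed
on a 9×9 grid with 60 epochs — sizes chosen so a full train–portray–
detect cycle runs in tens of milliseconds and 20-replicate studies finish
in seconds. On this grid the spot quantile is set to 0.85: a planted
module is 15% of the gene universe, hence ~12 of 81 units, and the
45×45-oriented default of 0.98 would leave fewer candidate cells than the
minimum component size. Recovery checks pass in ≥18 of 20 replicate
seeds; the phenotype-map correlation is the tightest of them (median
r ≈ 0.87, occasional seeds below the 0.5 bar because target groups have
only 4 samples per layer).

## Numerical conventions and degenerate inputs

- Grid coordinates are 0-based, row-major, (row, col); unit k ↔
  (k // cols, k % cols). All exports state this.
- TSV round trips use 12 significant digits.
- BH adjustment is order-preserving and clipped to [0, 1]. (It is not
  idempotent: re-adjusting adjusted values can only increase them.)
- Welch test with zero variance in both groups: (0, 1) on equal means,
  (±inf, 0) otherwise. Undersized groups are errors, not NaNs.
- Fisher enrichment of a spot equal to the universe is p = 1; empty spot
  or set is an error.
- Determinism: every stochastic component takes an explicit seed;
  identical (data, config, seed) reproduce bit-identical codebooks,
  assignments and TSV outputs.

## Known limitations

- Batch SOM quality depends on the radius schedule; no convergence
  diagnostics beyond the k-means-limit oracle are exposed.
- Spot detection is a global quantile threshold: it cannot separate two
  overlapping modules that merge into one connected component, and the
  quantile must be chosen with the grid size in mind (see above).
- The logistic phenotype maps fit one unit at a time; no multivariate or
  confounder-adjusted models are provided, and no causal reading is
  implied.
- Survival analysis is intentionally out of scope.
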