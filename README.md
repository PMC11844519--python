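# grccax

Group-regularized canonical correlation analysis (GRCCA) for bulk
transcriptomics, with the full surrounding pipeline: RNA-seq count filtering
and normalization, covariate residualization, multiple correspondence
analysis (MCA) of categorical toxicology exposures, WGCNA-style co-expression
module detection, permutation and bootstrap inference, a linear-model
differential-expression arm, and preranked GSEA / hypergeometric enrichment.

## The problem

Case-control differential expression in post-mortem brain tissue tests genes
one at a time and routinely disagrees with GWAS-derived risk gene sets, while
module-based methods (WGCNA) collapse each module to its first principal
component and discard most expression variance. Psychiatric disorders are
instead characterized by small, coordinated shifts distributed across many
co-expressed genes, entangled with medication and recreational drug exposure.

GRCCA addresses this by estimating a single canonical pair between the
expression matrix X (samples × genes) and a covariate matrix Y (diagnosis
indicators + toxicology MCA dimensions),

    LV_x = X·w_x,  LV_y = Y·w_y,   maximizing cov(LV_x, LV_y)
    subject to  w_xᵀ R w_x = 1,  w_yᵀ C_yy w_y = 1,
    R = λ(I − B) + μB,  λ = 1 − 1/p,  μ = 0.1,

where B averages weights within co-expression modules (the grouping vector,
module 0 = unassigned). Within-module deviations are shrunk hard, module mean
weights lightly — distributed module-level effects are rewarded. The retained
expression variance fraction f ∈ {0.1,…,1.0} is selected by permutation
testing; weight stability is assessed by bootstrap Z-scores; genes are
interpreted through structure correlations r_x = cor(X column, LV_x) with the
dual significance rule |Z| ≥ 2 and r_x FDR < 0.05.

Real tissue data of this design are controlled-access, so the package ships a
first-class synthetic generator (negative-binomial counts, block-correlated
modules via latent factors, a diagnosis-specific latent shift, and
diagnosis-correlated ternary toxicology exposures) with ground truth for
every benchmark. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
import pandas as pd
import grccax as g

cfg = g.SimulationConfig(seed=8, effect_modules=(1, 2, 3), effect_size=0.6)
counts, samples, truth = g.simulate_dataset(cfg)        # 2000 genes x 185 samples
expr = g.normalize_transform(g.filter_min_counts(counts))

X = expr.T                                              # samples x genes
Y = pd.get_dummies(samples["diagnosis"])[["SCZ", "BD", "MDD"]].astype(float)
mca = g.MCA().fit(g.impute_unknown(samples.filter(like="tox")))
dims = g.select_dimensions(mca.explained_inertia_)
Y = pd.concat([Y, mca.sample_coordinates_.iloc[:, [d - 1 for d in dims]]], axis=1)

groups = truth.true_modules.loc[X.columns].to_numpy()   # or g.ModuleDetector().fit(expr)
model, table = g.optimize_variance_fraction(X, Y, groups=groups, n_perm=999, seed=1)
print(f"chosen f: {model.chosen_f_}")
print(f"latent correlation: {model.latent_correlation_:.3f}")
print(f"model p: {model.perm_p_:.3f}")
print(model.y_structure_.round(3).head(3))
model.bootstrap_z(X, Y, n_boot=200, seed=2)
sig = g.significant_features(model)
print("significant genes:", len(sig))
print(sig.head(3).round(3))
```

prints

```
chosen f: 1.0
latent correlation: 0.642
model p: 0.001
          r      p    fdr
SCZ   0.749  0.000  0.000
BD   -0.063  0.396  0.462
MDD  -0.403  0.000  0.000
significant genes: 181
            r    p  fdr      Z  significant
G00044  0.460  0.0  0.0  3.059         True
G00046  0.425  0.0  0.0  2.975         True
G00078  0.423  0.0  0.0  3.650         True
```

The model keeps all expression variance (f = 1.0), finds a latent pair
correlated at 0.642 that no permuted dataset matches (p = 0.001, the floor at
999 permutations), identifies SCZ as the dominant covariate (r_y = 0.749),
and flags 181 genes as stable, significant contributors — concentrated in the
three modules that truly carry the planted effect.

The same stages are available from the shell:

```bash
grccax simulate --seed 8 --outdir run/
grccax run --outdir run/            # full pipeline with a manifest
grccax grcca --expr run/expression.tsv --covariates run/covariates.csv \
             --groups run/modules.tsv --outdir run/grcca/
```

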