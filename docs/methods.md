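# Methods

## The model

`grccax` links a wide, column-standardized expression matrix **X** (n samples
× p genes or transcripts) to a narrow covariate matrix **Y** (n × q; three 0/1
diagnosis indicators — SCZ, BD, MDD versus a control baseline — plus numeric
covariates such as toxicology MCA dimensions) through a single canonical pair

    LV_x = X w_x,   LV_y = Y w_y,

estimated by maximizing cov(LV_x, LV_y) subject to

    w_xᵀ R w_x = 1,   w_yᵀ C_yy w_y = 1,
    R = λ (I − B) + μ B,

where **B** is the block-averaging projector of a feature grouping vector
(co-expression module assignment; module 0, the unassigned "gray" set, is a
group of its own). λ = 1 − 1/p (close to 1) shrinks within-group deviations of
w_x hard; μ = 0.1 leaves group mean weights relatively cheap. The penalty
therefore rewards coordinated, distributed effects across a module — the
signature of transcriptional co-regulation — instead of isolated large
weights. Because I − B and B are orthogonal projections,

    R^{-1/2} = λ^{-1/2}(I − B) + μ^{-1/2} B

in closed form, and the fit reduces to an SVD of the cross-covariance between
the transformed expression X̃ = X R^{-1/2} (represented through its leading
principal components) and the C_yy-whitened Y. The Y side is left
unregularized (q ≪ n). Only the first canonical pair is estimated; sign
indeterminacy is resolved by forcing the covariate with the largest |r_y| to
be positive.

A generic ridge-RCCA would use (1 − λ)·C_xx + λI on the X side; at
λ = 1 − 1/p the covariance blending term is negligible and is deliberately
dropped, which is what makes the closed-form metric exact.

### Capacity control and inference

- **Variance fraction f** (grid 0.1–1.0 by 0.1): the smallest leading set of
  principal components of X̃ whose cumulative variance share reaches f is
  retained. f is chosen by permutation: rows of Y are permuted (equivalent to
  permuting X rows under the null, but cheaper because the X-side SVD is
  reused), the model refit, and p = (1 + #{null r ≥ observed}) / (1 + n_perm).
  With 1,000 permutations the smallest attainable p is 1/1001 ≈ 0.001. Ties
  across f break by larger observed latent correlation, then smaller f.
- **Bootstrap Z**: samples are resampled with replacement (default 1,000
  replicates), the model refit at fixed hyperparameters, each replicate
  sign-aligned to the point estimate via the correlation of its LV_y with the
  point-estimate LV_y on the resampled rows, and Z = weight / sd(bootstrap
  weights). A numerically zero sd is reported as a ±1e6 sentinel with a flag.
- **Structure correlations** r_x = cor(X column, LV_x), r_y = cor(Y column,
  LV_y), computed in sample, with two-sided t-distribution p (n − 2 df) and
  Benjamini–Hochberg FDR per side. Feature significance uses the dual rule
  |Z| ≥ 2 (inclusive) **and** r_x FDR < 0.05 (strict).

## Upstream stages

- **Count filtering**: keep features with ≥ 10 counts in ≥ 80% of samples
  (threshold ceil(0.8 n), so a feature passing in exactly 80% survives). An
  optional coefficient-of-variation filter (default cutoff 0.36, computed on
  the raw count scale) removes low-variation features, as used for
  transcript-resolution data.
- **Normalization**: median-of-ratios size factors (geometric-mean reference
  over all-positive features; library-size fallback) followed by
  log2(x/s + 1) — a variance-stabilizing stand-in that avoids NB dispersion
  fitting. Residualization regresses each feature on an intercept plus the
  numeric covariates (OLS, vectorized across features). A PC screen checks
  that no covariate remains correlated (BH FDR < 0.05) with any principal
  component explaining > 2% of variance.
- **Toxicology MCA**: ternary exposures (present/absent/unknown; unknown
  folded into absent) are expanded to an indicator matrix and decomposed by
  correspondence analysis (SVD of the standardized residuals of Z/total).
  Retained dimensions must each explain > 5% of inertia and jointly > 75%;
  the individual rule wins on conflict. Indicator-matrix MCA is used (no
  Burt matrix, no Benzécri correction) because it is exactly reproducible;
  per-dimension sign is fixed by the largest-|loading| category.
- **Co-expression modules**: unsigned Pearson adjacency |cor|^β (β = 3 for
  genes, 2 for transcripts), topological overlap matrix, average-linkage
  clustering of 1 − TOM, a *static* cut at a fixed height (defaults 0.980 /
  0.988), minimum module size 40 / 35, smaller clusters falling into module
  0. A static cut rather than the dynamic hybrid algorithm keeps the
  procedure exactly specifiable; the soft power can be chosen by the
  scale-free-fit criterion (smallest power with R² ≥ 0.8 of the log-log
  degree fit).
- **DGE arm**: per-feature OLS of the processed expression on intercept +
  diagnosis indicators + MCA dimensions; the SCZ coefficient, its t, p and
  FDR are the primary output and are compared (Pearson) with r_x.
- **Enrichment**: preranked GSEA (weighted-KS running sum, weight exponent 1,
  descending scores with ties broken by feature id, gene-sampling null of
  same-size sets, sign-matched one-sided p, NES = ES / mean |null ES| of the
  same sign) and one-sided hypergeometric overlap with Haldane-corrected odds
  ratios; BH across sets. Decile trajectories split a score vector into ten
  rank bins (decile 1 = most positive) and report the median/mean stage
  profile of each bin.

## The synthetic data generator

Per sample s, each module m draws a factor f_m(s) ~ N(0,1); gene i in module
m has latent z_i(s) = √ρ f_m(s) + √(1−ρ) e_i(s) (ρ = 0.7 by default),
unassigned genes are pure noise. An effect configuration adds a signed shift
(default 0.4 SD) to z for every gene of the affected modules in samples of the
affected diagnosis (SCZ). Counts are negative binomial with mean
L_s·exp(b_i + 0.3·z_i) — per-gene baselines log-uniform on [20, 2000],
library sizes log-uniform on [0.7, 1.4] — and dispersion α = 0.1 (var =
μ + αμ²), a typical gene-wise dispersion for deep bulk RNA-seq. The default
design is 185 samples: 55 controls, 44 SCZ, 35 BD, 51 MDD.

Seventeen ternary toxicology exposures are Bernoulli with drug-class-specific
probabilities per diagnosis (antipsychotics concentrated in SCZ/BD,
antidepressants in MDD/BD, mood stabilizers in BD, sedatives/opioids/
stimulants/alcohol/cannabis diffusely elevated in cases), then relabeled
"unknown" with probability 0.05. This produces several diagnosis-correlated
exposure axes — the confound structure the MCA + CCA stages exist to handle —
rather than a single artificial case-control axis. `null_config` zeroes the
expression effect and equalizes exposure probabilities across groups, making
group labels exchangeable for calibration studies.

What the generator does **not** emulate: 3′/GC bias, transcript-degradation
curves, cell-type composition shifts, gene-length effects, or realistic
gene-gene correlation beyond block structure. Passing tests therefore
demonstrate statistical correctness of the machinery under the assumed model,
not performance on real tissue.

## Numerical choices

- Standardization uses ddof = 1 throughout; constant columns are an error at
  fit time (and degenerate bootstrap replicates are dropped, erroring above
  10%).
- The X-side SVD discards singular values below 1e-12 of the largest; Y must
  be numerically full rank (smallest eigenvalue ≥ 1e-10 of the largest).
- Ranks and deciles break ties deterministically by feature id; module ids
  are renumbered by decreasing size with first-occurrence tie-break.
- Per-stage seeds in the pipeline are split from the global seed via
  `numpy.random.SeedSequence`, recorded in the run manifest.

## Benchmark problem sizes

The test and acceptance benchmarks run at deliberately compact sizes chosen to
exercise the study design while keeping the suites fast: module-recovery
benchmarks use 300 genes in four 50-gene blocks over the 185-sample design
(within-module correlation 0.7); calibration uses 100 null datasets of 500
genes × 100 samples with 199 permutations; recovery uses the full study scale
(2,000 genes, 20 modules, 185 samples, 999 permutations). On the synthetic
benchmark the dendrogram is cut at 0.995 rather than the 0.980 default:
count noise attenuates a latent correlation of 0.7 to ~0.41 in log-count
space, which lowers the whole TOM scale, and the cut height — as in any
co-expression analysis — must be read off the dendrogram of the data at hand.

## Known limitations

- A 0.4-SD latent shift confined to 3 of 20 modules is intrinsically marginal
  for this design: the best achievable latent correlation (~0.33 for a
  44/185-prevalence indicator) sits near the permutation null of the maximal
  canonical correlation across ~20 module directions, so single-dataset
  model p-values at that effect size are unstable; effects of 0.6 SD and
  above are detected at the permutation floor. The recovery benchmarks
  report rates over seeds for this reason.
- Only the first canonical pair is estimated; no deflation, no sparse (L1)
  variant, no out-of-sample projection.
- The exact-DESeq2 variance-stabilizing transform, surrogate-variable
  derivation, and NB dispersion modeling are out of scope; surrogate
  variables are consumed as ordinary numeric covariates.
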