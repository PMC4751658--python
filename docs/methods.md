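# Methods

This note documents the models implemented in `snpclass`, the defaults and why
they were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions that shape results.

## Binary probit threshold model

Each binary contrast is modelled through a latent liability

    l = W b + Z u + e,    e ~ N(0, I),    y_i = 1{ l_i > δ }.

The residual variance is fixed at 1 (probit identification) and the threshold
δ is fixed at 0 with an intercept column in W — the standard equivalent
parameterization of estimating a single free threshold. Inference is a
single-site data-augmentation Gibbs sampler:

1. liabilities from normals truncated at 0 by class (inverse-CDF sampling);
2. fixed effects b coordinate-wise from Gaussian full conditionals (flat
   prior);
3. feature effects u coordinate-wise against a maintained residual;
4. variance components from scaled-inverse-χ² full conditionals.

Priors on u:

* **ridge** — u_j ~ N(0, σ²_u) with a common variance. Regression on centered
  gene content under this prior is GBLUP: an internal cross-check verifies
  that the posterior-mean linear predictor matches a direct mixed-model-
  equation solve at the posterior-mean variance ratio to ρ > 0.99.
* **BayesA** — a variance per effect, σ²_j ~ scaled-inv-χ²(df, S); marginally
  a scaled-t prior. Predictions on polygenic simulated traits are nearly
  identical to ridge, which the tests check as a rank correlation.
* **BayesCπ** — spike-slab: u_j is 0 with probability 1−π and N(0, σ²_u)
  otherwise. Indicators are sampled with the effect integrated out of the
  likelihood ratio; π ~ Beta(1, 1) a priori and is updated from its Beta full
  conditional.

### Hyperprior defaults

σ²_u ~ scaled-inv-χ²(df = 5, scale S) with S set so the prior *mode* implies
a liability-scale genetic variance of R²/(1−R²) with R² = 0.5 (i.e. genetic
and residual variance equal a priori, the convention of the widely used
whole-genome regression software). For ridge and BayesA the implied variance
is spread over the summed feature variances. For BayesCπ the scale is
anchored to the *mean* column variance instead: the slab describes the
magnitude of a single nonzero effect. Spreading it over all columns makes
the slab collapse when few effects are real, after which the inclusion
likelihood ratio degenerates to 1 and π performs a random walk — the model
loses its selection behaviour exactly in the null situations where it is
most needed. The per-column anchoring keeps the spike-slab calibrated in
both regimes (verified on permuted-label simulations).

Chain defaults: 30 000 iterations, 15 000 burn-in, thinning 1, for
stand-alone fits; 60 000 / 20 000 for the eigenvector-inclusion and
heritability analyses; 2 000 / 500 inside each leave-one-out fold (a
feasibility default — full-length chains are a flag away). Predictive
probabilities are Monte-Carlo averages of Φ(η) over *all* kept draws, not Φ
at the posterior mean. Chains are bit-reproducible given a seed.

## Multinomial assembly

With binary success probabilities in hand:

* **OVA normalization** divides each class's binary probability by the sum —
  scale-invariant, exact for K = 2.
* **OVO voting** counts pairwise wins, p_k = 2/(K(K−1)) Σ_{k'≠k} c_kk'; exact
  ties credit neither side and argmax ties break to the lowest class index
  with a warning.
* **OVO coupling** solves p = Qp with Q_kk' = p_kk'/(K−1) off the diagonal
  and Q_kk = Σ_{l≠k} p_kl/(K−1). Q is column-stochastic with positive
  entries, so the stationary vector exists and is unique, and when the table
  is consistent with Pr-theory (p_kk' = p_k/(p_k+p_k')) the solution is the
  generating vector exactly. The linear system [(I−Q); 1′]p = (0,…,0,1)′ is
  solved by least squares with a power-iteration fallback (tol 1e−10).
  Classifier outputs of exactly 0/1 are clipped to [1e−6, 1−1e−6] first: the
  fixed point needs interior entries.

For inconsistent tables the least-squares projection of the determining
system and the Markov fixed point are *different* estimators; they are only
interchangeable (and tested against each other) on consistent tables.

### Multinomial breeding values

For a selection candidate with gene content z_n and a base population with
allele frequencies f and class fractions p_0, the expected offspring class
fractions are

    p_{n_k} ∝ Φ( w̄′ b_k + 0.5 (z_n − 2f)′ u_k − δ_k ),

normalized over classes, with g_n = p_n − p_0. The factor 0.5 halves the
candidate's centered genotype — one transmitted gamete. Effect vectors enter
at their posterior means (the ratio is not re-averaged over the posterior);
this matches how such predictors are used operationally and keeps breeding
values a deterministic function of a fitted model.

## Evaluation

Leave-one-out cross-validation retrains the full multiclass model for every
left-out sample; binary estimators center features on their own training
rows, so centering frequencies are recomputed per fold and never leak the
test sample. Metrics:

* accuracy — fraction of correct argmax assignments;
* multinomial Brier score, BS = N⁻¹ Σ_i Σ_j (p_ij − [y_i = j])², ranging 0–2;
* scaled Brier score sBS = 1 − BS/BS_baseline with the uniform-1/K baseline
  (BS_baseline = (K−1)/K exactly); 0 = no better than uniform guessing,
  1 = perfect, negative = worse than the baseline. A baseline using observed
  class frequencies is available as an option.

## Relationship matrices and population structure

* G = MM′/Σ2pᵢ(1−pᵢ) with M the gene-content matrix centered at 2p. Default
  centering uses the whole provided sample; cross-validation centers on
  training folds only. Sample-centering makes G singular (G1 = 0) and gives
  negative entries for below-average relationships — relationship summaries
  therefore keep true diagonals but exclude them from the within/between
  class means.
* A is built by the tabular method in topological pedigree order and is
  cross-checked against a recursive-kinship oracle in the tests.
* Cholesky factors (with a logged 1e−8 jitter when only PSD) turn either
  matrix into an n-feature regression design; under the ridge prior σ²_u is
  then itself the additive variance, and h² = σ²ₐ/(σ²ₐ + 1).

### Eigenvector inclusion (pEV)

For a class pair, G is eigendecomposed and subpopulation assignment is
regressed on the eigenvectors under the BayesCπ probit. Reported: the
posterior mean proportion of eigenvectors with nonzero effect (pEV), the
count nEV = pEV·(N−1) (exact identity on the realized proportion), and
per-eigenvector inclusion probabilities. Strong divergence concentrates all
inclusion mass on the leading eigenvector; entangled pairs need many.

Eigenvector columns enter *standardized* (orthonormal U times √n — a uniform
rescaling, since eigenvectors of a sample-centered G are orthogonal to the
constant and hence mean-zero). An alternative √eigenvalue scaling (the
parameterization whose ridge fit reproduces the animal model) is available
but documented as unsuitable for inclusion analysis: columns with near-null
eigenvalues carry no likelihood penalty, their indicators flip freely at π,
and pEV inflates regardless of signal.

### F_ST

Pairwise, per marker, the default is a moment/ANOVA estimator on allele
counts: with MSB and MSW the between/within mean squares over the 2n_k
allele counts of the two classes,

    σ̂²_α = (MSB − MSW)/n_c,    F̂ = σ̂²_α / (σ̂²_α + MSW).

Subtracting MSW removes the finite-sample inflation of the naive frequency
variance, so F̂ is unbiased for the generative divergence and equals exactly
1 at opposing fixation; the price is that exact frequency equality gives a
small negative value of order 1/(2n) rather than 0 (familiar from
moment-based F_ST estimators). The uncorrected plug-in ratio — weighted
between-class frequency variance over p̄(1−p̄), or over 2p̄(1−p̄) by flag —
is available via `corrected=False`.

Two aggregates are reported. The arithmetic mean of per-marker ratios is the
conventional table summary, but it is intrinsically deflated when divergence
is large (at generative F = 0.2 it reads ≈ 0.15): averaging per-locus ratios
whose numerator also appears in the denominator is a concave operation. The
`ratio_of_sums` aggregate — summed variance components before the ratio, the
combination recommended in the F-statistics literature — recovers the
generative F within a few percent across F ∈ [0.01, 0.2] and is the quantity
used for recovery checks. At the weak divergences typical of related breeds
(F ≈ 0.003–0.015) the two aggregates agree.

Global F_ST fits, per marker, gene content = mean + random subpopulation
effect + residual by a 1-D profile REML (the one-way model needs no general
mixed-model machinery). On the gene-content scale the between-group variance
is 4·var(p_k) and the within-group binomial variance ≈ 2p̄(1−p̄), so the raw
variance ratio estimates 2F/(1+F), not F; the reported value maps the
components back to the allele-frequency scale,

    F = (σ²_α/4) / (σ²_α/4 + σ²_ε/2),

which recovers the generative divergence (verified at K = 4). Monomorphic
markers are excluded with a warning. Raw components are reported alongside.

## Synthetic populations

The generator states a small world in the shape of a multi-breed SNP study:

* per-marker ancestral frequencies ~ Uniform(0.05, 0.95); subpopulation
  frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — the Balding–Nichols model, so
  the divergence parameter F *is* the expected F_ST;
* founder genotypes ~ Binomial(2, subpopulation frequency); optional half-sib
  families: shared sires with a fresh dam per offspring (mirroring pedigrees
  where nearly every dam is unique), offspring by gamete sampling;
* optional admixture: a fraction λ of one class draws each allele from either
  parent population according to an ancestry mix;
* a truth record (all frequencies, ancestries, effects) accompanies every
  dataset; everything is seed-deterministic.

Markers are simulated **unlinked**. The downstream methods act on
relationship and allele-frequency structure, which the model captures; what
a green test does *not* establish is behaviour under linkage disequilibrium,
ascertainment bias of genotyping arrays, genotyping error, or real breed
history (selection, migration waves). Binary liability traits are generated
as l = Zu + N(0,1) with effects rescaled so the in-sample heritability is
exact, labels by sign.

Default world: K = 4 classes sized (60, 70, 45, 12) — unequal, with one rare
class, about one-fifth the size of a typical breed-survey sample — with
1 000 markers and F = 0.05. Desk-scale recovery tests use 2 × 200 samples
and 5 000 markers where stated.

## Numerical choices

* Truncated-normal draws by inverse CDF with the normal quantile via a
  rational approximation plus one Halley refinement; arguments clamped to ±8
  standard units.
* Spike-slab inclusion odds computed on the log scale and clamped at ±35
  before exponentiation; π clamped to [1e−8, 1−1e−8].
* Eigenvalues clipped at 0 for cumulative-variance reporting; negative
  numerical eigenvalues excluded from variance totals; near-null eigenvector
  columns dropped (tol 1e−10 relative) with a log line.
* Missing genotypes are mean-imputed (2·freq per marker) after QC: imputed
  entries contribute exactly 0 to centered covariates and leave allele
  frequencies unchanged. MAF/call-rate QC uses strict `<` at the thresholds
  (ties are kept).
* Coupling tables are symmetrized exactly (p_k'k := 1 − p_kk') after
  clipping.
* The samplers are numba-compiled; the first call in a process pays a
  compilation cost of a few seconds.

## Known limitations

* The binary decomposition assumes independence between contrasts and
  ignores unobserved classes (independence of irrelevant alternatives); a
  multinomial probit with correlated liabilities is out of scope.
* Heritability of class assignment from a *saturated* probit animal model is
  weakly identified in small samples: any labeling is separable through a
  full-rank relationship factor, so under the null the posterior stays near
  the prior predictive (~0.6 with defaults at n = 200) rather than dropping
  toward 0. Null results should be read against a permutation reference, not
  against zero.
* Per-marker moment F_ST estimates can be slightly negative; the multi-locus
  aggregate is the quantity to interpret.
* Leave-one-out with Gibbs-sampled classifiers is expensive; the reduced
  per-fold chains trade Monte-Carlo error for feasibility (results are
  seed-stable and the full-length option exists).
* No LD, no genotyping error, no sex chromosomes (beyond an exclusion flag),
  no single-step or sparse-inverse pedigree algebra.
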