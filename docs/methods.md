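# Methods

This note documents the statistical models behind twaskit, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## The association model

A gene's genetically regulated expression is a linear combination of
cis-SNP dosages, `E = Σ_j w_j x_j`. With standardized per-SNP GWAS
z-scores `z`, a reference LD matrix `Σ`, and weights `w` estimated on
the reference panel, the gene-level statistic

    z_TWAS = w·z / sqrt(w Σ_λ wᵀ)

is standard normal under the null that no weighted SNP is associated
with the trait. The denominator is the variance of the weighted sum
under LD; the numerator behaves like a z-score for the predicted
expression. Because the reference panel is finite (and `Σ` may be
singular), the LD matrix is regularized as

    Σ_λ = (Σ + λ I) / (1 + λ),  default λ = 0.1.

The `1/(1+λ)` renormalization is deliberate: diagonals stay exactly 1,
so a single-SNP gene's statistic is identical to that SNP's GWAS z and
the unit-variance null contract is preserved; the smallest eigenvalue
is bounded below by `λ/(1+λ)`. Two-sided p-values are computed with the
complementary error function directly, which stays accurate for the
very small p-values (1e-30 and below) real scans produce; p-values
below ~1e-308 underflow to 0 in double precision.

The case-only test is the same statistic applied to a scan that
contrasts one case subtype against the other. Under a multinomial view
of subtype risk with expression log-odds `β₁` (ER+) and `β₂` (ER−), the
case-only z has mean proportional to `β₂ − β₁`, so the statistic tests
H₀: β₂ = β₁. The orientation is fixed so that a positive case-only z
means the effect allele (and hence higher predicted expression, for a
positive weight) raises the odds of ER− relative to ER+ disease; the
contrast direction is a pure convention and is documented here because
nothing in the inputs pins it down.

## Cis-heritability screening

Expression is modelled as `y = Xb + g + e`, `g ~ N(0, σ²g K)`,
`e ~ N(0, σ²e I)`, with `K = ZZᵀ/m` the GRM over column-standardized
cis dosages, and `h² = σ²g/(σ²g+σ²e)`. The restricted likelihood is
maximized exactly on the eigenbasis of `K`: rotating `y` and `X` by the
GRM's eigenvectors makes the covariance diagonal in the variance ratio
`γ = σ²g/σ²e`, `σ²e` profiles out in closed form, and a bracketing grid
plus bounded scalar minimization over `log γ` finds the optimum. We
chose this spectral formulation over Newton-type average-information
iterations because it is globally convergent with a single variance
component and needs no step-halving heuristics; the two approaches
maximize the same function, and the test suite verifies the optimum
against a brute-force grid search of the restricted likelihood
(Patterson–Thompson form, including the `log|XᵀX|` term that makes the
value invariant to reparameterizing the fixed effects).

The null σ²g = 0 lies on the boundary of the parameter space, so the
LRT statistic is referred to the 50:50 mixture of a point mass at zero
and χ²₁; an estimate at the variance floor (γ ≤ 1e-8) reports p = 1.
The screen keeps genes with p ≤ .01. The cis window defaults to 500 kb
around the gene boundary and is fully configurable. In the full-scale
design 20 expression PCs enter as fixed covariates; at simulation scale
the generator produces no structure for PCs to absorb, so the tests fit
with the intercept only.

## Expression predictors and selection

Expression is residualized on covariates once, then five models are
fitted to standardized dosages:

- **enet / lasso** — coordinate descent with the penalty chosen by
  inner fivefold cross-validation over 50 log-spaced penalties spanning
  three decades below the all-zero point (scikit-learn's
  ElasticNetCV/LassoCV); mixing parameter 0.5 for the elastic net.
- **blup** — the SNP-level best linear unbiased predictor: ridge with
  penalty `m σ²e/σ²g` taken from the gene's own REML fit.
- **top1** — the single SNP with the smallest marginal p keeps its
  marginal coefficient.
- **sparse_bayes** — a spike-and-slab Gibbs sampler: `w_j = δ_j b_j`,
  `δ_j ~ Bern(π)`, `b_j ~ N(0, σ²_b)`, `π ~ Beta(1, 10)`, inverse-gamma
  updates for the slab and noise variances, 400 sweeps with 100
  burn-in, posterior-mean weights, fixed seed. This is a sparse-Bayes
  hybrid of sparse and polygenic architectures; with the inclusion
  probability forced toward 1 it reduces to Bayesian ridge and its
  posterior mean tracks the BLUP solution (verified qualitatively in
  the tests).

Model score is the squared Pearson correlation between concatenated
out-of-fold predictions and observed expression under a seeded fivefold
partition (squared correlation rather than 1−SSE/SST, so a
well-correlated but miscalibrated predictor still scores; a constant
prediction scores 0 by definition). A gene qualifies when *any* model
reaches cv r² ≥ .01 — the best model then supplies the weights, with
ties broken in the fixed order enet, lasso, blup, sparse_bayes, top1.
Weights live on the standardized-dosage scale, which makes them
invariant to rescaling raw dosages and makes the TWAS statistic
invariant to the weight scale.

## Conditional and joint analyses

All conditional algebra operates on z-scores of standardized variables,
where joint and conditional effects follow from the same normal-
equations identities that individual-level regression would produce:

- feature correlation: `r_jk = w_jΣw_kᵀ / sqrt(w_jΣw_jᵀ · w_kΣw_kᵀ)`;
- joint gene effects: `b = R⁻¹ z`, per-gene joint z `b_i/√((R⁻¹)_ii)`;
- SNP conditional on genes: `z_cond = (z_s − ρᵀR⁻¹z_g)/√(1 − ρᵀR⁻¹ρ)`
  with `ρ_s = (Σw)_s/√(wΣwᵀ)`.

Tests validate both identities against individual-level OLS oracles on
simulated genotypes. Features with |r| > 0.95 are collapsed before
inversion (keeping the smallest marginal p) because real inversion
polymorphism regions produce essentially duplicate features whose joint
solve is numerically meaningless; a singular matrix after pruning is
ridge-stabilized with ε = 1e-6 and a warning. A gene is "retained"
after joint analysis when its conditional p < .05. A SNP whose
`1 − ρᵀR⁻¹ρ ≤ 0` is reported as fully explained (conditional p = 1)
rather than producing an undefined division.

Region summaries use the genome-wide threshold 5×10⁻⁸ and report
`ratio = (n_before − n_after)/n_before` (share of significant SNPs
explained; 1.0 by convention, flagged, when nothing was significant)
and `magnitude = index_p / min_conditional_p` (exactly 1 when the index
SNP is untouched; not bounded below by 1, since conditioning can
sharpen a p-value).

## The synthetic-data generator

The generator's defaults define the study conditions the tests run
under, and they mirror the target design where it is stated: GWAS
sample sizes default to 69,501 ER+ cases, 21,468 ER− cases and 105,974
controls; reference panels are small (hundreds of individuals — real
expression panels are smaller still, but desk-scale statistical tests
need some n); cis loci carry tens to hundreds of SNPs with MAF in
[0.05, 0.5]; cis-h² defaults to 0.3, in the range observed for
heritable transcripts.

- **Genotypes** are two haplotypes per individual, each a latent AR(1)
  Gaussian series (autocorrelation `ld_rho`, default 0.7) thresholded
  at the per-SNP MAF quantile. This gives tunable, geometrically
  decaying LD with realistic blockiness at high ρ, and {0,1,2} dosages
  by construction. It does not emulate recombination hotspots,
  population structure, or MAF-LD coupling.
- **Expression** is a linear predictor over standardized causal
  dosages, rescaled so its sample variance is exactly `h2_cis`, plus
  N(0, 1−h2_cis) noise. Effect sizes are Gaussian across causal SNPs.
- **GWAS scans** are drawn directly at the z-score level:
  `z ~ N(√N_eff · Σ b, Σ)` with `N_eff = 4/(1/n₁ + 1/n₂)` per scan and
  `b` the joint standardized SNP effects implied by the architecture —
  `b = α·w` for mediated loci, plus (or instead) a direct effect of
  magnitude `α√h²` on a non-eQTL SNP (pleiotropic) or on a SNP in LD
  with the lead eQTL (colocalized). The overall scan's α is the
  case-count-weighted mean of the subtype αs; the case-only mean is
  proportional to `α_neg − α_pos`. The four scans are drawn
  independently given the LD — shared-control correlation between scans
  is *not* modelled, so cross-scan joint statistics (not computed here)
  should not be read off these simulations. Simulating at the z level
  rather than sampling case-control cohorts keeps replicate studies
  cheap and matches the summary-statistics interface of everything
  downstream; it also means individual-level phenomena (case-control
  ascertainment, covariate confounding in the GWAS) are out of scope of
  what the passing tests demonstrate.
- **Seeding**: one master seed; each stage (panel, expression, scans)
  draws from a deterministically derived substream, so identical
  configurations are bit-for-bit reproducible and a fixed panel can be
  re-used across replicate GWAS draws by varying only the seed.

The effect-size scale at GWAS loci is user-set (`alpha_pos`,
`alpha_neg`), not calibrated to any consortium scan — the source
designs do not state a distribution, so tests choose values that put
power in an informative range rather than at saturation.

## Fixtures

`twaskit/data/table1_fixture.tsv` and `table2_fixture.tsv` transcribe
the published per-gene association table (30 genes with h², cv r² and
four scan p-values) and the per-region conditional-analysis summary
(21 regions). They serve the counting and conditional-arithmetic
regression tests and the acceptance script; no statistical routine
reads them.

## Problem sizes and numerical choices

Test and acceptance-script simulation sizes (reference panels of
400–1000 individuals, 30–100 SNPs, 100–2000 replicates) were picked so
Monte-Carlo standard errors sit comfortably inside the asserted
tolerances while the whole suite runs in a few minutes on one CPU.
Variance components are floored at 1e-8 of phenotypic variance to keep
the restricted likelihood finite; REML convergence tolerance is 1e-6 on
the variance-ratio search; LD factorizations add a 1e-8 ridge before
Cholesky. Harmonization drops strand-ambiguous (A/T, C/G) SNPs by
default since no frequency-based disambiguation is attempted, resolves
unambiguous strand flips, and never silently keeps an irreconcilable
allele pair.

## Known limitations

- The spike-and-slab sampler is a stand-in for a full Bayesian sparse
  linear mixed model: it shares the sparse+polygenic intent but not the
  exact prior or sampler, and its posterior is summarized only by mean
  weights.
- Single chromosome, one gene per simulated locus; multi-gene regions
  are built by concatenating loci.
- No FDR control (Bonferroni only), no fine-mapping or colocalization
  posteriors, no BGEN/PGEN input, no liftover, no multi-allelic sites.
- The case-only equivalence to the multinomial contrast is an
  approximation whose accuracy degrades at extreme case imbalance; the
  tests exercise moderate (≈3:1) imbalance only.
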