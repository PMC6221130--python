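# Methods

## The problem

Mendelian randomization (MR) uses germline genetic variants as instrumental
variables to estimate the causal effect of an exposure phenotype X on an
outcome phenotype Y. The instrument assumptions fail in a subtle way when
spouses do not pair at random: positive cross-trait assortment on X and Y
(say, people with high X pairing with partners with high Y) makes the
exposure-associated variants of one parent correlated with the
outcome-associated variants of the other. Offspring inherit both, so in the
offspring generation the exposure allele score is associated with the outcome
through a pathway that is not mediated by the exposure — a classic violation
of the exclusion restriction that no amount of pleiotropy-robust summary-data
machinery can see, because it affects *all* instruments equally.

`assortmr` simulates this process forward in time in mother–father–offspring
trios and implements the trio-based estimators that detect and remove the
bias.

## Generative model

Each scenario simulates a closed population of `n_trios` couples
(default 40,000) carrying `n_snps_x` + `n_snps_y` unlinked biallelic SNPs
(defaults 50 + 50) in Hardy–Weinberg equilibrium, with effect-allele
frequencies drawn once per dataset from Uniform(`maf_low`, `maf_high`)
(default 0.1–0.5). The exposure set GX and outcome set GY are disjoint — no
horizontal pleiotropy between X and Y.

Phenotypes are linear and additive. With Z_X the unweighted allele-count sum
over GX and var₀(Z_X) = Σ 2p(1−p) its theoretical founder variance,

    δ_X = sqrt(h²_X / var₀(Z_X))
    X   = δ_X Z_X + sqrt(c) U + e_X,            e_X ~ N(0, 1 − h²_X − c)
    Y   = β_XY X + δ_Y Z_Y + sqrt(c) U + e_Y,   e_Y ~ N(0, 1 − h²_Y − c)

where U ~ N(0,1) is a shared confounder and c (`confounder_share`,
default 0.2) its variance share. Founder phenotypes have unit variance and
founder narrow-sense heritabilities equal h²_X, h²_Y by construction. The
δ's are structural constants: under assortment the realized genetic variance
— and hence realized heritability and var(X) — drifts upward across
generations, which is a property of phenotypic assortment models, not a bug.
U being genotype-independent, `confounder_share` moves OLS confounding and
estimator precision but not the assortment bias itself; 0.2 is a moderate
confounding level chosen once.

Assortment operates on noisy phenotype proxies: X_P = X + e with
e ~ N(0, var(X)(1−P²)/P²), so cor(X, X_P) = P. The strength parameter
P ∈ (0,1] is the single knob; P = 0 is expressed as the `none` pattern.
Pairing uses bidirectional two-set sorting: couples are first paired at
random and split into two equal sets; under cross-trait assortment on (X, Y),
one set sorts women by X_P and men by Y_P, the other swaps the traits; the
rank-matched sets are concatenated. Within a set, the rank correlation of the
sorted proxies is exactly 1; averaged over the whole sample the realized
spouse correlations land at intermediate values (the harness records them per
scenario, e.g. cor(X_m, Y_f) ≈ 0.52 at P = 1, ≈ 0.2 at P ≈ 0.6). Single-trait
assortment sorts both sexes on the same trait in both sets.

Each couple leaves exactly two offspring (one daughter, one son), keeping the
population size constant across generations; per SNP and parent, one of the
two haplotype alleles is transmitted with probability ½ and the other is
recorded as nontransmitted. `n_generations` repeats the
phenotype → proxy → sort → mate cycle; the analyzed trios are the final
couples plus one of their two offspring chosen at random. Sibling pairings in
later generations are allowed by default (probability ~1/n per couple, i.e.
negligible at the default size); `forbid_sibs` reshuffles them away if set.

Auxiliary traits (`phenotype_defs`) are declared as linear combinations of
previously defined phenotypes, the scaled genetic scores δ_X Z_X / δ_Y Z_Y
(horizontal pleiotropy shared by every variant in the set), U, and fresh
noise — enough to express the assortment-on-correlated-traits scenarios of
the preset suites.

## Estimators

Instrument weights are per-SNP slopes of X on genotype, fitted one SNP at a
time in a random half (A) of the trios; scores are built in the other half
(B) to avoid overfitting the instrument (an override flag exists, and
externally supplied weights may be applied to the full sample). The weighted
allele score S (offspring), S^m, S^f (parents) and the nontransmitted scores
W^m, W^f (same weights on the nontransmitted parental alleles) feed three
two-stage least-squares (TSLS) estimators:

* **TSLS(1)** — Y on X, instrument S, no covariates. Consistent under random
  mating, biased under cross-trait assortment.
* **TSLS(2)** — Y on X with S^m, S^f as included covariates in both stages,
  instrument S. The parental scores block the assortment backdoor; their
  joint 2-df Wald test in the structural equation is the assortment test, and
  their signed coefficients give its direction.
* **TSLS(3)** — three endogenous regressors (offspring, mother, father X),
  instruments (S, W^m, W^f). The parental-phenotype coefficients estimate
  direct dynastic effects; their joint Wald test again flags
  assortment/dynastic bias. In simulation parental X is available; real-data
  use requires it in the trio table.

2SLS is computed by projection algebra with IV-consistent covariance
s²(X′P_Z X)⁻¹, s² from the structural residuals and n−k degrees of freedom
(HC0 robust covariance behind a flag, matching common practice for real-data
analyses); it agrees with `statsmodels`' sandbox IV2SLS to machine precision
and is tested against an independent closed-form oracle at 1e-8. All CIs are
normal-theory 95% intervals. Rank-deficient or under-identified systems raise
`IdentificationError`.

Summary-data MR methods (per-SNP statistics from simple regressions in half
B; a two-sample flag uses opposite halves): fixed-effect IVW with weights
β̂²_Xk/SE(β̂_Yk)²; MR-Egger as a weighted regression of β̂_Y on β̂_X with
intercept, weights 1/SE(β̂_Y)², multiplicative overdispersion floored at 1,
no SIMEX; weighted median via cumulative-weight interpolation at 50% with a
parametric-bootstrap SE; mode-based estimate as the mode of the
Gaussian-kernel-smoothed Wald-ratio density with bandwidth
φ·0.9·min(sd, mad/0.6745)·n^(−1/5), φ = 1 default, weighted or unweighted,
bootstrap SE. Heterogeneity diagnostics: Cochran's Q against χ²(J−1), the
Egger-intercept z-test, and a score-correlation test (exposure vs outcome
allele scores), which is the diagnostic actually sensitive to cross-trait
assortment.

For user data without phase, nontransmitted allele counts are inferred per
SNP and parent: homozygous parents are determined; heterozygous parents are
resolved through offspring homozygosity or the other parent's homozygosity;
the fully ambiguous het×het×het case takes the expected value ½ and a
per-trio ambiguity count is reported.

## Monte-Carlo harness

`run_scenario` runs independent replicates (simulate → weights on A → scores
on B → estimators), each seeded from `SeedSequence(master, spawn_key=(rep,))`
so any replicate is reproducible in isolation and results are invariant to
worker count (`n_jobs` uses joblib when > 1). `summarize` reports mean
estimate, bias (mean − true β_XY, with the structural β_XY as the truth also
under assortment), empirical SE (SD of estimates), mean model SE, false
rejection (95% CIs excluding the truth), power (CIs excluding 0) and the
assortment-test rejection rate. Failed replicates are recorded, not fatal.
Default `n_reps` is 500; the original experiments averaged 5,000 datasets,
and the reduced default trades a bias MC-SE of ~0.001 (at the default design,
per-replicate SD ≈ 0.022 with the 10-SNP instrument) for tractable runtime.

Presets encode the published designs: `table1` (24 configs: P × h²_Y ×
instrument-SNP count × |GY| under cross-trait assortment, no causal effect),
`table2` (4 configs: random mating, β_XY = 0.05, h² grid), `figure2`
(P × h² grid, one generation), `figure3` (generations 1–9 at P = 0.7), and
two suites where assortment acts on auxiliary traits genetically correlated
with X and/or Y via horizontal or vertical pleiotropy.

## Problem sizes used in the shipped checks

The acceptance script and the end-to-end tests rerun the full pipeline at the
published design (40,000 trios) with reduced replicate counts, chosen as the
package's own accuracy/runtime trade-off: 150 replicates for one-generation
bias points (MC SE ≈ 0.002), 250–300 for power/estimate points (power MC SE
≈ 3 pp), 100 for nine-generation points, 500 for the false-rejection band
[3%, 7%], and smaller populations (5,000–10,000 trios) for structural
property checks where bias is size-invariant.

## What the generator does and does not emulate

The simulation reproduces the mechanism — phenotype-proxy assortment inducing
cross-spouse genetic correlation and its accumulation over discrete
generations — under deliberately clean conditions: unlinked SNPs, purely
additive effects, Gaussian noise, constant population size, no LD, no
population structure, no geographic/social homogamy, no selection, mutation
or migration, and non-overlapping generations. Passing tests therefore show
the estimators behave as claimed under the model, not that real spouse
correlations are caused by assortment; in real data, ethnically or socially
structured mating can mimic it, and only the trio-based adjustments — not the
summary-data heterogeneity tests — are expected to flag it.

## Known limitations and reproduction notes

* Some generating constants of the original experiments (exact allele
  frequencies, confounder magnitude, error distributions, the precise
  multigenerational mating-pool construction) are not derivable from the
  published description; the defaults here follow the stated model with the
  documented choices above and are all configurable.
* One-generation bias values reproduce closely (e.g. 0.129 ± 0.005 vs the
  published 0.125 at P = 1, h²_X = h²_Y = 0.5). Nine-generation biases come
  out ~10% above the published 0.110/0.022 under the two-offspring
  closed-population rule, and the published power figures at h²_X = 50%
  (91.1% for plain TSLS) are not attainable under the stated design: the
  published SE of 0.010 for that same design implies z ≈ 5 and power ≈ 100%,
  which is what this implementation produces. These gaps are reported as
  computed, not tuned away.
* The MBE's NOME variant, SIMEX-corrected Egger, LD-aware weights, VCF/PLINK
  input and figure rendering are out of scope.
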