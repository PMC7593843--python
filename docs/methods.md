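# Methods

## Model and procedure

The package implements minority-class feature selection by reconstruction
error. The working assumption is that patients without late toxicity
("healthy", the majority class) share a joint genotype distribution that a
small autoencoder can represent well, while patients with toxicity
("unhealthy") deviate from that representation along the SNPs that carry
risk. The per-SNP statistic is

Δ_j = E[(x_j − x̂_j)² | unhealthy] − E[(x_j − x̂_j)² | healthy],

estimated on balanced test sets from networks trained on healthy patients
only. Under the null (a SNP carries no signal) both classes are
reconstructed equally well and Δ_j fluctuates around zero; a planted
association shifts the dosage distribution of cases away from the
representation the network learned, inflating their residuals on that
coordinate.

The procedure per endpoint:

1. derive binary labels from grade trajectories (below) and drop excluded
   patients;
2. for each of B replicates: sample S healthy patients without replacement
   (S = number of unhealthy), forming a 2S-row test set with all unhealthy
   patients; train a fresh network on the remaining healthy patients;
   compute the 2S × J squared-residual matrix; reduce it to the two
   per-class per-SNP means;
3. average the class means over replicates with equal weight per replicate
   (not pooled by rows, so replicates with identical test-set sizes and
   replicates across endpoints are weighted identically), difference them;
4. threshold Δ at the 70/80/90/95th percentiles of its own distribution
   (linear interpolation between order statistics, strict inequality), and
   label tier members small / moderate / large / large.

Equal-weight averaging, the interpolated percentile and strict membership
are deliberate fixed conventions: they make the statistic exactly testable
against hand computation, keep the tiers nested by construction, and make
a degenerate constant Δ select nothing rather than everything.

## Network and training

Architecture 43–40–30–20–30–40–43 with tanh hidden layers, a sigmoidal
20-node code and a linear output; 7,243 trainable parameters. The loss is
the mean per-sample squared Euclidean reconstruction error plus
λ · mean‖code‖₁. The squared (not plain) norm is used — the two read
identically at the optimum but differ in gradient dynamics, and the
selection statistic is rank-based, so the choice is not critical; the
L1 activity penalty on the bounded sigmoid code is the standard activity
regulariser that the sigmoid code is there to support. λ defaults to
1e-4, with 1e-5 exercised in the tests; the tier assignments are
insensitive to this order-of-magnitude choice because ranking, not the
absolute loss, drives selection.

Training is Adam (learning rate 0.001, β₁ = 0.9, β₂ = 0.999) for 400
epochs, full-batch by default: the training sets are ~1,100–1,300 rows,
the network is tiny, and full-batch makes each run a deterministic
function of (data, seed) with no shuffling stream to manage. Batch-wise
training is available through `NetworkSpec.batch_size` and is itself
seeded. Weights are Glorot-uniform, biases zero. Dosages are mapped to
[0,1] by a fixed /2 — never standardised against the data — so train and
test columns are on the same scale by construction and a frozen model can
be applied to new data without carrying scaling state. Non-finite losses
abort with a diagnostic rather than propagating NaNs into Δ.

The implementation is plain numpy with hand-written backpropagation: at
this parameter count a deep-learning framework would add dependency
weight without adding capability, and the explicit code is what the
package's tests verify against (e.g. the zero-model stub oracle).

## Endpoint derivation

Grades are ordinal CTCAE-style 0–4 at baseline, 12 and 24 months; only
those three visits are consulted. A patient is a case when the maximum
available follow-up grade reaches the endpoint threshold (bleeding ≥1,
frequency ≥2, haematuria ≥1, nocturia ≥2, stream ≥1). Exclusions, in
order of precedence: collagen vascular disease (always), TURB or
anti-muscarinic use (urinary endpoints), hemorrhoids at baseline
(bleeding), then the baseline rule, then missing follow-up.

Patients already at or above the threshold at baseline are handled by a
per-endpoint `baseline_policy`. The default, `exclude`, removes them; the
alternative, `recode_control`, keeps non-worsening trajectories as
controls and counts a follow-up grade *strictly above* the threshold as a
case. Both readings appear in practice and the two policies agree on the
case set whenever no baseline-prevalent patient worsens beyond the
threshold — which is exactly the population the synthetic generator
produces, so that consistency is a tested invariant. Raising the
threshold can never turn a control into a case (also tested).

## Synthetic cohort generator

The generator's defaults are the study conditions the package is tested
under: n = 1,400 patients, J = 43 panel SNPs, case prevalence 10%
(within the 4–18% range of the endpoints), five planted SNPs with odds
ratios 2.5–3.5 (inside the published panel's 0.19–4.36 range), minor
allele frequencies uniform on (0.05, 0.5), and one six-SNP LD block at
r² ≈ 0.9 mirroring the correlated overall-toxicity signal.

Genotypes are Binomial(2, maf) per SNP under Hardy–Weinberg equilibrium,
independent across SNPs except within the declared LD group, where each
SNP copies a shared latent two-haplotype genotype and redraws each allele
from Bernoulli(maf) with probability ε = 1 − (r²)^{1/4}; this preserves
the marginal allele frequency exactly (so maf = 0 stays monomorphic and
r² = 1 duplicates columns) and gives pairwise genotype correlation
(1−ε)². Dosages are integers {0,1,2} by default, with an optional
truncated-Gaussian perturbation to mimic imputed dosages.

Outcomes are independent Bernoulli draws from
logit p_i = β₀ + Σ_j β_j x_ij, with β₀ solved by bracketed root search so
the cohort-mean risk equals the target prevalence to ~1e-10 (the mean of
the logistic is strictly increasing in β₀). Grade trajectories are then
generated to *realise* the drawn outcome under the endpoint's rule —
cases get at least one follow-up grade at threshold, controls stay below
it — with exclusion features (hemorrhoids, TURB, anti-muscarinics,
collagen vascular disease, baseline-prevalent symptoms) planted on top at
configurable rates, all zero by default so that label derivation
round-trips the outcomes exactly.

What the generator does **not** emulate: population structure and
relatedness, genotyping or imputation error, dosage–covariate
confounding, non-genetic risk factors (dose, age, comorbidity),
between-endpoint correlation of symptoms, and epistasis. Passing tests
therefore show that the pipeline recovers additive single-SNP signals of
the published magnitude under clean HWE sampling — not that it would
validate SNPs in any particular real cohort.

## Problem sizes in the tests and acceptance script

Recovery and calibration checks run at B = 20 replicates over five master
seeds (recovery, seed stability) and 20 label permutations at B = 5
(null calibration); full-scale analyses use B = 50, and the `b` parameter
is exposed everywhere. These sizes give stable averages — the Δ ranking
is already well-resolved at B = 20 (cross-seed Spearman ≈ 0.9) — while
keeping a complete run of the suite plus the acceptance script to a few
hundred network trainings. The univariate arm's type-I calibration uses
500 null SNPs at n = 5,000.

## Univariate arm

One additive-coding logistic regression per SNP (`statsmodels` Logit),
Wald two-sided p on the slope, no covariate adjustment. Monomorphic
columns and complete separation are flagged unestimable instead of
raising. Bonferroni control is α/J; the display helper truncates to four
decimals (0.05/43 = 0.0011627… shown as 0.0011, matching the convention
of reporting thresholds to printed precision).

## Known limitations

- Δ has no attached inferential scale: the percentile tiers are relative
  to the panel's own Δ distribution, so at least some SNPs are always
  "selected" unless Δ is degenerate. Interpretation requires the
  permutation-null behaviour, which the tests check.
- The three hazard-ratio panel entries are carried as metadata only; no
  survival modelling is attempted.
- The composite overall-toxicity score behind the `overall_STAT` panel
  labels is not computed; those entries participate as features and
  cross-references only.
- Scaling beyond panel width (J in the millions) is out of scope; the
  dense numpy implementation is sized for panels, not genomes.
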