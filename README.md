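# toxsae

Sparse-autoencoder feature selection for SNP panels in strongly imbalanced
radiotherapy-toxicity cohorts, with a synthetic radiogenomic cohort
generator, CTCAE-style endpoint derivation and a univariate logistic
comparison arm.

## The problem

Late normal-tissue toxicity after prostate radiotherapy (rectal bleeding,
urinary frequency, haematuria, nocturia, decreased urinary stream) affects
a minority of patients — typically 4–18% of a cohort — and the genetic
risk factors reported for it have small effects. Classical validation by
per-SNP logistic regression loses power to multiple-testing correction
exactly because the event class is rare and the panel is wide. This
package implements an alternative: treat patients *with* toxicity as
outliers against a learned representation of patients *without* toxicity,
and ask which SNPs the representation fails to reconstruct for the
outlier class.

It is written for biostatisticians and radiogenomics researchers who want
to study or extend minority-class feature selection on panel-sized
genotype data, without access to any fee-gated cohort: the
`toxsae.simulate` module generates cohorts with the full statistical
structure the method assumes (Hardy–Weinberg genotypes, one
linkage-disequilibrium block, additive-logistic outcomes with planted
odds ratios, longitudinal grade trajectories and exclusion flags).

## The method

Let X ∈ ℝ^{N×J} hold additive dosages x_ij ∈ [0,2] for J = 43 panel SNPs
(scaled to [0,1] at the network input). A deep sparse autoencoder

  h_i = f(W x_i + b),  x̂_i = g(W′ h_i + b′)

with layer widths J–40–30–20–30–40–J (tanh hidden layers, sigmoid code,
linear output) is trained by Adam (learning rate 0.001, 400 epochs) to
minimise

  L = (1/N) Σ_i ‖x_i − x̂_i‖² + λ (1/N) Σ_i ‖h_i‖₁ ,  λ = 10⁻⁴,

on **healthy patients only**. For each of B = 50 replicates, S healthy
patients (S = number of unhealthy patients) are resampled into a balanced
test set together with all unhealthy patients; the remaining healthy
patients train a fresh network; the test set yields a reconstruction-error
matrix R ∈ ℝ^{2S×J} with r_ij = (x_ij − x̂_ij)². Per-class per-SNP mean
errors are averaged over replicates and differenced,

  Δ_j = mean RE_j(unhealthy) − mean RE_j(healthy),

and SNPs with Δ_j strictly above the 70th/80th/90th/95th percentile of
the Δ distribution are selected (top 30/20/10/5%), with effect-size
labels small / moderate / large / large. The comparison arm fits one
additive logistic regression per SNP (Wald test), with the Bonferroni
threshold 0.05/43 ≈ 0.0011.

The autoencoder is implemented directly in numpy (hand-written
backpropagation and Adam): the network is tiny (7,243 parameters) and a
full 400-epoch training takes about a second, so every run is
single-threaded, seeded and exactly reproducible.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1   # shared genotypes, 5 outcomes
python analysis/02_derive_endpoints.py           # endpoint labels + rates
python analysis/03_dsae_selection.py --seed 1    # autoencoder arm (B=20)
python analysis/04_univariate_baseline.py        # logistic comparison arm
python analysis/05_report.py                     # identification matrices
```

Step 02 prints the derived cohorts — e.g.

```
rectal_bleeding: 129 cases / 1158 available (11.1%), 242 excluded
urinary_frequency: 136 cases / 1234 available (11.0%), 166 excluded
```

meaning that of 1,400 simulated patients, 242 were excluded for the
bleeding endpoint (hemorrhoids, collagen vascular disease, baseline
symptoms, missing follow-up) and 11.1% of the rest are cases. Step 03
prints, per endpoint and tier, how many of the five planted SNPs were
recovered:

```
rectal_bleeding p70: 13 selected, 5/5 planted
rectal_bleeding p80: 9 selected, 5/5 planted
rectal_bleeding p90: 5 selected, 4/5 planted
rectal_bleeding p95: 3 selected, 3/5 planted
```

i.e. all five planted SNPs (odds ratios 2.5–3.5) sit in the top-20% tier
of the Δ distribution, and the strict top-5% tier still holds three of
them. Step 05 compares the arms:

```
rectal_bleeding: DSAE p80 5/5, univariate nominal 5/5, Bonferroni 5/5
nocturia:        DSAE p80 5/5, univariate nominal 5/5, Bonferroni 4/5
```

The same pipeline is available as a CLI (`toxsae simulate|label|run|
univariate|report`) driven by a YAML config with a single master seed;
every run writes a JSON manifest from which it can be reproduced
byte-identically.

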