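# streamdapc

Classify the ecological condition of headwater streams from 16S microbial
community tables.

Stream monitoring programs score ecological condition with the Benthic
Index of Biotic Integrity (BIBI), a continuous score in [1, 5] (1 = very
poor, 5 = very good) derived from benthic macroinvertebrate collections.
Collecting and identifying macroinvertebrates is slow and expensive;
bacterial and archaeal communities sampled from the water column or stream
sediment respond to the same stressor gradients and can be sequenced
cheaply. `streamdapc` implements the statistical machinery for replicating
BIBI condition assessments from an OTU count table: it is written for
microbial ecologists and bioassessment practitioners who have a
mothur-style OTU table, a GreenGenes-style taxonomy, and per-site condition
scores, and want to know how well — and through which taxa — the microbes
recover the macroinvertebrate-based assessment.

## Method

The core is Discriminant Analysis of Principal Components (DAPC). Given a
samples × taxa matrix **X** (rarefied to a common depth, optionally
aggregated to a taxonomic rank) and site categories *y* obtained by cutting
the BIBI into eight 0.5-unit classes:

1. **PCA** — column-centre **X** and keep the smallest number of principal
   components whose cumulative explained variance reaches a fraction
   *f* (default 0.95).
2. **LDA on component scores** — find axes **a** maximising the Rayleigh
   quotient **a**ᵀ**B a** / **a**ᵀ**W a** of between- to within-group
   scatter; all min(*g* − 1, *n*_PC) axes are retained for prediction.
3. **Assignment** — a new sample is projected into discriminant space and
   assigned by posterior probability under a shared-covariance Gaussian
   model with training priors.
4. **Indicator taxa** — each taxon's *contribution* on an axis is its
   squared composite coefficient (PCA basis × discriminant coefficients),
   normalised per axis to sum to 1; taxa reaching 0.03 on one of the first
   three axes are selected, and the whole evaluation can be re-run
   restricted to them.

Performance is estimated by 1,000 iterations of an 80/20 train/validation
split, reporting mean *overall* accuracy (exact category), *fuzzy* accuracy
(±1 category, which absorbs the arbitrariness of cutting a continuous
score), percentile 95% confidence intervals, and Cohen's κ =
(p_o − p_e)/(1 − p_e) with a permutation test against random assignment.

A synthetic community generator (`simulate_dataset`) produces OTU tables,
taxonomies and metadata with the structure this analysis assumes — fixed
depth, long-tailed order abundances, a heavy unclassified fraction, and a
minority of taxa whose abundances respond to the latent condition score —
so the whole pipeline is testable without sequencing data.

## Worked example

```python
from streamdapc import (
    AssessmentConfig, SyntheticConfig, aggregate, rarefy,
    restricted_reassessment, simulate_dataset,
)

table, taxonomy, metadata, truth = simulate_dataset(
    SyntheticConfig(seed=4, effect_size=2.0)
)
rarefied = rarefy(table, depth=1344, seed=4)
orders = aggregate(rarefied, taxonomy, "order")
report = restricted_reassessment(
    orders, metadata,
    AssessmentConfig(n_replicates=200, n_permutations=500, seed=4),
)
print(report.text_digest())
```

prints

```
Stream-condition classification report
samples: 82   variables: 10
replicates: 200

metric              mean    2.5%   97.5%
train_overall      0.834   0.773   0.909
train_fuzzy        0.991   0.970   1.000
val_overall        0.724   0.500   0.938
val_fuzzy          0.990   0.938   1.000

kappa[overall] = 0.6715
kappa[fuzzy] = 0.9832
kappa[overall_pvalue] = 0.0020
kappa[fuzzy_pvalue] = 0.0020

selected taxa (10):
  Bacteria;Planctomycetes;Betaplanctomycetes;Indicomicrobiales02  max_contribution=0.8804
  ...
```

Reading: a first-stage DAPC on all 103 classified orders selected 10
indicator orders (contribution ≥ 0.03 on one of the first three
discriminant axes); restricted to those 10, held-out sites land in the
exactly correct 0.5-unit BIBI category 72% of the time and within one
category 99% of the time, far above the chance agreement implied by the
category frequencies (κ = 0.67, permutation p ≈ 0.002). Two of the
selected orders are planted signal orders from the generator's truth
record; the rest ride along through compositional closure.

A command-line interface mirrors the library:
`streamdapc simulate | rarefy | aggregate | assess` (see `--help`).

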