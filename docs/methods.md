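# Methods

## Problem and model

Stream condition is scored by monitoring programs as a continuous Benthic
Index of Biotic Integrity (BIBI) in [1, 5]. To treat condition assessment
as classification, the score is cut into eight 0.5-unit categories with
half-open intervals (a, a + 0.5], the lower endpoint 1.0 folded into
category 1. This convention matches printed category labels of the form
"3.51–4.0" at two-decimal score resolution: 3.9 falls in category 6, 4.1 in
category 7. Cutting a continuous score is arbitrary near the boundaries,
which motivates the *fuzzy* criterion: a prediction into the observed or an
adjacent category (|Δ| ≤ 1) counts as correct. Of the 64 ordered category
pairs, 22 are fuzzy matches.

The classifier is a discriminant analysis of principal components (DAPC),
implemented from first principles:

- **PCA** by singular value decomposition of the column-centred matrix;
  explained-variance fractions from squared singular values. The retained
  count n_PC is the smallest k whose cumulative fraction reaches the
  requested variance fraction (default 0.95), clamped to [1, n − 1] and to
  the numerical rank. Centring only, no unit-variance scaling, by default
  (a `scale` flag exists): the tables are already on a common depth and
  scaling would inflate rare, noisy taxa.
- **Discriminant axes** from the symmetric-definite generalized
  eigenproblem B a = λ W a on component scores, where B and W are the
  between- and within-group scatter matrices. When W is numerically
  singular (common once n_PC exceeds n − g, i.e. precisely the overfitting
  regime) a ridge of 1e-8 × trace(W)/n_PC is added to its diagonal and the
  event logged. All min(g − 1, n_PC) axes are kept for prediction. Axes
  are rescaled so the pooled within-group variance of each discriminant
  score is 1, making Euclidean distance in discriminant space a pooled
  Mahalanobis distance.
- **Posteriors** from a shared spherical-covariance Gaussian model in
  discriminant space with training priors: log p(g|x) ∝ log π_g − d²_g/2,
  normalised by log-sum-exp. Ties break toward the lower-indexed class.
  With every component retained this reproduces ordinary LDA predictions
  exactly (verified against an independent implementation), because class
  mean differences lie entirely in the discriminant subspace.
- **Determinism**: PCA and discriminant axis signs are fixed by making the
  largest-magnitude loading positive, so identical inputs give
  bit-identical models.
- **Contributions**: the composite coefficient of taxon j on axis a is
  (V A)[j, a] (PCA basis times discriminant coefficients); its square,
  normalised per axis to sum to 1, is the contribution. Indicator taxa
  reach 0.03 on at least one of the first three axes (both the threshold
  and the axis count are configurable; the squared-normalised convention is
  the one on whose scale a 0.03 cutoff is meaningful).

## Evaluation machinery

`resample_evaluate` draws ⌈0.8 n⌉ training samples without replacement
(unstratified), refits the DAPC per replicate, and scores both splits for
overall and fuzzy accuracy; 1,000 replicates by default, summarised by
means and 2.5/97.5 percentile intervals. Degenerate training splits
(fewer than two categories) are redrawn, at most 100 times, rather than
stratifying — staying closest to plain random selection. Validation
samples whose observed category is absent from training are necessarily
errors under the overall criterion and are scored normally under the fuzzy
window. Per-replicate seeds are spawned from the configured seed, so
reports are exactly reproducible.

Cohen's κ = (p_o − p_e)/(1 − p_e) is computed on the validation confusion
pooled over replicates, in a plain form and a fuzzy (binary ±1-banded)
form in which both the observed and expected agreement are restricted to
the band; p_e = 1 yields κ = 0 by convention. Significance against random
assignment uses a label-permutation test. Because the margins are fixed
under permutation, κ is a monotone function of the integer agreement
count, so the permutation distribution is coarse and the conservative
estimator (1 + #{κ* ≥ κ})/(1 + B) is visibly non-uniform under the null; a
randomised tie-breaking variant (uniform draw within the tie mass) is
provided and is exactly uniform under exchangeability. The conservative
form remains the reporting default. The pooled pairs are not independent
across replicates (sites recur), so pooled p-values are descriptive rather
than exact; the calibration tests therefore use genuinely independent
draws.

`restricted_reassessment` fits one DAPC on all data, selects indicator
taxa by contribution threshold, subsets the table and repeats the full
resampling evaluation — both stages recorded in one report. Leave-one-out
accuracy (`loo_accuracy`) refits the entire PCA + discriminant per fold;
samples whose class has a single member are skipped with a warning.

## Preprocessing

Rarefaction draws each retained sample's row as a single multivariate
hypergeometric sample of `depth` reads (default 1,344, the normalised
depth of the tables this package targets) — one subsample per sample, the
convention of mothur's `sub.sample`, not an average over repeated
rarefactions. Samples below depth are dropped with a warning. Aggregation
keys are full lineage prefixes (kingdom;…;rank), never bare rank names, so
identically named orders under different classes stay separate; taxa
unclassified at the target rank are pooled and, by default, excluded for
phylum…genus (at the OTU level nothing is aggregated or dropped). Mass is
conserved: kept plus unclassified pools equal the source row totals.

## Synthetic data generator

`simulate_dataset` emulates one sampling combination of a normalised 16S
stream survey:

- **Sites**: 82 by default; BIBI drawn from the rating-class mixture
  very poor : poor : fair : good = 5 : 18 : 23 : 37, uniform within class.
- **Taxa**: ~100 orders with 1 + Poisson(4) OTUs each (~500 OTUs);
  order-level log-abundance baselines Normal(0, 1.5) plus OTU-level
  Normal(0, 1) offsets give a long-tailed community (a few dominant
  orders, many rare). 25% of non-signal OTUs receive lineages truncated
  at a fine rank (weights 0.50/0.25/0.15/0.07/0.03 for genus → phylum),
  emulating the heavy unclassified fraction of real reference-based
  classification.
- **Signal**: n_signal_taxa OTUs (default 15) shift log-abundance by
  effect_size × (BIBI − 3) (linear) or a tanh-saturating analogue
  (logistic-threshold). Their baselines are Normal(1.0, 0.5) — indicator
  taxa sit among the commoner community members, as observed in stream
  surveys. Under the default *clustered* placement the signal OTUs occupy
  dedicated orders (up to 5 each) and response direction alternates
  between orders, never within one — co-occurring indicators share
  ecology, and a within-order sign flip would cancel the aggregated
  signal artificially. *Scattered* placement spreads signal OTUs among
  ordinary orders, diluting order-level detectability (asserted
  directionally in the tests).
- **Noise**: site composition is a Dirichlet draw at total concentration
  500 (∞ disables it) around the softmax of the log-abundances; counts
  are a multinomial draw of 1,344 reads. Dirichlet-multinomial was chosen
  over Poisson-lognormal for its single concentration parameter and
  closed-form expectations.
- Optional environmental covariates (pH, DOC, NO3, Embed) are coupled to
  BIBI with fixed signs and realistic noise, for workflows that carry
  covariates through.

What the generator does **not** emulate: phylogenetic correlation between
taxa, spatial autocorrelation between sites, season/medium differences
within one dataset (each simulated table is a single combination), and
compositional effects beyond softmax closure. Passing tests on synthetic
data therefore demonstrate correctness of the machinery and its
statistical calibration, not the accuracy attainable on any real survey.

## Test and verification sizes

Statistical checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted margins while keeping the suite quick:
chance calibration uses 10 independent null communities × 40 resampling
replicates (the per-dataset difference between mean validation accuracy
and the margin-implied chance rate is the unit of analysis, since
replicates within one dataset are dependent); indicator recovery and the
overfitting-direction comparison use 30 simulated communities each; the
rarefaction expectation check uses 10,000 hypergeometric draws. "Strong"
effect in the recovery setting means effect_size = 4 with Dirichlet
concentration 2,000 — a response that dominates biological noise, so the
planted taxa genuinely carry the between-category signal. The
overfitting comparison uses a taxon-rich configuration (~1,000 OTUs,
concentration 150): the widening of the train-minus-validation gap at OTU
rank relative to order rank is a property of the many-noise-taxa regime,
and order-level aggregation pools both the planted signal and the
sampling noise.

## Known limitations

- With n_PC close to n − 1 the within-scatter ridge, not the data,
  conditions the discriminant; fitted axes in that regime are
  overfit by construction (this is the phenomenon the OTU-level
  evaluation quantifies, not a defect to be hidden).
- Contribution-based selection inherits compositional closure: taxa that
  merely compensate for true responders can pass the threshold.
- Percentile confidence intervals across resampling replicates mix
  split-to-split and estimation variance; they are honest descriptions of
  resampling spread, not standard errors of a population accuracy.
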