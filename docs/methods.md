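# Methods

## The model

A verbal-autopsy (VA) interview yields, for each death, a vector of
symptom responses: yes / no / don't-know for binary questions, a number
of days for duration questions, a coded answer for categorical ones.
Every response is reduced to a single endorsement bit: 1 iff the answer
is "yes", the duration strictly exceeds the symptom's cutoff, or the
code lies in the symptom's endorsing set; everything else — including
"don't know" and missing — is unendorsed. For a training set with
gold-standard causes, the endorsement rate `x[i, j]` is the fraction of
cause-*j* deaths endorsing symptom *i*, with don't-know and missing kept
in the denominator.

The Tariff for a cause-symptom pair is a robust z-like score of how
distinctive the symptom is for the cause:

    Tariff[i, j] = (x[i, j] − median_i) / IQR_i,

where the median and interquartile range are taken across causes for
the symptom. A symptom whose endorsement rate is constant across causes
has zero IQR; such pairs are *undefined*, stored as 0, and never
significant — they carry no discriminatory signal, and this is the
correct reading of the formula rather than an implementation refuge
(note the corollary: a symptom endorsed *only* by its own cause and
never elsewhere also has zero IQR once fewer than a quarter of causes
endorse it, so "perfect" symptoms get an undefined Tariff, not an
infinite one).

Significance is decided by a Monte-Carlo experiment: records are
resampled with replacement within each cause (per-cause totals held
fixed), Tariffs are recomputed per replicate, and a percentile
uncertainty interval is formed for every pair. A pair whose interval
touches or crosses zero is removed (Tariff set to 0). Surviving Tariffs
are rounded to the nearest 0.5, which treats similar values as equally
informative and limits over-fitting. Defaults follow published
practice: 500 replicates and a 99% interval.

Prediction is the additive scorer: a record's score for cause *j* is
the sum of the cause's rounded Tariffs over the record's endorsed
symptoms, and the predicted cause is the argmax, ties broken
deterministically by cause-list order. The production Tariff 2.0
refinement — ranking the score against a cause-balanced resampled
training pool, with minimum-score and rank cutoffs and an
"undetermined" category — is deliberately out of scope; the validation
machinery accepts any predictor through the same interface, so it is a
clean extension point. Because there is no "undetermined" output,
predicted cause fractions always sum to one.

## Validation design

Random train/test splits flatter population-level metrics because the
test cause composition mirrors the training one. Each validation
replicate therefore (1) splits records train/test stratified by cause
(default 75/25, at least one record on each side per cause), (2) draws
a target cause-specific mortality fraction (CSMF) vector from a
symmetric Dirichlet (default concentration 1), and (3) resamples the
held-out records with replacement into a test set matching the drawn
composition. Metrics are aggregated over replicates (default 500) as
medians with 2.5/97.5-percentile uncertainty intervals.

Metrics, each a single swappable function:

- **CCC** (chance-corrected concordance), per cause:
  `(TP_j/T_j − 1/N)/(1 − 1/N)` with `N` the size of the module's full
  cause list (not the causes present in a particular draw), undefined
  when the cause has no test records. Overall CCC is the unweighted
  mean of per-cause CCCs within a split, then the median across splits.
- **CSMF accuracy**: `1 − Σ|true_j − pred_j| / (2(1 − min_j true_j))`.
- **CCCSMF accuracy**: `(CSMFA − 0.632)/(1 − 0.632)`; 0.632 is the
  expected CSMF accuracy of random assignment under Dirichlet test
  compositions, so 0 means chance and negative values worse than
  chance.

The robustness analysis compares a fit on dataset A with a fit on the
pooled A∪B: proportions of significant pairs before and after,
retention of A-significant pairs, direction flips among jointly
significant pairs (a sign change of an insignificant pair is noise),
the largest Tariff changes (significance-masked raw values, filtered to
|Tariff| ≥ 1 in either fit and |Δ| ≥ 1), and per-cause/overall metric
deltas. "Changed significantly" is operationalized as disjoint 99%
bootstrap intervals of the two estimates; the right denominator for
"proportion changed" is debatable, so both all-pairs and
ever-significant denominators are reported.

## Synthetic data

The generator draws symptoms conditionally independently given cause —
exactly the structure the additive scorer assumes — with per-cause
endorsement probabilities, symmetric don't-know contamination (each
response independently replaced with probability `dont_know_rate`, so
effective endorsement is `p·(1 − dont_know_rate)`), and duration
symptoms drawn to cross their cutoff with the specified probability
(exponential tail above, uniform below; only the bit is identified
downstream). Because the generative probabilities are known, the
population Tariff matrix is computable exactly (`true_tariffs`) and
serves as a parameter-recovery oracle.

`phmrc_like_spec` mirrors the published combined cause composition of
the two source gold-standard studies (34 adult, 21 child, 6 neonate
causes; e.g. neonate counts 1372:831:549:281:197:88), scaled with a
floor of one case per cause. Endorsement profiles give every cause
three dedicated high-lift symptoms over a low baseline that *varies*
across causes — an exactly constant baseline would zero the IQR and
undefine the whole symptom row, which real endorsement rates never do.
A default don't-know rate of 5% reflects typical VA item-level
missingness.

What the generator does not emulate: symptom dependence given cause,
site and interviewer effects, recall bias, informative missingness,
free-text narratives. Passing tests therefore demonstrate correctness
of the estimator and pipeline mechanics under the model's own
assumptions, not field performance on real interviews.

## Numerical choices

- Median/IQR across causes use linear-interpolation quantiles (the
  numpy default). This affects third-decimal Tariffs; it is recorded
  here because no single convention is canonical.
- Bootstrap intervals use Efron's percentile rule with (B+1)p
  order-statistic quantiles (numpy `method="weibull"`). With few
  replicates relative to the requested tail (e.g. 100 replicates for a
  99% interval) this clamps to the extreme replicates, making the
  interval conservative; interpolated quantiles there are
  anti-conservative and inflate the per-pair false-positive rate.
- "Includes zero" is closed: an interval endpoint exactly at 0 removes
  the pair.
- Rounding to the 0.5 grid resolves exact .25/.75 ties away from zero,
  preserving sign magnitude; masking is applied before rounding (the
  two orders are observationally equivalent for reported values).
- Replicate RNG streams are spawned per replicate from the master seed,
  so results do not depend on execution order; Dirichlet splits are
  seeded by (seed, split index) and are individually reproducible.
- Duration cutoffs are schema fields; a helper sets them to the
  training-set median of positive durations per symptom. Endorsement
  requires strictly exceeding the cutoff.
- Resampled test records get a `#draw` suffix on their id so duplicate
  draws of the same record stay distinct in prediction output.

## Problem sizes

Package defaults are the published ones (500 bootstrap replicates, 500
validation splits). The test suite exercises the same code at
desk scale: 50–100 replicates, 20 splits, 4–20 causes with 40–200 cases
per cause — sizes at which every stochastic check has comfortable
margins while the full suite stays fast.

## Known limitations

- The additive argmax predictor is a simplification of production
  Tariff 2.0 (no rank-based cutoffs, no demographic restrictions, no
  undetermined category). Absolute CCC/CSMF levels are therefore not
  comparable to published production numbers, though the machinery of
  the robustness comparison is.
- When a fitted matrix is entirely insignificant (e.g. after a label
  permutation), the deterministic tie rule assigns every record the
  first cause; population-level metrics then sit at their degenerate
  floor rather than at the 0.632 chance anchor, which presumes spread
  random assignment. A chance-anchored CCCSMF requires a predictor that
  spreads ties; the deterministic rule trades that away for exact
  reproducibility.
- Ill-conditioned symptom rows (cross-cause IQR near zero) produce
  Tariffs of enormous magnitude whose estimates are unstable in exactly
  the way the published largest-change tables show for hallmark injury
  symptoms; the delta tables report them faithfully rather than
  winsorizing.
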