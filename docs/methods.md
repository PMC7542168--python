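# Methods

This note documents the statistical construction of the synthetic cohort,
the model and training choices, the evaluation conventions, and the limits
of what the synthetic experiments can show.

## The synthetic cohort

### What it emulates

The generator reproduces the published descriptive statistics of a large
MTurk Facebook cohort:

* twelve psychodiagnostic scale totals — CSSRS suicide total, PHQ-9, GAD-7,
  5-item RRS brooding, PSWQ, SWLS, UCLA-10, and the five BFI-10 traits —
  with their published means, SDs and full pairwise Pearson correlation
  matrix (N = 1650);
* nested binary risk labels at prevalences 36.03% (general risk: any
  suicidal ideation) and 13.17% (high risk: ideation with method, intent or
  plan), with high ⊂ general by construction;
* posting activity: a point mass of silent users (335/1985 ≈ 16.9%), and
  for posting users a right-skewed count distribution with mean 82.35 and
  SD 106.79, post lengths with mean 31.14 and SD 66.56 words;
* socio-demographics with small group differences in the published
  directions — the risk group younger (34.6 vs 38.3 years), poorer
  ($48,389 vs $58,563, with a ~0.2% missing-income rate so that
  pairwise-complete handling is exercised), and more active (a
  mean-preserving log-scale tilt of +0.24 on post counts, ≈ d = 0.2);
  gender (23.25% male) independent of risk.

### Correlated scores via a Gaussian copula

Each user draws a 12-dimensional standard-normal latent profile; each
coordinate is quantile-mapped through a fixed discrete marginal onto the
instrument's integer support. Marginals are discretized normals with tail
mass lumped into the support endpoints, whose (μ, σ) are solved by
least squares so the realized mean and SD equal the published targets
exactly. The CSSRS total is instead zero-inflated: P(0) = 1 − 0.3603 (the
non-ideating majority), and the positive part is 1 + negative-binomial,
moment-matched in closed form to overall mean 0.87 and SD 1.41.

Quantile mapping preserves rank correlations but attenuates Pearson
correlations — mildly for near-normal scales, substantially for the
zero-inflated suicide column (0.436 would shrink to ≈ 0.37 against PHQ-9).
The latent correlation of every pair is therefore *solved*, not copied:
the exact copula product moment E[gᵢ(Z₁)gⱼ(Z₂)] is evaluated by piecewise
Gauss–Legendre quadrature (16 nodes per discrete cell of one margin;
the conditional expectation of the other margin is smooth within a cell)
and inverted by bisection so the **discretized** scores reproduce the
published correlations. At 2 × 10⁶ users the realized values are 0.4362
(target 0.436, suicide–depression) and 0.7629 (target 0.762,
neuroticism–worry); at the working size n = 1650 sampling noise of ≈ 0.02
dominates. The solved latent matrix is repaired to the nearest
positive-semidefinite correlation matrix (alternating projections); for
the default calibration the solved matrix is already comfortably PSD
(minimum eigenvalue ≈ 0.12).

Risk labels rank users by the latent suicidality coordinate: the top
round(n·π_general) are general-risk, the top round(n·π_high) high-risk,
which guarantees nesting and exact realized prevalence. This mirrors the
instrument's logic, where a zero CSSRS total and a negative general-risk
label coincide.

### Posts and vocabulary

Post counts and lengths are lognormal, moment-matched to the published
mean/SD and truncated to positive integers; only the first two moments are
published, and the lognormal is the conventional choice for such activity
tails. A consequence worth knowing: the median of the matched lognormal
(~50 posts) is far above the published median of 10, because the published
moments describe the *filtered* cohort while the median described the
pre-filter one — the generator targets the moments.

Post text is sampled from a three-pool vocabulary: a Zipf-weighted neutral
pool (common English words plus deterministic pseudo-words that give the
tail enough distinct types for document-frequency contrasts), a distress
lexicon (~320 stems and generated morphological variants of negatively
charged, swearing, distress and physical-complaint words), and a
positive/belonging/religious lexicon. A user's distress-word rate is
`neg_base·exp(s·z)` gated by a per-user Bernoulli "discloses distress"
indicator with probability `sigmoid(3s·(z − 0.8))`, where z is latent
suicidality and s the calibration's `signal_strength`; the positive-word
rate decays as `exp(−0.5·s·z)`. The gate encodes the observation that most
users — including many at risk — never post explicit distress, and it is
what keeps the distress lexicon's document frequency informative for the
TF-IDF analysis. At s = 0 every user draws from the identical
distribution, giving a clean no-signal null. Idiomatic posts using
kill/die in non-suicidal contexts are injected at a small class-independent
rate (1% of posts), matching the finding that explicit lemmas almost never
appear in genuinely suicidal messages.

### Oracle embeddings

In oracle mode the embedding is a fixed random linear map of the latent
profile plus unit Gaussian noise,
`e = s·(A z)/√k + ε`, giving a known, tunable signal. With
`mediated_only=True` the suicide coordinate is excluded from the map, so
the label is informative *only* through the eleven auxiliary latents —
the regime in which hierarchical auxiliary supervision should pay off.

### What it does not emulate

No real language (syntax, topics, pragmatics), no temporal structure, no
images/reactions, no recruitment or attention-check artifacts, no
missingness beyond income, no measurement error model for the scales
beyond discretization. Passing tests therefore demonstrate that the
*pipeline* recovers planted structure under the published summary
statistics — not that any model would attain these numbers on real data.

## Models and training

* STM: input → FC(256) → FC(64) → sigmoid. MTM: shared trunk
  FC(256)→FC(64) with ReLU output; subnetworks FC(64) → linear heads of
  sizes 5/4/2 wired personality → psychosocial → psychiatric, each reading
  the previous output concatenated with the trunk; sigmoid suicide head on
  psychiatric ⊕ trunk. Partial variants keep one subnetwork, fed by the
  input (personality) or input ⊕ trunk (the others).
* Auxiliary targets are the scale totals, z-scored with training-portion
  statistics; SWLS is negated first so higher always means more risk. They
  are treated as continuous regression targets under MSE with weights
  λ = 1 each, against BCE weight 1 on the suicide head — the natural
  choice for standardized continuous targets, exposed in `ModelConfig` for
  sweeps. Gradients from all losses flow into the trunk (no stop-gradient).
* Training: Adam (lr 1e-3), batch 32, dropout 0.2 on hidden activations,
  early stopping on dev AUC with patience 8–10 and best-checkpoint restore,
  max 60–100 epochs. All randomness (init, shuffling, dropout) flows from
  one config seed; identical configs give bit-identical trajectories.
  Class imbalance is left to plain BCE (AUC is the metric); a `pos_weight`
  option exists.
* Everything is float64 numpy with hand-written backpropagation; the
  composite-loss gradients are verified against central finite differences
  to < 1e-4 relative error in the test suite.

## Evaluation conventions

* Splits: 70/15/15 with portion sizes floor/floor/remainder (701/150/151
  at n = 1002) and positives apportioned by largest remainder, making the
  risk prevalence equal across portions to within one user.
* AUC: trapezoidal integration of the ROC, identical to Mann–Whitney pair
  counting with ties at ½ (property-tested exactly).
* Confidence intervals over repeats: percentile interval of the repeat
  AUCs by default (a normal approximation is available); with five repeats
  this is a descriptive spread, not a calibrated interval.
* Effect sizes: d = √2·Φ⁻¹(AUC) under the equal-variance binormal model;
  d = 2t/√df for pooled two-sample t statistics (the pooled form, not
  Welch, because the published degrees of freedom are n₁+n₂−2), with a
  default d-CI half-width of 1.96·2/√df.
* Inclusion filter: drop zero-post users, then retain users with count
  **≥** the median of the posting users; retaining ties is the only rule
  consistent with a >50% retention rate, and the filter report also
  exposes the median over all users since the published text is ambiguous
  about the reference population.

## Interpretation conventions

* Threshold: the ROC point maximizing TPR/FPR; FPR = 0 points are excluded
  (infinite, uninformative ratio) and their count is flagged; ties break
  toward higher TPR, then higher threshold.
* TF-IDF: one concatenated document per confusion class (4-document
  corpus), score tf·log(N/df) after stop-word and non-alphabetic removal;
  words present in every class document score zero by construction. A
  per-user-document idf variant is available behind a flag. The keyword
  search uses fixed morphological variant lists rather than a stemmer, for
  auditability.

## Problem sizes and calibrated defaults

* The structure-recovery experiment runs oracle-mediated cohorts at
  n = 1002, D = 128, with `signal_strength = 0.15` — chosen once so that
  the STM operates near the published real-data operating point
  (mean test AUC ≈ 0.62); at that level the experiment gives
  STM 0.616 vs MTM 0.652 over 5 cohorts × 5 splits (21/25 wins, one-sided
  signed-rank p ≈ 6e-4). Five seeds × five repeats keeps the whole
  experiment around a minute of CPU.
* Text-mode demonstrations default to `signal_strength = 1.0`, where the
  lexicon tilt is strong enough for class-characteristic words to be
  recoverable from small cohorts (a few hundred users).
* The default pre-filter cohort size is 1650 so the activity-filter
  pipeline is exercised end to end.

## Known limitations

* The latent-correlation solve assumes the Gaussian copula is the right
  dependence family; real scale totals can have tail dependence it cannot
  represent.
* The published supplementary material (exact loss functions,
  hyperparameters, tuning protocol) is not public; the loss form and
  architecture defaults here are the package's own re-specification, and
  absolute AUC levels on synthetic data are not comparable to the
  published real-data values.
* The repeated-CV confidence intervals and the paired MTM−STM summaries
  describe variation across five random splits of one cohort; they do not
  propagate cohort-level sampling variability.
* The mock embedder preserves bag-of-tokens information only; word order
  and context, which motivate contextualized embedders, are invisible to
  it.
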