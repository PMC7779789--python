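# Methods

## Scoring model

A post's score in category *c* is the sum, over occurrences of lexicon
terms of category *c* in the segmented text, of the term's weight, with
the sign flipped when a negator token occurs within the preceding
`window` tokens (default 1, i.e. the immediately preceding token).
Reversal is a flag: any number of negators inside the window flips the
sign exactly once, so "not not help" with window 1 scores −w(help) —
this is the decided contract, not a claim about linguistics. A term
listed under several emotion categories contributes to each. Scores are
raw weighted sums: no length normalization by default (accumulation then
daily averaging is the procedure being modelled), with a
`length_normalize` toggle for sensitivity analysis.

The built-in segmenter is greedy longest-match against the union of
lexicon terms and negators, with single-character fallback; every
lexicon term occurring contiguously in the text is guaranteed to surface
as one token. Any callable `text -> tokens` can replace it (e.g. jieba
with the lexicon loaded as a custom dictionary), so segmentation
fidelity is decoupled from the statistical machinery. Terms are
canonicalized by NFC normalization, surrounding-whitespace stripping and
case-folding (a no-op for CJK).

Corpus inclusion mirrors the study design being reproduced: posts from
official verified accounts are dropped; for reposts only the attached
comment is kept (the reposted body is not the reposting user's own
expression), and comment-less reposts are dropped; user identifiers are
replaced by salted one-way hashes. An optional keyword substring filter
emulates crawl-time topic selection and is off for synthetic data.
Duplicates are not removed.

## Prosocial lexicon construction

Ratings are integers on a 9-point scale, complete over terms × raters.
Aggregation uses the arithmetic mean and the **sample** (n−1) SD —
raters are a sample of possible raters. Deletion conditions are strict
inequalities (mean < 6, SD > 2), so terms exactly at a boundary are
retained. Min–max normalization onto [1, 9] is applied to the
**post-filter** means; all-identical means make the affine map undefined
and raise unless the caller explicitly requests the midpoint fallback.
Reliability defaults to ICC(2,k) (two-way random effects, absolute
agreement, average of k raters; computed via pingouin, which labels it
ICC(A,k)), with mean pairwise Pearson r as an alternative since the
statistic behind published reliability figures of this kind is often
unstated. Lexicon overlap is |terms(a) ∩ terms(b)| / |terms(a)| after
canonicalization — a direction-sensitive containment fraction.

## Moderation analysis

y (daily prosocial), x (daily emotion) and m (daily new cases, raw
untransformed counts) are z-scored with sample SD; the product term is
formed from the standardized factors and **not** re-standardized, the
convention for standardized moderated regression. OLS gives analytic
SE/t/p with n − 4 residual df and the omnibus F (3, n − 4).
A nonparametric bootstrap (default 5000 case resamples of whole rows of
the once-standardized design, percentile 95% intervals, seeded)
accompanies the analytic intervals, because published pipelines of this
kind report both df-based t/p and bootstrap significance. Each emotion
is fitted in its own model; no multiple-testing correction is applied,
matching the design being reproduced.

Simple slopes: `slope(z) = B1 + B3·z`,
`SE² = Var(B1) + z²·Var(B3) + 2z·Cov(B1, B3)` from the coefficient
covariance, t with n − 4 df. Probe levels are high = M + 1SD and
low = max(M − 1SD, observed minimum): for strongly right-skewed
moderators (epidemic case counts) M − 1SD can be negative or below every
observation, and the observed minimum is the defensible substitute. The
substitution rule is applied uniformly to every model.

`replay_table2` runs the same slope arithmetic on printed coefficients
alone (a packaged JSON carries the published standardized B1/B3 per
emotion and the severity moments M = 1929.68, SD = 2325.36, min = 77),
reproducing the published conditional slopes to within coefficient
rounding (±0.02); SE/t are emitted only when a coefficient covariance is
supplied, since printed tables rarely include one.

## Synthetic-data generator

The generator emulates the study conditions: a 41-day window starting
2020-01-20, 800–2000 posts per day by default, a unimodal severity curve
(log-normal-shaped pulse, default peak at day 20, height 3500, Poisson
noise, floored at 77 cases — the minimum the real series shows), lexicon
words embedded in free text, negators, and a planted emotion × severity
interaction on prosocial word emission. Latent per-day emotion
intensities are i.i.d. normal, sample-standardized; the latent prosocial
series is `p = b0 + b1·e + b2·s + b3·e·s + ε` on standardized latents
(defaults b1 = b2 = 0.3, b3 = 0.4). With `noise_sd=None` the residual SD
is set to `sqrt(1 − b1² − b2² − b3²)` so p has unit variance and the
planted coefficients live on the same standardized scale the analysis
estimates.

Emission is log-linear Poisson: a post on day d contains
`Poisson(rate_c · exp(0.5 · latent_c,d))` terms of category c, drawn
uniformly from that category's vocabulary, shuffled with filler tokens.
Per-category base rates (0.04/post for anger up to 0.75 for prosocial)
are set so per-post mean scores land near the magnitudes daily Weibo
panels of this kind report — anger and surprise are rare, fear and
prosocial mentions common. Negators are inserted immediately before a
fraction (default 0.1) of lexicon occurrences, using an RNG stream
separate from content generation so datasets differing only in the
negation fraction share identical token content (the basis of the
sign-flip test). The synthetic language is whitespace-separable with
filler vocabulary disjoint from all lexicons, making the default
tokenizer exact and the scoring oracle closed-form.

What the generator does **not** emulate: real Chinese morphology and
segmentation ambiguity, user-level and network structure, temporal
autocorrelation beyond the severity pulse, topic drift, and duplicated
or spam content. Passing tests therefore validate the pipeline's
statistical machinery and contracts, not the linguistic accuracy of any
particular segmenter on real Weibo text.

`generate_latent_panel` exposes the day-level latents directly (no text
emission), which is the right surface for Monte-Carlo work on the
moderation stage: the planted coefficients act exactly, without
text-sampling measurement noise. Full-corpus recovery is attenuated for
rare categories — the daily mean of ~0.04 mentions/post measures the
latent noisily — so end-to-end checks at study-scale corpus sizes assess
sign recovery and detection power, while bias/coverage calibration runs
on latent panels (500 replicates of n = 41: coefficient bias < 0.02,
analytic 95% CI coverage of the interaction within [0.90, 0.98]).

## Numerical and design choices

- Seeds: every stochastic entry point takes an explicit seed; the
  pipeline derives per-model child seeds from the master seed via
  `SeedSequence.spawn`, making reports byte-identical across reruns.
- The bootstrap resamples rows of the design standardized once on the
  full sample (it does not re-standardize within resamples), matching
  standardize-then-analyze macro behaviour.
- Degenerate inputs fail loudly with context: zero-variance series,
  constant panel columns, rank-deficient designs, missing panel days or
  severity values (named date), malformed lexicon rows (named line).
- Problem sizes in the test suite are scaled to what the checks need:
  contract tests use tens of posts per day; the monotonicity and
  identifiability checks run at the generator's default study scale.

## Known limitations

- The longest-match tokenizer is exact only when lexicon terms actually
  appear contiguously; on real Chinese text a dedicated segmenter should
  be plugged in, and results will depend on it.
- Daily means ignore within-day post-count heteroscedasticity; days with
  few posts get equal weight, as in the procedure being modelled.
- The 41-point panel is treated as i.i.d. for inference; temporal
  autocorrelation is not modelled (nor robust/HC errors) — conclusions
  on real panels should be read accordingly.
- The bootstrap percentile interval can disagree with analytic CIs at
  n = 41 for skewed resampling distributions; both are reported.
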