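# emoprosocial

Lexicon-weighted emotion and prosocial scoring of social-media posts,
with moderated-regression inference of how epidemic severity changes the
emotion–prosociality relationship.

The package is for computational social scientists and psychologists who
study collective emotion and prosocial tendency in social-media text
during a crisis. It reimplements, end to end and with a synthetic-data
generator standing in for the non-redistributable crawled corpus, the
analysis style used on COVID-19-era Weibo data: dictionary-based affect
detection, daily aggregation against newly confirmed case counts, and
PROCESS-Model-1-style moderation with simple-slopes probing.

## Model

**Scoring.** Each post is segmented (built-in greedy longest-match
segmenter with a seam for an external Chinese segmenter such as jieba).
Every occurrence of a lexicon term contributes its intensity weight
*w* ∈ [1, 9] to its category — the six Ekman emotions (happiness, anger,
sadness, fear, disgust, surprise) from an affective lexicon, plus a
prosocial category from a rater-built lexicon. An occurrence directly
preceded by a negator counts as −*w* (a sign flag, applied once however
many negators precede). Per-post category scores are averaged within
calendar days to form a 41-row panel joined with daily new confirmed
cases *s*.

**Prosocial lexicon construction.** Candidate words rated 1–9 by
multiple raters are aggregated (mean, sample SD), filtered (deleted if
mean < 6 or SD > 2; boundaries kept), and the surviving means are
min–max rescaled onto [1, 9] to become weights. ICC(2,k) quantifies
inter-rater reliability; a term-overlap fraction compares lexicons.

**Moderation.** For each emotion *x*, with all variables standardized
(sample SD) before the product term is formed:

```
z_y = B0 + B1·z_x + B2·z_m + B3·(z_x·z_m) + e
```

where *y* is the daily prosocial score and *m* the daily case count.
Analytic OLS inference (df = n − 4) is reported alongside nonparametric
case-resampling bootstrap percentile 95% CIs. The conditional (simple)
slope of *x* at moderator z-score *z* is `B1 + B3·z`, probed at
high = M + 1SD (z = +1) and at a low level that substitutes the observed
minimum when M − 1SD falls below it — as it does for strongly skewed
case-count series.

## Worked example

`examples/` holds one short script per capability. Reconstructing the
published conditional slopes from printed coefficients alone
(`python examples/replay_published_slopes.py`):

```
  emotion        level  moderator_raw  moderator_z  slope
    anger high (M+1SD)        4255.04        1.000  1.220
    anger          low          77.00       -0.797 -0.163
  sadness high (M+1SD)        4255.04        1.000 -0.690
  sadness          low          77.00       -0.797  0.334
 surprise high (M+1SD)        4255.04        1.000 -0.730
 surprise          low          77.00       -0.797  0.384
```

Anger's effect on prosocial expression is strong at high severity
(slope 1.22) and absent at low severity (−0.16); sadness and surprise
flip sign between levels — the moderation the B3 coefficients encode.

Planting and recovering an interaction through the full pipeline
(`python examples/simulate_and_recover.py`):

```
simulated 12502 posts over 41 days (driving emotion: anger, planted b3 = 0.5)
daily panel: 41 rows, 12502 posts, severity 77-3575 cases/day

moderation fit (N = 41):  R2 = 0.33
  interaction B3 = 0.34  (planted 0.5), t = 2.37, p = 0.0233, bootstrap 95% CI [-0.01, 0.77]
  simple slope at high (M+1SD)  (z = +1.00): +0.68 (p = 0.0027)
  simple slope at low           (z = -1.00): +0.00 (p = 0.9889)
```

The estimate sits below the planted value because daily means of a
rarely mentioned emotion are a noisy measurement of the latent intensity
(attenuation); at the generator's full default corpus sizes the bias
shrinks (see `docs/methods.md`).

A thin CLI mirrors the library
(`emoprosocial simulate|build-lexicon|score|aggregate|analyze|run-all|replay-table2`),
each stage reading and writing documented plain-text dialects
(JSONL/CSV/TSV).

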