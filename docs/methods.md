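# Methods

This note documents the models, procedures and numerical choices behind
`buffercrops`, and what the synthetic-data tests do and do not show about
real archives.

## Data model

Five crops are analysed — rye, oat, millet, buckwheat, hemp — chosen for
their role as buffer crops in marginal north-eastern European
agriculture.  Wheat and barley are excluded by design: their sources
rarely resolve species/variety, so their rows carry no usable ecological
signal and would bias the minor crops' shares.

An **archaeobotanical context** is a sampling unit with a dating interval
(years AD) and either raw counts of identified remains or pre-computed
percentages (renormalised to sum to 100).  A **manor record** is one
inventory description with sown amounts per crop; a blank cell means the
crop was *not recorded* (presence flag false), while an explicit zero is
a recorded zero.  The distinction matters because mention counts —
"in how many inventories does millet appear at all?" — are a statistic of
recording, not of quantity.

## Temporal binning

* Grid: half-open bins `[b, b + 100)` for `b = 100, 200, …, 1700` AD.
  The 1–100 AD bin is outside the default grid (the archaeobotanical
  record there is effectively empty).
* Assignment: by interval midpoint.  A midpoint exactly on a boundary
  goes to the upper bin — deterministic and documented, nothing more.
* Exclusion: intervals wider than `max_span = 200` years (two bins)
  cannot be trusted to a single bin and are dropped.  The threshold is
  the tightest reading of "excessively wide ranges spanning several
  centuries" and is a config knob; results sensitive to it should be
  reported together with the value used.
* Aggregation: default is the unweighted mean over contexts of each
  context's five-crop percentage composition ("mean presence").  This
  weights contexts, not seeds, so one rich context cannot dominate a bin.
  A pooled-count mode (sum counts, then convert) and a site-level mode
  (average a site's contexts first) are provided for sensitivity
  analysis.
* Empty bins are *missing*, never zero: downstream correlation deletes
  them pairwise.  Interpreting absence of samples as absence of crops
  would manufacture signal.

## Climate proxies

The varve-thickness wetness record is smoothed with a **centred rolling
mean over a 50-calendar-year window** `[t − 25, t + 25)`; edge windows
are truncated, not padded, so the whole record contributes.  Defining
the window in calendar years (rather than sample counts) makes the
operation robust to unevenly spaced chronologies.  Smoothing precedes
binning; a raw-binned mode is available.  The temperature (CIT) record
is binned directly to the 100-year grid (bin mean over samples).

The two-region precipitation check averages each region's stations per
year, skipping stations missing that year — this is exactly why a
15-station mean is robust to wartime gaps — and Pearson-correlates the
two regional means over common years, optionally from a cutover year
(`--from-year`, e.g. 1930) onwards.  Annual totals derived from monthly
tables drop any year missing a month by default (configurable to a
≥ n-month tolerance with rescaling).

The cubic smoothing spline used for display/diagnostic smoothing is
`scipy`'s penalised regression spline with the year axis rescaled to
[0, 1] and the OLS line removed before fitting (the second-derivative
penalty annihilates linear trends, so this is mathematically identical
but numerically far better conditioned); `smooth_param = inf` returns
the least-squares-line limit exactly.

## Association statistics

With ≈ 17 bins of tied, bounded, non-Gaussian percentages, the defensible
association measure is the **tie-aware Spearman rank correlation**
(Pearson correlation of midranks), and the defensible calibration is a
**permutation null**: shuffle the climate vector, recompute ρ, repeat
`n_perm = 10,000` times.  Choices:

* p-value `(k + 1)/(n_perm + 1)` (add-one): never zero from a finite
  Monte-Carlo sample; the exact-enumeration oracle (n ≤ 8) reports the
  plain proportion, and tests reconcile the two conventions explicitly.
* Tie comparisons use a 1e-12 tolerance so permutations that achieve the
  observed ρ exactly are counted as "as extreme" — this makes the test
  slightly conservative (super-uniform p under the null), which is the
  safe direction.
* Two-sided by default; one-sided alternatives by flag.  Signed ρ plus a
  two-sided p is the conservative reading when sidedness is unstated.
* The climate vector is the one permuted; permuting the crop vector is
  statistically equivalent and exercised in tests.
* Missing bins: pairwise deletion only, never imputation.  Pairs with
  fewer than 3 joint bins, or with a constant crop vector, are skipped
  with a log entry.
* Each crop–proxy pair derives its own child seed from the suite seed
  (SeedSequence spawning), so any single pair can be replayed.
* No multiple-testing correction drives conclusions; a Benjamini–
  Hochberg column is emitted as advisory output.
* Shuffling is plain (exchangeable) permutation.  Century-scale proxies
  are autocorrelated, so the null is optimistic about effective sample
  size; block or phase-randomisation nulls are out of scope.

Implementation note: ranking commutes with permutation, so the null is
computed by permuting the *midranks* of y once-ranked — an
order-of-magnitude cheaper than re-ranking per shuffle and bit-identical
to it.

## Manor statistics

Shares are per-record: `share_c = sown_c / Σ sown` over the five analysed
crops, unit-free and therefore tolerant of heterogeneous volume units
across records.  Century summaries report unweighted mean shares and
mention counts over records.  The stability question — did practice
change across the 16th/17th/18th centuries? — is tested at the record
level (the record is the replicate; 44/60/138 records per century at
study scale):

* **rye → one-way ANOVA** (`F = MS_between / MS_within`, df `(k−1, N−k)`,
  upper-tail F): rye shares are abundant and near-normal.
* **oat, millet, buckwheat, hemp → Kruskal–Wallis** with tie correction
  `1 − Σ(t³−t)/(N³−N)` and a chi-square `k−1` reference: these shares are
  skewed and, for millet/hemp, mostly exact zeros, where rank tests with
  tie handling are the appropriate tool.

The assignment is fixed a priori; a Shapiro–Wilk report per crop is
emitted as advisory output only.  Degenerate inputs: zero within-group
variance with unequal means reports `F = inf, p = 0` with a flag;
all-identical data is an error, as is an all-tied Kruskal–Wallis pool.

## Synthetic-data generator

The generator defines the package's study conditions; its defaults are
frozen and not tuned per experiment.

* **Climate**: annual AR(1) noise around piecewise-constant period means,
  started at the stationary distribution.  Temperature: base 15 °C with a
  +0.8 °C Medieval Climate Anomaly segment (900–1300 AD), a −0.9 °C
  Little Ice Age segment (1300–1800 AD) and a +0.5 °C warm segment at
  200–400 AD; AR coefficient 0.7, innovation SD 0.35 °C.  Wetness (varve
  thickness, mm): base 1.0, −0.30 over 1300–1500 (dry early LIA), +0.45
  over 1500–1800 (wet late LIA); AR 0.7, SD 0.10.
* **Contexts**: 8 per 100-year bin (17 bins → 136 contexts, matching the
  ≈ 135-context study scale), 50 identified seeds per context, dating
  half-widths uniform on 10–150 years (so some contexts exceed the
  200-year exclusion, exercising that rule).  Composition model:
  `counts ~ Multinomial(50, softmax(a_c + b_T·T_z + b_P·P_z))` with the
  standardized proxies at the context's latent true year.  Couplings
  (per SD of proxy, on the linear predictor): millet `b_T = +1.2`,
  buckwheat `b_T = −1.2, b_P = +0.6`, hemp `b_P = +1.5, b_T = −0.6`,
  rye and oat 0.  No quantitative effect sizes exist for the real
  system; these values are calibrated once so that the qualitative sign
  pattern (thermophilic millet, cold/wet-adapted buckwheat and hemp) is
  recoverable with ≥ 80 % power at `n_perm = 2000` over 100 replicates —
  that recoverability is part of the generator's contract.  A
  ground-truth sidecar records the couplings so tests never
  reverse-engineer them.
* **Manors**: per century, shares `~ Dirichlet(α)` over the crops present
  in the record, with `α = (13.0, 8.5, 0.4, 1.8, 1.3)` (total 25) for all
  three centuries — mean shares ≈ 55 % rye, ≈ 35 % oat, ≈ 6 % buckwheat,
  ≈ 1 % millet/hemp, matching the historical pattern of rye dominance.
  Mention probabilities: rye 1.0 (anchors every inventory), oat 0.96,
  buckwheat 0.84, millet 1/3, hemp 0.15 — sparse minor-crop mentions.
  Amounts are shares times a log-normal total (median 25 "barrels").
  `SynthConfig.with_oat_shift(delta)` injects a century-specific mean
  shift for power studies, preserving total concentration.
* **Stations**: two regions × 15 stations over 1891–2017; regional
  signals share a common component with weight √0.82 so the regional
  means correlate near 0.82; station noise SD 45 mm; each station loses
  the 1914–18 and 1939–45 spells with probability 0.5.
* Reproducibility: every component draws from a child of
  `SeedSequence([seed, stream])`; identical (seed, config) give identical
  datasets.

**What the synthetic data does not emulate**: taphonomic preservation
bias (charred vs waterlogged recovery), spatially clustered sites,
radiocarbon-calibration multimodality (intervals are symmetric around
the true year), archival survival bias in inventories, and proxy dating
uncertainty.  Passing tests therefore demonstrate that the *pipeline*
recovers known structure under realistic sampling noise — not that the
real archives satisfy these models.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 1,000 random tied vectors
for the Spearman oracle; `n_perm = 10,000` against exact enumeration;
1,000 null replicates at `n_perm = 2,000` for calibration (rejection rate
at α = 0.05 expected in [0.037, 0.064]; slightly below 0.05 is expected
because tie-inclusive counting is conservative); 100 replicates for the
coupling-power and manor-stability studies; 10,000 random contexts for
the binning oracle.  All randomness descends from explicit integer
seeds; identical seeds give bit-identical results.

## Known limitations

* Midpoint dating ignores within-interval uncertainty; a probabilistic
  (uniform-over-interval) allocation is deliberately out of scope.
* Plain permutation ignores temporal autocorrelation (see above).
* The wide-interval exclusion threshold (200 y) is a judgement call;
  sensitivity to it should be part of any substantive claim.
* Compositional coupling means a strong effect on one crop induces
  opposite-signed shares in the others; uncoupled crops can therefore
  show modest spurious negative correlations in any single dataset.
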