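# Methods

## Model and procedure

The pipeline analyzes qPCR array-card screens of circulating microRNAs in
small rodent cohorts. Its quantities live on the Ct (cycle threshold)
scale: one PCR cycle is one doubling, lower Ct means more transcript.

**Normalization.** Each sample/card combination is normalized by its
global median: dCT = Ct − median Ct of the card's non-control assays in
that sample. Control and spike-in wells are excluded from the normalizer
by default (they carry technical, not biological, signal; an
`include_controls_in_normalizer` flag restores them). An even count of
values yields the mean of the central pair, so the per-(sample, card)
median of non-control dCT is 0 to 1e-9 by construction, and adding any
per-sample constant to the raw Ct leaves dCT unchanged. "Undetermined"
wells are a first-class MISSING state, not a capped value — the cascade's
early stages filter on missingness — though a `ct_cap` option can
substitute a fixed Ct on input.

**Differential expression.** ddCT = mean dCT(experimental) − mean
dCT(reference); log2 fold change = −ddCT (positive = up-regulated);
linear fold change = 2^(−ddCT). The test is a two-tailed unpaired t-test
on dCT values, Student (pooled variance) by default, matching the default
of the commercial statistics package such screens are typically analyzed
with; Welch is available. Assays with fewer than 2 valid values in either
group are flagged NOT_TESTABLE with a reason, never silently dropped.
A Kruskal–Wallis screen across naive/sham/experimental is provided for
three-group overviews.

**Filter cascade.** Six bins in fixed order: NOT_EXPRESSED, MISSINGNESS,
T_TEST, FOLD_CHANGE, CONFOUND_CORR, MIN_CT, else RETAINED. The order is
the narrative order of the screening protocol; it matters (an assay
failing both the t-test and the Ct ceiling is attributed to T_TEST) and is
fixed and tested. Statistics are recorded per assay only for the stages it
reached. Significance boundaries are strict: p < alpha passes, p = alpha
fails. The fold-change band is evaluated on the log2 scale — on a linear
scale a signed fold change cannot lie strictly inside (−1, 1), so the
"between −1 and 1" no-effect band is only meaningful for log2 values —
and the band is open (±1.0 exactly is retained). The seizure-burden
exclusion uses the signed correlation (`positive_only`) by default:
candidates whose dCT *rises* with seizure count or duration are taken to
reflect intrinsic epilepsy severity; an `absolute` mode is available since
the protocol wording is ambiguous about sign. It runs on normalized dCT
over experimental animals only (burden exists only for them), skipping
assays with fewer than 3 complete pairs. The weak-expression stage's
default reading of "minimum Ct above 30" is the minimum over samples
(`min_over_samples`); `all_samples` instead requires every sample at or
below the ceiling, which is also the Ct condition used for the separate
headline "screening hits" count (p < alpha plus the Ct condition,
reported outside the cascade).

**Statistical primitives.** Spearman uses average ranks for ties and, for
n ≤ 8, a two-sided exact permutation p (fraction of all n! orderings with
|r| at least the observed, tolerance 1e-12, ≈40k orderings at n = 8);
above that the t-approximation t = r·sqrt((n−2)/(1−r²)). Group sizes here
are 5–16, so the small-n exactness is the default that matters.
Degenerate conventions: zero variance in both t-test groups gives t = 0,
p = 1 at equal means and p = 0 (flagged) otherwise; zero rank variance
gives an undefined, flagged correlation. Benjamini–Hochberg is the
step-up rule with missing p-values propagating. t and Kruskal–Wallis
p-values come from scipy; BH, Spearman and the degenerate contracts are
implemented here and cross-checked in the tests against brute-force
enumeration, rank-then-Pearson, statsmodels and scipy oracles.

**Association analysis.** Correlations use pairwise-complete deletion
(n is tiny; listwise deletion would discard most animals). The
significance rule is r < −0.5 or r > 0.5 combined with p < 0.05 (q < 0.05
when FDR is requested); the BH family for the cross-model screen is all
phenotype parameters of one candidate. PCA standardizes variables by
default (behavioral units are incommensurate: seconds, grams, percent,
pg/ml), mean-imputes missing values (complete-case optional), drops
zero-variance variables with a warning, and fixes each component's sign
so its largest-magnitude loading is positive, making scores and loadings
reproducible across runs.

## Synthetic data generator

The generator emulates the screening design: ~750 assays plus 6 controls
split over two cards; naive/sham/experimental groups of 5/5/6; validation
cohorts of sham/experimental 12/12, 12/11, 12/13 and 6/4 across four
epilepsy models. Per assay, Ct = baseline + per-(sample, card) batch shift
(SD 1 cycle, removed exactly by the median normalizer) + group effect +
Gaussian noise; values at or beyond the limit of detection (40 cycles) are
censored to MISSING, plus 5% completely-at-random dropout. Baseline means
are uniform on 18–39 cycles with per-assay SD 0.3–1.0, so a realistic
fraction of assays sits near the LOD and exercises the missingness and
weak-expression stages.

Planted structure, recorded exactly as used in a `SyntheticTruth` object:

* *Differential* assays (default 20, half up/half down) shift the
  experimental group by ∓2 cycles with within-group SD 0.5. Up-regulation
  subtracts cycles — stated explicitly to pin the sign convention.
* *Confounded* assays (default 10) additionally carry the same-magnitude
  group shift — the cascade can only remove an assay at the confounder
  stage if it first survives the t-test and fold-change stages, as in the
  real protocol where the confounder-removed assays were all
  t-test-significant — and their experimental-group noise is coupled to
  the simulated seizure burden by a Gaussian copula at target Spearman
  0.9, using the analytic adjustment r_pearson = 2·sin(π·r_spearman/6).
* *Not-expressed* assays (default 20%) emit all-MISSING wells: they model
  reactions with no detectable template, which never cross threshold.
* *Phenotypes*: each linked parameter is drawn by Gaussian copula against
  its assay's dCT at a target rank correlation and mapped to its marginal
  (normal; percent in [0, 100] for saccharin preference; lognormal for
  BDNF). Integer link indices resolve to the best-expressed differential
  plants, which are the candidates the screen retains. Seizure burden is
  a Poisson count (mean 15) from a latent severity with lognormal
  per-seizure durations.

All randomness flows from one master seed through named child streams, so
identical configurations are bit-identical.

**What the generator does not emulate.** It is parametric: no attempt is
made to fit the empirical Ct distribution of any real deposit. Real
array-card data have hemolysis artifacts, plate-position effects,
non-Gaussian heavy-tailed wells and correlated microRNA families; none
are modeled. Passing the recovery tests therefore shows the *pipeline*
implements its rules correctly and has the stated power under idealized
noise — not that the biological screen itself has that power.

## Numerical and design notes

* The median normalizer is itself estimated from ~300 assays per card, so
  it carries per-sample noise that all dCT values on the card share. Two
  measured consequences: (i) the realized dCT–burden rank correlation of
  confounded plants is attenuated below the planted 0.9 (more so on
  sparsely occupied cards), and (ii) per-assay t-tests on one card are
  weakly positively correlated. Calibration checks of the aggregate
  t-test pass fraction therefore run on moderately sized cards (120
  assays), where the binomial band is still valid.
* With planted effects on a scaled-down card the median itself shifts
  toward the plants, biasing realized ddCT; recovery checks run at the
  full 750-assay design where this bias is ~0.1 cycle.
* The confounder exclusion rule (r > 0.5 and two-sided p < 0.05) has
  limited sensitivity at six experimental animals: for a planted rank
  correlation of 0.9 its per-assay removal probability is ~0.5 with the
  exact p-value (~0.65 with the t-approximation), and lower still once
  normalizer attenuation and LOD censoring act. This is a power limit of
  the rule at this sample size, visible in the recovery battery, and is
  worth remembering when interpreting "not burden-correlated" survivors
  of any real screen this size.
* Candidate sets are ordered by ascending t-test p; ties break
  lexicographically. CSV outputs round-trip at full float precision.
* Problem sizes in the test battery (1,000 random 8–28-assay datasets for
  bookkeeping; 200 replicates at full design for recovery; 200 × 120
  assays for calibration) keep the whole suite under a minute apart from
  the recovery battery (~20 s).

## Known limitations

* The cascade's 439-comparison differential stage is uncorrected by
  design (the protocol's choice); the pipeline reports it as-is and
  provides BH-FDR only where the protocol applied it.
* Exact permutation p-values are limited to n ≤ 8; validation-scale
  correlations (n ≈ 80) use the t-approximation.
* No vendor instrument-export parsing; inputs are plain CSV.
* No heatmap/cluster rendering; outputs are tables meant for downstream
  plotting.
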