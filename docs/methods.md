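# Methods

This note documents the models, estimators and design choices implemented in
`tapjid`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Joint interval distributions

For a day with events at times $t_1 < t_2 < \dots < t_n$, the inter-touch
intervals are $x_i = t_{i+1} - t_i$ (seconds). The day's behaviour is
summarised by the overlapping next-interval pairs
$(x_1, x_2), (x_2, x_3), \dots$ in $\log_{10}$ space.

**Estimator.** The JID is a kernel density estimate evaluated on a fixed
grid: the mean over pairs of isotropic bivariate Gaussians with standard
deviation equal to the bandwidth (default 0.1 log₁₀ units, no cross-term),
evaluated at the centers of a uniform $50 \times 50$ grid over
$[\log_{10} 0.03,\, 2.0]^2$ (≈ 30 ms to 100 s per axis; bin width ≈ 0.0705).
Choices worth stating explicitly:

- **Evaluation at bin centers**, not integration over bins. This keeps a
  closed-form oracle (the discretised Gaussian) and is what "discretising a
  continuous density" means operationally. The tests compare the
  implementation against both the analytic single-pair form and a naive
  per-pair per-bin double loop.
- **Normalisation.** Default `probability_mass`: entries divided by their
  sum, so each daily JID sums to 1. This removes the daily-volume confound
  before the scale-sensitive bin-wise *t*-tests. A `density` mode
  (integrates to 1 over log₁₀-area) is provided for display purposes.
- **Out-of-range pairs** are not clipped: their kernels are evaluated where
  they fall, and mass outside the grid is simply lost before
  renormalisation. A day whose pairs all lie > 5 SD outside the grid
  triggers a degenerate-density warning.
- **No boundary correction** at the grid edges.
- Orientation: rows (axis 0) index $\mathrm{ITI}_k$, columns (axis 1)
  $\mathrm{ITI}_{k+1}$.

Duplicate (same-millisecond) timestamps are collapsed at ingest — a zero ITI
has no $\log_{10}$ — and the collapse is logged, never silent.

## 2. Cluster-based permutation test

Given $n_a$ and $n_b$ daily JIDs in two groups:

1. per bin, a two-sample *t*-statistic (pooled-variance by default,
   $\mathrm{df} = n_a + n_b - 2$; Welch selectable). Positive *t* means
   group A exceeds group B. Bins with zero variance in both groups — the
   perpetually empty JID corners — are set to $t = 0$, flagged, and never
   enter clusters;
2. bins exceeding the two-sided critical value at the cluster-forming level
   (default $p < 0.01$) are partitioned into connected components,
   separately for positive and negative signs, under 4-connectivity
   (8-connectivity by flag);
3. the null distribution of the **maximal cluster size over both signs** is
   built by re-running steps 1–2 under $B$ random day-relabellings
   preserving group sizes (default $B = 1000$); permutations are not
   de-duplicated. An exhaustive mode enumerates all
   $\binom{n_a+n_b}{n_a}$ splits for small groups;
4. a cluster is significant when its size strictly exceeds the null's 95th
   percentile. Monte-Carlo p-values use the $+1$ correction
   $p = (1 + \#\{\text{null} \ge s\})/(B+1)$ and are therefore never 0;
   exhaustive p-values are exact counts. Taking the maximum over both signs
   controls the two-sided family.

The pipeline reports, alongside the 95th percentile, the null's median and
2.5/97.5 percentiles, so the full reference distribution is inspectable.

A structural property worth knowing when constructing extreme examples: the
max-size statistic saturates at the true effect's footprint, and a
day-level effect shared by all bins of a blob is reproduced whole by
label-aligned permutations. The floor $p$-value is therefore reached exactly
only when relabellings break the cluster up, which requires day-to-day
variability of honest scale — the tests document this with an exact
enumeration example.

## 3. Study design and contrasts

Days are grouped into pre-tapering / tapering / post-tapering periods; the
two transition tests are pre-vs-taper and taper-vs-post. The convulsion day
remains inside the tapering group by default (the monitored tapering period
contained the convulsive event); a switch excludes it. The period-average
JIDs and their signed difference maps are returned with the tests; averaged
probability-mass JIDs still sum to 1 and difference maps to 0.

The **seizure-day contrast** is purely descriptive: the seizure day's JID
minus the unweighted mean of the preceding `baseline_days` (default 3) days'
JIDs, summarised by net signed mass per quadrant. No test is attached — one
day against a baseline admits no day-level permutation. Quadrants are split
at the grid midpoint of each axis; this is a reporting convention only.

Low-count days (fewer than `min_day_events`, default 30) are flagged at
segmentation and excluded from group statistics by default, but retained in
the bookkeeping: usable + excluded = segmented days, exactly.

## 4. Day segmentation

"Study days" run rise-to-rise, not midnight-to-midnight, so the overnight
gap never contributes an ITI. Rise times come from a longest-nightly-gap
heuristic: within each noon-to-noon window, the longest event gap of at
least `min_sleep_gap` hours (default 3) whose end falls in a clock-time
search window (default 20:00–12:00, wrapping midnight) is taken as sleep;
its end is the rise time. Windows without a qualifying gap merge into the
following day with a logged warning. Day boundaries are half-open
$[\mathrm{rise}_i, \mathrm{rise}_{i+1})$; events before the first rise form
a flagged leading partial day. This is a deliberately simple stand-in for
dedicated sleep/rise-detection algorithms: it reproduces the only property
the analysis needs (a stable partition with no cross-boundary ITIs) and is
validated against the synthetic generator's ground-truth wake times (tests
require < 30 min error on ≥ 95 % of days).

## 5. Synthetic study generator

The generator produces labelled surrogate data matching the design of the
motivating study; all of its within-day structure is a package invention,
because the emulated study reports only daily totals.

- **Design**: 82 / 12 / 91 pre / taper / post days; the convulsion-day
  effect sits on the fourth tapering day by default.
- **Daily counts**: lognormal, median 3311, log-SD 0.469 fitted from the
  reported interquartile ratio (a lognormal cannot match both asymmetric
  quartiles exactly; the implied IQR is ≈ 2414–4543 against the reported
  2531–4766). Counts are rounded and floored at 2. A `fixed` law supports
  controlled tests.
- **ITI mixture** (log₁₀ s): baseline components
  (0.50, −0.65, 0.25), (0.28, 0.25, 0.30), (0.18, 1.20, 0.30),
  (0.04, 2.35, 0.25) — fast taps, within-session pauses, slow pauses, and
  sparse between-session gaps beyond the 100 s grid ceiling. Weights chosen
  so a median day's activity fits a 16 h waking window.
- **Effects**: tapering moves 0.15 of mixture weight from the slow to the
  fast component; the convulsion day moves 0.30 from fast to slow. These
  magnitudes are free parameters of the generator, chosen once so the
  configured effects are unambiguous in direction; they are not estimates
  of any real effect size.
- **Dependence**: consecutive log-ITIs are coupled by a Gaussian copula: a
  latent AR(1) series with lag-1 correlation `pair_correlation`
  (default 0.3) is mapped through the probability integral transform and
  the numerically inverted mixture CDF. The marginal is preserved exactly
  (up to a 4096-point grid interpolation); the induced *rank* correlation
  between consecutive intervals is ≈ the latent correlation. This gives the
  JIDs non-trivial joint structure without committing to a mechanistic
  model of tapping bursts.
- **Clock structure**: events occupy a waking window between a jittered
  rise (default 07:00 ± 30 min SD) and phone-down time (23:00 ± 30 min).
  When a day's drawn ITIs overrun the window, only the between-session gaps
  (> 100 s, invisible to the JID grid) are compressed to fit, preserving
  the on-grid ITI distribution exactly; a uniform rescale exists as a
  logged last resort but is essentially unreachable at default parameters.
  Timestamps are integer epoch milliseconds on a synthetic calendar
  (origin 2021-05-01 UTC); rounding collisions are bumped to keep streams
  strictly increasing.
- **Reproducibility**: each day has its own substream seeded by
  (study seed, day index), so identical configs give bit-identical streams
  and days are independent of generation order.

**What passing tests do and do not show.** The generator emulates daily
volumes, circadian gating, burst/gap interval structure, first-order
next-interval dependence, and clean directional effects. It does not model
app switching, screen sessions, typing cadence, weekday/weekend structure,
medication pharmacokinetics, or any within-period drift — so green tests
demonstrate that the *pipeline* recovers effects of the configured shape at
realistic data volumes, not that real tapering or seizures produce effects
of that size.

## 6. Numerical and testing choices

- KDE and t-map computations are vectorised (separable kernels; sufficient
  statistics per permutation); a full 185-day analysis with $B = 1000$ runs
  in seconds on one core.
- Statistical validation in the test suite uses replicated simulation at
  the design's own scale: type-I error of the full procedure is estimated
  from 500 null replicates (20 vs 20 baseline days, $B = 200$) and required
  to lie in [0.03, 0.07]; power to find a significant fast–fast cluster
  under the default tapering effect, and its sign reversal at restart, is
  estimated from 100 replicates of the full 82/12/91 design with $B = 200$
  in the replicate loop ($B = 1000$ remains the analysis default); the
  convulsion-day slow–slow shift is checked on 100 replicates of the
  day-vs-3-day contrast. Replicate counts were sized to keep the whole
  suite within a few minutes while leaving Monte-Carlo error well inside
  the asserted bands.
- The 95th percentile uses linear interpolation (`numpy.percentile`
  default); with integer cluster sizes and the strict `>` rule the realised
  test level sits slightly below 0.05, which the calibration band reflects.
- Degenerate inputs have defined behaviour throughout: empty studies are
  legal, empty pair sets raise an empty-input error for the caller to
  handle, all-zero bins are flagged rather than producing NaNs, and
  grid-incompatible JIDs raise rather than broadcast.

## 7. Known limitations

- The rise-time heuristic has no notion of naps, shift work or travel
  across time zones; it assumes one main sleep period per noon-to-noon
  window.
- Cluster inference uses cluster *size* only (no cluster-mass or TFCE
  statistic) and assumes exchangeability of days within the compared
  groups; day-to-day autocorrelation of behaviour would make the test
  anticonservative.
- The JID bandwidth is fixed, not adaptive, and the grid ceiling discards
  intervals beyond 100 s by construction.
- Single-subject scope: nothing here models between-subject variability.
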