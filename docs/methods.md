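# Methods

This note documents the models, parameter choices and numerical
conventions behind `comprank`, and what the synthetic cohort does and
does not establish about real recordings.

## Behavioral scoring

**Tube ranks.** Each day of a round-robin tube test is scored by bout
wins; rank is descending win count. A day is *linear* iff the win
vector is a permutation of (N−1, …, 0), i.e. a transitive tournament.
Tied win counts occur only on non-linear days, which the downstream
analyses exclude; ties are still resolved deterministically — a
two-way tie by the head-to-head bout, larger tie groups (cycles) by
lexicographic mouse id. The *stable hierarchy* day is the earliest day
from which linear ranks are identical on `window` (default 3)
consecutive calendar days.

**Tube-time inflection.** The assays show a drop of mean bout duration
once the hierarchy settles, but no operational definition of the
inflection is standard. We use the two-segment piecewise-constant
least-squares change point (exhaustive scan over split days) and
require the after-segment mean to be strictly lower; otherwise no
inflection is reported. On noisy two-level series (means 25 vs 8 s,
SD 2, 20 days) the split is recovered within ±1 day in > 90 % of
replicates.

**Competition scoring.** Stage winners (exiting the starting area,
reaching the reward zone) are decided by the earlier of the two mice's
timestamps; exact ties award 0.5 to each mouse so per-pair proportions
always sum to 1. The competitive order C1..CN sorts mice by overall
pellet proportion, breaking ties by ascending mean gate-open→RZ
latency. Latency is anchored at gate opening, not SA exit, because the
training criterion ("mean latency below 5 s on two consecutive days")
is anchored to release.

## Unit typing

Units are typed in the 3-D space (trough-to-peak latency, trough
half-width at half depth, absolute-area AUC), standardized per
dimension. For populations of ≤ 15 units the classifier finds the
globally optimal minimum-SSE bipartition by enumeration (2^(n−1)−1
proper bipartitions via bitmasks); larger populations use k-means
(k = 2, 50 restarts, fixed seed). The exact small-n path removes the
k-means local-optimum failure mode where enumeration is affordable; at
the default feature separation (class means ~6 within-class SD apart
on trough-to-peak latency) both paths agree. The cluster with the
smaller mean trough-to-peak latency is labeled narrow-spiking
(putative inhibitory).

**Burst index.** Autocorrelogram over lags (0, 300] ms with 1-ms bins,
zero lag excluded; the index is the mean bin count at 3–5 ms divided
by the mean at 200–300 ms. A homogeneous Poisson train has a flat
autocorrelogram and an index of ~1; doublet firing (3–5 ms
inter-spike intervals) inflates the numerator band. An empty baseline
band yields NaN (undefined), not an error.

**Bimodality validation.** Unit typing is cross-checked against the
pooled burst-index distribution with a dip-type statistic: the minimum,
over a 25-point quantile grid of candidate modes, of the maximum ECDF
deviation from a convex-left / concave-right fit (greatest convex
minorant and least concave majorant around the mode). The statistic is
location/scale invariant; its p-value is calibrated by Monte-Carlo
against uniform samples of the same size (200 draws by default). The
check passes when the pooled distribution rejects unimodality at 0.05
and the broad-spiking cluster is the more bursty one.

## Task categorization

Per-trial firing rates are spike counts in the half-open window
[RZ − 2 s, RZ + 2 s) divided by its length. The anchor and extent are
configuration options; ±2 s around reward-zone entry is a declared
default — the assays themselves do not pin the window. Each unit gets
two two-sided Mann–Whitney U contrasts (Welch t optional): win vs loss
trials and dominant- vs subordinate-opponent trials, at α = 0.05, with
no correction across units (each unit is treated as its own
experiment, matching per-unit category counts). The two significance
flags define the four mutually exclusive categories. Units with fewer
than 5 trials in any condition are unclassifiable and excluded from
numerators and denominators alike. Population percentages are rounded
half-away-from-zero to one decimal.

A caveat the synthetic cohort makes visible: when contest outcomes
follow graded competitiveness, win/loss is correlated with opponent
rank (a mid-ranked subject wins mostly against subordinates), so
competition modulation leaks into the rank contrast and inflates the
"both" category. The emulation preset therefore uses equal latent
competitiveness for the recorded groups, making the win outcome a fair
coin independent of opponent rank; the graded default remains for
behavioral scoring, where the gradient is the signal.

## Longitudinal Δz and cross-correlation

The day-d Δz-score of a population is (mean_d − mean_0)/SD_0, with the
baseline mean and SD taken from the per-trial rate distribution of the
pre-intervention day (pooled across the population's units; per-unit
z-scoring then averaging is available as an option), referenced so day
0 is 0. A zero baseline SD is an error.

Cross-correlation between day series x and y computes Pearson r on the
overlapping segment for each integer lag in [−max_lag, max_lag];
positive lag means y lags x. The default max lag is 15 days for a
21-day window, and every lag must retain at least 5 overlapping points.
Peak-lag ties resolve toward the smallest |lag|, negative first.
Significance per lag comes from a circular-shift null: y is rotated by
non-zero offsets, preserving each series' autocorrelation; when the
full shift group (n − 1 offsets) fits within the permutation budget it
is enumerated, making the randomization test exact — with 21-day
series, sampling 200 offsets with replacement from the 20 distinct
shifts instead produced per-lag type-I rates of 0.07–0.10 at a nominal
0.05. P-values are two-sided with the add-one correction and
uncorrected across lags (the band is a per-lag display).

## Synthetic cohort

The generator encodes the study conditions: groups of 4 mice,
round-robin food competition with 10 trials per pair (5 starts from
each area), a 379-unit population split 288/91 into broad/narrow
spiking with task-category quotas (86/22/14/166 excitatory,
12/10/6/63 inhibitory; largest-remainder quotas by default, multinomial
sampling optional), 21-day interventions, and a 10-day rank-change lag.

- **Contests.** Win probability is logistic in the latent
  competitiveness difference, p = 1/(1 + exp(−(c_i − c_j)/τ)), τ = 0.7;
  the scores default to an evenly spaced gradient per group. The
  eventual pellet winner tends to exit and reach the reward zone first
  (latency handicaps for the loser), reproducing the stage-consistent
  competitive order.
- **Spike trains.** Inhomogeneous Poisson at 5 Hz, multiplied by
  `modulation_gain` (default 2.0) in the analysis window on win trials
  (competition-related), dominant-opponent trials (rank-related), or
  multiplicatively stacked for both-related units — stacking keeps the
  two contrasts separable, whereas modulating on the union of
  conditions contaminates each contrast with the other. Broad-spiking
  units receive 3–5 ms doublets with probability 0.35 per spike, giving
  the bimodal burst-index distribution used for validation.
- **Waveforms.** A biphasic template (negative Gaussian trough, smaller
  positive peak) is parameterized directly by the three target
  features and rescaled so its realized absolute area equals the
  requested AUC; raw tetrode geometry is not modeled.
- **Tube/warm spot.** Upset probability decays linearly to zero by
  `tube_time_stable_day` (default 5), bout durations drop from ~25 s to
  ~8 s at stabilization, and warm-spot occupancy is softmax in latent
  dominance.
- **Longitudinal series.** Effects switch on the day after the
  intervention and ramp linearly over 5 days; the rank-related series
  follows the same trajectory delayed by `rank_lag_days` (default 10),
  and the tube-rank series changes after the competition change
  (hysteresis). The winning-proportion series is the cohort mean (6
  groups × 3 pairings × 10 trials = 180 trials/day); the per-day rate
  tables pool 2880 samples, the order of ~96 competition-related units
  × 30 trials across a recorded cohort. Longer ramps make the series
  nearly linear and the peak lag unidentifiable; the 5-day ramp with an
  immediate onset matches a progressive decline that is already visible
  on day 1.
- **Determinism.** All stages draw from sub-streams derived by stable
  hashing of (seed, stream name); identical seed and configuration give
  byte-identical tables.

What passing tests show — and do not. The cohort exercises the full
analysis chain against known ground truth: quota recovery, lag
recovery, test levels under null configurations. It does not emulate
electrode drift, sorting contamination, correlated population
variability, non-Poisson firing beyond doublets, or behavioral
non-stationarity within a session; agreement on synthetic data
therefore validates the code paths and their statistical calibration,
not the biological claims.

## Known limitations

- The task-relatedness test treats trials as exchangeable within
  condition; slow within-session drift would inflate both contrasts.
- The dip-type statistic restricts candidate modes to a quantile grid;
  this is part of the statistic's definition and is applied identically
  to the Monte-Carlo null, so calibration is unaffected, but it is not
  numerically identical to the classical dip.
- With graded competitiveness, the win/rank confound (above) is a
  property of the design, not the estimator; category counts from such
  sessions mix the two modulations.
- The tube-rank series is integer-valued and nearly constant under
  small effects; its cross-correlations are reported but fragile at
  desk scale.
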