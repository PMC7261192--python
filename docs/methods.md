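# Methods

This note documents the models implemented in `crossplice`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical edge-case decisions.

## Splicing quantification

PSI is computed per (event, sample) as `100 · long / (long + short)`; cells
with zero total reads are **undefined** (NaN), excluded from group means and
tests, and never imputed — the alternative (treating them as 0 or 50) would
bias ΔPSI for shallow events.  Events are retained when their mean total
reads across **all** samples is strictly greater than `min_mean_reads`
(default 10); the comparison is strict, so a mean of exactly 10 is dropped,
and the filter is monotone in its threshold.

ΔPSI is the difference of group means on defined replicates; the test is a
two-sided **equal-variance Student's t-test** by default (Welch behind
`equal_var=False` / `--welch`).  An event needs at least 2 defined replicates
per group to be testable; others are reported as `untestable`, distinct from
"tested, not significant".  Significance requires both |ΔPSI| strictly
greater than the threshold (default 10 percentage points) and p below alpha
(default 0.05).  **No multiple-testing correction is applied by default**:
the calling rule reproduces the common raw-threshold practice for targeted
splicing panels, and because the |ΔPSI| filter can only remove calls, the
realized false-call rate on null data sits far below the nominal alpha
(measured by the acceptance script, typically ≲0.5%).  Users wanting FDR
control should apply it to the returned p-values.

Degenerate t-tests (zero variance in both groups) are resolved by the limit
they approach: identical group means give p = 1, different means give p = 0.

Orthogonal validation (`validate_concordance`) accepts an RT-PCR replicate
set per condition and declares a sequencing call validated only when the
RT-PCR ΔPSI agrees in sign, exceeds 10 points in magnitude, and is itself
significant at 0.05; fewer than 2 replicates per condition is `untestable`.

## Overlap, regression, classification

The **universe** for all two-knockdown statistics is the intersection of
events testable in both comparisons (the natural choice when both comparisons
come from the same filtered table; `OverlapStats` always reports
`n_universe` so sensitivity to this definition can be checked).

The two-tailed hypergeometric p is **twice the smaller tail, capped at 1**
(default).  The tail construction matters only in asymmetric cases; the
alternative "sum of all outcomes no more likely than observed" (`minlike`,
the Fisher-exact convention) is provided, and both agree with exhaustive
enumeration over all small universes to machine precision (acceptance
criterion).  The doubled-tail p is super-uniform under the null (tested by
simulation).

Shared-event similarity is ordinary least squares of ΔPSI_B (y) on ΔPSI_A
(x), at least 3 points, reporting slope, intercept and R².  The axis
orientation is a convention; calling the function with arguments swapped
gives the other orientation.

Classification uses a `trend_threshold` (default **5 percentage points**) to
separate truly specific events from trending ones.  The value is a sensitivity
parameter, not doctrine: a same-direction sub-significant shift above the
threshold in the other knockdown is a "trend", at or below it (or any
opposite-sign shift) is "specific".  Events significant in both knockdowns
with opposite directions form a distinct `discordant` class that is surfaced
rather than folded into `shared`, because such predictions are the ones most
likely to fail orthogonal validation.  The classes partition the universe by
construction.

### Rescue experiments

`rescue_fraction = (PSI_rescue − PSI_kd) / (PSI_wt − PSI_kd)` from group
means, defined only when the knockdown moved PSI by more than 10 points
(otherwise `untestable`).  Call bands default to **no rescue < 0.25 ≤ partial
≤ 0.75 < full**; gradient experiments of this kind are semi-quantitative, so
the bands are configuration, not doctrine.  Model inference needs context the
PSI values do not carry — which factor was depleted, which was re-expressed,
and whether the event responds to both knockdowns — supplied as keyword
arguments: failure of the partner to rescue indicates the partner is either
already active on that event (antagonistic) or already saturating
(single-factor saturation), while partial rescue by either factor on a
both-sensitive event indicates cooperative regulation.  Without context the
call is still made and the model is `None`.  The rescue fraction is invariant
to exchanging the long/short isoform roles (PSI → 100 − PSI).

## Expression dynamics

Decay is modeled as a **single exponential**: the target is normalized to the
reference gene, rescaled to 1 at t = 0 (per condition, so conditions with
different starting levels are comparable on decay rate), and ln(abundance) is
fitted against time by OLS; k = −slope, t½ = ln 2 / k.  Normalization happens
before the log transform.  A non-positive fitted k means no measurable decay
and yields `half_life = NaN` with `defined = False` rather than an error —
a flat series is a legitimate biological result.  Below-detection
measurements are encoded as missing (NaN), never zero, excluded from the fit
and counted in `n_excluded`.  At least 3 usable timepoints are required
(the two-point closed form is reachable in testing via `min_points=2`).

Induction comparison normalizes each condition's time course to its own
t = 0, reports per-timepoint fold induction and the knockdown/wildtype ratio,
and flags "induction lost" when the knockdown's maximal induction falls below
`loss_threshold` (default 0.5) of the wildtype's maximum.

## Polysome profiling

Fractions are ordered light → heavy.  Spike-in normalization divides target
by spike-in per fraction and renormalizes to a distribution; because the two
channels share every fraction-specific recovery factor, the output is exactly
invariant to per-fraction rescaling.  The **polysome boundary** — the first
fraction counted as polysomal — is an explicit parameter defaulting to
⌈F/2⌉ + 1 and is recorded in every output, since gradient fractionation
schemes differ.  Classification uses the single statistic
`chx_shift = proportion(+CHX) − proportion(−CHX)` with a default threshold of
**0.15**: mRNAs above it are `efficient_elongation` (ribosomes run off
without CHX), at or below it `impaired_elongation` (CHX-independent
retention).  A single shift statistic rather than per-fraction testing
matches how such profiles are read in practice while staying testable.
Control transcripts are just another profile; nothing is hard-coded about
which mRNA is the control.

## Synthetic-data generator

The generator emulates a targeted splicing screen of ~5000 events in two RBP
knockdowns vs a common control, 3 replicates each, with a shared co-regulated
subset, factor-specific subsets, and sub-threshold "trending" subsets.

* **Count model**: negative-binomial total reads per (event, sample)
  (mean 200, dispersion 10 — overdispersed targeted sequencing) with a
  binomial long/short split at the replicate-level true PSI.  Replicate
  jitter is normal on the PSI scale (truncated to [0, 100]) so effect sizes
  are stated directly in ΔPSI percentage points.
* **Default class fractions** put the expected truth at ≈71 shared, ≈45
  A-specific, ≈37 B-specific and ≈300 trending events out of 5000 — a
  realistic regime for a pair of RBPs with heavily overlapping targets.
  Shared events couple the knockdowns with ΔPSI_B = 0.83 · ΔPSI_A plus
  event-level scatter proportional to the replicate noise; true effect
  magnitudes are uniform on 12–40 points, trends on 3–9 points.
* **psi_noise_sd default 3 points**: replicate-to-replicate PSI variability
  for targeted assays is not well tabulated; 3 points gives the stated
  calling rule (|ΔPSI| > 10, p < 0.05, n = 3) high power at effects ≥12
  points while keeping null calls rare, which matches how such screens
  behave.  The power and type-I tests in the acceptance suite measure both.
* A **single seed** drives one numpy Generator for everything; equal seeds
  give bit-identical tables, and ground truth is always emitted next to the
  data so tests never reverse-engineer it.

What it does **not** emulate: read-level data (counts only), probe-specific
biases, correlated replicate effects (batch structure), partial knockdown
gradients, or binding data.  Consequently, passing tests demonstrate that the
statistics do what they claim under a clean generative model — they do not
certify performance on real data with batch effects or probe artifacts.

One visible consequence of the trending class straddling the call threshold:
in a study-scale run, some trending events (true sub-threshold shift 3–9
points) are called significant in the second knockdown or classified as
specific, so realized classified counts deviate from the ground-truth class
counts.  This is a property of threshold-based calling itself, faithfully
reproduced, not a defect of the generator.

Decay simulation is exponential with mean-one multiplicative lognormal noise
(parameterized by a coefficient of variation) and a constant reference track.
Polysome simulation draws a heavy-fraction weight per class (+CHX efficient
0.75, −CHX efficient 0.15, impaired 0.70 regardless of CHX, each with small
jitter), places the light component strictly below the boundary and the heavy
component at/above it, and multiplies both channels by lognormal per-fraction
recovery factors that spike-in normalization cancels exactly.

## Problem sizes in the test and acceptance runs

The suite uses 2000-event tables for type-I and slope recovery, 1000 events
for power, 200 seeds per half-life grid point and per polysome class, and the
default 5000-event screen in the acceptance script; these sizes give
Monte-Carlo error comfortably below the asserted tolerances while the whole
suite runs in seconds.
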