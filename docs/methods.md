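# Methods

This note documents the models, parameter choices and numerical decisions
behind `fetalprsa`, and what the synthetic cohort does and does not
establish about real recordings.

## PRSA and the capacity statistic

Anchor selection compares the mean of the `T` intervals *starting at* the
candidate beat (inclusive) with the mean of the `T` preceding intervals;
deceleration anchors require a strict increase, acceleration anchors a
strict decrease, and ties are never anchors. For `T = 1` this is the
classical beat-to-beat criterion `x_i > x_{i-1}`. The capacity is the Haar
wavelet coefficient of the averaged series at the anchor,
`[Σ_{k=0..s-1} X(k) − Σ_{k=−s..−1} X(k)]/(2s)`; the implementation is
validated against a materialize-all-windows oracle to 1e−12 ms and against
the algebraic `s = 2` identity. Deceleration capacity is positive and
acceleration capacity negative by construction; all reported values are
absolute.

Defaults: `L = 50` beats (covers every scale since `s = T ≤ 50`),
`T = 1..50`, `s = T`. An entry is *unreliable* unless strictly more than
150 anchors contributed; unreliable entries are flagged, never dropped, so
report tables stay rectangular.

Candidate anchors must have both `T`-averages and the full `±L` window
inside one contiguous segment. For concatenated stable series this is the
conservative default; setting `allow_cross_boundary=True` lets windows
span junctions, which is how large `T` (above ~25) remains computable on
stable series whose segments are at most about a minute long — at the
cost of mixing beats from consecutive recovery periods, which is why such
entries are best read together with their reliability flag.

Eligibility (the 20 % rule, reconstructed beats, first beat of a segment)
removes beats only from the anchor lists; their values still enter moving
averages and PRSA windows. The 20 % rule is one-sided (only increases
relative to the immediately preceding beat disqualify) and, next to a
reconstructed gap, compares against the immediately preceding beat of the
reconstructed series — the natural reading once reconstruction has
restored a plausible local rhythm.

## Artifact reconstruction

Maximal runs of intervals above 1500 ms are merged into one gap (a single
misdetection event often produces several spurious intervals). The gap of
length `G` is replaced by `n = round(G/m)` beats of `G/n` ms each
(minimum one), `m` being the median of up to 10 preceding plus 10
following valid intervals, fewer at record edges. Rounding is
half-away-from-zero so the beat count is deterministic. Total recording
time is conserved to under 1 ms and the operation is idempotent.
Beat-quality QC measures the fraction of a window covered by original
(non-reconstructed) beats and requires strictly more than 0.9.

## Occlusion-response model

Onset `rr(t) = A + B(1 − e^{−t/τ_stim})`, release
`rr(t) = C + D e^{−t/τ_rec}`, fitted independently by unbounded
Levenberg–Marquardt on raw beats pooled across all occlusions
(respectively recoveries) of a phase — by default SEVERE, where the
response is largest. Initialization is deterministic: offsets from the
medians of the first/last 10 % of the branch, amplitude from their
difference, `τ` a third of the branch span, with restarts at 0.3x and 3x
if the optimizer fails or returns a non-positive `τ`. Fits report residual
RMS and are flagged when `τ` lands at an implausible bound (beyond ten
branch spans). With a 60 s occlusion, `τ_stim` values approaching the
occlusion length are weakly identified and noisy fits overestimate them;
the recovery branch, with `τ_rec` of a few seconds, is well identified.

Stable (deceleration-free) intervals run from 30 s after each occlusion's
end — more than three times the longest cohort recovery constant, so the
rate is substantially back at baseline — to the start of the next
occlusion (or the phase end). Phases without occlusions are one stable
interval. Concatenation keeps beats whose whole RR interval lies inside an
interval and records every junction as a segment boundary.

Each phase is analysed over its last 30 minutes (clipped, with a warning,
for shorter phases), paired with the last blood sample drawn at or before
the phase end; acidemia is maximal there and the pairing keeps exactly one
sample per subject and phase, avoiding correlation bias from unequal
sampling.

## Statistics

Spearman `rho` is Pearson correlation of mid-ranks; the p-value is an
exact permutation probability for `n ≤ 9` and the t approximation on
`n − 2` degrees of freedom otherwise. The paired Wilcoxon signed-rank test
drops zero differences, uses mid-ranks for ties, and computes the exact
two-sided p (`2·min(P(W≤w), P(W≥w))`, capped at 1) by subset-sum counting
over doubled ranks for `n ≤ 25`, switching to a normal approximation with
continuity and tie corrections above. Consecutive-phase comparisons
(BASELINE–MILD, MILD–MODERATE, MODERATE–SEVERE) are Bonferroni-corrected
by a factor 3 and summarized as maximal contiguous runs of `T` with
corrected `p < 0.05`. Quartiles use linear interpolation at positions
`1 + p(n−1)` — the convention that reproduces the cohort's published
interquartile bounds from its per-subject values. SDNN is the
`n−1`-denominator standard deviation of original (non-reconstructed)
intervals. Correlations pool subject x phase points over the four phases
BASELINE..SEVERE (a switch restricts to occlusion phases only).

## Synthetic cohort

The generator emulates the protocol geometry exactly: BASELINE 30 min,
MILD 60 min, MODERATE 60 min, SEVERE 120 min, RECOVERY 30 min; 60 s
occlusions with 90 s recoveries tiled through the occlusion phases
(24/24/48 events); blood samples every 20 min. The deterministic RR
component is `baseline + elevation(t)`, the elevation following the
occlusion-response exponentials with per-subject time constants drawn
uniformly from the cohort's published ranges (`τ_stim` 9.63–46.17 s,
`τ_rec` 3.38–7.88 s, preserving `τ_stim > τ_rec`). The implicit relation
between a beat's onset time and its RR value is solved by fixed-point
iteration, so noiseless beats lie exactly on the model — which is what
makes 0.1 %-level parameter recovery a meaningful test of the fitter
rather than of the generator.

Variability is a slow sinusoid (period 25 s) plus white beat-to-beat
noise, with phase-scaled amplitudes: amp/sd 4/2.5 ms in BASELINE, MILD and
RECOVERY, 8/5 ms in MODERATE and 12/8 ms in SEVERE. This is the simplest
mechanism that makes AC/DC rise with phase severity, consistent with the
autonomic activation the study observed; any richer model (AR, 1/f) could
be substituted behind the same configuration keys. Deceleration plateau
depths (+40/+120/+250 ms for MILD/MODERATE/SEVERE above a 400 ms baseline
RR) are not reported for the animals and are package choices made to
produce visually obvious SEVERE decelerations while preserving the
time-constant ordering; they are configuration, not claims. Biomarker
trajectories interpolate linearly between per-phase-end targets set to
the published cohort medians, reaching each target at the last sampling
time inside its phase, so the final SEVERE sample is pH 6.98 — below the
protocol's 7.00 stopping threshold. Artifacts arrive at 2 per hour
(Poisson), each merging the smallest run of beats whose summed RR exceeds
1500 ms, conserving total time.

All randomness flows from one seed: `SeedSequence(seed)` spawns one child
per subject, and each subject child spawns (tau draw, beat noise,
artifact placement) in that fixed order.

What passing tests on this cohort do show: the whole chain — generation,
reconstruction, anchor selection, capacity, windowing, concatenation,
fitting, statistics — is internally consistent, deterministic, and
reproduces the study's qualitative findings (monotone AC/DC escalation
across occlusion phases at `T = 2..5`, significant entire-vs-stable
differences during occlusion phases, `τ_rec ≪ τ_stim`, strong negative
rank correlation with pH). What they do not show: agreement with the
animal data's absolute AC/DC magnitudes, which depend on the real beat-to
beat dynamics (baroreflex, breathing-like rhythms, 1/f variability) that
the two-component variability model does not attempt to capture; the
per-subject published table would be required for that comparison and is
distributed only as a binary spreadsheet.

## Problem sizes and runtime choices

Default analyses sweep `T = 1..50` on ~4,200-beat phase windows for seven
subjects (~42,000 beats each over the 5-hour protocol); capacities are
computed in streaming cumulative-sum form, so the full cohort analysis
takes a few seconds. Parameter-recovery studies use 20 seeds at noise
sd 10 ms. The exact Wilcoxon enumeration covers `n ≤ 25`; the exact
Spearman permutation covers `n ≤ 9`, beyond which both switch to standard
approximations.

## Known limitations

- The variability model is stationary within a phase; real fRR shows
  drifting baselines and autocorrelated noise.
- `τ_stim` estimates are biased upward when `τ_stim` is not small relative
  to the occlusion duration; this mirrors a genuine identifiability limit
  of the 60 s protocol, not an implementation defect.
- Stable-series results at `T > 25` depend on the cross-boundary policy;
  both policies are implemented, with the conservative one as default.
- QC uses reconstructed-time coverage as a proxy for "correctly located
  beats"; misdetections that do not produce long intervals are invisible
  to it.
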