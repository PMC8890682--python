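# Methods

This note documents the models, algorithms, calibrations and numerical
choices behind `circakit`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Light schedules and zeitgeber time

A schedule is a list of experimental days, each carrying an absolute
lights-on/lights-off interval in minutes from the experiment start, or no
interval at all (constant darkness, DD). Time zero is day 1's *reference*
lights-on — 08:00 by convention — and zeitgeber time is always computed
against that reference: ZT0 = 08:00, ZT12 = 20:00. On jet-lag days the
light cycle moves but the ZT axis does not, so a phase-delayed activity
onset is visible as ZT > 12. Storing absolute minutes (rather than clock
times) makes the midnight-crossing shifted dark periods unambiguous: the
social-jet-lag (SJL) weekend runs lights 14:00–02:00, and "experimental day
d" is always delimited by the normal lights-on.

Protocol constructors:

* `make_ld(n)` — normal 12:12 LD, lights 08:00–20:00;
* `make_sjl(n_baseline, delay_h, n_recovery)` — baseline week, then the
  whole cycle translated *later* by `delay_h` (default 6 h) on two
  consecutive weekend days, then back to normal. We translate the entire
  cycle (lights 14:00–02:00) rather than delaying only the dark onset, so
  every lit day keeps a 12-h photoperiod — an invariant the test suite
  enforces for every generated schedule.
* `make_advance(n_baseline, advance_h, n_post)` — from the shift day
  onward the whole cycle runs `advance_h` earlier (dark onset 14:00 for
  the 6-h default). The transition night's dark period is shortened; all
  lit days keep 12 h of light.
* `make_dd(n)` — DD days carry no light interval at all (not a zero-length
  one), which keeps "is this day lit?" a crisp, testable predicate.

## Entrainment simulator

The behavioural generator is a one-dimensional discrete-time phase map.
Its state is the activity-onset phase ψ_d (ZT hours) on day d:

    ψ_{d+1} = ψ_d + (τ − 24) + Δ_d
    Δ_d     = sign(g_d) · min(δ_max(dir), r·|g_d|),   g_d = dark-onset ZT − ψ_d

where g_d is taken along the shorter circular arc, τ is the intrinsic
free-running period, r is the fractional phase correction per day, and
δ_max is direction-specific: delays (positive Δ) are capped at
`delta_delay_max`, advances at the smaller `delta_advance_max`, reflecting
the well-known asymmetry of rodent re-entrainment. On DD days Δ_d = 0 and
the phase free-runs with slope τ − 24 per day.

The *proportional-with-saturation* response (r·|g| capped at δ_max) is
deliberate. A pure clip-to-δ_max rule closes any residual gap smaller than
δ_max in a single day; after a 6-h delay that predicts full re-entrainment
on the second shifted day (a 6.0-h Sunday delay), which overshoots the
observed 4–5.5-h range. With r = 0.625 and δ_delay_max = 3.75 h/day the
map reproduces the observed behaviour end to end:

* Saturday (first shifted day): Δ = min(3.75, 0.625·6) = 3.75 h delay,
  inside the observed 3.5–4 h;
* Sunday: the remaining 2.25-h gap yields ≈1.4 h more, a cumulative
  ≈5.2 h, inside the observed 4–5.5 h;
* weekday recovery: capped at `delta_advance_max` per day — 0.7 h/day
  without a wheel leaves ≈1.7 h of delay on Friday (no recovery), while
  1.2 h/day plus the shortened intrinsic period (τ = 23.5) brings the
  wheel group back to its own baseline on the fifth weekday.

Presets fix the cohort conditions: `ND_NoWheel` (τ = 24.00 h,
δ_advance = 0.7 h/day), `ND_Wheel` (τ = 23.50 h, δ_advance = 1.2 h/day,
higher emission rate, wheel modality), and `HFD_*` variants that add a
constant 2-h peripheral phase delay to organ acrophases (high-fat feeding
delays peripheral clocks; the exact magnitude is a free calibration chosen
once to make diet effects visible at n = 6). Under entrainment with
τ = 23.5 the map's fixed point sits slightly *before* dark onset
(ψ* ≈ ZT11.2, where the daily −0.5-h drift balances the delay
correction) — the wheel cohort starts activity earlier than the no-wheel
cohort even under normal LD, as observed.

Activity emission: each day the active phase is [ψ_d + jitter, ψ_d + α)
with α = 12 h and Gaussian day-to-day jitter (SD 0.25 h, the simplest
model that makes detected onsets scatter realistically). Counts per 6-min
bin are Poisson with mean `lambda_active` inside the active phase (10 for
the area sensor, 40 for the wheel — wheels register far more counts; no
biomechanical wheel model is attempted) and `lambda_rest` = 0.5 outside.
Negative masking (light forcing active bins down to the rest rate) is
implemented and tested but **off** in the presets: a mouse that fully
suppressed activity until the delayed dark onset would show a 6-h Saturday
delay, whereas the observed 3.5–4-h delays mean activity starts while the
shifted lights are still on. The flag exists for users who want
masking-dominated actograms.

Determinism: every stochastic routine takes a `numpy` Generator (or a seed
in `SimConfig`); identical config + schedule + seed reproduces identical
counts bit for bit.

## Bioluminescence emulator

Each animal/organ series follows the in vivo PER2-reporter sampling
design: six samples at 4-h intervals starting 17:00 (ZT9, 13, 17, 21, 1,
5). The true signal is a cosine around an arbitrary mesor (10⁶
photons/min — only the percent-normalized values enter analysis):

    rate(t) = M · (1 + A% / 100 · cos(2π(ZT(t) − φ)/24)) · ε,

with multiplicative lognormal noise ε (unit mean, CV 0.05) and

    φ = baseline acrophase + coupling × behavioural shift + diet delay.

Baseline acrophases are the observed normal-LD group means per organ and
wheel condition: kidney ZT18.8 (wheel) / 17.5 (no wheel), liver 19.2 /
19.0, submandibular gland 19.5 / 18.9. `coupling` ∈ [0, 1] is the fraction
of the behavioural phase shift transmitted to the organ clock (1 by
default: peripheral phase tracks behaviour). Amplitude defaults to 20% of
mesor, matching the waveform excursions the normalized data show.

## Onset detection

The detector operationalises "transition from 6 h of inactivity to 6 h of
high activity" as the bin boundary t maximising

    S(t) = mean(counts in [t, t+6h)) − mean(counts in [t−6h, t)),

i.e. correlation with a step template, using means rather than a binarised
threshold so no free cut-off parameter is introduced. For each
experimental day the search runs from that day's ZT4 to the next day's
ZT4, so weekend onsets delayed by up to ~10 h stay attributed to their own
day. Ties break to the earliest boundary; windows at the recording edges
use the available bins. Days with all-zero counts or under 50% coverage
yield a missing onset and are excluded from means. The implementation is
verified against an exhaustive brute-force argmax oracle; equivalence with
any proprietary actigraphy software's internal rule is not claimed.

Delays: `onset_delays` subtracts the circular mean onset of the baseline
days, mapping each difference to (−12, +12] h (positive = later), so a
baseline at ZT23.5 and an onset at ZT0.5 give +1 h, not −23.

## Chi-squared periodogram

For each candidate period P (restricted to integer bin counts so folding
is exact; grid 20–28 h in 0.1-h steps at 6-min bins) the series is folded
into K complete cycles (trailing partial cycle discarded to keep column
means unbiased) and scored with the Sokolove–Bushell statistic

    Q_P = K·N·Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²,   N = K·P,

against a χ²(P−1) upper-α significance line. The best period maximises
Q_P − line. Q_P is invariant to scaling and shifting the counts (both are
property-tested). A flat series is rejected as degenerate, and recordings
shorter than two maximal candidate periods are rejected outright.

Finite-sample caveat: Q_P is exactly N·B/(B+W) (a scaled beta), not a
chi-square; with only ~8–12 folded cycles the χ² line is mildly
conservative (measured white-noise exceedance ≈0.042 at 10 days of data).
The type-I calibration test therefore uses 20-day white noise (~17–24
cycles per candidate), where the asymptotic null is accurate (measured
≈0.047, within Monte-Carlo error of 0.05). Period estimates themselves are
unaffected; only the significance flag inherits this slight conservatism
on short recordings.

The 0.1-h default grid is coarser than the two-decimal precision
free-running periods are conventionally reported at; the step is exposed
(`step_h`) for users with long recordings and finer bins.

## Single cosinor

`Cosinor` fits y = M + β·cos(ωt) + γ·sin(ωt) (ω = 2π/24 by default) by
least squares and reports mesor M, amplitude A = √(β²+γ²), acrophase
φ = atan2(γ, β)/ω mod 24 — as a peak time in ZT hours — and the
zero-amplitude F test (β = γ = 0, 2 numerator df) as the rhythmicity
p-value. The period stays fixed at 24 h: six samples over one cycle cannot
support free-period fitting. Preconditions: ≥4 distinct sample phases and
a full-rank design. Degenerate cases are handled explicitly: constant
input → A ≈ 0, p = 1; an exact noiseless cosine → p = 0 rather than a
0/0 F ratio. Percent normalization divides by the series mean and
multiplies by 100, so normalize-then-fit always returns a mesor of 100.

Group summaries use the circular mean of acrophases with a
circular-aware SEM (deviations unwrapped to (−12, 12] about the circular
mean, then treated linearly — adequate for the tightly clustered phases
here, SD ≪ 6 h). Fits failing rhythmicity at p ≥ 0.05 are counted and, by
default, still included (matching per-animal acrophase plots); a flag
excludes them.

## Group-comparison tree

`compare_groups` gates on per-group Kolmogorov–Smirnov normality with
estimated moments (Lilliefors; skipped for n < 4, where it has no power)
and Bartlett's variance homogeneity, then runs Student's t (equal
variances, because the Bartlett gate precedes it) or one-way ANOVA with
Tukey's HSD on the parametric branch, and Mann–Whitney or Kruskal–Wallis
with Dunn's z-tests (tie-corrected, Bonferroni-adjusted over the pair
family) otherwise. The chosen branch is recorded in the result so output
tables state which test produced each p-value. Circular quantities must be
unwrapped to a common branch first — the delay statistic and the
acrophase-versus-reference differences used by the experiment drivers do
exactly that.

## Experiment reproductions and problem sizes

`run_experiment` regenerates each study design at its published cohort
sizes (SJL behaviour 5+9 ND / 10+8 HFD; bioluminescence 6–7 per group;
DD 10 days with 9+7 animals) — sizes small enough that every experiment
runs in seconds. The bioluminescence experiments chain the two generators:
each animal's behavioural shift on the measurement day (Thursday, day 13,
for the SJL designs; day 11 for the 6-h advance) is read off its own
simulated actogram and fed to the organ emulator, so the peripheral
results inherit behavioural variability rather than being drawn around a
hard-coded shift.

## What the synthetic tests do and do not show

The generator encodes the hypothesised mechanisms (shorter τ and larger
advance capacity with wheel-running; proportional, saturating light
correction; organ phases coupled to behaviour). Passing recovery tests
therefore demonstrates that the *analysis chain* — onset detection, delay
statistics, periodogram, cosinor, comparison tree — recovers known ground
truth through the full pipeline at realistic noise and cohort sizes. It
does not validate the biological model itself, and the emulator omits
several features of real data: ultradian activity bouts, wheel-specific
emission dynamics, light masking interacting with phase (off by default),
inter-animal τ variability, and anesthesia or imaging artefacts in the
photon counts. Group-level agreement with the published summary statistics
is parameter recovery, not reproduction of the animal data, which were
never deposited.
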