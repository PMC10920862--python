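# Methods

## Scope and data model

The package analyses per-animal actigraphy: equally spaced, non-negative
integer activity counts plus a body-temperature channel, recorded in
5-minute bins for weeks. Two lighting protocols are modelled: an entrained
12:12 light–dark cycle (LD) and constant darkness (DD), described by a
`LightSchedule` that maps recording time (seconds since start) to zeitgeber
time (ZT, hours; ZT0 = lights-on) and light state. Intervals are half-open
`[lights_on, lights_off)`, so the lights-off instant belongs to the dark
phase and a transition-aligned bin 0 is the first dark bin. A boundary that
coincides with a query-span endpoint is not reported as a transition inside
the span. All internal time is seconds from recording start; ZT appears
only at presentation boundaries, which avoids wall-clock and DST
ambiguity. DD recordings keep the frozen ZT frame of the last LD anchor so
phase markers remain comparable as clock times.

## Synthetic recordings

The generator exists so every downstream stage has inputs with known ground
truth. It emulates the statistical structure the analyses assume, not any
particular device.

**Activity drive.** A latent drive s(t) ∈ [0, 1] relaxes exponentially
toward piecewise-constant targets: after each lights-off (real, or
subjective in DD with period τ) the target becomes 1 starting
`onset_latency` minutes later, approached with time constant `rise_time`;
at lights-on the target becomes `light_suppression` with time constant
`fall_time`. The piecewise-exponential solution is evaluated in closed form
segment by segment (validated in the tests against 1-s Euler integration
with a burn-in day). In DD the subjective day advances 24 h of phase per τ
real hours, so activity onset drifts by 24 − τ per day (≈ 0.3 h/day
earlier at τ = 23.7 h). A pure-cosine DD drive
(s = (1 + cos 2π(szt − 18)/24)/2) is available for spectral tests where a
single line spectrum is wanted. Zero `amplitude` denotes an arrhythmic
animal: the drive is identically zero and both channels are flat.

**Counts.** Expected counts per bin are `baseline_rate + amplitude · s`;
emitted counts are negative binomial with size k = `dispersion`
(variance μ + μ²/k), Poisson in the limit k = ∞ (the default), and exactly
`round(μ)` in deterministic mode. Rodent activity counts are typically
overdispersed; the dispersion knob lets tests set noise precisely. An
optional two-state (on/off) ultradian bout gate with exponential sojourns
is off by default.

**Temperature.** `temp_base + temp_amplitude ·` (s low-pass filtered with
time constant `temp_smooth`) plus Gaussian noise. Temperature is driven by
the smoothed drive, not by the realised counts, keeping the two channels
conditionally independent given the drive — the weakest defensible
coupling.

**Defaults** (per 5-min bin unless noted): baseline_rate 2, amplitude 20,
light_suppression 0.05, onset_latency 30 min, rise_time 20 min, fall_time
20 min, τ 23.7 h, dispersion ∞ (Poisson), temp_base 36 °C, temp_amplitude
1.5 °C, temp_smooth 30 min, temp_noise_sd 0.1 °C. These are round numbers
in the range of healthy laboratory-mouse telemetry: a ~10× dark/light
activity contrast, a ~1–1.5 °C day–night core-temperature swing, and the
textbook 23.7-h free-running period of C57BL/6 mice. The
`genotype_presets()` pair encodes the two study conditions: `wt_like` as
above, and `del_like` differing only in τ (+5.3 min), onset_latency
(10 min) and rise_time (10 min) — a longer free-running period plus a
faster lights-off response.

**Seeding.** One master seed; each animal uses
`SeedSequence(master_seed, spawn_key=(group_index, animal_index))`, giving
cohort-level reproducibility with animal-level independence. Deterministic
mode disables all noise and is bit-stable across seeds.

**What the generator does not emulate:** ultradian structure is optional
and crude; there is no two-process sleep homeostat, no torpor, no masking
beyond multiplicative suppression, no sex or strain effects, no cage-mate
interaction or fighting artifacts, and activity units are abstract counts
(all analyses are unit-free). Passing tests therefore demonstrate the
*estimators* are correct under the assumed structure, not that real
recordings satisfy that structure.

## Phase markers

Three centered moving averages of activity are computed (24 h, 3 h, 1 h);
positions whose full window leaves the record are undefined, so half a
window is lost at each end and edge days carry no markers. Per ZT day,
searching a ZT6 → ZT6-next-day window so the expected nocturnal onset
(~ZT12) is interior:

- **onset** — first upward crossing of the 3-h average through the 24-h
  average; **offset** — first subsequent downward crossing. The crossing
  time is the start of the first bin on the new side; ties break earliest.
  (One published description of this method words the onset crossing in
  the opposite direction — the long average exceeding the short — which
  inverts the standard convention; the short-above-long direction is used
  here and `MarkerOptions.invert_crossing` flips it.)
- **midpoint** — earliest time at which cumulative activity from onset
  reaches half the total over a fixed `midpoint_span` (default 16 h)
  anchored at onset; the span is a method constant rather than the
  measured alpha, and days whose span runs off the record end get no
  midpoint.
- **peak** — earliest maximum of the 1-h average within [onset, offset].

Days with no crossing are flagged invalid. Offsets may exceed ZT24
(carryover scale, never wrapped) so arithmetic means per animal are well
defined. Per-animal means across valid days are the units of group
inference — pooling animal-days would treat correlated days as independent.
Centered (not trailing) windows avoid a systematic half-window lag in every
marker; the cost is the lost edge days. Markers are invariant to positive
rescaling of activity and equivariant under time shifts.

## Period estimation

The free-running period is the dominant spectral peak of the activity
series in a 20–28 h band. Pipeline: subtract the mean (or a linear trend),
apply a Hann taper (suppresses leakage from the strong harmonics of
square-ish activity waveforms), zero-pad to 64× the record length, take the
squared modulus of the rFFT, locate the band-limited maximum, and refine it
by fitting a parabola to log power at the peak and its two grid neighbours.
The estimate is 1/(refined frequency).

The raw Fourier resolution of a 13-day record is ≈ 1.8 h near 24 h; the
padded-and-interpolated estimator recovers a noiseless 24.000-h cosine to
within 0.0001 h and a deterministic τ = 23.7 h square-ish simulation to
within 0.0001 h, and under default Poisson noise shows |bias| < 0.5 min
with SD < 1.5 min across seeds (both recomputed by the tests and the
acceptance script). That is sufficient to separate cohorts of five whose
programmed periods differ by 5.3 min. A peak on a band edge is flagged,
not an error; a band whose total power is below 10⁻⁹ of the spectrum total
raises "no circadian periodicity". The temperature channel can be analysed
behind a flag; activity is the default and the validated path.

## Transition responses and latency

Records rebin exactly (counts summed, temperatures averaged
missing-aware). Daily profiles average each ZT bin within animal across
complete days, then report mean and SEM (sample SD/√n) across animals —
SEM across animals, not across all animal-days, because animals are the
independent units. Lights-off-aligned matrices average all event windows
within animal on a relative grid whose bin 0 starts at the event. Per-bin
two-sample comparisons use the pooled-variance t by default (Welch behind
a flag) and report raw and Holm-adjusted p side by side: raw p mirrors the
uncorrected multiple-t-test presentation common in the field, adjusted p
is the defensible default. Bins with zero variance in both groups and
equal means are flagged degenerate rather than raised.

The lights-off **response latency** is the time from lights-off to the
first 15-min bin whose activity reaches `threshold_frac` (default 0.5) of
that day's dark-phase mean, averaged over days per animal. The threshold
form is this package's operationalisation of "faster activity rise after
lights off"; the fraction and bin width are exposed because no standard
definition exists.

## Group statistics

`students_t` implements the two-tailed pooled-variance test
(df = n₁ + n₂ − 2) with a Welch option; zero-variance cases degenerate to
p = 1 (equal means) or the p → 0 limit (unequal), flagged. `mann_whitney`
computes U from midranks and, for combined n ≤ 20, the exact two-sided p
by enumerating all C(n₁+n₂, n₁) assignments of the observed pooled values
(ties handled by enumerating the actual values) under the
"|U − n₁n₂/2| at least as extreme" rule; complete 5 vs 5 separation gives
2/252 ≈ 0.0079, the smallest attainable two-sided p at those sizes.
Beyond n = 20 a tie-corrected normal approximation with continuity
correction is used. The exact test is validated against a brute-force
pairwise-comparison oracle over every rank pattern with combined n ≤ 8 and
cross-checked against an independent library implementation; under a
continuous null its 5v5 rejection rate at α = 0.05 sits in [0.03, 0.05]
(conservative by discreteness). `holm_adjust` is the standard step-down
with monotonicity enforcement, cross-checked against statsmodels.

## Numerical choices and degenerate inputs

- Moving averages use cumulative sums; equality of the two averages is not
  a crossing (strict inequality on the new side), which makes the
  square-wave onset land one bin after the ideal instant — within the
  stated one-bin tolerance.
- Quadratic peak interpolation is skipped (flagged) at band edges or when
  log power has no local maximum; the grid peak is then reported.
- Missing temperature is NaN end to end; missing activity is not
  representable (a dropped bin is a format error) because every stage
  assumes a complete count grid.
- Writers are byte-deterministic: per-animal records use shortest
  round-trip float formatting (telemetry must survive write → read
  bit-identically); result tables and the JSON report use 6 significant
  digits and sorted keys.
- Record CSV validation reports 1-based row numbers counting the header.

## Problem sizes in the validation suite

The test suite and acceptance script use the study-scale conditions
throughout: 5 animals per group, 42 entrained days for marker/latency
analyses, 13 DD days for period analyses, 20 seeds for the noise
calibration, and 100 replicate experiments for each detection-rate
estimate. The full suite runs in well under a minute on one CPU.

## Known limitations

- The marker detector assumes one consolidated active phase per day;
  split-bout (bimodal) patterns yield the first crossing pair only.
- The FFT estimator requires a complete record; gapped series would need a
  Lomb–Scargle or chi-square periodogram, both out of scope.
- Phase markers on DD data are meaningful only through the frozen ZT frame;
  after many cycles the accumulated drift moves onsets outside the search
  window (13 days at τ = 23.7 h stays comfortably inside).
- The exact Mann–Whitney enumeration is O(C(n, n₁)) and is intended for
  the ≤ 20-sample regime it defaults to.
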