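# actirhythm

Long-term actigraphy analysis for circadian phenotyping of laboratory
rodents, built around implanted telemetry recordings (activity counts and
body temperature in fixed 5-minute bins over weeks). The package targets
the questions such recordings are collected to answer: *when* does an
animal's active phase start and end each day, *what* is its free-running
circadian period in constant darkness, and *how fast* does it respond to a
light transition — and whether two genotype groups differ in any of these.

It provides:

- **Light-cycle model** (`lightcycle`) — zeitgeber time (ZT; ZT0 =
  lights-on, ZT12 = lights-off under LD 12:12), light state, and transition
  enumeration for entrained (LD) and constant-darkness (DD) protocols.
- **Phase markers** (`phase`) — per-day activity *onset* and *offset* from
  the crossings of a short (3 h) and a long (24 h) centered moving average
  of activity; *midpoint* from cumulative activity over a 16-h span; *peak*
  from the 1-h moving average; alpha = offset − onset.
- **Period estimation** (`periodogram`) — the free-running period τ from a
  DD recording via the FFT power spectrum: mean-detrended, Hann-tapered,
  64× zero-padded, peak search in the 20–28 h band, quadratic log-power
  interpolation for sub-bin resolution.
- **Transition responses** (`response`) — daily mean ± SEM profiles
  (animals as the independent units), lights-off-aligned response matrices,
  per-bin Student's t-tests with Holm correction reported alongside raw p,
  and a lights-off response latency statistic.
- **Group statistics** (`stats`) — two-tailed pooled-variance Student's t
  (Welch optional) and the exact Mann–Whitney U test, whose small-sample p
  is computed by enumerating all C(n₁+n₂, n₁) group assignments. For
  complete separation at n = 5 vs 5 the two-sided exact p is 2/252 ≈ 0.0079.
- **Synthetic recordings** (`simulate`) — a seeded generator emulating the
  telemetry: an activity drive s(t) ∈ [0, 1] that relaxes exponentially to
  full expression after a latency at lights-off and back to a suppressed
  level at lights-on (free-running with period τ in DD), negative-binomial
  count noise with a Poisson limit, and a temperature channel coupled to a
  low-pass-filtered copy of the drive.
- **I/O and CLI** (`io`, `cli`) — a plain CSV dialect per animal
  (`animal_id,t_s,activity,temp_c`), a cohort manifest, deterministic
  result tables, and the `actirhythm` command with `simulate`, `phases`,
  `period`, `response`, and `report` subcommands.

## Worked example

Simulate two cohorts of five animals with the built-in genotype presets —
`wt_like` (τ = 23.7 h, lights-off latency 30 min) and `del_like`
(τ = 23.7 h + 5.3 min, latency 10 min, faster rise) — and run the full
analysis:

```python
import numpy as np
from actirhythm import (LightSchedule, genotype_presets, simulate_cohort,
                        detect_markers, summarize_markers, onset_latency,
                        estimate_period, students_t, mann_whitney)

presets = genotype_presets()
groups = [("wt", 5, presets["wt_like"]), ("del", 5, presets["del_like"])]

# 6 weeks entrained: phase markers and lights-off latency
recs = simulate_cohort(groups, LightSchedule("LD"), days=42, master_seed=1)
onsets, lats = {}, {}
for r in recs:
    s = summarize_markers({r.animal_id: detect_markers(r)})
    onsets.setdefault(r.group, []).append(float(s["onset_zt"].iloc[0]))
    lats.setdefault(r.group, []).append(onset_latency(r)[0])
print(np.mean(onsets["wt"]), np.mean(onsets["del"]))   # 12.80  12.37  (ZT h)
print(np.mean(lats["wt"]), np.mean(lats["del"]))       # 42.4   15.1   (min)
print(students_t(onsets["wt"], onsets["del"]).p_two_sided)  # 2.4e-10

# 13 days constant darkness: free-running period
drecs = simulate_cohort(groups, LightSchedule("DD"), days=13, master_seed=1)
pers = {}
for r in drecs:
    pers.setdefault(r.group, []).append(estimate_period(r).period_h)
diff_min = (np.mean(pers["del"]) - np.mean(pers["wt"])) * 60
print(round(diff_min, 2))                                   # 5.3  (min)
print(mann_whitney(pers["wt"], pers["del"]).p_two_sided)    # 0.0079
```

The detected onset is later than ZT12 by roughly the programmed latency
plus half the rise time; the del-like group starts moving ~27 min earlier
and its recovered period is 5.30 min longer — the estimator resolves a
difference ~20× finer than the raw 13-day FFT grid spacing near 24 h.

The same analysis from the shell:

```bash
actirhythm simulate --preset-pair wt_like,del_like --n 5 --days 42 --cycle LD --seed 1 --out cohort/
actirhythm phases   --manifest cohort/manifest.csv --out markers.csv
actirhythm response --manifest cohort/manifest.csv --event lights_off --window 60,360 --bin 15 --out response/
actirhythm report   --manifest cohort/manifest.csv --markers markers.csv --out report.json
```

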