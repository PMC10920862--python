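"""Synthetic actigraphy generator.

Emulates long-term telemetry recordings from group-housed mice: an entrained
light-dark (LD) rhythm whose activity drive rises with a latency after each
lights-off, a free-running constant-darkness (DD) rhythm with a programmable
endogenous period tau, overdispersed count noise on the activity channel, and
a body-temperature channel coupled to a low-pass-filtered copy of the same
drive.  Everything is seeded so downstream analyses are testable end to end
without animal data.

The activity drive s(t) lives in [0, 1].  Under LD it relaxes exponentially
toward 1 starting ``onset_latency`` minutes after each lights-off (time
constant ``rise_time``) and back toward ``light_suppression`` at lights-on
(time constant ``fall_time``).  Under DD the same relaxation follows a
subjective day of period ``tau`` (half-period active), so activity onset
drifts by 24 - tau hours per real day; a pure-cosine drive is available for
spectral tests.  Expected counts per bin are
``baseline_rate + amplitude * s``; emitted counts are negative binomial with
mean-dispersion parameterisation (Poisson in the limit dispersion = inf,
exactly the rounded mean in deterministic mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .lightcycle import LightSchedule
from .records import SECONDS_PER_DAY, ActigraphyRecord

__all__ = [
    "SimParams",
    "drive",
    "simulate_animal",
    "simulate_cohort",
    "genotype_presets",
    "expected_counts",
]


@dataclass(frozen=True)
class SimParams:
    """Tunable parameters of one simulated animal.

    Rates are expected counts per 5-min bin; time constants are minutes
    unless noted.  ``dispersion`` is the negative-binomial size parameter k
    (variance = mu + mu^2/k); ``math.inf`` gives Poisson counts.  With
    ``deterministic=True`` all noise is disabled and identical inputs give
    bit-identical outputs irrespective of seed.
    """

    baseline_rate: float = 2.0          # counts/bin during rest
    amplitude: float = 20.0             # added counts/bin at full drive
    light_suppression: float = 0.05     # fraction of drive expressed in light
    onset_latency: float = 30.0         # min, lights-off -> drive rise start
    rise_time: float = 20.0             # min, time constant of the rise
    fall_time: float = 20.0             # min, time constant of decay at lights-on
    tau: float = 23.7                   # h, free-running period (DD)
    dispersion: float = math.inf        # NB size k; inf = Poisson
    temp_base: float = 36.0             # deg C
    temp_amplitude: float = 1.5         # deg C
    temp_smooth: float = 30.0           # min, low-pass coupling drive -> temperature
    temp_noise_sd: float = 0.1          # deg C
    deterministic: bool = False
    dd_waveform: Literal["square", "cosine"] = "square"
    ultradian: bool = False             # optional two-state bout modulation
    ultradian_on_min: float = 40.0      # mean active-bout length
    ultradian_off_min: float = 20.0     # mean pause length

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.amplitude < 0:
            raise ValueError("baseline_rate and amplitude must be non-negative")
        if not 0.0 <= self.light_suppression <= 1.0:
            raise ValueError("light_suppression must lie in [0, 1]")
        if not 20.0 <= self.tau <= 28.0:
            raise ValueError("tau must lie in [20, 28] hours")
        for name in ("onset_latency", "rise_time", "fall_time", "temp_smooth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf for Poisson)")
        if self.dd_waveform not in ("square", "cosine"):
            raise ValueError("dd_waveform must be 'square' or 'cosine'")


# --------------------------------------------------------------------- #
# drive

def _subjective_zt(params: SimParams, schedule: LightSchedule, t_s: np.ndarray) -> np.ndarray:
    """Subjective ZT: advances 24 h of phase per tau real hours in DD, per 24 h in LD."""
    tau_eff = params.tau if schedule.cycle_kind == "DD" else schedule.cycle_length_h
    speed = schedule.cycle_length_h / tau_eff
    return (schedule.anchor_zt_at_start + (t_s / 3600.0) * speed) % schedule.cycle_length_h


def _drive_events(
    params: SimParams, schedule: LightSchedule, duration_s: float
) -> list[tuple[float, float, float]]:
    """Piecewise-constant relaxation targets: (time_s, target, time_constant_s).

    Lights-off (real or subjective) schedules a target of 1 after the onset
    latency with the rise time constant; lights-on schedules a target of
    ``light_suppression`` with the fall time constant.
    """
    ls = params.light_suppression
    latency_s = params.onset_latency * 60.0
    rise_s = params.rise_time * 60.0
    fall_s = params.fall_time * 60.0
    off_zt = schedule.lights_off_zt
    cyc = schedule.cycle_length_h

    if schedule.cycle_kind == "LD":
        period_s = cyc * 3600.0
        first_off = ((off_zt - schedule.anchor_zt_at_start) % cyc) * 3600.0
        first_on = ((0.0 - schedule.anchor_zt_at_start) % cyc) * 3600.0
    else:
        # subjective boundaries recur every tau hours
        period_s = params.tau * 3600.0
        scale = params.tau / cyc
        first_off = ((off_zt - schedule.anchor_zt_at_start) % cyc) * 3600.0 * scale
        first_on = ((0.0 - schedule.anchor_zt_at_start) % cyc) * 3600.0 * scale

    events: list[tuple[float, float, float]] = []
    t = first_off - period_s  # include the cycle before t=0 so latency spill-over is seen
    while t < duration_s:
        if t + latency_s < duration_s:
            events.append((t + latency_s, 1.0, rise_s))
        t += period_s
    t = first_on - period_s
    while t < duration_s:
        events.append((t, ls, fall_s))
        t += period_s
    events.sort(key=lambda e: e[0])
    return events


def drive(
    params: SimParams,
    schedule: LightSchedule,
    days: int,
    bin_seconds: int = 300,
) -> np.ndarray:
    """Noise-free activity drive s in [0, 1], one value per bin (midpoint).

    Solved exactly segment-by-segment: within each span of constant target u
    and time constant T, ``s(t) = u + (s0 - u) * exp(-(t - t0)/T)``.

    Zero amplitude means an arrhythmic animal: the drive is identically 0,
    so both channels (activity and the temperature it feeds) are flat.
    """
    duration_s = days * SECONDS_PER_DAY
    n_bins = duration_s // bin_seconds
    if params.amplitude == 0:
        return np.zeros(n_bins)
    t_mid = (np.arange(n_bins) + 0.5) * bin_seconds

    if params.dd_waveform == "cosine" and schedule.cycle_kind == "DD":
        szt = _subjective_zt(params, schedule, t_mid)
        cyc = schedule.cycle_length_h
        mid_dark = (schedule.lights_off_zt + cyc) / 2.0  # centre of the dark phase
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * (szt - mid_dark) / cyc))

    events = _drive_events(params, schedule, duration_s)
    # state at the first event: relax from the pre-history; seed with the
    # target in force before the first event (steady state)
    s = np.empty(n_bins)
    if not events:
        s.fill(params.light_suppression)
        return s
    starts = np.array([e[0] for e in events])
    seg_of_bin = np.searchsorted(starts, t_mid, side="right") - 1

    # segment initial values by forward recursion
    s0 = np.empty(len(events))
    prev_val = events[0][1]  # steady at the earliest target
    prev_t = events[0][0]
    for i, (t0, target, tc) in enumerate(events):
        if i == 0:
            s0[i] = prev_val
        else:
            pt0, ptar, ptc = events[i - 1]
            s0[i] = ptar + (s0[i - 1] - ptar) * math.exp(-(t0 - pt0) / ptc)
    targets = np.array([e[1] for e in events])
    tcs = np.array([e[2] for e in events])

    before = seg_of_bin < 0
    seg = np.clip(seg_of_bin, 0, None)
    s = targets[seg] + (s0[seg] - targets[seg]) * np.exp(
        -(t_mid - starts[seg]) / tcs[seg]
    )
    s[before] = events[0][1]
    return np.clip(s, 0.0, 1.0)


def expected_counts(
    params: SimParams,
    schedule: LightSchedule,
    days: int,
    bin_seconds: int = 300,
) -> np.ndarray:
    """Expected counts per bin: baseline_rate + amplitude * drive."""
    return params.baseline_rate + params.amplitude * drive(params, schedule, days, bin_seconds)


# --------------------------------------------------------------------- #
# sampling

def _lowpass(x: np.ndarray, time_constant_s: float, dt_s: float) -> np.ndarray:
    """First-order exponential low-pass, initialised at x[0] (steady start)."""
    a = 1.0 - math.exp(-dt_s / time_constant_s)
    b, ac = [a], [1.0, -(1.0 - a)]
    zi = signal.lfiltic(b, ac, y=[x[0]], x=[x[0]])
    y, _ = signal.lfilter(b, ac, x, zi=zi)
    return y


def _sample_counts(mu: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.deterministic:
        return np.round(mu).astype(np.int64)
    if math.isinf(params.dispersion):
        return rng.poisson(mu).astype(np.int64)
    k = params.dispersion
    p = k / (k + mu)
    return rng.negative_binomial(k, p).astype(np.int64)


def _ultradian_gate(
    n_bins: int, bin_seconds: int, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    """Two-state (on/off) bout gate with exponential sojourns, bin resolution."""
    gate = np.ones(n_bins)
    if params.deterministic:
        return gate
    t = 0.0
    on = True
    dur_s = n_bins * bin_seconds
    while t < dur_s:
        mean = params.ultradian_on_min if on else params.ultradian_off_min
        span = rng.exponential(mean * 60.0)
        if not on:
            i0 = int(t // bin_seconds)
            i1 = min(n_bins, int(math.ceil((t + span) / bin_seconds)))
            gate[i0:i1] = 0.0
        t += span
        on = not on
    return gate


def simulate_animal(
    params: SimParams,
    schedule: LightSchedule,
    days: int,
    seed: int | np.random.SeedSequence,
    animal_id: str = "sim",
    group: str = "sim",
    bin_seconds: int = 300,
) -> ActigraphyRecord:
    """Simulate one animal's activity and body-temperature record.

    ``days`` complete days at ``bin_seconds`` resolution.  Counts, the
    ultradian gate (if enabled) and temperature noise all derive from
    ``seed``; in deterministic mode the seed is irrelevant.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if (days * SECONDS_PER_DAY) % bin_seconds != 0:
        raise ValueError("days * 86400 must be a multiple of bin_seconds")
    rng = np.random.default_rng(seed)
    n_bins = days * SECONDS_PER_DAY // bin_seconds

    s = drive(params, schedule, days, bin_seconds)
    gate = _ultradian_gate(n_bins, bin_seconds, params, rng) if params.ultradian else 1.0
    mu = params.baseline_rate + params.amplitude * s * gate
    activity = _sample_counts(mu, params, rng)

    s_filt = _lowpass(s, params.temp_smooth * 60.0, bin_seconds)
    temperature = params.temp_base + params.temp_amplitude * s_filt
    if not params.deterministic and params.temp_noise_sd > 0:
        temperature = temperature + rng.normal(0.0, params.temp_noise_sd, n_bins)

    return ActigraphyRecord(
        animal_id=animal_id,
        group=group,
        bin_seconds=bin_seconds,
        activity=activity,
        temperature=temperature,
        schedule=schedule,
    )


def simulate_cohort(
    groups: Sequence[tuple[str, int, SimParams]],
    schedule: LightSchedule,
    days: int,
    master_seed: int,
    bin_seconds: int = 300,
) -> list[ActigraphyRecord]:
    """Simulate a multi-group cohort with per-animal independent substreams.

    Each animal's stream derives from ``SeedSequence(master_seed,
    spawn_key=(group_index, animal_index))``: the cohort is reproducible from
    the master seed while animals stay statistically independent.
    """
    labels = [g for g, _, _ in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    records: list[ActigraphyRecord] = []
    ids: set[str] = set()
    for gi, (group, n_animals, params) in enumerate(groups):
        if not group:
            raise ValueError("group labels must be non-empty")
        for ai in range(n_animals):
            aid = f"{group}_{ai + 1:02d}"
            if aid in ids:
                raise ValueError(f"duplicate animal id {aid!r}")
            ids.add(aid)
            ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(gi, ai))
            records.append(
                simulate_animal(
                    params, schedule, days, ss,
                    animal_id=aid, group=group, bin_seconds=bin_seconds,
                )
            )
    return records


def genotype_presets() -> dict[str, SimParams]:
    """Named parameter sets for the two genotype-like conditions.

    ``wt_like`` carries the textbook free-running period of laboratory mice
    (tau = 23.7 h); ``del_like`` runs 5.3 min longer and responds faster to
    lights-off (shorter onset latency and rise time), the hypersensitivity
    phenotype.  All remaining numbers are implementation defaults.
    """
    wt = SimParams(tau=23.7, onset_latency=30.0, rise_time=20.0)
    dl = replace(wt, tau=23.7 + 5.3 / 60.0, onset_latency=10.0, rise_time=10.0)
    return {"wt_like": wt, "del_like": dl}
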