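"""Daily profiles and light-transition response curves.

Quantifies how activity and body temperature track the light cycle: mean
daily profiles (per-animal day-averages, then across-animal mean +/- SEM —
animals are the independent units), lights-off-aligned response matrices,
per-bin two-sample comparisons with Holm correction reported alongside the
raw p-values, and a lights-off response latency statistic (time for activity
to reach a fraction of the animal's dark-phase mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .lightcycle import LightSchedule
from .records import SECONDS_PER_DAY, ActigraphyRecord
from .stats import TestResult, holm_adjust, students_t

__all__ = [
    "DailyProfile",
    "ResponseMatrix",
    "rebin",
    "daily_profile",
    "align_to_transition",
    "per_bin_compare",
    "onset_latency",
]

Variable = Literal["activity", "temperature"]


@dataclass
class DailyProfile:
    """Across-animal mean +/- SEM of per-animal day-averaged values vs ZT."""

    variable: Variable
    bin_minutes: int
    group: str
    bin_start_zt: np.ndarray   # hours, tiles [0, 24)
    mean: np.ndarray
    sem: np.ndarray
    n_animals: int


@dataclass
class ResponseMatrix:
    """Per-animal day-averaged series on a grid relative to a light transition.

    ``values[i, j]`` is animal i's average over all occurrences of the event;
    bin 0 starts at the event instant (half-open convention: the first bin
    after lights-off is a dark bin).
    """

    event: Literal["lights_off", "lights_on"]
    variable: Variable
    bin_minutes: int
    rel_bin_start_min: np.ndarray
    animal_ids: list[str]
    values: np.ndarray


def rebin(record: ActigraphyRecord, bin_minutes: int) -> ActigraphyRecord:
    """Coarsen a record's grid: activity summed, temperature averaged.

    Temperature averaging is missing-aware — a coarse bin is missing only
    when every fine bin inside it is missing.  Rebinning to the record's own
    width is the identity.
    """
    new_bs = bin_minutes * 60
    if new_bs == record.bin_seconds:
        return record
    if new_bs % record.bin_seconds != 0:
        raise ValueError(
            f"{bin_minutes}-min bins are not a multiple of the {record.bin_seconds}-s grid"
        )
    ratio = new_bs // record.bin_seconds
    if record.n_bins % ratio != 0:
        raise ValueError("record length is not a multiple of the rebin ratio")
    n_coarse = record.n_bins // ratio
    act = record.activity.reshape(n_coarse, ratio).sum(axis=1)
    temp_fine = record.temperature.reshape(n_coarse, ratio)
    with warnings.catch_warnings():
        # all-NaN rows are the intended "coarse bin missing" case
        warnings.simplefilter("ignore", RuntimeWarning)
        temp = np.nanmean(temp_fine, axis=1)
    return ActigraphyRecord(
        animal_id=record.animal_id,
        group=record.group,
        bin_seconds=new_bs,
        activity=act,
        temperature=temp,
        schedule=record.schedule,
    )


def _series(record: ActigraphyRecord, variable: Variable) -> np.ndarray:
    return np.asarray(
        record.activity if variable == "activity" else record.temperature, dtype=float
    )


def _zt_bin_offset(record: ActigraphyRecord) -> int:
    """Bin index offset such that bin (i + offset) % bins_per_day starts at ZT0."""
    anchor_s = record.schedule.anchor_zt_at_start * 3600.0
    off = anchor_s / record.bin_seconds
    if abs(off - round(off)) > 1e-9:
        raise ValueError("schedule anchor is not aligned to the bin grid")
    return int(round(off)) % record.bins_per_day


def per_animal_daily_mean(record: ActigraphyRecord, variable: Variable) -> np.ndarray:
    """One animal's per-ZT-bin average across all complete days."""
    x = _series(record, variable)
    bpd = record.bins_per_day
    days = record.n_bins // bpd
    if days < 1:
        raise ValueError("record shorter than one day")
    x = x[: days * bpd].reshape(days, bpd)
    with np.errstate(invalid="ignore"):
        day_mean = np.nanmean(x, axis=0)
    return np.roll(day_mean, _zt_bin_offset(record))


def daily_profile(
    records: Sequence[ActigraphyRecord],
    variable: Variable = "activity",
    bin_minutes: int = 5,
) -> DailyProfile:
    """Group daily profile: across-animal mean and SEM of per-animal means."""
    if len(records) < 2:
        raise ValueError("SEM needs at least 2 animals")
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError(f"records span more than one group: {sorted(groups)}")
    coarse = [rebin(r, bin_minutes) for r in records]
    bpd = coarse[0].bins_per_day
    if any(c.bins_per_day != bpd for c in coarse):
        raise ValueError("records do not share a bin grid")
    per_animal = np.vstack([per_animal_daily_mean(c, variable) for c in coarse])
    mean = per_animal.mean(axis=0)
    sem = per_animal.std(axis=0, ddof=1) / math.sqrt(len(records))
    return DailyProfile(
        variable=variable,
        bin_minutes=bin_minutes,
        group=groups.pop(),
        bin_start_zt=np.arange(bpd) * bin_minutes / 60.0,
        mean=mean,
        sem=sem,
        n_animals=len(records),
    )


def align_to_transition(
    records: Sequence[ActigraphyRecord],
    event: Literal["lights_off", "lights_on"] = "lights_off",
    window_minutes: tuple[float, float] = (60.0, 360.0),
    bin_minutes: int = 15,
    variable: Variable = "activity",
) -> ResponseMatrix:
    """Average each animal around every occurrence of a light transition.

    ``window_minutes = (pre, post)`` spans ``[-pre, +post)`` around the
    event; bin 0 is the first bin after the event instant.  Only event
    occurrences whose full window lies inside the record are used.  DD
    records have no transitions and are rejected.
    """
    pre_min, post_min = window_minutes
    bs = bin_minutes * 60
    n_pre = int(round(pre_min * 60 / bs))
    n_post = int(round(post_min * 60 / bs))
    if n_pre * bs != pre_min * 60 or n_post * bs != post_min * 60:
        raise ValueError("window must be a whole number of bins")
    rows = []
    ids = []
    for rec in records:
        if rec.schedule.cycle_kind != "LD":
            raise ValueError(f"{rec.animal_id}: no light transitions in a DD schedule")
        coarse = rebin(rec, bin_minutes)
        x = _series(coarse, variable)
        trans = [t for t in rec.schedule.transitions(0.0, rec.duration_s) if t.kind == event]
        segs = []
        for tr in trans:
            i0 = tr.t_s / bs
            if abs(i0 - round(i0)) > 1e-9:
                raise ValueError("transition not aligned to the bin grid")
            i0 = int(round(i0))
            if i0 - n_pre < 0 or i0 + n_post > coarse.n_bins:
                continue
            segs.append(x[i0 - n_pre : i0 + n_post])
        if not segs:
            raise ValueError(f"{rec.animal_id}: no complete event windows in record")
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(np.vstack(segs), axis=0))
        ids.append(rec.animal_id)
    return ResponseMatrix(
        event=event,
        variable=variable,
        bin_minutes=bin_minutes,
        rel_bin_start_min=(np.arange(-n_pre, n_post) * bin_minutes).astype(float),
        animal_ids=ids,
        values=np.vstack(rows),
    )


def per_bin_compare(
    matrix_a: ResponseMatrix,
    matrix_b: ResponseMatrix,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-tailed two-sample t-test per relative bin, Holm adjustment alongside.

    Units of inference are animals (rows of each matrix).  Bins where both
    groups have zero variance and equal means are flagged degenerate (p is
    NaN there) and excluded from the Holm family.
    """
    if not np.array_equal(matrix_a.rel_bin_start_min, matrix_b.rel_bin_start_min):
        raise ValueError("matrices are on different relative grids")
    if matrix_a.values.shape[0] < 2 or matrix_b.values.shape[0] < 2:
        raise ValueError("need at least 2 animals per group")
    rows = []
    for j, rel in enumerate(matrix_a.rel_bin_start_min):
        a = matrix_a.values[:, j]
        b = matrix_b.values[:, j]
        res = students_t(a, b, welch=welch)
        degenerate = res.degenerate and a.mean() == b.mean()
        rows.append(
            {
                "rel_min": float(rel),
                "mean_a": float(a.mean()),
                "sem_a": float(a.std(ddof=1) / math.sqrt(len(a))),
                "mean_b": float(b.mean()),
                "sem_b": float(b.std(ddof=1) / math.sqrt(len(b))),
                "t": float("nan") if degenerate else res.statistic,
                "df": res.df,
                "p_raw": float("nan") if degenerate else res.p_two_sided,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    df["p_holm"] = np.nan
    ok = ~df["p_raw"].isna()
    if ok.any():
        df.loc[ok, "p_holm"] = holm_adjust(df.loc[ok, "p_raw"].to_numpy())
    return df


def onset_latency(
    record: ActigraphyRecord,
    threshold_frac: float = 0.5,
    bin_minutes: int = 15,
) -> tuple[float, int, int]:
    """Mean lights-off response latency of one animal, in minutes.

    Per day: minutes from lights-off to the start of the first dark-phase
    bin whose activity reaches ``threshold_frac`` times that day's dark-phase
    mean.  Days with no crossing (or an all-zero dark phase) are flagged and
    excluded.  Returns ``(mean_latency_min, n_days_used, n_days_flagged)``;
    the mean is NaN when no day yields a latency.
    """
    if record.schedule.cycle_kind != "LD":
        raise ValueError("latency is defined for LD schedules only")
    if not 0.0 <= threshold_frac <= 1.0:
        raise ValueError("threshold_frac must lie in [0, 1]")
    coarse = rebin(record, bin_minutes)
    x = np.asarray(coarse.activity, dtype=float)
    bs = coarse.bin_seconds
    sch = record.schedule
    offs = [t.t_s for t in sch.transitions(0.0, record.duration_s) if t.kind == "lights_off"]
    ons = [t.t_s for t in sch.transitions(0.0, record.duration_s + SECONDS_PER_DAY)
           if t.kind == "lights_on"]
    latencies = []
    flagged = 0
    for t_off in offs:
        t_on = next((t for t in ons if t > t_off), None)
        if t_on is None:
            continue
        i0 = int(round(t_off / bs))
        i1 = min(int(round(t_on / bs)), coarse.n_bins)
        if i1 <= i0:
            continue
        dark = x[i0:i1]
        dark_mean = dark.mean()
        if dark_mean <= 0:
            flagged += 1
            continue
        hits = np.flatnonzero(dark >= threshold_frac * dark_mean)
        if hits.size == 0:
            flagged += 1
            continue
        latencies.append(hits[0] * bin_minutes)
    mean_lat = float(np.mean(latencies)) if latencies else float("nan")
    return mean_lat, len(latencies), flagged
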