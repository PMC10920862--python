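"""Circadian phase markers from moving-average crossings.

Per zeitgeber day the module locates four phase markers on the activity
series:

* **onset** — first time, within a ZT6-to-ZT6-next-day search window, at
  which the short (3-h) centered moving average rises above the long (24-h)
  centered moving average;
* **offset** — first subsequent downward crossing;
* **midpoint** — earliest time at which cumulative activity from onset
  reaches half the total over a fixed span (16 h by default) anchored at
  onset;
* **peak** — earliest maximum of the 1-h moving average within
  [onset, offset].

Alpha, the active-phase duration, is offset minus onset.  Offsets may exceed
ZT24 when the active phase crosses the ZT-day boundary; the carryover scale
is kept (never wrapped) so per-animal means stay on a linear scale.  All
windows are centered; positions whose full window falls outside the record
are undefined, so the first and last half-day of a record carry no markers.

DD records are analysed in the same frozen ZT frame (the schedule keeps the
last LD anchor), so markers drift by 24 - tau hours per day and remain
comparable as clock times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ActigraphyRecord

__all__ = ["MarkerOptions", "PhaseMarkers", "moving_average", "detect_markers", "summarize_markers"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerOptions:
    """Windows (hours) for the moving-average phase analysis."""

    window_long: float = 24.0
    window_onset: float = 3.0
    window_peak: float = 1.0
    midpoint_span: float = 16.0
    search_start_zt: float = 6.0
    search_end_zt: float = 30.0
    invert_crossing: bool = False  # flip which average must exceed which at onset

    def __post_init__(self) -> None:
        if self.window_onset >= self.window_long:
            raise ValueError("window_onset must be shorter than window_long")
        if self.midpoint_span > 24.0 or self.midpoint_span <= 0:
            raise ValueError("midpoint_span must lie in (0, 24] hours")
        if self.search_end_zt - self.search_start_zt < 12.0:
            raise ValueError("search window must span at least one expected active phase")


@dataclass
class PhaseMarkers:
    """Markers for one animal-day; times are ZT hours with carryover past 24."""

    day_index: int
    onset_zt: float = float("nan")
    offset_zt: float = float("nan")
    midpoint_zt: float = float("nan")
    peak_zt: float = float("nan")
    valid: bool = False

    @property
    def alpha(self) -> float:
        return self.offset_zt - self.onset_zt


def moving_average(series: np.ndarray, window_h: float, bin_seconds: int) -> np.ndarray:
    """Centered moving average; undefined (NaN) where the window is partial.

    The window of ``w`` bins centered at bin ``i`` covers bins
    ``[i - w//2, i - w//2 + w)``; no wrap-around, no partial windows.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(window_h * 3600.0 / bin_seconds))
    if w < 1:
        raise ValueError("window shorter than one bin")
    if len(x) < w:
        raise ValueError(f"series of {len(x)} bins shorter than {w}-bin window")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    means = (csum[w:] - csum[:-w]) / w  # window starting at bin j, j = 0..n-w
    out = np.full(len(x), np.nan)
    lo = w // 2
    out[lo : lo + len(means)] = means
    return out


def _zt_to_bin(record: ActigraphyRecord, zt_h: float) -> float:
    """Fractional bin index at absolute ZT hour (ZT-with-carryover from start)."""
    t_s = (zt_h - record.schedule.anchor_zt_at_start) * 3600.0
    return t_s / record.bin_seconds


def _bin_to_zt(record: ActigraphyRecord, i: int) -> float:
    return record.schedule.anchor_zt_at_start + i * record.bin_seconds / 3600.0


def detect_markers(
    record: ActigraphyRecord, opts: MarkerOptions = MarkerOptions()
) -> list[PhaseMarkers]:
    """Detect per-day onset/offset/midpoint/peak markers on one record.

    The crossing time is the start time of the first bin on the new side of
    the two moving averages.  Days whose search window is not fully covered
    by all three moving averages are skipped; days with no crossing are
    returned with ``valid=False``.  The midpoint is NaN when the 16-h span
    runs off the record end.
    """
    act = np.asarray(record.activity, dtype=float)
    bs = record.bin_seconds
    n = record.n_bins
    ma_long = moving_average(act, opts.window_long, bs)
    ma_short = moving_average(act, opts.window_onset, bs)
    ma_peak = moving_average(act, opts.window_peak, bs)

    if opts.invert_crossing:
        ma_short, ma_long = ma_long, ma_short

    above = ma_short > ma_long
    defined = ~(np.isnan(ma_short) | np.isnan(ma_long))

    span_bins = int(round(opts.midpoint_span * 3600.0 / bs))
    out: list[PhaseMarkers] = []
    total_days = record.duration_s // 86400
    for day in range(total_days):
        lo_f = _zt_to_bin(record, 24.0 * day + opts.search_start_zt)
        hi_f = _zt_to_bin(record, 24.0 * day + opts.search_end_zt)
        lo, hi = int(np.ceil(lo_f)), int(np.floor(hi_f))
        if lo < 1 or hi > n or not defined[max(lo - 1, 0) : hi].all():
            continue  # window not fully evaluable (record edges)
        mk = PhaseMarkers(day_index=day)

        onset_i = None
        for i in range(lo, hi):
            if above[i] and not above[i - 1]:
                onset_i = i
                break
        if onset_i is None:
            out.append(mk)
            continue
        offset_i = None
        for i in range(onset_i + 1, hi):
            if not above[i] and above[i - 1]:
                offset_i = i
                break
        if offset_i is None:
            out.append(mk)
            continue

        mk.onset_zt = _bin_to_zt(record, onset_i) - 24.0 * day
        mk.offset_zt = _bin_to_zt(record, offset_i) - 24.0 * day
        mk.valid = 0.0 < mk.alpha < 24.0

        # midpoint: earliest bin where cumulative activity from onset reaches
        # half the total over [onset, onset + span)
        if onset_i + span_bins <= n:
            seg = act[onset_i : onset_i + span_bins]
            csum = np.cumsum(seg)
            half = csum[-1] / 2.0
            if csum[-1] > 0:
                u = int(np.argmax(csum >= half))
                mk.midpoint_zt = _bin_to_zt(record, onset_i + u) - 24.0 * day

        # peak: earliest maximum of the 1-h moving average within [onset, offset]
        pk = ma_peak[onset_i : offset_i + 1]
        if np.isfinite(pk).any():
            rel = int(np.nanargmax(pk))
            mk.peak_zt = _bin_to_zt(record, onset_i + rel) - 24.0 * day
        out.append(mk)
    return out


def summarize_markers(
    markers_by_animal: dict[str, list[PhaseMarkers]],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-animal means of each marker across valid days.

    Means are taken on the ZT-with-carryover scale (offsets past 24 are kept
    as-is, never wrapped through 0).  Animals with zero valid days are
    excluded with a logged warning.  Columns: animal_id, group, n_days,
    onset_zt, offset_zt, midpoint_zt, peak_zt, alpha_h.
    """
    rows = []
    for animal_id, marks in markers_by_animal.items():
        valid = [m for m in marks if m.valid]
        if not valid:
            log.warning("animal %s: no valid marker days; excluded from summary", animal_id)
            continue
        mids = [m.midpoint_zt for m in valid if np.isfinite(m.midpoint_zt)]
        rows.append(
            {
                "animal_id": animal_id,
                "group": (groups or {}).get(animal_id, ""),
                "n_days": len(valid),
                "onset_zt": float(np.mean([m.onset_zt for m in valid])),
                "offset_zt": float(np.mean([m.offset_zt for m in valid])),
                "midpoint_zt": float(np.mean(mids)) if mids else float("nan"),
                "peak_zt": float(np.mean([m.peak_zt for m in valid])),
                "alpha_h": float(np.mean([m.alpha for m in valid])),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "group", "n_days",
            "onset_zt", "offset_zt", "midpoint_zt", "peak_zt", "alpha_h",
        ],
    )
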