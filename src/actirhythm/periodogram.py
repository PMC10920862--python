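"""Free-running circadian period estimation by FFT.

The spectral resolution of a 13-day record is coarse near 24 h (about
1.8 h), far coarser than physiologically meaningful period differences of a
few minutes.  Sub-bin localisation therefore combines heavy zero padding
(default 64x) with quadratic interpolation of log power over the discrete
peak and its two neighbours — a deterministic, standard estimator whose
accuracy is validated against known-period simulations.

Defaults: mean detrending, Hann taper (suppresses leakage from the strong
harmonic structure of square-ish activity profiles), search band 20-28 h,
activity channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as _signal

from .records import ActigraphyRecord

__all__ = ["PeriodEstimate", "power_spectrum", "estimate_period"]


@dataclass(frozen=True)
class PeriodEstimate:
    """Dominant circadian period and the settings that produced it."""

    period_h: float
    peak_power: float
    band: tuple[float, float]
    n_bins_used: int
    detrend: str
    window: str
    oversample: int
    interpolated: bool
    edge_peak: bool = False


def power_spectrum(
    record: ActigraphyRecord,
    detrend: Literal["mean", "linear"] = "mean",
    taper: Literal["none", "hann"] = "hann",
    oversample: int = 1,
    channel: Literal["activity", "temperature"] = "activity",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of the (detrended, tapered, zero-padded) series.

    Returns ``(freq, power)`` with frequency in cycles/hour and power the
    squared modulus of the DFT.  The zero-frequency bin is returned but is
    excluded from any downstream peak search.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    x = np.asarray(
        record.activity if channel == "activity" else record.temperature, dtype=float
    )
    if np.isnan(x).any():
        raise ValueError(f"{channel} series contains missing values")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 bins")
    if detrend == "mean":
        x = x - x.mean()
    elif detrend == "linear":
        x = _signal.detrend(x, type="linear")
    else:
        raise ValueError(f"unknown detrend {detrend!r}")
    if taper == "hann":
        x = x * _signal.windows.hann(n, sym=False)
    elif taper != "none":
        raise ValueError(f"unknown taper {taper!r}")
    n_fft = int(oversample) * n
    X = np.fft.rfft(x, n_fft)
    power = np.abs(X) ** 2
    freq = np.fft.rfftfreq(n_fft, d=record.bin_seconds / 3600.0)
    return freq, power


def estimate_period(
    record: ActigraphyRecord,
    band: tuple[float, float] = (20.0, 28.0),
    detrend: Literal["mean", "linear"] = "mean",
    taper: Literal["none", "hann"] = "hann",
    oversample: int = 64,
    channel: Literal["activity", "temperature"] = "activity",
) -> PeriodEstimate:
    """Free-running period: band-limited spectral peak with quadratic refinement.

    The maximal power on the oversampled grid within ``band`` (hours) is
    refined by fitting a parabola to log power at the peak and its two grid
    neighbours; the estimate is 1 / (refined frequency).  A peak on a band
    edge is flagged, not an error.  Raises when the whole band carries
    negligible power (< 1e-9 of total) — no circadian periodicity.
    """
    band_min, band_max = band
    if band_min <= 0 or band_min >= band_max:
        raise ValueError("band must satisfy 0 < min < max")
    if record.duration_s / 3600.0 < 3 * band_max:
        raise ValueError("record must cover at least 3 cycles of the longest band period")
    freq, power = power_spectrum(record, detrend, taper, oversample, channel)
    in_band = (freq > 0) & (freq >= 1.0 / band_max) & (freq <= 1.0 / band_min)
    if not in_band.any():
        raise ValueError("frequency grid has no points in the search band")
    total = power[1:].sum()
    idx = np.flatnonzero(in_band)
    k = idx[np.argmax(power[idx])]
    if total <= 0 or power[k] < 1e-9 * total:
        raise ValueError("no circadian periodicity: band power below floor")

    edge = k in (idx[0], idx[-1])
    interpolated = False
    f_hat = freq[k]
    if not edge and 0 < k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = np.log(power[k - 1]), np.log(power[k]), np.log(power[k + 1])
        denom = la - 2.0 * lb + lc
        if denom < 0:  # genuine local max in log power
            delta = 0.5 * (la - lc) / denom
            f_hat = freq[k] + delta * (freq[1] - freq[0])
            interpolated = True

    return PeriodEstimate(
        period_h=1.0 / f_hat,
        peak_power=float(power[k]),
        band=(band_min, band_max),
        n_bins_used=record.n_bins,
        detrend=detrend,
        window=taper,
        oversample=int(oversample),
        interpolated=interpolated,
        edge_peak=bool(edge),
    )
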