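"""The per-animal actigraphy container shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lightcycle import LightSchedule

__all__ = ["ActigraphyRecord"]

SECONDS_PER_DAY = 86400


@dataclass
class ActigraphyRecord:
    """One animal's equally spaced activity-count and body-temperature series.

    Activity is non-negative integer counts per bin (the telemetry unit is
    abstract); temperature is degrees Celsius, with missing samples stored
    as NaN — never as zero.  Bins tile the day: ``bin_seconds`` must divide
    86,400.  A bin covers ``[t_s, t_s + bin_seconds)`` with ``t_s`` measured
    from recording start.
    """

    animal_id: str
    group: str
    bin_seconds: int
    activity: np.ndarray
    temperature: np.ndarray
    schedule: LightSchedule

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.bin_seconds <= 0 or SECONDS_PER_DAY % self.bin_seconds != 0:
            raise ValueError(
                f"bin_seconds must be a positive divisor of 86400, got {self.bin_seconds}"
            )
        if self.activity.ndim != 1 or self.temperature.ndim != 1:
            raise ValueError("activity and temperature must be 1-D")
        if len(self.activity) != len(self.temperature):
            raise ValueError("activity and temperature must have equal length")
        if not np.issubdtype(self.activity.dtype, np.integer):
            as_int = np.asarray(self.activity)
            if not np.all(as_int == np.round(as_int)):
                raise ValueError("activity counts must be integral")
            self.activity = as_int.astype(np.int64)
        if np.any(self.activity < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.activity)

    @property
    def bins_per_day(self) -> int:
        return SECONDS_PER_DAY // self.bin_seconds

    @property
    def duration_s(self) -> int:
        return self.n_bins * self.bin_seconds

    @property
    def t_s(self) -> np.ndarray:
        """Bin start times, seconds since recording start."""
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_seconds

    def equals(self, other: "ActigraphyRecord") -> bool:
        """Bit-identical content comparison (NaN-aware on temperature)."""
        return (
            self.animal_id == other.animal_id
            and self.group == other.group
            and self.bin_seconds == other.bin_seconds
            and self.n_bins == other.n_bins
            and bool(np.array_equal(self.activity, other.activity))
            and bool(np.array_equal(self.temperature, other.temperature, equal_nan=True))
        )
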