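"""Lighting protocol model: zeitgeber time, light state, and transition times.

Zeitgeber time (ZT) is anchored to the light cycle: ZT0 is lights-on and,
under the standard 12:12 light-dark (LD) cycle, ZT12 is lights-off.  A
recording is described by the ZT at its first sample (``anchor_zt_at_start``)
plus the cycle kind: LD (entrained) or DD (constant darkness, the
free-running condition).  All internal time is seconds since recording
start; ZT appears only at presentation boundaries.

Intervals are half-open ``[lights_on, lights_off)``: the lights-off instant
itself belongs to the dark phase, so a transition-aligned bin 0 is the first
dark bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = ["LightSchedule", "Transition", "LD_DEFAULT", "DD_DEFAULT"]

CycleKind = Literal["LD", "DD"]


@dataclass(frozen=True)
class Transition:
    """One lighting boundary: the time (s) and which way the lights went."""

    t_s: float
    kind: Literal["lights_off", "lights_on"]


@dataclass(frozen=True)
class LightSchedule:
    """LD/DD cycle definition mapping recording time to ZT and light state.

    Parameters
    ----------
    cycle_kind : {"LD", "DD"}
        Entrained light-dark cycle or constant darkness.  For DD schedules
        ZT remains defined (frozen from the last LD anchor) so phase markers
        stay comparable as clock times.
    cycle_length_h : float
        Length of one zeitgeber day in hours (24 by convention).
    lights_off_zt : float
        ZT of lights-off; lights-on is ZT0 by convention.
    anchor_zt_at_start : float
        ZT at recording time t = 0.
    dd_start_s : float
        Recording time (s) from which the lights stay off permanently.
        Only meaningful for DD schedules; defaults to 0 (dark throughout).
    """

    cycle_kind: CycleKind = "LD"
    cycle_length_h: float = 24.0
    lights_off_zt: float = 12.0
    anchor_zt_at_start: float = 0.0
    dd_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_kind not in ("LD", "DD"):
            raise ValueError(f"cycle_kind must be 'LD' or 'DD', got {self.cycle_kind!r}")
        if self.cycle_length_h <= 0:
            raise ValueError("cycle_length_h must be positive")
        if not 0.0 <= self.lights_off_zt < self.cycle_length_h:
            raise ValueError(
                f"lights_off_zt must lie in [0, {self.cycle_length_h}), got {self.lights_off_zt}"
            )
        if self.dd_start_s < 0:
            raise ValueError("dd_start_s must be non-negative")

    # ------------------------------------------------------------------ #

    def zt_of(self, t_s: float) -> float:
        """ZT hours in ``[0, cycle_length_h)`` at recording time ``t_s`` seconds.

        Periodic with the cycle length; a recording anchored at lights-on
        maps t = 0 to ZT0 and t = 12 h to ZT12 under the 12:12 default.
        """
        if t_s < 0:
            raise ValueError(f"t_s must be non-negative, got {t_s}")
        return (self.anchor_zt_at_start + t_s / 3600.0) % self.cycle_length_h

    def light_state(self, t_s: float) -> Literal["light", "dark"]:
        """Light state at ``t_s``; half-open convention [on, off)."""
        if self.cycle_kind == "DD" and t_s >= self.dd_start_s:
            return "dark"
        zt = self.zt_of(t_s)
        return "light" if zt < self.lights_off_zt else "dark"

    def is_light(self, t_s) -> "np.ndarray":
        """Vectorized light_state: boolean array, True where lights are on."""
        import numpy as np

        t = np.asarray(t_s, dtype=float)
        if np.any(t < 0):
            raise ValueError("t_s must be non-negative")
        zt = (self.anchor_zt_at_start + t / 3600.0) % self.cycle_length_h
        lit = zt < self.lights_off_zt
        if self.cycle_kind == "DD":
            lit &= t < self.dd_start_s
        return lit

    def transitions(self, t0_s: float, t1_s: float) -> list[Transition]:
        """All lighting boundaries in the half-open span ``(t0_s, t1_s)``.

        A boundary coinciding with either span endpoint is excluded: a 48-h
        LD span anchored at ZT0 yields exactly lights_off@12h, lights_on@24h,
        lights_off@36h.  Ordered in time, each typed lights_off/lights_on;
        DD spans (beyond ``dd_start_s``) have none.
        """
        if t0_s >= t1_s:
            raise ValueError("span must satisfy t0 < t1")
        if self.cycle_kind == "DD":
            t1_s = min(t1_s, self.dd_start_s)
            if t0_s >= t1_s:
                return []
        period = self.cycle_length_h * 3600.0
        out: list[Transition] = []
        # boundary ZTs within one cycle: lights_on at ZT0, lights_off at lights_off_zt
        for zt_b, kind in ((0.0, "lights_on"), (self.lights_off_zt, "lights_off")):
            # recording times where zt_of(t) == zt_b:
            # t = (zt_b - anchor) mod cycle + k*cycle   (hours -> seconds)
            first = ((zt_b - self.anchor_zt_at_start) % self.cycle_length_h) * 3600.0
            t = first
            while t <= t0_s:
                t += period
            while t < t1_s:
                out.append(Transition(t_s=t, kind=kind))
                t += period
        out.sort(key=lambda tr: tr.t_s)
        return out


LD_DEFAULT = LightSchedule(cycle_kind="LD")
DD_DEFAULT = LightSchedule(cycle_kind="DD")
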