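"""Reading and writing the actigraphy CSV dialect, cohort manifest, and result tables.

Actigraphy CSV dialect (one file per animal)::

    animal_id,t_s,activity,temp_c
    wt_01,0,5,36.21
    wt_01,300,7,36.25

``t_s`` is integer seconds since recording start at the bin start; a bin
covers ``[t_s, t_s + bin_seconds)``.  Activity is a non-negative integer and
must form a complete uniform grid — a dropped bin is a format error, not
missing data.  A missing temperature is an empty cell, never 0.

All writers are byte-deterministic for fixed inputs; floats are written with
6 significant digits and JSON keys are sorted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lightcycle import LightSchedule
from .records import SECONDS_PER_DAY, ActigraphyRecord

__all__ = [
    "FormatError",
    "ManifestRow",
    "CohortManifest",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "load_cohort",
    "write_table",
    "write_json_report",
]

RECORD_HEADER = "animal_id,t_s,activity,temp_c"
MANIFEST_HEADER = "animal_id,group,file,cycle,lights_off_zt,anchor_zt_at_start,dd_start_s"


class FormatError(ValueError):
    """A file violates the dialect; the message names the offending row."""


def _fmt(x: float) -> str:
    """6-significant-digit float formatting; empty string for NaN."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}"


def _fmt_rt(x: float) -> str:
    """Shortest exact round-trip float formatting; empty string for NaN.

    Raw telemetry values must survive write -> read bit-identically, so the
    per-animal record writer does not truncate precision.
    """
    if math.isnan(x):
        return ""
    return repr(x)


# --------------------------------------------------------------------- #
# per-animal records

def write_record(record: ActigraphyRecord, path: str | Path) -> None:
    """Write one animal's record in the actigraphy CSV dialect."""
    lines = [RECORD_HEADER]
    t = record.t_s
    for i in range(record.n_bins):
        lines.append(
            f"{record.animal_id},{t[i]},{record.activity[i]},{_fmt_rt(float(record.temperature[i]))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_record(
    path: str | Path,
    schedule: LightSchedule | None = None,
    group: str = "",
) -> ActigraphyRecord:
    """Read and validate one actigraphy CSV file.

    Rejects: unknown headers, non-integer or negative activity, gaps or
    irregular spacing in ``t_s``, multiple animal ids in one file.  Row
    numbers in error messages are 1-based counting the header as row 1.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
    if header != RECORD_HEADER:
        raise FormatError(f"{path}: unknown header {header!r} (expected {RECORD_HEADER!r})")
    df = pd.read_csv(
        path, dtype={"animal_id": str, "t_s": str, "activity": str, "temp_c": str},
        keep_default_na=False,
    )
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    ids = df["animal_id"].unique()
    if len(ids) != 1:
        raise FormatError(f"{path}: more than one animal_id in file: {list(ids)}")

    def _bad_row(col: str, mask: np.ndarray, why: str) -> FormatError:
        row = int(np.flatnonzero(mask)[0]) + 2  # +1 header, +1 one-based
        return FormatError(f"{path}: row {row}: {why} in column {col!r}")

    for col in ("t_s", "activity"):
        vals = df[col].str.strip()
        ok = vals.str.fullmatch(r"[+-]?\d+").fillna(False).to_numpy()
        if not ok.all():
            raise _bad_row(col, ~ok, "non-integer value")
    t_s = df["t_s"].astype(np.int64).to_numpy()
    activity = df["activity"].astype(np.int64).to_numpy()
    if (activity < 0).any():
        raise _bad_row("activity", activity < 0, "negative count")
    if t_s[0] != 0:
        raise FormatError(f"{path}: row 2: t_s must start at 0, got {t_s[0]}")
    if len(t_s) > 1:
        steps = np.diff(t_s)
        bin_seconds = int(steps[0])
        bad = steps != bin_seconds
        if bin_seconds <= 0:
            raise FormatError(f"{path}: row 3: non-increasing t_s")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 3
            raise FormatError(f"{path}: row {row}: gap or irregular spacing in t_s")
    else:
        bin_seconds = 300
    if SECONDS_PER_DAY % bin_seconds != 0:
        raise FormatError(f"{path}: bin width {bin_seconds}s does not divide the day")

    temp_raw = df["temp_c"].str.strip()
    temperature = np.full(len(df), np.nan)
    nonempty = (temp_raw != "").to_numpy()
    if nonempty.any():
        try:
            temperature[nonempty] = temp_raw[nonempty].astype(float).to_numpy()
        except ValueError:
            ok = temp_raw.str.fullmatch(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?") | (temp_raw == "")
            raise _bad_row("temp_c", ~ok.to_numpy(), "unparseable temperature")

    return ActigraphyRecord(
        animal_id=str(ids[0]),
        group=group,
        bin_seconds=bin_seconds,
        activity=activity,
        temperature=temperature,
        schedule=schedule if schedule is not None else LightSchedule(),
    )


# --------------------------------------------------------------------- #
# cohort manifest

@dataclass(frozen=True)
class ManifestRow:
    animal_id: str
    group: str
    file: str
    cycle: str
    lights_off_zt: float = 12.0
    anchor_zt_at_start: float = 0.0
    dd_start_s: float | None = None

    def schedule(self) -> LightSchedule:
        return LightSchedule(
            cycle_kind=self.cycle,  # type: ignore[arg-type]
            lights_off_zt=self.lights_off_zt,
            anchor_zt_at_start=self.anchor_zt_at_start,
            dd_start_s=0.0 if self.dd_start_s is None else self.dd_start_s,
        )


@dataclass
class CohortManifest:
    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate animal_id in manifest: {dup}")
        for r in self.rows:
            if not r.group:
                raise FormatError(f"animal {r.animal_id!r}: empty group label")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.group not in seen:
                seen.append(r.group)
        return seen


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    lines = [MANIFEST_HEADER]
    for r in manifest.rows:
        dd = "" if r.dd_start_s is None else _fmt(float(r.dd_start_s))
        lines.append(
            f"{r.animal_id},{r.group},{r.file},{r.cycle},"
            f"{_fmt(r.lights_off_zt)},{_fmt(r.anchor_zt_at_start)},{dd}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
    if header != MANIFEST_HEADER:
        raise FormatError(f"{path}: unknown header {header!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows: list[ManifestRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        rownum = i + 2
        cycle = rec["cycle"].strip()
        if cycle not in ("LD", "DD"):
            raise FormatError(f"{path}: row {rownum}: cycle must be LD or DD, got {cycle!r}")
        try:
            rows.append(
                ManifestRow(
                    animal_id=rec["animal_id"].strip(),
                    group=rec["group"].strip(),
                    file=rec["file"].strip(),
                    cycle=cycle,
                    lights_off_zt=float(rec["lights_off_zt"] or 12.0),
                    anchor_zt_at_start=float(rec["anchor_zt_at_start"] or 0.0),
                    dd_start_s=float(rec["dd_start_s"]) if rec["dd_start_s"].strip() else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {rownum}: {exc}") from exc
    return CohortManifest(rows=rows)


def write_cohort(
    records: Sequence[ActigraphyRecord], out_dir: str | Path
) -> tuple[CohortManifest, Path]:
    """Write one CSV per record plus ``manifest.csv``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.animal_id}.csv"
        write_record(rec, out_dir / fname)
        sch = rec.schedule
        rows.append(
            ManifestRow(
                animal_id=rec.animal_id,
                group=rec.group,
                file=fname,
                cycle=sch.cycle_kind,
                lights_off_zt=sch.lights_off_zt,
                anchor_zt_at_start=sch.anchor_zt_at_start,
                dd_start_s=sch.dd_start_s if sch.cycle_kind == "DD" else None,
            )
        )
    manifest = CohortManifest(rows=rows)
    mpath = out_dir / "manifest.csv"
    write_manifest(manifest, mpath)
    return manifest, mpath


def load_cohort(manifest_path: str | Path) -> list[ActigraphyRecord]:
    """Load every record referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    records = []
    for row in manifest.rows:
        fpath = manifest_path.parent / row.file
        if not fpath.exists():
            raise FormatError(f"manifest references missing file {fpath}")
        rec = read_record(fpath, schedule=row.schedule(), group=row.group)
        if rec.animal_id != row.animal_id:
            raise FormatError(
                f"{fpath}: animal_id {rec.animal_id!r} does not match manifest {row.animal_id!r}"
            )
        records.append(rec)
    return records


# --------------------------------------------------------------------- #
# result tables and report

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer for result tables (6 significant digits)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False, lineterminator="\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else float(f"{f:.6g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json_report(report: Mapping[str, Any], path: str | Path) -> None:
    """JSON report with sorted keys and 6-significant-digit floats."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
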