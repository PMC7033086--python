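"""Containers and plain-text I/O for PET time-activity data.

All times are minutes internally; activities are kBq/ml and assumed
decay-corrected to the start of the first scan.  A tissue density of
1 g/ml is assumed throughout, so kBq/ml and kBq/g are interchangeable.

File dialects (TSV or CSV, sniffed from the delimiter):

* TAC table   — columns ``start_s`` (or ``start_min``), ``end_s``/``end_min``,
  then one activity column per volume of interest (VOI).
* blood table — columns ``time_min`` (or ``time_s``),
  ``whole_blood_kBq_ml``, ``plasma_kBq_ml``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ScheduleError",
    "FrameSchedule",
    "TissueTAC",
    "BloodSampleSeries",
    "StudyConfig",
    "frame_midpoints",
    "read_tac_table",
    "write_tac_table",
    "read_blood_samples",
    "write_blood_samples",
    "write_results",
]


class ValidationError(ValueError):
    """Raised when input data violate a container invariant."""


class ScheduleError(ValidationError):
    """Raised for inconsistent frame timing (overlap, non-monotone starts)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of a dynamic PET acquisition: frame starts and durations in minutes."""

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self):
        starts = _as_float_array(self.frame_starts, "frame_starts")
        durs = _as_float_array(self.frame_durations, "frame_durations")
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.size == 0:
            raise ScheduleError("schedule needs at least one frame")
        if starts.size != durs.size:
            raise ScheduleError("frame_starts and frame_durations differ in length")
        if np.any(durs <= 0):
            raise ScheduleError("frame durations must be positive")
        if np.any(starts < 0):
            raise ScheduleError("frame starts must be non-negative")
        if np.any(np.diff(starts) <= 0):
            raise ScheduleError("frame starts must be strictly increasing")
        ends = starts + durs
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ScheduleError("frames overlap")

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    @classmethod
    def uniform(cls, n_frames: int, duration_s: float, gap_s: float) -> "FrameSchedule":
        """Back-to-back frames of equal duration separated by a fixed gap (inputs in seconds)."""
        period = (duration_s + gap_s) / 60.0
        starts = np.arange(n_frames) * period
        durs = np.full(n_frames, duration_s / 60.0)
        return cls(starts, durs)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Mid-frame times in minutes; frame values are timestamped at these points."""
    return schedule.midpoints


@dataclass(frozen=True)
class TissueTAC:
    """One VOI's decay-corrected time-activity curve C(t), one value per frame."""

    voi_name: str
    schedule: FrameSchedule
    activity: np.ndarray  # kBq/ml

    def __post_init__(self):
        act = _as_float_array(self.activity, "activity")
        object.__setattr__(self, "activity", act)
        if act.size != self.schedule.n_frames:
            raise ValidationError(
                f"VOI {self.voi_name!r}: {act.size} activity values for "
                f"{self.schedule.n_frames} frames"
            )
        if np.any(act < 0):
            raise ValidationError(f"VOI {self.voi_name!r}: negative activity")

    @property
    def times(self) -> np.ndarray:
        return self.schedule.midpoints


@dataclass(frozen=True)
class BloodSampleSeries:
    """Well-counter blood samples: whole-blood and plasma activity vs time.

    A sample at t = 0 is the pre-injection background; it is stored but
    excluded from clearance fits (it is zero by construction).
    """

    sample_times: np.ndarray  # min
    whole_blood: np.ndarray  # kBq/ml
    plasma: np.ndarray  # kBq/ml

    def __post_init__(self):
        t = _as_float_array(self.sample_times, "sample_times")
        wb = _as_float_array(self.whole_blood, "whole_blood")
        pl = _as_float_array(self.plasma, "plasma")
        for name, arr in (("whole_blood", wb), ("plasma", pl)):
            if arr.size != t.size:
                raise ValidationError(f"{name} length does not match sample_times")
            if np.any(arr < 0):
                raise ValidationError(f"{name} has negative activity")
        if np.any(t < 0):
            raise ValidationError("sample times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must be strictly increasing (no duplicates)")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "whole_blood", wb)
        object.__setattr__(self, "plasma", pl)

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    def post_injection(self) -> "BloodSampleSeries":
        """Drop the t = 0 background row, if present."""
        mask = self.sample_times > 0
        if mask.all():
            return self
        return BloodSampleSeries(
            self.sample_times[mask], self.whole_blood[mask], self.plasma[mask]
        )


@dataclass(frozen=True)
class StudyConfig:
    """Tracer/protocol constants used by metabolite correction and boron scaling.

    Defaults are the FBPA study values: mean injected tracer mass 0.00102 g,
    specific radioactivity 4.41e10 kBq/mol (44.1 GBq/mmol), blood metabolite
    fractions 2.324% at 20 min and 3.966% at 50 min, therapeutic
    BPA-fructose dose 30 g, molecular weights FBPA 226.9, BPA-fructose 389.3
    and boron-10 10 g/mol.
    """

    injected_dose_g: float = 0.00102
    specific_activity_kBq_mol: float = 4.41e10
    metabolite_fractions: tuple = ((20.0, 0.02324), (50.0, 0.03966))
    therapeutic_dose_g: float = 30.0
    mw_boron: float = 10.0
    mw_fbpa: float = 226.9
    mw_bpa: float = 389.3

    def __post_init__(self):
        for name in ("injected_dose_g", "specific_activity_kBq_mol",
                     "therapeutic_dose_g", "mw_boron", "mw_fbpa", "mw_bpa"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if len(self.metabolite_fractions) < 1:
            raise ValidationError("need at least one metabolite fraction measurement")
        for t, f in self.metabolite_fractions:
            if t < 0:
                raise ValidationError("metabolite measurement time must be non-negative")
            if not (0 <= f < 1):
                raise ValidationError("metabolite fractions must lie in [0, 1)")


# ---------------------------------------------------------------------------
# file I/O


def _read_table(source) -> pd.DataFrame:
    """Read a TSV/CSV table; the delimiter is sniffed from the header line.

    Floats are parsed with the round-trip parser so write/read cycles are
    value-exact.
    """
    if isinstance(source, (str, os.PathLike)):
        if not os.path.exists(source):
            raise FileNotFoundError(f"input table not found: {source}")
        with open(source) as fh:
            header = fh.readline()
    else:
        header = source.readline()
        source.seek(0)
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(source, sep=sep, float_precision="round_trip")


def _time_column(columns, base: str):
    """Locate ``<base>_s`` / ``<base>_min`` and return (name, scale-to-minutes)."""
    for suffix, scale in (("_min", 1.0), ("_s", 1.0 / 60.0)):
        name = base + suffix
        if name in columns:
            return name, scale
    raise ValidationError(f"missing required column {base}_s or {base}_min")


def read_tac_table(source) -> dict[str, TissueTAC]:
    """Read a frame-wise TAC table into one :class:`TissueTAC` per VOI column."""
    df = _read_table(source)
    start_col, s_scale = _time_column(df.columns, "start")
    end_col, e_scale = _time_column(df.columns, "end")
    starts = df[start_col].to_numpy(float) * s_scale
    ends = df[end_col].to_numpy(float) * e_scale
    schedule = FrameSchedule(starts, ends - starts)
    voi_cols = [c for c in df.columns if c not in (start_col, end_col)]
    if not voi_cols:
        raise ValidationError("TAC table has no VOI columns")
    tacs: dict[str, TissueTAC] = {}
    for voi in voi_cols:
        col = df[voi]
        if col.isna().any():
            raise ValidationError(f"VOI column {voi!r} has missing values")
        tacs[voi] = TissueTAC(voi, schedule, col.to_numpy(float))
    return tacs


def write_tac_table(tacs: dict[str, TissueTAC], path, unit: str = "s") -> None:
    """Write TACs sharing one schedule; inverse of :func:`read_tac_table`."""
    items = list(tacs.values())
    schedule = items[0].schedule
    for t in items[1:]:
        if not (np.array_equal(t.schedule.frame_starts, schedule.frame_starts)
                and np.array_equal(t.schedule.frame_durations, schedule.frame_durations)):
            raise ValidationError("all TACs in one table must share a schedule")
    scale = 60.0 if unit == "s" else 1.0
    data = {
        f"start_{unit}": schedule.frame_starts * scale,
        f"end_{unit}": schedule.frame_ends * scale,
    }
    for t in items:
        data[t.voi_name] = t.activity
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_blood_samples(source) -> BloodSampleSeries:
    """Read a blood sample table (time, whole-blood and plasma activity)."""
    df = _read_table(source)
    time_col, scale = _time_column(df.columns, "time")
    for required in ("whole_blood_kBq_ml", "plasma_kBq_ml"):
        if required not in df.columns:
            raise ValidationError(f"missing required column {required!r}")
    return BloodSampleSeries(
        df[time_col].to_numpy(float) * scale,
        df["whole_blood_kBq_ml"].to_numpy(float),
        df["plasma_kBq_ml"].to_numpy(float),
    )


def write_blood_samples(series: BloodSampleSeries, path) -> None:
    pd.DataFrame(
        {
            "time_min": series.sample_times,
            "whole_blood_kBq_ml": series.whole_blood,
            "plasma_kBq_ml": series.plasma,
        }
    ).to_csv(path, sep="\t", index=False)


def write_results(df: pd.DataFrame, path) -> None:
    """Write a tidy result table (one row per VOI × model) as CSV."""
    df.to_csv(path, index=False)
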