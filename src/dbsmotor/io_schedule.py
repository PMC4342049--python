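"""Reading, validation and 1-second gridding of cage position recordings and
experiment schedules.

The home-cage monitor reports the animal's (x, y) position only when it
changes, at irregular times ranging from milliseconds to many seconds apart.
All downstream analysis runs on a regular 1-second grid, so the raw event
trace is interpolated onto integer seconds t = 1..N.  The default
interpolation is a zero-order hold (last observed position carried forward):
the monitor records *changes*, so the absence of an event means the animal
held its position.  Linear interpolation is available for sensitivity checks.

Time convention: 1-based integer seconds; windows are half-open [t, t+w).
Coordinates: centimeters, origin at one cage corner, axes parallel to the
walls (this makes wall-parallel movement exactly axis-aligned).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

SECONDS_PER_DAY = 86_400
#: default length of one light or dark phase (12 h)
PHASE_LENGTH_S = 43_200
#: canonical stimulation design: 10-min epochs every 3 h, first onset at 90 min
STIM_DURATION_S = 600
STIM_SPACING_S = 10_800
FIRST_ONSET_S = 5_400
CANONICAL_AMPERAGES = (75.0, 100.0, 125.0)
CANONICAL_FREQUENCIES = (50.0, 125.0, 175.0, 225.0)


class TraceParseError(ValueError):
    """Malformed row in a position file (message names the offending line)."""


class TraceValidationError(ValueError):
    """Structurally invalid trace (non-monotone time, non-finite values...)."""


class ScheduleValidationError(ValueError):
    """Inconsistent stimulation schedule (overlaps, bad durations...)."""


@dataclass(frozen=True)
class RawEventTrace:
    """Irregular position events: times (s) with cage coordinates (cm)."""

    event_times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or t.size < 2:
            raise TraceValidationError("trace needs at least 2 events")
        if x.shape != t.shape or y.shape != t.shape:
            raise TraceValidationError("time/x/y length mismatch")
        if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(t).all()):
            raise TraceValidationError("non-finite values in trace")
        if (t < 0).any():
            raise TraceValidationError("negative event times")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise TraceValidationError(
                f"event times not strictly increasing at row {bad[0] + 2}"
            )

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.event_times[0]), float(self.event_times[-1])


@dataclass
class TrajectoryRecording:
    """Positions on the complete 1-s grid t = 1..N, plus the light/dark clock.

    ``lights_on_s`` is the second at which the first phase starts (0 means the
    recording begins exactly at a phase boundary); phases alternate every
    ``phase_length_s`` seconds starting with ``starts_with``.
    """

    x: np.ndarray
    y: np.ndarray
    lights_on_s: int = 0
    phase_length_s: int = PHASE_LENGTH_S
    starts_with: str = "light"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise TraceValidationError("x/y must be equal-length 1-D arrays")
        if self.starts_with not in ("light", "dark"):
            raise ValueError("starts_with must be 'light' or 'dark'")

    @property
    def n_seconds(self) -> int:
        return int(self.x.size)

    @property
    def t(self) -> np.ndarray:
        """1-based second indices."""
        return np.arange(1, self.n_seconds + 1)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def is_light(self) -> np.ndarray:
        """Boolean per-second light indicator."""
        phase_idx = (self.t - 1 - self.lights_on_s) // self.phase_length_s
        even = phase_idx % 2 == 0
        return even if self.starts_with == "light" else ~even

    def day(self) -> np.ndarray:
        """1-based day index per second."""
        return (self.t - 1) // SECONDS_PER_DAY + 1


@dataclass
class StimulationSchedule:
    """Stimulation onsets (1-based seconds) with per-day amperage and
    per-interval frequency labels.  Intervals are [onset, onset+duration)."""

    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    duration_s: int = STIM_DURATION_S
    amperage_by_day: Sequence[float] = CANONICAL_AMPERAGES
    frequency_by_interval: Sequence[float] = ()

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.duration_s <= 0:
            raise ScheduleValidationError("duration must be positive")
        if self.onsets.size and (np.diff(self.onsets) < self.duration_s).any():
            raise ScheduleValidationError("stimulation intervals overlap")
        if len(self.frequency_by_interval) not in (0, self.n_stim):
            raise ScheduleValidationError(
                "frequency_by_interval must be empty or one entry per onset"
            )

    @property
    def n_stim(self) -> int:
        return int(self.onsets.size)

    def interval(self, k: int) -> tuple[int, int]:
        """Half-open [start, end) seconds of the k-th (0-based) interval."""
        s = int(self.onsets[k])
        return s, s + self.duration_s

    def amperage(self, k: int) -> float:
        day = (int(self.onsets[k]) - 1) // SECONDS_PER_DAY
        return float(self.amperage_by_day[min(day, len(self.amperage_by_day) - 1)])

    def frequency(self, k: int) -> float:
        if not len(self.frequency_by_interval):
            return float("nan")
        return float(self.frequency_by_interval[k])

    def phase(self, k: int, rec: TrajectoryRecording) -> str:
        return "light" if rec.is_light()[int(self.onsets[k]) - 1] else "dark"

    def mask(self, n_seconds: int, pad_after_s: int = 0) -> np.ndarray:
        """Boolean per-second mask of stimulated (plus padded) seconds."""
        m = np.zeros(n_seconds, dtype=bool)
        for k in range(self.n_stim):
            s, e = self.interval(k)
            m[s - 1 : min(e + pad_after_s, n_seconds + 1) - 1] = True
        return m


# ---------------------------------------------------------------------------
# Position file I/O
# ---------------------------------------------------------------------------

def read_trace(path: str | Path, delimiter: str | None = None) -> RawEventTrace:
    """Read a plain-text position file with columns time_s, x, y.

    Accepts CSV or TSV (sniffed unless ``delimiter`` is given) and tolerates
    a ``time`` column name alias.  Raises :class:`TraceParseError` naming the
    offending line for malformed rows, :class:`TraceValidationError` for
    non-monotone time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python")
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise TraceParseError(f"{path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    tcol = cols.get("time_s") or cols.get("time")
    if tcol is None or "x" not in cols or "y" not in cols:
        raise TraceParseError(f"{path}: expected columns time_s,x,y; got {list(df.columns)}")
    sub = df[[tcol, cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce")
    bad = np.nonzero(sub.isna().any(axis=1).to_numpy())[0]
    if bad.size:
        raise TraceParseError(f"{path}: malformed row at line {bad[0] + 2}")
    return RawEventTrace(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy(), sub.iloc[:, 2].to_numpy())


def write_trace(path: str | Path, trace: RawEventTrace) -> None:
    pd.DataFrame({"time_s": trace.event_times, "x": trace.x, "y": trace.y}).to_csv(
        path, index=False
    )


def interpolate_to_grid(
    trace: RawEventTrace,
    n_seconds: int,
    rule: str = "zoh",
    lights_on_s: int = 0,
    phase_length_s: int = PHASE_LENGTH_S,
    starts_with: str = "light",
) -> TrajectoryRecording:
    """Place a raw event trace on the integer-second grid t = 1..n_seconds.

    ``rule='zoh'`` (default) carries the last observed position forward;
    ``rule='linear'`` interpolates linearly between events.  Grid points
    before the first event take the first event's position; a grid that
    extends beyond the last event is a range error.
    """
    if n_seconds < 1:
        raise ValueError("n_seconds must be >= 1")
    t0, t_last = trace.span
    if n_seconds > t_last:
        raise ValueError(
            f"grid of {n_seconds}s extends beyond trace span ending at {t_last}s"
        )
    grid = np.arange(1, n_seconds + 1, dtype=float)
    if rule == "zoh":
        idx = np.searchsorted(trace.event_times, grid, side="right") - 1
        idx = np.clip(idx, 0, trace.n_events - 1)
        gx, gy = trace.x[idx], trace.y[idx]
    elif rule == "linear":
        gx = np.interp(grid, trace.event_times, trace.x)
        gy = np.interp(grid, trace.event_times, trace.y)
    else:
        raise ValueError(f"unknown interpolation rule {rule!r}")
    return TrajectoryRecording(
        gx, gy, lights_on_s=lights_on_s, phase_length_s=phase_length_s,
        starts_with=starts_with,
    )


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def canonical_schedule(
    n_days: int = 3,
    n_seconds: int | None = None,
    first_onset_s: int = FIRST_ONSET_S,
    spacing_s: int = STIM_SPACING_S,
    duration_s: int = STIM_DURATION_S,
    amperage_by_day: Sequence[float] = CANONICAL_AMPERAGES,
    frequencies: Sequence[float] = CANONICAL_FREQUENCIES,
) -> StimulationSchedule:
    """The canonical design: 8 stimulations/day every 3 h (4 light, 4 dark),
    one amperage per day, frequencies cycling per interval.  Intervals that
    do not fit completely inside ``n_seconds`` are dropped (a recording cut
    short mid-interval loses that interval)."""
    n_per_day = SECONDS_PER_DAY // spacing_s
    onsets = first_onset_s + spacing_s * np.arange(n_per_day * n_days)
    if n_seconds is not None:
        onsets = onsets[onsets + duration_s <= n_seconds]  # 1-based final second
    freq = [float(frequencies[k % len(frequencies)]) for k in range(onsets.size)]
    return StimulationSchedule(
        onsets=onsets + 1,  # 1-based grid seconds
        duration_s=duration_s,
        amperage_by_day=tuple(float(a) for a in amperage_by_day),
        frequency_by_interval=freq,
    )


def read_schedules(path: str | Path) -> tuple[StimulationSchedule, dict]:
    """Read a YAML/JSON schedule config.

    Keys: either ``canonical_design: {n_days, n_seconds}`` or explicit
    ``stim_onsets_s``; plus ``duration_s``, ``amperage_uA_by_day``,
    ``frequency_hz_by_interval``, ``lights_on_s``, ``phase_length_s``.
    Returns the stimulation schedule and the light/dark assignment dict.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    lightdark = {
        "lights_on_s": int(cfg.get("lights_on_s", 0)),
        "phase_length_s": int(cfg.get("phase_length_s", PHASE_LENGTH_S)),
        "starts_with": str(cfg.get("starts_with", "light")),
    }
    duration = int(cfg.get("duration_s", STIM_DURATION_S))
    amperage = tuple(cfg.get("amperage_uA_by_day", CANONICAL_AMPERAGES))
    if "canonical_design" in cfg and cfg["canonical_design"]:
        canon = cfg["canonical_design"]
        if canon is True:
            canon = {}
        sched = canonical_schedule(
            n_days=int(canon.get("n_days", 3)),
            n_seconds=canon.get("n_seconds"),
            duration_s=duration,
            amperage_by_day=amperage,
            frequencies=tuple(cfg.get("frequencies_hz", CANONICAL_FREQUENCIES)),
        )
    else:
        onsets = np.asarray(cfg.get("stim_onsets_s", []), dtype=int)
        sched = StimulationSchedule(
            onsets=onsets,
            duration_s=duration,
            amperage_by_day=amperage,
            frequency_by_interval=list(cfg.get("frequency_hz_by_interval", [])),
        )
    return sched, lightdark


def write_schedules(
    path: str | Path, schedule: StimulationSchedule, lightdark: dict | None = None
) -> None:
    cfg = {
        "stim_onsets_s": [int(s) for s in schedule.onsets],
        "duration_s": int(schedule.duration_s),
        "amperage_uA_by_day": [float(a) for a in schedule.amperage_by_day],
        "frequency_hz_by_interval": [float(f) for f in schedule.frequency_by_interval],
    }
    cfg.update(lightdark or {})
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
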