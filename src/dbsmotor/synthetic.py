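"""Doubly stochastic home-cage trajectory simulator.

Mouse movement is bursty: random bouts of movement of random lengths,
interspersed with quiescence.  The simulator realizes this as a two-state
semi-Markov process on the 1-second grid.  Quiescent seconds end with a
burst onset at a phase-dependent rate; a burst is either a wall-parallel
run (axis-aligned velocity, so its direction angles are exact multiples of
pi/2) or an interior excursion (a correlated random walk whose heading
diffuses, giving two-dimensional movement).  Burst durations are lognormal
by default (heavy-ish tails; exponential selectable), per-second step sizes
are gamma, and the cage walls reflect.  Light and dark phases differ in
burst-onset rate and in the share of bursts that are two-dimensional - the
circadian structure the analysis is designed to detect.  During stimulation
intervals the 2-D burst-onset rate (and optionally the 2-D step size) is
multiplied by a per-(amperage, frequency) factor, with an optional synergy
term for designated cells; the 1-D burst process is untouched.

Positions are reported only when they change, which is exactly what the
home-cage monitor does, so the event trace exercises the gridding path.
Every second carries a ground-truth state label (0 quiescent, 1 in a 1-D
burst, 2 in a 2-D burst) aligned to the analysis grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_schedule import (
    CANONICAL_AMPERAGES,
    CANONICAL_FREQUENCIES,
    PHASE_LENGTH_S,
    SECONDS_PER_DAY,
    RawEventTrace,
    StimulationSchedule,
    TrajectoryRecording,
    canonical_schedule,
)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cage model.

    Rates are per second; speeds and coordinates in cm.  Defaults encode a
    nocturnal animal: bursts arrive more often in dark and are mostly
    interior (2-D) there, while 1-D wall-running arrives at the same rate in
    both phases (onset_rate * (1 - p_2d) is matched across phases).
    """

    seed: int = 0
    cage_width_cm: float = 36.0
    cage_height_cm: float = 20.0
    n_days: int = 3
    n_seconds: int | None = None  # overrides n_days when set
    phase_length_s: int = PHASE_LENGTH_S
    starts_with: str = "light"
    lights_on_s: int = 0
    onset_rate: dict = field(default_factory=lambda: {"light": 0.01521, "dark": 0.03655})
    p_2d: dict = field(default_factory=lambda: {"light": 0.1667, "dark": 0.4444})
    duration_dist: str = "lognormal"  # or "exponential"
    duration_median_s: dict = field(default_factory=lambda: {"1d": 8.0, "2d": 12.0})
    duration_sigma: dict = field(default_factory=lambda: {"1d": 0.6, "2d": 0.6})
    speed_shape: float = 2.0
    speed_scale: dict = field(default_factory=lambda: {"1d": 1.0, "2d": 1.5})
    turn_sd_rad: float = 0.5
    #: post-burst quiescent dead time; longer than the 30-s classification
    #: window so two bursts never share a window (keeps ID labels exact)
    refractory_s: int = 35
    #: deceleration profile on the final steps of every burst: bouts stop by
    #: slowing down, so the terminal step (whose forward window sees a single
    #: segment and is therefore classed 1-D) carries negligible speed
    end_taper: tuple = (0.6, 0.3, 0.05)
    canonical_stim: bool = True
    stim_onsets_s: list | None = None
    stim_duration_s: int = 600
    amperage_by_day: tuple = CANONICAL_AMPERAGES
    frequencies: tuple = CANONICAL_FREQUENCIES
    #: 2-D burst-onset-rate multiplier per (amperage, frequency) cell
    stim_rate_multiplier: dict = field(default_factory=dict)
    #: 2-D per-second step-size multiplier per cell (default 1 everywhere)
    stim_speed_multiplier: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for phase in ("light", "dark"):
            if self.onset_rate[phase] < 0:
                raise ValueError("onset rates must be nonnegative")
            if not 0.0 <= self.p_2d[phase] <= 1.0:
                raise ValueError("p_2d must lie in [0, 1]")
        if self.refractory_s < 0:
            raise ValueError("refractory must be nonnegative")
        mean_step = self.speed_shape * max(self.speed_scale.values())
        if mean_step * 4 > min(self.cage_width_cm, self.cage_height_cm):
            raise ValueError(
                "cage too small for the step distribution: mean step "
                f"{mean_step:.1f} cm vs cage {self.cage_width_cm}x{self.cage_height_cm}"
            )

    @property
    def total_seconds(self) -> int:
        return int(self.n_seconds if self.n_seconds is not None
                   else self.n_days * SECONDS_PER_DAY)

    def mean_duration_s(self, kind: str) -> float:
        med = self.duration_median_s[kind]
        if self.duration_dist == "lognormal":
            return med * math.exp(self.duration_sigma[kind] ** 2 / 2.0)
        return med

    def expected_occupancy(self, phase: str, kind: str) -> float:
        """Expected fraction of non-stimulated ``phase`` seconds spent in
        bursts of ``kind``, from the renewal-cycle structure (geometric wait,
        burst duration, refractory dead time)."""
        lam = self.onset_rate[phase]
        if lam <= 0:
            return 0.0
        p2 = self.p_2d[phase]
        q = 1.0 - math.exp(-lam)
        mean_dur = p2 * self.mean_duration_s("2d") + (1 - p2) * self.mean_duration_s("1d")
        cycle = (1.0 / q - 1.0) + mean_dur + self.refractory_s
        p_kind = p2 if kind == "2d" else 1.0 - p2
        return p_kind * self.mean_duration_s(kind) / cycle

    def rate_multiplier(self, amperage: float, frequency: float) -> float:
        return float(self.stim_rate_multiplier.get((amperage, frequency), 1.0))

    def speed_multiplier(self, amperage: float, frequency: float) -> float:
        return float(self.stim_speed_multiplier.get((amperage, frequency), 1.0))

    def build_schedule(self) -> StimulationSchedule:
        if self.stim_onsets_s is not None:
            n_int = len(self.stim_onsets_s)
            freq = [float(self.frequencies[k % len(self.frequencies)])
                    for k in range(n_int)]
            return StimulationSchedule(
                onsets=np.asarray(self.stim_onsets_s, dtype=int),
                duration_s=self.stim_duration_s,
                amperage_by_day=self.amperage_by_day,
                frequency_by_interval=freq,
            )
        if self.canonical_stim:
            return canonical_schedule(
                n_days=self.n_days, n_seconds=self.total_seconds,
                duration_s=self.stim_duration_s,
                amperage_by_day=self.amperage_by_day,
                frequencies=self.frequencies,
            )
        return StimulationSchedule(onsets=np.array([], dtype=int),
                                   duration_s=self.stim_duration_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stim_rate_multiplier"] = [
            [a, f, m] for (a, f), m in self.stim_rate_multiplier.items()
        ]
        d["stim_speed_multiplier"] = [
            [a, f, m] for (a, f), m in self.stim_speed_multiplier.items()
        ]
        d["amperage_by_day"] = list(self.amperage_by_day)
        d["frequencies"] = list(self.frequencies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("stim_rate_multiplier", "stim_speed_multiplier"):
            if key in d and isinstance(d[key], list):
                d[key] = {(float(a), float(f)): float(m) for a, f, m in d[key]}
        for key in ("amperage_by_day", "frequencies", "end_taper"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationResult:
    trace: RawEventTrace
    recording: TrajectoryRecording
    schedule: StimulationSchedule
    labels: np.ndarray  # int8 per second: 0 quiescent, 1/2 burst type
    config: SimulationConfig


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    v = np.mod(u - lo, 2 * span)
    return lo + span - np.abs(v - span)


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the cage model; bit-reproducible for a given seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.total_seconds
    if n < 2:
        raise ValueError("need at least 2 seconds to simulate")
    w_cm, h_cm = config.cage_width_cm, config.cage_height_cm
    schedule = config.build_schedule()

    # per-second light indicator on the 1..n grid
    t0 = np.arange(n)
    phase_idx = (t0 - config.lights_on_s) // config.phase_length_s
    is_light = (phase_idx % 2 == 0) == (config.starts_with == "light")

    lam1 = np.where(is_light,
                    config.onset_rate["light"] * (1 - config.p_2d["light"]),
                    config.onset_rate["dark"] * (1 - config.p_2d["dark"]))
    lam2 = np.where(is_light,
                    config.onset_rate["light"] * config.p_2d["light"],
                    config.onset_rate["dark"] * config.p_2d["dark"])
    speed_mult = np.ones(n)
    for k in range(schedule.n_stim):
        s, e = schedule.interval(k)
        amp, freq = schedule.amperage(k), schedule.frequency(k)
        lam2[s - 1 : e - 1] *= config.rate_multiplier(amp, freq)
        speed_mult[s - 1 : e - 1] = config.speed_multiplier(amp, freq)

    lam_tot = lam1 + lam2
    p_onset = 1.0 - np.exp(-lam_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_2d_given_onset = np.where(lam_tot > 0, lam2 / lam_tot, 0.0)
    hits = np.nonzero(rng.random(n) < p_onset)[0]
    hits = hits[hits <= n - 2]  # a burst needs at least one step

    x = np.empty(n)
    y = np.empty(n)
    labels = np.zeros(n, dtype=np.int8)
    cur_x, cur_y = w_cm / 2.0, h_cm / 2.0
    x[0], y[0] = cur_x, cur_y
    filled = 0  # highest filled position index

    def draw_duration(kind: str) -> int:
        med = config.duration_median_s[kind]
        if config.duration_dist == "lognormal":
            d = rng.lognormal(mean=math.log(med), sigma=config.duration_sigma[kind])
        elif config.duration_dist == "exponential":
            d = rng.exponential(med)
        else:
            raise ValueError("duration_dist must be 'lognormal' or 'exponential'")
        return max(1, int(round(d)))

    i = 0  # next step index (0-based; step i moves position i -> i+1)
    while i <= n - 2:
        j = np.searchsorted(hits, i)
        if j >= hits.size:
            break
        h = int(hits[j])
        # quiescent run: positions i+1..h stay put
        if h + 1 > filled + 1:
            x[filled + 1 : h + 1] = cur_x
            y[filled + 1 : h + 1] = cur_y
        two_d = rng.random() < p_2d_given_onset[h]
        dur = min(draw_duration("2d" if two_d else "1d"), n - 1 - h)
        taper = np.asarray(config.end_taper, dtype=float)[max(0, len(config.end_taper) - dur):]
        if two_d:
            steps = rng.gamma(config.speed_shape, config.speed_scale["2d"], dur)
            steps[dur - taper.size:] *= taper
            steps = steps * speed_mult[h : h + dur]
            heading = rng.uniform(-np.pi, np.pi) + np.cumsum(
                rng.normal(0.0, config.turn_sd_rad, dur)
            )
            px = _fold(cur_x + np.cumsum(steps * np.cos(heading)), 0.0, w_cm)
            py = _fold(cur_y + np.cumsum(steps * np.sin(heading)), 0.0, h_cm)
        else:
            steps = rng.gamma(config.speed_shape, config.speed_scale["1d"], dur)
            steps[dur - taper.size:] *= taper
            direction = -1.0 if rng.random() < 0.5 else 1.0
            axis_path = np.cumsum(direction * steps)
            if rng.random() < 0.5:  # run parallel to the x walls
                px = _fold(cur_x + axis_path, 0.0, w_cm)
                py = np.full(dur, cur_y)
            else:
                px = np.full(dur, cur_x)
                py = _fold(cur_y + axis_path, 0.0, h_cm)
        x[h + 1 : h + 1 + dur] = px
        y[h + 1 : h + 1 + dur] = py
        labels[h : h + dur] = 2 if two_d else 1
        cur_x, cur_y = float(px[-1]), float(py[-1])
        filled = h + dur
        i = h + dur + config.refractory_s
    if filled < n - 1:
        x[filled + 1 :] = cur_x
        y[filled + 1 :] = cur_y

    recording = TrajectoryRecording(
        x, y, lights_on_s=config.lights_on_s,
        phase_length_s=config.phase_length_s, starts_with=config.starts_with,
    )
    # the monitor reports positions only when they change
    changed = np.concatenate([[True], (np.diff(x) != 0) | (np.diff(y) != 0)])
    changed[-1] = True  # close the trace so the grid span is covered
    times = np.nonzero(changed)[0] + 1.0
    trace = RawEventTrace(times, x[changed], y[changed])
    return SimulationResult(
        trace=trace, recording=recording, schedule=schedule, labels=labels,
        config=config,
    )


def make_null_config(
    seed: int = 0, n_days: int = 3, phase_symmetric: bool = False, **overrides
) -> SimulationConfig:
    """No-stimulation-effect configuration for type-I-error suites: the
    canonical schedule runs but every rate multiplier is 1.  With
    ``phase_symmetric`` the light and dark parameters are identical."""
    cfg = dict(seed=seed, n_days=n_days)
    if phase_symmetric:
        cfg["onset_rate"] = {"light": 0.005, "dark": 0.005}
        cfg["p_2d"] = {"light": 0.5, "dark": 0.5}
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def make_effect_config(
    seed: int = 0,
    n_days: int = 3,
    amp_rate_effect: dict | None = None,
    amp_speed_effect: dict | None = None,
    freq_speed_effect: dict | None = None,
    synergy: dict | None = None,
    effect_scale: float = 1.0,
    **overrides,
) -> SimulationConfig:
    """Graded stimulation-effect configuration for power/recovery suites.

    Amperage gates arousal: the 2-D burst-onset rate is multiplied by
    1 + effect_scale * amp_rate_effect (frequency-independent), so the 75-uA
    baseline (effect 0) is indistinguishable from no stimulation.  Response
    magnitude is graded through the per-second 2-D step size, whose
    multiplier is 1 + effect_scale*(amp_speed + freq_speed + synergy) on
    active cells - additive on the scale mean activity responds to linearly,
    so the injected synergy cell is what an additive-prediction screen
    should recover.  ``effect_scale`` scales every injected effect jointly
    (0 reproduces the null configuration).
    """
    amp_rate_effect = (
        {75.0: 0.0, 100.0: 5.0, 125.0: 8.0}
        if amp_rate_effect is None else amp_rate_effect
    )
    amp_speed_effect = (
        {75.0: 0.0, 100.0: 0.3, 125.0: 0.6}
        if amp_speed_effect is None else amp_speed_effect
    )
    freq_speed_effect = (
        {50.0: 0.0, 125.0: 0.25, 175.0: 0.25, 225.0: 0.25}
        if freq_speed_effect is None else freq_speed_effect
    )
    synergy = {(125.0, 125.0): 2.0} if synergy is None else synergy
    rate_mult, speed_mult = {}, {}
    for a, ra in amp_rate_effect.items():
        for f in freq_speed_effect:
            cell = (float(a), float(f))
            rate_mult[cell] = 1.0 + effect_scale * ra
            if ra > 0:
                speed_mult[cell] = 1.0 + effect_scale * (
                    amp_speed_effect[a] + freq_speed_effect[f] + synergy.get((a, f), 0.0)
                )
            else:
                speed_mult[cell] = 1.0
    cfg = dict(seed=seed, n_days=n_days, stim_rate_multiplier=rate_mult,
               stim_speed_multiplier=speed_mult)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# config / output files
# ---------------------------------------------------------------------------

def read_sim_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh) or {})


def write_sim_config(path: str | Path, config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    pd.DataFrame(
        {"t": np.arange(1, labels.size + 1), "state": labels}
    ).to_csv(path, index=False)
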