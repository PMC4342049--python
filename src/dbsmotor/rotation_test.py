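"""Translation-restricted permutation ("rotation") test for stimulation
effect, with FDR thresholding.

Within a stationary segment, unrestricted permutations destroy the time
dependence, so the only permutations that respect stationarity are
translations - rotations when the +-80-minute window around a stimulation
onset is viewed as a circle.  The window statistic (forward mean or
right-minus-left difference of one of the seven motor processes) is
recomputed at every integer-second circular translation; the p-value is the
proportion of translates whose value is at least the observed one (the
observed translate is included, so p >= 1/#translates and a constant window
gives p = 1).  The test is one-sided (greater): the hypothesis is that
stimulation *increases* activity.

Each stimulation interval contributes one null hypothesis per statistic;
evidence is aggregated by step-up false-discovery-rate thresholding
(Benjamini-Hochberg under independence, Benjamini-Yekutieli with the
sum-of-reciprocals constant under dependence).  Baseline 75-uA intervals
form their own family and are excluded from the headline 100/125-uA family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_schedule import StimulationSchedule, TrajectoryRecording
from .motor_processes import (
    DEFAULT_MEAN_WINDOW,
    DEFAULT_RL_WINDOW,
    FRACTION_PROCESSES,
    PROCESS_NAMES,
    MotorProcessSet,
    forward_mean,
    rl_difference,
)

DEFAULT_HALF_WIDTH_S = 80 * 60
STATISTIC_NAMES = ("fwd_mean", "rl_diff")


@dataclass
class RotationTestResult:
    stim_index: int
    statistic_name: str
    observed: float
    null_values: np.ndarray
    p_value: float
    truncated: bool = False


@dataclass
class FDRReport:
    """Step-up FDR decision at level q with threshold function (j/m)(q/cv)."""

    p_values: np.ndarray  # original order
    q: float
    mode: str
    cv: float
    n_significant: int
    significant: np.ndarray  # indices into the original order

    @property
    def m(self) -> int:
        return int(self.p_values.size)

    @property
    def sorted_p(self) -> np.ndarray:
        return np.sort(self.p_values)

    @property
    def thresholds(self) -> np.ndarray:
        j = np.arange(1, self.m + 1)
        return j / self.m * (self.q / self.cv)


def centered_window(
    series: np.ndarray,
    s_k: int,
    half_width_s: int = DEFAULT_HALF_WIDTH_S,
) -> tuple[np.ndarray, int, bool]:
    """Extract the +-half-width window of a per-second process around onset
    second ``s_k`` (1-based).

    Returns (window, offset, truncated): the window covers seconds
    [s_k - hw, s_k + hw) and ``offset`` is the in-window index of s_k.
    Windows clipped by the series boundary are truncated and flagged.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    lo = s_k - half_width_s - 1  # 0-based inclusive
    hi = s_k + half_width_s - 1  # 0-based exclusive
    truncated = lo < 0 or hi > n
    lo_c, hi_c = max(lo, 0), min(hi, n)
    if lo_c >= hi_c:
        raise ValueError(f"onset {s_k} outside the recorded series")
    return series[lo_c:hi_c], (s_k - 1) - lo_c, truncated


def rotation_null(
    window: np.ndarray,
    statistic: str = "fwd_mean",
    w: int | None = None,
    denominator: np.ndarray | None = None,
    offset: int | None = None,
    stim_index: int = 0,
    truncated: bool = False,
) -> RotationTestResult:
    """The translation null: the statistic at every integer-second circular
    translation of the window, with p = #{translates >= observed}/#translates.

    ``denominator`` turns the statistic into a windowed fraction (used for
    the angle-class processes); translates whose denominator window is empty
    are undefined and drop out of the proportion.
    """
    window = np.asarray(window, dtype=float)
    n = window.size
    if statistic not in STATISTIC_NAMES:
        raise ValueError(f"statistic must be one of {STATISTIC_NAMES}")
    if w is None:
        w = DEFAULT_MEAN_WINDOW if statistic == "fwd_mean" else DEFAULT_RL_WINDOW
    if offset is None:
        offset = n // 2
    if statistic == "fwd_mean":
        num = forward_mean(window, w, circular=True)
        if denominator is not None:
            den = forward_mean(np.asarray(denominator, float), w, circular=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                values = np.where(den > 0, num / den, np.nan)
        else:
            values = num
    else:
        if denominator is not None:
            rnum = forward_mean(window, w, circular=True)
            rden = forward_mean(np.asarray(denominator, float), w, circular=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(rden > 0, rnum / rden, np.nan)
            values = frac - np.roll(frac, w)
        else:
            values = rl_difference(window, w, circular=True)
    observed = values[offset]
    valid = np.isfinite(values)
    if not np.isfinite(observed):
        # no moving seconds in the observed window: no evidence either way
        p = 1.0
    else:
        p = float(np.sum(values[valid] >= observed)) / float(valid.sum())
    return RotationTestResult(
        stim_index=stim_index, statistic_name=statistic, observed=float(observed),
        null_values=values, p_value=p, truncated=truncated,
    )


def fdr_threshold(
    p_values, q: float = 0.05, mode: str = "independent"
) -> FDRReport:
    """Step-up FDR: reject the j smallest p-values for the largest j with
    p_(j) <= (j/m)(q/cv); cv = 1 under independence (Benjamini-Hochberg) or
    sum_{i=1}^m 1/i under dependence (Benjamini-Yekutieli)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRReport(p, q, mode, 1.0, 0, np.array([], dtype=int))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "independent":
        cv = 1.0
    elif mode == "correlated":
        cv = float(np.sum(1.0 / np.arange(1, p.size + 1)))
    else:
        raise ValueError("mode must be 'independent' or 'correlated'")
    order = np.argsort(p, kind="stable")
    thresh = np.arange(1, p.size + 1) / p.size * (q / cv)
    passing = np.nonzero(p[order] <= thresh)[0]
    j_star = int(passing[-1]) + 1 if passing.size else 0
    return FDRReport(
        p_values=p, q=q, mode=mode, cv=cv, n_significant=j_star,
        significant=np.sort(order[:j_star]),
    )


@dataclass
class Hypothesis1Result:
    """P-value table (one row per stimulation interval, one column per
    process x statistic) and per-family FDR reports."""

    p_table: pd.DataFrame
    fdr: dict[tuple[str, str], FDRReport] = field(default_factory=dict)

    def columns(self) -> list[str]:
        return [c for c in self.p_table.columns if ":" in c]


def hypothesis1_pipeline(
    processes: MotorProcessSet,
    schedule: StimulationSchedule,
    rec: TrajectoryRecording,
    statistics: tuple[str, ...] = STATISTIC_NAMES,
    process_names: tuple[str, ...] = PROCESS_NAMES,
    w1: int = DEFAULT_MEAN_WINDOW,
    w2: int = DEFAULT_RL_WINDOW,
    half_width_s: int = DEFAULT_HALF_WIDTH_S,
    q: float = 0.05,
    mode: str = "independent",
    baseline_amperage: float = 75.0,
) -> Hypothesis1Result:
    """Rotation test of every stimulation interval against its surrounding
    +-80-minute window, for each motor process and window statistic, followed
    by FDR thresholding.

    The FDR families are 'baseline' (75-uA intervals, reported separately as
    in a placebo arm) and 'headline' (all other amperages combined); an 'all'
    family over every interval is also reported.
    """
    if schedule.n_stim == 0:
        empty = pd.DataFrame()
        return Hypothesis1Result(p_table=empty, fdr={})
    if schedule.n_stim > 1:
        gaps = np.diff(np.sort(schedule.onsets))
        if (gaps < 2 * half_width_s + 1200).any():
            warnings.warn(
                "stimulation onsets closer than window width + 20 min: "
                "test windows overlap, independence across intervals is broken",
                stacklevel=2,
            )

    rows = []
    pcols: dict[str, list[float]] = {
        f"{name}:{stat}": [] for name in process_names for stat in statistics
    }
    for k in range(schedule.n_stim):
        s_k = int(schedule.onsets[k])
        rows.append(
            {
                "stim_index": k,
                "onset_s": s_k,
                "amperage_uA": schedule.amperage(k),
                "frequency_hz": schedule.frequency(k),
                "phase": schedule.phase(k, rec),
            }
        )
        for name in process_names:
            values, den = processes.series(name)
            win, offset, trunc = centered_window(values, s_k, half_width_s)
            dwin = None
            if den is not None:
                dwin, _, _ = centered_window(den, s_k, half_width_s)
            for stat in statistics:
                w = w1 if stat == "fwd_mean" else w2
                res = rotation_null(
                    win, statistic=stat, w=w, denominator=dwin, offset=offset,
                    stim_index=k, truncated=trunc,
                )
                pcols[f"{name}:{stat}"].append(res.p_value)

    table = pd.DataFrame(rows)
    for col, vals in pcols.items():
        table[col] = vals

    is_base = table["amperage_uA"] == baseline_amperage
    families = {
        "baseline": np.nonzero(is_base.to_numpy())[0],
        "headline": np.nonzero(~is_base.to_numpy())[0],
        "all": np.arange(len(table)),
    }
    fdr: dict[tuple[str, str], FDRReport] = {}
    for fam, idx in families.items():
        if idx.size == 0:
            continue
        for col in pcols:
            fdr[(fam, col)] = fdr_threshold(
                table.loc[idx, col].to_numpy(), q=q, mode=mode
            )
    return Hypothesis1Result(p_table=table, fdr=fdr)
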