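"""The seven per-second motor activity processes and their windowed statistics.

From the gridded positions r(t) = (x(t), y(t)) the velocity V(t) = r(t+1) - r(t)
yields the speed M(t) = |V(t)| and direction angle theta(t) in [-pi, pi)
(undefined at rest).  Location is fully recoverable from (M, theta) and the
starting point, so these two processes carry all of the information.

Movement over a forward w = 30 s window is classified as 0-, 1- or 2-dimensional:

* ID = 0 - the animal holds position (all window points coincide);
* ID = 1 - the points are collinear; D1 is the length of the spanned segment
  (extent of the projections onto the total-least-squares line, *not* the
  path length);
* ID = 2 - otherwise; D2 is the area of the convex hull of the points.

Speed splits by dimension class, M(t) = M1D(t) + M2D(t) wherever ID is 1 or 2,
and direction angles split into multiples of pi/2 (wall-parallel, "P") versus
non-multiples ("NP").  The seven processes analysed downstream are, in order:
M1D, D1, theta_P, theta_NP, M, M2D, D2 - the first three are one-dimensional
statistics, the last four carry two-dimensional information.

Two windowed statistics are applied to each process: a forward mean over
w1 = 600 s, and a right-minus-left difference of w2 = 120 s means (a high-pass
filter detecting rapid movement onset).  For the two angle-class indicator
processes the forward statistic is a *fraction* of the moving seconds in the
window, since the angle is undefined at rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import ConvexHull, QhullError

from .io_schedule import TrajectoryRecording

#: the seven motor processes in canonical order
PROCESS_NAMES = ("m1d", "d1", "theta_p", "theta_np", "m", "m2d", "d2")
ONE_DIM_PROCESSES = ("m1d", "d1", "theta_p")
TWO_DIM_PROCESSES = ("theta_np", "m", "m2d", "d2")
#: processes whose windowed statistic is a fraction of moving seconds
FRACTION_PROCESSES = ("theta_p", "theta_np")

DEFAULT_DIM_WINDOW = 30
DEFAULT_MEAN_WINDOW = 600
DEFAULT_RL_WINDOW = 120
DEFAULT_ANGLE_TOL = 1e-9
DEFAULT_COLLINEAR_TOL = 1e-6


class InsufficientDataError(ValueError):
    pass


@dataclass
class MotorProcessSet:
    """Per-second derived processes; arrays are indexed by t-1 for t = 1..N-1.

    ``id_``, ``d1``, ``d2``, ``m1d``, ``m2d`` are only defined where the
    forward w-second window fits (t <= N-w+1); the tail carries ID = -1 / NaN.
    """

    vx: np.ndarray
    vy: np.ndarray
    m: np.ndarray
    theta: np.ndarray  # NaN at rest
    is_p: np.ndarray  # float 0/1, 0 at rest
    is_np: np.ndarray
    moving: np.ndarray  # float 0/1 indicator M > 0
    id_: np.ndarray = field(default=None)  # type: ignore[assignment]
    d1: np.ndarray = field(default=None)  # type: ignore[assignment]
    d2: np.ndarray = field(default=None)  # type: ignore[assignment]
    m1d: np.ndarray = field(default=None)  # type: ignore[assignment]
    m2d: np.ndarray = field(default=None)  # type: ignore[assignment]
    w: int = DEFAULT_DIM_WINDOW

    @property
    def n(self) -> int:
        return int(self.m.size)

    def series(self, name: str) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (values, denominator) for one of the seven processes.

        The denominator is the moving indicator for the angle-class fraction
        processes and None for plain-mean processes.
        """
        if name in FRACTION_PROCESSES:
            return (self.is_p if name == "theta_p" else self.is_np), self.moving
        if name not in PROCESS_NAMES:
            raise KeyError(f"unknown process {name!r}; expected one of {PROCESS_NAMES}")
        return getattr(self, name if name != "m" else "m"), None

    def valid_length(self) -> int:
        """Number of leading seconds on which all seven processes are defined."""
        return int(np.sum(self.id_ >= 0)) if self.id_ is not None else self.n


def velocity_speed_angle(rec: TrajectoryRecording) -> MotorProcessSet:
    """Velocity, speed and direction angle (partial process set)."""
    if rec.n_seconds < 2:
        raise InsufficientDataError("need at least 2 gridded seconds")
    vx = np.diff(rec.x)
    vy = np.diff(rec.y)
    m = np.hypot(vx, vy)
    theta = np.where(m > 0, np.arctan2(vy, vx), np.nan)
    # arctan2 returns pi for (-x, +0); fold onto [-pi, pi) with -pi == pi
    theta = np.where(theta == np.pi, -np.pi, theta)
    moving = (m > 0).astype(float)
    is_p = np.where(m > 0, classify_angle(theta, DEFAULT_ANGLE_TOL), 0.0)
    is_np = moving - is_p
    return MotorProcessSet(vx=vx, vy=vy, m=m, theta=theta, is_p=is_p,
                           is_np=is_np, moving=moving)


def reconstruct_positions(
    m: np.ndarray, theta: np.ndarray, origin: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Rebuild the position path from speed and angle: the reconstruction
    identity r(t) = origin + sum_{j<t} M(j) (cos theta(j), sin theta(j)).

    Rest seconds (M = 0) contribute a zero step regardless of the undefined
    angle; a positive speed with an undefined angle is an inconsistency.
    """
    m = np.asarray(m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if m.shape != theta.shape:
        raise ValueError("m and theta must have equal length")
    bad = (m > 0) & ~np.isfinite(theta)
    if bad.any():
        raise ValueError(f"undefined angle with positive speed at step {np.argmax(bad)}")
    ang = np.where(m > 0, theta, 0.0)
    dx = np.where(m > 0, m * np.cos(ang), 0.0)
    dy = np.where(m > 0, m * np.sin(ang), 0.0)
    x = origin[0] + np.concatenate([[0.0], np.cumsum(dx)])
    y = origin[1] + np.concatenate([[0.0], np.cumsum(dy)])
    return np.column_stack([x, y])


def classify_angle(theta, tol: float = DEFAULT_ANGLE_TOL):
    """True where the angle is a multiple of pi/2 on the circle (P class).

    Distance is measured on the unit circle, so theta = pi (identified with
    -pi) is a multiple.  Works on scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    d = np.abs(np.mod(theta + np.pi / 4, np.pi / 2) - np.pi / 4)
    return (d <= tol).astype(float)


def classify_window_dimension(
    points: np.ndarray, tol_lin: float = DEFAULT_COLLINEAR_TOL
) -> tuple[int, float, float]:
    """Classify one w-point window as (ID, D1, D2).

    ID=0 when all points coincide within ``tol_lin`` (bounding-box diagonal);
    ID=1 when every point lies within ``tol_lin`` of the total-least-squares
    line, with D1 the extent of projections onto that line; ID=2 otherwise,
    with D2 the convex hull area.  Ties break toward the lower dimension:
    a degenerate hull (zero area) is re-classified as 1-D.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("window needs at least 2 points of shape (w, 2)")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if float(np.hypot(*(hi - lo))) <= tol_lin:
        return 0, 0.0, 0.0
    c = pts.mean(axis=0)
    pc = pts - c
    cov = pc.T @ pc
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, 1]  # principal direction
    nrm = evecs[:, 0]  # normal
    max_perp = float(np.abs(pc @ nrm).max())
    proj = pc @ u
    if max_perp <= tol_lin:
        return 1, float(proj.max() - proj.min()), 0.0
    try:
        area = float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        area = 0.0
    if area <= 0.0:
        return 1, float(proj.max() - proj.min()), 0.0
    return 2, 0.0, area


def dimension_processes(
    rec: TrajectoryRecording,
    w: int = DEFAULT_DIM_WINDOW,
    tol_lin: float = DEFAULT_COLLINEAR_TOL,
    base: MotorProcessSet | None = None,
) -> MotorProcessSet:
    """Full process set: dimension classification of every forward w-window
    plus the speed split M1D/M2D.

    Windows where the animal held position or moved exactly parallel to a
    wall are resolved vectorially; the remaining windows go through the exact
    per-window classifier.
    """
    if w < 2:
        raise InsufficientDataError("dimension window must cover >= 2 points")
    ps = base if base is not None else velocity_speed_angle(rec)
    n = ps.n  # = N - 1
    n_win = rec.n_seconds - w + 1
    if n_win < 1:
        raise InsufficientDataError("recording shorter than one dimension window")

    xw = sliding_window_view(rec.x, w)
    yw = sliding_window_view(rec.y, w)
    x_lo = xw.min(axis=1); x_hi = xw.max(axis=1)
    y_lo = yw.min(axis=1); y_hi = yw.max(axis=1)
    ext_x = x_hi - x_lo
    ext_y = y_hi - y_lo

    id_ = np.full(n, -1, dtype=np.int8)
    d1 = np.full(n, np.nan)
    d2 = np.full(n, np.nan)

    still = np.hypot(ext_x, ext_y) <= tol_lin
    horiz = ~still & (ext_y == 0.0)
    vert = ~still & (ext_x == 0.0)
    rest_idx = np.nonzero(~(still | horiz | vert))[0]

    id_[:n_win][still] = 0
    d1[:n_win][still] = 0.0
    d2[:n_win][still] = 0.0
    id_[:n_win][horiz] = 1
    d1[:n_win][horiz] = ext_x[horiz]
    d2[:n_win][horiz] = 0.0
    id_[:n_win][vert] = 1
    d1[:n_win][vert] = ext_y[vert]
    d2[:n_win][vert] = 0.0

    pts_all = rec.positions()
    for i in rest_idx:
        k, l1, a2 = classify_window_dimension(pts_all[i : i + w], tol_lin)
        id_[i], d1[i], d2[i] = k, l1, a2

    m1d = np.where(id_ == 1, ps.m, np.where(id_ >= 0, 0.0, np.nan))
    m2d = np.where(id_ == 2, ps.m, np.where(id_ >= 0, 0.0, np.nan))
    return MotorProcessSet(
        vx=ps.vx, vy=ps.vy, m=ps.m, theta=ps.theta, is_p=ps.is_p,
        is_np=ps.is_np, moving=ps.moving, id_=id_, d1=d1, d2=d2,
        m1d=m1d, m2d=m2d, w=w,
    )


def extract_processes(
    rec: TrajectoryRecording,
    w: int = DEFAULT_DIM_WINDOW,
    tol_lin: float = DEFAULT_COLLINEAR_TOL,
    angle_tol: float = DEFAULT_ANGLE_TOL,
) -> MotorProcessSet:
    """Convenience wrapper: velocity/speed/angle plus dimension processes."""
    ps = velocity_speed_angle(rec)
    if angle_tol != DEFAULT_ANGLE_TOL:
        ps.is_p = np.where(ps.m > 0, classify_angle(ps.theta, angle_tol), 0.0)
        ps.is_np = ps.moving - ps.is_p
    return dimension_processes(rec, w=w, tol_lin=tol_lin, base=ps)


def processes_to_frame(ps: MotorProcessSet) -> "pd.DataFrame":
    """Tabular per-second process file: one row per t, one column per process."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": np.arange(1, ps.n + 1),
            "m": ps.m, "theta": ps.theta, "is_p": ps.is_p, "is_np": ps.is_np,
            "moving": ps.moving, "id": ps.id_, "d1": ps.d1, "d2": ps.d2,
            "m1d": ps.m1d, "m2d": ps.m2d,
        }
    )


def frame_to_processes(df: "pd.DataFrame", w: int = DEFAULT_DIM_WINDOW) -> MotorProcessSet:
    """Rebuild a process set from a per-second process table (velocity
    components are not persisted and come back as NaN)."""
    n = len(df)
    nan = np.full(n, np.nan)
    return MotorProcessSet(
        vx=nan.copy(), vy=nan.copy(),
        m=df["m"].to_numpy(float), theta=df["theta"].to_numpy(float),
        is_p=df["is_p"].to_numpy(float), is_np=df["is_np"].to_numpy(float),
        moving=df["moving"].to_numpy(float),
        id_=df["id"].to_numpy(np.int8), d1=df["d1"].to_numpy(float),
        d2=df["d2"].to_numpy(float), m1d=df["m1d"].to_numpy(float),
        m2d=df["m2d"].to_numpy(float), w=w,
    )


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------

def _sliding_sum(series: np.ndarray, w: int) -> np.ndarray:
    """Sums over [i, i+w) for every valid start i (length n - w + 1)."""
    c = np.concatenate([[0.0], np.cumsum(series, dtype=float)])
    return c[w:] - c[:-w]


def forward_mean(series: np.ndarray, w1: int, circular: bool = False) -> np.ndarray:
    """Mean over the forward window [t, t+w1).

    Returns a full-length array; where the forward window does not fit the
    value is NaN, unless ``circular`` (window wraps around the series end,
    the convention used by the rotation test).
    """
    series = np.asarray(series, dtype=float)
    if w1 <= 0:
        raise ValueError("window width must be positive")
    n = series.size
    if circular:
        ext = np.concatenate([series, series[: w1 - 1]]) if w1 > 1 else series
        return _sliding_sum(ext, w1) / w1
    if n < w1:
        raise ValueError(f"series of length {n} shorter than window {w1}")
    out = np.full(n, np.nan)
    out[: n - w1 + 1] = _sliding_sum(series, w1) / w1
    return out


def forward_fraction(
    numerator: np.ndarray, denominator: np.ndarray, w1: int, circular: bool = False
) -> np.ndarray:
    """Windowed fraction: sum(numerator)/sum(denominator) over [t, t+w1).

    Used for the angle-class processes, where the denominator counts moving
    seconds; windows with no moving seconds are NaN.
    """
    num = forward_mean(numerator, w1, circular=circular)
    den = forward_mean(denominator, w1, circular=circular)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def rl_difference(series: np.ndarray, w2: int, circular: bool = False) -> np.ndarray:
    """Right-minus-left difference of w2-second means: mean over [t, t+w2)
    minus mean over [t-w2, t).  NaN where either side window does not fit
    (unless circular)."""
    series = np.asarray(series, dtype=float)
    if w2 <= 0:
        raise ValueError("window width must be positive")
    n = series.size
    if circular:
        right = forward_mean(series, w2, circular=True)
        return right - np.roll(right, w2)
    if n < 2 * w2:
        raise ValueError(f"series of length {n} shorter than two windows of {w2}")
    sums = _sliding_sum(series, w2)  # sums[i] over [i, i+w2)
    out = np.full(n, np.nan)
    out[w2 : n - w2 + 1] = (sums[w2:] - sums[: sums.size - w2]) / w2
    return out


def activity_decomposition(
    m1d: np.ndarray, m2d: np.ndarray, w1: int = DEFAULT_MEAN_WINDOW
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean Activity and its split into 2-D and 1-D components.

    Returns (A-bar, A-bar-2D, A-bar-1D); A-bar = A-bar-2D + A-bar-1D holds
    pointwise (zero-dimensional movement adds zero).
    """
    m1d = np.asarray(m1d, dtype=float)
    m2d = np.asarray(m2d, dtype=float)
    if m1d.shape != m2d.shape:
        raise ValueError("m1d and m2d must be aligned")
    abar = forward_mean(m1d + m2d, w1)
    return abar, forward_mean(m2d, w1), forward_mean(m1d, w1)
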