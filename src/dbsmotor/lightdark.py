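"""Light versus dark contrasts of 1-D and 2-D mean activity, and the 2-D
movement-fraction comparison.

Each 12-hour phase contributes three 3-hr analysis segments separated by
1 hr (minutes 30-210, 270-450 and 510-690 into the phase), so a canonical
3-day recording yields 18 segments; the +-30 min around every light/dark
transition falls in the separating hours by construction.  Stimulation
intervals and the 20 minutes after each are masked out.  Per segment the
mean of M1D or M2D gets a long-run-variance standard error; segment means
are averaged within each phase, and the dark-minus-light difference Y is
referred to a Gaussian null through z = Y / sqrt(Var(Y)) (justified by the
central limit theorem for stationary mixing means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_schedule import StimulationSchedule, TrajectoryRecording
from .dose_response import longrun_variance
from .rotation_test import FDRReport, fdr_threshold

SEGMENT_OFFSETS_MIN = ((30, 210), (270, 450), (510, 690))
POST_STIM_EXCLUSION_S = 1200


@dataclass
class Segment:
    start_s: int  # 1-based, inclusive
    end_s: int  # exclusive
    phase: str
    day: int
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_seconds(self) -> int:
        return self.end_s - self.start_s

    @property
    def n_usable(self) -> int:
        return int(self.n_seconds - self.excluded.sum())


@dataclass
class SegmentationPlan:
    segments: list[Segment]
    n_seconds: int

    def by_phase(self, phase: str) -> list[Segment]:
        return [s for s in self.segments if s.phase == phase]


@dataclass
class LightDarkContrast:
    dim: str  # '1d' or '2d'
    dark_mean: float
    light_mean: float
    est_var: float
    two_sided: bool = True

    @property
    def y(self) -> float:
        return self.dark_mean - self.light_mean

    @property
    def z(self) -> float:
        return self.y / float(np.sqrt(self.est_var))

    @property
    def p_value(self) -> float:
        if self.two_sided:
            return float(2 * stats.norm.sf(abs(self.z)))
        return float(stats.norm.sf(self.z))


def build_segmentation(
    rec: TrajectoryRecording, schedule: StimulationSchedule | None = None
) -> SegmentationPlan:
    """The 3-hr segmentation of every complete 12-h phase, with stimulation
    (plus 20-min tails) masked.  Segments fully masked are dropped with a
    warning; only phases fully inside the recording contribute."""
    n = rec.n_seconds
    stim_mask = (
        schedule.mask(n, pad_after_s=POST_STIM_EXCLUSION_S)
        if schedule is not None and schedule.n_stim
        else np.zeros(n, dtype=bool)
    )
    is_light = rec.is_light()
    day = rec.day()
    plen = rec.phase_length_s
    segments: list[Segment] = []
    phase_start = rec.lights_on_s  # 0-based second where the first phase begins
    while phase_start + plen <= n:
        phase_is_light = bool(is_light[phase_start])
        for lo_min, hi_min in SEGMENT_OFFSETS_MIN:
            lo = phase_start + lo_min * 60  # 0-based
            hi = phase_start + hi_min * 60
            if hi > n:
                continue
            excl = stim_mask[lo:hi].copy()
            seg = Segment(
                start_s=lo + 1, end_s=hi + 1,
                phase="light" if phase_is_light else "dark",
                day=int(day[lo]), excluded=excl,
            )
            if seg.n_usable == 0:
                warnings.warn(
                    f"segment at {seg.start_s}s fully excluded; dropped", stacklevel=2
                )
                continue
            segments.append(seg)
        phase_start += plen
    return SegmentationPlan(segments=segments, n_seconds=n)


def _longest_unmasked_run(values: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """The longest contiguous unmasked stretch of a segment (used for the
    long-run-variance lag structure when a mask splits the segment)."""
    keep = ~excluded & np.isfinite(values)
    if keep.all():
        return values
    padded = np.concatenate([[0], keep.astype(int), [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    if starts.size == 0:
        return values[:0]
    best = np.argmax(ends - starts)
    return values[starts[best] : ends[best]]


def segment_mean_and_variance(
    series: np.ndarray, seg: Segment
) -> tuple[float, float, int]:
    """Masked segment mean and its Eq-style long-run variance over n.

    The mean uses every usable second; the autocovariance structure comes
    from the longest unmasked run (masks are rare by design), and the
    variance of the mean divides by the usable count."""
    vals = series[seg.start_s - 1 : seg.end_s - 1]
    usable = vals[~seg.excluded & np.isfinite(vals)]
    if usable.size < 2:
        raise ValueError("segment has <2 usable seconds")
    run = _longest_unmasked_run(vals, seg.excluded)
    if run.size < 2:
        run = usable
    lrv = longrun_variance(run)
    return float(usable.mean()), lrv / usable.size, int(usable.size)


def lightdark_contrast(
    series: np.ndarray,
    plan: SegmentationPlan,
    dim: str,
    two_sided: bool = True,
) -> LightDarkContrast:
    """Dark-minus-light contrast of per-segment means of a 1-D or 2-D mean
    activity series, with variance propagated as the sum of the two
    phase-average variances."""
    phase_stats = {}
    for phase in ("light", "dark"):
        segs = plan.by_phase(phase)
        if not segs:
            raise ValueError(f"no usable {phase} segments: contrast undefined")
        means, varis = [], []
        for seg in segs:
            mu, v, _ = segment_mean_and_variance(series, seg)
            means.append(mu)
            varis.append(v)
        k = len(means)
        phase_stats[phase] = (float(np.mean(means)), float(np.sum(varis)) / k**2)
    est_var = phase_stats["dark"][1] + phase_stats["light"][1]
    return LightDarkContrast(
        dim=dim, dark_mean=phase_stats["dark"][0], light_mean=phase_stats["light"][0],
        est_var=est_var, two_sided=two_sided,
    )


def fraction_2d(
    id_series: np.ndarray,
    rec: TrajectoryRecording,
    schedule: StimulationSchedule | None = None,
    denominator: str = "moving",
) -> dict[tuple[str, str], float]:
    """Fraction of movement that is two-dimensional, per
    (light/dark x stim/non-stim) condition.

    The default denominator is the count of *moving* seconds (ID != 0); the
    all-seconds denominator is available via ``denominator='all'``.
    Conditions with an empty denominator are NaN (flagged with a warning).
    """
    id_series = np.asarray(id_series)
    n = id_series.size
    is_light = rec.is_light()[:n]
    stim = (
        schedule.mask(rec.n_seconds)[:n]
        if schedule is not None and schedule.n_stim
        else np.zeros(n, dtype=bool)
    )
    defined = id_series >= 0
    out = {}
    for phase, light_flag in (("light", True), ("dark", False)):
        for stim_label, stim_flag in (("nonstim", False), ("stim", True)):
            sel = defined & (is_light == light_flag) & (stim == stim_flag)
            if denominator == "moving":
                den = sel & (id_series > 0)
            elif denominator == "all":
                den = sel
            else:
                raise ValueError("denominator must be 'moving' or 'all'")
            num = sel & (id_series == 2)
            if den.sum() == 0:
                warnings.warn(
                    f"no {denominator} seconds in condition ({phase},{stim_label})",
                    stacklevel=2,
                )
                out[(phase, stim_label)] = float("nan")
            else:
                out[(phase, stim_label)] = float(num.sum() / den.sum())
    return out


def lightdark_fdr(
    contrasts: dict[str, dict[str, LightDarkContrast]], q: float = 0.05,
    mode: str = "independent",
) -> dict[str, FDRReport]:
    """Cohort-level FDR per dimension family: ``contrasts`` maps animal ->
    dim ('1d'/'2d') -> contrast; returns one step-up report per dim."""
    reports = {}
    dims = sorted({d for per_animal in contrasts.values() for d in per_animal})
    for dim in dims:
        ps = [per_animal[dim].p_value for per_animal in contrasts.values()
              if dim in per_animal]
        reports[dim] = fdr_threshold(np.asarray(ps), q=q, mode=mode)
    return reports
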