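"""Diagnostics supporting the piecewise-stationarity assumption.

The analysis treats a motor process as strictly stationary within 3-hr
segments, with parameters free to change across segments.  Two diagnostics
back this up: (i) sample autocovariance/autocorrelation functions with the
standard +-1.96/sqrt(n) bands, showing that within-segment correlation dies
out well before a 20-minute lag, and (ii) a frequency-domain equality test -
Thomson multitaper spectra of several same-phase segments compared through
their variance-normalized cumulative periodograms with a per-frequency
shuffle null (the Diggle-Fisher construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss
from statsmodels.tsa.stattools import acovf


@lru_cache(maxsize=8)
def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)

DEFAULT_NW = 4.0
DEFAULT_K = 7
DEFAULT_N_SHUFFLES = 1000


@dataclass
class AutocovarianceFunction:
    """Biased (1/n) sample autocovariance gamma(h), h = 0..max_lag."""

    lags: np.ndarray
    gamma: np.ndarray
    n: int
    segment_id: str | None = None

    @property
    def rho(self) -> np.ndarray:
        """Autocorrelation; identically zero for a constant series."""
        g0 = self.gamma[0]
        if g0 <= 0:
            return np.zeros_like(self.gamma)
        return self.gamma / g0


@dataclass
class SpectralEstimate:
    """Multitaper spectrum with its normalized cumulative periodogram."""

    frequencies: np.ndarray  # cycles per second, (0, 0.5]
    density: np.ndarray
    nw: float
    k: int

    @property
    def log_density(self) -> np.ndarray:
        return np.log(self.density)

    @property
    def cumulative_periodogram(self) -> np.ndarray:
        """Cumulative spectral mass normalized to end at 1 (variance
        normalization, so a common rescaling of the input cancels)."""
        c = np.cumsum(self.density)
        return c / c[-1]


@dataclass
class DiggleFisherResult:
    observed_max_diff: float
    shuffled_max_diffs: np.ndarray
    p_value: float
    n_shuffles: int
    seed: int | None = None


def sample_autocovariance(
    series: np.ndarray, max_lag: int, segment_id: str | None = None
) -> AutocovarianceFunction:
    """Biased sample autocovariance up to ``max_lag``; gamma(0) is the sample
    variance."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    g = acovf(series, adjusted=False, fft=True, nlag=max_lag)
    return AutocovarianceFunction(
        lags=np.arange(max_lag + 1), gamma=g, n=n, segment_id=segment_id
    )


def decorrelation_lag(
    acf: AutocovarianceFunction, band_n: int, settle_run: int = 5
) -> tuple[int, bool]:
    """Smallest lag after which the autocorrelation stays inside the
    +-1.96/sqrt(band_n) band; ``band_n`` is the combined sample size behind
    the estimate (e.g. 6 segments of 3600 s pooled -> 21600).

    The band is a pointwise 95% interval, so ~5% of lags poke outside it
    even for white noise; "stays inside" is therefore read as entering the
    band and remaining there for ``settle_run`` consecutive lags.  Returns
    (lag, exited); ``exited`` is False when the autocorrelation never
    settles, in which case the maximum lag is returned.
    """
    band = 1.96 / np.sqrt(band_n)
    rho = acf.rho
    inside = np.abs(rho[1:]) <= band  # lag 0 is trivially 1
    L = inside.size
    run = min(settle_run, L)
    # first lag h (1-based) opening a run of `run` consecutive inside-lags
    ok = np.convolve(inside.astype(int), np.ones(run, dtype=int), mode="valid") == run
    if not ok.any():
        return int(acf.lags[-1]), False
    return int(np.argmax(ok)) + 1, True


def multitaper_spectrum(
    series: np.ndarray, nw: float = DEFAULT_NW, k: int = DEFAULT_K
) -> SpectralEstimate:
    """Thomson multitaper spectral estimate (mean of K eigenspectra with DPSS
    tapers at time-bandwidth NW); the series is demeaned first.  Frequencies
    run over the positive Fourier grid up to Nyquist, excluding 0."""
    series = np.asarray(series, dtype=float)
    n = series.size
    if k < 1 or nw <= 0:
        raise ValueError("invalid taper parameters")
    if n < 2 * k:
        raise ValueError(f"series length {n} too short for {k} tapers")
    if k >= 2 * nw:
        raise ValueError("number of tapers should be < 2*NW")
    x = series - series.mean()
    tapers = _dpss_tapers(n, float(nw), int(k))  # (k, n), unit energy
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    density = spec.mean(axis=0)[1:]  # drop f = 0
    freqs = np.fft.rfftfreq(n, d=1.0)[1:]
    return SpectralEstimate(frequencies=freqs, density=density, nw=nw, k=k)


def phase_stationarity_report(
    series: np.ndarray,
    rec,
    start_hours: tuple[int, ...] = (4, 5, 6, 7),
    segment_length_s: int = 10_800,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
) -> dict[str, DiggleFisherResult]:
    """Within-phase stationarity check: compare multitaper spectra of 3-hr
    stretches starting at several hours into the first full light and dark
    phases (the stretches may overlap) via the Diggle-Fisher shuffle test.

    ``series`` is a per-second motor process aligned to ``rec``'s grid.
    Returns one test result per phase present in the recording.
    """
    series = np.asarray(series, dtype=float)
    is_light = rec.is_light()[: series.size]
    plen = rec.phase_length_s
    out: dict[str, DiggleFisherResult] = {}
    rng = np.random.default_rng(seed)
    last_fit = max(start_hours) * 3600 + segment_length_s
    for phase, flag in (("light", True), ("dark", False)):
        # first phase block of this kind whose analysis segments fit
        start = None
        p0 = rec.lights_on_s
        while p0 + last_fit <= series.size:
            if bool(is_light[min(p0, series.size - 1)]) == flag:
                start = p0
                break
            p0 += plen
        if start is None:
            continue
        spectra = []
        for h in start_hours:
            lo = start + h * 3600
            hi = lo + segment_length_s
            if hi > start + plen:
                raise ValueError(
                    f"segment at hour {h} does not fit inside the {phase} phase"
                )
            seg = series[lo:hi]
            spectra.append(multitaper_spectrum(seg, nw=nw, k=k))
        out[phase] = diggle_fisher_test(spectra, n_shuffles=n_shuffles, rng=rng)
    return out


def _max_diff_stat(cumulative: np.ndarray) -> float:
    """Max over frequency of the spread of cumulative periodograms (rows)."""
    return float((cumulative.max(axis=0) - cumulative.min(axis=0)).max())


def diggle_fisher_test(
    spectra: list[SpectralEstimate],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    decimate: int | None = None,
) -> DiggleFisherResult:
    """Shuffle test for equality of several spectra.

    If all segments share one spectrum, swapping the spectral ordinates of
    the segments at any single frequency leaves the ensemble statistically
    unchanged.  The statistic is the maximum, over frequencies, of the
    largest pairwise difference among the variance-normalized cumulative
    periodograms; its null distribution comes from ``n_shuffles`` random
    per-frequency shuffles of the raw spectral ordinates.  The p-value uses
    the add-one convention p = (1 + #{shuffled >= observed}) / (n_shuffles+1).

    The exchangeability argument needs ordinates that are independent across
    frequencies *within* a series.  Multitaper estimates are smoothed over
    the taper bandwidth (2 NW Fourier bins), so the test runs on a
    bandwidth-decimated subgrid (every ``decimate``-th ordinate; by default
    2*NW+1 bins, inferred from the estimates).  On the full grid the
    within-series smoothing makes the observed curves coherently wavier
    than any per-frequency shuffle and the test rejects everything.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0):
            raise ValueError("spectra are not on a common frequency grid")
    if decimate is None:
        decimate = int(np.ceil(2 * spectra[0].nw)) + 1
    dens = np.stack([s.density for s in spectra])[:, ::decimate]  # (s, F)
    cum = np.cumsum(dens, axis=1)
    cum /= cum[:, -1:]
    observed = _max_diff_stat(cum)

    if rng is None:
        rng = np.random.default_rng(seed)
    n_series, n_freq = dens.shape
    # independent permutation of the s ordinates at every frequency, for all
    # shuffles at once: argsort of random keys along the series axis
    keys = rng.random((n_shuffles, n_series, n_freq))
    perm = np.argsort(keys, axis=1)
    shuffled = np.take_along_axis(
        np.broadcast_to(dens, (n_shuffles, n_series, n_freq)), perm, axis=1
    )
    scum = np.cumsum(shuffled, axis=2)
    scum /= scum[:, :, -1:]
    spread = scum.max(axis=1) - scum.min(axis=1)
    stats = spread.max(axis=1)
    p = (1.0 + float(np.sum(stats >= observed))) / (n_shuffles + 1.0)
    return DiggleFisherResult(
        observed_max_diff=observed, shuffled_max_diffs=stats, p_value=p,
        n_shuffles=n_shuffles, seed=seed,
    )
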