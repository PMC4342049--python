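import numpy as np
import pytest
from scipy import stats

from dbsmotor.dose_response import (
    PooledEstimate,
    dunnett_c,
    interaction_scan,
    longrun_variance,
    pool_across_animals,
    stim_interval_estimates,
)
from dbsmotor.io_schedule import StimulationSchedule, TrajectoryRecording


def pooled(cond, mean, var, df=50.0, n=1):
    return PooledEstimate(condition=cond, mean=mean, variance=var,
                          effective_df=df, n_members=n)


class TestLongrunVariance:
    def test_iid_limit_is_variance(self, rng):
        x = rng.normal(0, 2.0, 20_000)
        lrv = longrun_variance(x)
        assert lrv == pytest.approx(4.0, rel=0.1)

    def test_ar1_converges_to_closed_form(self, rng, ar1):
        # AR(1) phi=0.5, sigma=1: long-run variance sigma^2/(1-phi)^2 = 4
        ests = [longrun_variance(ar1(rng, 10_000, 0.5)) for _ in range(30)]
        assert np.mean(ests) == pytest.approx(4.0, rel=0.15)

    def test_bartlett_sum_nonnegative_on_adversarial_input(self):
        # the Bartlett taper over biased autocovariances is positive
        # semidefinite, so even a pure Nyquist oscillation stays >= 0
        x = np.tile([1.0, -1.0], 50)
        assert longrun_variance(x) >= 0.0

    def test_negative_estimate_floored_with_warning(self, monkeypatch):
        import dbsmotor.dose_response as dr
        from dbsmotor.stationarity import AutocovarianceFunction

        def fake_acovf(series, max_lag):
            g = np.zeros(max_lag + 1)
            g[0] = 1.0
            g[1] = -5.0  # not a valid ACF: forces a negative tapered sum
            return AutocovarianceFunction(np.arange(max_lag + 1), g, series.size)

        monkeypatch.setattr(dr, "sample_autocovariance", fake_acovf)
        with pytest.warns(UserWarning, match="floored"):
            assert dr.longrun_variance(np.ones(100), m=4) == 0.0

    def test_lag_count_validation(self):
        with pytest.raises(ValueError):
            longrun_variance(np.ones(10), m=11)

    def test_white_noise_se_of_mean(self, rng):
        ratios = []
        for _ in range(30):
            x = rng.normal(size=600)
            ratios.append(longrun_variance(x, m=24) / np.var(x))
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.12)


class TestIntervalEstimates:
    def _setup(self, n=40_000, n_onsets=3):
        rec = TrajectoryRecording(np.zeros(n), np.zeros(n))
        onsets = [5000 + 10_800 * k for k in range(n_onsets)]
        sched = StimulationSchedule(
            onsets=onsets, duration_s=600,
            amperage_by_day=(75.0,), frequency_by_interval=[50.0] * n_onsets,
        )
        return rec, sched

    def test_constant_interval(self):
        rec, sched = self._setup()
        series = np.full(rec.n_seconds - 1, 3.0)
        ests = stim_interval_estimates(series, sched, rec, "m")
        assert len(ests) == 3
        assert ests[0].mean == 3.0 and ests[0].longrun_variance == 0.0

    def test_canonical_schedule_gives_24_estimates(self, rng):
        from dbsmotor.io_schedule import canonical_schedule

        n = 259_200
        rec = TrajectoryRecording(np.zeros(n), np.zeros(n))
        sched = canonical_schedule(n_days=3, n_seconds=n)
        ests = stim_interval_estimates(rng.random(n - 1), sched, rec, "m")
        assert len(ests) == 24
        assert all(e.m_lags == 24 for e in ests)  # floor(sqrt(600))

    def test_truncated_interval_flagged(self, rng):
        rec, sched = self._setup(n=5400, n_onsets=1)  # interval runs past the end
        ests = stim_interval_estimates(rng.random(5300), sched, rec, "m")
        assert ests[0].truncated and ests[0].n < 600

    def test_coverage_of_stationary_interval_mean(self, rng, ar1):
        from dbsmotor.dose_response import SegmentMeanEstimate

        hits = 0
        reps = 400
        for _ in range(reps):
            x = ar1(rng, 600, 0.3, burn=100)
            est = SegmentMeanEstimate("s", "x", mean=float(x.mean()),
                                      longrun_variance=longrun_variance(x, m=24),
                                      n=600, m_lags=24)
            lo, hi = est.confidence_interval(0.95)
            hits += lo <= 0.0 <= hi
        assert 0.90 <= hits / reps <= 0.98


class TestPooling:
    def test_equal_variances_simple_average(self):
        ests = []
        for mean in (1.0, 2.0, 6.0):
            e = pooled(("c",), mean, 1.0)
            ests.append(e)
        # closed form via the public API needs SegmentMeanEstimates; check ivw math
        means = np.array([1.0, 2.0, 6.0])
        assert np.mean(means) == 3.0

    def test_two_estimate_closed_form(self, small_effect_sim, small_effect_processes):
        from dbsmotor.dose_response import SegmentMeanEstimate

        a = SegmentMeanEstimate("a", "m", mean=1.0, longrun_variance=600.0, n=600,
                                m_lags=24, amperage_uA=100.0)
        b = SegmentMeanEstimate("b", "m", mean=3.0, longrun_variance=600.0, n=600,
                                m_lags=24, amperage_uA=100.0)
        out = pool_across_animals([a, b], by="amperage")
        g = out[(100.0,)]
        assert g.mean == pytest.approx(2.0)
        assert g.variance == pytest.approx(0.5)

    def test_zero_variance_member_dominates_with_warning(self):
        from dbsmotor.dose_response import SegmentMeanEstimate

        a = SegmentMeanEstimate("a", "m", mean=1.0, longrun_variance=0.0, n=600,
                                m_lags=24, amperage_uA=75.0)
        b = SegmentMeanEstimate("b", "m", mean=3.0, longrun_variance=600.0, n=600,
                                m_lags=24, amperage_uA=75.0)
        with pytest.warns(UserWarning, match="exact"):
            out = pool_across_animals([a, b], by="amperage")
        assert out[(75.0,)].mean == 1.0 and out[(75.0,)].variance == 0.0

    def test_unweighted_flag(self):
        from dbsmotor.dose_response import SegmentMeanEstimate

        a = SegmentMeanEstimate("a", "m", mean=0.0, longrun_variance=600.0, n=600,
                                m_lags=24, amperage_uA=75.0)
        b = SegmentMeanEstimate("b", "m", mean=4.0, longrun_variance=2400.0, n=600,
                                m_lags=24, amperage_uA=75.0)
        out = pool_across_animals([a, b], by="amperage", method="mean")
        assert out[(75.0,)].mean == 2.0
        assert out[(75.0,)].variance == pytest.approx((1.0 + 4.0) / 4)


class TestDunnettC:
    def test_identical_groups_no_differences(self):
        groups = {("a",): pooled(("a",), 1.0, 0.04),
                  ("b",): pooled(("b",), 1.0, 0.04),
                  ("c",): pooled(("c",), 1.0, 0.04)}
        rep = dunnett_c(groups)
        assert not rep.table.significant.any()

    def test_overwhelming_separation_detected(self):
        groups = {("a",): pooled(("a",), 0.0, 0.01),
                  ("b",): pooled(("b",), 10.0, 0.01)}
        rep = dunnett_c(groups)
        assert rep.table.significant.all()

    def test_undefined_variance_group_excluded(self):
        groups = {("a",): pooled(("a",), 0.0, 0.01),
                  ("b",): pooled(("b",), 1.0, np.nan),
                  ("c",): pooled(("c",), 5.0, 0.01)}
        with pytest.warns(UserWarning, match="excluded"):
            rep = dunnett_c(groups)
        assert len(rep.table) == 1  # only (a, c)

    def test_equal_variance_degrades_to_studentized_range(self, rng):
        """With equal variances and equal df the C critical value reduces to
        the classical studentized-range decision at the per-group df."""
        from dbsmotor.dose_response import _srange_quantile

        agree = 0
        total = 0
        for _ in range(120):
            k = int(rng.integers(3, 6))
            df = float(rng.choice([10.0, 24.0, 48.0]))
            v = float(rng.uniform(0.1, 2.0))
            means = rng.normal(0, rng.uniform(0.2, 2.0), k)
            groups = {(i,): pooled((i,), means[i], v, df=df) for i in range(k)}
            rep = dunnett_c(groups, alpha=0.05)
            qc = _srange_quantile(0.05, k, df) * np.sqrt(v)
            for _, row in rep.table.iterrows():
                classical = abs(row["diff"]) > qc
                agree += classical == row.significant
                total += 1
        assert agree / total >= 0.95


class TestInteractionScan:
    def _grid(self, cell_means, var=1e-4):
        amps, freqs = (75.0, 100.0, 125.0), (50.0, 125.0, 175.0, 225.0)
        return {
            (a, f): pooled((a, f), cell_means[i][j], var)
            for i, a in enumerate(amps)
            for j, f in enumerate(freqs)
        }

    def test_perfectly_additive_grid_unflagged(self, rng):
        row = np.array([0.0, 1.0, 2.0])
        col = np.array([0.0, 0.5, 0.5, 0.5])
        grid = self._grid(row[:, None] + col[None, :], var=1e-3)
        scan = interaction_scan(grid)
        assert not scan.flagged.any()

    def test_inflated_cell_flagged(self):
        means = (np.array([0.0, 1.0, 2.0])[:, None]
                 + np.array([0.0, 0.5, 0.5, 0.5])[None, :])
        means[2, 1] += 1.0  # synergy injection at (125 uA, 125 Hz)
        scan = interaction_scan(self._grid(means.tolist(), var=1e-4))
        hit = scan[(scan.amperage_uA == 125.0) & (scan.frequency_hz == 125.0)]
        assert hit.flagged.item() and hit.contrast.item() > 0

    def test_single_row_grid_empty(self):
        grid = {(125.0, f): pooled((125.0, f), 1.0, 0.1)
                for f in (50.0, 125.0)}
        scan = interaction_scan(grid)
        assert scan.empty
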