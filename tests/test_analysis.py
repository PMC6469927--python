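import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from vburrow.analysis import (RateBehaviorTable, bin_firing, extinction_trend,
                              habituation_curve, high_latency_fraction,
                              ingress_rate, make_rate_behavior_table,
                              rate_behavior_regression, spearman,
                              velocity_from_position)
from vburrow.core import SessionTrace, SpikeData
from vburrow.mouse import (MouseParams, StimulusResponse,
                           simulate_extinction_table, simulate_trial_table)


def table_from_rows(rows):
    cols = ["mouse_id", "stimulus_id", "trial_index", "max_displacement",
            "ingress", "latency"]
    return pd.DataFrame(rows, columns=cols)


class TestHabituationCurve:
    def test_flat_for_identical_displacements(self):
        rows = [(f"m{m}", 1, t, 7.0, True, 0.1)
                for m in range(3) for t in range(1, 6)]
        curve = habituation_curve(table_from_rows(rows))
        assert (curve["median_max_displacement"] == 7.0).all()

    def test_generated_habituation_declines(self):
        params = MouseParams(default_response=StimulusResponse(
            "ingress", p0=0.67, decay=0.5))
        tbl = simulate_trial_table(params, [1], 15, 20, seed=1)
        curve = habituation_curve(tbl)
        early = curve[curve.trial_index <= 3]["median_max_displacement"].mean()
        late = curve[curve.trial_index >= 10]["median_max_displacement"].mean()
        assert early > late

    def test_median_is_middle_order_statistic(self):
        vals = [3.0, 9.0, 5.0]
        rows = [("m0", 1, i + 1, v, True, 0.1) for i, v in enumerate(vals)]
        # one mouse, one trial per index: per-block median is the value
        curve = habituation_curve(table_from_rows(rows))
        assert list(curve["median_max_displacement"]) == vals
        # pooled across one block: middle order statistic by sorting
        rows = [(f"m{i}", 1, 1, v, True, 0.1) for i, v in enumerate(vals)]
        curve = habituation_curve(table_from_rows(rows))
        assert curve["median_max_displacement"].iloc[0] == sorted(vals)[1]

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            habituation_curve(pd.DataFrame())


class TestIngressRate:
    def test_known_fractions(self):
        rows = [("m0", 1, i + 1, 10.0, i < 11, 0.1) for i in range(15)]
        k, n, p = ingress_rate(table_from_rows(rows), (1, 15), 1)
        assert (k, n) == (11, 15)
        assert p == pytest.approx(11 / 15)

    def test_zero_rate(self):
        rows = [("m0", 1, i + 1, 0.1, False, math.nan) for i in range(15)]
        assert ingress_rate(table_from_rows(rows), (1, 15), 1)[2] == 0.0

    def test_pooled_39_of_54(self):
        # 9 mice x trials 2-7, 39 ingresses pooled -> 0.7222
        rows = []
        hits = 39
        for m in range(9):
            for t in range(2, 8):
                rows.append((f"m{m}", 1, t, 10.0, hits > 0, 0.1))
                hits -= 1
        k, n, p = ingress_rate(table_from_rows(rows), (2, 7), 1)
        assert (k, n) == (39, 54)
        assert p == pytest.approx(0.7222, abs=1e-4)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        rows = [(f"m{m}", 1, t, 10.0, bool(rng.integers(2)), 0.1)
                for m in range(5) for t in range(1, 8)]
        tbl = table_from_rows(rows)
        shuffled = tbl.sample(frac=1.0, random_state=1)
        assert ingress_rate(tbl, (1, 7), 1) == ingress_rate(shuffled, (1, 7), 1)

    def test_empty_range_raises(self):
        rows = [("m0", 1, 1, 10.0, True, 0.1)]
        with pytest.raises(ValueError):
            ingress_rate(table_from_rows(rows), (5, 9), 1)


class TestHighLatencyFraction:
    def test_all_fast(self):
        rows = [("m0", 1, t, 10.0, True, 0.5) for t in range(1, 6)]
        fr = high_latency_fraction(table_from_rows(rows), 1.0)
        assert (fr == 0.0).all()

    def test_all_slow(self):
        rows = [("m0", 1, t, 10.0, True, 1.5) for t in range(1, 6)]
        fr = high_latency_fraction(table_from_rows(rows), 1.0)
        assert (fr == 1.0).all()

    def test_indices_without_ingress_absent(self):
        rows = [("m0", 1, 1, 10.0, True, 0.5),
                ("m0", 1, 2, 0.1, False, math.nan)]
        fr = high_latency_fraction(table_from_rows(rows), 1.0)
        assert list(fr.index) == [1]

    def test_extinction_schedule_recovered(self):
        tbl = simulate_extinction_table(n_trials=12, n_mice=30, seed=3)
        fr = high_latency_fraction(tbl)
        rs, p = extinction_trend(fr)
        assert rs > 0 and p < 0.05


class TestSpearman:
    def test_perfect_monotone(self):
        rs, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rs == pytest.approx(1.0)
        rs, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rs == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rs, _ = spearman(x, y)
            # definitional oracle: average ranks then Pearson formula
            rx = sstats.rankdata(x)
            ry = sstats.rankdata(y)
            num = ((rx - rx.mean()) * (ry - ry.mean())).sum()
            den = math.sqrt(((rx - rx.mean()) ** 2).sum()
                            * ((ry - ry.mean()) ** 2).sum())
            assert rs == pytest.approx(num / den, abs=1e-12)

    def test_large_sample_p_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rs, p = spearman(x, y)
        ref = sstats.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        # n=4, perfect ordering: exact two-sided p = 2/4! = 1/12
        rs, p = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert rs == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestBinFiring:
    def test_single_spike(self):
        rates, mean = bin_firing(SpikeData([[0.5]]), 1.0, 3.0)
        assert rates.shape == (1, 3)
        assert list(rates[0]) == [1.0, 0.0, 0.0]
        assert list(mean) == [1.0, 0.0, 0.0]

    def test_empty_unit(self):
        rates, mean = bin_firing(SpikeData([[]]), 0.5, 2.0)
        assert not rates.any()

    def test_spike_count_conserved(self):
        rng = np.random.default_rng(1)
        spikes = SpikeData([np.sort(rng.uniform(0, 10, 200))
                            for _ in range(5)])
        rates, _ = bin_firing(spikes, 0.1, 10.0)
        assert rates.sum() * 0.1 == pytest.approx(1000)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(7)
        lam, dur = 20.0, 200.0
        n = rng.poisson(lam * dur)
        spikes = SpikeData([np.sort(rng.uniform(0, dur, n))])
        rates, mean = bin_firing(spikes, 0.1, dur)
        se = math.sqrt(lam / dur)
        assert abs(mean.mean() - lam) < 3 * se


class TestVelocity:
    def test_linear_ramp(self):
        fs = 1000.0
        pos = 10.0 * np.arange(2000) / fs
        v = velocity_from_position(pos, fs)
        assert np.allclose(v[50:-50], 10.0, atol=1e-6)

    def test_constant_position(self):
        v = velocity_from_position(np.full(500, 3.3), 1000.0)
        assert np.allclose(v, 0.0)

    def test_sinusoid_peak_velocity(self):
        fs, f0, amp = 1000.0, 2.0, 5.0
        t = np.arange(int(3 * fs)) / fs
        v = velocity_from_position(amp * np.sin(2 * np.pi * f0 * t), fs,
                                   smoothing_window=0.01)
        assert v.max() == pytest.approx(2 * np.pi * f0 * amp, rel=0.02)


class TestRateRegression:
    def make_table(self, mean_rate, unit_rates, position):
        n = len(mean_rate)
        return RateBehaviorTable(
            bin_width=0.1, mean_rate=np.asarray(mean_rate, float),
            unit_rates=np.asarray(unit_rates, float),
            position=np.asarray(position, float),
            abs_velocity=np.abs(np.gradient(position)),
            force=np.linspace(0, 1, n))

    def test_exact_linear_gives_r2_one(self):
        pos = np.linspace(0, 15, 1000)
        rate = 3.0 + 2.0 * pos
        tbl = self.make_table(rate, rate[None, :], pos)
        res = rate_behavior_regression(tbl)
        row = res[res.covariate == "position"].iloc[0]
        assert row.mean_rate == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(0)
        n = 10000
        pos = rng.normal(size=n)
        rate = rng.normal(size=n)
        tbl = self.make_table(rate, rate[None, :], pos)
        res = rate_behavior_regression(tbl)
        assert (res.mean_rate < 0.01).all()

    def test_matches_closed_form_ols(self):
        """R^2 equals the closed-form slope/intercept computation."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 50
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            tbl = self.make_table(y, y[None, :], x)
            r2 = rate_behavior_regression(tbl)
            got = r2[r2.covariate == "position"].iloc[0].mean_rate
            # closed-form OLS oracle
            b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            a = y.mean() - b * x.mean()
            rss = ((y - a - b * x) ** 2).sum()
            tss = ((y - y.mean()) ** 2).sum()
            assert got == pytest.approx(1 - rss / tss, abs=1e-10)

    def test_zero_variance_covariate_raises(self):
        tbl = self.make_table(np.arange(10.0), np.arange(10.0)[None, :],
                              np.zeros(10))
        with pytest.raises(ValueError):
            rate_behavior_regression(tbl)

    def test_uncoupled_rates_median_r2_negligible(self):
        """Firing generated independently of behaviour: median per-unit R^2
        stays in the paper-like negligible-coupling regime."""
        rng = np.random.default_rng(9)
        n = 10000
        pos = np.cumsum(rng.normal(0, 0.1, n))
        units = rng.poisson(2.0, size=(30, n)) / 0.1
        tbl = self.make_table(units.mean(axis=0), units, pos)
        res = rate_behavior_regression(tbl)
        assert (res.median_unit < 0.01).all()


def test_make_rate_behavior_table_alignment():
    fs = 1000.0
    n = 5000
    trace = SessionTrace(fs, np.linspace(0, 15, n), np.zeros(n),
                         np.full(n, 15.0), np.zeros(n, dtype=int))
    spikes = SpikeData([np.arange(0.05, 5.0, 0.01)])
    tbl = make_rate_behavior_table(spikes, trace, bin_width=0.1)
    assert len(tbl.mean_rate) == 50
    assert tbl.position[0] < tbl.position[-1]
    # rates constant at 100 spk/s except the first bin
    assert np.allclose(tbl.mean_rate[1:], 100.0)
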