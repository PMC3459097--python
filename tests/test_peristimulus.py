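"""ROI selection, peristimulus averaging, HRF fitting, group statistics."""

import numpy as np
import pandas as pd
import pytest

from neohrf.hrf import PRESET_METRICS, evaluate_hrf, get_preset
from neohrf.peristimulus import (
    PeristimulusAverage,
    compare_all_groups,
    compare_two_groups,
    epoch_average,
    fit_peristimulus,
    fit_ttp_age,
    holm_adjust,
    select_roi,
)
from neohrf.synth import Geometry, NoiseSpec, simulate_bold


class TestSelectROI:
    def test_ten_distinct_values_keep_top_voxel(self):
        """Linear-interpolation 90th percentile of 10 distinct values lies
        between ranks 9 and 10, so exactly the top voxel survives."""
        zmap = np.zeros((10, 1, 1))
        zmap[:, 0, 0] = np.arange(1.0, 11.0)
        coords = np.argwhere(zmap > 0)
        roi, degenerate = select_roi(zmap, coords)
        assert not degenerate
        assert len(roi) == 1
        assert zmap[tuple(roi[0])] == 10.0

    def test_hundred_distinct_values_keep_ten(self):
        rng = np.random.default_rng(0)
        zmap = rng.permutation(np.arange(100.0)).reshape(100, 1, 1) + 1
        coords = np.argwhere(zmap > 0)
        roi, _ = select_roi(zmap, coords)
        assert len(roi) == 10
        assert set(zmap[tuple(roi.T)]) == set(np.arange(91.0, 101.0))

    def test_all_equal_falls_back_to_all_voxels(self):
        zmap = np.full((4, 4, 1), 3.0)
        coords = np.argwhere(zmap > 0)
        roi, degenerate = select_roi(zmap, coords)
        assert degenerate
        assert len(roi) == 16

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            select_roi(np.zeros((2, 2, 2)), np.empty((0, 3)))


class TestEpochAverage:
    def test_constant_series_all_zero(self, event_design):
        series = np.full(event_design.n_volumes, 500.0)
        avg = epoch_average(series, event_design)
        assert np.all(avg.mean == 0.0)
        assert np.all(avg.sem == 0.0)

    def test_grid_runs_from_baseline_to_epoch_end(self, event_design):
        avg = epoch_average(np.full(1000, 1.0), event_design)
        assert avg.times[0] == -2.0
        assert avg.times[-1] == pytest.approx(39.0)
        assert avg.baseline_points == 4
        assert avg.n_epochs == 11  # first epoch lacks a baseline window

    def test_noiseless_mean_equals_preset_curve(
        self, noiseless_adult_run, event_design
    ):
        """End-to-end oracle: the averaged % change curve reproduces the
        generating preset curve at the grid points."""
        series = noiseless_adult_run.volumes[noiseless_adult_run.truth_mask][0]
        avg = epoch_average(series, event_design)
        expected = np.zeros_like(avg.times)
        post = avg.times >= 0
        unit = get_preset("adult").with_amplitude(1.0)  # run simulated at 1%
        expected[post] = evaluate_hrf(unit, avg.times[post])
        assert np.max(np.abs(avg.mean - expected)) < 1e-6

    def test_scale_invariance(self, noiseless_adult_run, event_design):
        series = noiseless_adult_run.volumes[noiseless_adult_run.truth_mask][0]
        a = epoch_average(series, event_design)
        b = epoch_average(series * 7.3, event_design)
        assert np.allclose(a.mean, b.mean, atol=1e-12)

    def test_nonpositive_baseline_rejected(self, event_design):
        with pytest.raises(ValueError, match="baseline"):
            epoch_average(np.zeros(1000), event_design)

    def test_too_few_epochs_rejected(self, event_design):
        series = np.full(1000, 100.0)
        with pytest.raises(ValueError, match="epochs"):
            epoch_average(series[:200], event_design)


class TestFitPeristimulus:
    def make_avg(self, params, tr=0.5, sem=0.0, rng=None):
        n_pre = 4
        times = (np.arange(83) - n_pre) * tr
        mean = np.zeros_like(times)
        post = times >= 0
        mean[post] = evaluate_hrf(params, times[post])
        if rng is not None:
            mean = mean + rng.normal(0, sem, mean.shape)
        return PeristimulusAverage(
            times=times, mean=mean,
            sem=np.full_like(times, sem), n_epochs=11,
        )

    @pytest.mark.parametrize("group", ["adult", "term", "preterm"])
    def test_exact_preset_curve_recovered(self, group):
        target = PRESET_METRICS[group]
        fit = fit_peristimulus(self.make_avg(get_preset(group)))
        m = fit.metrics
        assert m.time_to_peak == pytest.approx(target.time_to_peak, rel=0.01)
        assert m.peak_amplitude == pytest.approx(target.peak_amplitude, rel=0.01)
        assert m.undershoot_ratio == pytest.approx(
            target.undershoot_ratio, rel=0.01, abs=0.002
        )

    def test_all_zero_input_rejected(self):
        times = (np.arange(83) - 4) * 0.5
        avg = PeristimulusAverage(
            times=times, mean=np.zeros_like(times),
            sem=np.zeros_like(times), n_epochs=11,
        )
        with pytest.raises(ValueError, match="positive excursion"):
            fit_peristimulus(avg)

    def test_noise_robust_recovery(self):
        """Moderate noise (sd = peak/5): time-to-peak recovered within
        1 s on a handful of replicates."""
        target = PRESET_METRICS["adult"]
        errors = []
        for s in range(5):
            rng = np.random.default_rng(s)
            avg = self.make_avg(
                get_preset("adult"), sem=target.peak_amplitude / 5, rng=rng
            )
            m = fit_peristimulus(avg).metrics
            errors.append(abs(m.time_to_peak - target.time_to_peak))
        assert np.median(errors) <= 1.0


class TestGroupCompare:
    @staticmethod
    def table(values):
        return pd.DataFrame(
            {
                "time_to_peak": values,
                "peak_amplitude": values,
                "undershoot_ratio": values,
            }
        )

    def test_disjoint_samples_exact_p(self):
        """n1 = n2 = 3 fully separated: exact two-sided p = 2/C(6,3) = 0.1."""
        p = compare_two_groups(self.table([1, 2, 3]), self.table([4, 5, 6]))
        assert p["time_to_peak"] == pytest.approx(0.1)

    def test_holm_step_down_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_identical_samples_p_one(self):
        p = compare_two_groups(self.table([1, 2, 3]), self.table([1, 2, 3]))
        assert p["time_to_peak"] == pytest.approx(1.0)

    def test_paired_all_tied_degenerate(self):
        p = compare_two_groups(
            self.table([1, 2, 3]), self.table([1, 2, 3]), paired=True
        )
        assert p["time_to_peak"] == 1.0

    def test_paired_wilcoxon_exact(self):
        a = self.table([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        b = self.table([4.9, 5.7, 6.4, 7.0, 7.5, 8.0])
        p = compare_two_groups(a, b, paired=True)
        # all six differences positive: exact two-sided p = 2/2^6
        assert p["time_to_peak"] == pytest.approx(2 / 64)

    def test_unequal_paired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups(
                self.table([1, 2, 3]), self.table([1, 2, 3, 4]), paired=True
            )

    def test_three_group_table_holm_within_metric(self):
        tables = {
            "a": self.table([1, 2, 3, 4]),
            "b": self.table([5, 6, 7, 8]),
            "c": self.table([9, 10, 11, 12]),
        }
        res = compare_all_groups(tables)
        sub = res[res["metric"] == "time_to_peak"]
        assert len(sub) == 3
        assert np.all(sub["p_holm"] >= sub["p_raw"] - 1e-15)


class TestTTPAgeTrend:
    def test_exact_generative_form_r2_one(self):
        ages = np.linspace(30, 45, 12)
        ttps = 8.0 * np.exp(-0.2 * (ages - 30.0)) + 5.0
        fit = fit_ttp_age(ages, ttps)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(30, 46, 25)
        true = (6.0, 0.15, 5.0)
        ttps = true[0] * np.exp(-true[1] * (ages - 30.0)) + true[2]
        ttps = ttps + rng.normal(0, 0.05, ages.shape)
        fit = fit_ttp_age(ages, ttps)
        assert fit.a == pytest.approx(true[0], rel=0.1)
        assert fit.b == pytest.approx(true[1], rel=0.1)
        assert fit.c == pytest.approx(true[2], rel=0.1)

    def test_constant_ttps_flagged_degenerate(self):
        ages = np.linspace(30, 40, 8)
        fit = fit_ttp_age(ages, np.full(8, 7.0))
        assert fit.degenerate
        assert fit.predict(np.array([35.0]))[0] == pytest.approx(7.0, abs=1e-6)

    def test_prediction_band_contains_fit(self):
        ages = np.linspace(30, 45, 10)
        ttps = 8.0 * np.exp(-0.2 * (ages - 30.0)) + 5.0
        fit = fit_ttp_age(ages, ttps)
        lo, hi = fit.prediction_band(ages)
        assert np.all(lo <= fit.predict(ages)) and np.all(fit.predict(ages) <= hi)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ttp_age(np.array([30, 35, 40.0]), np.array([8, 7, 6.0]))
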