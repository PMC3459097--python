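"""Synthetic designs, BOLD runs and pulsatile vessel flow."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neohrf.cbf import cbf_from_measurements, instantaneous_flux
from neohrf.hrf import get_preset
from neohrf.peristimulus import epoch_average
from neohrf.synth import (
    Geometry,
    NoiseSpec,
    convolved_regressor,
    make_block_design,
    make_event_design,
    simulate_bold,
    simulate_pc_flow,
)


class TestEventDesign:
    def test_study_acquisition_has_12_epochs(self):
        d = make_event_design(0.5, 1000, 1.0, 40.5)
        assert len(d.onsets) == 12
        assert d.onsets[0] == 0.0

    def test_half_acquisition_has_6_epochs(self):
        # floor(250 / 41.5) = 6
        assert len(make_event_design(0.5, 500, 1.0, 40.5).onsets) == 6

    def test_epoch_longer_than_acquisition_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            make_event_design(0.5, 40, 1.0, 40.5)

    def test_onsets_volume_aligned(self):
        d = make_event_design(0.5, 1000, 1.0, 40.5)
        assert all(abs(o / d.tr - round(o / d.tr)) < 1e-9 for o in d.onsets)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tr=st.sampled_from([0.5, 1.0, 2.0]),
        n_volumes=st.integers(50, 2000),
        stim=st.floats(0.5, 4.0),
        isi=st.floats(5.0, 60.0),
    )
    def test_epoch_count_matches_brute_force(self, tr, n_volumes, stim, isi):
        """Closed form floor(T/(stim+isi)) vs explicit onset enumeration."""
        total = n_volumes * tr
        epoch = stim + isi
        expected = 0
        while (expected + 1) * epoch <= total + 1e-9:
            expected += 1
        if expected == 0:
            with pytest.raises(ValueError):
                make_event_design(tr, n_volumes, stim, isi)
        else:
            d = make_event_design(tr, n_volumes, stim, isi)
            assert len(d.onsets) == expected


class TestBlockDesign:
    def test_two_cycles(self):
        d = make_block_design(1.0, 96, 24.0, 24.0)
        assert d.onsets == (0.0, 48.0)

    def test_single_cycle(self):
        assert len(make_block_design(1.0, 48, 24.0, 24.0).onsets) == 1

    def test_zero_on_duration_rejected(self):
        with pytest.raises(ValueError):
            make_block_design(1.0, 96, 0.0, 24.0)

    def test_rest_first_shifts_onsets(self):
        d = make_block_design(1.0, 96, 24.0, 24.0, stimulation_first=False)
        assert d.onsets == (24.0,)


class TestSimulateBold:
    def test_noiseless_voxel_fits_regressor_exactly(self, event_design):
        run = simulate_bold(
            event_design, get_preset("adult"),
            Geometry(shape=(4, 4, 2), active_radius=0.5),
            NoiseSpec(white_sd=0.0), truth_amplitude=1.0, seed=1,
        )
        vox = run.volumes[run.truth_mask][0]
        x = convolved_regressor(event_design, get_preset("adult"))
        X = np.column_stack([np.ones_like(x), x])
        _, rss, *_ = np.linalg.lstsq(X, vox, rcond=None)
        assert float(rss[0]) < 1e-12

    def test_noiseless_peristimulus_peak_is_truth_amplitude(
        self, noiseless_adult_run, event_design
    ):
        series = noiseless_adult_run.volumes[noiseless_adult_run.truth_mask][0]
        avg = epoch_average(series, event_design)
        assert avg.mean.max() == pytest.approx(1.0, abs=0.01)

    def test_white_noise_sd_calibrated(self, event_design):
        run = simulate_bold(
            event_design, get_preset("adult"),
            Geometry(shape=(10, 10, 2), active_radius=0.5),
            NoiseSpec(white_sd=2.0), seed=7,
        )
        inactive = run.volumes[~run.truth_mask] - 1000.0
        assert 0.95 * 2.0 < inactive.std() < 1.05 * 2.0

    def test_identical_seed_identical_volumes(self, event_design):
        kw = dict(
            design=event_design, hrf=get_preset("term"),
            geometry=Geometry(shape=(6, 6, 2), active_radius=1.0),
            noise_spec=NoiseSpec(
                white_sd=3.0, drift_coefficients=(5.0,),
                oscillations=((1.0, 0.3),), corrupted_spans=((10, 20),),
            ),
            truth_amplitude=0.5, seed=42,
        )
        a, b = simulate_bold(**kw), simulate_bold(**kw)
        assert np.array_equal(a.volumes, b.volumes)

    def test_nonfinite_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=float("nan"))

    def test_cluster_must_fit_in_volume(self, event_design):
        geom = Geometry(shape=(4, 4, 2), active_center=(3, 3, 1),
                        active_radius=1.0)
        # center voxel inside, mask valid
        assert geom.active_mask().any()
        with pytest.raises(IndexError):
            Geometry(shape=(4, 4, 2), active_center=(9, 0, 0)).active_mask()


class TestPCFlow:
    def test_unit_conversion_constant_velocity(self):
        """1 cm/s over 1 mm^2 is 0.6 ml/min (10 mm/s * 1 mm^2 = 10 mm^3/s)."""
        m = simulate_pc_flow(21.0, 400.0, pulsatility=0.0, seed=0)
        for meas in m:
            v = meas.phase_velocities[0]
            assert instantaneous_flux(meas)[0] == pytest.approx(
                v * meas.area * 0.6, rel=1e-12
            )

    def test_total_flow_from_target(self):
        # 21.0 ml/100g/min * 1.05 g/ml * 400 ml / 100 = 88.2 ml/min
        m = simulate_pc_flow(21.0, 400.0, seed=0)
        res = cbf_from_measurements(m, 400.0)
        assert res.total_flow == pytest.approx(88.2, rel=1e-9)

    def test_zero_pulsatility_gives_constant_waveform(self):
        m = simulate_pc_flow(21.0, 400.0, pulsatility=0.0, seed=3)
        for meas in m:
            v = np.asarray(meas.phase_velocities)
            assert np.allclose(v, v[0])

    def test_round_trip_recovers_target(self):
        for target, volume in [(21.0, 400.0), (25.5, 350.0), (19.2, 446.5)]:
            m = simulate_pc_flow(target, volume, pulsatility=0.4, seed=9)
            res = cbf_from_measurements(m, volume)
            assert abs(res.global_cbf - target) / target < 1e-6

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_pc_flow(21.0, 400.0, split=(0.5, 0.4, 0.2))

    def test_deterministic_under_seed(self):
        a = simulate_pc_flow(21.0, 400.0, seed=5)
        b = simulate_pc_flow(21.0, 400.0, seed=5)
        assert all(
            x.phase_velocities == y.phase_velocities for x, y in zip(a, b)
        )
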