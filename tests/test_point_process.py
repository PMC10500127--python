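"""Point-process generators: interval statistics, discretization, taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpshot import (
    EventTrain,
    GammaIntervalSpec,
    analytic_renewal_psd,
    compound_train,
    events_to_pulse,
    interval_histogram,
    modulated_train,
    periodic_train,
    sample_gamma_train,
    train_statistics,
    welch_psd,
)

FS = 1000.0


class TestGammaIntervalSpec:
    def test_scale_is_derived_from_shape_and_rate(self):
        spec = GammaIntervalSpec(shape=10.0, rate=40.0)
        assert spec.scale == pytest.approx(1.0 / (10.0 * 40.0))
        assert spec.mean_interval == pytest.approx(1.0 / 40.0)
        assert spec.interval_cv == pytest.approx(10.0**-0.5)

    @pytest.mark.parametrize("shape,rate", [(0.0, 40.0), (-1.0, 40.0), (1.0, 0.0), (1.0, -5.0)])
    def test_nonpositive_parameters_rejected(self, shape, rate):
        with pytest.raises(ValueError):
            GammaIntervalSpec(shape, rate)

    @given(shape=st.floats(0.05, 1000.0), rate=st.floats(0.5, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_moment_identities_hold_for_any_spec(self, shape, rate):
        spec = GammaIntervalSpec(shape, rate)
        assert spec.scale * spec.shape * spec.rate == pytest.approx(1.0)
        assert spec.interval_cv == pytest.approx(shape**-0.5)


class TestGammaTrain:
    @pytest.mark.parametrize("shape", [0.1, 1.0, 10.0, 10**1.5])
    def test_interval_mean_and_cv_match_the_distribution(self, shape):
        # mean interval -> 1/rate and CV -> 1/sqrt(shape), within 3 SE
        spec = GammaIntervalSpec(shape, 40.0)
        train = sample_gamma_train(spec, 1000.0, seed=7)
        iv = train.intervals()
        n = iv.size
        se_mean = iv.std(ddof=1) / np.sqrt(n)
        assert abs(iv.mean() - 1.0 / 40.0) < 3 * se_mean
        cv = iv.std(ddof=1) / iv.mean()
        # SE of the CV for gamma intervals, delta method: CV*sqrt((1+2*CV^2)/(2n)) approx
        se_cv = cv * np.sqrt((1 + 2 * cv**2) / (2 * n))
        assert abs(cv - shape**-0.5) < 3.5 * se_cv

    def test_poisson_intervals_are_exponential(self):
        train = sample_gamma_train(GammaIntervalSpec(1.0, 40.0), 1000.0, seed=3)
        iv = train.intervals()
        assert iv.mean() == pytest.approx(0.025, rel=0.02)
        assert iv.std(ddof=1) / iv.mean() == pytest.approx(1.0, abs=0.02)

    def test_same_seed_reproduces_the_train(self):
        spec = GammaIntervalSpec(5.0, 30.0)
        a = sample_gamma_train(spec, 50.0, seed=11)
        b = sample_gamma_train(spec, 50.0, seed=11)
        c = sample_gamma_train(spec, 50.0, seed=12)
        np.testing.assert_array_equal(a.times, b.times)
        assert not np.array_equal(a.times, c.times)

    def test_times_within_duration_and_increasing(self):
        train = sample_gamma_train(GammaIntervalSpec(0.2, 80.0), 20.0, seed=1)
        assert train.times[0] >= 0
        assert train.times[-1] < 20.0
        assert np.all(np.diff(train.times) >= 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            sample_gamma_train(GammaIntervalSpec(1.0, 40.0), 0.0, seed=0)

    @given(
        shape=st.floats(0.1, 100.0),
        rate=st.floats(1.0, 100.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_any_train_is_a_valid_event_train(self, shape, rate, seed):
        train = sample_gamma_train(GammaIntervalSpec(shape, rate), 5.0, seed)
        if train.n_events:
            assert train.times[-1] < 5.0
            assert np.all(np.diff(train.times) >= 0)


class TestPeriodicTrain:
    def test_arithmetic_progression(self):
        train = periodic_train(40.0, 1.0)
        np.testing.assert_allclose(train.times, np.arange(40) / 40.0)
        assert train.n_events == 40

    def test_interval_variance_is_zero(self):
        train = periodic_train(40.0, 1000.0)
        assert np.ptp(train.intervals()) == pytest.approx(0.0, abs=1e-9)

    def test_interval_histogram_is_a_point_mass(self):
        train = periodic_train(40.0, 1000.0)
        hist = interval_histogram(train, bin_width=0.002, max_interval=0.1)
        mass_bin = np.argmax(hist.density)
        assert hist.bin_edges[mass_bin] <= 0.025 < hist.bin_edges[mass_bin + 1]
        assert hist.density[mass_bin] * 0.002 == pytest.approx(1.0)

    def test_power_spectrum_is_phase_invariant(self):
        a = welch_psd(events_to_pulse(periodic_train(40.0, 100.0, 0.0), FS))
        b = welch_psd(events_to_pulse(periodic_train(40.0, 100.0, 0.01), FS))
        np.testing.assert_allclose(a.power, b.power, atol=1e-12 * a.power.max())

    def test_offset_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            periodic_train(40.0, 1.0, phase_offset=0.03)


class TestCompoundTrain:
    def test_single_component_matches_plain_gamma_distribution(self):
        spec = GammaIntervalSpec(5.0, 40.0)
        mix = compound_train([spec], 300.0, seed=4)
        plain = sample_gamma_train(spec, 300.0, seed=5)
        from scipy.stats import ks_2samp

        stat, p = ks_2samp(mix.intervals(), plain.intervals())
        assert p > 0.01

    def test_mixture_interval_moments(self):
        comps = [GammaIntervalSpec(1.0, 50.0), GammaIntervalSpec(20.0, 80.0)]
        mix = compound_train(comps, 500.0, seed=6)
        expected_mean = 0.5 * (1 / 50.0 + 1 / 80.0)
        iv = mix.intervals()
        assert iv.mean() == pytest.approx(expected_mean, rel=0.05)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            compound_train([], 10.0, seed=0)

    def test_bad_weights_rejected(self):
        comps = [GammaIntervalSpec(1.0, 40.0), GammaIntervalSpec(2.0, 40.0)]
        with pytest.raises(ValueError):
            compound_train(comps, 10.0, seed=0, weights=[1.0])
        with pytest.raises(ValueError):
            compound_train(comps, 10.0, seed=0, weights=[-1.0, 2.0])


@pytest.fixture(scope="module")
def theta():
    return sample_gamma_train(GammaIntervalSpec(10**1.5, 7.0), 200.0, seed=20)


class TestModulatedTrain:
    def test_no_event_in_dropped_half_cycle(self, theta):
        period = 1.0 / 7.0
        carrier = GammaIntervalSpec(10**1.5, 80.0)
        out = modulated_train(carrier, theta, period, (0.0, 0.5), 200.0, seed=21)
        idx = np.searchsorted(theta.times, out.times, side="right") - 1
        phase = (out.times - theta.times[idx]) / period
        assert np.all(phase < 0.5)
        assert out.times[0] >= theta.times[0]

    def test_full_keep_window_preserves_carrier(self, theta):
        carrier = GammaIntervalSpec(10**1.5, 80.0)
        kept = modulated_train(carrier, theta, 1.0 / 7.0, (0.0, 1.0), 200.0, seed=22)
        raw = sample_gamma_train(carrier, 200.0, seed=22)
        expected = raw.times[raw.times >= theta.times[0]]
        # events whose latency exceeds one modulator period still fall in [0,1)
        # only if the next theta event has not occurred; with regular theta at
        # 7 Hz and keep=[0,1) every post-onset event survives
        surviving = expected[
            (expected - theta.times[np.searchsorted(theta.times, expected, "right") - 1])
            / (1.0 / 7.0)
            < 1.0
        ]
        np.testing.assert_array_equal(kept.times, surviving)

    def test_retained_rate_matches_kept_time_fraction(self, theta):
        period = 1.0 / 7.0
        carrier = GammaIntervalSpec(10**1.5, 80.0)
        out = modulated_train(carrier, theta, period, (0.0, 0.5), 200.0, seed=23)
        # oracle: measure the kept-time fraction directly on a fine grid
        grid = np.arange(theta.times[0], 200.0, 1e-3)
        idx = np.searchsorted(theta.times, grid, side="right") - 1
        phase = (grid - theta.times[idx]) / period
        frac = np.mean(phase < 0.5) * (200.0 - theta.times[0]) / 200.0
        assert out.rate == pytest.approx(80.0 * frac, rel=0.05)

    def test_empty_modulator_rejected(self):
        empty = EventTrain(np.array([]), 10.0)
        with pytest.raises(ValueError):
            modulated_train(GammaIntervalSpec(1.0, 40.0), empty, 0.1, (0.0, 0.5), 10.0, 0)


class TestEventsToPulse:
    def test_events_land_on_rounded_samples(self):
        train = EventTrain(np.array([0.1, 0.2]), 1.0)
        pulse = events_to_pulse(train, FS)
        assert pulse.values.sum() == 2
        assert pulse.values[100] == 1 and pulse.values[200] == 1

    def test_empty_train_gives_zeros(self):
        pulse = events_to_pulse(EventTrain(np.array([]), 1.0), FS)
        assert pulse.values.shape == (1000,)
        assert pulse.values.sum() == 0

    def test_bin_collision_clips_and_is_counted(self):
        train = EventTrain(np.array([0.1000, 0.1003]), 1.0)
        pulse = events_to_pulse(train, FS)
        assert pulse.values.sum() == 1
        assert pulse.n_collisions == 1
        counting = events_to_pulse(train, FS, mode="count")
        assert counting.values[100] == 2

    def test_unknown_mode_rejected(self):
        train = EventTrain(np.array([0.1]), 1.0)
        with pytest.raises(ValueError):
            events_to_pulse(train, FS, mode="analog")


class TestAnalyticRenewalPsd:
    def test_poisson_spectrum_is_flat_at_the_rate(self):
        f = np.arange(2.0, 501.0, 2.0)
        s = analytic_renewal_psd(GammaIntervalSpec(1.0, 40.0), f)
        np.testing.assert_allclose(s.power, 40.0, rtol=1e-10)

    def test_regular_process_peaks_at_its_rate_with_flat_tail(self):
        f = np.arange(2.0, 501.0, 2.0)
        s = analytic_renewal_psd(GammaIntervalSpec(10**1.5, 40.0), f)
        assert f[np.argmax(s.power)] == pytest.approx(40.0, abs=2.0)
        assert s.power[-1] == pytest.approx(40.0, rel=0.01)

    def test_bursty_process_spectrum_decays_monotonically(self):
        f = np.arange(2.0, 501.0, 2.0)
        s = analytic_renewal_psd(GammaIntervalSpec(0.1, 40.0), f)
        assert np.all(np.diff(s.power) < 0)

    def test_dc_rejected(self):
        with pytest.raises(ValueError):
            analytic_renewal_psd(GammaIntervalSpec(1.0, 40.0), [0.0, 2.0])


class TestIntervalHistogram:
    def test_poisson_density_is_exponential(self, poisson40_train):
        hist = interval_histogram(poisson40_train, 0.002, 0.2)
        expected = 40.0 * np.exp(-40.0 * hist.bin_centers)
        mask = expected > 1.0  # skip the far tail where counts are sparse
        np.testing.assert_allclose(hist.density[mask], expected[mask], rtol=0.25)

    def test_integral_close_to_one(self, poisson40_train):
        hist = interval_histogram(poisson40_train, 0.002, 0.5)
        assert hist.density.sum() * 0.002 == pytest.approx(1.0, abs=0.01)

    def test_regular_process_mode_near_mean_interval(self, regular40_train):
        hist = interval_histogram(regular40_train, 0.002, 0.1)
        mode = hist.bin_centers[np.argmax(hist.density)]
        assert mode == pytest.approx(0.025, abs=0.004)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            interval_histogram(EventTrain(np.array([0.1]), 1.0), 0.002, 0.1)


class TestTrainStatistics:
    def test_fano_ordering_matches_taxonomy(self):
        dur = 500.0
        fano = {
            shape: train_statistics(
                sample_gamma_train(GammaIntervalSpec(shape, 40.0), dur, seed=30), 1.0
            )["fano_factor"]
            for shape in (0.1, 1.0, 10**1.5)
        }
        assert fano[0.1] > 1.5
        assert abs(fano[1.0] - 1.0) < 0.15
        assert fano[10**1.5] < 0.5

    def test_short_recording_rejected(self):
        train = periodic_train(40.0, 5.0)
        with pytest.raises(ValueError):
            train_statistics(train, 1.0)
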