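import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiroqc import (
    CleanParams,
    DegenerateCurveError,
    InputError,
    Maneuver,
    compute_indices,
    compute_t_zero,
    differentiate,
    generate_clean,
    integrate_flow,
    smooth,
)

from .conftest import random_clean_params
from .oracles import dense_cumulative_volume, t_zero_exhaustive


class TestIntegrateFlow:
    def test_constant_flow_integrates_to_duration(self):
        t = np.arange(0, 1.0001, 0.01)
        v = integrate_flow(np.ones_like(t), t)
        assert v[0] == 0.0
        assert v[-1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_flow_gives_zero_volume(self):
        t = np.arange(0, 1.0001, 0.01)
        assert np.all(integrate_flow(np.zeros_like(t), t) == 0.0)

    def test_triangular_ramp_against_dense_riemann_oracle(self):
        def tri(t):
            return np.where(t <= 1.0, 2.0 * t, 2.0 * (2.0 - t))

        t = np.arange(0, 2.0001, 0.01)
        v = integrate_flow(tri(t), t)
        assert v[-1] == pytest.approx(2.0, abs=1e-3)
        t_dense, v_dense = dense_cumulative_volume(tri, 2.0, rate=1000.0)
        expected = np.interp(t, t_dense, v_dense)
        assert np.max(np.abs(v - expected)) < 1e-3

    def test_nondecreasing_for_nonnegative_flow(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 3, 0.01)
        f = np.abs(rng.standard_normal(t.size))
        assert np.all(np.diff(integrate_flow(f, t)) >= 0)

    @pytest.mark.parametrize(
        "flow,time",
        [
            (np.ones(5), np.arange(6.0)),
            (np.ones(5), np.array([0.0, 1.0, 1.0, 2.0, 3.0])),
        ],
    )
    def test_invalid_inputs_raise(self, flow, time):
        with pytest.raises(InputError):
            integrate_flow(flow, time)


class TestDifferentiate:
    def test_linear_signal_has_constant_slope(self):
        t = np.arange(0, 2, 0.01)
        d = differentiate(3.0 * t, t, order=1)
        assert np.max(np.abs(d[1:-1] - 3.0)) < 1e-9

    def test_constant_signal_has_zero_derivatives(self):
        t = np.arange(0, 2, 0.01)
        for order in (1, 2):
            assert np.max(np.abs(differentiate(np.full_like(t, 5.0), t, order))) < 1e-9

    def test_sine_first_derivative_matches_closed_form(self):
        t = np.arange(0, 1, 0.001)
        d = differentiate(np.sin(2 * np.pi * t), t, order=1)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(d[1:-1] - expected[1:-1])) < 1e-3

    def test_invalid_order_raises(self):
        t = np.arange(0, 1, 0.01)
        with pytest.raises(InputError):
            differentiate(t, t, order=3)

    def test_integrate_then_differentiate_recovers_band_limited_flow(self):
        # 100 Hz sampling, flow band-limited well below Nyquist.
        t = np.arange(0, 4, 0.01)
        f = 2.0 + np.sin(2 * np.pi * 0.9 * t) + 0.5 * np.cos(2 * np.pi * 1.6 * t)
        recovered = differentiate(integrate_flow(f, t), t, order=1)
        rel_err = np.max(np.abs(recovered[1:-1] - f[1:-1])) / np.max(np.abs(f))
        assert rel_err < 1e-3


class TestSmooth:
    def test_constant_signal_invariant(self):
        x = np.full(200, 3.7)
        assert np.allclose(smooth(x, 0.5, 100.0), x)

    def test_zero_window_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        assert np.array_equal(smooth(x, 0.0, 100.0), x)

    def test_impulse_amplitude_reduced_and_matches_local_fit_oracle(self):
        rng = np.random.default_rng(2)
        x = 0.1 * rng.standard_normal(101)
        x[50] += 1.0
        y = smooth(x, 0.05, 100.0)
        assert abs(y[50]) < abs(x[50])
        # independent local quadratic least-squares fit at the impulse sample
        w = 5  # 50 ms at 100 Hz
        idx = np.arange(50 - w // 2, 50 + w // 2 + 1)
        coeffs = np.polyfit(idx - 50, x[idx], 2)
        assert y[50] == pytest.approx(np.polyval(coeffs, 0.0), abs=1e-12)

    def test_window_longer_than_record_raises(self):
        with pytest.raises(InputError):
            smooth(np.zeros(50), 10.0, 100.0)


class TestTZero:
    def test_ramp_through_origin(self):
        t = np.arange(0, 5, 0.01)
        m = Maneuver.from_samples(t, volume=2.0 * t)
        assert abs(compute_t_zero(m)) <= 0.01 + 1e-9

    def test_shifted_ramp_crosses_at_half_second(self):
        t = np.arange(0, 8.0001, 0.01)
        m = Maneuver.from_samples(t, volume=np.maximum(0.0, 2.0 * (t - 0.5)))
        assert compute_t_zero(m) == pytest.approx(0.5, abs=0.02)

    def test_zero_flow_is_degenerate(self):
        t = np.arange(0, 2, 0.01)
        m = Maneuver(
            time=t,
            flow=np.zeros_like(t),
            volume=np.zeros_like(t),
            sample_rate=100.0,
        )
        with pytest.raises(DegenerateCurveError):
            compute_t_zero(m)

    def test_agrees_with_exhaustive_tangent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = generate_clean(random_clean_params(rng))
            assert abs(compute_t_zero(m) - t_zero_exhaustive(m)) <= 2.0 / m.sample_rate


class TestComputeIndices:
    def test_clean_generator_parameter_recovery(self, cfg):
        m = generate_clean(CleanParams(fvc=4.0, pef=8.0, rise_time=0.1, duration=8.0))
        ix = compute_indices(m, cfg)
        assert ix.fvc == pytest.approx(4.0, abs=0.02)
        assert ix.eotv <= 1e-3

    def test_exponential_volume_closed_form_fev1_ratio(self, cfg):
        tau = 0.5
        t = np.arange(0, 6.0001, 0.001)
        m = Maneuver.from_samples(t, volume=4.0 * (1.0 - np.exp(-t / tau)))
        tz = t_zero_exhaustive(m)
        ix = compute_indices(m, cfg)
        assert abs(ix.t_zero - tz) <= 2.0 / m.sample_rate
        assert ix.fev1 / ix.fvc == pytest.approx(1.0 - np.exp(-2.0), abs=1e-3)

    def test_constant_final_second_gives_zero_eotv(self, cfg):
        t = np.arange(0, 6.0001, 0.01)
        v = np.minimum(4.0, t)  # ramp, then flat from t = 4 s
        ix = compute_indices(Maneuver.from_samples(t, volume=v), cfg)
        assert ix.eotv == 0.0

    def test_short_record_flags_fev1_and_eotv_na(self, cfg):
        m = generate_clean(
            CleanParams(fvc=0.6, pef=8.0, rise_time=0.1, duration=0.9)
        )
        cfg_short = cfg.replace(z4_window=0.5)
        ix = compute_indices(m, cfg_short)
        assert np.isnan(ix.fev1) and np.isnan(ix.eotv)
        assert "FEV1" in ix.na_reasons and "EOTV" in ix.na_reasons

    def test_invariants_on_random_clean_fixtures(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = generate_clean(random_clean_params(rng))
            ix = compute_indices(m, cfg)
            assert 0.0 <= ix.fev1 <= ix.fvc + 1e-9
            assert ix.pef >= np.max(m.flow) - 1e-12
            assert ix.bev >= 0.0 and ix.eotv >= 0.0 and ix.fet100 >= 0.0
            assert ix.peft >= -ix.t_zero - 1e-9

    def test_indices_invariant_under_resampling(self, cfg):
        base = dict(fvc=4.0, pef=8.0, rise_time=0.1, duration=8.0)
        i100 = compute_indices(generate_clean(CleanParams(**base)), cfg)
        i500 = compute_indices(
            generate_clean(CleanParams(**base, sample_rate=500.0)), cfg
        )
        for name in ("fvc", "pef", "fet100"):
            a, b = getattr(i100, name), getattr(i500, name)
            assert abs(a - b) / a < 0.01


class TestManeuverIngest:
    def test_flow_only_and_volume_only_round_trip(self):
        t = np.arange(0, 5, 0.01)
        f = 3.0 * np.exp(-t)
        from_flow = Maneuver.from_samples(t, flow=f)
        from_vol = Maneuver.from_samples(t, volume=from_flow.volume)
        assert np.max(np.abs(from_vol.flow[1:-1] - f[1:-1])) < 0.01 * np.max(f)

    def test_nonuniform_time_is_resampled(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 5, 400))
        t[0], t[-1] = 0.0, 5.0
        m = Maneuver.from_samples(t, flow=np.exp(-t), resample_rate=100.0)
        assert m.sample_rate == 100.0
        assert np.allclose(np.diff(m.time), 0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"time": np.arange(5), "flow": np.ones(4)},
            {"time": np.zeros(10), "flow": np.ones(10)},
        ],
    )
    def test_invalid_samples_raise(self, kwargs):
        with pytest.raises(InputError):
            Maneuver.from_samples(**kwargs)

    def test_volume_offset_rejected(self):
        t = np.arange(0, 5, 0.01)
        with pytest.raises(InputError):
            Maneuver.from_samples(t, volume=1.0 + t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    amp=st.floats(0.1, 3.0),
    freq=st.floats(0.2, 1.0),
    offset=st.floats(0.5, 4.0),
)
def test_integration_differentiation_round_trip_property(amp, freq, offset):
    """Volume/flow duality: the derivative of the integral recovers any
    band-limited positive flow to 0.1% at 100 Hz."""
    t = np.arange(0, 4, 0.01)
    f = offset + amp * np.sin(2 * np.pi * freq * t)
    recovered = differentiate(integrate_flow(f, t), t, order=1)
    assert np.max(np.abs(recovered[1:-1] - f[1:-1])) / np.max(np.abs(f)) < 1e-3
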