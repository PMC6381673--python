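"""Window selection, residuals, sensitivities, the LM fit and its metric."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rodcascade as rc
from rodcascade.exceptions import ConfigError, MetricUndefinedError, WindowUndefinedError


@pytest.fixture(scope="module")
def nob_long_trace():
    """NOB trace past light-off so the trough is bracketed."""
    trace, truth = rc.generate_trace(
        "NOB", stimulus=rc.Stimulus(0.0, 0.3),
        grid=rc.SimulationGrid(0.0, 0.5, 1e-3, 5e-5))
    return trace, truth


class TestWindowSelection:
    def test_fixed_rule_keeps_samples_up_to_horizon(self):
        times = np.arange(301) * 1e-3
        trace = rc.ERGTrace(times, np.sin(times))
        start, stop = rc.select_fit_window(trace, "fixed", t_max=0.28)
        assert (start, stop) == (0, 281)  # t = 0.280 s inclusive
        assert times[stop - 1] <= 0.28 + 1e-12 < times[stop]

    def test_trough_rule_pads_past_extremum(self, nob_long_trace):
        trace, _ = nob_long_trace
        i_trough = int(np.argmax(np.abs(trace.amplitudes)))
        t_trough = trace.times[i_trough]
        start, stop = rc.select_fit_window(trace, "trough", pad=0.15)
        assert start == 0 and stop > i_trough
        assert trace.times[stop - 1] <= t_trough * 1.15 + 1e-12
        assert stop == len(trace) or trace.times[stop] > t_trough * 1.15

    def test_unbracketed_trough_is_an_error(self):
        times = np.arange(50) * 1e-3
        trace = rc.ERGTrace(times, -times)  # extremum at the final sample
        with pytest.raises(WindowUndefinedError):
            rc.select_fit_window(trace, "trough")

    def test_unknown_rule_rejected(self, nob_long_trace):
        with pytest.raises(ConfigError):
            rc.select_fit_window(nob_long_trace[0], "widest")


class TestResiduals:
    def test_self_consistency_is_zero(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        r = rc.residuals(trace, truth.params, truth.pools, fit_stimulus)
        assert np.max(np.abs(r)) <= 1e-9

    def test_constant_offset_passes_through(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        shifted = rc.ERGTrace(trace.times, trace.amplitudes + 3.5)
        r = rc.residuals(shifted, truth.params, truth.pools, fit_stimulus)
        np.testing.assert_allclose(r, 3.5, atol=1e-9)

    def test_noise_standard_deviation_recovered(self, fit_grid, fit_stimulus):
        trace, truth = rc.generate_trace(
            "NOB", stimulus=fit_stimulus, grid=fit_grid,
            noise=rc.NoiseSpec(sigma_fraction=0.02, seed=11))
        r = rc.residuals(trace, truth.params, truth.pools, fit_stimulus)
        assert np.std(r) == pytest.approx(truth.noise_sigma, rel=0.15)


class TestNumericalJacobian:
    def test_output_gain_column_is_analytic(self, nob, fit_grid):
        # with sign=+1, f is linear in k17 so df/dk17 = f / k17 exactly
        params, pools = nob
        stim = rc.Stimulus(0.0, 0.29)
        trace, _ = rc.generate_trace("NOB", stimulus=stim, grid=fit_grid, sign=1.0)
        J = rc.numerical_jacobian(trace, params, pools, ["k17"],
                                  stimulus=stim, sign=1.0)
        np.testing.assert_allclose(J[:, 0], trace.amplitudes / params.k17,
                                   rtol=1e-6, atol=1e-12)

    def test_forward_difference_truncation_halves_with_step(
            self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace

        def column(step):
            return rc.numerical_jacobian(trace, truth.params, truth.pools,
                                         ["k1u"], stimulus=fit_stimulus,
                                         step=step)[:, 0]

        ref = column(1e-7)  # near-exact reference
        e1 = np.linalg.norm(column(4e-3) - ref)
        e2 = np.linalg.norm(column(2e-3) - ref)
        assert e1 / e2 == pytest.approx(2.0, rel=0.25)

    def test_masked_parameters_get_no_column(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        J = rc.numerical_jacobian(trace, truth.params, truth.pools,
                                  ["k1u", "k17", "cG0"], stimulus=fit_stimulus)
        assert J.shape == (len(trace), 3)

    def test_normalization_reference_never_free(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        with pytest.raises(ConfigError):
            rc.numerical_jacobian(trace, truth.params, truth.pools, ["R0"],
                                  stimulus=fit_stimulus)


class TestLevenbergMarquardt:
    def test_truth_start_converges_immediately(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        cfg = rc.FitConfig(free=("k1u",), params=truth.params, pools=truth.pools,
                           window="fixed", t_max=0.28)
        res = rc.lm_fit(trace, cfg, stimulus=fit_stimulus)
        assert res.converged and res.n_iter <= 2
        assert res.relative_error_pct <= 1e-6

    def test_single_parameter_recovery(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        start = truth.params.replace(k1u=1.5 * truth.params.k1u)
        cfg = rc.FitConfig(free=("k1u",), params=start, pools=truth.pools,
                           window="fixed", t_max=0.28)
        res = rc.lm_fit(trace, cfg, stimulus=fit_stimulus)
        assert res.converged
        assert res.params.k1u == pytest.approx(0.6717, rel=1e-3)

    def test_two_parameter_recovery(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        start = truth.params.replace(k1u=1.5 * truth.params.k1u,
                                     k17=1.5 * truth.params.k17)
        cfg = rc.FitConfig(free=("k1u", "k17"), params=start, pools=truth.pools,
                           window="fixed", t_max=0.28)
        res = rc.lm_fit(trace, cfg, stimulus=fit_stimulus)
        assert res.converged
        assert res.params.k1u == pytest.approx(0.6717, rel=5e-3)
        assert res.params.k17 == pytest.approx(1649.2012, rel=5e-3)

    def test_accepted_costs_never_increase(self, fit_grid, fit_stimulus):
        trace, truth = rc.generate_trace(
            "NOB", stimulus=fit_stimulus, grid=fit_grid,
            noise=rc.NoiseSpec(sigma_fraction=0.05, seed=3))
        start = truth.params.replace(k1u=2.0 * truth.params.k1u)
        cfg = rc.FitConfig(free=("k1u", "k16"), params=start, pools=truth.pools,
                           window="fixed", t_max=0.28)
        res = rc.lm_fit(trace, cfg, stimulus=fit_stimulus)
        assert len(res.cost_history) >= 2
        assert np.all(np.diff(res.cost_history) <= 0.0)

    def test_samples_outside_window_never_influence_fit(self, fit_stimulus):
        trace, truth = rc.generate_trace(
            "NOB", stimulus=rc.Stimulus(0.0, 0.3),
            grid=rc.SimulationGrid(0.0, 0.3, 1e-3, 5e-5),
            noise=rc.NoiseSpec(sigma_fraction=0.02, seed=5))
        start = truth.params.replace(k1u=1.5 * truth.params.k1u)
        cfg = rc.FitConfig(free=("k1u",), params=start, pools=truth.pools,
                           window="fixed", t_max=0.25)
        res1 = rc.lm_fit(trace, cfg, stimulus=rc.Stimulus(0.0, 0.3))
        corrupted = trace.amplitudes.copy()
        corrupted[trace.times > 0.25 + 1e-12] += 500.0
        res2 = rc.lm_fit(rc.ERGTrace(trace.times, corrupted), cfg,
                         stimulus=rc.Stimulus(0.0, 0.3))
        assert res1.params.k1u == res2.params.k1u  # bit-identical path
        assert np.array_equal(res1.residual, res2.residual)

    def test_nonconvergence_reported_not_raised(self, nob_fit_trace, fit_stimulus):
        trace, truth = nob_fit_trace
        start = truth.params.replace(k1u=1.5 * truth.params.k1u)
        cfg = rc.FitConfig(free=("k1u",), params=start, pools=truth.pools,
                           window="fixed", t_max=0.28, max_iter=1)
        res = rc.lm_fit(trace, cfg, stimulus=fit_stimulus)
        assert not res.converged and res.message


class TestRelativeError:
    def test_perfect_and_null_models(self):
        data = np.array([1.0, -2.0, 3.0])
        assert rc.relative_error(data, data) == 0.0
        assert rc.relative_error(data, np.zeros(3)) == pytest.approx(100.0)

    def test_pythagorean_triple(self):
        assert rc.relative_error(np.array([3.0, 4.0]),
                                 np.array([3.0, 0.0])) == pytest.approx(80.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        data = np.array([1.0, 2.0, -1.5])
        model = np.array([0.9, 2.2, -1.0])
        assert rc.relative_error(c * data, c * model) == pytest.approx(
            rc.relative_error(data, model), rel=1e-9)

    def test_zero_data_norm_is_undefined(self):
        with pytest.raises(MetricUndefinedError):
            rc.relative_error(np.zeros(4), np.ones(4))


def test_group_average_converges_on_common_grid():
    grid = rc.SimulationGrid(0.0, 0.2, 2e-3, 5e-5)
    stim = rc.Stimulus(0.0, 0.21)
    traces = [
        rc.generate_trace("NOB", stimulus=stim, grid=grid,
                          noise=rc.NoiseSpec(0.05, seed=s))[0]
        for s in (1, 2, 3, 4)
    ]
    clean, _ = rc.generate_trace("NOB", stimulus=stim, grid=grid)
    mean = rc.average_traces(traces)
    d_mean = np.linalg.norm(mean.amplitudes - clean.amplitudes)
    d_single = np.linalg.norm(traces[0].amplitudes - clean.amplitudes)
    assert d_mean < d_single
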