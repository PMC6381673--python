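"""Fixed-step RK4 simulation: accuracy, conservation, qualitative shape."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import rodcascade as rc
from rodcascade.exceptions import ConfigError, IntegrationError
from rodcascade.model import _make_rhs


def _scipy_rhs(t, x, params, pools, stim):
    rhs = _make_rhs(params, pools)
    return rhs(*x, params.k1u if stim.active(t) else 0.0)


def test_dark_run_stays_at_fixed_point(nob):
    params, pools = nob
    stim = rc.Stimulus(10.0, 11.0)  # never on within the grid
    sim = rc.simulate(params, pools, stim, rc.SimulationGrid(0.0, 0.2, 1e-3, 1e-4))
    assert np.all(sim.signal == 0.0)
    assert np.all(sim.states == rc.dark_state(pools))


def test_step_halving_shows_fourth_order(nob):
    # smooth sub-problem: light on throughout, compare end states
    params, pools = nob
    stim = rc.Stimulus(0.0, 1.0)
    ends = []
    for dt in (2e-4, 1e-4, 5e-5):
        grid = rc.SimulationGrid(0.0, 0.2, 2e-3, dt)
        ends.append(rc.simulate(params, pools, stim, grid).states[-1])
    e_coarse = np.max(np.abs(ends[0] - ends[1]))
    e_fine = np.max(np.abs(ends[1] - ends[2]))
    order = np.log2(e_coarse / e_fine)
    assert order >= 3.5


def test_matches_adaptive_reference_solver(nob):
    params, pools = nob
    stim = rc.Stimulus(0.0, 0.31)
    sim = rc.simulate(params, pools, stim, rc.SimulationGrid(0.0, 0.3, 1e-3, 5e-5))
    ref = solve_ivp(_scipy_rhs, (0.0, 0.3), rc.dark_state(pools),
                    args=(params, pools, stim), t_eval=sim.times,
                    rtol=1e-11, atol=1e-13, method="LSODA")
    assert np.max(np.abs(sim.states - ref.y.T)) <= 1e-6


def test_flash_response_shape_and_return_to_dark(nob):
    # departs after onset, single trough, then monotone recovery to dark
    params, pools = nob
    sim = rc.simulate(params, pools, rc.Stimulus(0.0, 0.3),
                      rc.SimulationGrid(0.0, 4.0, 1e-3, 5e-5))
    f = sim.signal
    assert f[0] == 0.0
    i = int(np.argmax(np.abs(f)))
    assert 0 < i < len(f) - 1
    assert np.all(f[: i + 1] <= 0.0)  # negative-going a-wave
    after = np.abs(f[i:])
    assert np.all(np.diff(after) <= 1e-9 * after[0])  # monotone recovery
    trough = after[0]
    j = np.searchsorted(sim.times, 3.5)
    assert abs(f[j]) < 0.01 * trough  # back at dark value by 3.5 s


@pytest.mark.parametrize("group", ["NOB", "wild"])
@pytest.mark.parametrize("t_end", [0.3, 2.0])
def test_pool_bounds_conserved_nob_and_wild(group, t_end):
    params, pools = rc.fixture_parameters(group)
    sim = rc.simulate(params, pools, rc.Stimulus(0.0, 0.3),
                      rc.SimulationGrid(0.0, t_end, 1e-3, 5e-5))
    assert sim.diagnostics["max_pool_excess"] <= 1e-6
    assert not sim.diagnostics["negativity_warning"]


def test_drug_group_calcium_runs_negative_with_warning(drug):
    # the drug column's deep cGMP depletion makes the non-saturating Hill
    # efflux overwhelm Ca restoration; states are reported, not clipped
    params, pools = drug
    with pytest.warns(RuntimeWarning, match="dipped"):
        sim = rc.simulate(params, pools, rc.Stimulus(0.0, 0.3),
                          rc.SimulationGrid(0.0, 0.3, 1e-3, 5e-5))
    assert sim.diagnostics["min_state"] < -1.0
    assert sim.internal_states[:, 7].min() == sim.diagnostics["min_state"]


def test_peak_amplitude_monotone_in_photoactivation_rate(nob):
    params, pools = nob
    peaks = []
    for frac in (0.1, 0.5, 1.0):
        p = params.replace(k1u=frac * params.k1u)
        sim = rc.simulate(p, pools, rc.Stimulus(0.0, 0.31),
                          rc.SimulationGrid(0.0, 0.3, 1e-3, 5e-5))
        peaks.append(np.max(np.abs(sim.signal)))
    assert peaks[0] < peaks[1] < peaks[2]


class TestDarkEquilibriumCheck:
    @pytest.mark.parametrize("group", rc.FIXTURE_NAMES)
    def test_true_for_every_fixture(self, group):
        ok, resid = rc.check_dark_equilibrium(*rc.fixture_parameters(group))
        assert ok and resid == 0.0

    def test_displaced_cgmp_reports_restoring_flux(self, nob):
        params, pools = nob
        x = rc.dark_state(pools)
        x[5] = 0.9 * pools.cG0
        ok, resid = rc.check_dark_equilibrium(params, pools, state=x)
        assert not ok
        deriv = rc.reaction_rhs(x, params, pools, light_on=False)
        # cGMP buffer release alone restores component 6 at the displaced state
        assert deriv[5] == pytest.approx(params.k15 * 0.1 * pools.cG0, rel=1e-12)
        assert resid == np.max(np.abs(deriv))


def test_integration_failure_names_time(nob):
    # absurdly stiff rates blow up explicit RK4; the error carries t_fail
    params, pools = nob
    bad = params.replace(k4=1e9, k2=1e9)
    with pytest.raises(IntegrationError) as err:
        rc.simulate(bad, pools, rc.Stimulus(0.0, 1.0),
                    rc.SimulationGrid(0.0, 0.1, 1e-2, 1e-3))
    assert 0.0 < err.value.t_fail <= 0.1


def test_grid_validation():
    with pytest.raises(ConfigError):
        rc.SimulationGrid(0.0, 0.1, 1e-3, 3e-4)  # not an integer multiple
    with pytest.raises(ConfigError):
        rc.SimulationGrid(0.2, 0.1, 1e-3, 1e-4)
    with pytest.raises(ConfigError):
        rc.SimulationGrid(0.0, 0.1, 1e-4, 1e-3)  # internal coarser than output


def test_output_is_stride_subsample_of_internal(nob):
    params, pools = nob
    sim = rc.simulate(params, pools, rc.Stimulus(0.0, 0.2),
                      rc.SimulationGrid(0.0, 0.1, 1e-3, 2.5e-4))
    stride = sim.grid.stride
    assert np.array_equal(sim.signal, sim.internal_signal[::stride])
    assert np.array_equal(sim.states, sim.internal_states[::stride])
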