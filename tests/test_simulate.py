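"""Integrator behavior: chemostat limit, conservation, stability."""

import numpy as np
import pytest

import thermoniche as tn


def _constant_clim(temps):
    temps = np.asarray(temps, dtype=float)
    return tn.ClimatologyGrid(
        latitudes=np.arange(float(len(temps))),
        temperature=np.repeat(temps[:, None], 365, axis=1),
    )


def test_chemostat_relaxation_without_consumers():
    """With P = 0 the resource relaxes monotonically to R0 = 0.8 at dilution
    rate d = 0.864/d; per step |R - R0| shrinks by 1/(1 + d*dt) (the
    resource sinks are integrated implicitly)."""
    traits = tn.default_traits()
    params = tn.ModelParams()
    state = tn.ModelState(P=np.zeros((traits.n_species, 1)), R=np.array([1e-3]))
    T = np.array([15.0])
    devs = []
    for _ in range(400):
        devs.append(abs(state.R[0] - params.R_0))
        state = tn.step(state, T, traits, params)
    devs.append(abs(state.R[0] - params.R_0))
    devs = np.array(devs)
    ratio = 1.0 / (1.0 + params.d * params.dt)
    # geometric while the deviation is resolvable above float precision
    resolvable = devs[:60]
    assert np.allclose(resolvable[1:] / resolvable[:-1], ratio, rtol=1e-9)
    # e-folding time ~ 1/d = 1.157 d: after 5 days deviation is < 2%
    assert devs[int(5 / params.dt)] < 0.02 * devs[0]
    assert state.R[0] == pytest.approx(0.8, abs=1e-6)


def test_growth_at_optimum_with_no_mortality():
    """A lone species at its optimum temperature with abundant resource and
    gamma = 0 grows strictly over successive steps."""
    traits = tn.SpeciesTraits(z=np.array([20.0]))
    params = tn.ModelParams(gamma=0.0)
    state = tn.ModelState(P=np.array([[1e-3]]), R=np.array([0.8]))
    T = traits.t_fopt
    for _ in range(50):
        prev = state.P[0, 0]
        state = tn.step(state, T, traits, params)
        assert state.P[0, 0] > prev


def test_single_step_matches_hand_arithmetic():
    """One step of the documented scheme, recomputed with scalar arithmetic:
    explicit biomass update with clipping, Patankar-implicit resource."""
    traits = tn.SpeciesTraits(z=np.array([10.0, 25.0]), k=0.1)
    g = tn.ModelGrid(box_center_latitudes=np.array([0.0, 1.0]))
    tau = tn.build_dispersal_matrix(200.0, g)
    params = tn.ModelParams(gamma=0.1, K_H=200.0)
    P0 = np.array([[0.4, 0.02], [0.01, 1.3]])
    R0v = np.array([0.05, 0.3])
    T = np.array([12.0, 24.0])
    new = tn.step(tn.ModelState(P=P0.copy(), R=R0v.copy()), T, traits, params, tau=tau)

    dt, d, R0, k = params.dt, params.d, params.R_0, traits.k
    for j in range(2):
        lim = R0v[j] / (R0v[j] + k)
        cons, rel = 0.0, 0.0
        for i in range(2):
            mu = 0.81 * np.exp(0.0631 * T[j]) * (1 - ((T[j] - traits.z[i]) / 5.0) ** 2)
            mort = 0.1 * 0.81 * np.exp(0.0631 * T[j])
            other = 1 - j
            disp = tau[j, other] * P0[i, other] - tau[j, other] * P0[i, j]
            expected_P = P0[i, j] + dt * (mu * lim * P0[i, j] - mort * P0[i, j] + disp)
            expected_P = max(expected_P, 0.0)
            assert new.P[i, j] == pytest.approx(expected_P, rel=1e-12)
            if mu > 0:
                cons += mu * P0[i, j] / (R0v[j] + k)
            else:
                rel += -mu * lim * P0[i, j]
        expected_R = (R0v[j] + dt * (d * R0 + rel)) / (1 + dt * (d + cons))
        assert new.R[j] == pytest.approx(expected_R, rel=1e-12)


def test_dispersal_alone_conserves_biomass():
    """With growth and mortality switched off (a = 0), total biomass per
    species is invariant under dispersal to machine precision."""
    traits = tn.SpeciesTraits(z=np.array([0.0, 15.0, 30.0]), a=0.0)
    g = tn.ModelGrid(box_center_latitudes=np.arange(0.0, 15.0))
    tau = tn.build_dispersal_matrix(500.0, g)
    params = tn.ModelParams(gamma=0.05, K_H=500.0, d=0.0, R_0=0.0)
    rng = np.random.default_rng(11)
    state = tn.ModelState(P=rng.uniform(0.1, 2.0, (3, 15)), R=np.full(15, 0.4))
    totals0 = state.P.sum(axis=1)
    for _ in range(200):
        state = tn.step(state, np.full(15, 10.0), traits, params, tau=tau)
    assert np.allclose(state.P.sum(axis=1), totals0, rtol=1e-12)


def test_identical_boxes_stay_identical():
    """Two boxes with the same constant forcing and no dispersal follow
    bit-identical trajectories (deterministic, spatially symmetric model)."""
    clim = _constant_clim([18.0, 18.0])
    grid = tn.ModelGrid(clim.latitudes)
    params = tn.ModelParams(gamma=0.05, K_H=0.0, years=3, analysis_window_years=2)
    forcing = tn.to_forcing(clim, params.dt, 3, "constant")
    traj = tn.run_simulation(tn.default_traits(), grid, params, forcing)
    assert np.array_equal(traj.P_series[..., 0], traj.P_series[..., 1])
    assert np.array_equal(traj.R_series[:, 0], traj.R_series[:, 1])


def test_state_remains_non_negative():
    clim = _constant_clim(np.linspace(0, 28, 8))
    grid = tn.ModelGrid(clim.latitudes)
    params = tn.ModelParams(gamma=0.2, K_H=100.0, years=2, analysis_window_years=1)
    forcing = tn.to_forcing(clim, params.dt, 2, "constant")
    traj = tn.run_simulation(tn.default_traits(), grid, params, forcing)
    assert np.all(traj.P_series >= 0)
    assert np.all(traj.R_series >= 0)


def test_halving_timestep_changes_outcome_below_one_percent():
    """Scheme adequacy: halving dt changes the final-year mean community
    biomass in every box by < 1% in the control configuration."""
    clim = _constant_clim(np.linspace(2, 27, 10))
    grid = tn.ModelGrid(clim.latitudes)
    traits = tn.default_traits()
    finals = {}
    for dt, stride in ((0.125, 8), (0.0625, 16)):
        params = tn.ModelParams(gamma=0.05, K_H=0.0, years=10, dt=dt,
                                save_stride=stride, analysis_window_years=5)
        forcing = tn.to_forcing(clim, dt, 10, "constant")
        traj = tn.run_simulation(traits, grid, params, forcing)
        spy = traj.snapshots_per_year
        finals[dt] = traj.P_series[-spy:].mean(axis=0).sum(axis=0)  # per box
    rel = np.abs(finals[0.125] - finals[0.0625]) / finals[0.0625]
    assert np.all(rel < 0.01)


def test_trajectory_window_bookkeeping():
    clim = _constant_clim([10.0, 20.0])
    grid = tn.ModelGrid(clim.latitudes)
    params = tn.ModelParams(years=4, analysis_window_years=2)
    forcing = tn.to_forcing(clim, params.dt, 4, "constant")
    traj = tn.run_simulation(tn.default_traits(), grid, params, forcing)
    assert traj.n_snapshots == 2 * 365
    assert traj.window_years() == 2
    assert np.allclose(np.diff(traj.times), 1.0)
    assert traj.times[0] == pytest.approx((4 - 2) * 365.0)
    assert traj.yearly_means().shape == (2, 45, 2)
    # run maximum bounds every saved snapshot
    assert np.all(traj.P_series <= traj.P_max[None] + 1e-15)


def test_mismatched_forcing_rejected():
    clim = _constant_clim([10.0, 20.0])
    grid = tn.ModelGrid(np.arange(3.0))
    forcing = tn.to_forcing(clim, 0.125, 2, "constant")
    with pytest.raises(ValueError):
        tn.run_simulation(tn.default_traits(), grid,
                          tn.ModelParams(years=2, analysis_window_years=1), forcing)
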