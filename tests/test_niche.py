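"""Extantness, realized-niche estimation, diversity, transport."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

import thermoniche as tn
from thermoniche.niche import NICHE_GRID, _density_percentile_span


def make_traj(P_series, T_series=None, z=None, stride=8):
    """Assemble a Trajectory directly from snapshot arrays (daily snapshots
    unless stride says otherwise; window covers all supplied years)."""
    t, ns, nb = P_series.shape
    spy = int(round(365 / (stride * 0.125)))
    window = t // spy
    params = tn.ModelParams(years=window + 1, analysis_window_years=window,
                            save_stride=stride)
    if T_series is None:
        T_series = np.full((t, nb), 15.0)
    if z is None:
        z = np.linspace(0.0, 30.0, ns)
    return tn.Trajectory(
        times=np.arange(t) * stride * 0.125,
        P_series=np.asarray(P_series, dtype=float),
        R_series=np.full((t, nb), 0.1),
        T_series=np.asarray(T_series, dtype=float),
        P_max=P_series.max(axis=0),
        params=params,
        traits=tn.SpeciesTraits(z=np.asarray(z, dtype=float)),
        latitudes=np.arange(float(nb)),
        forcing_mode="constant",
    )


class TestExtantness:
    def test_constant_population_is_extant(self):
        P = np.zeros((5 * 365, 3, 1))
        P[:, 0, 0] = 1.0  # steady
        P[:, 1, 0] = 0.0  # never present
        traj = make_traj(P)
        rep = tn.classify_extant(traj)
        assert rep.extant[0, 0]
        assert not rep.extant[1, 0]

    def test_geometric_decay_fails_steadiness(self):
        """A species halving every year through the window is classified
        extirpated by the steady-state criterion even though it stays
        above the abundance threshold."""
        t = np.arange(5 * 365)
        P = np.zeros((t.size, 2, 1))
        P[:, 0, 0] = 1.0
        P[:, 1, 0] = 2.0 ** (-t / 365.0)  # halves each year
        traj = make_traj(P)
        traj.P_max[1, 0] = 1.0
        rep = tn.classify_extant(traj)
        assert rep.criterion1_pass[1, 0]
        assert not rep.criterion2_pass[1, 0]
        assert not rep.extant[1, 0]
        assert rep.extant[0, 0]

    def test_global_vs_per_box_reference(self):
        """A dispersal-fed remnant (1e-6 of the species' population scale,
        steady) is extant under the per-box reading but not the global one."""
        P = np.zeros((5 * 365, 1, 2))
        P[:, 0, 0] = 2.0
        P[:, 0, 1] = 2e-6
        traj = make_traj(P)
        assert not tn.classify_extant(traj, reference="global").extant[0, 1]
        assert tn.classify_extant(traj, reference="per_box").extant[0, 1]

    def test_window_longer_than_trajectory_rejected(self):
        P = np.ones((2 * 365, 2, 1))
        traj = make_traj(P)
        object.__setattr__(traj.params, "analysis_window_years", 5)
        with pytest.raises(ValueError):
            tn.classify_extant(traj)


class TestKDE:
    def test_matches_reference_implementation(self):
        """On an unbinned weighted sample the density agrees with scipy's
        gaussian_kde (Silverman bandwidth, weighted) to float precision."""
        rng = np.random.default_rng(7)
        x = rng.uniform(5, 25, 500)
        w = rng.uniform(0.1, 2.0, 500)
        ours, h = tn.weighted_kde_density(x, w, min_bandwidth=0.0)
        ref = gaussian_kde(x, bw_method="silverman", weights=w)
        assert np.allclose(ours, ref(NICHE_GRID), atol=1e-12)
        assert h == pytest.approx(np.sqrt(ref.covariance[0, 0]), rel=1e-9)

    def test_uniform_band_width_recovery(self):
        """Biomass uniform over [10, 20] °C: the 1-99 percentile span of the
        fitted density recovers the analytic 9.8 °C within bandwidth
        tolerance."""
        x = np.linspace(10.0, 20.0, 200001)
        density, _ = tn.weighted_kde_density(x, np.ones_like(x))
        w_r = _density_percentile_span(density, NICHE_GRID)
        assert w_r == pytest.approx(9.8, abs=0.3)
        assert 10.0 <= NICHE_GRID[np.argmax(density)] <= 20.0

    def test_point_mass_limit(self):
        """All biomass at one temperature: the optimum is that temperature
        and the width is set by the kernel floor alone."""
        x = np.full(200, 13.37)
        density, h = tn.weighted_kde_density(x, np.ones(200))
        assert h == 0.1  # bandwidth floor engaged
        assert NICHE_GRID[np.argmax(density)] == pytest.approx(13.4, abs=0.051)
        assert _density_percentile_span(density, NICHE_GRID) < 1.0

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(15, 2, 4000)
        w = rng.uniform(0.5, 1.5, 4000)
        d1, h1 = tn.weighted_kde_density(x, w)
        d2, h2 = tn.weighted_kde_density(x, 2.0 * w)
        assert np.array_equal(d1, d2) and h1 == h2

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            tn.weighted_kde_density(np.array([1.0]), np.array([0.0]))


class TestContrasts:
    @pytest.mark.parametrize("w_r,expected", [(10.0, 0.0), (15.0, 0.5), (5.0, -0.5)])
    def test_delta_w(self, w_r, expected):
        assert tn.delta_w(w_r) == pytest.approx(expected)

    def test_delta_w_requires_positive_fundamental_width(self):
        with pytest.raises(ValueError):
            tn.delta_w(5.0, 0.0)

    def test_delta_topt_values_and_flags(self):
        assert tn.delta_topt(20.0, 20.0) == (0.0, False)
        val, flag = tn.delta_topt(19.0, 20.0)
        assert val == pytest.approx(-0.05) and not flag
        val, flag = tn.delta_topt(2.0, 0.2)  # near-zero optimum blows up
        assert val == pytest.approx(9.0) and flag
        val, flag = tn.delta_topt(2.0, 0.0)
        assert np.isnan(val) and flag


class TestRealizedNiche:
    def test_species_extant_nowhere_has_no_niche(self):
        P = np.zeros((365, 2, 2))
        P[:, 0, :] = 1.0
        traj = make_traj(P)
        rep = tn.classify_extant(traj)
        with pytest.raises(ValueError, match="no realized niche"):
            tn.realized_niche(traj, rep, species=1)

    def test_biomass_rescaling_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(9)
        P = rng.uniform(0.5, 1.5, (365, 1, 4))
        T = np.tile(np.array([8.0, 12.0, 16.0, 20.0]), (365, 1))
        traj = make_traj(P, T_series=T, z=[10.0])
        rep = tn.classify_extant(traj)
        est1 = tn.realized_niche(traj, rep, 0)
        traj2 = make_traj(3.0 * P, T_series=T, z=[10.0])
        est2 = tn.realized_niche(traj2, rep, 0)
        assert est1.t_ropt == est2.t_ropt
        assert est1.w_r == pytest.approx(est2.w_r, rel=1e-12)

    def test_niche_table_schema(self):
        P = np.full((365, 2, 3), 1.0)
        T = np.tile(np.array([10.0, 15.0, 20.0]), (365, 1))
        traj = make_traj(P, T_series=T, z=[10.0, 12.0])
        df = tn.estimate_all_niches(traj)
        assert list(df.columns) == [
            "species", "z", "T_Fopt", "T_Ropt", "W_R", "delta_W",
            "delta_Topt", "n_boxes_present", "flag_low_T_Fopt",
        ]
        assert len(df) == 2
        assert np.all(df.W_R >= 0)


class TestDiversity:
    def test_all_zero_trajectory(self):
        traj = make_traj(np.zeros((365, 3, 2)))
        div = tn.diversity_profile(traj)
        assert np.all(div.S_bar == 0) and np.all(div.S_T == 0)

    def test_hand_counted_presence(self):
        """Species A present all window, B present half of every year:
        S_bar = 1.5, S_T = 2 (hand count)."""
        spy = 730  # stride 4 -> even number of snapshots per year
        P = np.zeros((5 * spy, 2, 1))
        P[:, 0, 0] = 1.0
        for y in range(5):
            P[y * spy: y * spy + spy // 2, 1, 0] = 1.0
        traj = make_traj(P, stride=4)
        div = tn.diversity_profile(traj)
        assert div.S_bar[0] == pytest.approx(1.5)
        assert div.S_T[0] == 2
        assert np.all(div.S_bar <= div.S_T)

    def test_transient_remnants_not_counted(self):
        """The steadiness gate keeps a decaying excluded competitor out of
        the diversity count even while it is above threshold."""
        t = np.arange(5 * 365)
        P = np.zeros((t.size, 2, 1))
        P[:, 0, 0] = 1.0
        P[:, 1, 0] = 0.5 * 10.0 ** (-t / 365.0)
        traj = make_traj(P)
        div = tn.diversity_profile(traj)
        assert div.S_T[0] == 1


class TestNetTransport:
    def test_source_sink_structure(self):
        """For a peaked biomass profile the maximum is a source (negative
        net transport), the transport sums to zero, and a uniform profile
        transports nothing."""
        nb = 9
        lats = np.arange(float(nb))
        profile = np.exp(-0.5 * ((lats - 4.0) / 1.5) ** 2)
        P = np.tile(profile, (10, 1, 1))
        traj = make_traj(P, T_series=np.tile(lats, (10, 1)), z=[15.0], stride=4)
        tau = tn.build_dispersal_matrix(100.0, tn.ModelGrid(lats))
        transport = tn.net_transport_diagnostic(traj, tau, species=0, snapshot=3)
        assert transport.sum() == pytest.approx(0.0, abs=1e-15)
        assert transport[4] < 0
        uniform = make_traj(np.ones((10, 1, nb)), stride=4)
        assert np.allclose(
            tn.net_transport_diagnostic(uniform, tau, 0, 0), 0.0, atol=1e-15
        )
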