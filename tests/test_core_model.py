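"""Occupancy, steady state, dynamics and linear-regime closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binddiscard import (
    KineticParams,
    estimate_kp_from_slope,
    integrate_dynamics,
    kp_grid,
    linear_regime,
    site_occupancy,
    steady_state,
    titration_curve,
)
from binddiscard.params import ParameterError


class TestSiteOccupancy:
    @pytest.mark.parametrize(
        "u, p, ka, expect",
        [
            (0.0, 0.0, 5.0, dict(p_empty=1.0, p_up=0.0, p_p=0.0)),
            (3.0, 0.0, 3.0, dict(p_up=0.5, p_empty=0.5)),
            (2000.0, 100.0, 1.0, dict(p_up=2000 / 2101, p_p=100 / 2101, p_empty=1 / 2101)),
        ],
    )
    def test_closed_form(self, u, p, ka, expect):
        occ = site_occupancy(u, p, ka)
        for k, v in expect.items():
            assert getattr(occ, k) == pytest.approx(v, rel=1e-12)

    @given(
        u=st.floats(0, 1e6),
        p=st.floats(0, 1e6),
        ka=st.floats(1e-3, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_probabilities_normalized(self, u, p, ka):
        occ = site_occupancy(u, p, ka)
        assert occ.p_empty + occ.p_up + occ.p_p == pytest.approx(1.0, abs=1e-12)
        for prob in (occ.p_empty, occ.p_up, occ.p_p):
            assert 0.0 <= prob <= 1.0
        assert occ.Z == pytest.approx(1 + occ.alpha_up + occ.alpha_p)

    @pytest.mark.parametrize("bad", [(-1, 0, 1), (0, -1, 1), (0, 0, 0), (np.nan, 0, 1)])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterError):
            site_occupancy(*bad)


class TestSteadyState:
    def test_no_sites_is_baseline(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.5)
        ss = steady_state(p)
        assert ss.NICD_tot == 2000.0
        assert ss.NICD_p == 0.0
        assert ss.converged

    def test_no_phosphorylation_protects(self):
        # kp=0: nothing is ever phosphorylated; binding can only sequester,
        # adding at most one protected molecule per site
        p = KineticParams(
            NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.0,
            k_alpha=0.1, N_e=0.0, N_s=20,
        )
        ss = steady_state(p)
        assert ss.NICD_p == pytest.approx(0.0, abs=1e-9)
        assert 2000.0 <= ss.NICD_tot <= 2000.0 + 20 + 1e-6

    def test_matches_long_time_integration(self, central_params):
        ss = steady_state(central_params)
        traj = integrate_dynamics(central_params, [0.0, 1e5])
        assert traj.NICD_tot_t[-1] == pytest.approx(ss.NICD_tot, rel=1e-6)

    def test_pool_bookkeeping(self, central_params):
        ss = steady_state(central_params)
        N = central_params.n_sites_total
        assert ss.NICD_tot == pytest.approx(ss.NICD_up + ss.NICD_p, rel=1e-12)
        assert ss.NICD_up == pytest.approx(ss.NICD_up_b + ss.NICD_up_ub, rel=1e-12)
        assert ss.NICD_p == pytest.approx(ss.NICD_p_b + ss.NICD_p_ub, rel=1e-12)
        assert ss.NICD_up_b + ss.NICD_p_b <= N + 1e-9
        assert min(ss.NICD_up_b, ss.NICD_p_b, ss.NICD_up_ub, ss.NICD_p_ub) >= -1e-9
        assert ss.residual_norm <= 1e-10 * central_params.NICD0

    def test_monotonicity_depends_on_net_drain(self):
        # sites lower total NICD iff the per-site drain kp'(1 - 1/Gp')
        # exceeds the one-molecule sequestration protection
        base = dict(NICD0=1000.0, Gamma_up=1 / 120, Gamma_p=1 / 8, k_alpha=0.5, N_e=0.0)
        draining = KineticParams(k_p=0.5, **base)  # kp' c = 56 > 1
        protecting = KineticParams(k_p=0.004, **base)  # kp' c = 0.448 < 1
        for p, decreasing in ((draining, True), (protecting, False)):
            tots = [steady_state(p.replace(N_s=n)).NICD_tot for n in (0, 10, 20)]
            diffs = np.diff(tots)
            assert np.all(diffs < 0) if decreasing else np.all(diffs > 0)

    def test_strong_binding_insensitive_to_k_alpha(self, central_params):
        # NICD_tot >> k_alpha: occupancy saturated, k_alpha irrelevant
        wt = central_params.replace(N_s=0)
        scale = wt.NICD0 / 100.0
        tots = [
            steady_state(wt.replace(k_alpha=f * scale)).NICD_tot
            for f in (0.01, 0.1, 1.0)
        ]
        assert (max(tots) - min(tots)) / min(tots) < 0.01

    def test_saturation_of_per_site_decrement(self, central_params):
        ns = np.arange(0, 61, 5)
        tots = np.array([steady_state(central_params.replace(N_s=int(n))).NICD_tot for n in ns])
        dec = -np.diff(tots)
        assert np.all(np.diff(dec) <= 1e-6)  # non-increasing marginal effect

    def test_linear_closed_form_agrees_in_validity_envelope(self):
        # wherever the stated load condition holds, the closed form is within 5%
        checked = 0
        for kp in (0.05, 0.2, 0.5):
            for ns in (0, 3, 6):
                p = KineticParams(
                    NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=kp,
                    k_alpha=1.0, N_e=5.4, N_s=ns,
                )
                lr = linear_regime(p)
                if not lr.valid:
                    continue
                approx = p.NICD0 + p.n_sites_total * lr.slope_dimensionless
                full = steady_state(p).NICD_tot
                assert approx == pytest.approx(full, rel=0.05)
                checked += 1
        assert checked >= 5

    def test_requires_positive_baseline(self):
        p = KineticParams(P_NICD=0.0, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.5, N_s=5)
        with pytest.raises(ParameterError):
            steady_state(p)


class TestDynamics:
    def test_zero_production_stays_at_zero(self):
        p = KineticParams(P_NICD=0.0, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.5, N_s=5)
        traj = integrate_dynamics(p, np.linspace(0, 500, 21))
        assert np.all(traj.NICD_tot_t == 0.0)

    def test_conservation_along_trajectory(self, central_params):
        traj = integrate_dynamics(central_params, np.linspace(0, 2000, 51))
        assert np.all(traj.NICD_up_t >= 0) and np.all(traj.NICD_p_t >= 0)
        np.testing.assert_allclose(
            traj.NICD_tot_t, traj.NICD_up_t + traj.NICD_p_t, rtol=1e-12
        )

    def test_dimensionless_mode_rescales_time(self, central_params):
        # t' = Gamma_up * t: the dimensionless system at t'=1 equals the
        # physical system at t = 1/Gamma_up
        phys = integrate_dynamics(central_params, [0.0, 120.0])
        dimless = integrate_dynamics(central_params, [0.0, 1.0], dimensionless_time=True)
        assert dimless.NICD_tot_t[-1] == pytest.approx(phys.NICD_tot_t[-1], rel=1e-6)

    def test_genotype_ordering_at_all_times(self, calibrated_kp):
        # wild type stays above both the halved-production genotype and the
        # genotype carrying 12 extra drain sites, at every positive time
        wt = KineticParams(
            NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=calibrated_kp, N_e=5.4
        )
        t = np.linspace(0, 2e4, 200)[1:]
        t = np.concatenate([[0.0], t])
        tot_wt = integrate_dynamics(wt, t).NICD_tot_t
        tot_het = integrate_dynamics(wt.replace(NICD0=1000.0), t).NICD_tot_t
        tot_sites = integrate_dynamics(wt.replace(N_s=12), t).NICD_tot_t
        assert np.all(tot_wt[1:] > tot_sites[1:])
        assert np.all(tot_wt[1:] > tot_het[1:])

    def test_bad_grid_rejected(self, central_params):
        with pytest.raises(ParameterError):
            integrate_dynamics(central_params, [1.0, 2.0])
        with pytest.raises(ParameterError):
            integrate_dynamics(central_params, [0.0, 2.0, 2.0])


class TestLinearRegime:
    def test_slope_closed_form(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=1.0)
        lr = linear_regime(p)  # kp' = 120, Gp' = 15
        assert lr.slope_dimensionless == pytest.approx(-112.0, rel=1e-12)

    def test_fast_phospho_decay_limit(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 120, Gamma_p=1e6, k_p=1.0)
        assert linear_regime(p).slope_dimensionless == pytest.approx(-120.0, rel=1e-6)

    def test_halved_rate_halves_slope(self, central_params):
        full = linear_regime(central_params)
        half = linear_regime(central_params.replace(k_p=central_params.k_p / 2))
        assert full.slope_dimensionless / half.slope_dimensionless == pytest.approx(2.0)

    def test_slow_phospho_decay_flagged(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 8, Gamma_p=1 / 120, k_p=1.0)
        assert not linear_regime(p).approximation_ok

    def test_intercept_and_normalized_slope(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.5, N_e=5.4)
        lr = linear_regime(p)
        assert lr.intercept == pytest.approx(2000 - 5.4 * 56.0)
        assert lr.slope_normalized == pytest.approx(-56.0 / (2000 - 5.4 * 56.0))


class TestKpEstimation:
    def test_zero_slope_means_zero_rate(self):
        assert estimate_kp_from_slope(0.0, 2000, 1 / 120, 1 / 8, 5.4) == 0.0

    def test_round_trip_through_linear_regime(self):
        p = KineticParams(NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=0.5, N_e=5.4)
        s = linear_regime(p).slope_normalized
        assert estimate_kp_from_slope(s, 2000, 1 / 120, 1 / 8, 5.4) == pytest.approx(
            0.5, rel=1e-9
        )

    def test_central_estimate_order_of_magnitude(self):
        kp = estimate_kp_from_slope(-0.0294, 2000, 1 / 120, 1 / 8, 5.4)
        assert 0.1 <= kp <= 10.0

    @pytest.mark.parametrize("slope", [0.01, float("nan")])
    def test_domain_errors(self, slope):
        with pytest.raises(ParameterError):
            estimate_kp_from_slope(slope, 2000, 1 / 120, 1 / 8, 5.4)


class TestKpGrid:
    def test_single_cell_equals_scalar(self):
        g = kp_grid([2000.0], [1 / 120], 1 / 8, -0.0294, 5.4)
        assert g.kp_values[0, 0] == estimate_kp_from_slope(-0.0294, 2000, 1 / 120, 1 / 8, 5.4)

    def test_monotone_in_abundance_and_decay(self):
        n0 = np.geomspace(100, 10000, 8)
        gu = np.geomspace(1 / 1000, 1 / 30, 8)
        g = kp_grid(n0, gu, 1 / 8, -0.0294, 5.4)
        assert np.isfinite(g.kp_values).all() and (g.kp_values > 0).all()
        assert np.all(np.diff(g.kp_values, axis=1) > 0)  # in NICD0
        assert np.all(np.diff(g.kp_values, axis=0) > 0)  # in Gamma_up

    def test_corners_match_scalar_oracle(self):
        n0 = np.geomspace(100, 10000, 5)
        gu = np.geomspace(1 / 1000, 1 / 30, 5)
        g = kp_grid(n0, gu, 1 / 8, -0.0294, 5.4)
        for i in (0, -1):
            for j in (0, -1):
                assert g.kp_values[i, j] == estimate_kp_from_slope(
                    -0.0294, n0[j], gu[i], 1 / 8, 5.4
                )

    def test_out_of_domain_cells_masked(self):
        # Gamma_up >= Gamma_p makes the inversion meaningless -> NaN cell
        g = kp_grid([2000.0], [1 / 8], 1 / 8, -0.0294, 5.4)
        assert math.isnan(g.kp_values[0, 0])


class TestTitration:
    def test_normalized_starts_at_one(self, central_params):
        df = titration_curve(central_params, [0, 6, 12, 18])
        assert df.loc[df.n_sites == 0, "nicd_tot_norm"].iloc[0] == 1.0

    def test_strictly_decreasing_when_draining(self, central_params):
        df = titration_curve(central_params, [0, 2, 4, 8, 16])
        assert np.all(np.diff(df["nicd_tot"].to_numpy()) < 0)

    def test_initial_slope_scales_with_phospho_rate(self):
        # halving kp halves the initial finite-difference slope (within 5%)
        slopes = {}
        for kp in (1.0, 0.5):
            p = KineticParams(
                NICD0=2000, Gamma_up=1 / 120, Gamma_p=1 / 8, k_p=kp, N_e=5.4
            )
            df = titration_curve(p, [0, 1, 2])
            t = df["nicd_tot"].to_numpy()
            slopes[kp] = t[1] - t[0]
        assert slopes[1.0] / slopes[0.5] == pytest.approx(2.0, rel=0.05)

    def test_requires_zero_point(self, central_params):
        with pytest.raises(ParameterError):
            titration_curve(central_params, [6, 12])
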