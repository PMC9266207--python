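"""Unit and property tests for the 13-state gating model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nav16sim import markov
from nav16sim.errors import InvalidParameterError
from nav16sim.markov import (
    BLOCKED,
    OPEN,
    PRESET_NAMES,
    MacroscopicCurrentParams,
    RateConstants,
    build_generator,
    current,
    get_preset,
    integrate_occupancy,
    steady_state,
)

VOLTAGES = (-120.0, -80.0, -40.0, 0.0, 40.0)


def long_time_occupancy(v, rates, t_total=10_000.0, dt=1.0):
    """Independent oracle: fixed-voltage relaxation by long integration.

    Matrix-exponential stepping is exact for constant voltage, so a 10 s
    relaxation lands on the stationary distribution without solver error.
    """
    p0 = np.zeros(13)
    p0[0] = 1.0
    _, P = integrate_occupancy(p0, [(v, t_total)], rates, dt=dt)
    return P[-1]


class TestGenerator:
    def test_rows_conserve_probability(self):
        for name in PRESET_NAMES:
            for v in VOLTAGES:
                Q = build_generator(v, get_preset(name))
                assert np.abs(Q.sum(axis=1)).max() < 1e-10

    def test_scheme_topology(self, wt):
        """Zero entries exactly where the scheme has no edge."""
        Q = build_generator(-40.0, wt)
        allowed = np.zeros((13, 13), dtype=bool)
        for n in range(4):  # closed tier
            allowed[n, n + 1] = allowed[n + 1, n] = True
            allowed[7 + n, 8 + n] = allowed[8 + n, 7 + n] = True
        allowed[4, OPEN] = allowed[OPEN, 4] = True       # C5 <-> O
        allowed[OPEN, BLOCKED] = allowed[BLOCKED, OPEN] = True
        allowed[11, 12] = allowed[12, 11] = True         # I5 <-> I6
        for n in range(5):                               # vertical ladder
            allowed[n, 7 + n] = allowed[7 + n, n] = True
        allowed[OPEN, 12] = allowed[12, OPEN] = True     # O <-> I6
        np.fill_diagonal(allowed, True)
        assert np.all((Q != 0) <= allowed)

    def test_wild_type_base_rates_at_0mV(self, wt):
        """Opening rate gamma and top activation rate alpha are 150 ms^-1."""
        Q = build_generator(0.0, wt)
        assert Q[4, OPEN] == pytest.approx(150.0)
        assert Q[3, 4] == pytest.approx(150.0)
        # 4:3:2:1 multiplicities on the closed tier
        assert Q[0, 1] == pytest.approx(4 * 150.0)
        assert Q[1, 0] == pytest.approx(3.0)

    def test_blocked_state_unreachable_when_epsilon_zero(self, wt):
        Q = build_generator(0.0, wt)
        col = Q[:, BLOCKED].copy()
        col[BLOCKED] = 0.0
        assert np.all(col == 0.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_generator(np.nan, get_preset("WT"))
        with pytest.raises(InvalidParameterError):
            RateConstants(alpha0=-1.0)
        with pytest.raises(InvalidParameterError):
            RateConstants(density_scale=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(v=st.floats(-120, 60),
           alpha0=st.floats(1.0, 400.0),
           oon=st.floats(0.1, 2.0))
    def test_generator_conservation_property(self, v, alpha0, oon):
        r = RateConstants(alpha0=alpha0, Oon=oon)
        Q = build_generator(v, r)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        off_diag = Q - np.diag(np.diag(Q))
        assert np.all(off_diag >= 0)


class TestLoopConsistency:
    """Detailed balance of the closed/inactivated rectangles.

    With the allosteric factors computed canonically from the on/off rates,
    every C/I rectangle balances whenever the two tiers share their
    voltage-dependent rates (alpha_i = alpha, beta_i = beta); this holds for
    the wild-type preset and for any coupled rate set.  The deliberate
    uncoupling of the mutant presets breaks it by construction.
    """

    @staticmethod
    def loop_products(Q):
        out = []
        for n in range(4):  # rectangle Cn, Cn+1, In+1, In
            cw = Q[n, n + 1] * Q[n + 1, 8 + n] * Q[8 + n, 7 + n] * Q[7 + n, n]
            ccw = Q[n, 7 + n] * Q[7 + n, 8 + n] * Q[8 + n, n + 1] * Q[n + 1, n]
            out.append((cw, ccw))
        return out

    @pytest.mark.parametrize("rates", [
        get_preset("WT"),
        RateConstants(alpha0=200.0, beta0=5.0, alpha_i0=200.0, beta_i0=5.0,
                      Con=0.01, Coff=0.3, Oon=1.2, Ooff=0.02),
    ], ids=["WT", "coupled-custom"])
    @pytest.mark.parametrize("v", [-80.0, -20.0, 20.0])
    def test_rectangles_balance_for_coupled_tiers(self, rates, v):
        for cw, ccw in self.loop_products(build_generator(v, rates)):
            assert cw == pytest.approx(ccw, rel=1e-10)

    def test_allosteric_factor_tracks_rates(self):
        r = RateConstants(Oon=1.2, Ooff=0.02, Con=0.01, Coff=0.3)
        assert r.a == pytest.approx(
            (1.2 * 0.3 / (0.02 * 0.01)) ** 0.25, rel=1e-12)
        r2 = r.replace(Oon=0.6)
        assert r2.a == pytest.approx(
            (0.6 * 0.3 / (0.02 * 0.01)) ** 0.25, rel=1e-12)


class TestSteadyState:
    def test_channel_shut_at_strong_hyperpolarization(self, wt):
        assert steady_state(-120.0, wt)[OPEN] < 1e-4

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_null_space_matches_long_integration(self, name):
        rates = get_preset(name)
        for v in VOLTAGES:
            p_null = steady_state(v, rates)
            p_ode = long_time_occupancy(v, rates)
            assert np.abs(p_null - p_ode).max() < 1e-6

    def test_degenerate_closed_tier_is_binomial(self):
        """No inactivation, no opening: per-subunit binomial occupancy.

        With all vertical rates and the opening rate at zero, the closed tier
        is a 4-subunit activation chain whose stationary law is
        Binomial(4, alpha/(alpha+beta)) — checked against long integration.
        """
        r = RateConstants(Con=0.0, Coff=0.0, Oon=0.0, Ooff=0.0,
                          gamma0=0.0, epsilon=0.0, zeta0=0.0)
        v = -40.0
        al = r.alpha0 * np.exp(v / r.k_alpha)
        be = r.beta0 * np.exp(-v / r.k_beta)
        p_sub = al / (al + be)
        from scipy.stats import binom
        expected = binom.pmf(np.arange(5), 4, p_sub)
        got = long_time_occupancy(v, r, t_total=2000.0, dt=0.5)
        assert np.abs(got[:5] - expected).max() < 1e-8
        assert np.abs(got[5:]).max() == 0.0


class TestIntegration:
    def test_steady_state_is_fixed_point(self, wt):
        p0 = steady_state(-60.0, wt)
        _, P = integrate_occupancy(p0, [(-60.0, 50.0)], wt, dt=0.025)
        assert np.abs(P - p0).max() < 1e-8

    def test_occupancy_conserved_through_step_protocol(self, wt):
        p0 = steady_state(-100.0, wt)
        _, P = integrate_occupancy(p0, [(-100.0, 5.0), (0.0, 50.0)], wt)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-8
        assert P.min() > -1e-9

    def test_step_response_has_transient_and_persistent_phases(self, wt):
        """Open probability rises to a single early peak then decays to a
        small sustained level (transient + persistent current morphology)."""
        p0 = steady_state(-100.0, wt)
        t, P = integrate_occupancy(p0, [(0.0, 50.0)], wt)
        po = P[:, OPEN]
        k_peak = int(np.argmax(po))
        assert t[k_peak] < 5.0
        assert po[k_peak] > 0.3
        tail = po[t > 45.0].mean()
        assert 0 < tail < 0.05 * po[k_peak]
        # single peak: nonincreasing after the maximum, up to tiny wiggle
        assert np.all(np.diff(po[k_peak:]) < 1e-9)

    def test_blocked_state_never_occupied_with_epsilon_zero(self, wt):
        p0 = steady_state(-100.0, wt)
        _, P = integrate_occupancy(p0, [(0.0, 50.0), (-100.0, 20.0)], wt)
        assert np.abs(P[:, BLOCKED]).max() == 0.0

    def test_sampling_grid_refinement_is_consistent(self, wt):
        """Halving dt leaves occupancies on shared sample times unchanged
        (per-segment matrix exponentials are exact for constant voltage)."""
        p0 = steady_state(-100.0, wt)
        _, P1 = integrate_occupancy(p0, [(0.0, 50.0)], wt, dt=0.05)
        _, P2 = integrate_occupancy(p0, [(0.0, 50.0)], wt, dt=0.025)
        assert np.abs(P1[-1] - P2[-1]).max() < 1e-6


class TestCurrent:
    def test_zero_open_probability_gives_zero_current(self):
        mp = MacroscopicCurrentParams(gbar=50.0)
        assert current(0.0, -20.0, mp) == 0.0

    def test_reversal_potential_nulls_current(self):
        mp = MacroscopicCurrentParams(gbar=50.0, E_Na=68.0)
        assert np.all(current(np.array([0.1, 0.5, 1.0]), 68.0, mp) == 0.0)

    def test_density_scaling_is_exact(self, wt):
        mp = MacroscopicCurrentParams(gbar=50.0)
        po = np.linspace(0.0, 0.8, 11)
        i_full = current(po, 0.0, mp, density_scale=1.0)
        i_scaled = current(po, 0.0, mp, density_scale=0.300)
        assert np.allclose(i_scaled, 0.300 * i_full, rtol=0, atol=0)

    def test_inward_below_reversal(self, wt):
        mp = MacroscopicCurrentParams(gbar=50.0, E_Na=68.0)
        assert current(0.5, 0.0, mp) < 0


class TestPresets:
    def test_shipped_condition_table(self):
        """The six conditions carry their published parameter values."""
        expected = {
            "WT": dict(density_scale=1.0, Coff=0.5, Oon=0.75, Ooff=0.005,
                       epsilon=0.0, alpha0=150.0, beta0=3.0, alpha_i0=150.0,
                       beta_i0=3.0, gamma0=150.0),
            "WT+CN21": dict(density_scale=0.300, Coff=0.5, Oon=1.3,
                            Ooff=0.005, epsilon=0.0, alpha0=92.0, beta0=3.0,
                            alpha_i0=150.0, beta_i0=3.0, gamma0=150.0),
            "R639C": dict(density_scale=1.72, Coff=0.25, Oon=0.75,
                          Ooff=0.007, epsilon=0.0, alpha0=277.5, beta0=3.7,
                          alpha_i0=110.0, beta_i0=4.0, gamma0=130.0),
            "R639C+CN21": dict(density_scale=0.878, Coff=0.25, Oon=0.75,
                               Ooff=0.007, epsilon=0.0, alpha0=277.5,
                               beta0=3.7, alpha_i0=110.0, beta_i0=4.0,
                               gamma0=130.0),
            "R850Q": dict(density_scale=1.23, Coff=0.4, Oon=1.018,
                          Ooff=0.018, epsilon=0.0, alpha0=85.0, beta0=0.9,
                          alpha_i0=126.0, beta_i0=3.4, gamma0=137.0),
            "R850Q+CN21": dict(density_scale=0.835, Coff=0.4, Oon=1.018,
                               Ooff=0.018, epsilon=0.0, alpha0=50.3,
                               beta0=0.9, alpha_i0=250.0, beta_i0=4.0,
                               gamma0=137.0),
        }
        for name, fields in expected.items():
            r = get_preset(name)
            for field, value in fields.items():
                assert getattr(r, field) == value, (name, field)

    def test_preset_json_round_trip(self, tmp_path):
        path = markov.save_presets(markov.PRESETS, tmp_path / "presets.json")
        loaded = markov.load_presets(path)
        assert loaded == markov.PRESETS

    def test_unknown_condition_errors(self):
        with pytest.raises(InvalidParameterError):
            get_preset("R9999X")
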