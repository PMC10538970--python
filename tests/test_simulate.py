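import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import phikinet as pk
from phikinet.mechanism import IrradiationSetup, Mechanism, ReactionStep, Species, Spectator
from phikinet.fixtures import (
    DEFAULT_SETUP,
    branch_system,
    isosbestic_system,
    primary_photoprocess,
    table1_system,
)
from phikinet.simulate import LN10, SimulationError, photokinetic_factor

# Reference state of the photoreversible system at t = 30 s and 60 s
T1_CX30 = 9.91197e-6
T1_CX60 = 8.57014e-6
T1_CY60 = 7.22959e-6
T1_ATOT30 = 0.42096
T1_AY60 = 0.2758036
T1_RX30 = -8.35686e-8
T1_RY60 = 2.06243e-8
T1_PAX30 = 3.61887e-6


class TestPhotokineticFactor:
    def test_zero_limit_is_ln10(self):
        assert photokinetic_factor(0.0) == pytest.approx(math.log(10.0), rel=1e-12)

    def test_unit_absorbance(self):
        assert photokinetic_factor(1.0) == pytest.approx(0.9, rel=1e-12)

    def test_reference_value(self):
        # (1 - 10^-0.42096) / 0.42096 by direct arithmetic
        assert photokinetic_factor(0.42096) == pytest.approx(1.4743682944, rel=1e-9)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            photokinetic_factor(-0.1)

    @given(st.floats(1e-12, 10.0), st.floats(1e-12, 10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_decreasing_and_continuous_near_zero(self, a, b):
        lo, hi = sorted((a, b))
        if lo < hi:
            assert photokinetic_factor(lo) > photokinetic_factor(hi)
        assert photokinetic_factor(lo) <= math.log(10.0)


class TestAbsorbedLight:
    @pytest.mark.parametrize(
        "a, atot, expected",
        [(0.19636204, 0.42096, 3.61887e-6), (0.2758036, 0.44558, 4.96385e-6)],
    )
    def test_reference_fluxes(self, a, atot, expected):
        assert pk.absorbed_light(a, atot, 1.25e-5) == pytest.approx(expected, rel=1e-4)

    def test_zero_absorbance_absorbs_nothing(self):
        assert pk.absorbed_light(0.0, 0.42096, 1.25e-5) == 0.0

    def test_species_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            pk.absorbed_light(0.5, 0.4, 1.25e-5)

    def test_shares_sum_to_total_absorbed_flux(self):
        parts = np.array([0.1, 0.15, 0.05])
        atot = parts.sum()
        total = sum(pk.absorbed_light(a, atot, 1.25e-5) for a in parts)
        assert total == pytest.approx(1.25e-5 * (1 - 10**-atot), rel=1e-12)


class TestRateLaw:
    def test_reference_state_rates(self, table1):
        m, s = table1
        r = pk.rate_law(m, s, np.array([9.91197e-6, 5.88738e-6]))
        assert r[0] == pytest.approx(T1_RX30, rel=0.01)
        assert r[1] == pytest.approx(-r[0], rel=1e-12)  # two-species conservation

    def test_zero_concentrations_give_zero_rates(self, table1):
        m, s = table1
        assert np.all(pk.rate_law(m, s, np.zeros(2)) == 0.0)

    def test_rates_sum_to_zero_with_spectator(self):
        m, s = branch_system()
        m = Mechanism(species=m.species, steps=m.steps, spectators=(Spectator("SPM1", 0.4),))
        c = np.array([1e-5, 3e-6, 2e-6])
        assert abs(pk.rate_law(m, s, c).sum()) < 1e-22

    def test_dimension_mismatch_rejected(self, table1):
        m, s = table1
        with pytest.raises(ValueError):
            pk.rate_law(m, s, np.zeros(3))


class TestSimulate:
    def test_reference_trajectory(self, table1, table1_trace):
        m, s = table1
        tr = table1_trace
        assert tr.times[0] == 0.0
        i30, i60 = 300, 600
        assert tr.conc[i30, 0] == pytest.approx(T1_CX30, rel=1e-3)
        assert tr.conc[i60, 0] == pytest.approx(T1_CX60, rel=1e-3)
        assert tr.conc[i60, 1] == pytest.approx(T1_CY60, rel=1e-3)
        assert tr.atot[i30] == pytest.approx(T1_ATOT30, rel=1e-3)

    def test_mass_conservation(self, table1_trace):
        c0 = table1_trace.c_total[0]
        assert np.max(np.abs(table1_trace.c_total - c0)) < 1e-9 * c0

    def test_fourth_order_convergence(self, table1):
        m, s = table1
        a = pk.simulate(m, s, 30.0, dt=0.1).conc[-1]
        b = pk.simulate(m, s, 30.0, dt=0.05).conc[-1]
        assert np.max(np.abs(a - b) / np.abs(a)) < 1e-8

    def test_primary_photoprocess_matches_closed_form(self):
        m, s = primary_photoprocess(phi=0.05)
        tr = pk.simulate(m, s, 120.0, dt=0.1, warn_linearity=False)
        eps_l = m.reactant.epsilon * s.l_irr
        ax0 = eps_l * m.reactant.c0
        kx = 0.05 * m.reactant.epsilon * s.p0 * s.l_irr * LN10
        lhs = 10.0 ** (eps_l * tr.conc[:, 0])
        rhs = 1.0 + (10.0**ax0 - 1.0) * np.exp(-kx * tr.times)
        assert np.max(np.abs(lhs - rhs) / rhs) < 1e-6

    def test_unstable_step_rejected_with_hint(self):
        m, s = primary_photoprocess(phi=1.0, eps_x=5e4, c0=2e-6)
        s = IrradiationSetup(lambda_irr=370.0, p0=1e-2, l_irr=1.65)
        with pytest.raises(SimulationError, match="smaller dt"):
            pk.simulate(m, s, 50.0, dt=5.0)

    def test_linearity_guideline_warning(self):
        m, s = table1_system()
        m = Mechanism(species=m.species, steps=m.steps, spectators=(Spectator("SPM1", 0.4),))
        with pytest.warns(UserWarning, match="linearity"):
            pk.simulate(m, s, 5.0, dt=0.1)


class TestTotalAbsorbance:
    def test_reference_value_and_t0(self, table1, table1_trace):
        m, s = table1
        atot = pk.total_absorbance_trace(table1_trace, m, s)
        assert atot[0] == pytest.approx(12004 * 1.65 * 1.58e-5, rel=1e-12)
        assert atot[300] == pytest.approx(T1_ATOT30, rel=1e-3)

    def test_spectator_shifts_series_additively(self, table1, table1_trace):
        m, s = table1
        m2 = Mechanism(species=m.species, steps=m.steps, spectators=(Spectator("SPM1", 0.5),))
        tr2 = pk.simulate(m2, s, 1.0, dt=0.1, warn_linearity=False)
        base = pk.total_absorbance_trace(
            pk.KineticTrace(tr2.times, tr2.conc, m.names), m, s
        )
        assert np.allclose(tr2.atot, base + 0.5, rtol=0, atol=1e-15)

    def test_observation_path_rescaling_round_trips(self, table1, table1_trace):
        m, s = table1
        s2 = IrradiationSetup(lambda_irr=s.lambda_irr, p0=s.p0, l_irr=s.l_irr, l_obs=1.0)
        observed = pk.total_absorbance_trace(table1_trace, m, s2, observed=True)
        restored = observed * (s2.l_irr / s2.path_obs)
        assert np.allclose(restored, table1_trace.atot, rtol=1e-14)


class TestPhotostationaryState:
    def test_reference_closed_form(self, table1):
        m, s = table1
        css = pk.photostationary_state(m, s)
        assert css[0] == pytest.approx(8.1165e-6, rel=1e-3)
        assert css.sum() == pytest.approx(1.58e-5, rel=1e-12)

    def test_irreversible_goes_to_completion(self):
        m, s = primary_photoprocess(phi=0.05)
        css = pk.photostationary_state(m, s)
        assert css[0] == 0.0 and css[1] == pytest.approx(1.58e-5)

    def test_closed_form_agrees_with_rk_limit(self, table1):
        m, s = table1
        closed = pk.photostationary_state(m, s)
        # force the long-time RK route by breaking the 2x2 special case
        m3 = Mechanism(
            species=m.species + (Species("Y2", 0.0),),
            steps=m.steps + (ReactionStep("Y1", "Y2", 1e-12),),
        )
        rk = pk.photostationary_state(m3, s, rate_tol=1e-16)[:2]
        assert np.max(np.abs(rk - closed)) < 1e-9


class TestIsosbestic:
    def test_atot_constant_and_first_order(self):
        m, s = isosbestic_system()
        tr = pk.simulate(m, s, 200.0, dt=0.1)
        assert np.ptp(tr.atot) < 1e-12
        # constant-PKF rate law is a linear ODE: compare with expm solution
        pkf = photokinetic_factor(tr.atot[0])
        eps_l = np.array([sp.epsilon for sp in m.species]) * s.l_irr
        M = np.zeros((2, 2))
        for st_ in m.steps:
            i, j = m.index(st_.source), m.index(st_.target)
            M[i, i] -= st_.phi * eps_l[i] * s.p0 * pkf
            M[j, i] += st_.phi * eps_l[i] * s.p0 * pkf
        c0 = np.array([sp.c0 for sp in m.species])
        for idx in (100, 500, 2000):
            expected = expm(M * tr.times[idx]) @ c0
            assert np.max(np.abs(tr.conc[idx] - expected)) < 1e-8 * c0[0]


class TestSpectatorAndConcentrationEffects:
    def test_all_initial_rates_slow_down_with_spectator(self):
        m, s = branch_system()
        prev = None
        for a in (0.0, 0.3, 0.8):
            m_a = Mechanism(species=m.species, steps=m.steps, spectators=(Spectator("S", a),))
            r = np.abs(pk.rate_law(m_a, s, np.array([sp.c0 for sp in m.species])))
            if prev is not None:
                assert np.all(r < prev)
            prev = r

    def test_r0x_increases_and_saturates_with_cx0(self, table1):
        m, s = table1
        from phikinet.mechanism import with_initial_concentration

        r0 = []
        for cx0 in (1e-6, 3e-6, 1e-5, 3e-5, 1e-4):
            r0.append(abs(pk.theoretical_initial_rates(with_initial_concentration(m, cx0), s)[0]))
        assert all(b > a for a, b in zip(r0, r0[1:]))
        limit = 0.062 * s.p0  # total-absorption asymptote
        r0_sat = abs(pk.theoretical_initial_rates(with_initial_concentration(m, 3e-4), s)[0])
        assert r0_sat < limit
        assert r0_sat == pytest.approx(limit, rel=1e-4)


def test_half_life_by_interpolation(table1, table1_trace):
    m, s = table1
    cx_inf = pk.photostationary_state(m, s)[0]
    t_half = pk.half_life(table1_trace, cx_inf)
    target = 0.5 * (1.58e-5 + cx_inf)
    assert np.interp(t_half, table1_trace.times, table1_trace.conc[:, 0]) == pytest.approx(
        target, rel=1e-6
    )
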