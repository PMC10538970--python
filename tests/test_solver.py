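import numpy as np
import pytest

import phikinet as pk
from phikinet.fixtures import (
    branch_system,
    consecutive_system,
    primary_photoprocess,
    table1_system,
)
from phikinet.phiorder import CoupledFit, FitQuality, PhiOrderModel
from phikinet.simulate import simulate_to_steady
from phikinet.solver import SolveError, select_timepoints, solve_epsilons, solve_phis

from test_phiorder import T1_ATOT_MODEL, T1_CX_MODEL, T1_CY_MODEL


@pytest.fixture(scope="module")
def published_fit():
    """CoupledFit assembled from the published fitted models of the reference system."""
    q = FitQuality(r2=1.0, sse=0.0, rmse=0.0)
    return CoupledFit(
        species=("X", "Y1"),
        models={"X": T1_CX_MODEL, "Y1": T1_CY_MODEL},
        quality={"X": q, "Y1": q},
        cc=3.175e-5,
        k_values=(0.09915, 0.04517),
        seed=0,
        n_starts=0,
        atot_model=T1_ATOT_MODEL,
        atot_quality=q,
    )


class TestInitialRateQuantumYields:
    def test_reference_reactant_qy(self, table1):
        m, s = table1
        r0 = pk.theoretical_initial_rates(m, s)[0]
        ax0 = m.reactant.epsilon * s.l_irr * m.reactant.c0
        assert pk.reactant_qy_sum(r0, s.p0, ax0) == pytest.approx(0.062, rel=1e-12)

    def test_zero_rate_means_zero_yield(self):
        assert pk.reactant_qy_sum(0.0, 1.25e-5, 0.3) == 0.0

    def test_sign_violations_rejected(self):
        with pytest.raises(ValueError):
            pk.reactant_qy_sum(1e-7, 1.25e-5, 0.3)
        with pytest.raises(ValueError):
            pk.branch_qy(-1e-7, 1.25e-5, 0.3)

    def test_branch_yields_recovered_from_fits(self):
        m, s = branch_system(phi1=0.03, phi3=0.05)
        tr = simulate_to_steady(m, s, dt=0.1)
        cf = pk.fit_species_traces(tr, m, seed=9, fit_atot=False)
        r0 = cf.initial_rates()
        ax0 = m.reactant.epsilon * s.l_irr * m.reactant.c0
        assert pk.reactant_qy_sum(r0["X"], s.p0, ax0) == pytest.approx(0.08, rel=5e-3)
        assert pk.branch_qy(r0["Y1"], s.p0, ax0) == pytest.approx(0.03, rel=5e-3)
        assert pk.branch_qy(r0["Y3"], s.p0, ax0) == pytest.approx(0.05, rel=5e-3)

    def test_sum_rule_is_algebraic(self):
        p0, ax0 = 1.25e-5, 0.31294
        r1, r3 = 2.1e-7, 1.3e-7
        total = pk.reactant_qy_sum(-(r1 + r3), p0, ax0)
        branches = pk.branch_qy(r1, p0, ax0) + pk.branch_qy(r3, p0, ax0)
        assert branches == pytest.approx(total, rel=1e-12)

    def test_single_product_branch_equals_sum(self):
        m, s = primary_photoprocess(phi=0.05)
        r0 = pk.theoretical_initial_rates(m, s)
        ax0 = m.reactant.epsilon * s.l_irr * m.reactant.c0
        assert pk.branch_qy(r0[1], s.p0, ax0) == pk.reactant_qy_sum(r0[0], s.p0, ax0)


class TestTimepointSelection:
    def test_published_pair_is_admissible_but_greedy_is_no_worse(self, published_fit):
        times = np.arange(0.0, 300.1, 0.1)
        chosen = select_timepoints(published_fit, 2, times)
        M_pub = published_fit.conc_at(np.array([30.0, 60.0]))
        M_sel = published_fit.conc_at(chosen)
        cond = lambda M: np.linalg.cond(M)
        assert cond(M_pub) < 1e6  # the published choice is well-conditioned
        assert cond(M_sel) <= cond(M_pub) * (1 + 1e-9)

    def test_duplicate_timepoints_rejected(self, published_fit, table1):
        _, s = table1
        with pytest.raises(SolveError, match="duplicate"):
            solve_epsilons(published_fit, s, [30.0, 30.0])

    def test_too_short_trace_rejected(self, published_fit):
        with pytest.raises(SolveError):
            select_timepoints(published_fit, 3, np.array([0.0, 10.0, 10.0]))


class TestStage2:
    def test_published_data_reproduces_published_epsilons(self, published_fit, table1):
        _, s = table1
        eps, cond = solve_epsilons(published_fit, s, [30.0, 60.0])
        assert eps[0] == pytest.approx(12006.43, rel=5e-4)
        assert eps[1] == pytest.approx(23120.78, rel=5e-4)
        assert cond < 100

    def test_exact_concentrations_recover_fed_epsilons(self, table1, table1_trace):
        m, s = table1
        eps, _ = solve_epsilons(table1_trace, s, [30.0, 60.0])
        assert eps[0] == pytest.approx(12004.0, rel=1e-6)
        assert eps[1] == pytest.approx(23123.0, rel=1e-6)

    def test_single_species_single_timepoint(self, table1):
        m, s = table1
        pm = PhiOrderModel(c_inf=1e-5, cc=0.5, terms=((2e-6, 0.05),))
        q = FitQuality(1.0, 0.0, 0.0)
        atot = PhiOrderModel(
            c_inf=1e-5 * 12004 * 1.65, cc=0.5, terms=((2e-6 * 12004 * 1.65, 0.05),)
        )
        cf = CoupledFit(
            species=("X",), models={"X": pm}, quality={"X": q}, cc=0.5,
            k_values=(0.05,), seed=0, n_starts=0, atot_model=atot, atot_quality=q,
        )
        eps, _ = solve_epsilons(cf, s, [25.0])
        assert eps[0] == pytest.approx(12004.0, rel=1e-12)


class TestStage3:
    def test_published_data_reproduces_published_yields(self, published_fit, table1):
        m, s = table1
        eps = np.array([12006.43, 23120.78])
        phis, cond = solve_phis(published_fit, m, s, eps, [30.0, 60.0])
        labels = [st.label for st in m.steps]
        assert phis[labels.index("X->Y1")] == pytest.approx(0.06198, rel=2e-3)
        assert phis[labels.index("Y1->X")] == pytest.approx(0.03399, rel=2e-3)
        assert cond < 100

    def test_exact_inputs_recover_fed_yields(self, table1, table1_trace):
        m, s = table1
        eps = np.array([12004.0, 23123.0])
        phis, _ = solve_phis(table1_trace, m, s, eps, [30.0, 60.0])
        assert phis[0] == pytest.approx(0.062, rel=1e-4)
        assert phis[1] == pytest.approx(0.034, rel=1e-4)

    def test_photostationary_rows_are_uninformative(self, table1, table1_fit):
        m, s = table1
        eps = np.array([12004.0, 23123.0])
        with pytest.raises(SolveError):
            # at the photostationary state every candidate rate vanishes
            solve_phis(table1_fit, m, s, eps, [280.0, 290.0, 299.0])


class TestSolveIntrinsics:
    def test_photoreversible_end_to_end(self, table1, table1_trace, table1_fit):
        m, s = table1
        rep = pk.solve_intrinsics(
            table1_trace, m, s, timepoints=[30.0, 60.0], truth=m, cf=table1_fit
        )
        assert rep.max_pct_err < 0.05
        assert rep.cond_epsilons < 100 and rep.cond_phis < 100

    def test_three_species_consecutive_recovery(self):
        m, s = consecutive_system(2)
        tr = simulate_to_steady(m, s, dt=0.1)
        rep = pk.solve_intrinsics(tr, m, s, use_trace=True, truth=m)
        assert rep.max_pct_err < 0.5

    def test_fit_and_trace_routes_agree_within_fit_error(self, table1, table1_trace, table1_fit):
        m, s = table1
        rep_fit = pk.solve_intrinsics(
            table1_trace, m, s, timepoints=[30.0, 60.0], truth=m, cf=table1_fit
        )
        rep_raw = pk.solve_intrinsics(
            table1_trace, m, s, timepoints=[30.0, 60.0], truth=m, use_trace=True
        )
        for name in m.names:
            assert rep_fit.epsilons[name] == pytest.approx(rep_raw.epsilons[name], rel=1e-3)

    def test_missing_species_trace_is_hard_error(self, table1, table1_trace):
        m, s = table1
        partial = pk.KineticTrace(
            times=table1_trace.times,
            conc=table1_trace.conc[:, :1],
            species=("X",),
            atot=table1_trace.atot,
        )
        with pytest.raises(SolveError, match="every species"):
            pk.solve_intrinsics(partial, m, s)

    def test_missing_atot_is_hard_error(self, table1, table1_trace):
        m, s = table1
        no_atot = pk.KineticTrace(
            times=table1_trace.times, conc=table1_trace.conc, species=m.names
        )
        with pytest.raises(SolveError, match="total-absorbance"):
            pk.solve_intrinsics(no_atot, m, s, use_trace=True)


@pytest.fixture(scope="module")
def primary():
    m, s = primary_photoprocess(phi=0.05)
    return m, s, simulate_to_steady(m, s, dt=0.1)


class TestIntegratedQuantumYields:
    def test_primary_integrated_recovers_fed_yield(self, primary):
        m, s, tr = primary
        assert pk.qy_primary_integrated(tr, m, s) == pytest.approx(0.05, rel=1e-3)

    def test_integral_and_rearranged_forms_agree(self, primary):
        # evaluated internally at one and two half-lives with a 1e-6 gate
        m, s, tr = primary
        pk.qy_primary_integrated(tr, m, s, cross_check_rtol=1e-6)

    def test_short_time_limit_matches_initial_rate_formula(self, primary):
        m, s, tr = primary
        phi_int = pk.qy_primary_integrated(tr, m, s, ts=[0.5, 1.0])
        r0 = pk.theoretical_initial_rates(m, s)[0]
        ax0 = m.reactant.epsilon * s.l_irr * m.reactant.c0
        assert phi_int == pytest.approx(pk.reactant_qy_sum(r0, s.p0, ax0), rel=1e-3)

    def test_absorbing_product_is_refused(self):
        m, s = primary_photoprocess(phi=0.05, eps_y=15000.0)
        tr = simulate_to_steady(m, s, dt=0.1)
        with pytest.raises(SolveError, match="absorbs"):
            pk.qy_primary_integrated(tr, m, s)

    def test_general_integral_recovers_reference_yields(self, table1, table1_trace):
        m, s = table1
        assert pk.qy_general_integral(table1_trace, m, s, "X->Y1") == pytest.approx(
            0.062, rel=5e-3
        )
        assert pk.qy_general_integral(table1_trace, m, s, "Y1->X") == pytest.approx(
            0.034, rel=5e-3
        )

    def test_general_integral_reduces_to_primary_closed_form(self, primary):
        m, s, tr = primary
        phi_gen = pk.qy_general_integral(tr, m, s, "X->Y1")
        phi_closed = pk.qy_primary_integrated(tr, m, s)
        assert phi_gen == pytest.approx(phi_closed, rel=1e-4)

    def test_total_absorbed_definition_is_inconsistent_when_product_absorbs(
        self, table1, table1_trace
    ):
        m, s = table1
        phi_warburg = pk.qy_total_absorbed(table1_trace, m, s)
        assert abs(phi_warburg - 0.062) / 0.062 > 0.10
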