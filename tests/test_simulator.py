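import dataclasses

import numpy as np
import pytest

from bdqsim import (
    Regimen,
    build_rate_matrix,
    qd_regimen,
    simulate_batch,
    simulate_profile,
    simulate_profile_ode,
    solve_step,
    typical_parameters,
)
from bdqsim.regimen import DoseEvent
from bdqsim.simulate import default_grid

from .conftest import make_theta


@pytest.fixture(scope="module")
def fast_ind(reference_cov):
    return typical_parameters(make_theta(), reference_cov)


@pytest.fixture(scope="module")
def week_qd():
    return qd_regimen(100, 7)


class TestLinearity:
    def test_doubling_dose_doubles_concentrations(self, fast_ind, week_qd):
        grid = default_grid(week_qd, resolution=1.0)
        c1 = simulate_profile(fast_ind, week_qd, grid).concentrations
        c2 = simulate_profile(fast_ind, week_qd.scaled(2.0), grid).concentrations
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-10)

    def test_vanishing_dose_limit(self, fast_ind, week_qd):
        grid = default_grid(week_qd, resolution=1.0)
        c = simulate_profile(fast_ind, week_qd.scaled(1e-12), grid).concentrations
        assert np.all(c <= 1e-10)

    def test_superposition_of_dose_events(self, fast_ind):
        a = Regimen("A", (DoseEvent(0.0, 300.0), DoseEvent(48.0, 100.0)), 96.0)
        b = Regimen("B", (DoseEvent(24.0, 200.0),), 96.0)
        both = Regimen("A+B", (DoseEvent(0.0, 300.0), DoseEvent(24.0, 200.0),
                               DoseEvent(48.0, 100.0)), 96.0)
        grid = np.linspace(0, 120, 241)
        ca = simulate_profile(fast_ind, a, grid).concentrations
        cb = simulate_profile(fast_ind, b, grid).concentrations
        cab = simulate_profile(fast_ind, both, grid).concentrations
        np.testing.assert_allclose(cab, ca + cb, rtol=1e-10, atol=1e-14)


class TestStructuralReduction:
    def test_matches_one_compartment_closed_form(self, reference_cov):
        theta = make_theta(intercompartmental_clearances=(0.0, 0.0, 0.0),
                           fraction_to_path1_typical=1.0,
                           absorption_lag_path1=0.0)
        ind = typical_parameters(theta, reference_cov)
        dose = 250.0
        reg = Regimen("single", (DoseEvent(0.0, dose),), 24.0)
        t = np.linspace(0.0, 72.0, 400)
        c = simulate_profile(ind, reg, t).concentrations
        ka = ind.absorption_rate_path1
        ke = ind.clearance / ind.central_volume
        f, v = ind.bioavailable_fraction, ind.central_volume
        expected = f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        np.testing.assert_allclose(c, expected, rtol=1e-8, atol=1e-12)


class TestBackendAgreement:
    def test_eigen_vs_ode_profile(self, params, typical_ds_male):
        reg = qd_regimen(200, 5)
        grid = default_grid(reg, resolution=1.0)
        eig = simulate_profile(typical_ds_male, reg, grid).concentrations
        ode = simulate_profile_ode(typical_ds_male, reg, grid, rtol=1e-10).concentrations
        np.testing.assert_allclose(eig, ode, rtol=1e-6, atol=1e-12 * eig.max())

    def test_solve_step_expm_vs_ode(self, fast_ind):
        A = build_rate_matrix(fast_ind)
        y0 = np.array([50.0, 30.0, 5.0, 1.0, 0.5, 0.1])
        y_expm = solve_step(A, y0, 12.0, method="expm")
        y_ode = solve_step(A, y0, 12.0, method="ode", rtol=1e-11)
        np.testing.assert_allclose(y_expm, y_ode, rtol=1e-6)

    def test_expm_fallback_for_defective_system(self, reference_cov):
        # absorption rate exactly equal to the elimination rate of the
        # decoupled one-compartment system -> defective (Jordan block)
        theta = make_theta(intercompartmental_clearances=(0.0, 0.0, 0.0),
                           fraction_to_path1_typical=1.0,
                           absorption_rate_path1=0.1,
                           apparent_clearance_typical=5.0,
                           central_volume_typical=50.0)  # ke = 0.1 = ka
        ind = typical_parameters(theta, reference_cov)
        reg = Regimen("single", (DoseEvent(0.0, 100.0),), 24.0)
        grid = np.linspace(0.0, 48.0, 97)
        c = simulate_profile(ind, reg, grid).concentrations
        ode = simulate_profile_ode(ind, reg, grid, rtol=1e-11).concentrations
        np.testing.assert_allclose(c, ode, rtol=1e-6, atol=1e-12)
        # closed form for ka == ke: C = F D ka t e^{-ka t} / V
        ka = 0.1
        expected = 100.0 * ka * grid * np.exp(-ka * grid) / 50.0
        np.testing.assert_allclose(c, expected, rtol=1e-6, atol=1e-12)


class TestPropagator:
    def test_zero_dt_is_identity(self, fast_ind):
        A = build_rate_matrix(fast_ind)
        y0 = np.arange(6, dtype=float)
        np.testing.assert_array_equal(solve_step(A, y0, 0.0), y0)

    def test_semigroup_property(self, fast_ind):
        A = build_rate_matrix(fast_ind)
        y0 = np.array([10.0, 20.0, 3.0, 0.0, 0.0, 0.0])
        twice = solve_step(A, solve_step(A, y0, 6.0), 6.0)
        once = solve_step(A, y0, 12.0)
        np.testing.assert_allclose(twice, once, rtol=1e-9)

    def test_invalid_inputs(self, fast_ind):
        A = build_rate_matrix(fast_ind)
        with pytest.raises(ValueError):
            solve_step(A, np.zeros(5), 1.0)
        with pytest.raises(ValueError):
            solve_step(np.full((6, 6), np.nan), np.zeros(6), 1.0)
        with pytest.raises(ValueError):
            solve_step(A, np.zeros(6), 1.0, method="magic")


class TestMassBalance:
    def test_deposited_equals_remaining_plus_eliminated(self, typical_ds_male):
        reg = qd_regimen(200, 14)
        res = simulate_batch([typical_ds_male], reg,
                             auc_times=np.array([14 * 24.0 + 24.0]),
                             t_end=14 * 24.0 + 24.0)
        # eliminated mass = CL * AUC for elimination from the central compartment
        eliminated = typical_ds_male.clearance * res.auc[0, -1]
        total = res.final_state[0].sum() + eliminated
        assert total == pytest.approx(res.deposited[0], rel=1e-8)

    def test_conservation_along_a_profile(self, fast_ind, week_qd):
        # at several horizons: remaining + CL*AUC(0,t) == deposited(t)
        for t_end in (24.0, 100.0, 200.0):
            res = simulate_batch([fast_ind], week_qd, auc_times=np.array([t_end]), t_end=t_end)
            eliminated = fast_ind.clearance * res.auc[0, 0]
            assert res.final_state[0].sum() + eliminated == pytest.approx(
                res.deposited[0], rel=1e-8)


class TestProfileContract:
    def test_zero_before_first_dose_and_nonnegative(self, fast_ind):
        reg = Regimen("late", (DoseEvent(48.0, 100.0),), 96.0)
        prof = simulate_profile(fast_ind, reg, np.linspace(0, 96, 200))
        before = prof.times < 48.0
        np.testing.assert_allclose(prof.concentrations[before], 0.0, atol=1e-14)
        assert np.all(prof.concentrations >= 0)

    def test_terminal_phase_monotone_decrease(self, typical_ds_male):
        reg = qd_regimen(200, 7)
        t = np.linspace(7 * 24.0 + 48.0, 7 * 24.0 + 24 * 30.0, 200)
        c = simulate_profile(typical_ds_male, reg, t).concentrations
        assert np.all(np.diff(c) < 0)

    def test_empty_regimen_and_bad_grid_rejected(self, fast_ind, week_qd):
        with pytest.raises(ValueError):
            simulate_batch([fast_ind], Regimen("empty", (), 24.0), conc_times=np.array([1.0]))
        with pytest.raises(ValueError):
            simulate_profile(fast_ind, week_qd, np.array([0.0, 2.0, 1.0]))

    def test_determinism(self, typical_ds_male, week_qd):
        a = simulate_profile(typical_ds_male, week_qd, resolution=1.0)
        b = simulate_profile(typical_ds_male, week_qd, resolution=1.0)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)

    def test_batch_conc_matches_single_profiles(self, params, typical_ds_male, fast_ind):
        ind2 = dataclasses.replace(typical_ds_male, clearance=typical_ds_male.clearance * 1.7)
        reg = qd_regimen(150, 4)
        grid = np.linspace(0, 120, 121)
        res = simulate_batch([typical_ds_male, ind2], reg, conc_times=grid)
        for i, ind in enumerate((typical_ds_male, ind2)):
            single = simulate_profile(ind, reg, grid).concentrations
            np.testing.assert_allclose(res.conc[i], single, rtol=1e-10, atol=1e-14)
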