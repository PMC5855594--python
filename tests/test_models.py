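"""Forward-simulation correctness of the kinetic binding models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from glycobind import (
    KineticParams,
    ModelKind,
    PhaseSchedule,
    equilibrium_response,
    kd_from_rates,
    simulate_bivalent_analyte,
    simulate_heterogeneous_analyte,
    simulate_heterogeneous_ligand,
    simulate_langmuir,
)
from glycobind.errors import UnsupportedModelError, ValidationError


def ode_oracle_1to1(ka, kd, rmax, conc, sched, rtol=1e-10, atol=1e-12):
    """Independent adaptive integration of dR/dt = ka C (Rmax - R) - kd R
    with C switched off after the association phase."""
    t = sched.time_grid()

    def rhs(t_, r, c):
        return ka * c * (rmax - r[0]) - kd * r[0]

    mask = t <= sched.t_assoc
    out = np.empty_like(t)
    sol1 = solve_ivp(rhs, (0.0, sched.t_assoc), [0.0], args=(conc,),
                     rtol=rtol, atol=atol, dense_output=True)
    out[mask] = sol1.sol(t[mask])[0]
    sol2 = solve_ivp(rhs, (sched.t_assoc, t[-1]), sol1.sol(sched.t_assoc),
                     args=(0.0,), rtol=rtol, atol=atol, dense_output=True)
    out[~mask] = sol2.sol(t[~mask])[0]
    return out


class TestLangmuir:
    def test_zero_concentration_gives_flat_zero(self, compound11_params, schedule):
        sg = simulate_langmuir(compound11_params, 0.0, schedule)
        assert np.all(sg.response == 0.0)

    def test_steady_state_approaches_req(self):
        # KD = 1 nM, C = 1 uM: Req = Rmax * C / (C + KD) ~ 99.90 RU
        p = KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 100.0)
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=10.0, dt=0.5)
        sg = simulate_langmuir(p, 1e-6, sched)
        req = 100.0 * 1e-6 / (1e-6 + 1e-9)
        assert sg.response[np.searchsorted(sg.time, 100.0)] == pytest.approx(req, rel=1e-6)

    def test_matches_independent_ode_integration(self, compound11_params, schedule):
        sg = simulate_langmuir(compound11_params, 1e-9, schedule)
        oracle = ode_oracle_1to1(5.9e6, 8.5e-5, 100.0, 1e-9, schedule)
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(sg.response - oracle)) / scale < 1e-6

    def test_starts_at_zero_and_stays_within_capacity(self, compound11_params, schedule):
        sg = simulate_langmuir(compound11_params, 250e-12, schedule)
        assert sg.response[0] == 0.0
        assert np.all(sg.response >= 0.0) and np.all(sg.response <= 100.0)

    def test_wrong_kind_rejected(self, schedule):
        p = KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 50.0, 1e5, 1e-2, 50.0)
        with pytest.raises(ValidationError):
            simulate_langmuir(p, 1e-9, schedule)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    log_ka=st.floats(4.0, 7.0),
    log_kd=st.floats(-5.0, -2.0),
    log_c=st.floats(-11.0, -6.0),
)
def test_association_monotone_dissociation_decaying_and_bounded(log_ka, log_kd, log_c):
    """1:1 phase shapes: non-decreasing association, non-increasing
    dissociation, response within [0, Rmax]."""
    p = KineticParams(ModelKind.LANGMUIR_1TO1, 10 ** log_ka, 10 ** log_kd, 100.0)
    sched = PhaseSchedule(t_assoc=120.0, t_dissoc=300.0, dt=2.0)
    sg = simulate_langmuir(p, 10 ** log_c, sched)
    assoc = sg.response[sg.time <= sched.t_assoc]
    dissoc = sg.response[sg.time >= sched.t_assoc]
    assert np.all(np.diff(assoc) >= -1e-12)
    assert np.all(np.diff(dissoc) <= 1e-12)
    assert np.all(sg.response >= -1e-12) and np.all(sg.response <= 100.0 + 1e-9)


class TestHeterogeneousLigand:
    def test_degenerate_second_site_reduces_to_langmuir(self, schedule):
        p2 = KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 100.0, 1e5, 1e-2, 0.0)
        p1 = KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 100.0)
        a = simulate_heterogeneous_ligand(p2, 1e-7, schedule)
        b = simulate_langmuir(p1, 1e-7, schedule)
        np.testing.assert_array_equal(a.response, b.response)

    def test_identical_sites_collapse_to_single_site(self, schedule):
        p2 = KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 50.0, 1e6, 1e-3, 50.0)
        p1 = KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 100.0)
        a = simulate_heterogeneous_ligand(p2, 1e-7, schedule)
        b = simulate_langmuir(p1, 1e-7, schedule)
        np.testing.assert_allclose(a.response, b.response, rtol=0, atol=1e-12)

    def test_superposition_of_independent_sites(self, schedule):
        p = KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 60.0, 1e5, 1e-2, 40.0)
        combined = simulate_heterogeneous_ligand(p, 1e-7, schedule)
        s1 = simulate_langmuir(KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 60.0), 1e-7, schedule)
        s2 = simulate_langmuir(KineticParams(ModelKind.LANGMUIR_1TO1, 1e5, 1e-2, 40.0), 1e-7, schedule)
        np.testing.assert_allclose(combined.response, s1.response + s2.response,
                                   rtol=0, atol=1e-12)


class TestBivalentAnalyte:
    def test_second_step_off_reduces_to_doubled_rate_langmuir(self):
        # with the second attachment off only the first event remains,
        # carrying the statistical factor 2 on association
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        pb = KineticParams(ModelKind.BIVALENT_ANALYTE, 1e6, 1e-3, 100.0, 0.0, 1e-2)
        p1 = KineticParams(ModelKind.LANGMUIR_1TO1, 2e6, 1e-3, 100.0)
        a = simulate_bivalent_analyte(pb, 1e-7, sched)
        b = simulate_langmuir(p1, 1e-7, sched)
        np.testing.assert_allclose(a.response, b.response, rtol=1e-6, atol=1e-7)

    def test_zero_concentration_stays_zero(self):
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        p = KineticParams(ModelKind.BIVALENT_ANALYTE, 1e6, 1e-3, 100.0, 1e-3, 5e-3)
        sg = simulate_bivalent_analyte(p, 0.0, sched)
        assert np.max(np.abs(sg.response)) < 1e-10

    @pytest.mark.parametrize("ka1,kd1,ka2,kd2,conc", [
        (1e6, 1e-3, 1e-3, 5e-3, 1e-7),
        (1e7, 1e-4, 1e-2, 1e-3, 1e-8),
        (1e5, 1e-2, 1e-4, 1e-2, 1e-6),
    ])
    def test_capacity_conserved(self, ka1, kd1, ka2, kd2, conc):
        """Occupied plus free capacity equals Rmax at every sample: the
        response can never exceed the immobilized amount."""
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        p = KineticParams(ModelKind.BIVALENT_ANALYTE, ka1, kd1, 100.0, ka2, kd2)
        sg = simulate_bivalent_analyte(p, conc, sched)
        free = 100.0 - sg.response
        assert np.all(sg.response >= -1e-8)
        assert np.all(free >= -1e-8)
        np.testing.assert_allclose(sg.response + free, 100.0, rtol=0, atol=1e-8)


class TestHeterogeneousAnalyte:
    def test_absent_second_species_reduces_to_langmuir(self):
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        ph = KineticParams(ModelKind.HETEROGENEOUS_ANALYTE, 1e6, 1e-3, 100.0, 2e5, 1e-2)
        p1 = KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 100.0)
        a = simulate_heterogeneous_analyte(ph, 1e-7, 0.0, sched)
        b = simulate_langmuir(p1, 1e-7, sched)
        np.testing.assert_allclose(a.response, b.response, rtol=1e-6, atol=1e-7)

    def test_indistinguishable_species_merge(self):
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        ph = KineticParams(ModelKind.HETEROGENEOUS_ANALYTE, 1e6, 1e-3, 100.0, 1e6, 1e-3)
        split = simulate_heterogeneous_analyte(ph, 5e-8, 5e-8, sched)
        merged = simulate_heterogeneous_analyte(ph, 1e-7, 0.0, sched)
        np.testing.assert_allclose(split.response, merged.response, rtol=1e-6, atol=1e-7)

    @pytest.mark.parametrize("conc_a,conc_b", [(1e-7, 1e-7), (1e-6, 1e-8), (1e-8, 1e-6)])
    def test_competition_respects_shared_capacity(self, conc_a, conc_b):
        sched = PhaseSchedule(t_assoc=100.0, t_dissoc=200.0, dt=1.0)
        p = KineticParams(ModelKind.HETEROGENEOUS_ANALYTE, 1e7, 1e-4, 100.0, 5e6, 1e-3)
        sg = simulate_heterogeneous_analyte(p, conc_a, conc_b, sched)
        assert np.all(sg.response <= 100.0 + 1e-8)


class TestEquilibriumResponse:
    def test_saturating_concentration_returns_capacity(self):
        p = KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 60.0, 1e5, 1e-2, 40.0)
        assert equilibrium_response(p, np.inf) == 100.0
        assert equilibrium_response(p, 1.0) == pytest.approx(100.0, rel=1e-6)

    def test_half_saturation_at_kd(self):
        p = KineticParams(ModelKind.LANGMUIR_1TO1, 1e6, 1e-3, 100.0)
        assert equilibrium_response(p, 1e-9) == pytest.approx(50.0)

    def test_compound11_half_saturation_concentration(self, compound11_params):
        # C set to kd/ka of the strongest-ligand regime gives Rmax/2
        assert equilibrium_response(compound11_params, 8.5e-5 / 5.9e6) == pytest.approx(50.0)

    def test_matches_long_time_association_limit(self):
        p = KineticParams(ModelKind.LANGMUIR_1TO1, 1e5, 1e-3, 80.0)
        conc = 3e-8
        t_eq = 50.0 / (p.ka1 * conc + p.kd1)
        sched = PhaseSchedule(t_assoc=t_eq, t_dissoc=0.0, dt=t_eq / 200)
        sg = simulate_langmuir(p, conc, sched)
        assert sg.response[-1] == pytest.approx(equilibrium_response(p, conc), rel=1e-9)

    def test_ode_kinds_unsupported(self):
        p = KineticParams(ModelKind.BIVALENT_ANALYTE, 1e6, 1e-3, 100.0, 1e-3, 5e-3)
        with pytest.raises(UnsupportedModelError):
            equilibrium_response(p, 1e-9)


class TestKdFromRates:
    @pytest.mark.parametrize("ka,kd,expected,rel", [
        (5.9e6, 8.5e-5, 1.4e-11, 0.03),   # strongest ligand, reported 1.4e-11
        (4.8e4, 4.0e-4, 8.3e-9, 0.005),   # ASF standard, reported 8.3e-9
        (1.0, 1.0, 1.0, 1e-15),
    ])
    def test_ratio_of_rates(self, ka, kd, expected, rel):
        assert kd_from_rates(ka, kd).value == pytest.approx(expected, rel=rel)

    def test_error_propagation_for_ratio(self):
        kd_eq = kd_from_rates(2.0, 8.0, se_ka=0.2, se_kd=0.4)
        assert kd_eq.value == 4.0
        assert kd_eq.stderr == pytest.approx(4.0 * np.sqrt(0.1 ** 2 + 0.05 ** 2))

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValidationError):
            kd_from_rates(0.0, 1.0)
        with pytest.raises(ValidationError):
            kd_from_rates(1.0, -1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(ka=st.integers(1, 10 ** 6), kd=st.integers(1, 10 ** 6),
           factor=st.sampled_from([2, 4, 8, 16, 32, 64]))
    def test_scale_consistency(self, ka, kd, factor):
        """KD depends only on the ratio kd/ka: a common power-of-two
        factor (exact in floating point) cancels exactly."""
        assert kd_from_rates(ka * factor, kd * factor).value == kd_from_rates(ka, kd).value


class TestValidation:
    def test_schedule_invariants(self):
        with pytest.raises(ValidationError):
            PhaseSchedule(t_assoc=0.0)
        with pytest.raises(ValidationError):
            PhaseSchedule(t_assoc=10.0, dt=10.0)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValidationError):
            KineticParams(ModelKind.LANGMUIR_1TO1, -1.0, 1e-3, 100.0)
        with pytest.raises(ValidationError):
            KineticParams(ModelKind.HETEROGENEOUS_LIGAND, 1e6, 1e-3, 100.0)
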