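"""Unit and property tests for the closed-form model layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import sabrekit as sk
from sabrekit.model import KAPPA_UNITY_TOL

# strategies over sensible pharmacological ranges
log_kds = st.floats(-10.0, -4.0)
efficacies = st.floats(0.01, 1.0)
gains = st.floats(0.01, 100.0)
log_concs = st.floats(-13.0, -1.0)


class TestSABREParameters:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            sk.SABREParameters(log_kd=np.nan, efficacy=1, gain=1)
        with pytest.raises(ValueError):
            sk.SABREParameters(log_kd=-7, efficacy=1.2, gain=1)
        with pytest.raises(ValueError):
            sk.SABREParameters(log_kd=-7, efficacy=1, gain=0.0)
        with pytest.raises(ValueError):
            sk.SABREParameters(log_kd=-7, efficacy=1, gain=1, hill=0.0)

    def test_shift_kappa_semantics(self):
        assert sk.ShiftKappa(2.0).left_shifted
        assert sk.ShiftKappa(0.5).right_shifted
        with pytest.raises(ValueError):
            sk.ShiftKappa(0.0)


class TestResponseGeneral:
    def test_zero_baseline_without_constitutive_activity(self):
        p = sk.SABREParameters(-7.0, efficacy=1.0, gain=10.0, efficacy_r0=0.0)
        assert sk.response_general(-30.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_constitutive_activity_gives_nonzero_basal(self):
        p = sk.SABREParameters(-7.0, efficacy=1.0, gain=10.0, efficacy_r0=0.1)
        basal = 0.1 * 10.0 / (0.1 * 10.0 - 0.1 + 1.0)
        assert sk.response_general(-30.0, p) == pytest.approx(basal, rel=1e-9)

    def test_at_kd_full_agonist(self):
        # direct hand evaluation of the closed form at L = Kd
        p = sk.SABREParameters(-6.64, efficacy=1.0, gain=30.84)
        assert sk.response_general(-6.64, p) == pytest.approx(
            30.84 / 31.84, rel=1e-12
        )

    def test_rejects_nonfinite_logL(self):
        p = sk.SABREParameters(-7.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="finite"):
            sk.response_general(np.nan, p)
        with pytest.raises(ValueError, match="finite"):
            sk.response_general([-7.0, np.inf], p)

    @given(log_kds, efficacies, gains)
    def test_reduces_to_simplified(self, log_kd, eps, gain):
        logL = np.linspace(log_kd - 4, log_kd + 4, 25)
        p = sk.SABREParameters(log_kd, eps, gain, efficacy_r0=0.0, hill=1.0)
        np.testing.assert_allclose(
            sk.response_general(logL, p),
            sk.response_simplified(logL, log_kd, eps, gain),
            rtol=1e-12,
        )

    @given(log_kds, efficacies, st.floats(0.0, 0.5), gains, st.floats(0.3, 3.0))
    def test_monotone_when_eps_dominates(self, log_kd, eps, e0, gain, hill):
        e0 = min(e0, eps)  # monotonicity guaranteed for eps >= eps_r0
        p = sk.SABREParameters(log_kd, eps, gain, efficacy_r0=e0, hill=hill)
        logL = np.linspace(log_kd - 6, log_kd + 6, 200)
        y = sk.response_general(logL, p)
        assert np.all(np.diff(y) >= -1e-12)


class TestResponseSimplified:
    def test_clark_reduction_half_occupancy(self):
        assert sk.response_simplified(-7.0, -7.0, 0.5, 1.0) == pytest.approx(0.25)

    def test_half_max_at_kd_over_gain_for_full_agonist(self):
        # Kobs = Kd/gamma when eps = 1
        log_kd, gain = -7.0, 15.0
        logL = log_kd - np.log10(gain)
        assert sk.response_simplified(logL, log_kd, 1.0, gain) == pytest.approx(0.5)

    def test_emax_limit_partial_agonist(self):
        # eps*gamma/(eps*gamma - eps + 1) with eps=0.178, gamma=30.84
        val = sk.response_simplified(-6.60 + 9, -6.60, 0.178, 30.84)
        assert val == pytest.approx(0.178 * 30.84 / (0.178 * 30.84 - 0.178 + 1),
                                    rel=1e-6)
        assert val == pytest.approx(0.8698, abs=5e-4)

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(ValueError, match="gain"):
            sk.response_simplified(-7.0, -7.0, 0.5, 0.0)

    @given(log_kds, efficacies)
    def test_gamma_one_equals_clark(self, log_kd, eps):
        logL = np.linspace(log_kd - 4, log_kd + 4, 31)
        hp = sk.HillParameters(log_ec50=log_kd, e_max=eps, hill=1.0)
        np.testing.assert_allclose(
            sk.response_simplified(logL, log_kd, eps, 1.0),
            sk.hill_response(logL, hp),
            rtol=1e-12,
        )

    @given(log_kds, st.floats(0.05, 1.0), gains)
    def test_strictly_increasing(self, log_kd, eps, gain):
        logL = np.linspace(log_kd - 6, log_kd + 6, 100)
        y = sk.response_simplified(logL, log_kd, eps, gain)
        assert np.all(np.diff(y) > 0)


class TestOccupancy:
    def test_half_at_kd(self):
        assert sk.occupancy(-7.0, -7.0) == pytest.approx(0.5)
        assert sk.occupancy(-7.0, -7.0, hill=2.0) == pytest.approx(0.5)

    def test_mass_action_decade(self):
        assert sk.occupancy(-6.0, -7.0) == pytest.approx(10.0 / 11.0)

    def test_invalid_hill(self):
        with pytest.raises(ValueError):
            sk.occupancy(-7.0, -7.0, hill=-1.0)


class TestKobsEmax:
    def test_full_agonist_shift(self):
        assert sk.k_obs(-7.0, 1.0, 20.0) == pytest.approx(-7.0 - np.log10(20.0))

    def test_partial_agonist_kobs(self):
        # kappa = 0.178*30.84 - 0.178 + 1 = 6.3115...
        assert sk.k_obs(-6.60, 0.178, 30.84) == pytest.approx(-7.40, abs=5e-3)

    def test_no_amplification_kobs_is_kd(self):
        assert sk.k_obs(-7.3, 0.4, 1.0) == pytest.approx(-7.3)

    def test_emax_full_agonist_is_one(self):
        for gain in (0.05, 1.0, 50.0):
            assert sk.e_max_pred(1.0, gain) == pytest.approx(1.0)

    def test_emax_no_amplification_is_eps(self):
        assert sk.e_max_pred(0.3, 1.0) == pytest.approx(0.3)

    def test_emax_attenuated_partial_agonist(self):
        assert sk.e_max_pred(0.823, 0.059) == pytest.approx(0.2153, abs=5e-4)

    @given(log_kds, efficacies, gains)
    def test_reproduces_brute_force_apex_and_midpoint(self, log_kd, eps, gain):
        """e_max_pred / k_obs must match apex and half-max located by grid
        search on the response curve itself (<0.1% relative)."""
        logL = np.linspace(log_kd - 8, log_kd + 8, 40001)
        y = sk.response_simplified(logL, log_kd, eps, gain)
        emax_grid = y[-1]  # monotone increasing -> apex at right edge
        assert emax_grid == pytest.approx(sk.e_max_pred(eps, gain), rel=1e-3)
        half = emax_grid / 2.0
        log_ec50_grid = np.interp(half, y, logL)
        ec50_rel = 10.0 ** (log_ec50_grid - sk.k_obs(log_kd, eps, gain))
        assert ec50_rel == pytest.approx(1.0, rel=1e-3)


class TestKappa:
    def test_experimental_shift_examples(self):
        assert sk.kappa_from_shift(-6.62, -7.72).kappa == pytest.approx(12.59, abs=5e-3)
        assert sk.kappa_from_shift(-6.62, -6.02).kappa == pytest.approx(0.251, abs=5e-4)
        assert sk.kappa_from_shift(-7.0, -7.0).kappa == pytest.approx(1.0)

    def test_parameter_shift_examples(self):
        assert sk.kappa_from_params(0.178, 30.84).kappa == pytest.approx(6.31, abs=0.05)
        assert sk.kappa_from_params(0.823, 0.059).kappa == pytest.approx(0.226, abs=0.02)
        # exact identity for a full agonist: kappa == gamma
        assert sk.kappa_from_params(1.0, 15.51).kappa == pytest.approx(15.51)

    def test_rejects_nonpositive_shift(self):
        with pytest.raises(ValueError):
            sk.kappa_from_params(1.0, -1.0)

    @given(log_kds, efficacies, gains)
    def test_two_routes_agree(self, log_kd, eps, gain):
        via_params = sk.kappa_from_params(eps, gain).kappa
        via_shift = sk.kappa_from_shift(log_kd, sk.k_obs(log_kd, eps, gain)).kappa
        assert via_shift == pytest.approx(via_params, rel=1e-10)

    @given(efficacies, gains)
    def test_sign_semantics(self, eps, gain):
        kappa = sk.kappa_from_params(eps, gain).kappa
        if gain > 1:
            assert kappa > 1
        elif gain < 1:
            assert kappa < 1
        else:
            assert kappa == pytest.approx(1.0)


class TestResponseFromOccupancy:
    def test_endpoints(self):
        assert sk.response_from_occupancy(0.0, 0.5, 10.0) == pytest.approx(0.0)
        assert sk.response_from_occupancy(1.0, 1.0, 10.0) == pytest.approx(1.0)

    def test_amplified_low_occupancy_near_full_response(self):
        # two-step oracle: invert occupancy, evaluate the response curve
        log_kd = -7.0
        logL = log_kd + np.log10(0.2 / 0.8)  # occupancy 0.2
        expected = sk.response_simplified(logL, log_kd, 1.0, 30.84)
        got = sk.response_from_occupancy(0.2, 1.0, 30.84)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.885, abs=1e-3)

    def test_rejects_out_of_range_occupancy(self):
        with pytest.raises(ValueError):
            sk.response_from_occupancy(1.2, 1.0, 10.0)
        with pytest.raises(ValueError):
            sk.response_from_occupancy(-0.1, 1.0, 10.0)

    @given(log_kds, efficacies, gains, st.floats(-5.0, 5.0))
    def test_composition_identity(self, log_kd, eps, gain, offset):
        logL = log_kd + offset
        f_occ = sk.occupancy(logL, log_kd)
        lhs = sk.response_from_occupancy(f_occ, eps, gain)
        rhs = sk.response_simplified(logL, log_kd, eps, gain)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    @given(efficacies, gains)
    def test_strictly_increasing_in_occupancy(self, eps, gain):
        f = np.linspace(0.0, 1.0, 101)
        y = sk.response_from_occupancy(f, eps, gain)
        assert np.all(np.diff(y) > 0)


class TestResponseFromOccupancyGeneric:
    def test_unity_limit_is_linear(self):
        f = np.linspace(0, 1, 11)
        y = sk.response_from_occupancy_generic(f, e_max=0.7, kappa=1.0 + 1e-12)
        np.testing.assert_allclose(y, 0.7 * f, rtol=1e-9)

    def test_matches_sabre_parametrisation(self):
        eps, gain = 0.3, 8.0
        kappa = eps * gain - eps + 1.0
        e_max = eps * gain / kappa
        f = np.linspace(0, 1, 21)
        np.testing.assert_allclose(
            sk.response_from_occupancy_generic(f, e_max, kappa),
            sk.response_from_occupancy(f, eps, gain),
            rtol=1e-12,
        )

    def test_arithmetic_example(self):
        val = sk.response_from_occupancy_generic(0.5, e_max=1.0, kappa=12.59)
        expected = 12.59 / 11.59 * 0.5 / (0.5 + 1.0 / 11.59)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(0.926, abs=1e-3)

    def test_right_shift_narrative_invert_for_kappa(self):
        # numeric solve: which kappa sends occupancy 0.8 to response 0.15?
        def gap(kappa):
            return sk.response_from_occupancy_generic(0.8, 1.0, kappa) - 0.15

        kappa = brentq(gap, 1e-4, 1.0 - 1e-9)
        assert kappa < 1.0  # right-shifted regime
        assert sk.response_from_occupancy_generic(0.8, 1.0, kappa) == pytest.approx(
            0.15, abs=1e-9
        )


class TestHillResponse:
    def test_half_max_at_ec50(self):
        hp = sk.HillParameters(-7.0, 0.8)
        assert sk.hill_response(-7.0, hp) == pytest.approx(0.4)

    def test_steep_slope_decade(self):
        hp = sk.HillParameters(-7.0, 0.6, hill=3.0)
        assert sk.hill_response(-6.0, hp) == pytest.approx(0.6 * 1000 / 1001)

    def test_published_morphine_row(self):
        hp = sk.HillParameters(-7.01, 0.942)
        assert sk.hill_response(-7.01, hp) == pytest.approx(0.471)


class TestOperationalResponse:
    def test_large_tau_tracks_occupancy_shape(self):
        op = sk.OperationalParameters(-7.0, tau=1e6)
        # apparent EC50 -> K_D/(tau+1): essentially full response at K_D
        assert sk.operational_response(-7.0, op) > 0.999

    def test_quarter_response(self):
        op = sk.OperationalParameters(-7.0, tau=1.0)
        logL = -7.0 + np.log10(0.5)
        assert sk.operational_response(logL, op) == pytest.approx(0.25)

    def test_apparent_emax(self):
        op = sk.OperationalParameters(-7.0, tau=3.0)
        assert sk.operational_response(2.0, op) == pytest.approx(0.75, rel=1e-6)


class TestChengPrusoff:
    def test_no_radioligand_no_correction(self):
        assert sk.cheng_prusoff(1e-7, 0.0, 1e-9) == pytest.approx(np.log10(1e-7))

    def test_equal_conc_halves(self):
        assert 10 ** sk.cheng_prusoff(1e-6, 1e-9, 1e-9) == pytest.approx(5e-7)

    def test_arithmetic(self):
        assert 10 ** sk.cheng_prusoff(1e-6, 3e-9, 1e-9) == pytest.approx(2.5e-7)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sk.cheng_prusoff(-1e-6, 1e-9, 1e-9)
        with pytest.raises(ValueError):
            sk.cheng_prusoff(1e-6, 1e-9, 0.0)


def test_reduction_chain_on_dense_grid():
    """Five-parameter form with eps_r0=0, n=1 equals the reduced form to
    machine precision over >=100 (logL, parameter) combinations."""
    rng = np.random.default_rng(42)
    count = 0
    for _ in range(12):
        log_kd = rng.uniform(-10, -4)
        eps = rng.uniform(0.01, 1.0)
        gain = 10.0 ** rng.uniform(-2, 2)
        logL = np.linspace(log_kd - 5, log_kd + 5, 11)
        p = sk.SABREParameters(log_kd, eps, gain)
        np.testing.assert_allclose(
            sk.response_general(logL, p),
            sk.response_simplified(logL, log_kd, eps, gain),
            rtol=1e-13,
        )
        count += logL.size
    assert count >= 100
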