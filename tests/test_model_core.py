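"""Single-exposure model: pharmacology, protraction, targeted and
non-targeted kill, and their multiplicative combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize

import imksurv as ik
from imksurv.params import SPECIFIC_ENERGY_COEF


def lea_catcheside_oracle(a_plus_c: float, duration: float) -> float:
    """Independent protraction oracle: the normalized double integral
    (2/T^2) int_0^T int_0^t exp(-(a+c)(t - t')) dt' dt for constant
    dose rate."""
    val, _ = integrate.dblquad(
        lambda tp, t: math.exp(-a_plus_c * (t - tp)),
        0.0,
        duration,
        0.0,
        lambda t: t,
        epsabs=1e-12,
        epsrel=1e-12,
    )
    return 2.0 * val / duration**2


class TestPharmacology:
    @pytest.mark.parametrize(
        "conc, expected, tol",
        [
            (0.0, 1.0, 0.0),  # no drug, full survival
            (92.07, 0.50015, 1e-4),  # midpoint at ED50: (max + min) / 2
            (100.0, 0.4663989, 1e-6),  # frozen direct evaluation
        ],
    )
    def test_examples(self, table1, conc, expected, tol):
        s = ik.pharmacological_survival(conc, table1.pharmacology)
        assert s == pytest.approx(expected, abs=max(tol, 1e-12))

    def test_negative_concentration_rejected(self, table1):
        with pytest.raises(ValueError):
            ik.pharmacological_survival(-1.0, table1.pharmacology)

    def test_monotone_non_increasing(self, table1):
        grid = np.linspace(0.0, 1000.0, 1000)
        s = ik.pharmacological_survival(grid, table1.pharmacology)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= table1.pharmacology.s_p_min) & (s <= 1.0))


class TestGamma:
    def test_table_value(self):
        # tabulated microdosimetric constant for 150 kVp X-rays, 1 um domain
        assert 0.954 <= ik.gamma_from_lineal_energy(4.683, 1.0) <= 0.956

    def test_inverse_square_in_diameter(self):
        assert ik.gamma_from_lineal_energy(4.683, 2.0) == pytest.approx(
            ik.gamma_from_lineal_energy(4.683, 1.0) / 4.0
        )

    def test_linear_in_lineal_energy(self):
        assert ik.gamma_from_lineal_energy(9.366, 1.0) == pytest.approx(
            2.0 * ik.gamma_from_lineal_energy(4.683, 1.0)
        )

    @pytest.mark.parametrize("y_d, d", [(0.0, 1.0), (-1.0, 1.0), (4.7, 0.0)])
    def test_domain_errors(self, y_d, d):
        with pytest.raises(ValueError):
            ik.gamma_from_lineal_energy(y_d, d)


class TestLeaCatcheside:
    def test_acute_limit(self):
        assert ik.lea_catcheside_factor(2.215, 0.0) == 1.0

    def test_one_hour_vs_oracle(self):
        f = ik.lea_catcheside_factor(2.215, 1.0)
        assert f == pytest.approx(0.540, abs=5e-4)
        assert f == pytest.approx(lea_catcheside_oracle(2.215, 1.0), abs=1e-9)

    def test_protracted_asymptote(self):
        T = 1e4
        assert ik.lea_catcheside_factor(2.215, T) == pytest.approx(
            2.0 / (2.215 * T), rel=1e-3
        )

    def test_oracle_agreement_on_log_grid(self):
        ac = 2.215
        for T in np.logspace(-4, 2, 50):
            assert abs(
                ik.lea_catcheside_factor(ac, T) - lea_catcheside_oracle(ac, T)
            ) < 1e-6

    def test_bounded_and_monotone(self):
        grid = np.logspace(-6, 3, 200)
        f = ik.lea_catcheside_factor(2.215, grid)
        assert np.all((f > 0) & (f <= 1.0))
        assert np.all(np.diff(f) <= 0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            ik.lea_catcheside_factor(2.215, -0.1)


class TestTargeted:
    def test_zero_dose(self, table1):
        e = ik.Exposure(dose=0.0, acute=True)
        assert ik.targeted_log_survival(e, table1.targeted, table1.gamma) == 0.0

    def test_acute_4gy(self, table1):
        # (0.053 + 0.954*0.069)*4 + 0.069*16, frozen
        e = ik.Exposure(dose=4.0, acute=True)
        assert ik.targeted_log_survival(e, table1.targeted, table1.gamma) == pytest.approx(
            1.579304, abs=1e-6
        )

    def test_protracted_4gy_matches_oracle_f(self, table1):
        # 4 Gy at 1 Gy/min: T = 1/15 h; quadratic term scaled by oracle F
        e = ik.Exposure(dose=4.0, dose_rate=60.0)
        f = lea_catcheside_oracle(table1.targeted.a_plus_c, 4.0 / 60.0)
        expected = (0.053 + 0.954 * 0.069) * 4.0 + f * 0.069 * 16.0
        got = ik.targeted_log_survival(e, table1.targeted, table1.gamma)
        assert got == pytest.approx(expected, abs=1e-8)
        assert got == pytest.approx(1.52691, abs=1e-4)


class TestDelta:
    @pytest.mark.parametrize(
        "conc, expected, tol",
        [
            (0.0, 0.760, 1e-12),  # zero-concentration limit
            (92.07, 4.4675, 1e-4),  # sigmoid midpoint
            (100.0, 5.761056, 1e-5),  # frozen direct evaluation
        ],
    )
    def test_examples(self, table1, conc, expected, tol):
        d = ik.delta_of_concentration(conc, table1.non_targeted, table1.ed50)
        assert d == pytest.approx(expected, abs=tol)

    def test_monotone_non_decreasing(self, table1):
        grid = np.linspace(0.0, 1000.0, 1000)
        d = ik.delta_of_concentration(grid, table1.non_targeted, table1.ed50)
        assert np.all(np.diff(d) >= -1e-15)
        assert d[0] == table1.non_targeted.delta_min


class TestNonTargeted:
    def test_zero_dose(self, table1):
        assert ik.nontargeted_log_survival(0.0, 5.0, table1.non_targeted, table1.gamma) == 0.0

    def test_4gy_baseline_delta(self, table1):
        got = ik.nontargeted_log_survival(4.0, 0.760, table1.non_targeted, table1.gamma)
        assert got == pytest.approx(0.189930, abs=1e-5)

    def test_bounded_by_quarter_delta_with_equality_at_half_activation(self, table1):
        nt, g = table1.non_targeted, table1.gamma
        delta = 3.0
        doses = np.linspace(0.0, 60.0, 2000)
        vals = np.array([ik.nontargeted_log_survival(d, delta, nt, g) for d in doses])
        assert np.all(vals <= delta / 4.0 + 1e-12)
        # p(D) = 1/2 where the activation exponent reaches ln 2
        d_half = optimize.brentq(
            lambda D: (nt.alpha_b + g * nt.beta_b) * D + nt.beta_b * D**2 - math.log(2.0),
            0.0,
            60.0,
            xtol=1e-12,
        )
        at_half = ik.nontargeted_log_survival(d_half, delta, nt, g)
        assert abs(at_half - delta / 4.0) < 1e-9


class TestCombined:
    def test_untreated_unirradiated(self, table1):
        assert ik.combined_survival(ik.Exposure(dose=0.0, acute=True), table1) == 1.0

    def test_4gy_no_drug(self, table1):
        got = ik.combined_survival(ik.Exposure(dose=4.0, acute=True), table1)
        assert got == pytest.approx(math.exp(-1.579304 - 0.189930), abs=1e-6)
        assert got == pytest.approx(0.17046, abs=1e-4)

    def test_4gy_100um(self, table1):
        e = ik.Exposure(dose=4.0, concentration=100.0, acute=True)
        assert ik.combined_survival(e, table1) == pytest.approx(0.022783, abs=1e-5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        dose=st.floats(0.0, 20.0),
        conc=st.floats(0.0, 500.0),
    )
    def test_log_factorization_exact(self, table1, dose, conc):
        e = ik.Exposure(dose=dose, concentration=conc, acute=True)
        s_p = ik.pharmacological_survival(conc, table1.pharmacology)
        te = ik.targeted_log_survival(e, table1.targeted, table1.gamma)
        delta = ik.delta_of_concentration(conc, table1.non_targeted, table1.ed50)
        nte = ik.nontargeted_log_survival(dose, delta, table1.non_targeted, table1.gamma)
        assert ik.log_combined_survival(e, table1) == math.log(s_p) - te - nte
        assert 0.0 < ik.combined_survival(e, table1) <= 1.0

    def test_reduces_to_lq_without_bystander_term(self, table1):
        nt0 = ik.NonTargetedParams(
            alpha_b=table1.non_targeted.alpha_b,
            beta_b=table1.non_targeted.beta_b,
            delta_min=0.0,
            delta_max=0.0,
            r_delta=table1.non_targeted.r_delta,
        )
        params = ik.ModelParameters(
            pharmacology=table1.pharmacology,
            microdosimetry=table1.microdosimetry,
            targeted=table1.targeted,
            non_targeted=nt0,
        )
        t, g = table1.targeted, table1.gamma
        for dose in (0.0, 1.0, 2.5, 4.0, 10.0):
            for conc in (0.0, 80.0):
                e = ik.Exposure(dose=dose, dose_rate=60.0, concentration=conc)
                f = ik.lea_catcheside_factor(t.a_plus_c, e.duration)
                lq = math.exp(-(t.alpha0 + g * t.beta0) * dose - f * t.beta0 * dose**2)
                s_p = ik.pharmacological_survival(conc, table1.pharmacology)
                assert ik.combined_survival(e, params) == pytest.approx(
                    s_p * lq, rel=1e-14
                )


class TestExposure:
    def test_duration_derived(self):
        e = ik.Exposure(dose=4.0, dose_rate=60.0)
        assert e.duration == pytest.approx(4.0 / 60.0)

    def test_acute_forces_zero_duration(self):
        assert ik.Exposure(dose=4.0, acute=True).duration == 0.0

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            ik.Exposure(dose=4.0, dose_rate=60.0, duration=1.0)

    @pytest.mark.parametrize("kwargs", [
        {"dose": -1.0}, {"dose": 1.0, "dose_rate": 0.0}, {"dose": 1.0, "concentration": -5.0},
    ])
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            ik.Exposure(**kwargs)


def test_specific_energy_coefficient_from_first_principles():
    # 4 y / (rho pi d^2) with keV->J and um->m bookkeeping, unit density
    kev_per_um = 1.602176634e-16 / 1e-6  # J/m
    rho = 1000.0  # kg/m^3
    coef = 4 * kev_per_um / (rho * math.pi * 1e-12)  # d^2 in um^2 -> m^2
    assert SPECIFIC_ENERGY_COEF == pytest.approx(coef, rel=1e-12)
    assert SPECIFIC_ENERGY_COEF == pytest.approx(0.204, abs=5e-4)
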