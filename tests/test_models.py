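"""Closed-form forward models: frozen-value checks and algebraic limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosorb import (
    BatchConditions,
    CovolumeSingularityError,
    EnergeticDecomposition,
    IPDParams,
    PFOParams,
    PSOParams,
    SLMRGParams,
    ValidationError,
    adsorption_energy,
    batch_capacity,
    effective_concentration,
    energetic_parameter,
    ipd_capacity,
    pfo_capacity,
    pso_capacity,
    removal_efficiency,
    saturation_capacity,
    slmrg_capacity,
)
from conftest import TABLE1

KB = 1.380649  # Boltzmann constant in the 1e-23 J/K units of the a column


class TestEffectiveConcentration:
    def test_ideal_limit_is_identity(self):
        p = SLMRGParams(n=1, nm=1, a=0.0, b=0.0, w=1)
        assert effective_concentration(10.0, p, 293.0) == pytest.approx(10.0, abs=0)

    def test_empty_solution(self):
        p = SLMRGParams(n=1, nm=1, a=5.0, b=0.01, w=1)
        assert effective_concentration(0.0, p, 293.0) == 0.0

    def test_van_der_waals_correction_hand_value(self):
        # b=0.008 L/mg and a chosen so that 2*a*beta = 0.04 L/mg at 293 K:
        # f(10) = 10/0.92 * e^(0.08/0.92) * e^(-0.4), evaluated independently
        a = 0.02 * KB * 293.0
        p = SLMRGParams(n=1, nm=1, a=a, b=0.008, w=1)
        assert effective_concentration(10.0, p, 293.0) == pytest.approx(
            7.948023041, rel=1e-9
        )

    def test_covolume_singularity_named(self):
        p = SLMRGParams(n=1, nm=1, a=0.0, b=0.01, w=1)
        with pytest.raises(CovolumeSingularityError, match="co-volume bound"):
            effective_concentration(100.0, p, 293.0)

    def test_continuous_in_ce(self, owp_293_params):
        # finite, nonnegative and jump-free on the whole open domain
        ce = np.linspace(0.0, 0.7 / owp_293_params.b, 2000)
        f = effective_concentration(ce, owp_293_params, 293.0)
        assert np.all(np.isfinite(f)) and np.all(f >= 0)
        step = ce[1] - ce[0]
        assert np.max(np.abs(np.diff(f))) < 50.0 * step  # bounded local slope


class TestSlmrgCapacity:
    def test_zero_at_origin(self, owp_293_params):
        assert slmrg_capacity(0.0, owp_293_params, 293.0) == 0.0

    def test_langmuir_half_saturation(self):
        # a=b=0, n=1: the model is Langmuir and qe(w) = Nm/2
        p = SLMRGParams(n=1.0, nm=80.0, a=0.0, b=0.0, w=12.5)
        assert slmrg_capacity(12.5, p, 293.0) == pytest.approx(40.0, rel=1e-14)

    def test_frozen_hand_value(self, owp_293_params):
        # closed form evaluated independently at 30 significant digits
        assert slmrg_capacity(10.0, owp_293_params, 293.0) == pytest.approx(
            42.34590960238090, rel=1e-12
        )

    def test_reduces_to_hill_form_without_real_gas_terms(self):
        ce = np.linspace(0.01, 200.0, 97)
        for n in (0.5, 1.0, 2.3):
            p = SLMRGParams(n=n, nm=55.0, a=0.0, b=0.0, w=9.0)
            hill = n * 55.0 / (1.0 + (9.0 / ce) ** n)
            np.testing.assert_allclose(slmrg_capacity(ce, p, 293.0), hill, rtol=1e-12)

    @pytest.mark.parametrize("key", sorted(TABLE1), ids=lambda k: f"{k[0]}-{k[1]}K")
    def test_monotone_in_effective_concentration_and_bounded(self, key):
        # qe is a strictly increasing function of the effective concentration
        # f, so it is nondecreasing wherever f is; for strong cohesion
        # pressure, f itself turns over at high Ce and qe follows it down.
        params = SLMRGParams(**TABLE1[key])
        temperature = float(key[1])
        ce = np.linspace(1e-6, 0.9 / params.b, 400)
        f = effective_concentration(ce, params, temperature)
        qe = slmrg_capacity(ce, params, temperature)
        rising = np.diff(f) >= 0
        assert np.all(np.diff(qe)[rising] >= -1e-10)
        assert np.all(np.diff(qe)[~rising] <= 1e-10)
        assert np.all(qe >= 0)
        assert np.all(qe < saturation_capacity(params))

    @pytest.mark.parametrize(
        "key", [("OWP", 293), ("OWP", 303), ("OWPSA", 293), ("OWPSA", 303)],
        ids=lambda k: f"{k[0]}-{k[1]}K",
    )
    def test_weak_cohesion_isotherms_monotone_everywhere(self, key):
        # with the cohesion term small on the domain the isotherm is an
        # L-shaped nondecreasing curve all the way to the co-volume bound
        params = SLMRGParams(**TABLE1[key])
        ce = np.linspace(1e-6, 0.9 / params.b, 400)
        qe = slmrg_capacity(ce, params, float(key[1]))
        assert np.all(np.diff(qe) >= -1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            SLMRGParams(n=-1, nm=50, a=0, b=0, w=1)
        with pytest.raises(ValidationError):
            SLMRGParams(n=1, nm=50, a=0, b=0, w=float("nan"))


class TestEnergeticParameter:
    def test_zero_energy_gives_cs(self):
        d = EnergeticDecomposition(cs=100.0, ea=0.0, temperature=293.0)
        assert energetic_parameter(d) == pytest.approx(100.0)

    def test_analytic_decade(self):
        ea = 8.314 * 293.0 * math.log(10.0)
        d = EnergeticDecomposition(cs=100.0, ea=ea, temperature=293.0)
        assert energetic_parameter(d) == pytest.approx(10.0, rel=1e-12)

    def test_adsorption_energy_of_fitted_w(self):
        # 8.314 * 293 * ln(100/9.283), hand arithmetic
        assert adsorption_energy(9.283, 100.0, 293.0) == pytest.approx(5790.3, abs=0.5)

    def test_negative_energy_warned_not_rejected(self):
        with pytest.warns(UserWarning, match="negative"):
            ea = adsorption_energy(150.0, 100.0, 293.0)
        assert ea < 0

    @given(
        cs=st.floats(1.0, 1e4),
        ea=st.floats(-2e4, 5e4),
        t=st.floats(250.0, 400.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_identity(self, cs, ea, t):
        w = energetic_parameter(EnergeticDecomposition(cs=cs, ea=ea, temperature=t))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = adsorption_energy(w, cs, t)
        assert back == pytest.approx(ea, rel=1e-10, abs=1e-6)


class TestKineticForwardModels:
    def test_pso_half_saturation(self):
        p = PSOParams(qe=40.0, k2=0.001)
        assert pso_capacity(1.0 / (0.001 * 40.0), p) == pytest.approx(20.0, rel=1e-14)

    def test_pfo_hand_value(self):
        p = PFOParams(qe=40.0, k1=0.01)
        assert pfo_capacity(100.0, p) == pytest.approx(25.28482235314231, rel=1e-12)

    def test_ipd_line(self):
        assert ipd_capacity(25.0, IPDParams(kid=2.0, c=5.0)) == pytest.approx(15.0)

    def test_boundary_conditions(self):
        pfo = PFOParams(qe=40.0, k1=0.01)
        pso = PSOParams(qe=40.0, k2=0.001)
        assert pfo_capacity(0.0, pfo) == 0.0
        assert pso_capacity(0.0, pso) == 0.0
        assert ipd_capacity(0.0, IPDParams(kid=2.0, c=5.0)) == 5.0
        t = np.geomspace(1, 500, 50)
        assert np.all(np.diff(pfo_capacity(t, pfo)) > 0)
        assert np.all(np.diff(pso_capacity(t, pso)) > 0)
        assert pfo_capacity(1e9, pfo) == pytest.approx(40.0)
        assert pso_capacity(1e9, pso) == pytest.approx(40.0, rel=1e-6)

    def test_pfo_pso_agree_to_first_order_at_small_t(self):
        # with qe*k1 = qe^2*k2 both initial rates coincide
        qe, k1 = 40.0, 0.01
        k2 = k1 / qe
        t = 1e-7
        ratio = pfo_capacity(t, PFOParams(qe, k1)) / pso_capacity(t, PSOParams(qe, k2))
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            pfo_capacity(-1.0, PFOParams(qe=40.0, k1=0.01))


class TestBatchMassBalance:
    def test_printed_efficiency(self):
        # qe = 39.77 mg/g at C0 = 50 mg/L and dose 1 g/L
        cond = BatchConditions(c0=50.0, volume=0.02, mass=0.02)
        assert removal_efficiency(39.77, cond) == pytest.approx(79.54, abs=1e-10)

    def test_no_uptake(self):
        cond = BatchConditions(c0=50.0, volume=0.02, mass=0.02)
        assert batch_capacity(50.0, cond) == 0.0
        assert removal_efficiency(0.0, cond) == 0.0

    def test_mass_balance_inversion(self):
        cond = BatchConditions(c0=50.0, volume=0.02, mass=0.02)
        qe = batch_capacity(10.23, cond)
        assert qe == pytest.approx(39.77, rel=1e-12)

    def test_ce_above_c0_rejected(self):
        cond = BatchConditions(c0=50.0, volume=0.02, mass=0.02)
        with pytest.raises(ValidationError, match="exceeds"):
            batch_capacity(60.0, cond)
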