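"""Parameter estimation: linearizations, nonlinear recovery, segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosorb import (
    DomainError,
    FitOptions,
    GeneratorSpec,
    IPDParams,
    KineticTrace,
    PFOParams,
    PSOParams,
    SLMRGParams,
    fit_ipd_segments,
    fit_kinetics_nonlinear,
    fit_pfo_linear,
    fit_pso_linear,
    fit_slmrg,
    gen_ipd_three_regime,
    gen_isotherm,
    gen_kinetics,
    goodness,
    ipd_capacity,
    pfo_capacity,
    pso_capacity,
)
from biosorb.fitting import SLMRG
from conftest import TABLE1


class TestGoodness:
    def test_perfect_fit(self):
        r2, rmse = goodness([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_params=1)
        assert (r2, rmse) == (1.0, 0.0)

    def test_hand_example(self):
        r2, rmse = goodness([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], n_params=1)
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(math.sqrt(1.0 / 3.0))

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = goodness(obs, np.full(4, obs.mean()), n_params=1)
        assert r2 == pytest.approx(0.0)

    def test_constant_observed_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r2, rmse = goodness([2.0, 2.0, 2.0], [2.0, 2.1, 1.9], n_params=1)
        assert math.isnan(r2) and rmse > 0

    @given(
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_r2_invariant_under_affine_unit_change(self, scale, shift):
        obs = np.array([1.0, 2.5, 3.0, 4.5, 6.0])
        pred = np.array([1.2, 2.2, 3.3, 4.4, 5.8])
        r2_raw, _ = goodness(obs, pred, n_params=2)
        r2_scaled, _ = goodness(scale * obs + shift, scale * pred + shift, n_params=2)
        assert r2_scaled == pytest.approx(r2_raw, rel=1e-9)


class TestKineticLinearizations:
    def test_pso_linearization_is_lossless(self):
        p = PSOParams(qe=40.0, k2=0.001)
        t = np.array([5.0, 15, 30, 60, 120, 240, 480])
        trace = KineticTrace(t=t, qt=pso_capacity(t, p))
        res = fit_pso_linear(trace)
        assert res.params.qe == pytest.approx(40.0, rel=1e-10)
        assert res.params.k2 == pytest.approx(0.001, rel=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        # slope 1/qe = 0.025, intercept 1/(k2 qe^2) = 0.625
        y = trace.t / trace.qt
        slope = np.polyfit(trace.t, y, 1)[0]
        assert slope == pytest.approx(0.025, rel=1e-10)

    def test_pfo_linearization_slope(self):
        p = PFOParams(qe=40.0, k1=0.0115)
        t = np.linspace(5, 300, 12)
        trace = KineticTrace(t=t, qt=pfo_capacity(t, p))
        res = fit_pfo_linear(trace, qe_exp=40.0)
        assert res.params.k1 == pytest.approx(0.0115, rel=1e-10)
        assert res.params.qe == pytest.approx(40.0, rel=1e-10)
        y = np.log10(40.0 - trace.qt)
        slope = np.polyfit(trace.t, y, 1)[0]
        assert slope == pytest.approx(-0.0115 / math.log(10.0), rel=1e-10)

    def test_pfo_requires_plateau_above_trace(self):
        trace = KineticTrace(t=[1.0, 2, 3, 4], qt=[5.0, 10, 20, 41])
        with pytest.raises(DomainError, match="index 3"):
            fit_pfo_linear(trace, qe_exp=40.0)

    def test_pso_constant_trace_flagged_degenerate(self):
        trace = KineticTrace(t=[1.0, 2, 3, 4], qt=[20.0, 20, 20, 20])
        res = fit_pso_linear(trace)
        assert res.params.qe == pytest.approx(20.0)
        assert any("degenerate" in note for note in res.notes)


class TestNonlinearKinetics:
    @pytest.mark.parametrize("model,params", [
        ("pfo", PFOParams(qe=39.77, k1=0.012)),
        ("pso", PSOParams(qe=47.2, k2=3.5e-4)),
    ])
    def test_noiseless_recovery(self, model, params):
        trace = gen_kinetics(model, params, GeneratorSpec(seed=0))
        res = fit_kinetics_nonlinear(model, trace, FitOptions(n_starts=8, seed=0))
        for name, true in vars(params).items():
            assert getattr(res.params, name) == pytest.approx(true, rel=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_linearization_on_noiseless_pso(self):
        params = PSOParams(qe=40.0, k2=0.001)
        trace = gen_kinetics("pso", params, GeneratorSpec(seed=0))
        lin = fit_pso_linear(trace)
        non = fit_kinetics_nonlinear("pso", trace, FitOptions(n_starts=8, seed=0))
        assert non.params.qe == pytest.approx(lin.params.qe, rel=1e-6)
        assert non.params.k2 == pytest.approx(lin.params.k2, rel=1e-6)

    def test_noisy_fit_sanity(self):
        params = PSOParams(qe=40.0, k2=0.001)
        spec = GeneratorSpec(seed=3, noise_model="multiplicative-gaussian", noise_sd=0.05)
        trace = gen_kinetics("pso", params, spec)
        res = fit_kinetics_nonlinear("pso", trace, FitOptions(n_starts=8, seed=0))
        assert 0.0 < res.r2 < 1.0
        assert res.rmse > 0.0


class TestIpdSegments:
    def test_single_exact_line(self):
        t = np.linspace(1, 100, 9)
        trace = KineticTrace(t=t, qt=ipd_capacity(t, IPDParams(kid=2.0, c=5.0)))
        seg = fit_ipd_segments(trace, n_segments=1)
        assert seg.segments[0].kid == pytest.approx(2.0, rel=1e-10)
        assert seg.segments[0].c == pytest.approx(5.0, rel=1e-10)
        assert seg.breakpoints == ()

    def test_three_regime_breakpoints_recovered(self):
        segments = (
            IPDParams(kid=4.0, c=0.0),
            IPDParams(kid=1.2, c=18.0),
            IPDParams(kid=0.05, c=38.0),
        )
        trace = gen_ipd_three_regime(segments, breakpoints=(40.0, 200.0),
                                     n_per_segment=5)
        seg = fit_ipd_segments(trace, n_segments=3)
        assert seg.breakpoints == (5, 10)
        assert seg.sse == pytest.approx(0.0, abs=1e-16)
        for fitted, true in zip(seg.segments, segments):
            assert fitted.kid == pytest.approx(true.kid, rel=1e-8, abs=1e-10)
            assert fitted.c == pytest.approx(true.c, rel=1e-8, abs=1e-8)

    def test_flat_plateau_final_segment(self):
        segments = (
            IPDParams(kid=4.0, c=0.0),
            IPDParams(kid=1.2, c=18.0),
            IPDParams(kid=0.0, c=40.0),
        )
        trace = gen_ipd_three_regime(segments, breakpoints=(40.0, 200.0))
        seg = fit_ipd_segments(trace, n_segments=3)
        assert seg.segments[2].kid == pytest.approx(0.0, abs=1e-10)

    def test_origin_flag(self):
        t = np.linspace(1, 100, 9)
        through = KineticTrace(t=t, qt=ipd_capacity(t, IPDParams(kid=2.0, c=0.0)))
        away = KineticTrace(t=t, qt=ipd_capacity(t, IPDParams(kid=2.0, c=5.0)))
        assert fit_ipd_segments(through, 1).through_origin
        assert not fit_ipd_segments(away, 1).through_origin

    def test_too_few_points_rejected(self):
        trace = KineticTrace(t=[1.0, 2, 3, 4, 5, 6], qt=[1.0, 2, 3, 4, 5, 6])
        with pytest.raises(Exception, match="segments"):
            fit_ipd_segments(trace, n_segments=3)


class TestSlmrgFit:
    def test_noiseless_recovery_owp(self, owp_293_params, ce_grid_owp):
        data = gen_isotherm(owp_293_params, 293.0, GeneratorSpec(grid=ce_grid_owp))
        res = fit_slmrg(data, FitOptions(n_starts=32, seed=1))
        for name in ("n", "nm", "a", "b", "w"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(owp_293_params, name), rel=0.01
            )
        assert res.r2 == pytest.approx(1.0, abs=1e-8)
        assert res.rmse == pytest.approx(0.0, abs=1e-8)

    def test_objective_no_worse_than_truth_on_noisy_data(self, owp_293_params, ce_grid_owp):
        spec = GeneratorSpec(seed=11, noise_model="multiplicative-gaussian",
                             noise_sd=0.02, grid=ce_grid_owp)
        data = gen_isotherm(owp_293_params, 293.0, spec)
        model = SLMRG(data)
        res = model.fit(FitOptions(n_starts=32, seed=1))
        sse_fit = float(np.sum((model.predict(res.params) - data.qe) ** 2))
        sse_true = float(np.sum((model.predict(owp_293_params) - data.qe) ** 2))
        assert sse_fit <= sse_true + 1e-12

    def test_summary_reports_qsat(self, owp_293_params, ce_grid_owp):
        data = gen_isotherm(owp_293_params, 293.0, GeneratorSpec(grid=ce_grid_owp))
        res = fit_slmrg(data, FitOptions(n_starts=8, seed=1))
        text = res.summary()
        assert "Qsat" in text and "R^2" in text

    def test_requires_six_points(self):
        params = SLMRGParams(**TABLE1[("OWP", 293)])
        data = gen_isotherm(params, 293.0, GeneratorSpec(grid=np.array([1.0, 5, 10, 20, 50])))
        with pytest.raises(Exception, match="at least 6"):
            fit_slmrg(data)
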