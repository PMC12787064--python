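"""Parameter recovery: Phi-order fits, quantum yield, k_bim extraction,
numeric fitting for the schemes without closed forms."""

import numpy as np
import pytest

from phikin.analytic import (
    phi_order_absorbance,
    rate_constant_scheme_a,
    rate_constant_scheme_b,
)
from phikin.core import LN10, SchemeSpec
from phikin.inference import (
    compare_classical_models,
    extract_kbim,
    fit_numeric_kbim,
    fit_phi_order,
    initial_rate_from_fit,
    quantum_yield_from_initial_rate,
)
from phikin.numeric import KineticTrace, OdeSystem, integrate
from phikin.synthdata import NoiseModel, generate_trace

from conftest import DEMO, make_setup, make_species, scheme_a_for


def analytic_trace(a0=0.5, kr=1e-3, n=50, sigma=0.0, seed=0):
    scheme, species, setup = scheme_a_for(a0, kr)
    t = np.linspace(0.0, 5.0 / kr, n)
    noise = NoiseModel(sigma=sigma, seed=seed) if sigma else None
    return generate_trace(scheme, species, setup, t, noise=noise)


class TestFitPhiOrder:
    def test_noiseless_recovery_is_exact(self):
        trace = analytic_trace()
        fit = fit_phi_order(trace)
        assert fit.converged
        assert fit.param("kr") == pytest.approx(1e-3, rel=1e-10)

    def test_noisy_recovery_within_two_percent(self):
        trace = analytic_trace(sigma=0.002, seed=42)
        fit = fit_phi_order(trace)
        assert fit.param("kr") == pytest.approx(1e-3, rel=0.02)
        assert fit.stderr("kr") > 0

    def test_free_a0_recovers_both_parameters(self):
        trace = analytic_trace()
        fit = fit_phi_order(trace, fix_a0=False)
        assert fit.param("kr") == pytest.approx(1e-3, rel=1e-8)
        assert fit.param("A0") == pytest.approx(0.5, rel=1e-8)

    def test_constant_trace_flagged_non_photoreactive(self):
        t = np.linspace(0.0, 100.0, 20)
        trace = KineticTrace(
            t=t,
            concentrations={"X": np.full_like(t, 1e-5)},
            absorbance=np.full_like(t, 0.5),
            metadata={"reactant": "X"},
        )
        fit = fit_phi_order(trace)
        assert any("non_photoreactive" in n for n in fit.notes)
        assert fit.param("kr") * 100.0 < 1e-6

    def test_too_few_points_rejected(self):
        trace = analytic_trace(n=50)
        short = KineticTrace(
            t=trace.t[:3],
            concentrations={k: v[:3] for k, v in trace.concentrations.items()},
            absorbance=trace.absorbance[:3],
            metadata=trace.metadata,
        )
        with pytest.raises(ValueError, match="insufficient points"):
            fit_phi_order(short)


class TestInitialRateAndQuantumYield:
    def test_zero_rate_constant_gives_zero_rate(self):
        trace = analytic_trace()
        fit = fit_phi_order(trace)
        fit.params["kr"]["value"] = 0.0
        assert initial_rate_from_fit(fit, epsilon_x_l_irr=6201.46) == 0.0

    def test_reference_initial_rate(self):
        # direct evaluation: -kr (1 - 10^-A0) / (ln10 eps l)
        trace = analytic_trace()
        fit = fit_phi_order(trace)
        fit.params["kr"]["value"] = 9.082e-6
        fit.params["A0"] = {"value": 0.05, "stderr": None}
        r0 = initial_rate_from_fit(fit, epsilon_x_l_irr=6201.5)
        assert r0 == pytest.approx(-6.916e-11, rel=1e-3)

    def test_high_absorbance_rate_cap(self):
        trace = analytic_trace()
        fit = fit_phi_order(trace)
        kr = fit.param("kr")
        r0 = initial_rate_from_fit(fit, epsilon_x_l_irr=6201.5, a0=50.0)
        assert r0 == pytest.approx(-kr / (LN10 * 6201.5), rel=1e-12)

    def test_quantum_yield_reference_value(self):
        phi = quantum_yield_from_initial_rate(-1e-9, p0=1e-6, a0=0.05)
        assert phi == pytest.approx(9.196e-3, rel=1e-3)

    def test_quantum_yield_zero_rate(self):
        assert quantum_yield_from_initial_rate(0.0, p0=1e-6, a0=0.5) == 0.0

    def test_quantum_yield_undefined_without_absorption(self):
        with pytest.raises(ValueError):
            quantum_yield_from_initial_rate(-1e-9, p0=1e-6, a0=0.0)

    def test_round_trip_quantum_yield_from_photolysis_trace(self):
        # unimolecular photolysis (no bimolecular channel): simulate, fit,
        # differentiate at t=0, invert the initial-rate relation
        setup = make_setup()
        species = make_species("b", DEMO["C_X0"], DEMO["C_Xp0"], DEMO["eps_X"])
        scheme = SchemeSpec("b", k_bim=0.0, phi_direct=DEMO["phi"])
        kr = rate_constant_scheme_b(0.0, DEMO["C_Xp0"], DEMO["phi"], setup, DEMO["eps_X"])
        t = np.linspace(0.0, 5.0 / kr, 60)
        trace = integrate(OdeSystem(scheme, species, setup), t)
        fit = fit_phi_order(trace)
        eps_l = DEMO["eps_X"] * DEMO["l_irr"]
        r0 = initial_rate_from_fit(fit, epsilon_x_l_irr=eps_l)
        phi = quantum_yield_from_initial_rate(r0, p0=setup.P0, a0=fit.param("A0"))
        assert phi == pytest.approx(DEMO["phi"], abs=1e-6)


class TestExtractKbim:
    def test_round_trip_scheme_a(self):
        setup = make_setup()
        kr = rate_constant_scheme_a(DEMO["k_bim"], DEMO["C_Xp0"], setup, DEMO["eps_X"])
        k = extract_kbim(kr, SchemeSpec("a", k_bim=0.0), DEMO["C_Xp0"], setup, DEMO["eps_X"])
        assert k == pytest.approx(DEMO["k_bim"], rel=1e-14)

    def test_reference_inversion(self):
        setup = make_setup()
        k = extract_kbim(3.7869e-8, SchemeSpec("a"), DEMO["C_Xp0"], setup, DEMO["eps_X"])
        assert k == pytest.approx(1.7e-2, rel=1e-3)

    def test_scheme_b_full_photolysis_budget_gives_zero(self):
        setup = make_setup()
        kr = rate_constant_scheme_b(0.0, DEMO["C_Xp0"], DEMO["phi"], setup, DEMO["eps_X"])
        scheme = SchemeSpec("b", k_bim=0.0, phi_direct=DEMO["phi"])
        k = extract_kbim(kr, scheme, DEMO["C_Xp0"], setup, DEMO["eps_X"], phi=DEMO["phi"])
        # zero up to the round-off of the forward/inverse float arithmetic
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_quantum_yield_rejected(self):
        setup = make_setup()
        kr = rate_constant_scheme_b(0.0, DEMO["C_Xp0"], DEMO["phi"], setup, DEMO["eps_X"])
        scheme = SchemeSpec("b", k_bim=0.0, phi_direct=DEMO["phi"])
        with pytest.raises(ValueError, match="inconsistent"):
            extract_kbim(kr * 0.5, scheme, DEMO["C_Xp0"], setup, DEMO["eps_X"], phi=DEMO["phi"])


class TestFitNumericKbim:
    def test_scheme_c_noiseless_recovery(self, fast_scheme_c):
        scheme, species, setup = fast_scheme_c
        t = np.linspace(0.0, 1.5e4, 30)
        trace = integrate(OdeSystem(scheme, species, setup), t)
        fit = fit_numeric_kbim(
            trace, "c", species, setup, phi=scheme.phi_direct, bounds=(0.0, 20.0)
        )
        assert fit.converged
        assert fit.param("k_bim") == pytest.approx(scheme.k_bim, rel=0.01)

    def test_reactant_only_trace_is_unidentifiable(self, fast_scheme_c):
        scheme, species, setup = fast_scheme_c
        t = np.linspace(0.0, 1.5e4, 30)
        full = integrate(OdeSystem(scheme, species, setup), t)
        x_only = KineticTrace(
            t=t,
            concentrations={"X": full.species("X")},
            metadata={k: v for k, v in full.metadata.items() if k != "role_names"},
        )
        fit = fit_numeric_kbim(
            x_only, "c", species, setup, phi=scheme.phi_direct, bounds=(0.0, 20.0)
        )
        assert not fit.converged
        assert any("unidentifiable" in n or "flat_objective" in n for n in fit.notes)

    def test_scheme_d_noisy_recovery(self):
        setup = make_setup(P0=1e-6, l_irr=1.0)
        eps, k_bim = 5000.0, 50.0
        c0 = 0.5 / eps
        species = make_species("d", C_X0=c0, eps_X=eps)
        scheme = SchemeSpec("d", k_bim=k_bim)
        t = np.linspace(0.0, 1.5e5, 40)
        noise = NoiseModel(kind="additive_gaussian_concentration", sigma=0.01 * c0, seed=7)
        trace = generate_trace(scheme, species, setup, t, noise=noise)
        fit = fit_numeric_kbim(trace, "d", species, setup, bounds=(0.0, 500.0))
        assert fit.param("k_bim") == pytest.approx(k_bim, rel=0.05)


class TestCompareClassicalModels:
    def test_first_order_limit_mono_exponential_competitive(self):
        trace = analytic_trace(a0=0.005, kr=1e-3, n=60)
        ranked = {r.model: r.rss for r in compare_classical_models(trace)}
        scale = np.sum(trace.species("X") ** 2)
        # both residuals are tiny relative to the signal in the limit regime
        assert ranked["mono_exponential"] < 1e-4 * scale
        assert ranked["phi_order"] <= ranked["mono_exponential"]

    def test_zeroth_order_limit_linear_competitive(self):
        a0, kr = 2.5, 1e-3
        scheme, species, setup = scheme_a_for(a0, kr)
        # early window: first ~10% of the decay
        t = np.linspace(0.0, 0.25 * LN10 / kr, 40)
        trace = generate_trace(scheme, species, setup, t)
        ranked = {r.model: r.rss for r in compare_classical_models(trace)}
        scale = np.sum(trace.species("X") ** 2)
        assert ranked["zeroth_order_linear"] < 1e-4 * scale
        assert ranked["phi_order"] <= 10 * ranked["zeroth_order_linear"]

    def test_scheme_d_defeats_all_models(self):
        # dimerisation kinetics fit neither classical nor Phi-order forms
        setup = make_setup(P0=1e-6, l_irr=1.0)
        eps = 5000.0
        c0 = 0.5 / eps
        species = make_species("d", C_X0=c0, eps_X=eps)
        scheme = SchemeSpec("d", k_bim=50.0)
        t = np.linspace(0.0, 3e5, 60)
        trace = integrate(OdeSystem(scheme, species, setup), t)
        results = {r.model: r for r in compare_classical_models(trace)}
        floor = max(trace.metadata["step_halving_error"], np.finfo(float).eps) * c0
        for model in ("mono_exponential", "reciprocal_second_order", "phi_order"):
            rms = np.sqrt(results[model].rss / trace.n_points)
            assert rms > 1e3 * floor
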