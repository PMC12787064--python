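"""Fitting kinetic traces: Phi-order, classical comparators, numeric k_bim.

The quantification workflow mirrors the analytical structure of the rate
laws: for schemes with a closed form the trace is fitted with the Phi-order
law (a single-parameter fit once the initial absorbance is pinned to the
first observation), and the thermal rate constant or quantum yield is
recovered by inverting the rate-constant formula.  For schemes without a
closed form (c, d) the trace is fitted by repeated RK4 integration with
k_bim as the only unknown, a bounded scalar optimisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .analytic import phi_order_absorbance
from .core import (
    LN10,
    ROLE_PRODUCT_YPRIME,
    ROLE_PRODUCT_YTPRIME,
    ROLE_REACTANT,
    IrradiationSetup,
    SchemeSpec,
    SpeciesTable,
)
from .numeric import KineticTrace, OdeSystem, integrate

__all__ = [
    "FitResult",
    "fit_phi_order",
    "initial_rate_from_fit",
    "quantum_yield_from_initial_rate",
    "extract_kbim",
    "fit_numeric_kbim",
    "compare_classical_models",
]

MIN_FIT_POINTS = 5


@dataclass
class FitResult:
    """Outcome of one model fit.

    ``params`` maps parameter name -> {"value": ..., "stderr": ...} with the
    standard error from the Gauss-Newton covariance approximation at the
    optimum (approximate; documented as such).
    """

    model: str
    params: dict[str, dict[str, float | None]]
    rss: float
    residuals: np.ndarray
    n_points: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def param(self, name: str) -> float:
        return float(self.params[name]["value"])

    def stderr(self, name: str) -> float | None:
        se = self.params[name]["stderr"]
        return None if se is None else float(se)

    def to_json(self, **extra) -> str:
        payload = {
            "model": self.model,
            "params": {
                k: {kk: (None if vv is None else float(vv)) for kk, vv in v.items()}
                for k, v in self.params.items()
            },
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "notes": list(self.notes),
        }
        payload.update(extra)
        return json.dumps(payload, indent=2, sort_keys=True)


def _gn_stderr(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    """Gauss-Newton parameter standard errors at the optimum."""
    dof = max(n - p, 1)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _trace_absorbance(trace: KineticTrace) -> np.ndarray:
    if trace.absorbance is not None:
        return np.asarray(trace.absorbance, dtype=float)
    eps = trace.metadata.get("epsilon_x")
    l_irr = trace.metadata.get("l_irr")
    reactant = trace.metadata.get("reactant")
    if eps and l_irr and reactant in trace.concentrations:
        return eps * l_irr * trace.species(reactant)
    raise ValueError(
        "trace carries no absorbance and no (epsilon_x, l_irr, reactant) "
        "metadata to convert concentrations"
    )


def fit_phi_order(trace: KineticTrace, fix_a0: bool = True) -> FitResult:
    """Nonlinear least-squares fit of the Phi-order law to a trace.

    By default the initial absorbance is fixed to the first observation so
    kr is the unique fitting parameter; pass ``fix_a0=False`` to free it.
    The starting value for kr comes from the exact linearisation of the
    integrated law — ln(10^A - 1) is linear in t with slope -kr — which is a
    convergence-safe initialisation.

    Unweighted least squares on absorbance (spectrophotometric noise is
    approximately homoscedastic in absorbance units).
    """
    if trace.n_points < MIN_FIT_POINTS:
        raise ValueError(
            f"insufficient points for fitting (need >= {MIN_FIT_POINTS}, got {trace.n_points})"
        )
    t = trace.t
    a = _trace_absorbance(trace)
    a0_obs = float(a[0])
    notes: list[str] = []

    span = float(t[-1] - t[0]) if t.size > 1 else 1.0
    # exact linearisation: z = ln(10^A - 1) = z0 - kr t
    with np.errstate(over="ignore"):
        z_arg = np.expm1(a * LN10)
    mask = z_arg > 0
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(z_arg[mask]), 1)[0]
        kr0 = max(-slope, 0.0)
    else:
        kr0 = 0.0
    if kr0 == 0.0:
        kr0 = 1.0 / span  # flat or pathological trace; give the optimiser a scale

    if fix_a0:

        def resid(theta):
            return phi_order_absorbance(t, a0_obs, theta[0]) - a

        x0, lower = [kr0], [0.0]
        names = ["kr"]
    else:

        def resid(theta):
            return phi_order_absorbance(t, theta[1], theta[0]) - a

        x0, lower = [kr0, max(a0_obs, 1e-6)], [0.0, 0.0]
        names = ["kr", "A0"]

    sol = least_squares(resid, x0=x0, bounds=(lower, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(np.sum(sol.fun**2))
    stderr = _gn_stderr(sol.jac, rss, t.size, len(names))
    params = {nm: {"value": float(v), "stderr": float(se)} for nm, v, se in zip(names, sol.x, stderr)}
    if fix_a0:
        params["A0"] = {"value": a0_obs, "stderr": None}

    kr_hat = params["kr"]["value"]
    if kr_hat * span < 1e-6:
        notes.append("non_photoreactive: no measurable decay over the trace window")
    return FitResult(
        model="phi_order",
        params=params,
        rss=rss,
        residuals=sol.fun,
        n_points=t.size,
        converged=bool(sol.success),
        notes=notes,
    )


def initial_rate_from_fit(
    fit: FitResult,
    epsilon_x_l_irr: float,
    a0: float | None = None,
) -> float:
    """Initial reactant rate r0 (M s^-1) implied by a Phi-order fit.

    Differentiating the fitted law at t = 0 and converting absorbance to
    concentration: r0 = -kr * (1 - 10^-A0) / (ln 10 * eps_X * l_irr).
    Negative for a depleting reactant.
    """
    if epsilon_x_l_irr is None or epsilon_x_l_irr <= 0:
        raise ValueError("epsilon_x * l_irr must be > 0")
    a0 = fit.param("A0") if a0 is None else a0
    kr = fit.param("kr")
    return -kr * (-math.expm1(-LN10 * a0)) / (LN10 * epsilon_x_l_irr)


def quantum_yield_from_initial_rate(r0: float, p0: float, a0: float) -> float:
    """Quantum yield from the fitted initial rate: Phi = -r0 / (P0 (1 - 10^-A0)).

    Valid for a unimolecular photolysis trace (k_bim = 0) acquired under the
    same irradiation conditions; undefined at A0 = 0 (no absorption).
    """
    if p0 <= 0:
        raise ValueError("P0 must be > 0")
    if a0 <= 0:
        raise ValueError("quantum yield undefined from this route at A0 = 0")
    return -r0 / (p0 * (-math.expm1(-LN10 * a0)))


def extract_kbim(
    kr: float,
    scheme: SchemeSpec,
    c_xprime0: float,
    setup: IrradiationSetup,
    epsilon_x: float,
    phi: float | None = None,
) -> float:
    """Invert the rate-constant formula to recover k_bim from a fitted kr.

    Scheme a: k_bim = kr / (C_X'(0) P0 eps_X l_irr ln10); scheme b subtracts
    the known quantum-yield branch first.  Raises if the quantum yield
    exceeds the total kr budget (negative k_bim flags inconsistent inputs).
    """
    if kr < 0:
        raise ValueError("kr must be >= 0")
    denom = c_xprime0 * setup.P0 * epsilon_x * setup.l_irr * LN10
    if denom <= 0:
        raise ValueError("C_X'(0), P0 and epsilon_x must all be > 0")
    if scheme.scheme_id == "a":
        return kr / denom
    if scheme.scheme_id == "b":
        if phi is None:
            phi = scheme.phi_direct
        k_total = kr / (setup.P0 * epsilon_x * setup.l_irr * LN10)
        k_bim_cxp0 = k_total - phi
        if k_bim_cxp0 < -1e-12 * max(k_total, phi):
            raise ValueError(
                f"inconsistent inputs: quantum yield {phi:g} exceeds the total "
                f"rate-constant budget {k_total:g}"
            )
        return max(k_bim_cxp0, 0.0) / c_xprime0
    raise ValueError(f"k_bim extraction from kr applies to schemes a/b, not {scheme.scheme_id!r}")


def _kbim_sensitive_columns(trace: KineticTrace, scheme_id: str) -> list[str]:
    role_names = trace.metadata.get("role_names", {})
    if scheme_id == "c":
        wanted = [
            role_names.get(ROLE_PRODUCT_YPRIME, "Yprime"),
            role_names.get(ROLE_PRODUCT_YTPRIME, "Ytprime"),
        ]
    else:  # scheme d: every species responds to k_bim
        wanted = list(trace.species_names)
    return [name for name in wanted if name in trace.concentrations]


def fit_numeric_kbim(
    trace: KineticTrace,
    scheme_id: str,
    species: SpeciesTable,
    setup: IrradiationSetup,
    phi: float | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
    rtol: float = 1e-8,
) -> FitResult:
    """Recover k_bim for schemes (c)/(d) by repeated RK4 integration.

    Minimises the residual sum of squares between the trace and the
    integrated rate law over k_bim alone (bounded, derivative-free scalar
    optimisation).  For scheme (c) the photochemical quantum yield must be
    known (it is determined separately from the reactant trace, which
    carries no information on k_bim); the fit then uses the k_bim-sensitive
    intermediate and terminal product columns.

    A trace containing only k_bim-insensitive species yields a
    warning-carrying result, as does a flat objective over the bounds.
    """
    if scheme_id not in ("c", "d"):
        raise ValueError("numeric k_bim fitting applies to schemes c and d")
    if scheme_id == "c" and phi is None:
        raise ValueError("scheme c requires the photochemical quantum yield phi")
    if trace.n_points < MIN_FIT_POINTS:
        raise ValueError(
            f"insufficient points for fitting (need >= {MIN_FIT_POINTS}, got {trace.n_points})"
        )
    lo, hi = bounds
    if not 0 <= lo < hi:
        raise ValueError("bounds must satisfy 0 <= lower < upper")

    columns = _kbim_sensitive_columns(trace, scheme_id)
    notes: list[str] = []
    if not columns:
        notes.append(
            "unidentifiable: trace contains only k_bim-independent species; "
            "k_bim cannot be recovered from this window"
        )
        params = {"k_bim": {"value": float("nan"), "stderr": None}}
        return FitResult("numeric_scheme_" + scheme_id, params, float("nan"),
                         np.array([]), trace.n_points, False, notes)

    data = np.concatenate([trace.species(c) for c in columns])
    phi_val = float(phi) if phi is not None else 0.0

    def simulate(k_bim: float, n_sub=None) -> tuple[np.ndarray, KineticTrace]:
        scheme = SchemeSpec(scheme_id, k_bim=k_bim, phi_direct=phi_val if scheme_id == "c" else 0.0)
        system = OdeSystem(scheme, species, setup, simplified=True)
        sim = integrate(system, trace.t, rtol=rtol, n_sub=n_sub)
        model = np.concatenate([sim.species(c) for c in columns])
        return model, sim

    # fix the discretisation once (at the upper bound, the stiffest case) so
    # the objective is smooth in k_bim
    probe = SchemeSpec(scheme_id, k_bim=hi, phi_direct=phi_val if scheme_id == "c" else 0.0)
    probe_trace = integrate(OdeSystem(probe, species, setup), trace.t, rtol=rtol)
    per_interval = max(probe_trace.metadata["n_steps"] // max(trace.n_points - 1, 1), 1)
    n_sub = np.full(max(trace.n_points - 1, 1), per_interval, dtype=int)

    def objective(k_bim: float) -> float:
        model, _ = simulate(k_bim, n_sub=n_sub)
        return float(np.sum((model - data) ** 2))

    rss_probe = [objective(lo), objective(0.5 * (lo + hi)), objective(hi)]
    spread = max(rss_probe) - min(rss_probe)
    if spread <= 1e-12 * max(max(rss_probe), 1e-300):
        notes.append("flat_objective: k_bim is unidentifiable from this trace window")

    sol = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": max(1e-10, 1e-8 * hi)})
    k_hat = float(sol.x)
    rss = float(sol.fun)
    model, _ = simulate(k_hat, n_sub=n_sub)
    residuals = model - data

    # Gauss-Newton stderr via a finite-difference sensitivity
    dk = max(1e-6 * max(k_hat, hi * 1e-3), 1e-12)
    model_hi, _ = simulate(k_hat + dk, n_sub=n_sub)
    jac = ((model_hi - model) / dk)[:, None]
    stderr = _gn_stderr(jac, rss, data.size, 1)[0]

    params = {"k_bim": {"value": k_hat, "stderr": float(stderr)}}
    return FitResult(
        model="numeric_scheme_" + scheme_id,
        params=params,
        rss=rss,
        residuals=residuals,
        n_points=trace.n_points,
        converged=bool(sol.success) and "flat_objective" not in "".join(notes),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# classical comparator models
# ---------------------------------------------------------------------------


def _fit_scalar(model, t, c, k0: float, name: str) -> FitResult:
    def resid(theta):
        return model(t, theta[0]) - c

    sol = least_squares(resid, x0=[max(k0, 1e-300)], bounds=([0.0], [np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(np.sum(sol.fun**2))
    stderr = _gn_stderr(sol.jac, rss, t.size, 1)[0]
    return FitResult(
        model=name,
        params={"k": {"value": float(sol.x[0]), "stderr": float(stderr)}},
        rss=rss,
        residuals=sol.fun,
        n_points=t.size,
        converged=bool(sol.success),
    )


def compare_classical_models(trace: KineticTrace, species: str | None = None) -> list[FitResult]:
    """Fit the classical comparator models and the Phi-order form to one
    species' concentration trace and rank them by residual sum of squares.

    Models: mono-exponential C0 e^(-kt) (first order), reciprocal
    C0/(1 + k C0 t) (thermal second order), zeroth-order linear C0 - k t,
    and the Phi-order form (kr and effective A0 free).  C0 is pinned to the
    first observation throughout.  Purely diagnostic: no model is declared
    "true", the ranking shows which functional families the data tolerates.
    """
    if trace.n_points < MIN_FIT_POINTS:
        raise ValueError(
            f"insufficient points for fitting (need >= {MIN_FIT_POINTS}, got {trace.n_points})"
        )
    name = species or trace.metadata.get("reactant") or trace.species_names[0]
    c = trace.species(name)
    t = trace.t
    c0 = float(c[0])
    if c0 <= 0:
        raise ValueError("first observation must be positive")

    # crude inverse-timescale guesses
    span = float(t[-1] - t[0])
    pos = c > 0
    if pos.sum() >= 2:
        k_exp0 = max(-np.polyfit(t[pos], np.log(c[pos]), 1)[0], 1e-3 / span)
    else:
        k_exp0 = 1.0 / span

    results = [
        _fit_scalar(lambda tt, k: c0 * np.exp(-k * tt), t, c, k_exp0, "mono_exponential"),
        _fit_scalar(lambda tt, k: c0 / (1.0 + k * c0 * tt), t, c, k_exp0 / c0,
                    "reciprocal_second_order"),
        _fit_scalar(lambda tt, k: c0 - k * tt, t, c, c0 * k_exp0 / 2, "zeroth_order_linear"),
    ]

    a0_guess = trace.metadata.get("epsilon_x", 0.0) * trace.metadata.get("l_irr", 0.0) * c0
    a0_guess = a0_guess if a0_guess > 0 else 1.0

    def phi_model(theta):
        kr, a0 = theta
        return c0 * phi_order_absorbance(t, a0, kr) / a0 - c

    sol = least_squares(phi_model, x0=[k_exp0, a0_guess],
                        bounds=([0.0, 1e-9], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(np.sum(sol.fun**2))
    stderr = _gn_stderr(sol.jac, rss, t.size, 2)
    results.append(
        FitResult(
            model="phi_order",
            params={
                "kr": {"value": float(sol.x[0]), "stderr": float(stderr[0])},
                "A0": {"value": float(sol.x[1]), "stderr": float(stderr[1])},
            },
            rss=rss,
            residuals=sol.fun,
            n_points=t.size,
            converged=bool(sol.success),
        )
    )
    return sorted(results, key=lambda r: r.rss)
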