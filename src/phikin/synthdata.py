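"""Synthetic kinetic traces with seeded noise, and solvability-condition audits.

The generator stands in for experimental absorbance/concentration traces
acquired under continuous monochromatic irradiation: the model trace
(analytic for schemes a/b, RK4 for c/d) plus additive Gaussian measurement
noise.  Noise is applied in the absorbance domain by default
(spectrophotometer-like, approximately homoscedastic in AU); a
concentration-domain variant emulates HPLC-style monitoring.  Negative
noisy values are kept, not clipped, so that fitting sees realistic noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .analytic import (
    PhiOrderParams,
    phi_order_absorbance,
    product_Y_trace,
    product_Yprime_trace,
    rate_constant_scheme_a,
    rate_constant_scheme_b,
)
from .core import (
    ROLE_COREACTANT,
    ROLE_PRODUCT_Y,
    ROLE_PRODUCT_YPRIME,
    ROLE_REACTANT,
    IrradiationSetup,
    SchemeSpec,
    Species,
    SpeciesTable,
)
from .numeric import KineticTrace, OdeSystem, integrate

__all__ = [
    "NoiseModel",
    "ConditionReport",
    "generate_trace",
    "check_conditions",
    "validity_sweep",
    "COREACTANT_EXCESS_RATIO",
    "DEFAULT_LLR_CEILING",
]

#: Excess-co-reactant validity gate: C_X(0) / C_X'(0) must not exceed this.
COREACTANT_EXCESS_RATIO = 0.10

#: Default Beer-Lambert linearity ceiling (decadic absorbance units).
DEFAULT_LLR_CEILING = 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise.

    kind: "additive_gaussian_absorbance" (sigma in AU) or
    "additive_gaussian_concentration" (sigma in M); the seed is recorded in
    the trace metadata so regeneration is bit-identical.
    """

    kind: str = "additive_gaussian_absorbance"
    sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "additive_gaussian_absorbance",
            "additive_gaussian_concentration",
        ):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class ConditionReport:
    """Audit of the four closed-form solvability conditions."""

    cond_i_only_X_absorbs: bool
    offending_absorbers: tuple[str, ...]
    cond_ii_monochromatic: bool
    cond_iii_within_LLR: bool
    max_absorbance: float
    llr_ceiling: float
    cond_iv_excess_coreactant: bool
    concentration_ratio: float | None

    @property
    def overall_valid(self) -> bool:
        return (
            self.cond_i_only_X_absorbs
            and self.cond_ii_monochromatic
            and self.cond_iii_within_LLR
            and self.cond_iv_excess_coreactant
        )


def _analytic_trace(
    scheme: SchemeSpec,
    species: SpeciesTable,
    setup: IrradiationSetup,
    t_grid: np.ndarray,
) -> KineticTrace:
    x = species.reactant
    xp = species.coreactant
    if xp is None:
        raise ValueError("schemes a/b require a co-reactant species")
    eps_l = x.epsilon * setup.l_irr
    a0 = eps_l * x.C0
    if scheme.scheme_id == "a":
        kr = rate_constant_scheme_a(scheme.k_bim, xp.C0, setup, x.epsilon)
    else:
        kr = rate_constant_scheme_b(scheme.k_bim, xp.C0, scheme.phi_direct, setup, x.epsilon)
    absorbance = phi_order_absorbance(t_grid, a0, kr)
    c_x = absorbance / eps_l if eps_l > 0 else np.full_like(absorbance, x.C0)
    conc = {x.name: c_x}
    if scheme.scheme_id == "a":
        yp = species.by_role(ROLE_PRODUCT_YPRIME)
        conc[yp.name] = x.C0 - c_x
        conc[xp.name] = xp.C0 - (x.C0 - c_x)
    else:
        params = PhiOrderParams(a0, kr, k_bim_cxp0=scheme.k_bim * xp.C0, phi=scheme.phi_direct)
        y = species.by_role(ROLE_PRODUCT_Y)
        yp = species.by_role(ROLE_PRODUCT_YPRIME)
        conc[y.name] = np.atleast_1d(product_Y_trace(t_grid, params, x.epsilon, setup.l_irr))
        conc[yp.name] = np.atleast_1d(product_Yprime_trace(t_grid, params, x.epsilon, setup.l_irr))
        conc[xp.name] = xp.C0 - conc[yp.name]
    meta = {
        "scheme": scheme.scheme_id,
        "generator": "analytic",
        "kr": kr,
        "k_bim": scheme.k_bim,
        "phi_direct": scheme.phi_direct,
        "P0": setup.P0,
        "l_irr": setup.l_irr,
        "epsilon_x": x.epsilon,
        "c_x0": x.C0,
        "reactant": x.name,
        "absorbance_column": f"A_{x.name}",
        "role_names": {s.role: s.name for s in species},
        "noisy": False,
    }
    return KineticTrace(t=t_grid, concentrations=conc, absorbance=np.atleast_1d(absorbance), metadata=meta)


def generate_trace(
    scheme: SchemeSpec,
    species: SpeciesTable,
    setup: IrradiationSetup,
    t_grid,
    noise: NoiseModel | None = None,
) -> KineticTrace:
    """Generate a (possibly noisy) kinetic trace for any scheme.

    Schemes a/b are evaluated from their closed forms; c/d are integrated
    with RK4.  Solvability conditions are audited and a warning (not an
    error) is emitted when violated.  With a noise model, the same
    (configuration, seed) pair always regenerates the identical trace.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    report = check_conditions(scheme, species, setup)
    if not report.overall_valid and scheme.scheme_id != "d":
        warnings.warn(
            "solvability conditions violated: "
            + _condition_summary(report),
            stacklevel=2,
        )
    if scheme.scheme_id in ("a", "b"):
        trace = _analytic_trace(scheme, species, setup, t_grid)
    else:
        system = OdeSystem(scheme, species, setup, simplified=True)
        trace = integrate(system, t_grid)

    if noise is None or noise.sigma == 0:
        return trace

    rng = np.random.default_rng(noise.seed)
    x = species.reactant
    eps_l = x.epsilon * setup.l_irr
    conc = {k: v.copy() for k, v in trace.concentrations.items()}
    absorbance = None if trace.absorbance is None else trace.absorbance.copy()
    if noise.kind == "additive_gaussian_absorbance":
        if absorbance is None or eps_l <= 0:
            raise ValueError("absorbance-domain noise requires an absorbing reactant")
        absorbance = absorbance + rng.normal(0.0, noise.sigma, size=t_grid.size)
        conc[x.name] = absorbance / eps_l
        n_neg = int(np.count_nonzero(absorbance < 0))
    else:
        n_neg = 0
        for name in conc:
            conc[name] = conc[name] + rng.normal(0.0, noise.sigma, size=t_grid.size)
            n_neg += int(np.count_nonzero(conc[name] < 0))
        n_neg = n_neg // max(len(conc), 1)
        if absorbance is not None and eps_l > 0:
            absorbance = eps_l * conc[x.name]
    if n_neg > 0.10 * t_grid.size:
        warnings.warn(
            f"noise sigma {noise.sigma:g} drives {n_neg}/{t_grid.size} points negative",
            stacklevel=2,
        )
    meta = dict(trace.metadata)
    meta.update(
        generator="synthetic",
        noisy=True,
        noise_kind=noise.kind,
        noise_sigma=noise.sigma,
        seed=noise.seed,
    )
    return KineticTrace(t=t_grid, concentrations=conc, absorbance=absorbance, metadata=meta)


def _condition_summary(report: ConditionReport) -> str:
    parts = []
    if not report.cond_i_only_X_absorbs:
        parts.append(f"(i) other absorbers at lambda_irr: {', '.join(report.offending_absorbers)}")
    if not report.cond_ii_monochromatic:
        parts.append("(ii) irradiation not declared monochromatic/collimated")
    if not report.cond_iii_within_LLR:
        parts.append(
            f"(iii) A_X(0) = {report.max_absorbance:.3g} exceeds LLR ceiling {report.llr_ceiling:g}"
        )
    if not report.cond_iv_excess_coreactant:
        parts.append(
            f"(iv) C_X(0)/C_X'(0) = {report.concentration_ratio:.3g} exceeds "
            f"{COREACTANT_EXCESS_RATIO:g}"
        )
    return "; ".join(parts) or "all conditions hold"


def check_conditions(
    scheme: SchemeSpec,
    species: SpeciesTable,
    setup: IrradiationSetup,
    llr_ceiling: float = DEFAULT_LLR_CEILING,
    monochromatic: bool = True,
) -> ConditionReport:
    """Audit the four conditions under which the closed forms hold.

    (i) only the reactant absorbs at lambda_irr; (ii) monochromatic,
    collimated irradiation (declarative, from the configuration); (iii) the
    reactant's initial absorbance falls within its Beer-Lambert linearity
    range (configurable ceiling); (iv) the co-reactant is in sufficient
    excess, C_X(0) <= 0.10 C_X'(0).  Scheme (d) has no co-reactant, so (iv)
    holds vacuously there.
    """
    x = species.reactant
    offenders = tuple(
        s.name for s in species if s.role != ROLE_REACTANT and s.epsilon > 0
    )
    a0 = x.epsilon * setup.l_irr * x.C0
    xp = species.coreactant
    if xp is not None and xp.C0 > 0:
        ratio = x.C0 / xp.C0
        cond_iv = ratio <= COREACTANT_EXCESS_RATIO
    elif scheme.scheme_id == "d":
        ratio = None
        cond_iv = True
    else:
        ratio = float("inf") if x.C0 > 0 else None
        cond_iv = False
    return ConditionReport(
        cond_i_only_X_absorbs=not offenders,
        offending_absorbers=offenders,
        cond_ii_monochromatic=bool(monochromatic),
        cond_iii_within_LLR=a0 <= llr_ceiling,
        max_absorbance=a0,
        llr_ceiling=llr_ceiling,
        cond_iv_excess_coreactant=cond_iv,
        concentration_ratio=ratio,
    )


def validity_sweep(
    ratios,
    k_bim: float,
    c_xprime0: float,
    setup: IrradiationSetup,
    epsilon_x: float,
    n_points: int = 60,
    horizon: float = 5.0,
) -> list[tuple[float, float]]:
    """Quantify the excess-co-reactant approximation as a function of
    C_X(0)/C_X'(0).

    For each ratio, integrates the full rate law (co-reactant depleting,
    only X absorbing) and compares the reactant trace against the frozen-
    co-reactant closed form; returns (ratio, max relative deviation of C_X,
    relative to C_X(0)) pairs.  Deviations grow monotonically with the
    ratio — the 0.10 gate is where they become material.
    """
    ratios = list(ratios)
    if any(not 0 < r < 1 for r in ratios):
        raise ValueError("ratios must lie in (0, 1)")
    out = []
    kr = k_bim * c_xprime0 * setup.P0 * epsilon_x * setup.l_irr * np.log(10.0)
    if kr <= 0:
        raise ValueError("the sweep needs a non-zero rate constant")
    t_grid = np.linspace(0.0, horizon / kr, n_points)
    scheme = SchemeSpec("a", k_bim=k_bim)
    for r in ratios:
        c_x0 = r * c_xprime0
        table = SpeciesTable(
            (
                Species("X", epsilon_x, c_x0, ROLE_REACTANT),
                Species("Xprime", 0.0, c_xprime0, ROLE_COREACTANT),
                Species("Yprime", 0.0, 0.0, ROLE_PRODUCT_YPRIME),
            )
        )
        general = integrate(OdeSystem(scheme, table, setup, simplified=False), t_grid)
        a0 = epsilon_x * setup.l_irr * c_x0
        analytic_cx = phi_order_absorbance(t_grid, a0, kr) / (epsilon_x * setup.l_irr)
        dev = float(np.max(np.abs(general.species("X") - analytic_cx)) / c_x0)
        out.append((float(r), dev))
    return out
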