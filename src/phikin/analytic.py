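"""Closed-form Phi-order rate laws for schemes (a) and (b), and yield formulas.

Under the four solvability conditions (only X absorbs; monochromatic,
collimated, non-isosbestic irradiation; reactant absorbance within its
Beer-Lambert linearity range; co-reactant in large excess so its
concentration is effectively frozen) the reactant absorbance obeys
"Phi-order kinetics":

    A_X(t) = log10(1 + (10^A0 - 1) * exp(-kr * t))

a decadic logarithm with an exponential argument.  The overall rate constant
kr (s^-1) collects the photochemical and, where present, bimolecular
branches:

    scheme a:  kr = k_bim * C_X'(0) * P0 * eps_X * l_irr * ln 10
    scheme b:  kr = (k_bim * C_X'(0) + Phi) * P0 * eps_X * l_irr * ln 10

The Phi-order trace interpolates between a mono-exponential (first-order)
decay at small A0 and a linear (zeroth-order) decay at large A0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LN10, IrradiationSetup

__all__ = [
    "PhiOrderParams",
    "phi_order_absorbance",
    "rate_constant_scheme_a",
    "rate_constant_scheme_b",
    "pseudo_first_order_rate_constant",
    "product_Y_trace",
    "product_Yprime_trace",
    "product_Y_asymptote",
    "product_Yprime_asymptote",
    "mass_balance_residual",
    "limit_regime",
    "photonic_yield",
]

#: Beyond this value of kr*t the exponential has underflowed; the asymptote
#: is returned exactly instead of evaluating exp().
_EXP_UNDERFLOW = 700.0

#: Default regime-classification thresholds on the initial absorbance.
FIRST_ORDER_A0 = 0.01
ZEROTH_ORDER_A0 = 2.0


@dataclass(frozen=True)
class PhiOrderParams:
    """Parameters of a Phi-order decay, optionally with scheme-b branching.

    Attributes
    ----------
    A0 : float
        Initial reactant absorbance along l_irr (dimensionless decadic).
    kr : float
        Overall Phi-order rate constant (s^-1).
    k_bim_cxp0 : float
        Bimolecular branch strength k_bim * C_X'(0) (dimensionless, scheme b).
    phi : float
        Direct-photolysis quantum yield (dimensionless, scheme b).
    """

    A0: float
    kr: float
    k_bim_cxp0: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValueError("A0 must be >= 0")
        if self.kr < 0:
            raise ValueError("kr must be >= 0")
        if self.k_bim_cxp0 < 0 or self.phi < 0:
            raise ValueError("branching terms must be >= 0")

    @property
    def branching_total(self) -> float:
        return self.k_bim_cxp0 + self.phi

    def absorbance(self, t):
        return phi_order_absorbance(t, self.A0, self.kr)


def _as_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def _maybe_scalar(out, t_in):
    return float(out) if (np.isscalar(t_in) or np.ndim(t_in) == 0) else out


def phi_order_absorbance(t, a0: float, kr: float):
    """Phi-order integrated rate law: A(t) = log10(1 + (10^A0 - 1) e^(-kr t)).

    Strictly decreasing from A0 at t = 0 towards 0; accepts scalar or array
    times.  For kr*t beyond the exponential underflow range the asymptote 0
    is returned exactly.
    """
    if a0 < 0 or kr < 0:
        raise ValueError("a0 and kr must be >= 0")
    t = _as_time(t)
    x = np.minimum(kr * t, _EXP_UNDERFLOW)
    out = np.log10(1.0 + np.expm1(a0 * LN10) * np.exp(-x))
    out = np.where(kr * t > _EXP_UNDERFLOW, 0.0, out)
    return _maybe_scalar(out, t)


def rate_constant_scheme_a(
    k_bim: float,
    c_xprime0: float,
    setup: IrradiationSetup,
    epsilon_x: float,
) -> float:
    """Overall Phi-order rate constant of scheme (a), in s^-1.

    kr = k_bim * C_X'(0) * P0 * eps_X * l_irr * ln 10.
    """
    if min(k_bim, c_xprime0, epsilon_x) < 0:
        raise ValueError("arguments must be >= 0")
    return k_bim * c_xprime0 * setup.P0 * epsilon_x * setup.l_irr * LN10


def rate_constant_scheme_b(
    k_bim: float,
    c_xprime0: float,
    phi: float,
    setup: IrradiationSetup,
    epsilon_x: float,
) -> float:
    """Overall rate constant of scheme (b): both the bimolecular and the
    direct-photolysis channel deplete X.

    kr = (k_bim * C_X'(0) + Phi) * P0 * eps_X * l_irr * ln 10.
    With phi = 0 this is the scheme-(a) constant; with k_bim = 0 it is the
    unimolecular photolysis rate constant.
    """
    if min(k_bim, c_xprime0, phi, epsilon_x) < 0:
        raise ValueError("arguments must be >= 0")
    return (k_bim * c_xprime0 + phi) * setup.P0 * epsilon_x * setup.l_irr * LN10


def pseudo_first_order_rate_constant(
    k_bim: float,
    c_xprime0: float,
    setup: IrradiationSetup,
    epsilon_x: float,
) -> float:
    """Diagnostic pseudo-first-order constant k_bim*C_X'(0)*P0*eps_X*l_irr.

    This is the constant obtained when a mono-exponential is forced onto the
    data; it differs from the Phi-order rate constant by the missing ln 10
    factor and must never be conflated with kr.
    """
    return rate_constant_scheme_a(k_bim, c_xprime0, setup, epsilon_x) / LN10


def _product_trace(t, prefactor_branch, params: PhiOrderParams, epsilon_x, l_irr):
    if epsilon_x * l_irr <= 0:
        raise ValueError("epsilon_x * l_irr must be > 0 to convert absorbance to concentration")
    total = params.branching_total
    if total <= 0:
        raise ValueError("scheme-b branching terms must not both be zero")
    t = _as_time(t)
    ten_neg_a0 = 10.0 ** (-params.A0)
    x = np.minimum(params.kr * t, _EXP_UNDERFLOW)
    inner = ten_neg_a0 + (1.0 - ten_neg_a0) * np.exp(-x)
    out = -(1.0 / (epsilon_x * l_irr)) * (prefactor_branch / total) * np.log10(inner)
    return _maybe_scalar(out, t)


def product_Y_trace(t, params: PhiOrderParams, epsilon_x: float, l_irr: float):
    """Scheme-b photolysis product Y concentration (M).

    C_Y(t) = -(1/(eps_X l_irr)) * Phi/(k_bim C_X'(0) + Phi)
             * log10(10^-A0 + (1 - 10^-A0) e^(-kr t))

    Zero at t = 0, rising monotonically to the branching-ratio asymptote
    C_X(0) * Phi / (k_bim C_X'(0) + Phi).
    """
    return _product_trace(t, params.phi, params, epsilon_x, l_irr)


def product_Yprime_trace(t, params: PhiOrderParams, epsilon_x: float, l_irr: float):
    """Scheme-b bimolecular product Y' concentration (M); the Y formula with
    the quantum yield replaced by k_bim C_X'(0) in the prefactor."""
    return _product_trace(t, params.k_bim_cxp0, params, epsilon_x, l_irr)


def product_Y_asymptote(c_x0: float, params: PhiOrderParams) -> float:
    """Long-time limit of C_Y: C_X(0) * Phi / (k_bim C_X'(0) + Phi)."""
    return c_x0 * params.phi / params.branching_total


def product_Yprime_asymptote(c_x0: float, params: PhiOrderParams) -> float:
    """Long-time limit of C_Y': C_X(0) * k_bim C_X'(0) / (k_bim C_X'(0) + Phi)."""
    return c_x0 * params.k_bim_cxp0 / params.branching_total


def mass_balance_residual(c_x, c_y, c_yprime, c_x0: float):
    """Scheme-b mass balance defect C_X(0) - (C_X + C_Y + C_Y') at matched times.

    Identically zero (to round-off) for the analytic scheme-b triple; a
    non-zero value flags corrupted or inconsistent traces.
    """
    c_x = np.asarray(c_x, dtype=float)
    out = c_x0 - (c_x + np.asarray(c_y, dtype=float) + np.asarray(c_yprime, dtype=float))
    return float(out) if out.ndim == 0 else out


def limit_regime(
    a0: float,
    low: float = FIRST_ORDER_A0,
    high: float = ZEROTH_ORDER_A0,
) -> str:
    """Classify the kinetic regime implied by the initial absorbance.

    A0 <= ``low``  -> "first_order"  (Phi-order trace ~ A0 exp(-kr t));
    A0 >= ``high`` -> "zeroth_order" (early trace ~ A0 - (kr/ln10) t);
    otherwise      -> "phi_order".
    Boundary values are assigned to the limiting regime.
    """
    if a0 < 0:
        raise ValueError("a0 must be >= 0")
    if not 0 < low < high:
        raise ValueError("thresholds must satisfy 0 < low < high")
    if a0 <= low:
        return "first_order"
    if a0 >= high:
        return "zeroth_order"
    return "phi_order"


def photonic_yield(
    c0: float,
    ct,
    setup: IrradiationSetup,
    t,
    is_product: bool = False,
) -> float:
    """Photonic yield PY = (C(0) - C(t)) / (P0 * t), sign-flipped for products.

    The overall efficiency of a photoreaction relative to the photons
    delivered to the reactor (not those absorbed); dimensionless.  Under
    scheme (a) the photonic yields of X, X' and Y' coincide at every time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("photonic yield is undefined for t <= 0")
    delta = c0 - np.asarray(ct, dtype=float)
    out = (-delta if is_product else delta) / (setup.P0 * t_arr)
    return _maybe_scalar(out, t)
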