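"""Rate-law right-hand sides for all four schemes and a fixed-step RK4 integrator.

Schemes (a) and (b) admit closed forms (see :mod:`phikin.analytic`); schemes
(c) and (d) do not, and are only accessible numerically.  The integrator is
a classical fourth-order Runge-Kutta with automatic step refinement: the
whole trajectory is recomputed with halved steps until the final state is
stable to a relative tolerance, so every returned trace carries its own
measured self-consistency error.

Simplified systems (solvability conditions applied) use the reactant
absorbance as the state variable for schemes a/b, mirroring the change of
variable in the closed-form derivation; concentrations are derived after the
fact.  The general (non-simplified) system keeps all species absorbing and
lets the co-reactant deplete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    LN10,
    ROLE_COREACTANT,
    ROLE_PRODUCT_Y,
    ROLE_PRODUCT_YDPRIME,
    ROLE_PRODUCT_YPRIME,
    ROLE_PRODUCT_YTPRIME,
    ROLE_REACTANT,
    IrradiationSetup,
    SchemeSpec,
    SpeciesTable,
    photokinetic_factor,
)

__all__ = [
    "IntegrationError",
    "KineticTrace",
    "OdeSystem",
    "rhs_general",
    "rhs_simplified",
    "integrate",
    "scheme_c_shape_diagnostics",
]

#: Concentrations more negative than this are an integration bug, not chemistry.
_NEGATIVE_SLACK = -1e-12

_SCHEME_ROLES = {
    "a": (ROLE_REACTANT, ROLE_COREACTANT, ROLE_PRODUCT_YPRIME),
    "b": (ROLE_REACTANT, ROLE_COREACTANT, ROLE_PRODUCT_Y, ROLE_PRODUCT_YPRIME),
    "c": (
        ROLE_REACTANT,
        ROLE_COREACTANT,
        ROLE_PRODUCT_YPRIME,
        ROLE_PRODUCT_YDPRIME,
        ROLE_PRODUCT_YTPRIME,
    ),
    "d": (ROLE_REACTANT, ROLE_PRODUCT_Y),
}


class IntegrationError(RuntimeError):
    """Step refinement failed to reach the requested self-consistency."""


@dataclass
class KineticTrace:
    """A kinetic trace: time grid, per-species concentrations, optional absorbance.

    Attributes
    ----------
    t : ndarray
        Strictly increasing time grid (s).
    concentrations : dict[str, ndarray]
        Per-species concentration series (M), keyed by species name.
    absorbance : ndarray or None
        Reactant absorbance along l_irr, when tracked.
    metadata : dict
        Provenance: scheme, parameters, generator tag
        ("analytic" | "rk4" | "synthetic"), seed if stochastic, and any
        integrator diagnostics.
    """

    t: np.ndarray
    concentrations: dict[str, np.ndarray]
    absorbance: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("t must be a non-empty 1-D array")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        clipped = {}
        for name, series in self.concentrations.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"series {name!r} length does not match t")
            if np.any(arr < _NEGATIVE_SLACK) and not self.metadata.get("noisy", False):
                raise ValueError(
                    f"species {name!r} went negative beyond numerical slack "
                    f"(min {arr.min():.3e}); integration bug, not chemistry"
                )
            if not self.metadata.get("noisy", False):
                arr = np.clip(arr, 0.0, None)
            clipped[name] = arr
        self.concentrations = clipped
        if self.absorbance is not None:
            self.absorbance = np.asarray(self.absorbance, dtype=float)
            if self.absorbance.shape != self.t.shape:
                raise ValueError("absorbance length does not match t")

    @property
    def n_points(self) -> int:
        return self.t.size

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[name]

    def to_frame(self, include_absorbance: bool = False) -> pd.DataFrame:
        """Tabular view: t_s column, one column per species.

        The exported dialect carries concentrations only; the reactant
        absorbance is recoverable from the Beer-Lambert metadata
        (epsilon_x, l_irr).  Pass ``include_absorbance=True`` for an extra
        A_<reactant> column in interactive use.
        """
        data: dict[str, np.ndarray] = {"t_s": self.t}
        for name, series in self.concentrations.items():
            data[name] = series
        if include_absorbance and self.absorbance is not None:
            data[self.metadata.get("absorbance_column", "A_X")] = self.absorbance
        return pd.DataFrame(data)


def _require_roles(scheme: SchemeSpec, species: SpeciesTable) -> dict[str, object]:
    roles = {}
    for role in _SCHEME_ROLES[scheme.scheme_id]:
        s = species.by_role(role)
        if s is None:
            raise ValueError(f"scheme {scheme.scheme_id!r} requires a species with role {role!r}")
        roles[role] = s
    return roles


@dataclass
class OdeSystem:
    """A scheme's rate law bound to its species table and irradiation setup.

    ``simplified=True`` applies the four solvability conditions (only X
    absorbs, frozen co-reactant); ``simplified=False`` evaluates the full
    rate law with every species' absorptivity and a depleting co-reactant
    (available for scheme a, where the closed form it is compared against
    exists).
    """

    scheme: SchemeSpec
    species: SpeciesTable
    setup: IrradiationSetup
    simplified: bool = True

    def __post_init__(self) -> None:
        self._roles = _require_roles(self.scheme, self.species)
        if not self.simplified and self.scheme.scheme_id != "a":
            raise ValueError(
                "the general (non-simplified) rate law is implemented for scheme 'a'"
            )

    # -- state layout -------------------------------------------------------
    @property
    def state_names(self) -> tuple[str, ...]:
        sid = self.scheme.scheme_id
        if not self.simplified:
            return ("C_X", "C_Xprime", "C_Yprime")
        if sid == "a":
            return ("A_X",)
        if sid == "b":
            return ("A_X", "C_Y", "C_Yprime")
        if sid == "c":
            return ("C_X", "C_Yprime", "C_Ytprime")
        return ("C_X",)  # scheme d

    def initial_state(self) -> np.ndarray:
        sid = self.scheme.scheme_id
        x = self._roles[ROLE_REACTANT]
        a0 = x.epsilon * self.setup.l_irr * x.C0
        if not self.simplified:
            return np.array([x.C0, self._roles[ROLE_COREACTANT].C0, 0.0])
        if sid == "a":
            return np.array([a0])
        if sid == "b":
            return np.array([a0, 0.0, 0.0])
        if sid == "c":
            return np.array([x.C0, 0.0, 0.0])
        return np.array([x.C0])

    # -- derivative rule ----------------------------------------------------
    def make_rhs(self) -> Callable[[np.ndarray], np.ndarray]:
        """Return a fast autonomous derivative closure y -> dy/dt."""
        sid = self.scheme.scheme_id
        setup = self.setup
        x = self._roles[ROLE_REACTANT]
        eps_l = x.epsilon * setup.l_irr
        p0 = setup.P0
        k_bim = self.scheme.k_bim
        phi = self.scheme.phi_direct

        if not self.simplified:
            xp = self._roles[ROLE_COREACTANT]
            yp = self._roles[ROLE_PRODUCT_YPRIME]
            eps_xp_l = xp.epsilon * setup.l_irr
            eps_yp_l = yp.epsilon * setup.l_irr

            def rhs(y: np.ndarray) -> np.ndarray:
                c_x, c_xp, c_yp = y
                a_x = eps_l * max(c_x, 0.0)
                a_tot = a_x + eps_xp_l * max(c_xp, 0.0) + eps_yp_l * max(c_yp, 0.0)
                pa_x = a_x * p0 * photokinetic_factor(a_tot)
                r = -k_bim * pa_x * max(c_xp, 0.0)
                return np.array([r, r, -r])

            return rhs

        if sid in ("a", "b"):
            c_xp0 = self._roles[ROLE_COREACTANT].C0
            k_total = (k_bim * c_xp0 + phi) if sid == "b" else k_bim * c_xp0
            coeff_a = k_total * p0 * eps_l  # dA/dt prefactor, Phi-order kr / ln 10

            if sid == "a":

                def rhs(y: np.ndarray) -> np.ndarray:
                    frac = -math.expm1(-LN10 * max(y[0], 0.0))  # 1 - 10^-A
                    return np.array([-coeff_a * frac])

                return rhs

            def rhs(y: np.ndarray) -> np.ndarray:
                frac = -math.expm1(-LN10 * max(y[0], 0.0))
                return np.array(
                    [-coeff_a * frac, phi * p0 * frac, k_bim * c_xp0 * p0 * frac]
                )

            return rhs

        if sid == "c":
            c_xp0 = self._roles[ROLE_COREACTANT].C0
            k_th = k_bim * c_xp0  # thermal pseudo-first-order constant, s^-1

            def rhs(y: np.ndarray) -> np.ndarray:
                c_x, c_yp, _ = y
                frac = -math.expm1(-LN10 * eps_l * max(c_x, 0.0))
                photo = phi * p0 * frac
                thermal = k_th * max(c_yp, 0.0)
                return np.array([-photo, photo - thermal, thermal])

            return rhs

        # scheme d: the reactant is both the absorber and the ground-state partner
        def rhs(y: np.ndarray) -> np.ndarray:
            c_x = max(y[0], 0.0)
            frac = -math.expm1(-LN10 * eps_l * c_x)
            return np.array([-k_bim * p0 * frac * c_x])

        return rhs

    # -- trace assembly -----------------------------------------------------
    def trace_from_states(self, t: np.ndarray, states: np.ndarray, **metadata) -> KineticTrace:
        """Expand integrator states into per-species concentration series."""
        sid = self.scheme.scheme_id
        x = self._roles[ROLE_REACTANT]
        eps_l = x.epsilon * self.setup.l_irr
        conc: dict[str, np.ndarray] = {}
        absorbance = None

        if not self.simplified:
            xp = self._roles[ROLE_COREACTANT]
            yp = self._roles[ROLE_PRODUCT_YPRIME]
            conc[x.name] = states[:, 0]
            conc[xp.name] = states[:, 1]
            conc[yp.name] = states[:, 2]
            absorbance = eps_l * states[:, 0]
        elif sid == "a":
            xp = self._roles[ROLE_COREACTANT]
            yp = self._roles[ROLE_PRODUCT_YPRIME]
            absorbance = states[:, 0]
            c_x = absorbance / eps_l if eps_l > 0 else np.full_like(absorbance, x.C0)
            conc[x.name] = c_x
            conc[yp.name] = x.C0 - c_x
            conc[xp.name] = xp.C0 - (x.C0 - c_x)
        elif sid == "b":
            xp = self._roles[ROLE_COREACTANT]
            absorbance = states[:, 0]
            c_x = absorbance / eps_l if eps_l > 0 else np.full_like(absorbance, x.C0)
            conc[x.name] = c_x
            conc[self._roles[ROLE_PRODUCT_Y].name] = states[:, 1]
            conc[self._roles[ROLE_PRODUCT_YPRIME].name] = states[:, 2]
            conc[xp.name] = xp.C0 - states[:, 2]
        elif sid == "c":
            xp = self._roles[ROLE_COREACTANT]
            conc[x.name] = states[:, 0]
            conc[xp.name] = xp.C0 - states[:, 2]
            conc[self._roles[ROLE_PRODUCT_YPRIME].name] = states[:, 1]
            conc[self._roles[ROLE_PRODUCT_YDPRIME].name] = x.C0 - states[:, 0]
            conc[self._roles[ROLE_PRODUCT_YTPRIME].name] = states[:, 2]
            absorbance = eps_l * states[:, 0]
        else:  # d
            conc[x.name] = states[:, 0]
            conc[self._roles[ROLE_PRODUCT_Y].name] = x.C0 - states[:, 0]
            absorbance = eps_l * states[:, 0]

        meta = {
            "scheme": sid,
            "simplified": self.simplified,
            "k_bim": self.scheme.k_bim,
            "phi_direct": self.scheme.phi_direct,
            "P0": self.setup.P0,
            "l_irr": self.setup.l_irr,
            "epsilon_x": x.epsilon,
            "c_x0": x.C0,
            "reactant": x.name,
            "absorbance_column": f"A_{x.name}",
            "role_names": {role: s.name for role, s in self._roles.items()},
            "noisy": False,
        }
        meta.update(metadata)
        return KineticTrace(t=t, concentrations=conc, absorbance=absorbance, metadata=meta)


def rhs_simplified(
    state,
    scheme: SchemeSpec,
    species: SpeciesTable,
    setup: IrradiationSetup,
) -> np.ndarray:
    """Derivatives of the simplified (solvability-conditions) rate law.

    State layout per scheme: a -> [A_X]; b -> [A_X, C_Y, C_Y'];
    c -> [C_X, C_Y', C_Y''']; d -> [C_X].
    """
    system = OdeSystem(scheme, species, setup, simplified=True)
    return system.make_rhs()(np.asarray(state, dtype=float))


def rhs_general(
    state,
    scheme: SchemeSpec,
    species: SpeciesTable,
    setup: IrradiationSetup,
) -> np.ndarray:
    """Derivatives of the full rate law (all species absorbing, X' depleting).

    State layout: [C_X, C_X', C_Y'].  The rate couples the absorbed photon
    flux (via the multi-species photokinetic factor) to the co-reactant:
    dC_X/dt = -k_bim * Pa_X * C_X'.
    """
    system = OdeSystem(scheme, species, setup, simplified=False)
    return system.make_rhs()(np.asarray(state, dtype=float))


def _rk4_run(rhs, y0: np.ndarray, t_grid: np.ndarray, n_sub: np.ndarray) -> np.ndarray:
    out = np.empty((t_grid.size, y0.size))
    out[0] = y0
    y = y0.astype(float)
    for i in range(t_grid.size - 1):
        h = (t_grid[i + 1] - t_grid[i]) / n_sub[i]
        for _ in range(n_sub[i]):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
    return out


def integrate(
    system: OdeSystem,
    t_grid,
    rtol: float = 1e-8,
    max_refinements: int = 16,
    n_sub: np.ndarray | None = None,
    **metadata,
) -> KineticTrace:
    """Integrate a scheme's rate law over ``t_grid`` with classical RK4.

    The initial substep obeys max|rate| * h <= 1e-3 * state scale; the whole
    trajectory is then recomputed with doubled substep counts until the
    final state changes by less than ``rtol`` (relative, per component).
    The measured change is stored as ``metadata["step_halving_error"]``.

    Passing an explicit ``n_sub`` (substeps per output interval) skips the
    refinement loop — used when many integrations on a fixed grid must share
    identical discretisation, e.g. inside an optimiser.

    Raises :class:`IntegrationError` if refinement does not converge.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    y0 = system.initial_state()
    rhs = system.make_rhs()

    if t_grid.size == 1:
        return system.trace_from_states(
            t_grid, y0[None, :], generator="rk4", step_halving_error=0.0, n_steps=0, **metadata
        )

    if n_sub is not None:
        n_sub = np.asarray(n_sub, dtype=int)
        states = _rk4_run(rhs, y0, t_grid, n_sub)
        return system.trace_from_states(
            t_grid,
            states,
            generator="rk4",
            step_halving_error=float("nan"),
            n_steps=int(n_sub.sum()),
            **metadata,
        )

    scale = float(np.max(np.abs(y0)))
    scale = scale if scale > 0 else 1.0
    max_rate = float(np.max(np.abs(rhs(y0))))
    dt = np.diff(t_grid)
    if max_rate > 0:
        h0 = 1e-3 * scale / max_rate
        n_sub = np.maximum(np.ceil(dt / h0).astype(int), 1)
    else:
        n_sub = np.ones(dt.size, dtype=int)

    states = _rk4_run(rhs, y0, t_grid, n_sub)
    for _ in range(max_refinements):
        finer = _rk4_run(rhs, y0, t_grid, 2 * n_sub)
        col_scale = np.max(np.abs(finer), axis=0)
        col_scale[col_scale == 0] = 1.0
        err = float(np.max(np.abs(finer[-1] - states[-1]) / col_scale))
        if err < rtol:
            return system.trace_from_states(
                t_grid,
                finer,
                generator="rk4",
                step_halving_error=err,
                n_steps=int((2 * n_sub).sum()),
                **metadata,
            )
        states = finer
        n_sub = 2 * n_sub
    raise IntegrationError(
        f"RK4 step halving did not converge below rtol={rtol:g} after "
        f"{max_refinements} refinements (last error {err:.3e}, "
        f"{int(n_sub.sum())} steps)"
    )


def scheme_c_shape_diagnostics(trace: KineticTrace) -> dict:
    """Detect the two-regime signature of scheme (c) traces.

    Looks for an interior maximum in the intermediate Y' (formed
    photochemically from X, consumed thermally to Y''') and a single
    inflection (sigmoid) in the terminal product Y'''.  Returns a dict with
    ``Yprime_has_interior_max``, ``Ytprime_sigmoid`` and, where found,
    ``max_time`` and ``inflection_time`` (s).
    """
    if trace.n_points < 5:
        raise ValueError("trace too short for shape diagnostics (need >= 5 points)")

    role_names = trace.metadata.get("role_names", {})
    lower = {s.lower(): s for s in trace.species_names}
    yp_name = role_names.get(ROLE_PRODUCT_YPRIME, lower.get("yprime", "Yprime"))
    ytp_name = role_names.get(ROLE_PRODUCT_YTPRIME, lower.get("ytprime", "Ytprime"))
    yp = trace.species(yp_name)
    ytp = trace.species(ytp_name)
    t = trace.t

    tol = 1e-9 * max(float(np.max(np.abs(yp))), 1e-300)
    idx = int(np.argmax(yp))
    has_max = (
        0 < idx < yp.size - 1
        and yp[idx] > yp[0] + tol
        and yp[idx] > yp[-1] + tol
    )
    max_time = float(t[idx]) if has_max else None

    d2 = np.diff(ytp, 2)
    d2_tol = 1e-9 * max(float(np.max(np.abs(d2))) if d2.size else 0.0, 1e-300)
    signs = np.where(d2 > d2_tol, 1, np.where(d2 < -d2_tol, -1, 0))
    nz = signs[signs != 0]
    changes = int(np.count_nonzero(np.diff(nz))) if nz.size else 0
    sigmoid = changes == 1 and float(np.max(np.abs(ytp))) > 0
    inflection_time = None
    if sigmoid:
        flip = np.nonzero(np.diff(nz))[0][0]
        orig_idx = np.nonzero(signs != 0)[0][flip + 1]
        inflection_time = float(t[orig_idx + 1])

    return {
        "Yprime_has_interior_max": bool(has_max),
        "Ytprime_sigmoid": bool(sigmoid),
        "max_time": max_time,
        "inflection_time": inflection_time,
    }
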