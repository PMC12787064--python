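"""Domain types and light-absorption bookkeeping for monochromatic photokinetics.

The physical setting is a well-stirred, slab-shaped photoreactor under
continuous, collimated, strictly monochromatic irradiation at a non-isosbestic
wavelength.  A photoactive reactant X absorbs part of the incident photon flux
and, depending on the reaction topology (scheme), its excited state either
reacts with an excess co-reactant X', undergoes direct photolysis, or
dimerises with ground-state X.

Unit system (fixed package-wide, no conversion layer):

========================  =============================
time                      s
concentration             mol dm^-3 (M)
path length               cm
incident photon flux P0   einstein dm^-3 s^-1
absorptivity epsilon      M^-1 cm^-1 (decadic)
absorbance                dimensionless (decadic)
========================  =============================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LN10",
    "PKF_SERIES_THRESHOLD",
    "ROLE_REACTANT",
    "ROLE_COREACTANT",
    "ROLE_PRODUCT_Y",
    "ROLE_PRODUCT_YPRIME",
    "ROLE_PRODUCT_YDPRIME",
    "ROLE_PRODUCT_YTPRIME",
    "ROLES",
    "SCHEMES",
    "ConfigError",
    "IrradiationSetup",
    "Species",
    "SpeciesTable",
    "SchemeSpec",
    "AbsorbanceState",
    "photokinetic_factor",
    "absorbed_photon_rate",
    "absorbance_from_concentration",
    "concentration_from_absorbance",
    "convert_pathlength",
    "total_absorbance",
    "problem_from_dict",
]

LN10 = math.log(10.0)

#: Below this total absorbance the photokinetic factor is evaluated by its
#: truncated power series (three terms) instead of the 0/0-prone closed form.
PKF_SERIES_THRESHOLD = 1e-6

ROLE_REACTANT = "reactant_X"
ROLE_COREACTANT = "coreactant_Xprime"
ROLE_PRODUCT_Y = "product_Y"
ROLE_PRODUCT_YPRIME = "product_Yprime"
ROLE_PRODUCT_YDPRIME = "product_Ydprime"
ROLE_PRODUCT_YTPRIME = "product_Ytprime"

ROLES = frozenset(
    {
        ROLE_REACTANT,
        ROLE_COREACTANT,
        ROLE_PRODUCT_Y,
        ROLE_PRODUCT_YPRIME,
        ROLE_PRODUCT_YDPRIME,
        ROLE_PRODUCT_YTPRIME,
    }
)

SCHEMES = ("a", "b", "c", "d")


class ConfigError(ValueError):
    """A configuration block is missing or has an invalid field."""

    def __init__(self, field_name: str, message: str | None = None):
        self.field = field_name
        super().__init__(message or f"invalid or missing configuration field: {field_name}")


@dataclass(frozen=True)
class IrradiationSetup:
    """Irradiation geometry and photon delivery.

    Parameters
    ----------
    lambda_irr : float
        Irradiation wavelength (nm).  Metadata for provenance; the kinetics
        are monochromatic at this wavelength by assumption.
    P0 : float
        Incident photon flux delivered to the reactor
        (einstein dm^-3 s^-1); the irradiated volume and area are implicit
        in this volumetric figure.
    l_irr : float
        Optical path of the irradiation beam inside the sample (cm).
    l_obs : float
        Optical path of the spectrophotometric observation beam (cm).
    temperature_label : str
        Free-text temperature tag carried as metadata.  The thermal rate
        constant k_bim is taken as given at this temperature; no Arrhenius
        model is applied.
    V_irr, S_irr : float, optional
        Irradiated volume (dm^3) and area (cm^2), metadata only.
    """

    lambda_irr: float
    P0: float
    l_irr: float
    l_obs: float
    temperature_label: str = "ambient"
    V_irr: float | None = None
    S_irr: float | None = None

    def __post_init__(self) -> None:
        for name in ("lambda_irr", "P0", "l_irr", "l_obs"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ConfigError(name, f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class Species:
    """One chemical species: name, absorptivity at lambda_irr, initial concentration, role."""

    name: str
    epsilon: float
    C0: float
    role: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("name", "species name must be non-empty")
        if self.role not in ROLES:
            raise ConfigError("role", f"unknown species role {self.role!r}; expected one of {sorted(ROLES)}")
        if not (math.isfinite(self.epsilon) and self.epsilon >= 0):
            raise ConfigError("epsilon", f"epsilon must be >= 0, got {self.epsilon!r}")
        if not (math.isfinite(self.C0) and self.C0 >= 0):
            raise ConfigError("C0", f"C0 must be >= 0, got {self.C0!r}")


@dataclass(frozen=True)
class SpeciesTable:
    """Ordered collection of species with exactly one photoactive reactant X."""

    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        if isinstance(self.species, list):
            object.__setattr__(self, "species", tuple(self.species))
        reactants = [s for s in self.species if s.role == ROLE_REACTANT]
        if len(reactants) != 1:
            raise ConfigError(
                "species",
                f"exactly one species must be tagged {ROLE_REACTANT}, found {len(reactants)}",
            )
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("species", "species names must be unique")

    def __iter__(self) -> Iterator[Species]:
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def reactant(self) -> Species:
        return next(s for s in self.species if s.role == ROLE_REACTANT)

    def by_role(self, role: str) -> Species | None:
        """Return the species with the given role, or None if absent."""
        for s in self.species:
            if s.role == role:
                return s
        return None

    @property
    def coreactant(self) -> Species | None:
        return self.by_role(ROLE_COREACTANT)


@dataclass(frozen=True)
class SchemeSpec:
    """One of the four bimolecular photoreaction topologies.

    scheme a : X --hv--> X*,  X* + X' --k_bim--> Y'
    scheme b : as (a) plus concurrent direct photolysis X --hv,Phi--> Y
    scheme c : X --hv,Phi--> Y' + Y'',  then thermal Y' + X' --k_bim--> Y'''
    scheme d : X --hv--> X*,  X* + X --k_bim--> Y  (photodimerisation)

    Notes on units of ``k_bim``: for the photon-coupled step of schemes a, b
    and d the rate term k_bim * Pa * C closes dimensionally with k_bim in
    M^-1 (an einstein being a mole of photons).  The ground-state thermal
    step of scheme c (k_bim * C_X' * C_Y') instead requires M^-1 s^-1.  This
    package adopts M^-1 s^-1 for scheme c and M^-1 otherwise; see
    :attr:`k_bim_units`.  The two conventions are deliberately kept visible
    rather than silently unified.
    """

    scheme_id: str
    k_bim: float = 0.0
    phi_direct: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme_id not in SCHEMES:
            raise ConfigError("scheme", f"scheme must be one of {SCHEMES}, got {self.scheme_id!r}")
        if not (math.isfinite(self.k_bim) and self.k_bim >= 0):
            raise ConfigError("k_bim", f"k_bim must be >= 0, got {self.k_bim!r}")
        if not (math.isfinite(self.phi_direct) and 0.0 <= self.phi_direct <= 1.0):
            raise ConfigError("phi_direct", f"phi_direct must lie in [0, 1], got {self.phi_direct!r}")
        if self.scheme_id in ("a", "d") and self.phi_direct != 0.0:
            raise ConfigError(
                "phi_direct",
                f"scheme {self.scheme_id!r} has no direct photolysis channel; phi_direct must be 0",
            )

    @property
    def k_bim_units(self) -> str:
        """Unit convention for k_bim under this scheme (see class docstring)."""
        return "M^-1 s^-1" if self.scheme_id == "c" else "M^-1"


@dataclass(frozen=True)
class AbsorbanceState:
    """Reactant and total medium absorbance along the irradiation path."""

    A_X: float
    A_tot: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A_X) and self.A_X >= 0):
            raise ValueError(f"A_X must be >= 0, got {self.A_X!r}")
        if not (math.isfinite(self.A_tot) and self.A_tot >= 0):
            raise ValueError(f"A_tot must be >= 0, got {self.A_tot!r}")
        # tiny slack for round-off when A_tot is assembled as a float sum
        if self.A_X > self.A_tot * (1.0 + 1e-12) + 1e-15:
            raise ValueError(
                f"invariant violation: A_X ({self.A_X}) exceeds A_tot ({self.A_tot})"
            )


def photokinetic_factor(a_tot):
    """Photokinetic factor PKF(A) = (1 - 10^-A) / A.

    The dimensionless absorption-saturation factor multiplying the incident
    flux in the absorbed-photon-rate expression.  Continuous, strictly
    decreasing, bounded in (0, ln 10]; the A -> 0 limit is ln 10.  Below
    ``PKF_SERIES_THRESHOLD`` the truncated series
    ln10 * (1 - x/2 + x^2/6), x = A ln10, is used to avoid 0/0.

    Accepts scalars or arrays; raises ValueError on negative input.
    """
    a = np.asarray(a_tot, dtype=float)
    if np.any(a < 0):
        raise ValueError("photokinetic factor is undefined for negative absorbance")
    x = a * LN10
    safe = np.where(a > 0, a, 1.0)
    closed = -np.expm1(-x) / safe
    series = LN10 * (1.0 - x / 2.0 + x * x / 6.0)
    out = np.where(a < PKF_SERIES_THRESHOLD, series, closed)
    if np.isscalar(a_tot) or np.ndim(a_tot) == 0:
        return float(out)
    return out


def absorbed_photon_rate(state: AbsorbanceState, setup: IrradiationSetup) -> float:
    """Rate of photon absorption by the reactant X (einstein dm^-3 s^-1).

    Pa_X = A_X * P0 * PKF(A_tot).  When X is the only absorber
    (A_X = A_tot) this reduces to P0 * (1 - 10^-A_X).  Bounded by
    0 <= Pa_X <= P0.
    """
    return float(state.A_X * setup.P0 * photokinetic_factor(state.A_tot))


def absorbance_from_concentration(C, epsilon: float, l: float):
    """Beer-Lambert: A = epsilon * l * C (decadic, along path l in cm)."""
    if epsilon < 0 or l < 0:
        raise ValueError("epsilon and l must be >= 0")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    out = epsilon * l * C
    return float(out) if out.ndim == 0 else out


def concentration_from_absorbance(A, epsilon: float, l: float):
    """Inverse Beer-Lambert: C = A / (epsilon * l); requires epsilon*l > 0."""
    if epsilon * l <= 0:
        raise ValueError(
            "cannot infer concentration from absorbance for a non-absorbing species (epsilon*l = 0)"
        )
    A = np.asarray(A, dtype=float)
    out = A / (epsilon * l)
    return float(out) if out.ndim == 0 else out


def convert_pathlength(A_obs, setup: IrradiationSetup):
    """Rescale an absorbance measured along l_obs to the irradiation path l_irr."""
    A_obs = np.asarray(A_obs, dtype=float)
    if np.any(A_obs < 0):
        raise ValueError("absorbance must be >= 0")
    out = A_obs * setup.l_irr / setup.l_obs
    return float(out) if out.ndim == 0 else out


def total_absorbance(
    species: SpeciesTable,
    concentrations: Mapping[str, float],
    setup: IrradiationSetup,
) -> AbsorbanceState:
    """Assemble reactant and total medium absorbance along l_irr.

    ``concentrations`` must provide an entry for every species in the table;
    the total is the Beer-Lambert sum over all species, the reactant term is
    tracked separately.
    """
    a_tot = 0.0
    a_x = 0.0
    for s in species:
        if s.name not in concentrations:
            raise ValueError(f"missing concentration for species {s.name!r}")
        c = concentrations[s.name]
        if c is None or not math.isfinite(c):
            raise ValueError(f"invalid concentration for species {s.name!r}: {c!r}")
        term = s.epsilon * setup.l_irr * c
        a_tot += term
        if s.role == ROLE_REACTANT:
            a_x = term
    return AbsorbanceState(A_X=a_x, A_tot=a_tot)


# ---------------------------------------------------------------------------
# configuration block
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG_FIELDS = ("scheme", "P0", "lambda_irr", "l_irr", "species")


def problem_from_dict(config: Mapping) -> tuple[SchemeSpec, SpeciesTable, IrradiationSetup]:
    """Build (SchemeSpec, SpeciesTable, IrradiationSetup) from a config mapping.

    Expected keys: scheme ("a".."d"), P0, lambda_irr, l_irr, species (list of
    {name, epsilon, C0, role}); optional: l_obs (defaults to l_irr), k_bim,
    phi_direct, temperature_label, V_irr, S_irr.  All numeric fields in the
    package unit system.  Raises :class:`ConfigError` naming the first
    missing or invalid field.
    """
    if not isinstance(config, Mapping):
        raise ConfigError("config", "configuration must be a mapping")
    for name in _REQUIRED_CONFIG_FIELDS:
        if name not in config or config[name] is None:
            raise ConfigError(name)
    setup = IrradiationSetup(
        lambda_irr=float(config["lambda_irr"]),
        P0=float(config["P0"]),
        l_irr=float(config["l_irr"]),
        l_obs=float(config.get("l_obs", config["l_irr"])),
        temperature_label=str(config.get("temperature_label", "ambient")),
        V_irr=config.get("V_irr"),
        S_irr=config.get("S_irr"),
    )
    raw_species = config["species"]
    if not isinstance(raw_species, Sequence) or not raw_species:
        raise ConfigError("species", "species must be a non-empty list")
    records = []
    for i, entry in enumerate(raw_species):
        if not isinstance(entry, Mapping):
            raise ConfigError("species", f"species[{i}] must be a mapping")
        for key in ("name", "epsilon", "C0", "role"):
            if key not in entry:
                raise ConfigError(f"species[{i}].{key}")
        records.append(
            Species(
                name=str(entry["name"]),
                epsilon=float(entry["epsilon"]),
                C0=float(entry["C0"]),
                role=str(entry["role"]),
            )
        )
    table = SpeciesTable(tuple(records))
    scheme = SchemeSpec(
        scheme_id=str(config["scheme"]),
        k_bim=float(config.get("k_bim", 0.0)),
        phi_direct=float(config.get("phi_direct", 0.0)),
    )
    return scheme, table, setup
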