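"""Shared fixtures: species-table builders and the demonstration scenario.

The "demo" parameter set (a dilute UV-absorbing drug-like reactant with a
large co-reactant excess under weak continuous irradiation) is used across
modules: C_X(0) = 8.1e-6 M, C_X'(0) = 1.3e-4 M, l_irr = 0.86 cm,
eps_X = 7211 M^-1 cm^-1, P0 = 1.2e-6 einstein dm^-3 s^-1, Phi = 5.3e-4,
k_bim = 1.7e-2.
"""

from __future__ import annotations

import numpy as np
import pytest

from phikin.core import (
    ROLE_COREACTANT,
    ROLE_PRODUCT_Y,
    ROLE_PRODUCT_YDPRIME,
    ROLE_PRODUCT_YPRIME,
    ROLE_PRODUCT_YTPRIME,
    ROLE_REACTANT,
    IrradiationSetup,
    SchemeSpec,
    Species,
    SpeciesTable,
)

DEMO = dict(
    C_X0=8.1e-6,
    C_Xp0=1.3e-4,
    l_irr=0.86,
    eps_X=7211.0,
    P0=1.2e-6,
    phi=5.3e-4,
    k_bim=1.7e-2,
)


def make_setup(P0=1.2e-6, l_irr=0.86, l_obs=1.0, lambda_irr=365.0):
    return IrradiationSetup(lambda_irr=lambda_irr, P0=P0, l_irr=l_irr, l_obs=l_obs)


def make_species(scheme_id, C_X0, C_Xp0=0.0, eps_X=7211.0, eps_other=0.0):
    """Species table for a scheme, with only X absorbing by default."""
    rows = [Species("X", eps_X, C_X0, ROLE_REACTANT)]
    if scheme_id in ("a", "b", "c"):
        rows.append(Species("Xprime", eps_other, C_Xp0, ROLE_COREACTANT))
    if scheme_id in ("b", "d"):
        rows.append(Species("Y", eps_other, 0.0, ROLE_PRODUCT_Y))
    if scheme_id in ("a", "b", "c"):
        rows.append(Species("Yprime", eps_other, 0.0, ROLE_PRODUCT_YPRIME))
    if scheme_id == "c":
        rows.append(Species("Ydprime", eps_other, 0.0, ROLE_PRODUCT_YDPRIME))
        rows.append(Species("Ytprime", eps_other, 0.0, ROLE_PRODUCT_YTPRIME))
    return SpeciesTable(tuple(rows))


def scheme_a_for(a0: float, kr: float):
    """A scheme-(a) problem whose simplified dynamics have the given A0, kr.

    Unit absorptivity/path/flux; k_bim chosen so the Phi-order constant is kr.
    """
    setup = IrradiationSetup(lambda_irr=365.0, P0=1.0, l_irr=1.0, l_obs=1.0)
    species = make_species("a", C_X0=a0, C_Xp0=max(a0, 1e-12) / 0.05, eps_X=1.0)
    k_bim = kr / (species.coreactant.C0 * np.log(10.0))
    return SchemeSpec("a", k_bim=k_bim), species, setup


@pytest.fixture
def demo_setup():
    return make_setup(P0=DEMO["P0"], l_irr=DEMO["l_irr"])


@pytest.fixture
def demo_scheme_c(demo_setup):
    species = make_species("c", DEMO["C_X0"], DEMO["C_Xp0"], DEMO["eps_X"])
    scheme = SchemeSpec("c", k_bim=DEMO["k_bim"], phi_direct=DEMO["phi"])
    return scheme, species, demo_setup


@pytest.fixture
def fast_scheme_c():
    """Time-compressed scheme-c scenario (P0 and k_bim scaled x100) for
    fitting tests that integrate repeatedly."""
    setup = make_setup(P0=DEMO["P0"] * 100, l_irr=DEMO["l_irr"])
    species = make_species("c", DEMO["C_X0"], DEMO["C_Xp0"], DEMO["eps_X"])
    scheme = SchemeSpec("c", k_bim=DEMO["k_bim"] * 100, phi_direct=DEMO["phi"])
    return scheme, species, setup


@pytest.fixture
def demo_config_dict():
    return {
        "scheme": "a",
        "P0": DEMO["P0"],
        "lambda_irr": 365.0,
        "l_irr": DEMO["l_irr"],
        "l_obs": 1.0,
        "k_bim": DEMO["k_bim"],
        "species": [
            {"name": "X", "epsilon": DEMO["eps_X"], "C0": DEMO["C_X0"], "role": "reactant_X"},
            {"name": "Xprime", "epsilon": 0.0, "C0": DEMO["C_Xp0"], "role": "coreactant_Xprime"},
            {"name": "Yprime", "epsilon": 0.0, "C0": 0.0, "role": "product_Yprime"},
        ],
    }
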