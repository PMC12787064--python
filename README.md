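# phikin

Φ-order kinetics of bimolecular photoreactions: closed-form integrated rate
laws where they exist, fixed-step Runge–Kutta simulation where they do not,
and the quantification machinery around both — rate constants, quantum
yield, photonic yield — with fitting and synthetic-data tooling for
parameter recovery.

## The problem

Light-driven bimolecular reactions (a photoexcited reactant X\* reacting
with a ground-state partner X′, or with another X) are routinely analysed
with thermal kinetic models — second-order, pseudo-first-order, or
mono-exponential fits. Those models contain neither the incident photon
flux nor the light actually absorbed, so they misrepresent the physical
system: only the photoexcited fraction of X can react. Under continuous
monochromatic, collimated irradiation of a well-stirred slab reactor, the
correct reactant rate law couples the flux `P0` (einstein dm⁻³ s⁻¹) to the
absorbed fraction through the photokinetic factor

```
PKF(A_tot) = (1 − 10^(−A_tot)) / A_tot,          Pa_X = A_X · P0 · PKF(A_tot)
```

`phikin` implements four reaction topologies ("schemes"):

* **a** — X —hν→ X\*, then X\* + X′ —k_bim→ Y′
* **b** — scheme a plus a concurrent direct photolysis X —hν,Φ→ Y
* **c** — X —hν,Φ→ Y′ + Y″, then the thermal step Y′ + X′ —k_bim→ Y‴
* **d** — photodimerisation: X\* + X —k_bim→ Y

Under four conditions (only X absorbs at λ_irr; monochromatic collimated
light at a non-isosbestic wavelength; the reactant absorbance within its
Beer–Lambert linearity range; co-reactant excess C_X(0) ≤ 0.10 C_X′(0)),
schemes a/b integrate in closed form to **Φ-order kinetics**:

```
A_X(t) = log₁₀(1 + (10^A0 − 1) e^(−kr t))

kr = k_bim C_X′(0) P0 ε_X l_irr ln10                      (scheme a)
kr = (k_bim C_X′(0) + Φ) P0 ε_X l_irr ln10                (scheme b)
```

a decadic logarithm with an exponential argument that interpolates between
first-order decay (A0 ≲ 0.01) and zeroth-order decay (A0 ≳ 2). Scheme b's
products follow the same logarithmic time factor split by the branching
ratio Φ : k_bim C_X′(0). Schemes c and d have no closed form; their rate
laws are integrated numerically (classical RK4 with automatic step
refinement) and k_bim is recovered by single-parameter numeric fitting.
Overall efficiency is reported as the photonic yield
PY = (C(0) − C(t)) / (P0 t).

## Worked example

```python
import numpy as np
from phikin import *

setup = IrradiationSetup(lambda_irr=365, P0=1.2e-6, l_irr=0.86, l_obs=1.0)
species = SpeciesTable((
    Species("X",      7211.0, 8.1e-6, "reactant_X"),
    Species("Xprime",    0.0, 1.3e-4, "coreactant_Xprime"),
    Species("Yprime",    0.0, 0.0,    "product_Yprime"),
))
scheme = SchemeSpec("a", k_bim=1.7e-2)

report = check_conditions(scheme, species, setup)
print("conditions hold:", report.overall_valid,
      "| ratio C_X0/C_X'0 =", round(report.concentration_ratio, 4))

kr = rate_constant_scheme_a(scheme.k_bim, 1.3e-4, setup, 7211.0)
print(f"kr = {kr:.4e} s^-1")

t = np.linspace(0, 5/kr, 50)
trace = generate_trace(scheme, species, setup, t,
                       noise=NoiseModel(sigma=0.002, seed=42))
fit = fit_phi_order(trace)
print(f"fitted kr = {fit.param('kr'):.4e} +/- {fit.stderr('kr'):.1e} s^-1")
print(f"k_bim = {extract_kbim(fit.param('kr'), scheme, 1.3e-4, setup, 7211.0):.4e} M^-1")
```

prints

```
conditions hold: True | ratio C_X0/C_X'0 = 0.0623
kr = 3.7869e-08 s^-1
fitted kr = 3.8265e-08 +/- 9.6e-10 s^-1
k_bim = 1.7178e-02 M^-1
```

The solvability audit passes (the co-reactant is in 16-fold excess), the
Φ-order rate constant of this slow bimolecular photoreaction is
3.79×10⁻⁸ s⁻¹, and a single-parameter fit of a noisy synthetic absorbance
trace (σ = 0.002 AU) recovers it — and the underlying thermal constant
k_bim = 1.7×10⁻² M⁻¹ — to about 1%.

The same workflow is available from the shell (see `examples/scheme_a.yaml`):

```
phikin simulate -c examples/scheme_a.yaml -o trace.csv --sigma 0.002 --seed 42
phikin fit      -c examples/scheme_a.yaml -i trace.csv -o fit.json
phikin check    -c examples/scheme_a.yaml
phikin sweep    -c examples/scheme_a.yaml --ratios 0.01,0.05,0.1,0.5
```

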