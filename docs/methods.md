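# Methods

## Physical model and assumptions

`phikin` models a well-stirred, slab-shaped photoreactor under continuous,
collimated, strictly monochromatic irradiation at a non-isosbestic
wavelength λ_irr. The reactant X absorbs a fraction of the incident
volumetric photon flux P0 (einstein dm⁻³ s⁻¹, the irradiated volume and
area being implicit in that figure), and only the photoexcited fraction can
react. The absorbed photon rate is

    Pa_X(t) = A_X(t) · P0 · PKF(A_tot(t)),   PKF(A) = (1 − 10^(−A)) / A,

with decadic absorbances along the irradiation path (A = ε l_irr C). The
excited state X\* is never an explicit state variable: its steady-state
population and all loss channels are folded into the quantum yield Φ and
the photon-coupled rate constant k_bim, which is the standard reduction for
continuous-irradiation photokinetics. Polychromatic irradiation turns the
rate law into an integro-differential equation with no closed form and is
out of scope.

Four topologies are covered (schemes a–d, see README). Closed forms exist
for a and b only under four conditions: (i) X is the sole absorber at
λ_irr, (ii) the light is monochromatic and collimated at a non-isosbestic
wavelength, (iii) the reactant absorbance stays inside its Beer–Lambert
linearity range (LLR), and (iv) the co-reactant is in large excess so its
concentration is effectively frozen, with validity up to
C_X(0) = 0.10 C_X′(0). `synthdata.check_conditions` audits all four; the
generator warns (but does not refuse) when they fail.

## Rate laws and state variables

For schemes a/b the simplified dynamics are integrated in the absorbance
variable, dA_X/dt = −(kr/ln10)(1 − 10^(−A_X)), mirroring the change of
variable used to derive the closed form and avoiding a redundant ε·l
multiplication; concentrations are derived afterwards. The closed-form
solution is the Φ-order law

    A_X(t) = log₁₀(1 + (10^A0 − 1) e^(−kr t)),

with kr from the scheme-a or scheme-b rate-constant formula ("Log" decadic,
"ln" natural, exactly as in the derivation). Scheme b's two products share
the same logarithmic time factor scaled by the branching fractions
Φ/(k_bim C_X′(0) + Φ) and k_bim C_X′(0)/(k_bim C_X′(0) + Φ); their
asymptotes sum to C_X(0) exactly (mass balance).

Scheme c is a three-state system (C_X, C_Y′, C_Y‴) whose reactant decays by
the unimolecular Φ-order law while the intermediate Y′ is consumed by a
ground-state thermal step k_bim C_X′(0) C_Y′; scheme d couples the absorber
to itself, dC_X/dt = −k_bim P0 (1 − 10^(−A_X)) C_X. Neither admits a closed
form, which is why both are numeric-only here.

### Units and the two k_bim conventions

The package-wide unit system is fixed (s, M, cm, einstein dm⁻³ s⁻¹, decadic
absorbance) and no unit-conversion layer is provided; every quantity is
documented in these units at the type level. The photon-coupled rate term
of schemes a, b and d closes dimensionally with k_bim in M⁻¹ (an einstein
being a mole of photons); the ground-state thermal step of scheme c instead
requires M⁻¹ s⁻¹. `SchemeSpec.k_bim_units` records the convention per
scheme rather than silently unifying them, because the two constants are
genuinely different physical objects. Temperature is metadata only: k_bim
is taken as given at the stated temperature, with no Arrhenius model.

The pseudo-first-order constant k_bim C_X′(0) P0 ε l (without the ln 10
factor) that a forced mono-exponential fit produces is exposed separately
as `pseudo_first_order_rate_constant`, a diagnostic that must not be
confused with the Φ-order kr: the small-A0 limit of the Φ-order law decays
with kr itself (which contains ln 10).

## Numerical choices

* **Photokinetic factor at small absorbance.** PKF is 0/0 at A = 0; below
  A = 10⁻⁶ it is evaluated by the three-term series
  ln10·(1 − x/2 + x²/6), x = A ln10. Three terms keep the branch mismatch
  at the switchover below 10⁻¹² (a two-term series would leave ≈2×10⁻¹²,
  the third-order term); truncation error is ~10⁻¹⁸.
* **Integrator.** Classical fixed-step RK4. The initial substep obeys
  max|rate|·h ≤ 10⁻³ × the state scale; the whole trajectory is then
  recomputed with doubled substep counts until the final state is stable to
  1e−8 relative per component, and the measured change is stored on the
  trace (`step_halving_error`), so every numeric trace carries its own
  self-consistency error. Inside the k_bim optimiser the discretisation is
  frozen once (probed at the stiffest bound) so the objective is smooth in
  k_bim. No stiff solvers, embedded pairs or event detection: the systems
  here are small and non-stiff, and scipy's adaptive RK45 serves as an
  independent cross-check in the tests, not as the implementation.
* **Long times / underflow.** Beyond kr·t = 700 the exponential underflows;
  closed forms return their asymptote exactly.
* **Negative concentrations.** Values within −10⁻¹² (absolute) are clipped
  to zero; anything more negative raises — it signals an integration bug,
  not chemistry. Noisy synthetic traces are exempt: measurement noise may
  legitimately drive points negative and clipping would bias fits.
* **Limit-regime thresholds.** A0 ≤ 0.01 is classified first-order
  (mirroring the series-validity bound ε l C ≤ 0.01 for linearising
  1 − 10^(−A)), A0 ≥ 2 zeroth-order, in between Φ-order; boundaries go to
  the limiting regime and both thresholds are arguments.
* **LLR ceiling.** The linearity-range bound of condition (iii) has no
  universal number; the default ceiling is 2.0 AU and is configurable.

## Fitting

`fit_phi_order` does unweighted nonlinear least squares on absorbance
(photometric noise is approximately homoscedastic in AU; per-point weights
can be added by the caller by pre-scaling). A0 is fixed to the first
observation by default so kr is the unique parameter, matching how the
closed form is used in practice; `fix_a0=False` frees it. The initial guess
comes from the exact linearisation ln(10^A − 1) = const − kr·t, which is
globally linear in t and therefore convergence-safe. Parameter standard
errors use the Gauss–Newton covariance at the optimum and are approximate.

The quantum yield is recovered from the fitted model, not from raw
early-time differencing: r0 is the analytic t = 0 derivative of the fitted
law converted to concentration units, and Φ = −r0 / (P0 (1 − 10^(−A0))).
Raw differencing is available to callers via the trace arrays but the
fitted route is the default because it uses all points.

`fit_numeric_kbim` is a bounded, derivative-free scalar minimisation
(Brent) of the RSS between the trace and repeated RK4 integrations, with
k_bim the only unknown — for scheme c the quantum yield must be known
first (determined separately from the reactant trace, which contains no
k_bim information; a reactant-only trace is reported as unidentifiable, as
is a flat objective over the bounds).

`compare_classical_models` fits mono-exponential, reciprocal second-order,
zeroth-order linear and the Φ-order family to a single species and ranks
them by RSS. It is diagnostic only: no model is declared true. On
photodimerisation (scheme d) traces all the families, including Φ-order,
leave residuals orders of magnitude above the integrator's self-consistency
floor — the model-inadequacy signature that motivates numeric fitting
there.

## Synthetic data

The generator emulates continuous-irradiation monochromatic traces: the
exact model trace (closed form for a/b, RK4 for c/d) plus additive Gaussian
noise, seeded and recorded in the provenance metadata so regeneration is
bit-identical. Default noise is σ = 0.002 AU in the absorbance domain —
typical photometric repeatability of a bench UV-vis spectrophotometer — and
a concentration-domain variant (independent per-species draws) emulates
HPLC-style monitoring; no public noise figures exist for this class of
experiment, so these defaults are the package's own choice. Not modelled:
instrument drift, baseline wander, shot noise, scattering, non-collimated
geometries. Passing recovery tests therefore demonstrate estimator
correctness under idealised homoscedastic noise, not robustness to
structured instrumental error.

The co-reactant bookkeeping in generated traces depletes X′
stoichiometrically even though the rate law freezes C_X′ at its initial
value (condition iv); this is what makes the scheme-a photonic yields of
X, X′ and Y′ coincide, and it is the physically consistent reading of the
approximation.

## Problem sizes

The demonstration scenario (C_X(0) = 8.1×10⁻⁶ M, C_X′(0) = 1.3×10⁻⁴ M,
l_irr = 0.86 cm, ε_X = 7211 M⁻¹ cm⁻¹, P0 = 1.2×10⁻⁶ einstein dm⁻³ s⁻¹,
Φ = 5.3×10⁻⁴, k_bim = 1.7×10⁻²) is integrated once at full scale (80
points over 2.5×10⁶ s) for the shape and closed-form checks. The repeated-
integration fitting experiments use a time-compressed variant (P0 and
k_bim ×100, identical dimensionless shape) with 30-point grids, and the
kr-recovery experiment uses 100 seeded 50-point traces: these sizes give
sub-percent estimator noise while keeping the experiments quick to re-run.

## Known limitations

* Monochromatic, collimated, well-stirred slab geometry only.
* The general (all-species-absorbing, co-reactant-depleting) rate law is
  implemented for scheme a, where the closed form it is compared against
  exists; it is numeric-only and flagged non-analytic.
* Single-trace fitting; no global multi-trace fits, Bayesian posteriors, or
  model-selection criteria beyond RSS ranking.
* Uncertainties are Gauss–Newton approximations, adequate near a
  well-identified optimum and optimistic elsewhere.
* The scheme-c thermal timescale depends on the M⁻¹ s⁻¹ reading of k_bim
  (see the unit note above); shape diagnostics, not absolute times, are the
  robust output of that scenario.
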