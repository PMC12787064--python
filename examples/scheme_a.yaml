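# Scheme (a) demonstration: dilute UV-absorbing reactant with a 16-fold
# co-reactant excess under weak continuous monochromatic irradiation.
# Units: s, M, cm, einstein dm^-3 s^-1, decadic absorbance.
scheme: a
P0: 1.2e-6
lambda_irr: 365.0
l_irr: 0.86
l_obs: 1.0
k_bim: 1.7e-2
species:
  - {name: X,      epsilon: 7211.0, C0: 8.1e-6, role: reactant_X}
  - {name: Xprime, epsilon: 0.0,    C0: 1.3e-4, role: coreactant_Xprime}
  - {name: Yprime, epsilon: 0.0,    C0: 0.0,    role: product_Yprime}
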