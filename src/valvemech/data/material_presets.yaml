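# Material catalog for aortic valve leaflet tissue and cells.
#
# Fung-type entries: U = C/2 (exp(Q) - 1) + K ((J^2 - 1)/2 - ln J),
# Q quadratic in the Green-Lagrange strain expressed in the fiber frame
# (f = circumferential, s = radial, n = through-thickness).
# Units: MPa for C and K; b1..b3 dimensionless.
#
# Isotropic entries: Young modulus E_mod (MPa), Poisson ratio nu.
# `model` selects the finite-strain extension used by the FE solver
# (compressible neo-Hookean by default; Saint Venant-Kirchhoff available).

fung:
  intact_leaflet: {C: 2.82e-03, b1: 0.01, b2: 2.84, b3: 1.97, K: 50.0}
  fibrosa:        {C: 3.48e-06, b1: 5.49, b2: 81.48, b3: -0.08, K: 50.0}
  ventricularis:  {C: 5.09e-06, b1: 4.86, b2: 5.02, b3: -1.63e-03, K: 50.0}

isotropic:
  spongiosa:   {E_mod: 0.02,   nu: 0.49, model: neo_hookean}
  vic:         {E_mod: 9.0e-04, nu: 0.45, model: neo_hookean}
  aortic_wall: {E_mod: 2.0,    nu: 0.30, model: neo_hookean}
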