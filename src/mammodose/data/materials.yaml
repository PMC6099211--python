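# Built-in material definitions.
#
# mass_fractions may reference bare elements ("O") or simple chemical
# formulas ("LiF", "C10H8O4"), which are expanded to elemental fractions by
# stoichiometric mass ratio at load time.  Densities in g/cm^3.
#
# Tissue compositions: adipose and glandular follow the Hammerstein-style
# elemental compositions commonly used for breast dosimetry; skin follows
# ICRU 44.  The 50/50 phantom material and the TLD chip composition are
# derived at load time (see materials.py).
air:
  density: 1.20479e-3
  mass_fractions: {C: 1.24e-4, N: 0.755267, O: 0.231781, Ar: 0.012827}
water:
  density: 1.0
  mass_fractions: {H: 0.111898, O: 0.888102}
adipose:
  density: 0.93
  mass_fractions: {H: 0.112, C: 0.619, N: 0.017, O: 0.252}
glandular:
  density: 1.04
  mass_fractions: {H: 0.102, C: 0.184, N: 0.032, O: 0.677, P: 0.005}
skin:
  density: 1.09
  mass_fractions: {H: 0.100, C: 0.204, N: 0.042, O: 0.645, Na: 0.002,
                   P: 0.001, S: 0.002, Cl: 0.003, K: 0.001}
tld:
  # LiF:Mg,Cu,P chip: 99.5% LiF, 0.2% Mg, 0.004% Cu, 0.296% P
  density: 2.48
  mass_fractions: {LiF: 0.995, Mg: 2.0e-3, Cu: 4.0e-5, P: 2.96e-3}
pet:
  density: 1.38
  mass_fractions: {C10H8O4: 1.0}
carbon_fiber:
  density: 1.55
  mass_fractions: {C: 1.0}
pmma:
  density: 1.19
  mass_fractions: {C5H8O2: 1.0}
aluminum:
  density: 2.699
  mass_fractions: {Al: 1.0}
beryllium:
  density: 1.848
  mass_fractions: {Be: 1.0}
rhodium:
  density: 12.41
  mass_fractions: {Rh: 1.0}
tungsten:
  density: 19.25
  mass_fractions: {W: 1.0}
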