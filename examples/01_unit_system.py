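"""Map the reduced simulation units onto physical (DNA-like) scales.

The model works in reduced Lennard-Jones units: bead diameter sigma,
energy eps0 and bead mass m are all 1.  Identifying sigma with the Kuhn
length of double-stranded DNA (1.5 nm), a bead mass of 936 amu and room
temperature (295 K, with kT = 1.2 eps0) fixes every other unit.
"""

import poretrans as pt

params = pt.SimulationParameters()

print(f"time unit t_LJ       : {pt.lj_time_unit(params):.1f} ps")
print(f"energy scale eps0    : {pt.epsilon0_joules(params):.3g} J")
lower, upper = pt.force_regime_bounds(params)
print(f"force regime bounds  : ({lower:.3f}, {upper:.3f}) eps0/sigma")
for f in (1.0, 2.0):
    print(f"pulling force f = {f:g} : {pt.classify_force(params, f)}")

# The bounds bracket the pulling forces for which the driving neither
# vanishes against the entropic barrier (below kT/(sigma N^nu)) nor
# overwhelms the chain's relaxation entirely (above kT/sigma): f = 1 falls
# inside (medium), f = 2 above (strong).
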