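# Production preset: nine pore attractions x four diameters x two forces,
# 1500 events per condition for converged waiting-time statistics.
n_monomers: 50
kT: 1.2
friction: 0.7
fene_k: 30.0
fene_r0: 1.5
pore_length: 6.0
pore_radius: [1.5, 2.0, 2.5, 3.0]
pore_epsilon: [0.1, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
pull_force: [1.0, 2.0]
timestep: 0.005
rng_seed: 2024
n_events: 1500
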