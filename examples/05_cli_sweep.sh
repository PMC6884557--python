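#!/bin/sh
# Small command-line sweep: simulate, analyze, report.
# The config is flat YAML; list-valued condition keys define the grid.
set -e

cat > /tmp/sweep.yaml <<'EOF'
n_monomers: 50
pore_radius: [1.5, 2.5]
pore_epsilon: [1.0, 8.0]
pull_force: 2.0
rng_seed: 11
n_events: 5
EOF

poretrans simulate --config /tmp/sweep.yaml --out /tmp/sweep_out
poretrans analyze --events /tmp/sweep_out
poretrans report --events /tmp/sweep_out

echo "crossing report (strong vs weak attraction):"
cat /tmp/sweep_out/tables/crossing_report.csv
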