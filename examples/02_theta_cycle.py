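"""One theta cycle through the circuit, phase by phase.

A stimulus is presented for three 30-step settling phases: at the theta
trough the monosynaptic pathway (EC -> CA1 -> EC_out) produces the
network's own reconstruction; at the peak the trisynaptic pathway's
Schaffer collaterals (CA3 -> CA1) drive recall; in the plus phase the
input is imposed one-to-one on EC_out as the learning target.  The
differences between these snapshots are the two error signals.
"""

import numpy as np

from thetahippo.network import (
    ArchitectureConfig,
    ConditionParams,
    build_network,
    learn_from_trace,
    run_theta_cycle,
)
from thetahippo.patterns import generate_vocabulary, make_training_set

vocab = generate_vocabulary(rng=0)
net = build_network(ArchitectureConfig(n_ca3=40), rng=1)
pattern = make_training_set(vocab, 1, 8, rng=2)[0].ec_vector

trace = run_theta_cycle(net, pattern, mode="train")
print(f"settling steps for the full train cycle: {net.step_count} "
      f"(3 phases x 30)")
for phase in ("TT", "TP", "PLUS"):
    snap = trace.phases[phase]
    act = {layer: int((snap[layer] > 0).sum())
           for layer in ("dg", "ca3", "ca1", "ec_out")}
    print(f"{phase:>4}: active units {act}")

print("\nplus-phase EC_out equals the input (ground-truth clamp):",
      bool(np.array_equal(trace.phases['PLUS']['ec_out'], pattern)))

before = net.weight_checksum()
learn_from_trace(net, trace, ConditionParams())
print(f"weight checksum before/after one update: {before:.2f} -> "
      f"{net.weight_checksum():.2f} (plastic projections moved)")
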