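"""Fixed-density networks and the small-world quotient.

Thresholds two 128-channel weight matrices at 10% density — one purely
random, one with a planted clustered module — and prints clustering C,
characteristic path length L, and the small-world quotient
Q = (C/C_random) / (L/L_random) against ten Erdos-Renyi references.
"""

import numpy as np

from jdnet import network_metrics

rng = np.random.default_rng(0)


def symmetric_uniform(n):
    w = np.triu(rng.uniform(size=(n, n)), 1)
    return w + w.T


random_w = symmetric_uniform(128)

clustered_w = symmetric_uniform(128)
clustered_w[:40, :40] += 1.0  # strongly coupled 40-channel module
clustered_w = np.triu(clustered_w, 1)
clustered_w = clustered_w + clustered_w.T

for name, w in (("random weights", random_w), ("planted module", clustered_w)):
    m = network_metrics(w, density=0.10, n_rand=10, seed=1)
    print(
        f"{name:15s} edges={m.n_edges}  C={m.c_actual:.3f}  L={m.l_actual:.3f}  "
        f"ecc={m.eccentricity:.2f}  Q={m.q:.2f}"
    )

print(
    "\nAt 10% density every 128-node graph has exactly 813 edges. A random"
    "\nmatrix self-normalizes to Q near 1; concentrating the strongest"
    "\ncouplings in one module raises clustering and the quotient."
)
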