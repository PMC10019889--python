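"""Generalize the learning rule to temporal plasticity kernels.

The base rule pairs presynaptic activity at t-1 with postsynaptic activity
at t.  Replacing that pairing by exponential pre->post / post->pre kernels
recovers the base rule exactly for a kernel supported at lag 1, and a small
grid search over kernel shapes shows which time constants still estimate
the transition structure well.
"""

import numpy as np

import srnn
from srnn.plasticity import delta_lag1_kernel

env = srnn.ring(10)
walks = [srnn.simulate_walk(env, srnn.ring_actions(0.5, 0.25, 0.25), 400, seed=s) for s in (0, 1)]

# exact recovery of the base rule by the lag-1 kernel
X = srnn.walk_inputs(walks[0])
cfg = srnn.RNNConfig(gamma_B=0.0)
base = srnn.run_session(X, cfg, record_activity=False)
kern = srnn.run_session(X, cfg, rule=delta_lag1_kernel(), record_activity=False)
print(f"lag-1 kernel vs base rule: max |dJ| = {np.abs(base.state.J - kern.state.J).max():.2e}")

grid = [
    {"kind": "delta_lag1"},
    {"sign_minus": -1, "tau_plus": 1.0, "tau_minus": 1.0},
    {"sign_minus": -1, "tau_plus": 3.0, "tau_minus": 3.0},
    {"sign_minus": 1, "tau_plus": 3.0, "tau_minus": 3.0},
]
table = srnn.kernel_search(grid, walks, n_inits=2, seed=0)
print(table[["kind", "sign_minus", "tau_plus", "tau_minus", "min_error", "min_error_clipped"]]
      .to_string(index=False))
print("lower min_error = better recovery of the empirical transition matrix")
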