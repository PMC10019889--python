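"""Learn a circular track's transition structure with the local plasticity rule.

A forward-biased random walk on a 20-state ring drives the recurrent network
at zero learning gain; the adaptive learning rate turns the STDP +
decorrelative-normalization rule into an exact running average, so the
synaptic matrix converges to the transposed empirical transition matrix.
"""

import numpy as np

import srnn

env = srnn.ring(20)
actions = srnn.ring_actions(p_fwd=0.5, p_stay=0.25, p_back=0.25)
walk = srnn.simulate_walk(env, actions, n_steps=5400, seed=1)

cfg = srnn.RNNConfig(gamma_B=0.0, lambda_=1.0, lr_mode="adaptive")
res = srnn.run_session(srnn.walk_inputs(walk), cfg, record_activity=False)

emp = srnn.empirical_transition_matrix(walk)
truth = srnn.true_transition_matrix(env, actions)
mean_row_sum, _ = srnn.row_sum_T(res.state.J)

print(f"mean row sum of T estimate : {mean_row_sum:.6f}  (1.0 = correctly normalized)")
print(f"|J^T - empirical T|_max    : {np.abs(res.state.J.T - emp.T).max():.2e}  (exact recovery)")
print(f"MAE to ground-truth T      : {srnn.mae_matrix(res.state.J.T, truth.T):.4f}  (walk sampling noise)")
M_hat = srnn.sr_from_J(res.state.J, 0.6).M
M_true = srnn.sr_from_T(truth, 0.6).M
print(f"MAE of SR matrix (gamma=0.6): {srnn.mae_matrix(M_hat, M_true):.4f}")
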