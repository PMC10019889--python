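"""Map the stable learning regime of the recurrent gain.

Learning with recurrent amplification is a positive-feedback loop: above a
critical learning gain the synaptic matrix's spectrum crosses 1/gamma_B and
the dynamics diverge.  A saturating (tanh) nonlinearity extends the stable
regime.  Reduced scale: 1,800-step walks, 3 seeds per gain.
"""

import srnn

for nonlinearity in ("linear", "tanh"):
    sweep = srnn.stability_sweep(
        [0.4, 0.5, 0.6, 0.7, 0.8], nonlinearity, n_seeds=3, seed=0, n_steps=1800,
    )
    summary = sweep.groupby("gamma_B")["stable"].agg(["sum", "count"])
    print(f"{nonlinearity} dynamics:")
    for gamma, row in summary.iterrows():
        print(f"  gamma_B={gamma:.1f}: {int(row['sum'])}/{int(row['count'])} runs subcritical")
    print(f"  largest fully stable gain: {srnn.largest_stable_gamma(sweep)}")
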