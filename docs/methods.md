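# Methods

This note documents the model, the defaults and the numerical choices made
where the design was genuinely open, in the package's own words.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The environment is a finite Markov chain: a 1D circular track (`ring`) or a
2D square arena (`grid`) of 5 cm bins, with one timestep = 1/3 s (15 cm/s
movement).  The agent's policy enters only through the action model; there
is no reward or value computation.  The successor representation at
discount γ is `M = (I − γT)^{-1}` for the row-stochastic transition matrix
T.

The network is a discrete-time rate RNN of N neurons, one per input feature
dimension.  `J[i, j]` is the synapse from neuron j to neuron i (note this
is the transpose of the reinforcement-learning index convention for T).
Steady-state activity under input φ is:

* **closed form** (linear transfer): `x = (I − γJ)^{-1} φ`, computed by a
  linear solve;
* **truncated** (linear): `x = Σ_{t=0}^{t_max} γ^t J^t φ` by iterated
  matrix–vector products;
* **iterative** (tanh transfer): `x ← γ J tanh(x) + φ` for `t_max` steps
  from `x = 0`.

`t_max` is the smallest integer with `γ^t_max < 1e-4` (at least 1), so the
truncated series matches the solve within the geometric tail bound.

Learning updates every synapse with locally available quantities:

```
ΔJ_ij = η_j [ x_i(t) x_j(t−1) − x_j(t−1) Σ_k J_ik x_k(t−1) ]
```

The first term is STDP-like potentiation pairing presynaptic activity one
step back with current postsynaptic activity; the second is an anti-Hebbian
normalization that subtracts the network's own one-step prediction and, for
overlapping features, decorrelates inputs.  Self-synapses are not treated
specially in the base rule (the kernel variant exposes a separate diagonal
scale `alpha_d`).  The network runs in two modes: learning at gain
`gamma_B` with plasticity on, retrieval at gain `gamma_R` with plasticity
off; retrieval gain can be chosen freely per query.

## Adaptive learning rate and the two trace conventions

The adaptive rate is `η_j = min(1 / n_j, 1)` with the trace
`n ← α_n x + λ n` (defaults `α_n = 1`, `λ = 1`); zero-trace neurons use the
cap η = 1, so a neuron's first departure performs a full-strength one-shot
write.

Two orderings of the trace update relative to the weight update are in
circulation and they are *not* equivalent when a state transitions to
itself:

* `exclude_current` (default): η is computed from the strict past trace
  `n(t) = Σ_{t'<t} λ^{t−t'} x(t')` — operationally, decay the trace,
  compute η, apply the weight update, then fold in x(t).  Under this
  convention one-hot learning at `gamma_B = 0`, `λ = 1` is an exact
  running average: the learned J equals the transposed empirical transition
  matrix to machine precision, stay transitions included.  This identity is
  the package's strongest oracle and the default exists to preserve it.
* `include_current`: fold x(t) into the trace first, then compute η
  (`RNNConfig.trace_convention = "include_current"`).  This is the
  convention the learning-phase simulations with `gamma_B > 0` use (its
  larger effective trace damps one-shot writes of amplified activity); at
  `gamma_B = 0` it differs from the default only on stay transitions, where
  it loses the exactness property.

## Learning-rate regimes: sparse vs dense inputs

The adaptive rate is a device for sparse (one-hot-like) inputs, where the
per-column update is a running average.  For dense overlapping features the
first-visit updates are unnormalized LMS steps of size `Σ_j η_j φ_j²`;
when that exceeds the LMS stability limit the weights diverge.  The
package's dense-feature experiments (successor features on the 2D arena,
field-size sweeps) therefore use the static rate, default
`η = 10^-1.5`, which keeps the learning a stable stochastic-approximation
flow; the sparse-ring and one-hot experiments use the adaptive rate.  The
independent (Oja-like, per-synapse) normalization control diverges on dense
correlated features under either rate — the decorrelative term is what
keeps the weights bounded there.

## Stability of learning at elevated gain

With `gamma_B > 0` the learning loop is self-amplifying: activity is
amplified by `(I − γJ)^{-1}`, writes enlarge J, which amplifies activity
further.  A run is called unstable when the maximum real eigenvalue of
`gamma_B · J` reaches 1 at any logged checkpoint (default every 100 steps);
sessions halt on detection with the state preserved.  The package's
stability sweep (`srnn.stability_sweep`) measures, per gain on a 0.1 grid,
whether 5 seeded forward-biased ring walks stay subcritical; the sweep uses
the `include_current` trace and closed-form (linear) or iterative (tanh)
dynamics.  The failure mode is an early-session resonance: a self-synapse
or short loop transiently drives a (possibly complex) eigenvalue of γJ
toward 1 while η is still large; the resolvent then amplifies the next
write and the frozen trace locks the network in the supercritical state.
Because the trigger is a rare early event, the empirical threshold is a
probabilistic transition rather than a sharp boundary; the saturating tanh
transfer eliminates the resonance channel and extends the stable range of
`gamma_B` by well over a grid step.  The acceptance script reports the
largest fully stable gain for both transfer functions as `t2` and `t3`.

## Feature encodings

For N states the generator draws N binary feature dimensions with
on-probability p, blurs each dimension across the state geometry with a
Gaussian of standard deviation σ (in cm, converted to bins; kernel
truncated at a 1σ radius and renormalized; rings wrap, grids reflect), then
min-subtracts and max-normalizes each dimension.  All-constant dimensions
are flagged degenerate and zeroed.  The dataset sparsity s is the median
over states of `‖φ‖₁ / N` — note s is *measured after* blurring and
normalization, so it is systematically larger than p (on a 20-state ring,
p = 0.05 at σ = 7.5 cm yields s ≈ 0.10).  Spatial correlation is controlled
by σ alone.

## Place-field pipeline

Rate maps are occupancy-normalized (activity sums and occupancy smoothed
with the same Gaussian, default 1 bin, then divided); zero-occupancy bins
are flagged and excluded, never zero-filled.  Field detection uses a
circular time-shift permutation null (uniform offsets of at least 30 s, 250
permutations by default), which preserves the activity autocorrelation.
Candidate fields are contiguous regions at ≥ 50% of the map peak covering
at least 4 bins (ring contiguity wraps); a field is significant when its
peak exceeds the 1 − α quantile of null map peaks (α = 0.05).  Field sizes
are reported as fractions of the arena; population histograms use integer
field-count bins 0…8+ and ten equal size bins on (0, 0.5]; KL divergences
are in bits, with the reference histogram Laplace-smoothed (pseudo-count
0.5) only when it has empty bins under the model's support, so identical
distributions give exactly 0.

Peak shifts on the ring use minimal circular differences in cm (ties break
to the lower bin; negative = opposite the travel direction).  The packaged
peak-shift experiment learns online at `gamma_B = 0` while recording the
linear closed-form SR readout at `gamma_R = 0.8` during the first and last
two minutes of a half-hour session; the per-neuron peak shift between the
two windows is averaged per walk.  The linear readout matters: the tanh
readout's saturation flattens field tops and hides the sub-bin backward
drift that dense overlapping inputs produce.

## Synthetic data: what it does and does not emulate

All inputs are synthetic.  Walks are exact Markov chains on the discretized
arena; the 2D foraging generator (14 × 14 grid at 3 frames/s, 28-minute
windows, ≥ 85% coverage required) emulates the coverage statistics of
random foraging but none of the kinematic structure of real behaviour
(speed modulation, wall-following, heading persistence), and the feature
generator produces stationary, noise-free encodings with a single
controllable correlation scale.  Consequently, passing tests show the
algorithms are implemented correctly and behave as designed under Markovian
exploration; they do not show that real neural data are fit well, and the
place-field statistics computed here calibrate the pipeline rather than
reproduce recorded populations.

## Numerical choices and scales

* Matrix solves use LAPACK via `numpy.linalg.solve`/`inv`; the closed-form
  weight oracle `J = R(−1) R(0)^{-1}` uses raw (uncentred, unnormalized)
  second moments over matched transition windows — the only convention that
  reproduces `J = T̂ᵀ` for one-hot series — and refuses singular `R(0)`
  unless a pseudo-inverse is explicitly allowed.
* TD loss is the mean squared Euclidean norm of `φ + γ Mᵀφ' − Mᵀφ` over
  sampled observed transitions (default sample size 1,000); for recurrent
  readouts the same loss is evaluated through the network's steady state.
* Kernel search fixes each cell's post→pre sign and time constants and fits
  the amplitudes `(A+, |A−|, α_d, α_n)` with an injected derivative-free
  optimizer (`minimize(f, x0, seed)`; Nelder–Mead by default), scoring the
  mean-squared error of the final J against the transposed empirical
  transition matrix over a small walk distribution; cells whose fitted
  potentiation amplitude is below 10⁻³ of the grid's median are set to a
  high-error sentinel, and a 0.03-clipped column is provided for heatmaps.
* Default scales: 20-state ring, 5,400-step sessions (a half hour at
  3 steps/s), 5 seeds per sweep point, 2,000-step walks for learning-speed
  comparisons, 20 walks for the peak-shift experiment, 200 neurons / 250
  permutations for detection calibration.  These sizes make the full suite
  and the acceptance script run in minutes on one CPU while keeping every
  statistical check comfortably powered.

## Known limitations

* The spectral-stability transition under the closed-form linear dynamics
  is stochastic near its boundary (see above); reported largest-stable
  gains are grid values and can move by one 0.1 step between seed sets.
* The tanh network in this implementation remains subcritical for all
  tested learning gains up to 0.9; its instability onset, if any, lies
  outside the swept grid.
* The moment-matched random-weight control is not a strong TD-loss
  baseline in these synthetic settings (the input term dominates the TD
  error), so TD comparisons here are between learners.
* Continuous-time dynamics, spiking, reward/value readouts, and
  data-derived (e.g. grid-cell) input bases are out of scope.
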