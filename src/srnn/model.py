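"""Core RNN-S model: steady-state SR retrieval and the local learning rule.

The network is a rate RNN whose steady state under input ``phi`` retrieves a
row of the successor representation: with synaptic weights ``J = T^T`` and
gain ``gamma``, ``x_ss = (I - gamma J)^{-1} phi = M^T phi`` where
``M = (I - gamma T)^{-1}``.  ``J[i, j]`` is the synapse from neuron j to
neuron i (note: transposed relative to the reinforcement-learning
convention for ``T``).

Learning combines a temporally asymmetric (STDP-like) potentiation term with
an anti-Hebbian decorrelative normalization::

    dJ_ij = eta_j * ( x_i(t) x_j(t-1) - x_j(t-1) * sum_k J_ik x_k(t-1) )

The per-presynaptic-neuron learning rate can be static or adaptive,
``eta_j = min(1 / n_j, 1)`` with ``n_j`` a lambda-discounted trace of neuron
j's activity — fast one-shot learning on first visits, slow refinement later.

The network operates in two modes: a *learning* mode at gain ``gamma_B``
(kept low for stability) and a plasticity-off *retrieval* mode whose gain
``gamma_R`` can be modulated freely to retrieve the SR at any horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import mae_matrix, max_real_eig

__all__ = [
    "RNNConfig",
    "RNNState",
    "SRMatrix",
    "UnstableDynamicsError",
    "sr_from_T",
    "steady_state_linear",
    "choose_tmax",
    "steady_state_truncated",
    "steady_state_tanh",
    "weight_update",
    "update_trace",
    "step_learn",
    "step_retrieve",
    "run_session",
    "SessionResult",
    "walk_inputs",
]


class UnstableDynamicsError(RuntimeError):
    """Recurrent dynamics at the requested gain are unstable."""


@dataclass(frozen=True)
class SRMatrix:
    """Successor representation matrix and the discount it was computed at."""

    M: np.ndarray
    gamma: float

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.M, dtype=dtype)


@dataclass(frozen=True)
class RNNConfig:
    """Model hyperparameters.

    Parameters
    ----------
    gamma_B:
        Gain during learning, in [0, 1).  0 short-circuits the dynamics
        (activity equals the input).
    gamma_R:
        Gain during retrieval, in [0, 1); freely modulable after learning.
    lambda_:
        Trace discount in (0, 1]; 1 makes the adaptive rate a running mean.
    lr_mode:
        ``"adaptive"`` (eta = min(1/n, 1) per presynaptic neuron) or
        ``"static"`` (uniform ``eta_static``).
    eta_static:
        Static learning rate; default 10**-1.5.
    nonlinearity:
        ``"linear"`` or ``"tanh"`` recurrent transfer function.
    dynamics:
        ``"closed_form"`` (matrix solve, linear only), ``"truncated"``
        (finite power series), or ``"iterative"`` (fixed-point iteration,
        required for tanh).
    tol_tmax:
        Tail tolerance for choosing the number of recurrent steps.
    alpha_n:
        Scale of the activity contribution to the trace.
    trace_convention:
        ``"exclude_current"`` uses the strict past trace
        ``n(t) = sum_{t'<t} lambda^(t-t') x(t')`` when forming eta — this is
        the convention under which one-hot learning reproduces the empirical
        transition matrix exactly.  ``"include_current"`` folds x(t) into the
        trace before computing eta.
    """

    gamma_B: float = 0.0
    gamma_R: float = 0.6
    lambda_: float = 1.0
    lr_mode: str = "adaptive"
    eta_static: float = 10 ** -1.5
    nonlinearity: str = "linear"
    dynamics: str = "closed_form"
    tol_tmax: float = 1e-4
    alpha_n: float = 1.0
    trace_convention: str = "exclude_current"

    def __post_init__(self) -> None:
        if not 0 <= self.gamma_B < 1 or not 0 <= self.gamma_R < 1:
            raise ValueError("gamma_B and gamma_R must lie in [0, 1)")
        if not 0 < self.lambda_ <= 1:
            raise ValueError("lambda_ must lie in (0, 1]")
        if self.eta_static <= 0:
            raise ValueError("eta_static must be positive")
        if self.lr_mode not in ("static", "adaptive"):
            raise ValueError("lr_mode must be 'static' or 'adaptive'")
        if self.nonlinearity not in ("linear", "tanh"):
            raise ValueError("nonlinearity must be 'linear' or 'tanh'")
        if self.dynamics not in ("closed_form", "truncated", "iterative"):
            raise ValueError("dynamics must be 'closed_form', 'truncated' or 'iterative'")
        if self.nonlinearity == "tanh" and self.dynamics == "closed_form":
            raise ValueError("closed-form dynamics require a linear nonlinearity")
        if self.trace_convention not in ("exclude_current", "include_current"):
            raise ValueError("unknown trace convention")


@dataclass
class RNNState:
    """Mutable network state: synapses, activity trace, previous activity."""

    J: np.ndarray
    n: np.ndarray
    x_prev: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n_neurons: int) -> "RNNState":
        return cls(
            J=np.zeros((n_neurons, n_neurons)),
            n=np.zeros(n_neurons),
            x_prev=np.zeros(n_neurons),
            t=0,
        )

    def copy(self) -> "RNNState":
        return RNNState(self.J.copy(), self.n.copy(), self.x_prev.copy(), self.t)


def sr_from_T(T, gamma: float) -> SRMatrix:
    """Ground-truth SR matrix ``M = (I - gamma T)^{-1}`` for row-stochastic T."""
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    if isinstance(T, np.ndarray):
        Tm = T.astype(float)
    elif hasattr(T, "kind") and hasattr(T, "T"):
        # a TransitionMatrix dataclass carries its array in attribute .T
        Tm = np.asarray(T.T, dtype=float)
    else:
        Tm = np.asarray(T, dtype=float)
    n = Tm.shape[0]
    M = np.linalg.inv(np.eye(n) - gamma * Tm)
    return SRMatrix(M, gamma)


def sr_from_J(J: np.ndarray, gamma: float) -> SRMatrix:
    """SR matrix encoded by recurrent weights at retrieval gain ``gamma``.

    ``M^T = (I - gamma J)^{-1}``, i.e. ``M = (I - gamma J^T)^{-1}``; for
    ``J = T^T`` this is the SR of ``T``.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    return SRMatrix(np.linalg.inv(np.eye(n) - gamma * J.T), gamma)


def steady_state_linear(J: np.ndarray, gamma: float, phi: np.ndarray, check_stability: bool = True) -> np.ndarray:
    """Closed-form steady state ``x = (I - gamma J)^{-1} phi``."""
    J = np.asarray(J, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if gamma == 0:
        return phi.copy()
    if check_stability and gamma * max_real_eig(J) >= 1.0:
        raise UnstableDynamicsError(
            f"max real eigenvalue of gamma*J is {gamma * max_real_eig(J):.4f} >= 1"
        )
    n = J.shape[0]
    return np.linalg.solve(np.eye(n) - gamma * J, phi)


def choose_tmax(gamma: float, tol: float = 1e-4) -> int:
    """Number of recurrent steps: smallest t with ``gamma**t < tol`` (min 1)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    if gamma == 0:
        return 1
    t = max(0, int(np.ceil(np.log(tol) / np.log(gamma))))
    while gamma ** t >= tol:
        t += 1
    while t > 0 and gamma ** (t - 1) < tol:
        t -= 1
    return max(1, t)


def steady_state_truncated(J: np.ndarray, gamma: float, phi: np.ndarray, t_max: int) -> np.ndarray:
    """Finite power series ``x = sum_{t=0}^{t_max} gamma^t J^t phi``.

    Computed by iterated matrix-vector products, never explicit powers.
    """
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    J = np.asarray(J, dtype=float)
    phi = np.asarray(phi, dtype=float)
    x = phi.copy()
    term = phi.copy()
    for _ in range(t_max):
        term = gamma * (J @ term)
        x += term
    return x


def steady_state_tanh(J: np.ndarray, gamma: float, phi: np.ndarray, t_max: int) -> np.ndarray:
    """Iterative steady state with a saturating nonlinearity.

    Runs ``x <- gamma J tanh(x) + phi`` for ``t_max`` steps from ``x = 0``
    (the unit-step-size discretization of the rate dynamics).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    J = np.asarray(J, dtype=float)
    phi = np.asarray(phi, dtype=float)
    x = np.zeros_like(phi)
    for _ in range(t_max):
        x = gamma * (J @ np.tanh(x)) + phi
        if not np.all(np.isfinite(x)):
            raise UnstableDynamicsError("non-finite activity during iterative dynamics")
    return x


def weight_update(J: np.ndarray, x_t: np.ndarray, x_prev: np.ndarray, eta) -> np.ndarray:
    """STDP + decorrelative-normalization weight change.

    ``dJ_ij = eta_j * (x_i(t) x_j(t-1) - x_j(t-1) sum_k J_ik x_k(t-1))``,
    with ``eta`` indexed by the presynaptic neuron j (column-wise; a scalar
    eta is broadcast).
    """
    x_t = np.asarray(x_t, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    eta = np.asarray(eta, dtype=float)
    dJ = np.outer(x_t, x_prev) - np.outer(J @ x_prev, x_prev)
    return dJ * eta


def update_trace(n: np.ndarray, x_t: np.ndarray, lambda_: float, alpha_n: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Trace and adaptive learning rate, current activity included.

    ``n' = alpha_n * x_t + lambda_ * n`` and ``eta_j = min(1 / n'_j, 1)``
    with ``eta_j = 1`` for zero-trace neurons (full-strength one-shot
    learning on first activation).
    """
    n_new = alpha_n * np.asarray(x_t, dtype=float) + lambda_ * np.asarray(n, dtype=float)
    return n_new, _eta_from_trace(n_new)


def _eta_from_trace(n: np.ndarray) -> np.ndarray:
    eta = np.ones_like(n)
    pos = n > 0
    eta[pos] = np.minimum(1.0 / n[pos], 1.0)
    return eta


def _learning_eta(state: RNNState, x_t: np.ndarray, cfg: RNNConfig) -> np.ndarray:
    """Per-presynaptic learning rates for the current step; mutates the trace.

    Under ``exclude_current`` the trace is decayed, eta taken from the strict
    past, and the current activity folded in afterwards; under
    ``include_current`` the Algorithm-style ordering is used.
    """
    if cfg.lr_mode == "static":
        state.n, _ = update_trace(state.n, x_t, cfg.lambda_, cfg.alpha_n)
        return np.full(x_t.shape, cfg.eta_static)
    if cfg.trace_convention == "include_current":
        state.n, eta = update_trace(state.n, x_t, cfg.lambda_, cfg.alpha_n)
        return eta
    state.n = cfg.lambda_ * state.n
    eta = _eta_from_trace(state.n)
    state.n = state.n + cfg.alpha_n * x_t
    return eta


def _activity(J: np.ndarray, gamma: float, phi: np.ndarray, cfg: RNNConfig, check_stability: bool) -> np.ndarray:
    if gamma == 0:
        return np.asarray(phi, dtype=float).copy()
    if cfg.nonlinearity == "tanh":
        return steady_state_tanh(J, gamma, phi, choose_tmax(gamma, cfg.tol_tmax))
    if cfg.dynamics == "truncated":
        return steady_state_truncated(J, gamma, phi, choose_tmax(gamma, cfg.tol_tmax))
    return steady_state_linear(J, gamma, phi, check_stability=check_stability)


def step_learn(state: RNNState, phi_t: np.ndarray, cfg: RNNConfig, check_stability: bool = False) -> tuple[RNNState, np.ndarray]:
    """One learning-mode step: activity, trace/eta, weight update.

    Mutates and returns ``state`` along with the step's activity.  Stability
    checks are deferred to the session logging cadence by default.
    """
    phi_t = np.asarray(phi_t, dtype=float)
    x_t = _activity(state.J, cfg.gamma_B, phi_t, cfg, check_stability)
    if not np.all(np.isfinite(x_t)):
        raise UnstableDynamicsError("non-finite activity in learning mode")
    eta = _learning_eta(state, x_t, cfg)
    state.J += weight_update(state.J, x_t, state.x_prev, eta)
    state.x_prev = x_t
    state.t += 1
    return state, x_t


def step_retrieve(state: RNNState, phi_t: np.ndarray, cfg: RNNConfig, gamma_R: float | None = None) -> np.ndarray:
    """One retrieval-mode step: pure readout, no state mutation."""
    gamma = cfg.gamma_R if gamma_R is None else gamma_R
    return _activity(state.J, gamma, np.asarray(phi_t, dtype=float), cfg, check_stability=True)


def walk_inputs(walk, feature_set=None) -> np.ndarray:
    """Stack the per-step input vectors for a walk (one-hot if no features)."""
    states = walk.states
    if feature_set is None:
        n = walk.env.n_states
        X = np.zeros((states.size, n))
        X[np.arange(states.size), states] = 1.0
        return X
    return feature_set.Phi[states]


@dataclass
class SessionResult:
    """Outcome of :func:`run_session`."""

    activity: np.ndarray
    state: RNNState
    log: pd.DataFrame
    events: list
    completed: bool


def run_session(
    inputs: np.ndarray,
    cfg: RNNConfig,
    schedule: np.ndarray | None = None,
    rule: object = "stdp_decorrelative",
    oracle_T: np.ndarray | None = None,
    log_every: int = 100,
    halt_on_instability: bool = True,
    record_activity: bool = True,
) -> SessionResult:
    """Run a full learning/retrieval session over an input stream.

    Parameters
    ----------
    inputs:
        Steps x N array of input vectors (see :func:`walk_inputs`).
    schedule:
        Per-step mode flags, 0 = learning, 1 = retrieval; all-learning if
        omitted.
    rule:
        ``"stdp_decorrelative"`` (the default local rule),
        ``"independent"`` (Oja-like per-synapse normalization), or a
        :class:`srnn.plasticity.PlasticityKernel` for the kernel-generalized
        rule.
    oracle_T:
        Optional ground-truth transition matrix; logs MAE of ``J^T`` to it.
    log_every:
        Cadence (steps) of the metrics log, where spectral stability is also
        checked; on instability an event is recorded and, by default,
        learning halts with the state preserved for inspection.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2:
        raise ValueError("inputs must be a steps x N array")
    n_steps, n_neurons = inputs.shape
    if schedule is None:
        schedule = np.zeros(n_steps, dtype=int)
    schedule = np.asarray(schedule, dtype=int)
    if schedule.shape != (n_steps,):
        raise ValueError("schedule length must match the input stream")

    from . import plasticity as _plasticity  # deferred: avoids import cycle
    from .baselines import independent_norm_update

    kernel = rule if isinstance(rule, _plasticity.PlasticityKernel) else None
    if kernel is not None:
        buffer = _plasticity.ActivityBuffer(kernel.t_k, n_neurons)

    state = RNNState.zeros(n_neurons)
    activity = np.zeros((n_steps, n_neurons)) if record_activity else None
    records: list[dict] = []
    events: list[tuple] = []
    completed = True

    def log_row(step: int) -> bool:
        lam = max_real_eig(state.J) if np.all(np.isfinite(state.J)) else np.inf
        row = {
            "step": step,
            "row_sum_mean": float(state.J.sum(axis=0).mean()),
            "max_real_eig": lam,
            "gamma_max_eig": cfg.gamma_B * lam,
        }
        if oracle_T is not None:
            row["mae_T"] = mae_matrix(state.J.T, oracle_T)
        records.append(row)
        return np.isfinite(lam) and cfg.gamma_B * lam < 1.0

    for t in range(n_steps):
        phi = inputs[t]
        try:
            if schedule[t] == 1:
                x_t = step_retrieve(state, phi, cfg)
                state.x_prev = x_t
                state.t += 1
            elif kernel is not None:
                x_t = _activity(state.J, cfg.gamma_B, phi, cfg, check_stability=False)
                if not np.all(np.isfinite(x_t)):
                    raise UnstableDynamicsError("non-finite activity in learning mode")
                x_prev = state.x_prev
                buffer.push(x_t)
                if cfg.lr_mode == "static":
                    state.n = kernel.alpha_n * x_t + cfg.lambda_ * state.n
                    eta = np.full(n_neurons, cfg.eta_static)
                elif cfg.trace_convention == "include_current":
                    state.n = kernel.alpha_n * x_t + cfg.lambda_ * state.n
                    eta = _eta_from_trace(state.n)
                else:
                    state.n = cfg.lambda_ * state.n
                    eta = _eta_from_trace(state.n)
                    state.n = state.n + kernel.alpha_n * x_t
                dJ = _plasticity.kernel_delta_J(state.J, buffer, kernel, x_prev)
                state.J += dJ * eta
                state.x_prev = x_t
                state.t += 1
            elif rule == "independent":
                x_t = _activity(state.J, cfg.gamma_B, phi, cfg, check_stability=False)
                if not np.all(np.isfinite(x_t)):
                    raise UnstableDynamicsError("non-finite activity in learning mode")
                eta = _learning_eta(state, x_t, cfg)
                state.J += independent_norm_update(state.J, x_t, state.x_prev, eta)
                state.x_prev = x_t
                state.t += 1
            else:
                state, x_t = step_learn(state, phi, cfg)
        except UnstableDynamicsError:
            events.append(("instability", t))
            completed = False
            log_row(t)
            break
        if record_activity:
            activity[t] = x_t
        if (t + 1) % log_every == 0 or t == n_steps - 1:
            stable = log_row(t + 1)
            if not stable and schedule[t] == 0:
                events.append(("instability", t + 1))
                if halt_on_instability:
                    completed = False
                    if record_activity:
                        activity = activity[: t + 1]
                    break

    log = pd.DataFrame.from_records(records)
    if activity is None:
        activity = np.zeros((0, n_neurons))
    return SessionResult(activity=activity, state=state, log=log, events=events, completed=completed)
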