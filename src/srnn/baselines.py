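"""Comparison models: feedforward TD learner, independent normalization, random net.

The FF-TD model is the canonical successor-representation learner: the SR
matrix M lives in the feedforward weights from input to output neurons and is
updated by temporal-difference learning.  Unlike the recurrent rule, the TD
update at synapse j->i needs information about multiple input neurons, so it
is not local.

The independent-normalization variant replaces the decorrelative term of the
recurrent rule with a per-synapse Oja-like decay; on one-hot activity the two
rules coincide exactly, on dense correlated activity they diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import mae_matrix, td_loss

__all__ = [
    "FFState",
    "fftd_update_onehot",
    "fftd_update_features",
    "fftd_lr_search",
    "independent_norm_update",
    "random_network",
    "DEFAULT_ETA_GRID",
]

#: default learning-rate grid for the FF-TD search: logarithmic 1e-3 .. 10^-0.5
DEFAULT_ETA_GRID = tuple(10 ** e for e in np.linspace(-3.0, -0.5, 6))


@dataclass
class FFState:
    """Feedforward SR weights; ``M[j, i]`` maps source state j to predicted state i."""

    M: np.ndarray
    eta: float

    @classmethod
    def zeros(cls, n_states: int, eta: float) -> "FFState":
        return cls(np.zeros((n_states, n_states)), eta)


def fftd_update_onehot(state: FFState, s: int, s_next: int, gamma: float, eta: float | None = None) -> FFState:
    """One-hot TD update: only row ``s`` changes, its diagonal target carries +1.

    ``dM[s, i] = eta * ([i == s] + gamma M[s_next, i] - M[s, i])``.
    """
    M = state.M
    n = M.shape[0]
    if not (0 <= s < n and 0 <= s_next < n):
        raise ValueError("invalid state index")
    eta = state.eta if eta is None else eta
    target = gamma * M[s_next] - M[s]
    target = target.copy()
    target[s] += 1.0
    M[s] += eta * target
    return state


def fftd_update_features(state: FFState, phi: np.ndarray, phi_next: np.ndarray, gamma: float, eta: float | None = None) -> FFState:
    """Feature-based TD update ``dM^T = eta (phi + gamma M^T phi' - M^T phi) phi^T``.

    Reduces exactly to the one-hot update when both inputs are one-hot.
    """
    eta = state.eta if eta is None else eta
    phi = np.asarray(phi, dtype=float)
    phi_next = np.asarray(phi_next, dtype=float)
    MT = state.M.T
    delta = phi + gamma * (MT @ phi_next) - MT @ phi
    state.M += eta * np.outer(phi, delta)
    return state


def run_fftd(inputs: np.ndarray, gamma: float, eta: float) -> FFState:
    """Train FF-TD over a stream of input vectors (consecutive pairs)."""
    inputs = np.asarray(inputs, dtype=float)
    n = inputs.shape[1]
    state = FFState.zeros(n, eta)
    for t in range(1, inputs.shape[0]):
        fftd_update_features(state, inputs[t - 1], inputs[t], gamma)
    return state


def fftd_lr_search(
    eta_grid,
    inputs: np.ndarray,
    gamma: float,
    true_M: np.ndarray | None = None,
    td_samples: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[float, dict[float, float]]:
    """Grid search over the TD learning rate.

    The objective is the MAE to the true M when it is known (one-hot inputs),
    otherwise the TD loss on the supplied transition samples.  Returns the
    best eta and the full error curve.
    """
    eta_grid = list(eta_grid)
    if not eta_grid:
        raise ValueError("empty learning-rate grid")
    if true_M is None and td_samples is None:
        raise ValueError("need either true_M or td_samples as the objective")
    errors: dict[float, float] = {}
    for eta in eta_grid:
        state = run_fftd(inputs, gamma, eta)
        if true_M is not None:
            errors[eta] = mae_matrix(state.M, true_M)
        else:
            errors[eta] = td_loss(state.M, td_samples, gamma)
    best = min(errors, key=errors.get)
    return best, errors


def independent_norm_update(J: np.ndarray, x_t: np.ndarray, x_prev: np.ndarray, eta) -> np.ndarray:
    """Oja-like per-synapse normalization update.

    ``dJ_ij = eta_j * (x_i(t) x_j(t-1) - J_ij x_j(t-1)^2)`` — identical to
    the decorrelative rule for one-hot activity, but normalizes each synapse
    independently for dense activity.
    """
    x_t = np.asarray(x_t, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    eta = np.asarray(eta, dtype=float)
    dJ = np.outer(x_t, x_prev) - J * (x_prev ** 2)[None, :]
    return dJ * eta


def random_network(n: int, reference_J: np.ndarray, seed: int) -> np.ndarray:
    """Random weights of magnitude comparable to a learned matrix.

    I.i.d. normal entries matching the elementwise mean and standard
    deviation of ``reference_J`` (first two moments only).
    """
    reference_J = np.asarray(reference_J, dtype=float)
    mu = float(reference_J.mean())
    sd = float(reference_J.std())
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full((n, n), mu)
    return rng.normal(mu, sd, size=(n, n))
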