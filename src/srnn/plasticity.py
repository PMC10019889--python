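"""Kernel-generalized plasticity rule and the kernel-parameter search harness.

The lag-1 STDP potentiation of the base rule generalizes to a convolution of
the activity history with a pair of exponential kernels: a pre->post side
``K+(t) = A+ exp(-t/tau+)`` and a post->pre side ``K-(t) = A- exp(-t/tau-)``
(amplitude sign free), each with finite temporal support ``t_k`` steps.
Self-synapse updates carry a separate scale ``alpha_d`` and the trace update
a scale ``alpha_n``.

The base rule is the special case of a kernel supported at lag 1 only
(constructed explicitly, not as a tau -> 0 limit).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .envs import Walk, empirical_transition_matrix

__all__ = [
    "PlasticityKernel",
    "ActivityBuffer",
    "delta_lag1_kernel",
    "kernel_eval",
    "kernel_delta_J",
    "kernel_weight_update",
    "kernel_search",
    "nelder_mead_optimizer",
]

#: default temporal support of the kernels, in steps
DEFAULT_T_K = 20


@dataclass(frozen=True)
class PlasticityKernel:
    """Exponential pre->post / post->pre plasticity kernel parameters.

    ``weights_plus``/``weights_minus`` may carry explicit per-lag weight
    arrays (lags 0..t_k), overriding the exponential parameterization — used
    for the delta-like lag-1 kernel that reproduces the base rule.
    """

    A_plus: float = 1.0
    tau_plus: float = 1.0
    A_minus: float = 0.0
    tau_minus: float = 1.0
    alpha_d: float = 1.0
    alpha_n: float = 1.0
    t_k: int = DEFAULT_T_K
    weights_plus: np.ndarray | None = field(default=None)
    weights_minus: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.t_k < 1:
            raise ValueError("t_k must be >= 1")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.weights_plus is None and self.A_plus <= 0:
            raise ValueError("the pre->post kernel amplitude must be positive")
        for name in ("weights_plus", "weights_minus"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float)
                if w.shape != (self.t_k + 1,):
                    raise ValueError(f"{name} must have length t_k + 1")
                object.__setattr__(self, name, w)

    def lag_weights(self, t_k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-lag weights (lags 0..t_k) of the two kernel sides.

        ``t_k`` defaults to the kernel's own support; explicit weight arrays
        are truncated or zero-padded to the requested length.
        """
        t_k = self.t_k if t_k is None else t_k
        lags = np.arange(t_k + 1)

        def build(explicit, A, tau):
            if explicit is None:
                return kernel_eval(A, tau, lags)
            out = np.zeros(t_k + 1)
            m = min(t_k + 1, explicit.size)
            out[:m] = explicit[:m]
            return out

        return (
            build(self.weights_plus, self.A_plus, self.tau_plus),
            build(self.weights_minus, self.A_minus, self.tau_minus),
        )


def delta_lag1_kernel(alpha_d: float = 1.0, alpha_n: float = 1.0, t_k: int = DEFAULT_T_K) -> PlasticityKernel:
    """Kernel supported at lag 1 only: recovers the base STDP rule exactly."""
    w_plus = np.zeros(t_k + 1)
    w_plus[1] = 1.0
    return PlasticityKernel(
        A_plus=1.0,
        alpha_d=alpha_d,
        alpha_n=alpha_n,
        t_k=t_k,
        weights_plus=w_plus,
        weights_minus=np.zeros(t_k + 1),
    )


def kernel_eval(A: float, tau: float, t) -> np.ndarray | float:
    """Exponential kernel value ``A * exp(-t / tau)`` at lag(s) ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lags must be non-negative")
    out = A * np.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


class ActivityBuffer:
    """Ring buffer of the last ``t_k + 1`` activity vectors (newest first)."""

    def __init__(self, t_k: int, n_neurons: int):
        self.t_k = t_k
        self.n_neurons = n_neurons
        self._buf: deque[np.ndarray] = deque(maxlen=t_k + 1)

    def push(self, x: np.ndarray) -> None:
        self._buf.appendleft(np.asarray(x, dtype=float))

    def __len__(self) -> int:
        return len(self._buf)

    def lagged(self) -> np.ndarray:
        """(t_k + 1) x N array of activity at lags 0..t_k (zero-padded)."""
        out = np.zeros((self.t_k + 1, self.n_neurons))
        for lag, x in enumerate(self._buf):
            out[lag] = x
        return out


def kernel_delta_J(J: np.ndarray, buffer: ActivityBuffer, kernel: PlasticityKernel, x_prev: np.ndarray) -> np.ndarray:
    """Un-scaled kernel weight change for the current step.

    ``k+``/``k-`` are the kernel-weighted sums of the buffered activity
    (lags 0..t_k, lag 0 = current step); the raw change is
    ``x(t) k+^T + k- x(t)^T`` with diagonal entries replaced by the
    ``alpha_d``-scaled pre->post term, minus the decorrelative normalization
    ``(J x(t-1)) x(t-1)^T``.
    """
    if len(buffer) == 0:
        raise ValueError("activity buffer is empty")
    lagged = buffer.lagged()
    x_t = lagged[0]
    w_plus, w_minus = kernel.lag_weights(buffer.t_k)
    k_plus = w_plus @ lagged
    k_minus = w_minus @ lagged
    dJK = np.outer(x_t, k_plus) + np.outer(k_minus, x_t)
    np.fill_diagonal(dJK, kernel.alpha_d * x_t * k_plus)
    x_prev = np.asarray(x_prev, dtype=float)
    return dJK - np.outer(J @ x_prev, x_prev)


def kernel_weight_update(state, buffer: ActivityBuffer, kernel: PlasticityKernel, lambda_: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Kernel weight change plus the ``alpha_n``-scaled trace update.

    Does not mutate ``state``; returns ``(dJ, n_new)`` where ``dJ`` is the
    un-eta-scaled change and ``n_new = alpha_n x(t) + lambda n``.
    """
    dJ = kernel_delta_J(state.J, buffer, kernel, state.x_prev)
    x_t = buffer.lagged()[0]
    n_new = kernel.alpha_n * x_t + lambda_ * state.n
    return dJ, n_new


def nelder_mead_optimizer(maxiter: int = 80):
    """Default derivative-free optimizer satisfying minimize(f, x0, seed)."""

    def minimize(f, x0, seed):  # noqa: ARG001 - deterministic, seed unused
        res = _scipy_minimize(f, x0, method="Nelder-Mead", options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-6})
        return res.x, float(res.fun)

    return minimize


def _cell_kernel(cell: dict, params: np.ndarray, t_k: int) -> PlasticityKernel:
    a_plus, a_minus_mag, alpha_d, alpha_n = params
    a_plus = max(abs(a_plus), 1e-9)
    alpha_n = max(abs(alpha_n), 1e-6)
    if cell.get("kind") == "delta_lag1":
        w = np.zeros(t_k + 1)
        w[1] = a_plus
        return PlasticityKernel(
            A_plus=a_plus,
            alpha_d=alpha_d,
            alpha_n=alpha_n,
            t_k=t_k,
            weights_plus=w,
            weights_minus=np.zeros(t_k + 1),
        )
    return PlasticityKernel(
        A_plus=a_plus,
        tau_plus=cell["tau_plus"],
        A_minus=cell["sign_minus"] * abs(a_minus_mag),
        tau_minus=cell["tau_minus"],
        alpha_d=alpha_d,
        alpha_n=alpha_n,
        t_k=t_k,
    )


def kernel_search(
    grid: list[dict],
    walks: list[Walk],
    n_inits: int = 3,
    seed: int = 0,
    optimizer=None,
    t_k: int = DEFAULT_T_K,
    sentinel_error: float = 1.0,
    clip: float = 0.03,
) -> pd.DataFrame:
    """Grid search over kernel shapes with derivative-free amplitude fitting.

    Each grid cell fixes the sign of the post->pre side and the two time
    constants (or is the explicit ``{"kind": "delta_lag1"}`` cell); the free
    amplitudes ``(A+, |A-|, alpha_d, alpha_n)`` are fitted by the injected
    optimizer to minimize the mean-squared error between the final learned J
    and the transposed empirical transition matrix, averaged over the supplied
    walk distribution.  The minimum over ``n_inits`` initializations is
    recorded per cell; cells whose fitted ``A+`` is negligibly small relative
    to the grid's median learned amplitude are set to a high-error sentinel,
    and a clipped error column is provided for heatmap views.
    """
    from .model import RNNConfig, run_session, walk_inputs  # deferred import cycle

    if len(grid) == 0:
        raise ValueError("empty kernel grid")
    if len(walks) == 0:
        raise ValueError("empty walk distribution")
    optimizer = optimizer or nelder_mead_optimizer()

    cfg = RNNConfig(gamma_B=0.0, lr_mode="adaptive", lambda_=1.0)
    prepared = [
        (walk_inputs(w), empirical_transition_matrix(w)) for w in walks
    ]

    def objective_for(cell: dict):
        def objective(params: np.ndarray) -> float:
            kernel = _cell_kernel(cell, params, t_k)
            total = 0.0
            for X, emp in prepared:
                res = run_session(X, cfg, rule=kernel, log_every=10 ** 9, record_activity=False)
                if not res.completed or not np.all(np.isfinite(res.state.J)):
                    return 1e6
                diff = (res.state.J.T - emp.T)[emp.visited]
                total += float(np.mean(diff ** 2))
            return total / len(prepared)

        return objective

    ss = np.random.SeedSequence(seed)
    rows = []
    for cell, cell_ss in zip(grid, ss.spawn(len(grid))):
        rng = np.random.default_rng(cell_ss)
        objective = objective_for(cell)
        best_err, best_params, failures = np.inf, None, 0
        inits = [np.array([1.0, 0.1, 1.0, 1.0])]
        inits += [rng.uniform([0.05, 0.0, 0.0, 0.2], [2.0, 1.0, 2.0, 2.0]) for _ in range(max(0, n_inits - 1))]
        for i, x0 in enumerate(inits):
            try:
                x_best, f_best = optimizer(objective, x0, int(rng.integers(2 ** 31)))
            except Exception:
                failures += 1
                continue
            if f_best < best_err:
                best_err, best_params = f_best, x_best
        rows.append(
            {
                "kind": cell.get("kind", "exp"),
                "sign_minus": cell.get("sign_minus", 0),
                "tau_plus": cell.get("tau_plus", np.nan),
                "tau_minus": cell.get("tau_minus", np.nan),
                "min_error": best_err,
                "A_plus": abs(best_params[0]) if best_params is not None else np.nan,
                "A_minus": (cell.get("sign_minus", 0) * abs(best_params[1])) if best_params is not None else np.nan,
                "alpha_d": best_params[2] if best_params is not None else np.nan,
                "alpha_n": abs(best_params[3]) if best_params is not None else np.nan,
                "n_failures": failures,
            }
        )
    table = pd.DataFrame.from_records(rows)
    # sentinel for cells whose fitted potentiation amplitude vanished
    med_amp = np.nanmedian(table["A_plus"])
    negligible = table["A_plus"] < 1e-3 * max(med_amp, 1e-12)
    table.loc[negligible, "min_error"] = sentinel_error
    table["min_error_clipped"] = np.minimum(table["min_error"], clip)
    return table
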