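"""Discrete state-space environments and random-walk simulation.

An agent's foraging behaviour is modelled as a Markov chain over a discretized
arena: a 1D circular track (``ring``) or a 2D square arena (``grid``).  One
simulation timestep corresponds to 1/3 s and spatial bins are 5 cm apart
(15 cm/s movement), so a half-hour session is 5,400 steps.

State indexing is 0-based everywhere; ring neighbours wrap modulo ``n_states``
and grid states enumerate row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Environment",
    "ActionModel",
    "Walk",
    "TransitionMatrix",
    "ring",
    "grid",
    "ring_actions",
    "grid_actions",
    "true_transition_matrix",
    "simulate_walk",
    "empirical_transition_matrix",
    "simulate_foraging_trajectory",
    "discretize_trajectory",
]

#: steps per second used throughout (one timestep = 1/3 s)
DEFAULT_DT = 1.0 / 3.0
#: spatial bin spacing in cm
DEFAULT_BIN_SIZE = 5.0
#: a half-hour 1D session at 3 steps/s
DEFAULT_SESSION_STEPS = 5400


class CoverageError(ValueError):
    """Raised when a trajectory covers too little of the arena."""


@dataclass(frozen=True)
class Environment:
    """A discretized arena.

    Parameters
    ----------
    geometry:
        ``"ring"`` (1D circular track) or ``"grid"`` (2D square arena).
    n_states:
        Number of spatial bins; for a grid this is ``h * w``.
    shape:
        ``(h, w)`` for grids, ``None`` for rings.
    bin_size:
        Bin spacing in cm.
    dt:
        Duration of one timestep in seconds.
    """

    geometry: str
    n_states: int
    shape: tuple[int, int] | None = None
    bin_size: float = DEFAULT_BIN_SIZE
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.geometry not in ("ring", "grid"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_states < 2:
            raise ValueError("n_states must be at least 2")
        if self.bin_size <= 0 or self.dt <= 0:
            raise ValueError("bin_size and dt must be positive")
        if self.geometry == "grid":
            if self.shape is None:
                raise ValueError("grid environments need a (h, w) shape")
            h, w = self.shape
            if h < 2 or w < 2 or h * w != self.n_states:
                raise ValueError("grid shape must be (h, w) with h, w >= 2 and h*w == n_states")
        elif self.shape is not None:
            raise ValueError("ring environments take no shape")


def ring(n_states: int, bin_size: float = DEFAULT_BIN_SIZE, dt: float = DEFAULT_DT) -> Environment:
    """A circular track with ``n_states`` bins."""
    return Environment("ring", n_states, None, bin_size, dt)


def grid(h: int, w: int, bin_size: float = DEFAULT_BIN_SIZE, dt: float = DEFAULT_DT) -> Environment:
    """A 2D arena of ``h`` x ``w`` bins, states enumerated row-major."""
    return Environment("grid", h * w, (h, w), bin_size, dt)


@dataclass(frozen=True)
class ActionModel:
    """Per-step action probabilities.

    Ring actions are ``(forward, stay, backward)``.  Grid actions are a
    probability vector over ``(stay, up, down, left, right)``; moves off the
    arena edge are removed per state and the remainder renormalized.
    """

    geometry: str
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("action probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("action probabilities must sum to 1")
        n_expected = 3 if self.geometry == "ring" else 5
        if len(self.probs) != n_expected:
            raise ValueError(f"{self.geometry} actions need {n_expected} probabilities")


def ring_actions(p_fwd: float = 1 / 3, p_stay: float = 1 / 3, p_back: float = 1 / 3) -> ActionModel:
    return ActionModel("ring", (p_fwd, p_stay, p_back))


def grid_actions(probs: tuple[float, ...] | None = None) -> ActionModel:
    """Grid action model; uniform over {stay, 4 axis neighbours} by default."""
    if probs is None:
        probs = (0.2,) * 5
    return ActionModel("grid", tuple(probs))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix, ``T[j, i] = P(next=i | current=j)``.

    ``visited`` flags rows with at least one observed departure; for
    ground-truth matrices every row is flagged visited.  Empirical rows with
    zero visits are all-zero, never NaN, and downstream error computations
    exclude them.
    """

    T: np.ndarray
    kind: str = "ground_truth"
    visited: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        object.__setattr__(self, "T", T)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("T must be square")
        if self.visited is None:
            object.__setattr__(self, "visited", np.ones(T.shape[0], dtype=bool))
        else:
            object.__setattr__(self, "visited", np.asarray(self.visited, dtype=bool))
        if np.any(T < -1e-12) or np.any(T > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = T[self.visited].sum(axis=1)
        tol = 1e-9 if self.kind == "empirical" else 1e-9
        if rows.size and np.max(np.abs(rows - 1.0)) > tol:
            raise ValueError("visited rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


@dataclass(frozen=True)
class Walk:
    """A realized state sequence on an environment."""

    states: np.ndarray
    env: Environment
    seed: int | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", s)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("a walk needs at least one state")
        if np.any(s < 0) or np.any(s >= self.env.n_states):
            raise ValueError("state indices out of range")

    def __len__(self) -> int:
        return self.states.size


def _grid_moves(env: Environment) -> list[tuple[int, int]]:
    # (drow, dcol) for (stay, up, down, left, right)
    return [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]


def true_transition_matrix(env: Environment, actions: ActionModel) -> TransitionMatrix:
    """Ground-truth T implied by the action model on the environment.

    On the ring, ``T[j, (j+1) % n] = p_fwd``, ``T[j, j] = p_stay`` and
    ``T[j, (j-1) % n] = p_back``.  On the grid, probability mass of
    out-of-bounds moves is dropped and each row renormalized.
    """
    if actions.geometry != env.geometry:
        raise ValueError(f"action model for {actions.geometry!r} used on {env.geometry!r} environment")
    n = env.n_states
    T = np.zeros((n, n))
    if env.geometry == "ring":
        p_fwd, p_stay, p_back = actions.probs
        for j in range(n):
            T[j, (j + 1) % n] += p_fwd
            T[j, j] += p_stay
            T[j, (j - 1) % n] += p_back
    else:
        h, w = env.shape  # type: ignore[misc]
        moves = _grid_moves(env)
        for j in range(n):
            r, c = divmod(j, w)
            for p, (dr, dc) in zip(actions.probs, moves):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    T[j, rr * w + cc] += p
        T /= T.sum(axis=1, keepdims=True)
    return TransitionMatrix(T, "ground_truth")


def simulate_walk(
    env: Environment,
    actions: ActionModel,
    n_steps: int,
    seed: int,
    start: int = 0,
) -> Walk:
    """Simulate a seeded random walk of ``n_steps`` transitions.

    Returns a walk of length ``n_steps + 1``; identical seeds yield identical
    walks.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 <= start < env.n_states:
        raise ValueError(f"invalid start index {start}")
    T = true_transition_matrix(env, actions).T
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    states = np.empty(n_steps + 1, dtype=int)
    states[0] = start
    s = start
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t + 1] = s
    return Walk(states, env, seed)


def empirical_transition_matrix(walk: Walk) -> TransitionMatrix:
    """Empirical T from observed transitions.

    ``T[j, i]`` is the count of j->i transitions divided by the number of
    departures from j.  Rows of states never seen as a source are all-zero
    and flagged unvisited.
    """
    s = walk.states
    if s.size < 2:
        raise ValueError("walk must contain at least one transition")
    n = walk.env.n_states
    counts = np.zeros((n, n))
    np.add.at(counts, (s[:-1], s[1:]), 1.0)
    departures = counts.sum(axis=1)
    visited = departures > 0
    T = np.zeros_like(counts)
    T[visited] = counts[visited] / departures[visited, None]
    return TransitionMatrix(T, "empirical", visited)


def simulate_foraging_trajectory(
    duration_min: float = 28.0,
    fps: float = 30.0,
    arena_cm: float = 70.0,
    seed: int = 0,
    step_std_cm: float = 2.0,
) -> dict[str, np.ndarray]:
    """Synthetic continuous 2D foraging trajectory (random-walk positions).

    Emulates position-tracking of an animal randomly foraging in a square
    arena: smooth reflected Gaussian steps at the camera frame rate.  Returns
    ``{"t": seconds, "x": cm, "y": cm}``.
    """
    n = int(round(duration_min * 60.0 * fps))
    if n < 1:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_std_cm, size=(n, 2))
    pos = np.cumsum(steps, axis=0) + arena_cm / 2.0
    # reflect into [0, arena_cm)
    pos = np.abs(np.mod(pos, 2 * arena_cm) - arena_cm)
    pos = np.clip(pos, 0.0, np.nextafter(arena_cm, 0.0))
    t = np.arange(n) / fps
    return {"t": t, "x": pos[:, 0], "y": pos[:, 1]}


def discretize_trajectory(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    grid_h: int,
    grid_w: int,
    target_fps: float = 3.0,
    min_coverage: float = 0.85,
    window_minutes: float | None = None,
    arena_bounds: tuple[float, float, float, float] | None = None,
    bin_size: float = DEFAULT_BIN_SIZE,
) -> Walk:
    """Discretize a continuous (x, y) trajectory into a grid-state walk.

    The trajectory is decimated to ``target_fps``, optionally truncated to the
    first ``window_minutes``, and positions are binned on a ``grid_h`` x
    ``grid_w`` grid spanning the data (or explicit ``arena_bounds``
    ``(xmin, xmax, ymin, ymax)``).  Raises :class:`CoverageError` if the
    fraction of distinct states visited falls below ``min_coverage``; callers
    wanting the resample-until-covered behaviour should loop over seeds.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    input_fps = (t.size - 1) / (t[-1] - t[0]) if t.size > 1 else target_fps
    stride = max(1, int(round(input_fps / target_fps)))
    t, x, y = t[::stride], x[::stride], y[::stride]
    if window_minutes is not None:
        keep = t - t[0] < window_minutes * 60.0
        t, x, y = t[keep], x[keep], y[keep]
    if arena_bounds is None:
        arena_bounds = (x.min(), x.max(), y.min(), y.max())
    xmin, xmax, ymin, ymax = arena_bounds
    if np.any((x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)):
        raise ValueError("positions outside arena bounds")
    col = np.clip(((x - xmin) / (xmax - xmin) * grid_w).astype(int), 0, grid_w - 1)
    row = np.clip(((y - ymin) / (ymax - ymin) * grid_h).astype(int), 0, grid_h - 1)
    states = row * grid_w + col
    coverage = np.unique(states).size / (grid_h * grid_w)
    if coverage < min_coverage:
        raise CoverageError(
            f"arena coverage {coverage:.3f} below required {min_coverage:.3f}"
        )
    env = grid(grid_h, grid_w, bin_size=bin_size, dt=1.0 / target_fps)
    return Walk(states, env)
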