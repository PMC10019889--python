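"""Per-state input feature encodings.

States are fed to the network as N-dimensional input vectors ``phi``.  The
simplest choice is a one-hot code; more realistic hippocampal inputs are
dense, spatially correlated features.  Those are generated by drawing random
binary vectors (on-probability ``p``), blurring each feature dimension across
the state geometry with a Gaussian of scale ``sigma`` (cm), then
min-subtracting and max-normalizing per feature dimension.

Sparsity ``s`` of a feature set is the median over states of the L1 norm of
the state's vector divided by N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .envs import Environment

__all__ = [
    "FeatureSet",
    "one_hot_features",
    "generate_features",
    "measure_sparsity",
    "spatial_correlation_profile",
    "state_distances",
]


@dataclass(frozen=True)
class FeatureSet:
    """States-by-features matrix ``Phi`` with generation metadata.

    ``Phi[s]`` is the input vector presented when the agent occupies state
    ``s``.  ``degenerate`` flags feature dimensions that were constant before
    normalization (zeroed out, excluded from correlation profiles).
    """

    Phi: np.ndarray
    env: Environment
    p: float
    sigma: float
    s: float
    seed: int | None = None
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        Phi = np.asarray(self.Phi, dtype=float)
        object.__setattr__(self, "Phi", Phi)
        if Phi.shape != (self.env.n_states, self.env.n_states):
            raise ValueError("Phi must be n_states x n_states")
        if np.any(Phi < -1e-12) or np.any(Phi > 1 + 1e-12):
            raise ValueError("feature entries must lie in [0, 1]")
        if self.degenerate is None:
            object.__setattr__(self, "degenerate", np.zeros(Phi.shape[1], dtype=bool))

    @property
    def n_states(self) -> int:
        return self.Phi.shape[0]


def one_hot_features(env: Environment) -> FeatureSet:
    """One-hot encoding: ``Phi`` is the identity, sparsity ``1/N``."""
    n = env.n_states
    return FeatureSet(np.eye(n), env, p=1.0 / n, sigma=0.0, s=1.0 / n)


def _blur_over_geometry(col: np.ndarray, env: Environment, sigma_bins: float) -> np.ndarray:
    """Gaussian blur of one feature dimension across the state geometry.

    The kernel is truncated at a radius of 1 standard deviation (and
    renormalized); rings wrap around, grids reflect at the boundary.
    """
    if sigma_bins <= 0:
        return col
    if env.geometry == "ring":
        return gaussian_filter1d(col, sigma_bins, mode="wrap", truncate=1.0)
    h, w = env.shape  # type: ignore[misc]
    return gaussian_filter(col.reshape(h, w), sigma_bins, mode="reflect", truncate=1.0).ravel()


def generate_features(env: Environment, p: float, sigma: float, seed: int) -> FeatureSet:
    """Random dense feature encodings at on-probability ``p``, blur ``sigma`` cm.

    Each of the N feature dimensions is an independent binary draw over
    states, blurred over the geometry, then min-subtracted and max-normalized
    (column-wise over states).  All-constant pre-normalization dimensions are
    flagged degenerate and zeroed.
    """
    if not 0 < p <= 1:
        raise ValueError("on-probability p must lie in (0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    n = env.n_states
    rng = np.random.default_rng(seed)
    Phi = (rng.random((n, n)) < p).astype(float)
    sigma_bins = sigma / env.bin_size
    for k in range(n):
        Phi[:, k] = _blur_over_geometry(Phi[:, k], env, sigma_bins)
    lo = Phi.min(axis=0)
    hi = Phi.max(axis=0)
    degenerate = hi - lo <= 1e-12
    Phi -= lo
    live = ~degenerate
    Phi[:, live] /= (hi - lo)[live]
    Phi[:, degenerate] = 0.0
    fs = FeatureSet(Phi, env, p=p, sigma=sigma, s=0.0, seed=seed, degenerate=degenerate)
    object.__setattr__(fs, "s", measure_sparsity(fs))
    return fs


def measure_sparsity(fs: FeatureSet) -> float:
    """Median over states of (L1 norm of the state's vector) / N."""
    Phi = fs.Phi
    if Phi.size == 0:
        raise ValueError("empty feature set")
    return float(np.median(np.abs(Phi).sum(axis=1) / Phi.shape[1]))


def state_distances(env: Environment) -> np.ndarray:
    """Pairwise spatial distances between states in cm."""
    n = env.n_states
    if env.geometry == "ring":
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d)
        return d * env.bin_size
    h, w = env.shape  # type: ignore[misc]
    r, c = np.divmod(np.arange(n), w)
    return np.hypot(r[:, None] - r[None, :], c[:, None] - c[None, :]) * env.bin_size


def spatial_correlation_profile(fs: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """Mean Pearson correlation of state vectors, binned by spatial distance.

    Returns ``(distances, mean_correlation)`` where distances are the unique
    pairwise bin distances (cm).  Degenerate feature dimensions are excluded.
    For ``sigma > 0`` the curve decreases with distance.
    """
    live = ~fs.degenerate
    X = fs.Phi[:, live]
    if X.shape[1] < 2:
        raise ValueError("need at least two non-degenerate feature dimensions")
    C = np.corrcoef(X)
    D = state_distances(fs.env)
    dists = np.unique(D)
    prof = np.array([C[D == d].mean() for d in dists])
    return dists, prof
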