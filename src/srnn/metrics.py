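"""Scalar evaluations: recovery errors, normalization, TD loss, stability.

Also houses the closed-form steady-state weight oracle
``J = R_phiphi(-1) R_phiphi(0)^{-1}`` built from raw lagged second moments of
the input series — for one-hot inputs this reduces to the transposed
empirical transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LaggedCorrelation",
    "mae_matrix",
    "row_sum_T",
    "td_loss",
    "max_real_eig",
    "stability_flag",
    "lagged_correlations",
    "closed_form_J",
]


class SingularCorrelationError(np.linalg.LinAlgError):
    """Zero-lag correlation matrix is singular and pseudo-inverse was not allowed."""


@dataclass(frozen=True)
class LaggedCorrelation:
    """Raw (non-centered, non-normalized) lagged second moments of an input series.

    ``R0[i, j]`` averages ``phi_i(t) phi_j(t)`` over the source frames of the
    observed transition pairs; ``Rm1[i, j]`` averages ``phi_i(t) phi_j(t-1)``
    over the same pairs.  Raw moments (not Pearson correlations) are used
    because only this convention reproduces ``J = T^T`` for one-hot inputs.
    """

    R0: np.ndarray
    Rm1: np.ndarray
    n_samples: int


def mae_matrix(A: np.ndarray, B: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean absolute error over (optionally row-masked) entries.

    ``mask`` is a boolean row flag vector; ``False`` rows (e.g. unvisited
    sources of an empirical transition matrix) are excluded.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    diff = np.abs(A - B)
    if mask is not None:
        diff = diff[np.asarray(mask, dtype=bool)]
    return float(diff.mean())


def row_sum_T(J: np.ndarray) -> tuple[float, np.ndarray]:
    """Row sums of the transition-matrix estimate encoded in ``J``.

    ``J`` estimates ``T^T``, so the row sums of the T estimate are the column
    sums of ``J``.  Returns ``(mean, per_row_vector)``; a correctly
    normalized estimate has every value equal to 1.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    sums = J.sum(axis=0)
    return float(sums.mean()), sums


def td_loss(M: np.ndarray, samples: list[tuple[np.ndarray, np.ndarray]], gamma: float) -> float:
    """Mean squared temporal-difference error over sampled transitions.

    For each observed pair ``(phi, phi')`` the TD error vector is
    ``phi + gamma M^T phi' - M^T phi``; the loss is the mean of its squared
    Euclidean norm over the sample set.
    """
    if len(samples) == 0:
        raise ValueError("need at least one transition sample")
    MT = np.asarray(M, dtype=float).T
    total = 0.0
    for phi, phi_next in samples:
        delta = phi + gamma * (MT @ phi_next) - MT @ phi
        total += float(delta @ delta)
    return total / len(samples)


def td_loss_readout(readout, samples: list[tuple[np.ndarray, np.ndarray]], gamma: float) -> float:
    """TD loss evaluated through an arbitrary readout ``phi -> M^T phi``.

    Used for recurrent readouts (e.g. the tanh steady state) where no explicit
    M matrix exists; reduces to :func:`td_loss` when
    ``readout = lambda phi: M.T @ phi``.
    """
    if len(samples) == 0:
        raise ValueError("need at least one transition sample")
    total = 0.0
    for phi, phi_next in samples:
        delta = phi + gamma * readout(phi_next) - readout(phi)
        total += float(delta @ delta)
    return total / len(samples)


def max_real_eig(J: np.ndarray) -> float:
    """Largest real part over the eigenvalue spectrum of ``J``."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    if not np.all(np.isfinite(J)):
        raise ValueError("J contains non-finite entries")
    return float(np.linalg.eigvals(J).real.max())


def stability_flag(J: np.ndarray, gamma: float) -> bool:
    """True iff the linear recurrent dynamics at gain ``gamma`` are stable.

    Unstable means the maximum real eigenvalue of ``gamma * J`` reaches 1.
    """
    return gamma * max_real_eig(J) < 1.0


def lagged_correlations(phi_series: np.ndarray) -> LaggedCorrelation:
    """Raw zero-lag and lag-(-1) second-moment matrices of an input series.

    ``phi_series`` is steps x N.  Both moments average over the same
    ``len - 1`` transition pairs: R0 over source frames, Rm1 pairing each
    frame with its predecessor.
    """
    X = np.asarray(phi_series, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a series of at least 2 input vectors")
    src = X[:-1]
    dst = X[1:]
    m = src.shape[0]
    R0 = src.T @ src / m
    Rm1 = dst.T @ src / m
    return LaggedCorrelation(R0, Rm1, m)


def closed_form_J(phi_series: np.ndarray, allow_pinv: bool = False) -> np.ndarray:
    """Steady-state weights ``J = R(-1) R(0)^{-1}`` from an input series.

    For a one-hot series this equals the transposed empirical transition
    matrix.  A singular R(0) (e.g. never-visited states) raises
    :class:`SingularCorrelationError` unless ``allow_pinv`` permits a
    pseudo-inverse solution.
    """
    corr = lagged_correlations(phi_series)
    n = corr.R0.shape[0]
    # R0 is symmetric PSD; singular iff rank-deficient
    if np.linalg.matrix_rank(corr.R0, hermitian=True) < n:
        if not allow_pinv:
            raise SingularCorrelationError(
                "zero-lag correlation matrix is singular; pass allow_pinv=True"
            )
        return corr.Rm1 @ np.linalg.pinv(corr.R0, hermitian=True)
    return corr.Rm1 @ np.linalg.inv(corr.R0)
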