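"""Spatial-coding analysis: rate maps, field detection, statistics, shifts.

Rate maps are occupancy-normalized mean firing rates per spatial bin.  Place
fields are detected with a permutation test: the null preserves the temporal
autocorrelation of the activity trace by circularly shifting it relative to
the position sequence, and a candidate field (contiguous supra-threshold
region) is significant when its peak exceeds the (1 - alpha) quantile of the
null map peaks.  Population statistics (field counts, field sizes as arena
fractions) are summarized as histograms and compared between populations by
a summed KL divergence in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .envs import Environment, Walk

__all__ = [
    "RateMap",
    "PlaceFieldSummary",
    "FieldDetection",
    "rate_map",
    "detect_fields",
    "summarize_neuron",
    "field_statistics",
    "kl_divergence",
    "combined_kl",
    "split_half_kl",
    "peak_shift",
    "lap_activity_map",
    "COUNT_BINS_MAX",
    "SIZE_BIN_EDGES",
]

#: field-count histogram bins are the integers 0 .. COUNT_BINS_MAX (last bin open)
COUNT_BINS_MAX = 8
#: field-size-fraction histogram: 10 equal bins over (0, 0.5]
SIZE_BIN_EDGES = np.linspace(0.0, 0.5, 11)

#: permutation-test defaults: minimum circular offset (seconds) and count
DEFAULT_MIN_SHIFT_S = 30.0
DEFAULT_N_PERM = 250


@dataclass
class RateMap:
    """Occupancy-normalized, smoothed firing-rate map.

    ``map`` is 1 x n for rings (stored as a length-n vector) or h x w for
    grids.  ``visited`` flags bins with nonzero occupancy; unvisited bins
    hold NaN and are excluded from statistics, never zero-filled.
    """

    map: np.ndarray
    occupancy: np.ndarray
    smoothing_sigma: float
    env: Environment

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    def peak(self) -> float:
        return float(np.nanmax(self.map))


def _bin_shape(env: Environment) -> tuple:
    return (env.n_states,) if env.geometry == "ring" else env.shape


def _smooth(arr: np.ndarray, sigma: float, env: Environment) -> np.ndarray:
    if sigma <= 0:
        return arr
    mode = "wrap" if env.geometry == "ring" else "reflect"
    return ndimage.gaussian_filter(arr, sigma, mode=mode)


def _raw_map(activity: np.ndarray, states: np.ndarray, env: Environment, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    n = env.n_states
    occ = np.bincount(states, minlength=n).astype(float)
    tot = np.bincount(states, weights=activity, minlength=n)
    shape = _bin_shape(env)
    occ = occ.reshape(shape)
    tot = tot.reshape(shape)
    # smooth numerator and occupancy with the same kernel, then divide
    occ_s = _smooth(occ, sigma, env)
    tot_s = _smooth(tot, sigma, env)
    out = np.full(shape, np.nan)
    good = occ_s > 0
    out[good] = tot_s[good] / occ_s[good]
    out[occ == 0] = np.nan
    return out, occ


def rate_map(activity: np.ndarray, walk: Walk, smoothing_sigma: float = 1.0) -> RateMap:
    """Mean rate per spatial bin (sum of activity / visits), Gaussian-smoothed.

    ``smoothing_sigma`` is in bins; zero-occupancy bins are flagged NaN.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != len(walk):
        raise ValueError("activity and walk must be aligned")
    m, occ = _raw_map(activity, walk.states, walk.env, smoothing_sigma)
    return RateMap(m, occ, smoothing_sigma, walk.env)


def _candidate_fields(m: np.ndarray, env: Environment, threshold_frac: float, min_bins: int) -> list[np.ndarray]:
    """Contiguous supra-threshold regions of a (smoothed) rate map."""
    peak = np.nanmax(m)
    if not np.isfinite(peak) or peak <= 0:
        return []
    above = np.nan_to_num(m, nan=-np.inf) >= threshold_frac * peak
    if env.geometry == "ring":
        labels, n_lab = ndimage.label(above)
        if n_lab > 1 and above[0] and above[-1]:
            labels[labels == labels[-1]] = labels[0]
    else:
        labels, n_lab = ndimage.label(above)
    fields = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        if mask.sum() >= min_bins:
            fields.append(mask)
    return fields


@dataclass
class FieldDetection:
    """Significant fields of one neuron."""

    field_masks: list[np.ndarray]
    is_place_cell: bool
    null_peak_threshold: float
    rate_map: RateMap


def detect_fields(
    rmap: RateMap,
    activity: np.ndarray,
    walk: Walk,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int = 0,
    min_shift_s: float = DEFAULT_MIN_SHIFT_S,
    threshold_frac: float = 0.5,
    min_field_bins: int = 4,
) -> FieldDetection:
    """Permutation-test place-field detection for one neuron.

    Null maps circularly time-shift the activity relative to the positions by
    a uniform random offset at least ``min_shift_s`` away from zero (in
    either direction), preserving the activity autocorrelation.  Candidate
    fields are contiguous regions at >= ``threshold_frac`` of the map peak
    with at least ``min_field_bins`` bins; each is significant when its peak
    exceeds the (1 - alpha) quantile of the null map peaks.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != len(walk):
        raise ValueError("activity and walk must be aligned")
    if not np.any(activity > 0):
        return FieldDetection([], False, np.nan, rmap)
    n_steps = activity.shape[0]
    min_shift = int(round(min_shift_s / walk.env.dt))
    min_shift = min(min_shift, max(1, n_steps // 4))
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n_steps - min_shift, size=n_perm)
    null_peaks = np.empty(n_perm)
    for k, sh in enumerate(shifts):
        m, _ = _raw_map(np.roll(activity, sh), walk.states, walk.env, rmap.smoothing_sigma)
        null_peaks[k] = np.nanmax(m)
    thresh = float(np.quantile(null_peaks, 1.0 - alpha))
    fields = []
    for mask in _candidate_fields(rmap.map, walk.env, threshold_frac, min_field_bins):
        if np.nanmax(np.where(mask, rmap.map, np.nan)) > thresh:
            fields.append(mask)
    return FieldDetection(fields, len(fields) > 0, thresh, rmap)


@dataclass
class PlaceFieldSummary:
    """Per-neuron field statistics; sizes are fractions of the arena area."""

    is_place_cell: bool
    n_fields: int
    field_sizes: list[float]


def summarize_neuron(detection: FieldDetection) -> PlaceFieldSummary:
    n_bins = detection.rate_map.occupancy.size
    sizes = [float(mask.sum()) / n_bins for mask in detection.field_masks]
    return PlaceFieldSummary(detection.is_place_cell, len(detection.field_masks), sizes)


def field_statistics(summaries: list[PlaceFieldSummary]) -> dict:
    """Population histograms of field counts and field sizes.

    Returns normalized histograms (field counts over integer bins
    0..{COUNT_BINS_MAX}+ across all neurons; field sizes of place cells over
    10 equal bins on (0, 0.5]), the place-cell fraction and the fieldless
    fraction.
    """
    if not summaries:
        raise ValueError("need at least one neuron")
    counts = np.array([min(s.n_fields, COUNT_BINS_MAX) for s in summaries])
    count_hist = np.bincount(counts, minlength=COUNT_BINS_MAX + 1).astype(float)
    count_hist /= count_hist.sum()
    sizes = np.concatenate([s.field_sizes for s in summaries if s.is_place_cell] or [np.array([])])
    if sizes.size:
        size_hist, _ = np.histogram(np.clip(sizes, 1e-12, 0.5), bins=SIZE_BIN_EDGES)
        size_hist = size_hist.astype(float) / size_hist.sum()
    else:
        size_hist = np.zeros(len(SIZE_BIN_EDGES) - 1)
    return {
        "count_hist": count_hist,
        "size_hist": size_hist,
        "place_cell_fraction": float(np.mean([s.is_place_cell for s in summaries])),
        "fieldless_fraction": float(np.mean([s.n_fields == 0 for s in summaries])),
    }


def kl_divergence(P: np.ndarray, Q: np.ndarray, pseudocount: float = 0.5) -> float:
    """KL divergence sum(P log2(P / Q)) in bits over matched bins.

    When the reference Q has empty bins under P's support, Q is Laplace
    smoothed (``pseudocount`` spread over bins, renormalized) to avoid
    division by zero; otherwise it is used as is, so identical distributions
    give exactly 0 bits.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("histograms must share binning")
    if np.any((Q == 0) & (P > 0)):
        Q = Q + pseudocount / Q.size
        Q = Q / Q.sum()
    mask = P > 0
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def combined_kl(model_stats: dict, reference_stats: dict) -> float:
    """Summed KL (bits) of the size and count histograms against a reference."""
    return kl_divergence(model_stats["size_hist"], reference_stats["size_hist"]) + kl_divergence(
        model_stats["count_hist"], reference_stats["count_hist"]
    )


def split_half_kl(summaries: list[PlaceFieldSummary], n_splits: int = 20, seed: int = 0) -> np.ndarray:
    """Distribution of combined KL between random half-populations."""
    if len(summaries) < 4:
        raise ValueError("need at least 4 neurons to split")
    rng = np.random.default_rng(seed)
    out = np.empty(n_splits)
    idx = np.arange(len(summaries))
    half = len(summaries) // 2
    for k in range(n_splits):
        perm = rng.permutation(idx)
        a = [summaries[i] for i in perm[:half]]
        b = [summaries[i] for i in perm[half: 2 * half]]
        out[k] = combined_kl(field_statistics(a), field_statistics(b))
    return out


def _circular_shift_bins(late: int, early: int, n: int) -> int:
    """Minimal signed circular difference late - early, in bins."""
    d = (late - early) % n
    if d >= n / 2:
        d -= n
    return d


def peak_shift(
    activity_all: np.ndarray,
    walk: Walk,
    early_window: tuple[int, int],
    late_window: tuple[int, int],
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Per-neuron circular place-field peak shift (cm), late minus early.

    Peaks are rate-map argmaxes within each step window (ties broken toward
    the lower bin).  Negative shifts point opposite the travel direction
    (backward).  Neurons with no activity in either window get NaN.
    """
    if walk.env.geometry != "ring":
        raise ValueError("peak shifts are defined on ring walks")
    activity_all = np.asarray(activity_all, dtype=float)
    n = walk.env.n_states
    e0, e1 = early_window
    l0, l1 = late_window
    if e1 <= e0 or l1 <= l0:
        raise ValueError("windows must be non-empty")
    shifts = np.full(activity_all.shape[0], np.nan)
    for i, act in enumerate(activity_all):
        maps = []
        ok = True
        for (a, b) in ((e0, e1), (l0, l1)):
            sub = Walk(walk.states[a:b], walk.env)
            m, _ = _raw_map(act[a:b], sub.states, walk.env, smoothing_sigma)
            if not np.any(np.nan_to_num(m) > 0):
                ok = False
                break
            maps.append(np.nan_to_num(m, nan=-np.inf))
        if not ok:
            continue
        early_pk = int(np.argmax(maps[0]))
        late_pk = int(np.argmax(maps[1]))
        shifts[i] = _circular_shift_bins(late_pk, early_pk, n) * walk.env.bin_size
    return shifts


def lap_activity_map(activity: np.ndarray, walk: Walk) -> np.ndarray:
    """Laps x position array of mean rate per bin, lap boundaries at completed circuits.

    Laps are delimited by the cumulative (unwrapped) circular displacement
    from the start state crossing multiples of the track length.
    """
    if walk.env.geometry != "ring":
        raise ValueError("lap maps are defined on ring walks")
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != len(walk):
        raise ValueError("activity and walk must be aligned")
    n = walk.env.n_states
    s = walk.states
    steps = (np.diff(s) + n // 2) % n - n // 2
    unwrapped = np.concatenate([[0], np.cumsum(steps)])
    lap_idx = np.floor_divide(unwrapped, n)
    n_laps = int(lap_idx.max())
    if n_laps < 1:
        raise ValueError("fewer than one completed lap")
    out = np.full((n_laps, n), np.nan)
    for lap in range(n_laps):
        sel = lap_idx == lap
        if not np.any(sel):
            continue
        occ = np.bincount(s[sel], minlength=n).astype(float)
        tot = np.bincount(s[sel], weights=activity[sel], minlength=n)
        good = occ > 0
        out[lap, good] = tot[good] / occ[good]
    return out
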