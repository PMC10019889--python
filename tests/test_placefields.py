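"""Rate maps, permutation-test field detection, statistics, shifts, laps."""

import numpy as np
import pytest

import srnn
from srnn.envs import Walk
from srnn.placefields import (
    PlaceFieldSummary,
    SIZE_BIN_EDGES,
    detect_fields,
    field_statistics,
    lap_activity_map,
    peak_shift,
    rate_map,
    summarize_neuron,
)


@pytest.fixture
def grid_walk():
    env = srnn.grid(8, 8)
    return srnn.simulate_walk(env, srnn.grid_actions(), 4000, seed=0)


class TestRateMap:
    def test_constant_activity_uniform_map(self, grid_walk):
        rm = rate_map(np.ones(len(grid_walk)), grid_walk, smoothing_sigma=1.0)
        visited = rm.visited
        assert np.allclose(rm.map[visited], 1.0)

    def test_indicator_activity_unsmoothed_is_delta(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 2000, seed=1)
        k = 5
        act = (walk.states == k).astype(float)
        rm = rate_map(act, walk, smoothing_sigma=0.0)
        assert rm.map[k] == pytest.approx(1.0)
        others = np.arange(20) != k
        assert np.allclose(rm.map[others & rm.visited], 0.0)

    def test_unvisited_bins_flagged_nan(self):
        env = srnn.ring(6)
        walk = Walk(np.array([0, 1, 0, 1, 0]), env)
        rm = rate_map(np.ones(5), walk, smoothing_sigma=0.0)
        assert np.isnan(rm.map[3])
        assert not rm.visited[3]

    def test_length_mismatch_rejected(self, grid_walk):
        with pytest.raises(ValueError):
            rate_map(np.ones(10), grid_walk)


class TestDetectFields:
    def test_single_bump_neuron_has_exactly_one_field(self, grid_walk):
        env = grid_walk.env
        k = 3 * 8 + 4
        act = 5.0 * (grid_walk.states == k).astype(float)
        rm = rate_map(act, grid_walk, smoothing_sigma=1.0)
        det = detect_fields(rm, act, grid_walk, n_perm=150, seed=0)
        assert det.is_place_cell
        assert len(det.field_masks) == 1
        assert det.field_masks[0][3, 4]

    def test_uniform_neurons_rarely_flagged(self, grid_walk, rng):
        flagged = 0
        for i in range(20):
            act = rng.random(len(grid_walk))
            rm = rate_map(act, grid_walk, smoothing_sigma=1.0)
            det = detect_fields(rm, act, grid_walk, n_perm=150, alpha=0.05, seed=i)
            flagged += det.is_place_cell
        assert flagged <= 4  # alpha + generous sampling slack on 20 neurons

    def test_silent_neuron_is_not_place_cell(self, grid_walk):
        act = np.zeros(len(grid_walk))
        rm = rate_map(act, grid_walk)
        det = detect_fields(rm, act, grid_walk, n_perm=150, seed=0)
        assert not det.is_place_cell and det.field_masks == []

    def test_too_few_permutations_rejected(self, grid_walk):
        act = np.ones(len(grid_walk))
        rm = rate_map(act, grid_walk)
        with pytest.raises(ValueError):
            detect_fields(rm, act, grid_walk, n_perm=50)


class TestFieldStatistics:
    def test_point_mass_on_single_field_population(self):
        summaries = [PlaceFieldSummary(True, 1, [0.12]) for _ in range(8)]
        stats = field_statistics(summaries)
        assert stats["count_hist"][1] == 1.0
        assert stats["place_cell_fraction"] == 1.0
        assert stats["fieldless_fraction"] == 0.0

    def test_mixed_population_histogram(self):
        summaries = (
            [PlaceFieldSummary(False, 0, [])] * 3
            + [PlaceFieldSummary(True, 1, [0.1])] * 5
            + [PlaceFieldSummary(True, 2, [0.1, 0.2])] * 2
        )
        stats = field_statistics(summaries)
        assert np.allclose(stats["count_hist"][:3], [0.3, 0.5, 0.2])
        assert stats["fieldless_fraction"] == pytest.approx(0.3)

    def test_fieldless_neurons_excluded_from_sizes(self):
        summaries = [PlaceFieldSummary(False, 0, []), PlaceFieldSummary(True, 1, [0.3])]
        stats = field_statistics(summaries)
        assert stats["size_hist"].sum() == pytest.approx(1.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            field_statistics([])


class TestKLDivergence:
    def test_identical_distributions_zero(self):
        P = np.array([0.25, 0.75])
        assert srnn.kl_divergence(P, P.copy()) == 0.0

    def test_half_vs_quarter_example(self):
        val = srnn.kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        expected = 0.5 * np.log2(2) + 0.5 * np.log2(2 / 3)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.2075, abs=5e-4)

    def test_zero_reference_bins_smoothed(self):
        val = srnn.kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert np.isfinite(val) and val > 0

    def test_unmatched_bins_rejected(self):
        with pytest.raises(ValueError):
            srnn.kl_divergence(np.ones(3) / 3, np.ones(4) / 4)

    def test_combined_of_identical_summaries_zero(self):
        summaries = [PlaceFieldSummary(True, 1, [0.1])] * 6
        stats = field_statistics(summaries)
        assert srnn.combined_kl(stats, stats) == 0.0


class TestSplitHalfKL:
    def test_homogeneous_population_zero(self):
        summaries = [PlaceFieldSummary(True, 1, [0.125])] * 20
        out = srnn.split_half_kl(summaries, n_splits=5, seed=0)
        assert np.allclose(out, 0.0)

    def test_seeded_reproducibility(self, rng):
        summaries = [
            PlaceFieldSummary(True, int(rng.integers(1, 4)), list(rng.uniform(0.05, 0.4, 2)))
            for _ in range(30)
        ]
        a = srnn.split_half_kl(summaries, n_splits=8, seed=5)
        b = srnn.split_half_kl(summaries, n_splits=8, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            srnn.split_half_kl([PlaceFieldSummary(True, 1, [0.1])] * 3)


class TestPeakShift:
    def _activity_for_peaks(self, walk, peaks):
        """Each neuron fires when the agent is at its assigned peak bin."""
        acts = np.zeros((len(peaks), len(walk)))
        for i, p in enumerate(peaks):
            acts[i] = (walk.states == p).astype(float)
        return acts

    def test_identical_windows_zero_shift(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 4000, seed=2)
        acts = self._activity_for_peaks(walk, list(range(20)))
        shifts = peak_shift(acts, walk, (0, 2000), (0, 2000))
        assert np.allclose(shifts[np.isfinite(shifts)], 0.0)

    def test_backward_rotation_is_minus_one_bin(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 6000, seed=3)
        early = (0, 3000)
        late = (3000, 6000)
        n_neurons = 20
        acts = np.zeros((n_neurons, len(walk)))
        for i in range(n_neurons):
            acts[i, : 3001] = (walk.states[: 3001] == i).astype(float)
            acts[i, 3001:] = (walk.states[3001:] == (i - 1) % 20).astype(float)
        shifts = peak_shift(acts, walk, early, late, smoothing_sigma=0.0)
        assert np.allclose(shifts[np.isfinite(shifts)], -5.0)

    def test_circular_wrap_minimal_difference(self, ring20, forward_actions):
        walk = srnn.simulate_walk(ring20, forward_actions, 6000, seed=4)
        acts = np.zeros((1, len(walk)))
        acts[0, :3001] = (walk.states[:3001] == 0).astype(float)
        acts[0, 3001:] = (walk.states[3001:] == 19).astype(float)
        shifts = peak_shift(acts, walk, (0, 3000), (3000, 6000), smoothing_sigma=0.0)
        assert shifts[0] == pytest.approx(-5.0)

    def test_grid_walk_rejected(self, grid_walk):
        with pytest.raises(ValueError):
            peak_shift(np.ones((1, len(grid_walk))), grid_walk, (0, 10), (10, 20))


class TestLapActivityMap:
    def test_forward_deterministic_laps_are_indicator_rows(self):
        env = srnn.ring(6)
        walk = srnn.simulate_walk(env, srnn.ring_actions(1, 0, 0), 18, seed=0)
        k = 2
        act = (walk.states == k).astype(float)
        laps = lap_activity_map(act, walk)
        assert laps.shape == (3, 6)
        assert np.allclose(laps[:, k], 1.0)
        off = np.arange(6) != k
        assert np.allclose(laps[:, off], 0.0)

    def test_doubled_rate_second_lap(self):
        env = srnn.ring(4)
        walk = srnn.simulate_walk(env, srnn.ring_actions(1, 0, 0), 8, seed=0)
        act = np.ones(9)
        act[4:8] = 2.0
        laps = lap_activity_map(act, walk)
        assert np.allclose(laps[1], 2 * laps[0])

    def test_incomplete_lap_rejected(self):
        env = srnn.ring(10)
        walk = Walk(np.array([0, 1, 2, 3]), env)
        with pytest.raises(ValueError):
            lap_activity_map(np.ones(4), walk)

    def test_grid_rejected(self, grid_walk):
        with pytest.raises(ValueError):
            lap_activity_map(np.ones(len(grid_walk)), grid_walk)


class TestFieldSizeGrowsWithCorrelation:
    def test_monotone_field_size_in_sigma(self):
        """Mean contiguous-field size of learned representations grows with
        the spatial correlation scale of the inputs (3-point grid, 2 seeds)."""
        from srnn.placefields import _candidate_fields

        env = srnn.grid(14, 14)
        agg = {sigma: [] for sigma in (0.0, 5.0, 10.0)}
        for seed in (0, 1):
            walk = srnn.simulate_walk(env, srnn.grid_actions(), 5000, seed=seed)
            for sigma in agg:
                fs = srnn.generate_features(env, p=0.03, sigma=sigma, seed=seed)
                X = srnn.walk_inputs(walk, fs)
                # static rate: the stable regime for dense overlapping inputs
                cfg = srnn.RNNConfig(gamma_B=0.0, lr_mode="static", eta_static=10 ** -1.5,
                                     nonlinearity="tanh", dynamics="iterative", gamma_R=0.75)
                res = srnn.run_session(X, cfg, record_activity=False, log_every=10 ** 9)
                M = srnn.sr_from_J(res.state.J, 0.75).M
                R = fs.Phi @ M.T
                fracs = []
                for i in range(env.n_states):
                    rm = rate_map(R[:, i][walk.states], walk, smoothing_sigma=1.0)
                    for mask in _candidate_fields(rm.map, env, 0.5, 4):
                        fracs.append(mask.sum() / env.n_states)
                agg[sigma].append(np.mean(fracs) if fracs else 0.0)
        means = [np.mean(agg[s]) for s in sorted(agg)]
        assert means[0] < means[1] < means[2]
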