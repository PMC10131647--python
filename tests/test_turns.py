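"""Change-point detection and turn extraction."""

import numpy as np
import pytest

from turncoord.kinematics import SegmentYawSignal, angular_velocity, segment_yaw
from turncoord.turns import (
    TurnConfig,
    best_single_split,
    detect_change_points,
    detect_turns,
)

FS = 200.0


def exhaustive_split(x):
    """Independent oracle: try every split, numpy statistics only."""
    best_k, best_cost = None, np.inf
    for k in range(1, len(x)):
        cost = np.sum((x[:k] - np.mean(x[:k])) ** 2) + np.sum(
            (x[k:] - np.mean(x[k:])) ** 2
        )
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    return best_k, best_cost


def optimal_segmentation(x, penalty, max_cps=3):
    """Brute-force optimal penalized segmentation (exhaustive over index sets)."""
    from itertools import combinations

    n = len(x)

    def rss(a, b):
        seg = x[a:b]
        return np.sum((seg - seg.mean()) ** 2)

    best = (rss(0, n), ())
    for m in range(1, max_cps + 1):
        for cps in combinations(range(1, n), m):
            bounds = (0, *cps, n)
            cost = sum(rss(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            total = cost + penalty * m
            if total < best[0] - 1e-9:
                best = (total, cps)
    return list(best[1])


class TestBestSingleSplit:
    def test_two_plateaus(self):
        k, cost = best_single_split(np.array([0.0, 0, 0, 10, 10, 10]))
        assert (k, cost) == (3, 0.0)

    def test_constant_signal_tie_breaks_to_first_index(self):
        k, cost = best_single_split(np.array([5.0, 5, 5, 5]))
        assert k == 1
        assert cost == 0.0

    def test_mid_bump_matches_exhaustive(self):
        x = np.array([0.0, 0, 10, 10, 0, 0])
        assert best_single_split(x) == pytest.approx(exhaustive_split(x))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_signals_match_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 200))
        x = rng.normal(size=T)
        if seed % 3 == 0 and T > 4:  # add a genuine mean shift sometimes
            x[T // 2 :] += rng.normal() * 3
        k, cost = best_single_split(x)
        k0, cost0 = exhaustive_split(x)
        assert k == k0
        assert cost == pytest.approx(cost0, abs=1e-8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            best_single_split(np.array([1.0]))


class TestDetectChangePoints:
    def test_sharp_staircase_yields_exactly_one_change_point(self):
        x = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        res = detect_change_points(x, penalty=5.0)
        assert res.indices == [100]
        assert res.cost == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_yields_no_change_points(self):
        """With a 10*var*log(T) penalty, pure noise stays unsegmented."""
        rng = np.random.default_rng(12345)
        T = 500
        hits = 0
        for _ in range(200):
            x = rng.normal(size=T)
            if detect_change_points(x, 10 * np.var(x) * np.log(T)).indices:
                hits += 1
        assert hits <= 10  # >= 95% of runs clean

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_optimum_on_short_staircases(self, seed):
        rng = np.random.default_rng(100 + seed)
        T = int(rng.integers(20, 51))
        n_cps = int(rng.integers(0, 3))
        cps_true = sorted(rng.choice(np.arange(5, T - 5), size=n_cps, replace=False))
        levels = rng.permutation([0.0, 12.0, 24.0])
        x = np.empty(T)
        bounds = [0, *cps_true, T]
        for lvl, (a, b) in zip(levels, zip(bounds[:-1], bounds[1:])):
            x[a:b] = lvl
        x += rng.normal(0, 0.5, T)
        penalty = 25.0
        got = detect_change_points(x, penalty).indices
        want = optimal_segmentation(x, penalty)
        assert got == want

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 80), rng.normal(6, 1, 80)])
        base = detect_change_points(x, 20.0).indices
        scaled = detect_change_points(2.0 * x + 3.0, 4.0 * 20.0).indices
        assert scaled == base

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            detect_change_points(np.zeros(10), -1.0)

    def test_cost_decreases_with_penalty(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300).cumsum()
        costs = [detect_change_points(x, p).cost for p in (1000.0, 100.0, 10.0)]
        assert costs[0] >= costs[1] >= costs[2]


class TestDetectTurns:
    def test_four_turns_recovered_with_boundaries_in_transition_span(self, nf_sim):
        trial, truth = nf_sim
        for seg in ("head", "sternum", "pelvis"):
            yaw = segment_yaw(trial.segment_markers(seg), seg)
            events = detect_turns(yaw, angular_velocity(yaw))
            assert len(events) == 4
            for ev, ts, te in zip(events, truth.turn_starts[seg], truth.turn_ends[seg]):
                mid = (ts + te) / 2
                assert ts - 0.1 <= ev.start_s <= mid
                assert mid <= ev.end_s <= te + 0.1

    def test_magnitude_strictly_clipped_below_nominal(self, nf_sim):
        """Smooth transitions are under-read; no overshoot ever."""
        trial, _ = nf_sim
        yaw = segment_yaw(trial.segment_markers("head"), "head")
        for ev in detect_turns(yaw, angular_velocity(yaw)):
            assert ev.magnitude_deg < 180.0

    def test_straight_walking_gives_no_turns(self):
        rng = np.random.default_rng(0)
        yaw = SegmentYawSignal("head", rng.normal(0, 0.3, 2000), FS)
        assert detect_turns(yaw, angular_velocity(yaw)) == []

    def test_alternating_directions_reported(self, nf_sim):
        trial, truth = nf_sim
        yaw = segment_yaw(trial.segment_markers("head"), "head")
        events = detect_turns(yaw, angular_velocity(yaw))
        assert [e.direction for e in events] == list(truth.directions.astype(int))

    def test_occlusion_gap_inside_turn_drops_that_turn(self, nf_sim):
        trial, truth = nf_sim
        markers = [
            type(m)(m.label, m.positions.copy(), m.fs)
            for m in trial.segment_markers("head")
        ]
        # blank 0.5 s in the middle of the second turn
        mid = (truth.turn_starts["head"][1] + truth.turn_ends["head"][1]) / 2
        i = int(mid * FS)
        markers[0].positions[i : i + 100] = np.nan
        yaw = segment_yaw(markers, "head")
        events = detect_turns(yaw, angular_velocity(yaw))
        assert len(events) == 3
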