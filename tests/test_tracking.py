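import itertools

import numpy as np
import pytest

from fishtrack.head_detect import HeadDetection
from fishtrack.tracking import (TrackInitializationError, TrackingParams, TrackSet,
                                TrackState, build_cost_matrix, cost,
                                direction_change, initialize_tracks,
                                position_change, solve_assignment, step_tracks,
                                track_sequence)

D1 = TrackingParams(omega=0.5, pc_max=60, dc_max=180, t_o=300, n_fish=20)


def det(x, y, theta=0.0, frame=0):
    return HeadDetection(x=x, y=y, width=16.0, frame_index=frame, theta_deg=theta)


def state(tid, x, y, theta=0.0, frame=0, status="detected"):
    return TrackState(track_id=tid, x=x, y=y, theta_deg=theta, frame_index=frame, status=status)


def brute_force_assignment(A):
    """Exhaustive minimum-cost matching oracle (never uses an inf entry)."""
    n, m = A.shape
    best_pairs, best_cost = [], np.inf
    k = min(n, m)
    rows = range(n)
    for rsub in itertools.combinations(rows, k):
        for csub in itertools.permutations(range(m), k):
            pairs = [(i, j) for i, j in zip(rsub, csub) if np.isfinite(A[i, j])]
            c = sum(A[i, j] for i, j in pairs)
            # prefer more matches, then lower cost
            key = (-len(pairs), c)
            if key < (-len(best_pairs), best_cost):
                best_pairs, best_cost = pairs, c
    return best_pairs, best_cost


def test_position_and_direction_change():
    assert position_change(state(1, 5, 5), det(5, 5)) == 0.0
    assert position_change(state(1, 0, 0), det(3, 4)) == 5.0
    assert position_change(state(1, 10, 10), det(10, 70)) == 60.0
    assert direction_change(10.0, 10.0) == 0.0
    assert direction_change(350.0, 10.0) == 20.0
    assert direction_change(0.0, 180.0) == 180.0


def test_cost_normalization():
    assert cost(0.0, 0.0, D1) == 0.0
    for w in (0.0, 0.3, 0.5, 1.0):
        p = TrackingParams(omega=w, pc_max=60, dc_max=180, t_o=300, n_fish=2)
        assert cost(60.0, 180.0, p) == pytest.approx(1.0)
    assert cost(30.0, 90.0, D1) == pytest.approx(0.5)


def test_cost_matrix_gating():
    far = [state(1, 0, 0), state(2, 1000, 1000)]
    dets = [det(5000, 5000)]
    A = build_cost_matrix(far, dets, D1)
    assert np.all(np.isinf(A))

    A = build_cost_matrix([state(1, 0, 0, theta=0.0)], [det(3, 4, theta=0.0)], D1)
    assert A.shape == (1, 1)
    assert A[0, 0] == pytest.approx(0.5 * 5 / 60)

    tracks = [state(1, 0, 0), state(2, 500, 0), state(3, 900, 0)]
    dets = [det(10, 0), det(400, 0), det(20, 0)]
    A = build_cost_matrix(tracks, dets, D1)
    assert np.isfinite(A[0, 0]) and np.isinf(A[0, 1]) and np.isfinite(A[0, 2])


def test_degenerate_direction_costs_midpoint():
    A = build_cost_matrix([state(1, 0, 0, theta=0.0)], [det(0, 0, theta=None)], D1)
    assert A[0, 0] == pytest.approx((1 - D1.omega) * 0.5)


def test_assignment_simple_and_forced_off_greedy():
    pairs = solve_assignment(np.array([[0.1, 0.9], [0.9, 0.1]]))
    assert sorted(pairs) == [(0, 0), (1, 1)]
    A = np.array([[0.2, 0.3], [0.1, np.inf]])
    pairs = solve_assignment(A)
    assert sorted(pairs) == [(0, 1), (1, 0)]  # greedy would take (0,0) and fail


def test_assignment_never_uses_gated_entries():
    A = np.array([[np.inf, np.inf], [0.1, np.inf]])
    pairs = solve_assignment(A)
    assert pairs == [(1, 0)]


@pytest.mark.parametrize("shape", [(3, 3), (4, 6), (6, 4), (6, 6)])
def test_assignment_matches_brute_force(shape):
    rng = np.random.default_rng(11)
    for _ in range(25):
        A = rng.uniform(0, 1, shape)
        A[rng.random(shape) < 0.2] = np.inf
        pairs = solve_assignment(A)
        oracle_pairs, oracle_cost = brute_force_assignment(A)
        assert len(pairs) == len(oracle_pairs)
        assert sum(A[i, j] for i, j in pairs) == pytest.approx(oracle_cost)


def test_initialize_forward_scan_and_failure():
    frames = [[det(0, 0)], [det(0, 0)], [det(0, 0), det(9, 9)]]
    ts = initialize_tracks(frames, 2)
    assert ts.start_frame == 2
    assert [s.track_id for s in ts.frames[0]] == [1, 2]
    with pytest.raises(TrackInitializationError):
        initialize_tracks(frames, 5)


def test_step_all_matched_at_zero_cost():
    ts = TrackSet(n=2, start_frame=0,
                  frames=[[state(1, 10, 10, 45.0), state(2, 50, 50, 90.0)]])
    ev = step_tracks(ts, [det(50, 50, 90.0, 1), det(10, 10, 45.0, 1)], D1, 1)
    assert ev == {"matched": 2, "propagated": 0, "dropped": 0}
    s1, s2 = ts.frames[-1]
    assert (s1.x, s1.y, s1.status) == (10, 10, "detected")
    assert (s2.x, s2.y, s2.status) == (50, 50, "detected")


def test_step_m_less_than_n_propagates():
    ts = TrackSet(n=3, start_frame=0,
                  frames=[[state(1, 10, 10, 0.0), state(2, 50, 50, 90.0), state(3, 90, 90, 180.0)]])
    ev = step_tracks(ts, [det(11, 10, 0.0, 1), det(91, 90, 180.0, 1)], D1, 1)
    assert ev["matched"] == 2 and ev["propagated"] == 1
    s2 = ts.frames[-1][1]
    assert s2.status == "propagated"
    assert (s2.x, s2.y, s2.theta_deg) == (50, 50, 90.0)  # unchanged state


def test_step_m_greater_than_n_drops_surplus():
    ts = TrackSet(n=1, start_frame=0, frames=[[state(1, 10, 10, 0.0)]])
    ev = step_tracks(ts, [det(200, 10, 0.0, 1), det(12, 10, 0.0, 1)], D1, 1)
    assert ev["matched"] == 1 and ev["dropped"] == 1
    assert ts.frames[-1][0].x == 12


def test_zero_detection_frame_propagates_all():
    ts = TrackSet(n=2, start_frame=0, frames=[[state(1, 0, 0), state(2, 9, 9)]])
    ev = step_tracks(ts, [], D1, 1)
    assert ev["propagated"] == 2
    assert all(s.status == "propagated" for s in ts.frames[-1])


def test_propagation_is_a_fixpoint_and_conserves_n():
    params = TrackingParams(omega=0.5, pc_max=60, dc_max=180, t_o=300, n_fish=2)
    frames = [[det(0, 0, 0.0, 0), det(100, 0, 0.0, 0)]] + [[]] * 5
    ts, events = track_sequence(frames, params)
    assert all(len(f) == 2 for f in ts.frames)
    for s0, sk in zip(ts.frames[0], ts.frames[-1]):
        assert (s0.x, s0.y, s0.theta_deg) == (sk.x, sk.y, sk.theta_deg)
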