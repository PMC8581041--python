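"""Attractor regions, first-passage times and averaged transition paths."""

import numpy as np
import pytest

from spikescape import (define_regions, first_passage_times,
                        extract_transition_paths, average_path,
                        find_minima, estimate_pss, analytic_references)
from spikescape.transitions import (AttractorRegion, TransitionPathSet,
                                    OverlappingRegionsError,
                                    pooled_first_passage_times)
from spikescape.rates import RateTrajectory


def _traj(points, dt_ms=10.0):
    pts = np.asarray(points, float)
    return RateTrajectory(t=dt_ms * np.arange(1, len(pts) + 1),
                          r1=pts[:, 0], r2=pts[:, 1],
                          window=dt_ms, stride=dt_ms)


A = AttractorRegion("A", (0.0, 0.0), (1.0, 1.0))
B = AttractorRegion("B", (10.0, 0.0), (1.0, 1.0))


def test_region_membership_is_elliptic():
    r = AttractorRegion("X", (5.0, 5.0), (2.0, 1.0))
    assert r.contains((6.9, 5.0))
    assert not r.contains((5.0, 6.1))
    assert not r.contains((7.1, 5.0))


def test_define_regions_from_attractors(tw_traj):
    att = find_minima(estimate_pss(tw_traj, bins=35), rate_threshold=25.0)
    regions = define_regions(att, semi_axes=5.0)
    assert {r.label for r in regions} == {"SS", "DS1", "DS2"}
    with pytest.raises(OverlappingRegionsError):
        define_regions(att, semi_axes=15.0)


def test_single_transition_mfpt_equals_elapsed_time():
    pts = [(0, 0), (3, 0), (6, 0), (10, 0)]
    res = first_passage_times(_traj(pts), A, B)
    assert res.K == 1
    assert res.mfpt == pytest.approx((40 - 10) / 1000.0)
    assert res.n_censored == 0


def test_no_transitions_gives_undefined_mfpt():
    res = first_passage_times(_traj([(0, 0), (3, 0), (0, 0)]), A, B)
    assert res.K == 0
    assert np.isnan(res.mfpt)
    assert res.n_censored == 1  # armed but never completed


def test_escape_clock_counts_dwell_and_failed_excursions():
    """The sample spans first arming in A to first entry into B, including
    returns to A in between."""
    pts = [(0, 0), (4, 0), (0.5, 0), (0, 0.2), (5, 0), (10, 0), (10, 0.1)]
    res = first_passage_times(_traj(pts), A, B)
    assert res.K == 1
    # armed at sample 0 (t=10), reaches B at sample 5 (t=60)
    assert res.mfpt == pytest.approx(0.050)


def test_path_starts_at_last_point_inside_source():
    pts = [(0, 0), (4, 0), (0.5, 0), (5, 0), (10, 0), (10, 0.1)]
    ps = extract_transition_paths(_traj(pts), A, B)
    assert ps.K == 1
    path = ps.paths[0]
    # last point inside A is sample 2 (0.5, 0); first inside B is sample 4
    assert path[0, 1:].tolist() == [0.5, 0.0]
    assert path[-1, 1:].tolist() == [10.0, 0.0]
    assert len(path) == 3
    # no interior point is inside B
    assert not any(B.contains(p[1:]) for p in path[:-1])


def test_empty_path_set_allowed_but_not_averaged():
    ps = extract_transition_paths(_traj([(0, 0), (2, 0), (0, 0)]), A, B)
    assert ps.K == 0
    with pytest.raises(ValueError):
        average_path(ps)


def test_average_of_single_path_is_its_resampling():
    pts = [(0.5, 0), (3, 1), (7, -1), (9.5, 0)]
    ps = extract_transition_paths(_traj(pts), A, B)
    avg = average_path(ps, n_points=7)
    assert avg.mean_path.shape == (7, 2)
    assert avg.mean_path[0].tolist() == [0.5, 0.0]
    assert avg.mean_path[-1].tolist() == [9.5, 0.0]


def test_mirror_symmetric_paths_average_on_diagonal():
    up = np.array([(1, 1), (3, 6), (6, 8), (9, 9)], float)
    down = up[:, ::-1]
    paths = [np.column_stack([np.arange(4), p[:, 0], p[:, 1]])
             for p in (up, down)]
    ps = average_path(TransitionPathSet("A", "B", paths), n_points=20)
    assert np.allclose(ps.mean_path[:, 0], ps.mean_path[:, 1])


def test_forward_paths_of_reversed_equal_reversed_backward_paths():
    """Exact region-swap symmetry under time reversal."""
    pts = [(0, 0), (2, 1), (5, 2), (8, 1), (10, 0),   # A -> B
           (9, 2), (6, 3), (3, 2), (0, 0.5)]          # B -> A
    traj = _traj(pts)
    backward = extract_transition_paths(traj, B, A)
    forward_rev = extract_transition_paths(traj.reversed(), A, B)
    assert backward.K == forward_rev.K == 1
    assert np.allclose(forward_rev.paths[0][:, 1:],
                       backward.paths[0][::-1, 1:])


def test_double_well_mfpt_matches_quadrature(dw_traj, dw_spec):
    """Empirical MFPT vs the 1D mean-exit-time double integral, within 20%."""
    ref = analytic_references(dw_spec)
    ax = 3.0
    left = AttractorRegion("L", tuple(dw_spec.well_positions[0]), (ax, ax))
    right = AttractorRegion("R", tuple(dw_spec.well_positions[1]), (ax, ax))
    res_lr = first_passage_times(dw_traj, left, right)
    res_rl = first_passage_times(dw_traj, right, left)
    K = res_lr.K + res_rl.K
    assert K >= 40  # symmetric wells: pool both directions
    mfpt = np.concatenate([res_lr.samples, res_rl.samples]).mean()
    theory = ref.mfpt_quadrature(x_start=left.center[0] + ax,
                                 x_target=right.center[0] - ax)
    assert mfpt == pytest.approx(theory, rel=0.25)


def test_pooling_fpt_across_trajectories():
    t1 = _traj([(0, 0), (5, 0), (10, 0)])
    t2 = _traj([(0, 0), (10, 0)])
    res = pooled_first_passage_times([t1, t2], A, B)
    assert res.K == 2
    assert res.mfpt == pytest.approx(np.mean([0.020, 0.010]))
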