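"""Coarse-grained transition counting and probability-flux estimation."""

import numpy as np
import pytest

from spikescape import coarse_grain, count_transitions, flux_field
from spikescape.flux import (CoarseGrid, make_coarse_grid, estimate_flux,
                             pooled_flux, tangential_component,
                             curl_sign_consistency, circulation_sign)
from spikescape.landscape import estimate_pss

UNIT_GRID = CoarseGrid(np.linspace(0, 1, 3), np.linspace(0, 1, 3))  # 2x2


def test_constant_trajectory_single_state():
    pts = np.tile([[0.2, 0.2]], (50, 1))
    ix, iy, grid, _ = coarse_grain(pts, grid=UNIT_GRID)
    assert np.all(ix == 0) and np.all(iy == 0)
    tallies, _ = count_transitions(pts, grid=UNIT_GRID)
    f = flux_field(tallies, t_total=1.0, grid=UNIT_GRID)
    assert np.all(f.w1 == 0) and np.all(f.w2 == 0)
    assert np.all(f.Jx == 0) and np.all(f.Jy == 0)


def test_coarse_grain_matches_histogram_occupancy(ou_traj):
    edges = (np.linspace(15, 35, 11), np.linspace(15, 35, 11))
    grid = CoarseGrid(*edges)
    ix, iy, _, _ = coarse_grain(ou_traj, grid=grid)
    occ = np.zeros((10, 10))
    np.add.at(occ, (ix, iy), 1)
    hist = estimate_pss(ou_traj, edges=edges)
    assert np.array_equal(occ, hist.counts)


def test_single_step_right_crossing():
    pts = np.array([[0.2, 0.2], [0.7, 0.2]])
    tallies, _ = count_transitions(pts, grid=UNIT_GRID)
    assert tallies.N1_pos[0, 0] == 1
    assert tallies.N1_neg.sum() == 0 and tallies.N2_pos.sum() == 0


def test_multibox_jump_interpolated():
    grid = CoarseGrid(np.linspace(0, 3, 4), np.linspace(0, 1, 3))  # 3x2
    pts = np.array([[0.5, 0.2], [2.5, 0.2]])  # jumps across two faces
    tallies, _ = count_transitions(pts, grid=grid)
    assert tallies.N1_pos[0, 0] == 1
    assert tallies.N1_pos[1, 0] == 1


def test_diagonal_corner_jump_orders_crossings():
    # segment from (0.40, 0.45) to (0.90, 0.55): crosses x=0.5 (t=0.2)
    # strictly before y=0.5 (t=0.5)
    pts = np.array([[0.40, 0.45], [0.90, 0.55]])
    tallies, _ = count_transitions(pts, grid=UNIT_GRID)
    assert tallies.N1_pos[0, 0] == 1   # crossed while still in lower row
    assert tallies.N2_pos[1, 0] == 1   # then rose in the right column
    # mirrored segment: the y face goes first, in the left column
    tallies2, _ = count_transitions(pts[:, ::-1].copy(), grid=UNIT_GRID)
    assert tallies2.N2_pos[0, 0] == 1
    assert tallies2.N1_pos[0, 1] == 1


def test_clockwise_cycle_hand_count():
    """C full cycles through the 4 boxes: every face carries net count C."""
    C = 7
    loop = np.array([[0.25, 0.25], [0.25, 0.75], [0.75, 0.75], [0.75, 0.25]])
    pts = np.vstack([np.tile(loop, (C, 1)), loop[:1]])
    tallies, _ = count_transitions(pts, grid=UNIT_GRID)
    t_total = 2.0
    f = flux_field(tallies, t_total, UNIT_GRID)
    assert tallies.N2_pos[0, 0] == C       # (0,0)->(0,1)
    assert tallies.N1_pos[0, 1] == C       # (0,1)->(1,1)
    assert tallies.N2_neg[1, 0] == C       # (1,1)->(1,0)
    assert tallies.N1_neg[0, 0] == C       # (1,0)->(0,0)
    rate = C / t_total
    assert f.Jx[0, 0] == pytest.approx(-rate / 2)
    assert f.Jy[0, 0] == pytest.approx(+rate / 2)
    # rotation about the center is clockwise (negative circulation)
    assert circulation_sign(f, (0.5, 0.5)) == -1
    frac, _, n = curl_sign_consistency(f, (0.5, 0.5))
    assert n == 4 and frac == 1.0


def test_time_reversal_negates_flux(ou_traj):
    grid = make_coarse_grid(ou_traj, 8, 8)
    tallies, _ = count_transitions(ou_traj, grid=grid)
    f = flux_field(tallies, 10.0, grid)
    rev_pts = ou_traj.points[::-1]
    tallies_r, _ = count_transitions(rev_pts, grid=grid)
    f_r = flux_field(tallies_r, 10.0, grid)
    assert np.allclose(f.w1, -f_r.w1)
    assert np.allclose(f.Jx, -f_r.Jx)
    assert np.allclose(f.Jy, -f_r.Jy)


def test_gradient_double_well_flux_vanishes(dw_traj, dw_spec):
    """Detailed balance: mean ||J|| indistinguishable from 0 (3 block SEs)."""
    f = estimate_flux(dw_traj.points, t_total=dw_spec.duration,
                      N1=15, N2=15, n_blocks=10)
    visited = f.magnitude > 0
    mean_J = f.magnitude[visited].mean()
    mean_se = f.se_magnitude[visited].mean()
    assert mean_J < 3 * mean_se


def test_rotational_flux_curls_with_known_sign(rot_traj, rot_spec, refs):
    f = estimate_flux(rot_traj.points, t_total=rot_spec.duration,
                      N1=12, N2=12, n_blocks=10)
    ref = refs(rot_spec)
    frac, n_major, n = curl_sign_consistency(f, rot_spec.offset,
                                             noise_floor_se=2.0)
    assert n >= 10
    assert frac >= 0.95
    assert circulation_sign(f, rot_spec.offset) == ref.circulation_sign


def test_rotational_flux_grows_with_omega(rot_spec):
    from spikescape import simulate_langevin, LangevinSpec
    import dataclasses
    slow = dataclasses.replace(rot_spec, omega=0.3, duration=1500.0, seed=21)
    fast = dataclasses.replace(rot_spec, omega=3.0, duration=1500.0, seed=21)
    mags = []
    for spec in (slow, fast):
        tr = simulate_langevin(spec)
        f = estimate_flux(tr.points, t_total=spec.duration, N1=10, N2=10)
        mags.append(np.mean(f.magnitude))
    assert mags[1] > 2 * mags[0]


def test_pooled_flux_counts_no_seam_crossings():
    """Pooling two trajectories must not count the jump between them."""
    a = np.tile([[0.25, 0.25]], (10, 1))
    b = np.tile([[0.75, 0.75]], (10, 1))
    f = pooled_flux([a, b], grid=UNIT_GRID)
    assert np.all(f.w1 == 0) and np.all(f.w2 == 0)


def test_flux_io_roundtrip(tmp_path, rot_traj, rot_spec):
    f = estimate_flux(rot_traj.points[:5000], t_total=100.0, N1=6, N2=6)
    f.to_hdf5(tmp_path / "f.h5")
    f.to_quiver_csv(tmp_path / "f.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "f.csv")
    assert len(df) == 36
    assert np.allclose(df["Jx"].to_numpy().reshape(6, 6), f.Jx)


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        count_transitions(np.empty((0, 2)), grid=UNIT_GRID)
    with pytest.raises(ValueError):
        make_coarse_grid(np.array([[1.0, 1.0]]), N1=1, N2=5)
    with pytest.raises(ValueError):
        flux_field(count_transitions(np.array([[0.2, 0.2]]),
                                     grid=UNIT_GRID)[0], 0.0, UNIT_GRID)
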