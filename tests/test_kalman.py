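"""Analysis step: block Kalman gain, node assembly and state update."""

import numpy as np
import pytest

from voxelda.grids import (
    StaggeredGrid,
    VelocityField,
    divergence,
    interpolate_to_centers,
)
from voxelda.kalman import (
    NodeGain,
    analysis_update,
    assemble_node_gain,
    compute_contributions,
    voxel_gain,
)
from voxelda.observation import VoxelGrid, build_mapping, observe_centers


def _rand_spd(rng, k):
    a = rng.standard_normal((k, 3, 3))
    return np.einsum("kij,klj->kil", a, a) + 0.05 * np.eye(3)


def dense_gain_oracle(mapping, pf, robs, innov):
    """Full-matrix Kalman gain K = P H^T (H P H^T + R)^-1 with
    block-diagonal P and the node-counting H; independent of the block
    implementation."""
    n, mv = mapping.n_nodes, mapping.m_v
    H = np.zeros((3 * mv, 3 * n))
    for vi in range(mv):
        nodes = mapping.members_of(vi)
        for g in nodes:
            H[3 * vi : 3 * vi + 3, 3 * g : 3 * g + 3] = np.eye(3) / len(nodes)
    P = np.zeros((3 * n, 3 * n))
    for g in range(n):
        P[3 * g : 3 * g + 3, 3 * g : 3 * g + 3] = pf[g]
    R = np.zeros((3 * mv, 3 * mv))
    for vi in range(mv):
        R[3 * vi : 3 * vi + 3, 3 * vi : 3 * vi + 3] = robs[vi]
    K = P @ H.T @ np.linalg.inv(H @ P @ H.T + R)
    return (K @ innov.ravel()).reshape(n, 3)


def test_perfect_observation_limit():
    # one node per voxel (H = I) and R = 0: the correction is the
    # innovation itself, so the analysis equals the observation
    rng = np.random.default_rng(3)
    pf = _rand_spd(rng, 1)
    innov = rng.standard_normal(3)
    c = voxel_gain(pf, np.zeros((3, 3)), innov)
    assert np.abs(c[0] - innov).max() < 1e-10


def test_zero_prior_covariance_gives_zero_correction(rng):
    pf = np.zeros((4, 3, 3))
    c = voxel_gain(pf, np.eye(3), rng.standard_normal(3))
    assert np.abs(c).max() == 0.0


def test_singular_innovation_covariance_raises():
    with pytest.raises(np.linalg.LinAlgError):
        voxel_gain(np.zeros((2, 3, 3)), np.zeros((3, 3)), np.ones(3))


def test_two_node_scalar_voxel_matches_dense_evaluation():
    # p_g = {1, 3}, r = 0.5, innovation 1 in the x-component:
    # S = (1 + 3)/4 + 0.5 = 1.5, contributions p_g * (1/2) / S = {1/3, 1}
    pf = np.zeros((2, 3, 3))
    pf[0, 0, 0], pf[1, 0, 0] = 1.0, 3.0
    r = np.diag([0.5, 1.0, 1.0])
    c = voxel_gain(pf, r, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(c[:, 0], [1.0 / 3.0, 1.0])


def test_block_gain_equals_dense_oracle_on_random_instances():
    # disjoint random instances, <= 4 voxels, <= 8 nodes per voxel
    rng = np.random.default_rng(42)
    for trial in range(25):
        nvx = rng.integers(1, 3)
        nvy = rng.integers(1, 3)
        kx = rng.integers(1, 3)
        ky = rng.integers(1, 5)
        grid = StaggeredGrid(
            (max(3, nvx * kx), max(3, nvy * ky), 1),
            (0.3, 0.2, 1.0),
            (True, False, True),
        )
        vox = VoxelGrid(
            (0.0, 0.0, 0.0),
            (kx * 0.3, ky * 0.2, 1.0),
            (grid.shape[0] // kx, grid.shape[1] // ky, 1),
        )
        m = build_mapping(grid, vox)
        pf = _rand_spd(rng, m.n_nodes)
        robs = _rand_spd(rng, m.m_v)
        innov = rng.standard_normal((m.m_v, 3))
        k_block = assemble_node_gain(
            compute_contributions(m, pf, robs, innov), m
        ).values.reshape(-1, 3)
        k_dense = dense_gain_oracle(m, pf, robs, innov)
        rel = np.abs(k_block - k_dense).max() / max(np.abs(k_dense).max(), 1e-30)
        assert rel < 1e-10


def test_assembly_weights():
    # a node in one voxel keeps its contribution; a border node in two
    # voxels receives the average of the two contributions
    grid = StaggeredGrid((5, 3, 1), (0.2, 0.2, 1.0), (True, False, True))
    # voxel edges on the center column x = 0.5: that column is shared
    vox = VoxelGrid((0.1, 0.0, 0.0), (0.4, 0.6, 1.0), (2, 1, 1))
    m = build_mapping(grid, vox)
    assert m.v_g.max() == 2
    contribs = {}
    for gv, (pos, nodes) in m.groups.items():
        arr = np.zeros(nodes.shape + (3,))
        arr[0] = 1.0  # voxel 0 contributes 1
        arr[1] = 3.0  # voxel 1 contributes 3
        contribs[gv] = (nodes, arr)
    gain = assemble_node_gain(contribs, m).values.reshape(-1, 3)
    shared = np.nonzero(m.v_g == 2)[0]
    only0 = np.setdiff1d(m.members_of(0), shared)
    assert np.allclose(gain[shared], 2.0)  # (1 + 3)/2
    assert np.allclose(gain[only0], 1.0)  # Psi = 1
    outside = np.nonzero(m.v_g == 0)[0]
    if outside.size:
        assert np.abs(gain[outside]).max() == 0.0


def test_analysis_update_zero_gain_is_identity(wall_grid, rng):
    f = VelocityField.zeros(wall_grid)
    f.u[...] = rng.standard_normal(f.u.shape)
    gain = NodeGain(np.zeros(wall_grid.shape + (3,)))
    out = analysis_update(f, gain, wall_grid, reproject=False)
    assert np.array_equal(out.u, f.u)


def test_analysis_update_uniform_gain_shifts_interior(periodic_grid):
    f = VelocityField.zeros(periodic_grid)
    k = np.zeros(periodic_grid.shape + (3,))
    k[..., 0] = 0.7
    out = analysis_update(f, NodeGain(k), periodic_grid, reproject=False)
    assert np.allclose(out.u, 0.7)


def test_perfect_observation_composition_smooth_innovation():
    # fully observed window, R = 0, smooth (affine) innovation: observing
    # the analysis returns the observation sample
    grid = StaggeredGrid((8, 6, 1), (0.25, 0.25, 1.0), (True, False, True))
    vox = VoxelGrid((0.0, 0.0, 0.0), (0.25, 0.25, 1.0), (8, 6, 1))  # dw = 0
    m = build_mapping(grid, vox)
    f = VelocityField.zeros(grid)
    uc = interpolate_to_centers(f, grid).reshape(-1, 3)
    yy = grid.centers(1)
    d = np.zeros((m.m_v, 3))
    d[:, 0] = np.tile(0.3 + 0.2 * yy, grid.shape[0])  # affine in y
    pf = np.tile(np.eye(3) * 4.0, (m.n_nodes, 1, 1))
    innov = d - observe_centers(uc, m)
    gain = assemble_node_gain(
        compute_contributions(m, pf, np.zeros((m.m_v, 3, 3)), innov), m
    )
    out = analysis_update(f, gain, grid, reproject=False)
    out_obs = observe_centers(interpolate_to_centers(out, grid).reshape(-1, 3), m)
    # interior voxels (the wall rows see the pinned no-slip faces)
    interior = np.ones((8, 6), bool)
    interior[:, [0, -1]] = False
    err = np.abs((out_obs - d)[:, 0].reshape(8, 6)[interior]).max()
    assert err < 1e-10


def test_no_correction_beyond_window(periodic_grid, rng):
    # gain vanishes outside the active voxels; faces more than one cell
    # away from the window are untouched by the update
    vox = VoxelGrid((0.0, 0.0, 0.0), (2 * np.pi / 4, 2 * np.pi / 4, 1.0), (4, 4, 1))
    mask = np.zeros((4, 4, 1), bool)
    mask[1, 1, 0] = True
    m = build_mapping(periodic_grid, VoxelGrid(vox.origin, vox.spacing, vox.shape, mask))
    pf = _rand_spd(rng, m.n_nodes)
    innov = rng.standard_normal((m.m_v, 3))
    gain = assemble_node_gain(
        compute_contributions(m, pf, _rand_spd(rng, m.m_v), innov), m
    )
    outside = ~m.inside_window()
    assert np.abs(gain.values[outside]).max() == 0.0
    f = VelocityField.zeros(periodic_grid)
    f.u[...] = rng.standard_normal(f.u.shape)
    out = analysis_update(f, gain, periodic_grid, reproject=False)
    changed = np.abs(out.u - f.u) > 0
    # updated u-faces lie within the window or on its boundary faces
    inside = m.inside_window()[..., 0]
    grown = inside | np.roll(inside, 1, 0) | np.roll(inside, -1, 0)
    assert not np.any(changed[~grown])
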