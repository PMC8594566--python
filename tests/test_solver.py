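"""Forward-model verification: fringe forcing, projection, conservation
and canonical analytic flows."""

import numpy as np
import pytest

from voxelda.grids import StaggeredGrid, VelocityField, divergence
from voxelda.solver import (
    FringeRegion,
    SolverConfig,
    advance_to,
    compute_dt,
    fringe_force,
    no_slip_walls,
    project,
    rk3_step,
)


def _tg_field(grid):
    f = VelocityField.zeros(grid)
    xu, yu, _ = grid.component_mesh(0)
    xv, yv, _ = grid.component_mesh(1)
    f.u[...] = np.cos(xu) * np.sin(yu)
    f.v[...] = -np.sin(xv) * np.cos(yv)
    return f


# -- fringe forcing ---------------------------------------------------------

def test_fringe_zero_rate_gives_zero_force(periodic_grid):
    region = FringeRegion.from_predicate(
        periodic_grid, lambda x, y, z: x < 3.0, lam=0.0, target=(1.0, 0.0, 0.0)
    )
    f = VelocityField.zeros(periodic_grid)
    forces = fringe_force(f, periodic_grid, region, 0, 0.01)
    assert all(np.abs(a).max() == 0.0 for a in forces)


def test_fringe_fixed_point_at_target(periodic_grid):
    region = FringeRegion.from_predicate(
        periodic_grid, lambda x, y, z: np.full(x.shape, True), lam=7.0,
        target=(0.4, 0.0, 0.0),
    )
    f = VelocityField.zeros(periodic_grid)
    f.u[...] = 0.4
    forces = fringe_force(f, periodic_grid, region, 0, 0.01)
    assert all(np.abs(a).max() < 1e-14 for a in forces)


def test_fringe_stability_scaled_rate():
    # alpha = 0.5, dt = 0.01 -> lambda = 1/(alpha dt) = 200 inside
    grid = StaggeredGrid((8, 8, 1), (0.5, 0.5, 1.0), (True, True, True))
    region = FringeRegion.from_predicate(
        grid, lambda x, y, z: np.full(x.shape, True), lam=1.0,
        target=(1.0, 0.0, 0.0), stability_scaled=True,
    )
    f = VelocityField.zeros(grid)
    forces = fringe_force(f, grid, region, 1, 0.01, alphas=(1 / 3, 0.5, 1.0))
    assert np.allclose(forces[0], 200.0 * (1.0 - 0.0))


def test_fringe_negative_rate_rejected(periodic_grid):
    with pytest.raises(ValueError):
        FringeRegion.from_predicate(
            periodic_grid, lambda x, y, z: x < 1.0, lam=-1.0, target=(0, 0, 0)
        )


def test_stability_scaled_fringe_locks_onto_target():
    # a solenoidal target (so the projection does not fight the forcing)
    # is reached to within 1% of its amplitude in five steps
    n = 32
    grid = StaggeredGrid((n, n, 1), (2 * np.pi / n,) * 2 + (1.0,), (True, True, True))
    amp = 0.3
    tgt = _tg_field(grid)
    region = FringeRegion.from_predicate(
        grid, lambda x, y, z: np.full(x.shape, True), lam=1.0,
        target=(amp * tgt.u, amp * tgt.v, tgt.w), stability_scaled=True,
    )
    cfg = SolverConfig(nu=1e-3, dt=0.01)
    f = VelocityField.zeros(grid)
    for _ in range(5):
        f = rk3_step(f, grid, cfg, (region,), 0.01)
    assert np.abs(f.u - amp * tgt.u).max() < 0.01 * amp


# -- projection and conservation --------------------------------------------

def test_projection_idempotent_on_solenoidal_field(periodic_grid):
    f = _tg_field(periodic_grid)
    before = f.u.copy()
    project(f, periodic_grid, 0.1)
    assert np.abs(f.u - before).max() < 1e-12


def test_projection_removes_divergence(periodic_grid, rng):
    f = VelocityField.zeros(periodic_grid)
    f.u[...] = rng.standard_normal(f.u.shape)
    f.v[...] = rng.standard_normal(f.v.shape)
    project(f, periodic_grid, 0.05)
    assert np.abs(divergence(f, periodic_grid).values).max() < 1e-12


def test_projection_wall_axis(wall_grid, rng):
    f = VelocityField.zeros(wall_grid)
    f.u[...] = rng.standard_normal(f.u.shape)
    f.v[...] = rng.standard_normal(f.v.shape)
    no_slip_walls(f, wall_grid)
    project(f, wall_grid, 0.05)
    assert np.abs(divergence(f, wall_grid).values).max() < 1e-11
    assert np.abs(f.v[:, 0]).max() == 0.0  # wall faces untouched


def test_momentum_conserved_periodic(rng):
    n = 24
    grid = StaggeredGrid((n, n, 1), (2 * np.pi / n,) * 2 + (1.0,), (True, True, True))
    f = VelocityField.zeros(grid)
    f.u[...] = 0.3 + 0.1 * rng.standard_normal(f.u.shape)
    f.v[...] = 0.1 * rng.standard_normal(f.v.shape)
    project(f, grid, 1.0)
    cfg = SolverConfig(nu=0.01, dt=0.01)
    m0 = (f.u.mean(), f.v.mean())
    for _ in range(5):
        f = rk3_step(f, grid, cfg, (), 0.01)
    assert abs(f.u.mean() - m0[0]) < 1e-12
    assert abs(f.v.mean() - m0[1]) < 1e-12


# -- canonical flows --------------------------------------------------------

def test_taylor_green_energy_decay():
    n = 64
    grid = StaggeredGrid((n, n, 1), (2 * np.pi / n,) * 2 + (1.0,), (True, True, True))
    nu = 0.05
    cfg = SolverConfig(nu=nu, cfl=0.3, dt_max=0.02)
    f = _tg_field(grid)
    e0 = (f.u**2).mean() + (f.v**2).mean()
    f = advance_to(f, grid, cfg, (), 2.0)
    e1 = (f.u**2).mean() + (f.v**2).mean()
    assert abs(e1 / e0 / np.exp(-4 * nu * 2.0) - 1) < 0.01


def test_taylor_green_grid_convergence_slope():
    # pointwise error against the analytic vortex decays with slope ~2
    nu, t_end = 0.05, 0.5
    errs = []
    for n in (16, 32, 64):
        grid = StaggeredGrid((n, n, 1), (2 * np.pi / n,) * 2 + (1.0,), (True, True, True))
        cfg = SolverConfig(nu=nu, dt=0.005)
        f = _tg_field(grid)
        f = advance_to(f, grid, cfg, (), t_end)
        xu, yu, _ = grid.component_mesh(0)
        exact = np.cos(xu) * np.sin(yu) * np.exp(-2 * nu * t_end)
        errs.append(np.abs(f.u - exact).max())
    slopes = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
    assert slopes.min() > 1.7


def test_laminar_channel_converges_to_poiseuille():
    ny = 32
    grid = StaggeredGrid((4, ny, 1), (1.0, 2.0 / ny, 1.0), (True, False, True))
    cfg = SolverConfig(nu=0.01, cfl=0.4, dt_max=0.02, bulk_axis=0, bulk_velocity=2.0 / 3.0)
    f = VelocityField.zeros(grid)
    yc = grid.centers(1)
    f.u[...] = 0.85 * (yc * (2 - yc))[None, :, None]
    f.u += cfg.bulk_velocity - f.u.mean()
    f = advance_to(f, grid, cfg, (), 200.0)
    prof = f.u.mean(axis=(0, 2))
    exact = yc * (2 - yc)
    assert np.abs(prof - exact).max() / exact.max() < 0.005


def test_zero_field_stays_zero(wall_grid):
    cfg = SolverConfig(nu=0.01, dt=0.01)
    f = VelocityField.zeros(wall_grid)
    f = rk3_step(f, wall_grid, cfg, (), 0.01)
    assert np.abs(f.u).max() == 0.0 and np.abs(f.v).max() == 0.0


# -- time stepping contracts -------------------------------------------------

def test_advance_to_identity_and_semigroup(periodic_grid):
    cfg = SolverConfig(nu=0.02, dt=0.01)
    f = _tg_field(periodic_grid)
    same = advance_to(f.copy(), periodic_grid, cfg, (), f.t)
    assert np.array_equal(same.u, f.u)
    one = advance_to(f.copy(), periodic_grid, cfg, (), 0.2)
    two = advance_to(
        advance_to(f.copy(), periodic_grid, cfg, (), 0.12), periodic_grid, cfg, (), 0.2
    )
    assert np.abs(one.u - two.u).max() < 1e-10


def test_advance_to_rejects_past_target(periodic_grid):
    cfg = SolverConfig(nu=0.02, dt=0.01)
    f = _tg_field(periodic_grid)
    f.t = 1.0
    with pytest.raises(ValueError):
        advance_to(f, periodic_grid, cfg, (), 0.5)


def test_no_slip_on_periodic_axis_rejected(periodic_grid):
    f = VelocityField.zeros(periodic_grid)
    with pytest.raises(ValueError):
        no_slip_walls(f, periodic_grid, axes=[0])


def test_no_slip_zeroes_wall_faces_and_tangential_wall_value(wall_grid, rng):
    from voxelda.solver import _avg_c2f_full

    f = VelocityField.zeros(wall_grid)
    f.u[...] = rng.standard_normal(f.u.shape)
    f.v[...] = rng.standard_normal(f.v.shape)
    no_slip_walls(f, wall_grid)
    assert np.abs(f.v[:, 0]).max() == 0.0 and np.abs(f.v[:, -1]).max() == 0.0
    # tangential velocity interpolated onto the wall plane is exactly zero
    u_at_yfaces = _avg_c2f_full(f.u, 1, False)
    assert np.abs(u_at_yfaces[:, 0]).max() == 0.0
    assert np.abs(u_at_yfaces[:, -1]).max() == 0.0


def test_compute_dt_respects_fringe_rate(periodic_grid):
    cfg = SolverConfig(nu=1e-4, cfl=0.5, dt_max=1.0)
    region = FringeRegion.from_predicate(
        periodic_grid, lambda x, y, z: x < 1.0, lam=100.0, target=(0, 0, 0)
    )
    f = VelocityField.zeros(periodic_grid)
    dt = compute_dt(f, periodic_grid, cfg, (region,))
    assert dt <= 0.5 * 2.5 / 100.0 + 1e-15
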