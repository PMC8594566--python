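"""Incompressible Navier-Stokes forward model on the staggered grid.

The forward model between two Kalman analysis steps is a direct numerical
simulation: explicit advection (divergence form) and diffusion with
second-order central differences, a three-stage Runge-Kutta scheme, and a
pressure projection after every stage so the velocity stays discretely
divergence-free.  Inflow profiles, immersed objects and data-driven walls
are imposed with fringe forcing, a volumetric penalty

    f(x, t) = lambda(x) * (U(x, t) - u(x, t))

that relaxes the solution toward a target velocity ``U`` inside the fringe
region.  When the target is time dependent the penalty rate can be tied to
the Runge-Kutta stage so the stage update lands exactly on the target
(``lambda = 1 / (alpha_k * dt)``), which keeps the explicit treatment of
the force stable for any ``dt``.

The Poisson problem of the projection is solved spectrally: FFT along
periodic axes and a type-II cosine transform (homogeneous Neumann at the
walls, consistent with the staggered pressure stencil) along wall axes, so
the discrete divergence after projection is at round-off level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.fft as sp_fft

from .grids import StaggeredGrid, VelocityField, divergence

__all__ = [
    "SolverConfig",
    "FringeRegion",
    "fringe_force",
    "no_slip_walls",
    "project",
    "rk3_step",
    "advance_to",
    "compute_dt",
]

#: Stage coefficients of the classical explicit three-stage scheme
#: u_k = u_0 + alpha_k dt R(u_{k-1}); its stability polynomial is
#: 1 + z + z^2/2 + z^3/6 (third-order for linear problems).
RK3_ALPHAS = (1.0 / 3.0, 1.0 / 2.0, 1.0)


@dataclass
class SolverConfig:
    """Physical and numerical parameters of the flow solver.

    ``nu`` is the kinematic viscosity (length^2/time).  Either a fixed time
    step ``dt`` or a CFL number is used; the viscous and fringe stability
    limits are always enforced on top of the advective CFL.  An optional
    constant bulk velocity (volume-average of one component) is maintained
    by a uniform body force, the standard constant-mass-flux driving of
    channel flow.
    """

    nu: float
    rho: float = 1.0
    dt: Optional[float] = None
    cfl: float = 0.35
    dt_max: float = 0.1
    div_tol: float = 1e-8
    rk_alphas: tuple[float, ...] = RK3_ALPHAS
    bulk_axis: Optional[int] = None
    bulk_velocity: Optional[float] = None
    re: Optional[float] = None
    u_ref: float = 1.0
    l_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("kinematic viscosity must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("time step must be positive")


TargetFn = Callable[[float], tuple[np.ndarray, np.ndarray, np.ndarray]]


class FringeRegion:
    """Penalty region driving the flow toward a target velocity.

    Parameters
    ----------
    lam
        Per-component penalty rate arrays (one per velocity component, on
        that component's face grid); non-negative, zero outside the region.
    target
        Either a tuple of three constants / face arrays, or a callable
        ``t -> (U, V, W)`` returning face arrays, for time-dependent
        targets.
    stability_scaled
        If set, the rate inside the region is replaced by
        ``1 / (alpha_k * dt)`` at every Runge-Kutta stage.
    """

    def __init__(
        self,
        lam: tuple[np.ndarray, np.ndarray, np.ndarray],
        target,
        stability_scaled: bool = False,
        name: str = "fringe",
    ) -> None:
        self.lam = tuple(np.asarray(a, dtype=float) for a in lam)
        for a in self.lam:
            if np.any(a < 0):
                raise ValueError("fringe rate lambda must be non-negative")
        self.masks = tuple(a > 0 for a in self.lam)
        self.target = target
        self.stability_scaled = bool(stability_scaled)
        self.name = name

    @classmethod
    def from_predicate(
        cls,
        grid: StaggeredGrid,
        predicate: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
        lam: float,
        target=(0.0, 0.0, 0.0),
        stability_scaled: bool = False,
        name: str = "fringe",
    ) -> "FringeRegion":
        """Build a region from a geometric predicate evaluated at the face
        points of each velocity component."""
        lams = []
        for comp in range(3):
            xx, yy, zz = grid.component_mesh(comp)
            lams.append(lam * predicate(xx, yy, zz).astype(float))
        return cls(tuple(lams), target, stability_scaled, name)

    def target_at(self, t: float, grid: StaggeredGrid):
        if callable(self.target):
            return self.target(t)
        out = []
        for comp in range(3):
            tc = self.target[comp]
            arr = np.broadcast_to(np.asarray(tc, dtype=float), grid.face_shape(comp))
            out.append(arr)
        return tuple(out)

    def max_rate(self) -> float:
        return max((float(a.max()) if a.size else 0.0) for a in self.lam)


def fringe_force(
    state: VelocityField,
    grid: StaggeredGrid,
    region: FringeRegion,
    substep: int,
    dt: float,
    alphas: Sequence[float] = RK3_ALPHAS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Volumetric force ``lambda (U - u)`` on each component's face grid.

    With ``stability_scaled`` set, ``lambda = 1 / (alpha(substep) * dt)``
    inside the region, which makes the explicit stage update land on the
    target exactly.
    """
    targets = region.target_at(state.t, grid)
    forces = []
    for comp, u in enumerate(state.components()):
        if region.stability_scaled:
            lam = region.masks[comp] / (alphas[substep] * dt)
        else:
            lam = region.lam[comp]
        forces.append(lam * (targets[comp] - u))
    return tuple(forces)


def no_slip_walls(
    fld: VelocityField, grid: StaggeredGrid, axes: Optional[Sequence[int]] = None
) -> VelocityField:
    """Zero the wall-normal velocity on the boundary faces of wall axes.

    The tangential no-slip condition is imposed inside the stencils through
    odd ghost extension about the wall plane (so the interpolated wall
    velocity vanishes); only the normal faces are stored explicitly.
    """
    if axes is None:
        axes = [a for a in range(3) if not grid.periodic[a]]
    for axis in axes:
        if grid.periodic[axis]:
            raise ValueError(f"axis {axis} is periodic; cannot place a wall on it")
        comp = fld.components()[axis]
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[axis] = 0
        last[axis] = -1
        comp[tuple(first)] = 0.0
        comp[tuple(last)] = 0.0
    return fld


# -- finite-difference helpers (single axis, periodicity-aware) -------------

def _avg_f2c(a, axis, per):
    if per:
        return 0.5 * (a + np.roll(a, -1, axis=axis))
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    return 0.5 * (a[tuple(lo)] + a[tuple(hi)])


def _avg_c2f_full(a, axis, per):
    # centers -> all faces of that axis; odd ghost across walls so the
    # tangential wall value is exactly zero (no-slip)
    if per:
        return 0.5 * (a + np.roll(a, 1, axis=axis))
    first = [slice(None)] * a.ndim
    last = [slice(None)] * a.ndim
    first[axis] = slice(0, 1)
    last[axis] = slice(-1, None)
    pad = np.concatenate([-a[tuple(first)], a, -a[tuple(last)]], axis=axis)
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    return 0.5 * (pad[tuple(lo)] + pad[tuple(hi)])


def _avg_c2f_interior(a, axis, per):
    if per:
        return 0.5 * (a + np.roll(a, 1, axis=axis))
    lo = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    return 0.5 * (a[tuple(lo)] + a[tuple(hi)])


def _ddx_f2c(a, axis, per, d):
    if per:
        return (np.roll(a, -1, axis=axis) - a) / d
    return np.diff(a, axis=axis) / d


def _ddx_c2f(a, axis, per, d):
    # derivative of center data at that axis' faces (interior faces on wall
    # axes)
    if per:
        return (a - np.roll(a, 1, axis=axis)) / d
    return np.diff(a, axis=axis) / d


def _d2_face(a, axis, per, d):
    if per:
        return (np.roll(a, -1, axis=axis) + np.roll(a, 1, axis=axis) - 2 * a) / d**2
    lo = [slice(None)] * a.ndim
    mid = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -2)
    mid[axis] = slice(1, -1)
    hi[axis] = slice(2, None)
    return (a[tuple(lo)] - 2 * a[tuple(mid)] + a[tuple(hi)]) / d**2


def _d2_center(a, axis, per, d):
    if per:
        return (np.roll(a, -1, axis=axis) + np.roll(a, 1, axis=axis) - 2 * a) / d**2
    first = [slice(None)] * a.ndim
    last = [slice(None)] * a.ndim
    first[axis] = slice(0, 1)
    last[axis] = slice(-1, None)
    pad = np.concatenate([-a[tuple(first)], a, -a[tuple(last)]], axis=axis)
    lo = [slice(None)] * a.ndim
    mid = [slice(None)] * a.ndim
    hi = [slice(None)] * a.ndim
    lo[axis] = slice(0, -2)
    mid[axis] = slice(1, -1)
    hi[axis] = slice(2, None)
    return (pad[tuple(lo)] - 2 * pad[tuple(mid)] + pad[tuple(hi)]) / d**2


def _interior_slice(axis: int):
    s = [slice(None)] * 3
    s[axis] = slice(1, -1)
    return tuple(s)


def momentum_rhs(
    fld: VelocityField, grid: StaggeredGrid, nu: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advection (divergence form) plus diffusion for the three momentum
    components, evaluated at the points being updated (interior faces on
    wall axes, every face on periodic axes)."""
    comps = fld.components()
    out = []
    for c in range(3):
        perm = (c, (c + 1) % 3, (c + 2) % 3)
        inv = tuple(np.argsort(perm))
        a = np.transpose(comps[c], perm)
        b1 = np.transpose(comps[perm[1]], perm)
        b2 = np.transpose(comps[perm[2]], perm)
        d0, d1, d2 = (grid.spacing[p] for p in perm)
        p0, p1, p2 = (grid.periodic[p] for p in perm)

        # own-axis flux d(a a)/dx0
        ac = _avg_f2c(a, 0, p0)
        t0 = _ddx_c2f(ac * ac, 0, p0, d0)

        # transverse flux d(b1 a)/dx1 at the corner points
        b1_on = _avg_c2f_interior(b1, 0, p0)
        a_c1 = _avg_c2f_full(a, 1, p1)
        if not p0:
            a_c1 = a_c1[_interior_slice(0)]
        t1 = _ddx_f2c(b1_on * a_c1, 1, p1, d1)

        # transverse flux d(b2 a)/dx2
        b2_on = _avg_c2f_interior(b2, 0, p0)
        a_c2 = _avg_c2f_full(a, 2, p2)
        if not p0:
            a_c2 = a_c2[_interior_slice(0)]
        t2 = _ddx_f2c(b2_on * a_c2, 2, p2, d2)

        lap = _d2_face(a, 0, p0, d0)
        l1 = _d2_center(a, 1, p1, d1)
        l2 = _d2_center(a, 2, p2, d2)
        if not p0:
            l1 = l1[_interior_slice(0)]
            l2 = l2[_interior_slice(0)]

        rhs = -(t0 + t1 + t2) + nu * (lap + l1 + l2)
        out.append(np.transpose(rhs, inv))
    return tuple(out)


# -- pressure projection ----------------------------------------------------

def _laplacian_eigenvalues(grid: StaggeredGrid) -> np.ndarray:
    eig = []
    for axis in range(3):
        n, d = grid.shape[axis], grid.spacing[axis]
        k = np.arange(n)
        if grid.periodic[axis]:
            lam = 2.0 * (np.cos(2.0 * np.pi * k / n) - 1.0) / d**2
        else:
            lam = 2.0 * (np.cos(np.pi * k / n) - 1.0) / d**2
        eig.append(lam)
    return (
        eig[0][:, None, None] + eig[1][None, :, None] + eig[2][None, None, :]
    )


def poisson_solve(rhs: np.ndarray, grid: StaggeredGrid) -> np.ndarray:
    """Solve the discrete Poisson equation with periodic / wall-Neumann
    boundary conditions; the zero-mean mode is removed."""
    arr = rhs.astype(complex)
    for axis in range(3):
        if grid.periodic[axis]:
            arr = sp_fft.fft(arr, axis=axis)
        else:
            arr = sp_fft.dct(arr.real, type=2, axis=axis, norm="ortho") + 1j * sp_fft.dct(
                arr.imag, type=2, axis=axis, norm="ortho"
            )
    denom = _laplacian_eigenvalues(grid)
    denom_safe = np.where(np.abs(denom) < 1e-14, 1.0, denom)
    arr = arr / denom_safe
    arr[np.abs(denom) < 1e-14] = 0.0
    for axis in range(2, -1, -1):
        if grid.periodic[axis]:
            arr = sp_fft.ifft(arr, axis=axis)
        else:
            arr = sp_fft.idct(arr.real, type=2, axis=axis, norm="ortho") + 1j * sp_fft.idct(
                arr.imag, type=2, axis=axis, norm="ortho"
            )
    return arr.real


def project(fld: VelocityField, grid: StaggeredGrid, dt_eff: float) -> VelocityField:
    """Pressure projection: remove the divergent part of the velocity.

    Solves ``lap(phi) = div(u*) / dt_eff`` and corrects
    ``u = u* - dt_eff grad(phi)``; wall-normal boundary faces are not
    touched (homogeneous Neumann on phi).
    """
    div = divergence(fld, grid).values
    phi = poisson_solve(div / dt_eff, grid)
    comps = fld.components()
    for axis in range(3):
        g = _ddx_c2f(phi, axis, grid.periodic[axis], grid.spacing[axis])
        if grid.periodic[axis]:
            comps[axis][...] -= dt_eff * g
        else:
            comps[axis][_interior_slice(axis)] -= dt_eff * g
    fld.p = phi * dt_eff  # pseudo-pressure of the step
    return fld


# -- time stepping ----------------------------------------------------------

def compute_dt(
    state: VelocityField,
    grid: StaggeredGrid,
    cfg: SolverConfig,
    regions: Sequence[FringeRegion] = (),
) -> float:
    """Advective CFL with viscous and fringe-rate stability caps."""
    if cfg.dt is not None:
        return cfg.dt
    dt = cfg.dt_max
    for axis, comp in enumerate(state.components()):
        if grid.shape[axis] == 1:
            continue
        umax = float(np.abs(comp).max())
        if umax > 1e-12:
            dt = min(dt, cfg.cfl * grid.spacing[axis] / umax)
    inv2 = sum(1.0 / d**2 for d, n in zip(grid.spacing, grid.shape) if n > 1)
    dt = min(dt, 0.6 * 2.5 / (4.0 * cfg.nu * inv2))
    for region in regions:
        if not region.stability_scaled:
            lam = region.max_rate()
            if lam > 0:
                dt = min(dt, 0.5 * 2.5 / lam)
    return dt


def _apply_bulk_constraint(fld: VelocityField, cfg: SolverConfig) -> None:
    if cfg.bulk_axis is None or cfg.bulk_velocity is None:
        return
    comp = fld.components()[cfg.bulk_axis]
    comp += cfg.bulk_velocity - comp.mean()


def rk3_step(
    state: VelocityField,
    grid: StaggeredGrid,
    cfg: SolverConfig,
    regions: Sequence[FringeRegion] = (),
    dt: Optional[float] = None,
) -> VelocityField:
    """Advance one time step with the three-stage Runge-Kutta scheme.

    Every stage applies advection + diffusion + fringe forces explicitly and
    is followed by a pressure projection, wall enforcement and (if
    configured) the bulk-velocity constraint.
    """
    if dt is None:
        dt = compute_dt(state, grid, cfg, regions)
    t0 = state.t
    base = state.copy()
    cur = state.copy()
    for k, alpha in enumerate(cfg.rk_alphas):
        rhs = momentum_rhs(cur, grid, cfg.nu)
        forces = [np.zeros_like(r) for r in rhs]
        for region in regions:
            f = fringe_force(cur, grid, region, k, dt, cfg.rk_alphas)
            for axis in range(3):
                fa = f[axis]
                if not grid.periodic[axis]:
                    fa = fa[_interior_slice(axis)]
                forces[axis] += fa
        new = base.copy()
        comps = new.components()
        for axis in range(3):
            upd = alpha * dt * (rhs[axis] + forces[axis])
            if grid.periodic[axis]:
                comps[axis][...] = base.components()[axis] + upd
            else:
                comps[axis][_interior_slice(axis)] = (
                    base.components()[axis][_interior_slice(axis)] + upd
                )
        no_slip_walls(new, grid)
        project(new, grid, alpha * dt)
        no_slip_walls(new, grid)
        _apply_bulk_constraint(new, cfg)
        new.t = t0 + alpha * dt
        cur = new
    cur.t = t0 + dt
    if not np.isfinite(cur.u).all() or not np.isfinite(cur.v).all():
        raise FloatingPointError(
            f"solver produced non-finite values at t={cur.t:.6g} (dt={dt:.3g})"
        )
    return cur


def advance_to(
    state: VelocityField,
    grid: StaggeredGrid,
    cfg: SolverConfig,
    regions: Sequence[FringeRegion] = (),
    t_target: float = 0.0,
    observer: Optional[Callable[[VelocityField], None]] = None,
) -> VelocityField:
    """Integrate until ``t_target``, shortening the last step to land on it
    exactly.  Returns the forecast state."""
    if t_target < state.t - 1e-12:
        raise ValueError("t_target lies in the past of the state")
    cur = state
    while cur.t < t_target - 1e-12:
        dt = compute_dt(cur, grid, cfg, regions)
        dt = min(dt, t_target - cur.t)
        cur = rk3_step(cur, grid, cfg, regions, dt)
        if observer is not None:
            observer(cur)
    cur.t = t_target
    return cur
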