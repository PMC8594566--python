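"""Twin-experiment factories: ground-truth runs, synthetic voxel
observation extraction, and the three case families.

* Confined cylinder (quasi-2D, Re = 150): periodic vortex shedding in a
  channel of width 2h with a cylinder of diameter h at (9h, h); inflow
  plug flow imposed by fringe forcing, the cylinder itself modeled as a
  fringe region with zero target velocity.
* Turbulent channel (Re = 5000): periodic streamwise/spanwise directions,
  no-slip walls, constant bulk velocity 0.667; the initial Poiseuille
  profile is destabilized with random divergence-free perturbations.
* Pulsatile jet (synthetic): a round pulsatile jet inside a cylindrical
  phantom mask, emulating the structure of a valve-flow acquisition
  pipeline (walls from zero-valued data, inflow from the lowest data
  slices, heart-rate 70 beats/min, non-uniform phase schedule refined x3).

Voxel lattices for extraction tile the observation window with
``(1 + dw)`` nodes per voxel and axis, so the downsampling factor ``dw``
controls the data resolution (``dw = 0`` is node-resolution identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .ensemble import PhaseSchedule, RunningMoments, phase_average_samples
from .grids import StaggeredGrid, VelocityField, interpolate_to_centers
from .observation import (
    GridVoxelMapping,
    ObservationSample,
    ObservationSet,
    VoxelGrid,
    build_mapping,
    observe_centers,
)
from .solver import FringeRegion, SolverConfig, advance_to

__all__ = [
    "CaseBundle",
    "cylinder_case",
    "channel_case",
    "pulsatile_jet_case",
    "window_voxels",
    "downsample",
    "run_spin_up",
    "extract_observations",
    "estimate_period",
    "shedding_period",
    "voxel_mean_field",
    "phase_mean_rmse",
]

#: Reference shedding period of the full-scale confined-cylinder flow.
CYLINDER_REFERENCE_PERIOD = 1.9951


@dataclass
class CaseBundle:
    """Everything needed to run a case: grid, solver settings, fringe
    regions for the ground truth and for the DA prediction, the phase
    schedule and the observation windows."""

    name: str
    grid: StaggeredGrid
    solver: SolverConfig
    truth_regions: tuple[FringeRegion, ...]
    da_regions: tuple[FringeRegion, ...]
    schedule: PhaseSchedule
    windows: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]]
    d_diag: float
    dw: int
    spin_up: float
    params: dict = field(default_factory=dict)

    def window_voxels(self, window: str, dw: Optional[int] = None) -> VoxelGrid:
        lo, hi = self.windows[window]
        return window_voxels(self.grid, lo, hi, self.dw if dw is None else dw)


# -- voxel lattice construction ---------------------------------------------

def window_voxels(
    grid: StaggeredGrid,
    lo: tuple[float, float, float],
    hi: tuple[float, float, float],
    dw: int,
) -> VoxelGrid:
    """Voxel lattice tiling the window ``[lo, hi]`` with ``(1 + dw)`` grid
    nodes per voxel and axis.

    The window bounds must coincide with cell faces and the node count per
    axis must be divisible by ``1 + dw`` (collapsed single-layer axes are
    kept as one voxel layer).
    """
    if dw < 0:
        raise ValueError("dw must be >= 0")
    origin, spacing, shape = [], [], []
    for a in range(3):
        d = grid.spacing[a]
        o = grid.origin[a]
        i0 = (lo[a] - o) / d
        i1 = (hi[a] - o) / d
        if abs(i0 - round(i0)) > 1e-9 or abs(i1 - round(i1)) > 1e-9:
            raise ValueError("window bounds must lie on cell faces")
        i0, i1 = int(round(i0)), int(round(i1))
        ncells = i1 - i0
        if grid.shape[a] == 1:
            origin.append(o + i0 * d)
            spacing.append(ncells * d)
            shape.append(1)
            continue
        k = dw + 1
        if ncells % k != 0:
            raise ValueError(
                f"window node count {ncells} on axis {a} is not divisible "
                f"by 1 + dw = {k}"
            )
        origin.append(o + i0 * d)
        spacing.append(k * d)
        shape.append(ncells // k)
    return VoxelGrid(tuple(origin), tuple(spacing), tuple(shape), None, dw)


def downsample(
    grid: StaggeredGrid,
    lo: tuple[float, float, float],
    hi: tuple[float, float, float],
    dw: int,
) -> VoxelGrid:
    """Coarsened voxel lattice for the given window (alias of
    :func:`window_voxels` with explicit ``dw``)."""
    return window_voxels(grid, lo, hi, dw)


# -- case factories ---------------------------------------------------------

def cylinder_case(scale: str = "full") -> CaseBundle:
    """Quasi-2D flow past a confined cylinder at Re = 150.

    Channel 32h x 2h, cylinder of diameter h centered at (9h, h), no-slip
    walls, plug inflow U = (1, 0, 0) enforced by a fringe region
    (lambda = 50) at the end of the periodic streamwise direction, the
    cylinder modeled by a fringe region with zero target (lambda = 100).
    """
    h = 1.0
    if scale == "full":
        nx, ny = 256, 32
    elif scale == "reduced":
        nx, ny = 128, 16
    else:
        raise ValueError("scale must be 'full' or 'reduced'")
    grid = StaggeredGrid(
        (nx, ny, 1), (32 * h / nx, 2 * h / ny, h), (True, False, True)
    )
    solver = SolverConfig(nu=h * 1.0 / 150.0, cfl=0.32, dt_max=0.02, re=150.0)

    inflow = FringeRegion.from_predicate(
        grid,
        lambda x, y, z: x >= 30.0 * h,
        lam=50.0,
        target=(1.0, 0.0, 0.0),
        name="inflow",
    )
    cyl = FringeRegion.from_predicate(
        grid,
        lambda x, y, z: (x - 9.0 * h) ** 2 + (y - h) ** 2 <= (0.5 * h) ** 2,
        lam=100.0,
        target=(0.0, 0.0, 0.0),
        name="cylinder",
    )
    schedule = PhaseSchedule.uniform(CYLINDER_REFERENCE_PERIOD, 20)
    windows = {
        "w1": ((7.0, 0.5, 0.0), (11.0, 1.5, h)),
        "w2": ((7.0, 0.5, 0.0), (9.0, 1.5, h)),
        "w3": ((9.0, 0.5, 0.0), (11.0, 1.5, h)),
        "w4": ((7.0, 0.0, 0.0), (11.0, 2.0, h)),
        "w5": ((7.0, 0.0, 0.0), (9.0, 2.0, h)),
        "w6": ((9.0, 0.0, 0.0), (11.0, 2.0, h)),
        "full": ((0.0, 0.0, 0.0), (32.0, 2.0, h)),
    }
    spin_up = 100 * CYLINDER_REFERENCE_PERIOD if scale == "full" else 60.0
    return CaseBundle(
        name=f"cylinder-{scale}",
        grid=grid,
        solver=solver,
        truth_regions=(inflow, cyl),
        da_regions=(inflow,),
        schedule=schedule,
        windows=windows,
        d_diag=1000.0,
        dw=1,
        spin_up=spin_up,
        params={"h": h, "probe": (15.0 * h, h), "cylinder_center": (9.0 * h, h)},
    )


def _solenoidal_perturbation(
    grid: StaggeredGrid, amplitude: float, rng: np.random.Generator, modes: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random smooth divergence-free velocity perturbation from the curl of
    a low-mode vector potential, vanishing at the walls."""
    lx, ly, lz = grid.extents
    xu, yu, zu = grid.component_mesh(0)
    xv, yv, zv = grid.component_mesh(1)
    xw, yw, zw = grid.component_mesh(2)
    du = np.zeros(grid.face_shape(0))
    dv = np.zeros(grid.face_shape(1))
    dw_ = np.zeros(grid.face_shape(2))
    for _ in range(modes):
        kx = rng.integers(1, 4) * 2 * np.pi / lx
        kz = rng.integers(1, 4) * 2 * np.pi / lz
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        amp = rng.uniform(0.5, 1.0)
        # stream-function-like mode in (x, y) and (z, y); psi ~ sin(pi y/ly)
        # so the curl vanishes at the walls
        du += amp * np.sin(kx * xu + ph1) * np.cos(np.pi * yu / ly) * np.pi / ly
        dv += amp * kx * np.cos(kx * xv + ph1) * np.sin(np.pi * yv / ly) * (-1)
        dw_ += amp * np.sin(kz * zw + ph2) * np.cos(np.pi * yw / ly) * np.pi / ly
        dv += amp * kz * np.cos(kz * zv + ph2) * np.sin(np.pi * yv / ly) * (-1)
    scale = amplitude / max(
        np.abs(du).max(), np.abs(dv).max(), np.abs(dw_).max(), 1e-12
    )
    return du * scale, dv * scale, dw_ * scale


def channel_case(
    scale: str = "full",
    perturbation_amplitude: float = 0.1,
    seed: int = 12345,
    update_interval: float = 0.5,
) -> CaseBundle:
    """Wall-bounded turbulent channel at Re = 5000.

    Domain 4 pi h x 2h x 2 pi h, periodic in x and z, no-slip walls in y,
    constant bulk velocity 0.667 in x; the initial condition is the
    Poiseuille profile with centerline velocity 1 plus seeded random
    solenoidal perturbations.  Single-phase (statistically steady)
    schedule with the given update interval.
    """
    h = 1.0
    if scale == "full":
        n = 60
    elif scale == "reduced":
        n = 24
    else:
        raise ValueError("scale must be 'full' or 'reduced'")
    grid = StaggeredGrid(
        (n, n, n),
        (4 * np.pi * h / n, 2 * h / n, 2 * np.pi * h / n),
        (True, False, True),
    )
    solver = SolverConfig(
        nu=1.0 / 5000.0,
        cfl=0.32,
        dt_max=0.05,
        re=5000.0,
        bulk_axis=0,
        bulk_velocity=0.667,
    )
    schedule = PhaseSchedule.steady(update_interval)
    pih = float(np.pi * h)
    windows = {
        "w1": ((2 * pih - pih / 4, 0.5, 0.0), (2 * pih + pih / 4, 1.5, 2 * pih)),
        "w2": ((2 * pih - pih / 4, 0.0, 0.0), (2 * pih + pih / 4, 2.0, 2 * pih)),
        "w3": ((0.0, 0.5, 0.0), (4 * pih, 1.5, 2 * pih)),
        "w4": ((0.0, 0.0, 0.0), (4 * pih, 2.0, 2 * pih)),
    }
    return CaseBundle(
        name=f"channel-{scale}",
        grid=grid,
        solver=solver,
        truth_regions=(),
        da_regions=(),
        schedule=schedule,
        windows=windows,
        d_diag=10.0,
        dw=2,
        spin_up=200.0 if scale == "full" else 80.0,
        params={
            "h": h,
            "perturbation_amplitude": perturbation_amplitude,
            "perturbation_seed": seed,
        },
    )


def channel_initial_state(bundle: CaseBundle, perturbed: bool = True) -> VelocityField:
    """Poiseuille initial condition, optionally with the seeded random
    solenoidal perturbation that triggers transition."""
    grid = bundle.grid
    fld = VelocityField.zeros(grid)
    _, yu, _ = grid.component_mesh(0)
    h = bundle.params["h"]
    fld.u[...] = yu * (2 * h - yu) / h**2
    if perturbed:
        rng = np.random.default_rng(bundle.params["perturbation_seed"])
        du, dv, dw_ = _solenoidal_perturbation(
            grid, bundle.params["perturbation_amplitude"], rng
        )
        fld.u += du
        fld.v += dv
        fld.w += dw_
    from .solver import no_slip_walls, project

    no_slip_walls(fld, grid)
    project(fld, grid, 1.0)
    no_slip_walls(fld, grid)
    return fld


#: Non-uniform division of the heart cycle (s): dense sampling through
#: systole, sparse through diastole; heart rate 70 beats/min.
JET_PHASE_TIMES_COARSE = (
    0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12, 0.13, 0.14, 0.15,
    0.16, 0.17, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.60, 0.70,
)


def pulsatile_jet_case(
    shape: tuple[int, int, int] = (18, 27, 18),
    phantom_radius: float = 1.1,
    jet_radius: float = 0.5,
    peak_velocity: float = 1.0,
) -> CaseBundle:
    """Synthetic pulsatile round jet inside a cylindrical phantom.

    The stream-wise direction is y; the phantom wall and the inflow are
    enforced by stability-scaled fringe regions (walls with zero target,
    inflow from the prescribed pulsatile profile), mirroring a pipeline in
    which wall and inflow conditions come from voxel data slices.  The
    pulse period is 60/70 s and the coarse 22-interval phase schedule is
    refined by a factor of 3 for the assimilation (66 intervals).
    """
    period = 60.0 / 70.0
    lx, ly, lz = 3.0, 4.5, 3.0
    grid = StaggeredGrid(
        shape, (lx / shape[0], ly / shape[1], lz / shape[2]),
        (True, True, True), origin=(-lx / 2, 0.0, -lz / 2),
    )
    solver = SolverConfig(nu=1.0 / 4900.0, cfl=0.3, dt_max=0.01, re=4900.0)

    def waveform(t: float) -> float:
        # systolic pulse: smooth ejection over ~0.35T, then diastole
        tau = (t % period) / period
        sys_frac = 0.35
        if tau < sys_frac:
            return float(np.sin(np.pi * tau / sys_frac) ** 2)
        return 0.0

    inflow_height = 0.5
    xu, yu, zu = grid.component_mesh(1)  # v-component mesh (stream-wise)

    def inflow_profile(t: float):
        r2 = xu**2 + zu**2
        vy = (
            peak_velocity
            * waveform(t)
            * np.exp(-((np.sqrt(r2) / jet_radius) ** 8))
        )
        return (
            np.zeros(grid.face_shape(0)),
            vy,
            np.zeros(grid.face_shape(2)),
        )

    inflow = FringeRegion.from_predicate(
        grid,
        lambda x, y, z: y <= inflow_height,
        lam=1.0,
        target=inflow_profile,
        stability_scaled=True,
        name="inflow",
    )
    wall = FringeRegion.from_predicate(
        grid,
        lambda x, y, z: (x**2 + z**2 >= phantom_radius**2) | (y >= ly - 0.3),
        lam=1.0,
        target=(0.0, 0.0, 0.0),
        stability_scaled=True,
        name="phantom-wall",
    )
    schedule = PhaseSchedule(period, JET_PHASE_TIMES_COARSE).refined(3)
    windows = {
        "bulk": (
            (-lx / 2, inflow_height * 2, -lz / 2),
            (lx / 2, ly - 0.5, lz / 2),
        ),
        "full": ((-lx / 2, 0.0, -lz / 2), (lx / 2, ly, lz / 2)),
    }
    # snap window bounds to cell faces
    snapped = {}
    for k, (lo, hi) in windows.items():
        lo2, hi2 = [], []
        for a in range(3):
            d, o = grid.spacing[a], grid.origin[a]
            lo2.append(o + round((lo[a] - o) / d) * d)
            hi2.append(o + round((hi[a] - o) / d) * d)
        snapped[k] = (tuple(lo2), tuple(hi2))
    return CaseBundle(
        name="pulsatile-jet",
        grid=grid,
        solver=solver,
        truth_regions=(inflow, wall),
        da_regions=(inflow, wall),
        schedule=schedule,
        windows=snapped,
        d_diag=10.0,
        dw=2,
        spin_up=0.0,
        params={
            "period": period,
            "waveform": waveform,
            "phantom_radius": phantom_radius,
            "coarse_schedule": PhaseSchedule(period, JET_PHASE_TIMES_COARSE),
        },
    )


# -- ground truth and observation extraction --------------------------------

def run_spin_up(
    bundle: CaseBundle,
    state: Optional[VelocityField] = None,
    t_end: Optional[float] = None,
    observer=None,
) -> VelocityField:
    """Integrate the ground-truth configuration through its transient."""
    if state is None:
        state = VelocityField.zeros(bundle.grid)
    t_end = bundle.spin_up if t_end is None else t_end
    return advance_to(
        state, bundle.grid, bundle.solver, bundle.truth_regions, t_end, observer
    )


def extract_observations(
    bundle: CaseBundle,
    state: VelocityField,
    voxels: VoxelGrid,
    n_pulses: int,
    schedule: Optional[PhaseSchedule] = None,
    keep_samples: bool = True,
    truth_moments: bool = True,
    mask_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[ObservationSet, Optional[RunningMoments], VelocityField]:
    """Run the ground truth over ``n_pulses`` pulses and collect per-pulse
    voxel samples at every phase time, then phase-average them into an
    observation set.

    ``mask_fn`` (voxel-center coordinates -> bool) zeroes mean and
    covariance outside a region of interest, emulating masked acquisition.
    Also accumulates node-level phase moments of the truth for twin
    evaluation when ``truth_moments`` is set.
    """
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    schedule = bundle.schedule if schedule is None else schedule
    mapping = build_mapping(bundle.grid, voxels)
    t0 = state.t
    samples = []
    tm = (
        RunningMoments(bundle.grid.shape, schedule.n_phases, 0.0)
        if truth_moments
        else None
    )
    cur = state
    for s in range(1, n_pulses + 1):
        for phi in range(schedule.n_phases):
            cur = advance_to(
                cur,
                bundle.grid,
                bundle.solver,
                bundle.truth_regions,
                t0 + schedule.time_of(s, phi),
            )
            uc = interpolate_to_centers(cur, bundle.grid)
            samples.append(
                ObservationSample(
                    s, phi, observe_centers(uc.reshape(-1, 3), mapping)
                )
            )
            if tm is not None:
                tm.update(phi, uc)
    obs = phase_average_samples(
        samples, voxels, schedule.phase_times, schedule.period, keep_samples
    )
    if mask_fn is not None:
        centers = _voxel_centers(voxels, mapping)
        outside = ~mask_fn(centers)
        obs.mean[:, outside] = 0.0
        obs.cov[:, outside] = 0.0
        if obs.samples is not None:
            obs.samples[:, :, outside] = 0.0
    return obs, tm, cur


def _voxel_centers(voxels: VoxelGrid, mapping: GridVoxelMapping) -> np.ndarray:
    idx = np.array(np.unravel_index(mapping.voxel_ids, voxels.shape)).T
    return np.asarray(voxels.origin) + (idx + 0.5) * np.asarray(voxels.spacing)


# -- period estimation -------------------------------------------------------

def estimate_period(t: np.ndarray, x: np.ndarray) -> float:
    """Dominant oscillation period by FFT with local parabolic peak
    interpolation; the signal is resampled uniformly first."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 16:
        raise ValueError("signal too short for period estimation")
    tu = np.linspace(t[0], t[-1], t.size)
    xu = np.interp(tu, t, x)
    xu = (xu - xu.mean()) * np.hanning(xu.size)
    mag = np.abs(np.fft.rfft(xu))
    k = int(np.argmax(mag[1:]) + 1)
    df = 1.0 / (tu[-1] - tu[0])
    # refine around the discrete peak: scan the windowed DFT magnitude on a
    # fine frequency lattice, then parabolic interpolation of the maximum
    freqs = (k + np.linspace(-1.0, 1.0, 401)) * df
    amp = np.abs(np.exp(-2j * np.pi * np.outer(freqs, tu)) @ xu)
    j = int(np.argmax(amp))
    if 0 < j < amp.size - 1:
        a, b, c = amp[j - 1], amp[j], amp[j + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if abs(denom) > 1e-30 else 0.0
    else:
        delta = 0.0
    freq = freqs[j] + delta * (freqs[1] - freqs[0])
    return 1.0 / freq


def shedding_period(
    bundle: CaseBundle,
    state: Optional[VelocityField] = None,
    n_cycles: float = 25.0,
) -> tuple[float, VelocityField]:
    """Measure the vortex-shedding period of a cylinder bundle from the
    cross-stream velocity at a downstream wake probe.

    Spins up the case if no state is given, then records the probe signal
    over about ``n_cycles`` nominal periods and applies
    :func:`estimate_period`.
    """
    grid = bundle.grid
    px, py = bundle.params["probe"]
    iu = int((px - grid.origin[0]) / grid.spacing[0]) % grid.shape[0]
    jv = int((py - grid.origin[1]) / grid.spacing[1])
    times, vals = [], []

    def probe(fld: VelocityField) -> None:
        times.append(fld.t)
        vals.append(fld.v[iu, jv, 0])

    if state is None:
        state = run_spin_up(bundle)
    t_end = state.t + n_cycles * bundle.schedule.period
    state = advance_to(
        state, grid, bundle.solver, bundle.truth_regions, t_end, observer=probe
    )
    return estimate_period(np.asarray(times), np.asarray(vals)), state


# -- twin evaluation ---------------------------------------------------------

def voxel_mean_field(
    mean_field: np.ndarray, mapping: GridVoxelMapping
) -> np.ndarray:
    """Replace every node value by its voxel average (voxel-discretized
    version of a node field); nodes outside the window keep their value."""
    flat = mean_field.reshape(-1, 3).copy()
    obs = observe_centers(mean_field.reshape(-1, 3), mapping)
    acc = np.zeros_like(flat)
    for gv, (pos, nodes) in mapping.groups.items():
        np.add.at(acc, nodes.ravel(), np.repeat(obs[pos], gv, axis=0))
    psi = mapping.psi
    inside = psi > 0
    flat[inside] = acc[inside] * psi[inside, None]
    return flat.reshape(mean_field.shape)


def phase_mean_rmse(
    a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Root-mean-square difference of two node vector fields, optionally
    restricted to a node mask."""
    diff = (np.asarray(a) - np.asarray(b)) ** 2
    mag = diff.sum(axis=-1)
    if mask is not None:
        mag = mag[mask]
    return float(np.sqrt(mag.mean()))
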