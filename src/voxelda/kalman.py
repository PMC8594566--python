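"""Stochastic ensemble Kalman analysis: per-voxel block gains, node-level
assembly and the full data-assimilation driver.

The state covariance is block-diagonal over grid nodes (3x3 per node) and
the observation covariance block-diagonal over voxels, so the Kalman gain
never has to be formed globally.  For a single voxel ``v`` with ``g_v``
member nodes and block observation operator ``h`` (entries ``1/g_v`` on
each diagonal), the innovation covariance is the 3x3 matrix

    S_v = h p^f h^T + r_v = (1/g_v^2) sum_g p^f_g + r_v ,

and the correction contributed to member node ``g`` is

    p^f_g (1/g_v) S_v^{-1} (d_v - h u^f) .

Nodes shared by several voxels average their contributions with weights
``1/v_g``; nodes outside every active voxel receive no correction.  The
correction is computed on center-collocated velocities and redistributed
to the staggered faces by the adjoint of the center interpolation; by
default the analysis state is re-projected so it remains discretely
divergence-free (the forward model's precondition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .ensemble import PhaseSchedule, RunningMoments
from .grids import StaggeredGrid, VelocityField, interpolate_to_centers, spread_to_faces
from .observation import (
    GridVoxelMapping,
    ObservationSet,
    innovation,
    observe_centers,
)
from .solver import FringeRegion, SolverConfig, advance_to, no_slip_walls, project

__all__ = [
    "KalmanConfig",
    "NodeGain",
    "voxel_gain",
    "compute_contributions",
    "assemble_node_gain",
    "analysis_update",
    "run_da",
    "DARun",
]


@dataclass
class KalmanConfig:
    """Settings of the analysis loop.

    ``sampling`` selects how the per-pulse observation sample is produced:
    ``"cycle"`` replays stored per-pulse samples (pulse ``s`` uses stored
    sample ``(s - 1) mod p``), ``"perturb"`` draws ``d ~ N(dbar, r)`` per
    voxel.  ``d_diag`` is the covariance regularization D handed to the
    forecast moments.  All randomness comes from ``seed``.
    """

    n_pulses: int
    d_diag: float = 10.0
    sampling: str = "cycle"
    seed: int = 0
    reproject: bool = True
    obs_cov_scale: float = 1.0
    analysis_burn_in: int = 0

    def __post_init__(self) -> None:
        if self.sampling not in ("cycle", "perturb"):
            raise ValueError("sampling must be 'cycle' or 'perturb'")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")


@dataclass
class NodeGain:
    """Center-collocated correction vectors, zero outside the window."""

    values: np.ndarray  # grid.shape + (3,)


def voxel_gain(
    p_blocks: np.ndarray, r_v: np.ndarray, innov_v: np.ndarray
) -> np.ndarray:
    """Correction contributions of one voxel to its member nodes.

    Parameters
    ----------
    p_blocks
        ``(g_v, 3, 3)`` forecast covariance blocks of the member nodes.
    r_v
        ``(3, 3)`` observation covariance of the voxel.
    innov_v
        ``(3,)`` innovation ``d_v - h u^f``.

    Returns ``(g_v, 3)`` contributions ``p_g (1/g_v) S^{-1} innov``.
    """
    g_v = p_blocks.shape[0]
    s_mat = p_blocks.sum(axis=0) / g_v**2 + r_v
    try:
        w = np.linalg.solve(0.5 * (s_mat + s_mat.T), innov_v)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "innovation covariance singular; with D > 0 this indicates a "
            "misconfigured observation set"
        ) from err
    return (p_blocks @ w) / g_v


def compute_contributions(
    mapping: GridVoxelMapping,
    pf_flat: np.ndarray,
    obs_cov: np.ndarray,
    innov: np.ndarray,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Batched per-voxel gains for all active voxels.

    Returns, per ``g_v`` group, the member-node index matrix ``(K, g_v)``
    and the contribution array ``(K, g_v, 3)``.
    """
    out = {}
    for gv, (pos, nodes) in mapping.groups.items():
        pg = pf_flat[nodes]  # (K, g_v, 3, 3)
        s_mat = pg.sum(axis=1) / gv**2 + obs_cov[pos]
        s_mat = 0.5 * (s_mat + np.swapaxes(s_mat, -1, -2))
        w = np.linalg.solve(s_mat, innov[pos][..., None])[..., 0]  # (K, 3)
        contrib = np.einsum("kgij,kj->kgi", pg, w) / gv
        out[gv] = (nodes, contrib)
    return out


def assemble_node_gain(
    contributions: dict[int, tuple[np.ndarray, np.ndarray]],
    mapping: GridVoxelMapping,
) -> NodeGain:
    """Interpolate per-voxel contributions to the nodes:
    ``k_g = sum_v Psi_{g,v} contribution_{v,g}`` with ``Psi = 1/v_g``."""
    k = np.zeros((mapping.n_nodes, 3))
    for gv, (nodes, contrib) in contributions.items():
        np.add.at(k, nodes.ravel(), contrib.reshape(-1, 3))
    k *= mapping.psi[:, None]
    return NodeGain(k.reshape(mapping.grid.shape + (3,)))


def analysis_update(
    forecast: VelocityField,
    gain: NodeGain,
    grid: StaggeredGrid,
    reproject: bool = True,
) -> VelocityField:
    """Apply the analysis correction ``u^a = u^f + k`` to the staggered
    state, optionally restoring the divergence-free constraint."""
    out = forecast.copy()
    du, dv, dw = spread_to_faces(gain.values, grid)
    out.u += du
    out.v += dv
    out.w += dw
    no_slip_walls(out, grid)
    if reproject:
        project(out, grid, 1.0)
        no_slip_walls(out, grid)
    return out


def _draw_sample(
    obs: ObservationSet, phase: int, pulse: int, cfg: KalmanConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.sampling == "cycle" and obs.samples is not None:
        p = obs.samples.shape[0]
        return obs.samples[(pulse - 1) % p, phase]
    # Gaussian perturbation of the mean with the stored covariance
    cov = obs.cov[phase] * cfg.obs_cov_scale
    vals, vecs = np.linalg.eigh(0.5 * (cov + np.swapaxes(cov, -1, -2)))
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))[:, None, :]
    z = rng.standard_normal((obs.m_v, 3))
    return obs.mean[phase] + np.einsum("vij,vj->vi", root, z)


@dataclass
class DARun:
    """Outputs of a data-assimilation run."""

    state: VelocityField
    forecast_moments: RunningMoments
    analysis_moments: RunningMoments
    schedule: PhaseSchedule
    diagnostics: list = field(default_factory=list)
    seed: int = 0


def run_da(
    state: VelocityField,
    grid: StaggeredGrid,
    solver_cfg: SolverConfig,
    regions: Sequence[FringeRegion],
    schedule: PhaseSchedule,
    obs: ObservationSet,
    mapping: GridVoxelMapping,
    kcfg: KalmanConfig,
    diagnostics_fn: Optional[Callable[[int, int, VelocityField], dict]] = None,
) -> DARun:
    """Pulse/phase loop of the assimilation algorithm.

    For every pulse ``s`` and phase ``phi``: advance the forward model to
    ``t_phi + (s - 1) T``, fold the forecast into the running phase
    moments, select the observation sample, compute the block Kalman gain
    and apply the analysis update; the analysis state seeds the next
    forecast.
    """
    if obs.n_phases != schedule.n_phases:
        raise ValueError("observation set and schedule phase counts differ")
    rng = np.random.default_rng(kcfg.seed)
    fmom = RunningMoments(grid.shape, schedule.n_phases, kcfg.d_diag)
    amom = RunningMoments(grid.shape, schedule.n_phases, kcfg.d_diag)
    diagnostics = []
    cur = state
    for s in range(1, kcfg.n_pulses + 1):
        for phi in range(schedule.n_phases):
            t_n = schedule.time_of(s, phi)
            cur = advance_to(cur, grid, solver_cfg, regions, t_n)
            uc = interpolate_to_centers(cur, grid)
            fmom.update(phi, uc)
            pf = fmom.covariance_flat(phi)
            d_sample = _draw_sample(obs, phi, s, kcfg, rng)
            innov = innovation(
                d_sample, observe_centers(uc.reshape(-1, 3), mapping)
            )
            contrib = compute_contributions(
                mapping, pf, obs.cov[phi] * kcfg.obs_cov_scale, innov
            )
            gain = assemble_node_gain(contrib, mapping)
            cur = analysis_update(cur, gain, grid, reproject=kcfg.reproject)
            if s > kcfg.analysis_burn_in:
                amom.update(phi, interpolate_to_centers(cur, grid))
            if diagnostics_fn is not None:
                diagnostics.append(diagnostics_fn(s, phi, cur))
    return DARun(
        state=cur,
        forecast_moments=fmom,
        analysis_moments=amom,
        schedule=schedule,
        diagnostics=diagnostics,
        seed=kcfg.seed,
    )
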