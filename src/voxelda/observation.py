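"""Voxel observation grid and the discrete observation operator.

Observed data live on a Cartesian lattice of cubic voxels, coarser than the
computational grid.  The observation operator averages the (center
collocated) grid velocities over the nodes inside each voxel with equal
weights ``1/g_v``, where ``g_v`` is the number of member nodes.  Voxel
membership uses closed intervals: a node exactly on a shared voxel border
(within a tolerance of ``1e-9 h``) belongs to all adjacent voxels, and a
node inside ``v_g`` voxels receives their Kalman contributions with
interpolation weights ``1/v_g``.

Cross-voxel observation covariance is taken to be zero, so every voxel
carries an independent 3-vector mean and 3x3 covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import StaggeredGrid, VelocityField, interpolate_to_centers

__all__ = [
    "VoxelGrid",
    "GridVoxelMapping",
    "ObservationSample",
    "ObservationSet",
    "build_mapping",
    "observe",
    "innovation",
]

BORDER_RTOL = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """Cartesian voxel lattice with an active-window mask.

    ``spacing`` is the voxel edge length per axis, ``shape`` the voxel
    counts.  ``active`` marks which voxels carry data (observation
    windows); ``None`` means all.  ``dw`` is the downsampling factor used
    to generate the lattice (metadata; voxels comprise ``(1+dw)^3``
    adjacent nodes when aligned with the computational grid).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    active: Optional[np.ndarray] = None
    dw: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("voxel counts must be >= 1")
        if self.dw < 0:
            raise ValueError("downsampling factor dw must be >= 0")
        if self.active is not None and tuple(self.active.shape) != tuple(self.shape):
            raise ValueError("active mask shape must match voxel shape")

    @property
    def n_active(self) -> int:
        return int(self.active.sum()) if self.active is not None else int(
            np.prod(self.shape)
        )

    def active_mask(self) -> np.ndarray:
        if self.active is not None:
            return self.active.astype(bool)
        return np.ones(self.shape, dtype=bool)

    def with_window(
        self, lo: tuple[float, float, float], hi: tuple[float, float, float]
    ) -> "VoxelGrid":
        """Restrict the active mask to voxels fully inside [lo, hi]."""
        mask = self.active_mask().copy()
        for a in range(3):
            edges = self.origin[a] + np.arange(self.shape[a] + 1) * self.spacing[a]
            tol = BORDER_RTOL * self.spacing[a]
            ok = (edges[:-1] >= lo[a] - tol) & (edges[1:] <= hi[a] + tol)
            sl = [None, None, None]
            sl[a] = slice(None)
            mask &= ok[tuple(sl)]
        return VoxelGrid(self.origin, self.spacing, self.shape, mask, self.dw)


class GridVoxelMapping:
    """Discrete observation operator between grid nodes and active voxels.

    Holds, for every active voxel, the flat indices of its member nodes
    (``g_v`` per voxel, operator weight ``1/g_v``) and, for every node, the
    number ``v_g`` of active voxels containing it (interpolation weight
    ``1/v_g``; zero outside the window).  Voxels are grouped by ``g_v`` so
    the analysis step can run batched.
    """

    def __init__(
        self,
        grid: StaggeredGrid,
        voxels: VoxelGrid,
        voxel_ids: np.ndarray,
        groups: dict[int, tuple[np.ndarray, np.ndarray]],
        v_g: np.ndarray,
    ) -> None:
        self.grid = grid
        self.voxels = voxels
        self.voxel_ids = voxel_ids  # flat voxel index per active voxel (ordered)
        self.groups = groups  # g_v -> (positions into active order, node idx [K, g_v])
        self.v_g = v_g  # per-node containing-voxel count, flat over grid.shape
        self.n_nodes = int(np.prod(grid.shape))
        self.m_v = len(voxel_ids)

    @property
    def psi(self) -> np.ndarray:
        """Interpolation weight 1/v_g per node (0 outside the window)."""
        with np.errstate(divide="ignore"):
            w = np.where(self.v_g > 0, 1.0 / np.maximum(self.v_g, 1), 0.0)
        return w

    def members_of(self, active_index: int) -> np.ndarray:
        """Flat node indices inside the active voxel at position
        ``active_index`` of the active ordering."""
        for gv, (pos, nodes) in self.groups.items():
            hit = np.nonzero(pos == active_index)[0]
            if hit.size:
                return nodes[hit[0]]
        raise IndexError(active_index)

    def g_v_of(self, active_index: int) -> int:
        return len(self.members_of(active_index))

    def inside_window(self) -> np.ndarray:
        """Boolean mask over grid nodes that receive corrections."""
        return (self.v_g > 0).reshape(self.grid.shape)


def _axis_membership(grid: StaggeredGrid, voxels: VoxelGrid, axis: int) -> list[np.ndarray]:
    """For each voxel slab along `axis`, the center indices inside it
    (closed intervals, border tolerance 1e-9 h)."""
    x = grid.centers(axis)
    h = voxels.spacing[axis]
    o = voxels.origin[axis]
    tol = BORDER_RTOL * h
    out = []
    for j in range(voxels.shape[axis]):
        lo, hi = o + j * h, o + (j + 1) * h
        out.append(np.nonzero((x >= lo - tol) & (x <= hi + tol))[0])
    return out


def build_mapping(grid: StaggeredGrid, voxels: VoxelGrid) -> GridVoxelMapping:
    """Construct the node<->voxel membership for all active voxels.

    Raises if any active voxel contains no grid node (a misconfigured
    window should fail loudly rather than be skipped).
    """
    dom_lo = np.asarray(grid.origin)
    dom_hi = dom_lo + np.asarray(grid.extents)
    vox_lo = np.asarray(voxels.origin)
    vox_hi = vox_lo + np.asarray(voxels.spacing) * np.asarray(voxels.shape)
    tol = np.asarray(voxels.spacing) * BORDER_RTOL
    if np.any(vox_lo < dom_lo - tol) or np.any(vox_hi > dom_hi + tol):
        raise ValueError("voxel window extends outside the computational domain")

    per_axis = [_axis_membership(grid, voxels, a) for a in range(3)]
    mask = voxels.active_mask()
    strides = np.array(
        [grid.shape[1] * grid.shape[2], grid.shape[2], 1]
    )  # C-order flat node indices

    voxel_ids = []
    member_lists = []
    for flat_v in np.nonzero(mask.ravel())[0]:
        i, j, k = np.unravel_index(flat_v, voxels.shape)
        ix, iy, iz = per_axis[0][i], per_axis[1][j], per_axis[2][k]
        gv = len(ix) * len(iy) * len(iz)
        if gv == 0:
            raise ValueError(
                f"active voxel {(i, j, k)} contains no grid node; "
                "check the window/voxel configuration"
            )
        nodes = (
            ix[:, None, None] * strides[0]
            + iy[None, :, None] * strides[1]
            + iz[None, None, :] * strides[2]
        ).ravel()
        voxel_ids.append(flat_v)
        member_lists.append(nodes)

    v_g = np.zeros(int(np.prod(grid.shape)), dtype=int)
    for nodes in member_lists:
        np.add.at(v_g, nodes, 1)

    groups: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    for pos, nodes in enumerate(member_lists):
        groups.setdefault(len(nodes), ([], []))
        groups[len(nodes)][0].append(pos)
        groups[len(nodes)][1].append(nodes)
    packed = {
        gv: (np.asarray(pos), np.vstack(nl))
        for gv, (pos, nl) in sorted(groups.items())
    }
    return GridVoxelMapping(grid, voxels, np.asarray(voxel_ids), packed, v_g)


def observe(fld: VelocityField, mapping: GridVoxelMapping) -> np.ndarray:
    """Voxel averages of the center-interpolated velocity: the action of the
    per-voxel observation blocks (rows summing to one).

    Returns an ``(m_v, 3)`` array ordered like ``mapping.voxel_ids``.
    """
    uc = interpolate_to_centers(fld, mapping.grid).reshape(-1, 3)
    return observe_centers(uc, mapping)


def observe_centers(uc_flat: np.ndarray, mapping: GridVoxelMapping) -> np.ndarray:
    """Voxel averaging of already center-collocated node vectors."""
    if uc_flat.shape != (mapping.n_nodes, 3):
        raise ValueError("collocated field does not match the mapped grid")
    out = np.empty((mapping.m_v, 3))
    for gv, (pos, nodes) in mapping.groups.items():
        out[pos] = uc_flat[nodes].mean(axis=1)
    return out


def innovation(sample: np.ndarray, forecast_obs: np.ndarray) -> np.ndarray:
    """Element-wise observation-minus-forecast difference ``d - h u^f``."""
    sample = np.asarray(sample)
    forecast_obs = np.asarray(forecast_obs)
    if sample.shape != forecast_obs.shape:
        raise ValueError("sample and forecast observation differ in shape")
    return sample - forecast_obs


@dataclass
class ObservationSample:
    """Per-pulse, per-phase voxel velocity vectors."""

    pulse: int
    phase: int
    values: np.ndarray  # (m_v, 3)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observation sample contains non-finite values")


@dataclass
class ObservationSet:
    """Per-phase voxel means and covariances (optionally with the per-pulse
    samples retained)."""

    voxels: VoxelGrid
    phase_times: np.ndarray  # (n_phases,)
    period: float
    n_pulses: int
    mean: np.ndarray  # (n_phases, m_v, 3)
    cov: np.ndarray  # (n_phases, m_v, 3, 3)
    samples: Optional[np.ndarray] = None  # (p, n_phases, m_v, 3)

    @property
    def n_phases(self) -> int:
        return len(self.phase_times)

    @property
    def m_v(self) -> int:
        return self.mean.shape[1]

    def validate(self, atol: float = 1e-12) -> None:
        sym = np.abs(self.cov - np.swapaxes(self.cov, -1, -2)).max()
        if sym > atol:
            raise ValueError(f"covariances not symmetric (max asymmetry {sym:.2e})")
        eig = np.linalg.eigvalsh(0.5 * (self.cov + np.swapaxes(self.cov, -1, -2)))
        if eig.min() < -1e-12:
            raise ValueError(f"covariance not PSD (min eigenvalue {eig.min():.2e})")
        if self.samples is not None:
            recon = self.samples.mean(axis=0)
            err = np.abs(recon - self.mean).max()
            if err > 1e-10:
                raise ValueError(
                    f"retained samples do not reproduce the mean (max {err:.2e})"
                )

    def restrict(
        self, lo: tuple[float, float, float], hi: tuple[float, float, float]
    ) -> "ObservationSet":
        """Observation set limited to the voxels fully inside ``[lo, hi]``
        (a data window cut out of a larger acquisition)."""
        new_vox = self.voxels.with_window(lo, hi)
        old_active = np.nonzero(self.voxels.active_mask().ravel())[0]
        new_active = np.nonzero(new_vox.active_mask().ravel())[0]
        pos = {v: i for i, v in enumerate(old_active)}
        keep = np.asarray([pos[v] for v in new_active])
        return ObservationSet(
            voxels=new_vox,
            phase_times=self.phase_times,
            period=self.period,
            n_pulses=self.n_pulses,
            mean=self.mean[:, keep],
            cov=self.cov[:, keep],
            samples=None if self.samples is None else self.samples[:, :, keep],
        )

    # -- HDF5 container -----------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format"] = "voxelda-observations-1"
            f.attrs["period"] = self.period
            f.attrs["n_pulses"] = self.n_pulses
            f.attrs["dw"] = self.voxels.dw
            f.create_dataset("phases", data=self.phase_times)
            g = f.create_group("voxel_grid")
            g.attrs["origin"] = self.voxels.origin
            g.attrs["spacing"] = self.voxels.spacing
            g.attrs["shape"] = self.voxels.shape
            g.create_dataset("active", data=self.voxels.active_mask())
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("cov", data=self.cov)
            if self.samples is not None:
                f.create_dataset("samples", data=self.samples)

    @classmethod
    def from_hdf5(cls, path) -> "ObservationSet":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["voxel_grid"]
            voxels = VoxelGrid(
                tuple(g.attrs["origin"]),
                tuple(g.attrs["spacing"]),
                tuple(int(n) for n in g.attrs["shape"]),
                np.asarray(g["active"]).astype(bool),
                int(f.attrs["dw"]),
            )
            samples = np.asarray(f["samples"]) if "samples" in f else None
            return cls(
                voxels=voxels,
                phase_times=np.asarray(f["phases"]),
                period=float(f.attrs["period"]),
                n_pulses=int(f.attrs["n_pulses"]),
                mean=np.asarray(f["mean"]),
                cov=np.asarray(f["cov"]),
                samples=samples,
            )
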