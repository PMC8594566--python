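"""Staggered Cartesian (MAC) grid geometry and field containers.

Velocity components live on the faces normal to their own axis, pressure at
cell centers.  Axes are either periodic or bounded by no-slip walls.  On a
periodic axis there are as many faces as cells (face ``i`` is the left face
of cell ``i``); on a wall axis the two boundary faces are included, so there
are ``n + 1`` faces and the wall faces carry the (pinned) normal velocity.

A quasi-2D configuration is represented by collapsing the span-wise axis to
a single periodic cell layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StaggeredGrid",
    "VelocityField",
    "ScalarField",
    "divergence",
    "interpolate_to_centers",
    "spread_to_faces",
]


@dataclass(frozen=True)
class StaggeredGrid:
    """Uniform Cartesian staggered grid.

    Parameters
    ----------
    shape
        Number of cells per axis ``(nx, ny, nz)``.
    spacing
        Cell size per axis (length units).
    periodic
        Periodicity flag per axis.  A non-periodic axis is bounded by
        no-slip walls at both ends.
    origin
        Coordinate of the lower domain corner.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    periodic: tuple[bool, bool, bool]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.periodic) != 3:
            raise ValueError("shape, spacing and periodic must have length 3")
        for n, d, per in zip(self.shape, self.spacing, self.periodic):
            if d <= 0:
                raise ValueError("grid spacing must be positive")
            if n < 1:
                raise ValueError("grid needs at least one cell per axis")
            if n < 3 and not (per and n == 1):
                # resolved axes need >= 3 cells; a single periodic layer is
                # the quasi-2D collapse of the span-wise axis
                raise ValueError(
                    "axes must have >= 3 cells unless collapsed to a single "
                    "periodic layer"
                )

    # -- geometry -----------------------------------------------------------
    @property
    def extents(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape, self.spacing))

    @property
    def ndim_resolved(self) -> int:
        return sum(1 for n in self.shape if n > 1)

    def n_faces(self, axis: int) -> int:
        return self.shape[axis] if self.periodic[axis] else self.shape[axis] + 1

    def face_shape(self, axis: int) -> tuple[int, int, int]:
        s = list(self.shape)
        s[axis] = self.n_faces(axis)
        return tuple(s)

    def centers(self, axis: int) -> np.ndarray:
        n, d, o = self.shape[axis], self.spacing[axis], self.origin[axis]
        return o + (np.arange(n) + 0.5) * d

    def faces(self, axis: int) -> np.ndarray:
        d, o = self.spacing[axis], self.origin[axis]
        return o + np.arange(self.n_faces(axis)) * d

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.centers(a) for a in range(3)), indexing="ij")

    def component_mesh(self, comp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinates of the face points carrying velocity component `comp`."""
        coords = [
            self.faces(a) if a == comp else self.centers(a) for a in range(3)
        ]
        return np.meshgrid(*coords, indexing="ij")

    @property
    def cell_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class ScalarField:
    """Cell-centered scalar values at one time instant."""

    values: np.ndarray
    t: float = 0.0


@dataclass
class VelocityField:
    """Staggered velocity components plus cell-centered pressure."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, grid: StaggeredGrid, t: float = 0.0) -> "VelocityField":
        return cls(
            u=np.zeros(grid.face_shape(0)),
            v=np.zeros(grid.face_shape(1)),
            w=np.zeros(grid.face_shape(2)),
            p=np.zeros(grid.shape),
            t=t,
        )

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.u, self.v, self.w)

    def copy(self) -> "VelocityField":
        return VelocityField(
            self.u.copy(), self.v.copy(), self.w.copy(), self.p.copy(), self.t
        )

    def check_finite(self) -> None:
        for name, a in (("u", self.u), ("v", self.v), ("w", self.w), ("p", self.p)):
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(f"non-finite values in component {name}")

    def validate_shapes(self, grid: StaggeredGrid) -> None:
        expected = [grid.face_shape(a) for a in range(3)] + [grid.shape]
        actual = [self.u.shape, self.v.shape, self.w.shape, self.p.shape]
        for exp, act in zip(expected, actual):
            if tuple(act) != tuple(exp):
                raise ValueError(
                    f"field shape {act} does not match grid expectation {exp}"
                )


# -- discrete operators -----------------------------------------------------

def divergence(fld: VelocityField, grid: StaggeredGrid) -> ScalarField:
    """Centered finite-difference divergence at every cell center."""
    fld.validate_shapes(grid)
    out = np.zeros(grid.shape)
    for axis, comp in enumerate(fld.components()):
        d = grid.spacing[axis]
        if grid.periodic[axis]:
            out += (np.roll(comp, -1, axis=axis) - comp) / d
        else:
            out += np.diff(comp, axis=axis) / d
    return ScalarField(out, t=fld.t)


def interpolate_to_centers(fld: VelocityField, grid: StaggeredGrid) -> np.ndarray:
    """Two-point average of each face component to cell centers.

    Returns an array of shape ``grid.shape + (3,)`` with the three velocity
    components collocated at the cell centers.  Exact for fields affine in
    each coordinate.
    """
    fld.validate_shapes(grid)
    out = np.empty(grid.shape + (3,))
    for axis, comp in enumerate(fld.components()):
        if grid.periodic[axis]:
            out[..., axis] = 0.5 * (comp + np.roll(comp, -1, axis=axis))
        else:
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            out[..., axis] = 0.5 * (comp[tuple(lo)] + comp[tuple(hi)])
    return out


def spread_to_faces(
    correction: np.ndarray, grid: StaggeredGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adjoint of the center interpolation: cell-centered vector increments
    redistributed to the staggered faces.

    Interior faces receive the mean of the two adjacent cell values; wall
    faces of a bounded axis receive nothing (the normal velocity there is
    pinned to zero by the no-slip condition).
    """
    if correction.shape != grid.shape + (3,):
        raise ValueError("correction must be cell-centered with 3 components")
    out = []
    for axis in range(3):
        k = correction[..., axis]
        if grid.periodic[axis]:
            out.append(0.5 * (k + np.roll(k, 1, axis=axis)))
        else:
            face = np.zeros(grid.face_shape(axis))
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            mid = [slice(None)] * 3
            mid[axis] = slice(1, -1)
            face[tuple(mid)] = 0.5 * (k[tuple(lo)] + k[tuple(hi)])
            out.append(face)
    return tuple(out)
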