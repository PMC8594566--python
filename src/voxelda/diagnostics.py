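"""Flow statistics used for validation: friction Reynolds number, wall
units, turbulent kinetic energy, Reynolds-stress profiles and vorticity."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ensemble import RunningMoments
from .grids import ScalarField, StaggeredGrid, VelocityField

__all__ = [
    "DiagnosticsRecord",
    "friction_reynolds",
    "to_wall_units",
    "tke",
    "rss_profile",
    "vorticity",
]


@dataclass
class DiagnosticsRecord:
    t: float
    re_tau: Optional[float] = None
    u_tau: Optional[float] = None
    tke: Optional[float] = None
    extras: dict = field(default_factory=dict)


def friction_reynolds(
    u_x: np.ndarray,
    grid: StaggeredGrid,
    nu: float,
    l_ref: float = 1.0,
    wall_axis: int = 1,
    walls: str = "both",
) -> tuple[float, float]:
    """Friction Reynolds number and friction velocity from the wall shear.

    The streamwise velocity gradient at the wall is evaluated with a
    one-sided first-order difference from the first off-wall node
    (distance ``spacing/2``), averaged over the wall plane(s).  Then
    ``U_tau = sqrt(nu |du/dy|)`` and ``Re_tau = U_tau L_ref / nu``.

    ``u_x`` is the streamwise component on its face grid or any array whose
    ``wall_axis`` dimension matches the cell count of that axis.
    """
    if grid.periodic[wall_axis]:
        raise ValueError("no wall on a periodic axis")
    dy = grid.spacing[wall_axis]
    first = np.take(u_x, 0, axis=wall_axis)
    last = np.take(u_x, -1, axis=wall_axis)
    grads = {
        "bottom": np.abs(first).mean() / (dy / 2),
        "top": np.abs(last).mean() / (dy / 2),
    }
    if walls == "both":
        grad = 0.5 * (grads["bottom"] + grads["top"])
    elif walls in grads:
        grad = grads[walls]
    else:
        raise ValueError("walls must be 'both', 'bottom' or 'top'")
    u_tau = float(np.sqrt(nu * grad))
    re_tau = u_tau * l_ref / nu
    return re_tau, u_tau


def to_wall_units(
    y: np.ndarray, u: np.ndarray, u_tau: float, nu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize wall distance and velocity: ``y+ = y U_tau / nu``,
    ``u+ = u / U_tau``."""
    if u_tau <= 0:
        raise ValueError("friction velocity must be positive")
    return np.asarray(y) * u_tau / nu, np.asarray(u) / u_tau


def tke(
    moments: RunningMoments,
    phase: int = 0,
    mask: Optional[np.ndarray] = None,
    include_d: bool = False,
) -> float:
    """Volume-averaged turbulent kinetic energy: half the trace of the
    fluctuation covariance averaged over the volume of interest.

    The D regularization is excluded by default so the value measures
    physical fluctuations; the D-inclusive variant exists for debugging.
    """
    cov = moments.covariance(phase, include_d=include_d)
    trace = cov[..., 0, 0] + cov[..., 1, 1] + cov[..., 2, 2]
    if mask is not None:
        if mask.shape != trace.shape:
            raise ValueError("mask shape must match the node shape")
        if not mask.any():
            raise ValueError("empty volume mask")
        trace = trace[mask]
    return float(0.5 * trace.mean())


def rss_profile(
    moments: RunningMoments,
    phase: int,
    axis: int,
    index: tuple[int, int],
    components: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Covariance component profile along a grid line.

    ``axis`` is the free axis; ``index`` gives the fixed node indices of
    the two remaining axes in ascending axis order.  Component ordering
    follows the covariance matrix indices (0=x, 1=y, 2=z).
    """
    cov = moments.covariance(phase, include_d=False)
    other = [a for a in range(3) if a != axis]
    sl = [slice(None)] * 3
    for a, i in zip(other, index):
        if not 0 <= i < cov.shape[a]:
            raise IndexError("profile line outside the domain")
        sl[a] = i
    i, j = components
    return cov[tuple(sl)][..., i, j]


def vorticity(fld: VelocityField, grid: StaggeredGrid) -> ScalarField:
    """Span-wise vorticity ``w_z = du_y/dx - du_x/dy`` at cell centers
    (quasi-2D diagnostic), by central differences of the collocated field."""
    from .grids import interpolate_to_centers

    uc = interpolate_to_centers(fld, grid)

    def _ddx(a, axis):
        d = grid.spacing[axis]
        if grid.periodic[axis]:
            return (np.roll(a, -1, axis=axis) - np.roll(a, 1, axis=axis)) / (2 * d)
        out = np.gradient(a, d, axis=axis)
        return out

    om = _ddx(uc[..., 1], 0) - _ddx(uc[..., 0], 1)
    return ScalarField(om, t=fld.t)
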