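"""Phase-indexed running ensemble statistics over pulses.

For pulsatile flow the forecast ensemble is built from periodically
repeated pulses: the state at phase time ``t_phi`` of pulse ``r`` is one
realization of the phase ensemble, ``t_n = t_phi + (r - 1) T``.  The
running mean and covariance over pulses are accumulated per grid node and
phase with a one-pass (Welford) update; the finalized covariance is
regularized with a diagonal ``D``,

    p^f_(s) = (D + sum_r (u_(r) - mu_(s)) (u_(r) - mu_(s))^T) / s ,

which keeps it positive definite for small ensembles and decays like
``1/s``.  Divisors are ``1/s`` and ``1/p`` (the biased sample forms).

A statistically steady flow is the single-phase special case: one phase
whose "period" is the update interval, so the phase average becomes a time
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .observation import ObservationSample, ObservationSet, VoxelGrid

__all__ = [
    "PhaseSchedule",
    "RunningMoments",
    "phase_average_samples",
    "reynolds_decompose",
]


@dataclass(frozen=True)
class PhaseSchedule:
    """Pulse period and phase times within one pulse.

    ``phase_times`` are strictly increasing and lie in ``(0, period]``.
    Steady (single-phase) mode uses one phase with
    ``period == phase_times[0] == update interval``.
    """

    period: float
    phase_times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.phase_times, dtype=float)
        if self.period <= 0:
            raise ValueError("pulse period must be positive")
        if t.size < 1:
            raise ValueError("at least one phase time is required")
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("phase times must be strictly increasing and > 0")
        if t[-1] > self.period * (1 + 1e-12):
            raise ValueError("phase times must not exceed the pulse period")

    @classmethod
    def uniform(cls, period: float, n_phases: int) -> "PhaseSchedule":
        t = period * (np.arange(1, n_phases + 1) / n_phases)
        return cls(period, tuple(t))

    @classmethod
    def steady(cls, interval: float) -> "PhaseSchedule":
        """Single-phase schedule: ensemble averaging over time with a fixed
        update interval."""
        return cls(interval, (interval,))

    @property
    def n_phases(self) -> int:
        return len(self.phase_times)

    @property
    def is_steady(self) -> bool:
        return self.n_phases == 1

    def time_of(self, pulse: int, phase: int) -> float:
        """Absolute time of phase index ``phase`` (0-based) in pulse
        ``pulse`` (1-based): ``t_phi + (pulse - 1) T``."""
        if not 0 <= phase < self.n_phases:
            raise IndexError("phase index out of range")
        if pulse < 1:
            raise ValueError("pulse index is 1-based")
        return self.phase_times[phase] + (pulse - 1) * self.period

    def refined(self, factor: int) -> "PhaseSchedule":
        """Subdivide every (cyclic) phase interval into ``factor`` equal
        parts, increasing the temporal resolution of the schedule."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        t = np.asarray(self.phase_times)
        starts = np.concatenate([[t[-1] - self.period], t[:-1]])
        fine = []
        for a, b in zip(starts, t):
            for k in range(1, factor + 1):
                fine.append(a + (b - a) * k / factor)
        fine = np.asarray(sorted(x if x > 0 else x + self.period for x in fine))
        return PhaseSchedule(self.period, tuple(fine))


class RunningMoments:
    """Per-node, per-phase running mean and D-regularized covariance.

    ``shape`` is the spatial node shape; vectors are 3-component.  ``d_diag``
    is the diagonal of the regularization matrix D (velocity-squared
    units), chosen larger than the expected covariance of the flow.
    """

    def __init__(
        self, shape: tuple[int, ...], n_phases: int, d_diag: float | Sequence[float]
    ) -> None:
        d = np.asarray(d_diag, dtype=float) * np.ones(3)
        if np.any(d < 0):
            raise ValueError("D must be non-negative")
        self.shape = tuple(shape)
        self.n_phases = int(n_phases)
        self.d_diag = d
        n = int(np.prod(shape))
        self.count = np.zeros(n_phases, dtype=int)
        self.mean = np.zeros((n_phases, n, 3))
        self.m2 = np.zeros((n_phases, n, 3, 3))

    # -- accumulation -------------------------------------------------------
    def update(self, phase: int, values: np.ndarray) -> None:
        """One-pass (Welford) update with a new ensemble member for the
        given phase.  ``values`` has shape ``shape + (3,)``."""
        if not 0 <= phase < self.n_phases:
            raise IndexError("phase index out of range")
        x = np.asarray(values, dtype=float).reshape(-1, 3)
        if x.shape[0] != self.mean.shape[1]:
            raise ValueError("field shape does not match the moments container")
        s = self.count[phase] + 1
        delta = x - self.mean[phase]
        self.mean[phase] += delta / s
        delta2 = x - self.mean[phase]
        self.m2[phase] += delta[:, :, None] * delta2[:, None, :]
        self.count[phase] = s

    # -- finalization -------------------------------------------------------
    def mean_field(self, phase: int) -> np.ndarray:
        if self.count[phase] == 0:
            raise ValueError("no samples accumulated for this phase")
        return self.mean[phase].reshape(self.shape + (3,))

    def covariance(self, phase: int, include_d: bool = True) -> np.ndarray:
        """Finalized covariance ``(D + sum of outer deviations) / s`` for
        every node, shape ``shape + (3, 3)``."""
        s = self.count[phase]
        if s == 0:
            raise ValueError("covariance undefined before the first sample")
        out = self.m2[phase].copy()
        if include_d:
            out[:, np.arange(3), np.arange(3)] += self.d_diag
        return (out / s).reshape(self.shape + (3, 3))

    def covariance_flat(self, phase: int, include_d: bool = True) -> np.ndarray:
        return self.covariance(phase, include_d).reshape(-1, 3, 3)

    # -- checkpointing ------------------------------------------------------
    def to_hdf5(self, h5group) -> None:
        h5group.attrs["d_diag"] = self.d_diag
        h5group.attrs["shape"] = self.shape
        h5group.create_dataset("count", data=self.count)
        h5group.create_dataset("mean", data=self.mean)
        h5group.create_dataset("m2sum", data=self.m2)

    @classmethod
    def from_hdf5(cls, h5group) -> "RunningMoments":
        shape = tuple(int(n) for n in h5group.attrs["shape"])
        count = np.asarray(h5group["count"])
        obj = cls(shape, len(count), np.asarray(h5group.attrs["d_diag"]))
        obj.count = count
        obj.mean = np.asarray(h5group["mean"])
        obj.m2 = np.asarray(h5group["m2sum"])
        return obj


def phase_average_samples(
    samples: Sequence[ObservationSample],
    voxels: VoxelGrid,
    phase_times: Sequence[float],
    period: float,
    keep_samples: bool = True,
) -> ObservationSet:
    """Phase mean and (biased, divisor ``p``) covariance of per-pulse voxel
    samples, grouped by phase index."""
    n_phases = len(phase_times)
    by_phase: dict[int, list[ObservationSample]] = {i: [] for i in range(n_phases)}
    for smp in samples:
        if not 0 <= smp.phase < n_phases:
            raise ValueError(f"sample phase {smp.phase} out of range")
        by_phase[smp.phase].append(smp)
    counts = {i: len(v) for i, v in by_phase.items()}
    if min(counts.values()) == 0:
        empty = [i for i, c in counts.items() if c == 0]
        raise ValueError(f"phases without samples: {empty}")
    p = counts[0]
    if any(c != p for c in counts.values()):
        raise ValueError("unequal pulse counts across phases")
    m_v = samples[0].values.shape[0]
    mean = np.zeros((n_phases, m_v, 3))
    cov = np.zeros((n_phases, m_v, 3, 3))
    stored = np.zeros((p, n_phases, m_v, 3)) if keep_samples else None
    for i in range(n_phases):
        grp = sorted(by_phase[i], key=lambda s: s.pulse)
        x = np.stack([s.values for s in grp])  # (p, m_v, 3)
        mean[i] = x.mean(axis=0)
        dev = x - mean[i]
        cov[i] = np.einsum("pvi,pvj->vij", dev, dev) / p
        if keep_samples:
            stored[:, i] = x
    return ObservationSet(
        voxels=voxels,
        phase_times=np.asarray(phase_times, dtype=float),
        period=float(period),
        n_pulses=p,
        mean=mean,
        cov=cov,
        samples=stored,
    )


def reynolds_decompose(
    values: np.ndarray, moments: RunningMoments, phase: int
) -> np.ndarray:
    """Fluctuation part of a field: member minus the current phase mean."""
    x = np.asarray(values, dtype=float)
    return x - moments.mean_field(phase).reshape(x.shape)
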