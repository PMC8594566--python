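"""Configuration files, result containers and run manifests.

YAML case configurations are schema-validated (unknown keys rejected,
defaults materialized); fields and observation sets are stored in HDF5,
snapshots additionally as legacy-ASCII VTK rectilinear grids for
visualization; every run directory carries a JSON manifest with the
configuration digest and the seeds of all random streams, so a run can be
reproduced from its manifest alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .grids import StaggeredGrid, VelocityField

__all__ = [
    "CaseConfig",
    "load_config",
    "save_config",
    "RunManifest",
    "write_results",
    "write_velocity_h5",
    "read_velocity_h5",
    "write_vtk_rectilinear",
]

_CASES = ("cylinder", "channel", "jet")
_SCALES = ("full", "reduced")
_SAMPLING = ("cycle", "perturb")


@dataclass
class CaseConfig:
    """Validated case configuration.

    Only the knobs of the twin-experiment pipeline live here; the case
    geometry itself comes from the case factory named by ``case``.
    """

    case: str = "cylinder"
    scale: str = "reduced"
    seed: int = 0
    window: str = "full"
    dw: Optional[int] = None
    pulses: int = 10
    n_phases: Optional[int] = None
    period: Optional[float] = None
    spin_up: Optional[float] = None
    d_diag: Optional[float] = None
    sampling: str = "cycle"
    update_interval: float = 0.5
    perturbation_amplitude: float = 0.1
    analysis_burn_in: int = 0
    nu: Optional[float] = None
    cfl: Optional[float] = None

    def validate(self) -> "CaseConfig":
        def fail(name, msg):
            raise ValueError(f"config field '{name}': {msg}")

        if self.case not in _CASES:
            fail("case", f"must be one of {_CASES}")
        if self.scale not in _SCALES:
            fail("scale", f"must be one of {_SCALES}")
        if self.sampling not in _SAMPLING:
            fail("sampling", f"must be one of {_SAMPLING}")
        if self.pulses < 1:
            fail("pulses", "must be >= 1")
        if self.dw is not None and self.dw < 0:
            fail("dw", "must be >= 0")
        if self.nu is not None and self.nu <= 0:
            fail("nu", "kinematic viscosity must be positive")
        if self.cfl is not None and not 0 < self.cfl <= 1.0:
            fail("cfl", "must lie in (0, 1]")
        if self.period is not None and self.period <= 0:
            fail("period", "must be positive")
        if self.update_interval <= 0:
            fail("update_interval", "must be positive")
        if self.d_diag is not None and self.d_diag < 0:
            fail("d_diag", "must be >= 0")
        return self

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> CaseConfig:
    """Load and validate a YAML case configuration; unknown keys are
    rejected with a field-level message and defaults are materialized."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dc_fields(CaseConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CaseConfig(**raw).validate()


def save_config(cfg: CaseConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    case: str
    schedule: dict
    format_version: str = "1"
    package_version: str = _pkg_version
    diagnostics_summary: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# -- HDF5 snapshots ---------------------------------------------------------

def write_velocity_h5(path, fld: VelocityField, grid: StaggeredGrid) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t"] = fld.t
        f.attrs["shape"] = grid.shape
        f.attrs["spacing"] = grid.spacing
        f.attrs["origin"] = grid.origin
        f.attrs["periodic"] = [int(p) for p in grid.periodic]
        f.attrs["layout"] = (
            "MAC staggering; axis order (x, y, z); component i on faces of "
            "axis i, pressure at cell centers"
        )
        for name, arr in zip(("u", "v", "w", "p"), (fld.u, fld.v, fld.w, fld.p)):
            f.create_dataset(name, data=arr)


def read_velocity_h5(path) -> tuple[VelocityField, StaggeredGrid]:
    import h5py

    with h5py.File(path, "r") as f:
        grid = StaggeredGrid(
            tuple(int(n) for n in f.attrs["shape"]),
            tuple(float(d) for d in f.attrs["spacing"]),
            tuple(bool(p) for p in f.attrs["periodic"]),
            tuple(float(o) for o in f.attrs["origin"]),
        )
        fld = VelocityField(
            np.asarray(f["u"]),
            np.asarray(f["v"]),
            np.asarray(f["w"]),
            np.asarray(f["p"]),
            float(f.attrs["t"]),
        )
    return fld, grid


# -- VTK (legacy ASCII rectilinear) ----------------------------------------

def write_vtk_rectilinear(path, grid: StaggeredGrid, fields: dict) -> None:
    """Write cell-centered scalar/vector fields as a legacy-ASCII VTK
    rectilinear grid (points at cell centers)."""
    xs = [grid.centers(a) for a in range(3)]
    npts = int(np.prod(grid.shape))
    lines = [
        "# vtk DataFile Version 3.0",
        "voxelda snapshot",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}",
    ]
    for name, x in zip(("X", "Y", "Z"), xs):
        lines.append(f"{name}_COORDINATES {len(x)} float")
        lines.append(" ".join(f"{v:.8g}" for v in x))
    lines.append(f"POINT_DATA {npts}")
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 4 and arr.shape[-1] == 3:
            lines.append(f"VECTORS {name} float")
            data = arr.transpose(2, 1, 0, 3).reshape(-1, 3)  # x fastest per VTK
            lines.extend(" ".join(f"{v:.8g}" for v in row) for row in data)
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            data = arr.transpose(2, 1, 0).ravel()
            lines.extend(f"{v:.8g}" for v in data)
    Path(path).write_text("\n".join(lines) + "\n")


# -- run outputs ------------------------------------------------------------

def append_diagnostics_csv(path, rows: list[dict]) -> None:
    path = Path(path)
    if not rows:
        return
    keys = list(rows[0].keys())
    new = not path.exists()
    with path.open("a", newline="") as f:
        w = csv.DictWriter(f, fieldnames=keys)
        if new:
            w.writeheader()
        w.writerows(rows)


def write_results(
    out_dir,
    cfg: CaseConfig,
    grid: StaggeredGrid,
    run=None,
    diagnostics: Optional[list[dict]] = None,
) -> RunManifest:
    """Write the outputs of a DA run: per-phase mean/covariance fields
    (HDF5), a VTK snapshot of the final state, the diagnostics time series
    (CSV) and the JSON run manifest.  Returns the manifest."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched = {}
    if run is not None:
        sched = {
            "period": run.schedule.period,
            "n_phases": run.schedule.n_phases,
            "phase_times": list(map(float, run.schedule.phase_times)),
        }
        with h5py.File(out / "analysis.h5", "w") as f:
            f.attrs["seed"] = run.seed
            g = f.create_group("analysis_moments")
            run.analysis_moments.to_hdf5(g)
            g = f.create_group("forecast_moments")
            run.forecast_moments.to_hdf5(g)
        write_velocity_h5(out / "state.h5", run.state, grid)
        from .grids import interpolate_to_centers

        write_vtk_rectilinear(
            out / "state.vtk",
            grid,
            {"velocity": interpolate_to_centers(run.state, grid), "pressure": run.state.p},
        )
    if diagnostics:
        append_diagnostics_csv(out / "diagnostics.csv", diagnostics)
    manifest = RunManifest(
        config_digest=cfg.digest(),
        seed=cfg.seed,
        case=cfg.case,
        schedule=sched,
        diagnostics_summary={"n_records": len(diagnostics or [])},
    )
    manifest.write(out / "manifest.json")
    return manifest
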