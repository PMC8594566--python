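# voxelda

**Stochastic ensemble Kalman filtering of voxel-based velocity
observations with an incompressible Navier–Stokes forward model.**

Volumetric velocimetry — tomographic PIV and, prospectively, 4D flow
MRI — measures pulsatile and turbulent flow as *voxel averages*: per voxel
`v` and cardiac phase `φ` a mean velocity `d̄_{v;φ}` and a 3×3 covariance
`r_{v;φ}`, at a resolution that misses the small scales that determine
turbulent kinetic energy, Reynolds stresses and wall shear. `voxelda`
enhances such data by assimilating them into a direct numerical simulation
of the flow on a finer grid, producing phase-resolved mean fields and
covariances at the solver's resolution.

The filter is a stochastic ensemble Kalman filter whose ensemble is built
from the *pulses* of the periodic flow: the state at phase time `t_φ` of
pulse `s` (`t_n = t_φ + (s−1)T`) is one ensemble member, so the phase
ensemble mean corresponds to the Reynolds-averaged flow `⟨u⟩_φ` and its
covariance to the Reynolds stress tensor. Forecast moments are accumulated
per node with the regularized running covariance

    p^f_(s) = (D + Σ_{r≤s} (u_(r) − μ_(s))(u_(r) − μ_(s))ᵀ) / s ,

and the analysis update exploits the block structure of the voxel
observation operator `H` (entries `1/g_v` over the `g_v` nodes of each
voxel): per voxel, `S_v = (1/g_v²) Σ_g p^f_g + r_v` and node `g` receives
`p^f_g (1/g_v) S_v⁻¹ (d_v − h u^f)`, interpolated across overlapping
voxels with weights `1/v_g` — so the full gain
`K = P Hᵀ(H P Hᵀ + R)⁻¹` never has to be formed. Between updates the
forward model is a second-order staggered-grid (MAC) projection solver
with explicit RK3 time stepping and fringe forcing for inflows, immersed
objects and data-driven walls.

Three twin-experiment case families ship with the package: a quasi-2D
confined cylinder at Re = 150 (periodic vortex shedding), a turbulent
channel at Re = 5000 (statistically steady, single-phase mode), and a
synthetic pulsatile jet in a cylindrical phantom emulating the structure
of a valve-flow acquisition pipeline.

## Worked example

Reduced-scale cylinder twin experiment: generate ground truth, extract
full-domain voxel observations (2×2-node voxels), assimilate them from a
zero initial state *without* the cylinder's boundary condition, and
compare the reconstructed wake against the truth:

```python
import numpy as np
from voxelda.cases import (cylinder_case, run_spin_up, shedding_period,
                           extract_observations, voxel_mean_field,
                           phase_mean_rmse)
from voxelda.ensemble import PhaseSchedule
from voxelda.observation import build_mapping
from voxelda.kalman import KalmanConfig, run_da
from voxelda.grids import VelocityField

b = cylinder_case("reduced")
b.spin_up = 150.0
state = run_spin_up(b)                             # past the transient
T, state = shedding_period(b, state, n_cycles=25)  # measured pulse period
sched = PhaseSchedule.uniform(T, 20)
vox = b.window_voxels("full")                      # whole-domain window, dw=1
obs, truth, _ = extract_observations(b, state, vox, n_pulses=50, schedule=sched)

mapping = build_mapping(b.grid, vox)
kcfg = KalmanConfig(n_pulses=50, d_diag=b.d_diag, seed=1, analysis_burn_in=25)
run = run_da(VelocityField.zeros(b.grid), b.grid, b.solver, b.da_regions,
             sched, obs, mapping, kcfg)

xc = b.grid.centers(0)
wake = np.zeros(b.grid.shape, bool); wake[(xc > 10) & (xc < 16)] = True
err = np.mean([phase_mean_rmse(run.analysis_moments.mean_field(p),
                               truth.mean_field(p), wake) for p in range(20)])
vdisc = np.mean([phase_mean_rmse(voxel_mean_field(truth.mean_field(p), mapping),
                                 truth.mean_field(p), wake) for p in range(20)])
print(f"period {T:.4f} s, wake RMSE {err:.4f}, voxel discretization {vdisc:.4f}")
```

Output:

```
period 2.7750 s, wake RMSE 0.0176, voxel discretization 0.2636
```

The assimilated phase-mean wake error (0.018, in units of the inflow
velocity) is an order of magnitude below the discretization error of the
voxel data themselves (0.26) — the filter has added sub-voxel structure
from the forward model, which is the point of the method. (The reduced
128×16 grid sheds at 2.78 s; at the full 256×32 resolution the period is
1.99 s.)

The same pipeline is available from the shell:

```bash
voxelda make-case --name cylinder --scale reduced --out case/
voxelda run-truth --config case/case.yaml --out case/
voxelda extract-obs --config case/case.yaml --truth case/truth.h5 --out case/
voxelda run-da --config case/case.yaml --obs case/obs.h5 --out case/results --seed 1
voxelda report --results case/results --out case/report
```

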