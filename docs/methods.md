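# Methods

## Problem and model

Volumetric flow measurements (tomographic PIV, 4D flow MRI) deliver
velocities as voxel averages: per voxel `v` and cardiac phase `φ` a mean
3-vector `d̄_{v;φ}` and a 3×3 covariance `r_{v;φ}`, both coarser in space
and time than the flow structures of interest. `voxelda` enhances such data
by assimilating them into a direct numerical simulation of the
incompressible Navier–Stokes equations with a stochastic ensemble Kalman
filter (SEnKF, the "perturbed observations" EnKF variant).

The central modeling idea is that for pulsatile or statistically steady
turbulent flow the *pulses themselves* form the filter ensemble: the state
at phase time `t_φ` of pulse `s` (`t_n = t_φ + (s−1)T`) is one realization
of the phase ensemble. The phase-ensemble mean then plays the role of the
Reynolds-averaged mean flow and the ensemble covariance the role of the
Reynolds stress tensor, so the filter corrects the mean flow and inherits a
physically meaningful uncertainty from the turbulence itself. A
statistically steady flow is the single-phase special case (the "period" is
the update interval `Δτ`, phase averaging becomes time averaging).

### Forecast statistics

Per grid node `g` and phase `φ` the forecast mean and covariance are
accumulated over pulses with a one-pass (Welford) update; the finalized
covariance is regularized,

    p^f_(s) = (D + Σ_{r≤s} (u_(r) − μ_(s))(u_(r) − μ_(s))ᵀ) / s ,

with `D` diagonal (velocity² units), chosen one order of magnitude above
the expected flow covariance (1000 for the laminar cylinder case, 10 for
the channel). `D` keeps `p^f` positive definite while the ensemble is
small — at `s = 1` the covariance *is* `D`, so the first analyses trust the
data strongly — and its influence decays exactly as `1/s`. Divisors are the
biased `1/s` and `1/p` forms throughout, consistent with the filter
formulas rather than unbiased estimation. Cross-node and cross-voxel
covariances are taken to be zero, which is what makes the per-voxel block
factorization below exact at the implementation level.

### Observation operator and block gain

Voxel membership of grid nodes uses closed intervals with a border
tolerance of `1e-9·h`: a node exactly on a shared border belongs to all
adjacent voxels. The observation operator averages the `g_v` member nodes
of each voxel with equal weights `1/g_v` (no partial-volume weighting);
velocity is first interpolated from the staggered faces to cell centers so
all three components are collocated, as voxel data are. For one voxel the
innovation covariance is the 3×3 matrix

    S_v = (1/g_v²) Σ_g p^f_g + r_v ,

and member node `g` receives the correction `p^f_g (1/g_v) S_v⁻¹ (d_v − h u^f)`.
Nodes inside `v_g` voxels average their per-voxel contributions with
weights `Ψ = 1/v_g`; nodes outside every active voxel receive no
correction. With `D > 0` the matrix `S_v` is provably invertible, so a
singular solve is treated as a configuration error rather than silently
pseudo-inverted. On instances where voxels share no nodes this block form
is algebraically identical to the dense gain `K = P Hᵀ(H P Hᵀ + R)⁻¹`
(asserted in tests against a dense oracle); with shared border nodes the
`Ψ`-weighted assembly is the method's defined interpolation, not an
identity.

The correction is computed on the collocated nodes and redistributed to
the staggered faces by the adjoint of the center interpolation (interior
faces take the mean of the two adjacent cell corrections; wall-normal
boundary faces stay pinned). This round trip is exact for corrections
affine in each coordinate and smooths sharper ones slightly. Because the
algebraic update does not respect discrete continuity, the analysis state
is re-projected by default so the forward model's divergence-free
precondition holds; this can be disabled for limit-case studies.

### Observation sampling

Per assimilation pulse one observation *sample* is needed. Two modes
exist: `cycle` replays stored per-pulse samples (pulse `s` uses stored
sample `(s−1) mod p`) and is the default whenever samples were retained;
`perturb` draws `d ~ N(d̄, r)` per voxel via an eigenvalue square root
(robust to exactly singular `r`, e.g. masked voxels). Every random draw
comes from one seeded generator recorded in the run manifest.

## Forward model

Incompressible Navier–Stokes on a uniform staggered (MAC) grid:
pressure at cell centers, velocity components on their face families.
Axes are periodic or bounded by no-slip walls; a quasi-2D configuration
collapses the span-wise axis to one periodic layer.

* **Spatial discretization** — second-order central differences with
  advection in divergence (flux) form, which conserves momentum to
  round-off on periodic domains. Tangential no-slip enters through odd
  ghost extension about the wall plane (the interpolated wall velocity is
  exactly zero); wall-normal boundary faces are pinned.
* **Time integration** — explicit three-stage Runge–Kutta
  `u_k = u_0 + α_k Δt R(u_{k−1})` with `α = (1/3, 1/2, 1)`; its stability
  polynomial is the classical third-order one (imaginary-axis limit √3).
  The time step obeys an advective CFL (default 0.32–0.35), a viscous cap
  and a cap from the largest explicit fringe rate.
* **Projection** — after every stage the velocity is projected: the
  Poisson problem is solved spectrally, FFT along periodic axes and a
  type-II cosine transform (cell-centered homogeneous Neumann) along wall
  axes. This inverts the discrete 7-point Laplacian exactly, so the
  post-projection divergence is at round-off.
* **Fringe forcing** — inflow profiles, outflow damping, immersed objects
  and data-driven walls are imposed by the volumetric penalty
  `f = λ(x)(U(x,t) − u)`. For time-dependent targets the rate can be tied
  to the stage, `λ = 1/(α_k Δt)`, which makes the explicit stage land on
  the target exactly and is unconditionally stable. The immersed cylinder
  uses `λ = 100` with zero target; the inflow fringe `λ = 50`.
* **Bulk constraint** — a constant volume-averaged streamwise velocity
  (0.667 for the channel) is maintained by a uniform body force, the
  standard constant-mass-flux driving.

Verification: Taylor–Green kinetic energy decays within 1% of
`exp(−4νk²t)` over one turnover at 64²; pointwise error converges with
slope ≈ 2; a bulk-forced laminar channel converges to the parabolic
profile within 0.5%; the projection is idempotent on solenoidal fields.

## Synthetic cases (what the generator emulates)

* **Confined cylinder** (quasi-2D, Re = 150, channel 32h×2h, blockage
  0.5, cylinder at (9h, h)): periodic vortex shedding; grid 256×32 cells
  at full scale (128×16 reduced). After a 100-period spin-up the measured
  shedding period at full scale is within 0.5% of the reference value
  1.9951 s; shorter spin-ups sample a still-converging transient. Data
  windows 1–6 follow the published layout, with windows 2/3 splitting
  window 1 at the cylinder center.
* **Turbulent channel** (Re = 5000, 4πh×2h×2πh, bulk 0.667): Poiseuille
  initial condition destabilized with seeded random solenoidal low-mode
  perturbations of 10% amplitude (a deliberate replacement of
  Tollmien–Schlichting wave seeding — the filter itself triggers
  transition in the assimilation runs, so the exact seeding mechanism of
  the truth is peripheral). Desk-scale resolution is 24³ cells; the
  full-scale default is 60³ (divisible by the voxel factors 3 and 5 the
  downsampling study needs).
* **Pulsatile jet** (synthetic phantom stand-in): a round pulsatile jet
  (heart rate 70 beats/min, systolic-peaked waveform) inside a cylindrical
  phantom on an all-periodic padded domain; phantom walls and inflow are
  enforced by stability-scaled fringe regions driven by (zero-valued and
  lowest-slice) data, and the non-uniform 22-interval phase schedule is
  refined ×3 to 66 intervals. It emulates the *structure* of a physical
  valve-flow acquisition pipeline, not its physics.

Voxel extraction tiles a window with `(1+dw)` nodes per voxel and axis
(`dw = 0` is node-resolution identity; `dw = 1` gives the cylinder's 2×2×2
voxels, `dw = 2` the 3×3×3 of the jet/channel). Extracted per-pulse voxel
samples are phase-averaged into mean and covariance with divisor `p`.
Masked acquisition (vessel walls) is emulated by zeroing mean and
covariance outside a region of interest.

What the synthetic data do **not** contain: instrument noise (no Gaussian
measurement error is added on top of the voxel averaging), point-spread
functions, non-Gaussian MRI noise, or model error (twin experiments use
the same solver for truth and assimilation). Passing twin tests therefore
demonstrates correct filter mechanics and information propagation, not
robustness to real measurement physics.

## Diagnostics

* `friction_reynolds`: wall gradient from the first off-wall node with a
  one-sided first-order difference (distance Δy/2), averaged over both
  walls by default; `U_τ = √(ν|∂u/∂y|)`, `Re_τ = U_τ L_ref/ν`. For the
  laminar parabola at Re = 5000 this gives the closed form
  `√(2·5000) = 100` up to the O(Δy) one-sided-difference error.
* `to_wall_units`: `y⁺ = y U_τ/ν`, `u⁺ = u/U_τ`.
* `tke`: volume average of half the trace of the fluctuation covariance;
  the `D` regularization is excluded by default so the value measures
  physical fluctuations (a D-inclusive variant exists for debugging).
* `rss_profile`, `vorticity` (span-wise component, quasi-2D).

## Numerical choices and edge cases

* Shedding-period estimation: the probe signal is resampled uniformly,
  Hann-windowed, the FFT peak refined by a fine frequency scan plus
  parabolic interpolation; ≥ 20 cycles are used.
* Voxels containing no grid node raise an error (misconfigured windows
  should fail loudly); observation windows must lie on cell faces.
* The analysis loop lands on phase times exactly by shortening the last
  time step.
* Identical configuration and seed give bit-identical runs; the manifest
  records the config digest and seed.

## Problem sizes used by the shipped tests

The test suite runs the cylinder twin at 128×16 cells with 50 pulses and
20 phases, the channel property suite at 24³ cells with 120 update
intervals of 0.5 s for `dw ∈ {1,2,3}`, and the full-scale (256×32)
cylinder only for the shedding-period measurement. The full-scale channel
study (60³ cells, thousands of time units) is supported by the same code
paths but is a long-running configuration by design and is not part of the
default suite.

## Known limitations

* Second-order spatial accuracy: coarse grids under-resolve the cylinder
  boundary layer (the reduced 128×16 case sheds with a period ~40% longer
  than the full-scale flow; twin consistency is unaffected since truth and
  assimilation share the solver).
* No covariance localization or inflation beyond `D`; cross-voxel and
  cross-node correlations are ignored by construction.
* The face redistribution of the analysis correction slightly smooths
  non-smooth corrections (exact only for per-axis affine fields).
* Stretched or curvilinear grids, LES closures and fluid–structure
  interaction are out of scope.
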