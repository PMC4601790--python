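# Methods

## Model

Five species: cytoplasmic MinD:ADP, MinD:ATP and MinE (densities ρ,
proteins/µm³) and membrane-bound MinD and MinD:MinE complex (densities σ,
proteins/µm²).  Cytoplasmic species diffuse (D_D = D_E = 2.5 µm²/s);
membrane species do not move at all — an acknowledged idealization of the
model that produces spatially pinned membrane clusters ("starry night") in
the stochastic version.  Reactions: nucleotide exchange (k_ex = 1/s),
spontaneous membrane attachment of MinD:ATP (k_D = 0.025 µm/s), cooperative
recruitment by membrane-bound MinD (k_dD = 0.0015 µm³/s), MinE binding
(k_E = 0.093 µm³/s) and hydrolysis/release (k_de = 0.7/s).  The network
moves molecules between pools without creating or destroying them, so total
MinD and total MinE are exact invariants; the solvers are constructed to
conserve them to round-off (deterministic) or exactly as integers
(stochastic).

Default concentrations are 1273 µm⁻³ MinD and 446 µm⁻³ MinE — the wild-type
lineal densities 1000/µm and 350/µm divided by the cross-section of a
radius-0.5 µm cylinder — applied per unit volume in every geometry.

## Geometry

Shapes are defined by signed distance functions: the pill is a capsule
(exact SDF), and every flattened shape is the set of points within
`thickness/2` of the inward-offset 2D outline in the mid-plane, which
produces flat faces and an exactly semicircular rim.  Flattened cells use
thickness 0.4 µm throughout.  Voxelization samples the SDF at cell-centered
voxels (grid spacing dx, default 0.05 µm; long axis along y, flattened
normal along z, symmetric grids so mirror-symmetric shapes yield
mirror-symmetric masks).  Boundary-voxel interior volumes come from 4³
sub-sampling; interior volume landing in voxels whose center is outside is
split equally among inside face-neighbors, so the voxel-summed volume is an
unbiased estimate (pill at dx = 0.05: 0.04% volume error, 0.12% area error).

Membrane area per voxel is computed by triangulating the zero level set
(marching cubes) and assigning each triangle's area to the voxel containing
its centroid; naive face counting would overestimate the area of oblique
surfaces by up to ~50%.  The wall-delta coupling δ(d_w)·X becomes
X·(a_i/v_i) in boundary voxel i, which preserves the total exchange flux
exactly.  Boundary voxels holding less than 10% of a full voxel are merged
into their interior neighbors (equal split, preserving symmetry) to avoid
stiff exchange rates.

The irregular flattened shapes (`shapeA`, `shapeB`) are parametric
stand-ins for microchannel-deformed cells whose true outlines are not
numerically specified anywhere: cosine-series radius functions
r(θ) = Σ a_k cos(kθ) with documented coefficients.  Cosine-only series make
the outline symmetric across the long axis; nonzero odd harmonics break the
end-to-end symmetry, leaving exactly one in-plane mirror plane.  shapeB is
just over 5 µm wide, matching the reported widths of strongly deformed
cells.  All quantitative results for these two shapes are
approximation-dependent by construction.  `stadiumA`/`stadiumB` are
discorectangles matched to the corresponding irregular shape in outline
aspect ratio, thickness and volume; the match solves for the outline width
by 1D root finding on the closed-form stadium volume (Steiner formula for
the r-neighborhood of the eroded outline) and reproduces the reference
volumes to < 0.1%.

## Deterministic solver

Explicit forward Euler with flux-form 7-point diffusion (no-flux walls) and
pointwise reactions; dt = 0.5·dx²/(6·D_max).  Boundary-voxel volumes enter
the dynamics floored at half a full voxel: partial volumes below ~50% would
push the local diffusion eigenvalue past the explicit stability bound, and
the floor keeps the default step stable while leaving typical boundary
voxels (50–100% coverage) untouched.  The integrator is validated against
an adaptive ODE solution of the well-mixed model (single voxel, relative
error < 10⁻⁴ over 100 s), against the linear stability analysis (measured
harmonic-mode growth rates in a thin strip within 5% of the leading
Jacobian eigenvalue), and by self-convergence (period of a 3 µm disc
changes by 0.7% between dx = 0.2 and 0.1 µm).

The homogeneous state is a fixed point, so runs start from uniform
MinD:ADP and MinE plus either a seeded 1% random multiplicative
perturbation or a deterministic polar gradient.  Production figures in
`analysis/` use the polar-gradient seed for flattened shapes because it
projects directly onto the slowest unstable mode; near-threshold shapes
otherwise spend hundreds of seconds amplifying the random seed's tiny
component on that mode.

## Stochastic solver

The same network as a jump process: integer counts per voxel, unimolecular
rates n·k, membrane attachment n_DATP·k_D·a_i/v_i, recruitment
n_DATP·k_dD·(n_σD+n_σDE)/v_i, MinE binding k_E·n_E·n_σD/v_i (v_i the actual
boundary-voxel interior volume, not dx³), hydrolysis n_σDE·k_de, and
diffusion hops at D/dx² per molecule per open face.  Two exact samplers:
the next-subvolume method (per-voxel next-event times in an indexed binary
heap) for production, and the direct method as the correctness reference —
their end-state distributions on a 2-voxel system agree by chi-squared test
(p ≈ 0.6).  Initial placement is a multinomial scatter proportional to
voxel volume, all MinD as MinD:ADP.  Exponential waiting times are redrawn
after every rate change (memorylessness makes this exact).  Further
validation: first-order decay matches 100·e^(−0.7t) across 600 replicas;
free-molecule MSD is 2Dt per axis; well-mixed replica means track the ODE
solution within 0.2% in a regime where every one of the five pools holds
≥ 10⁴ molecules.  (With the standard rates, a well-mixed compartment drives
the cytoplasmic MinE pool down to a few molecules, where the stochastic
mean genuinely departs from the ODE by finite-size effects — that regime
tests physics, not sampler correctness, so the mean-field check uses a rate
set chosen to keep all pools large.)

## Linear stability analysis

For the infinite 0.40 µm slab (membrane on both faces) and the infinite
radius-0.5 µm cylinder (membrane on the lateral wall), the steady state of
the five equations is solved across the thin dimension (finite volumes,
16 points; BDF relaxation followed by a Newton polish with the two
conserved totals imposed as constraints; residual < 10⁻⁸).  Harmonic
perturbations e^{iqx} in the unbounded direction add −Dq² to the diffusing
species; the growth rate at half-wavelength l is the largest real part of
the eigenvalues of the (3N+2·faces)-dimensional Jacobian at q = π/l, and
the stability limit is the bisected zero crossing (bracketed to 0.005 µm).

Results with the default parameters: cylinder 2.076 µm — reproducing the
classic ~2 µm half-wavelength limit of the cylindrical analysis, which is
the available independent benchmark for the method — and slab 2.096 µm.
The slab limit is remarkably robust: resolved vs well-mixed thickness
differ by 0.016 µm, 8 vs 24 grid points by < 0.01 µm, and varying the
thickness from 0.2 to 1.0 µm moves it only between 2.12 and 2.15 µm
(well-mixed), because the totals are prescribed per volume and the
membrane-to-volume ratio largely cancels.  Flattening in itself therefore
barely changes the instability threshold in this model.  The instability is
oscillatory (a complex eigenvalue pair crosses the axis).  Consistently,
deterministic discs with longest chord below the limit relax to a
motionless state and discs above it develop sustained oscillations; the
finite-disc onset sits somewhat above the infinite-slab limit because the
unstable mode must fit in the domain (a 3 µm disc oscillates, at 2.6 µm the
growth is already very slow).

At q → 0 the two conserved totals give two zero eigenvalues; at q → ∞ the
three diffusing modes are crushed by −Dq² while the immobile membrane
species retain finite (negative) relaxation rates, so the short-wavelength
limit is stable but not diffusion-dominated.

## Oscillation quantification

Polar regions are the extreme thirds of the long-axis extent of the mask;
region totals count all four MinD pools weighted by per-voxel volume/area,
so stochastic counts are reproduced exactly.  The cross-correlation is
mean-subtracted, averaged over the available overlap at each lag
(restricted to half the record), and normalized by its extremum nearest
zero lag.  The decoherence model −cos(2πτ/T)e^(−τ/τ_c) is fitted by
nonlinear least squares, initialized from the first zero crossing (T₀) and
the 1/e point of the |C| maxima envelope (τ_c0), repeated from three
jittered starts.

Deterministic trajectories are effectively infinitely coherent, which the
exponential fit cannot represent with finite precision; coherence is
therefore also reported as the envelope decay over ten periods, read off an
exponential trend fitted through all |C| local maxima in the range.
Individual maxima wobble by O(T/overlap) from the finite correlation
window, so first-vs-last comparisons are unreliable at the percent level
while the trend fit is stable (deterministic pill: 0.6% over ten periods;
stadium: 1.4%).

Recovery study: the fit is exact on noiseless curves (< 0.1%).  For noisy
phase-diffusion replicas the τ_c estimator's sampling error scales as
√(τ_c/duration) — the information is the number of coherence volumes in the
record — so the study uses records of 2×10⁶ s (≈ 6500 coherence times, 2 s
stride) to put the per-replica standard deviation near 2%; with T = 58 s,
τ_c = 306 s and additive noise of 0.1, 99 of 100 seeded replicas recover
both parameters within 5%.

Maxima tracking samples frames every 2.5 s, projects all MinD pools along
the flattened normal, blurs with the Gaussian PSF, and takes the global
argmax; an arrow is emitted when the maximum moves ≥ 0.5 µm from the
previous arrow head.  Deterministic pill tracks are strictly bipolar (all
arrow heads in the polar thirds).

## Optics

Projections are line integrals weighted by per-voxel interior volume (plus
membrane contributions weighted by per-voxel area), so the projected total
equals the 3D molecule count exactly.  The PSF is the widefield Gaussian
approximation σ = c·λ/NA with c = 0.21 (configurable; which Gaussian-fit
variant applies is not pinned down, so the constant is a parameter), NA 1.3
and λ = 650 nm by default, giving σ = 0.105 µm.  Blurring uses a normalized
discrete kernel (truncated at 4σ) with zero-padded boundaries; coarse-grid
images are pixel-replicated to ≤ σ/2 pixels before blurring.

## Synthetic signals

The signal generator is a phase-diffusing oscillator: phase increments
ω·dt + N(0, 2·dt/τ_c), channels ±cos φ plus independent Gaussian noise.
Its exact cross-correlation is the damped cosine with the specified T and
τ_c, which makes it the natural ground-truth generator for the fit stage.
It emulates the temporal statistics of the stochastic polar counts only —
not amplitude fluctuations, shot noise, or any spatial structure — so
recovery results validate the analysis pipeline, not the spatial model.

## Problem sizes and runtimes

Tests and analysis run the lattice solvers at dx = 0.1 µm (the stability
analyses and geometry checks use finer resolutions where relevant; the
shape library and acceptance quantities are computed at the 0.05 µm
production grid).  Deterministic runs cover 700–1600 s of cell time;
the stochastic pill run in `analysis/` covers 600 s (≈ 13 periods): it
shows the qualitative contrast — finite coherence of order ten periods
versus the deterministic model's effectively infinite coherence — but both
its period (47 s at dx = 0.1 versus 39 s deterministic) and its coherence
time are rough single-trajectory, coarse-grid estimates.  Precise coherence
comparisons between the flattened shapes require multi-thousand-second
lattice trajectories at dx = 0.05 and are validated instead at the pipeline
level with matched synthetic signals.

## Known limitations

* No membrane diffusion (model property): stochastic membrane clusters are
  pinned where they form.
* The irregular outlines are documented approximations; their polar-third
  fractions (28–31%) sit inside, but do not span, the 19–33% range of the
  traced experimental shapes, and all shapeA/shapeB numbers inherit this
  approximation.
* The explicit deterministic scheme is first-order in time; accuracy is
  certified by the oracle and self-convergence tests rather than by scheme
  order.
* The finite-disc oscillation threshold is only loosely tied to the
  infinite-slab limit (mode confinement); the consistency checks use discs
  well below and well above the limit.
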