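# minflat

Lattice simulations of Min-protein pole-to-pole oscillations in wild-type
and mechanically flattened *Escherichia coli* cells.

*E. coli* places its division plane with the MinC/MinD/MinE system: MinD
cycles between the cytoplasm and the membrane, driven by MinE-stimulated ATP
hydrolysis, and the resulting pole-to-pole oscillation keeps the division
inhibitor MinC away from mid-cell.  When cells are forced into thin slits
they flatten into wide, irregular pancake-like shapes, and the spatial
regularity of the oscillation degrades.  This package implements the
standard five-species reaction–diffusion model of the Min system on
voxelized 3D cell geometries — as a deterministic finite-difference
integrator and as an exact stochastic (next-subvolume) sampler — together
with the analysis pipeline used to quantify the oscillations.

## Model

Cytoplasmic densities ρ (proteins/µm³) and membrane-bound densities σ
(proteins/µm²) evolve under

    ∂ρ_D:ADP/∂t = D_D ∇²ρ_D:ADP − k_ex ρ_D:ADP + δ(d_w) k_de σ_DE
    ∂ρ_D:ATP/∂t = D_D ∇²ρ_D:ATP + k_ex ρ_D:ADP − δ(d_w)[k_D + k_dD(σ_D+σ_DE)] ρ_D:ATP
    ∂ρ_E/∂t     = D_E ∇²ρ_E + δ(d_w) k_de σ_DE − δ(d_w) k_E σ_D ρ_E
    ∂σ_D/∂t     = −k_E σ_D ρ_E + [k_D + k_dD(σ_D+σ_DE)] ρ_D:ATP
    ∂σ_DE/∂t    = −k_de σ_DE + k_E σ_D ρ_E

where d_w is the distance to the nearest wall and δ(d_w) confines membrane
exchange to the wall.  Defaults are the standard rate set
(D_D = D_E = 2.5 µm²/s, k_ex = 1/s, k_D = 0.025 µm/s, k_dD = 0.0015 µm³/s,
k_de = 0.7/s, k_E = 0.093 µm³/s) and wild-type concentrations of 1273 µm⁻³
MinD and 446 µm⁻³ MinE (1000/µm and 350/µm in a radius-0.5 µm cylinder).

Oscillation regularity is quantified by the cross-correlation of total MinD
in the two polar thirds of the cell,
C(τ) ∝ ∫ (N_top(t) − N̄_top)(N_bottom(t+τ) − N̄_bottom) dt, fitted with the
decoherence model C(τ) = −cos(2πτ/T)·exp(−τ/τ_c), where T is the period and
τ_c the coherence time.  A linear stability analysis of the homogeneous
steady state yields the largest half-wavelength at which the system is
stable — cells smaller than this limit do not oscillate.

## Worked example

```python
from minflat import HUANG_RATES, InitialCondition, build_pill
from minflat.detsim import run
from minflat.oscillometry import cross_correlation, fit_decoherence, polar_counts

pill = build_pill(length=4.0, radius=0.5, dx=0.1)       # wild-type capsule
traj = run(pill, HUANG_RATES, InitialCondition(seed=1),
           t_end=1100.0, output_stride=1.0)
series = polar_counts(traj, pill)                # MinD in the polar thirds
lags, c = cross_correlation(series.after(200.0)) # drop the start-up transient
fit = fit_decoherence(lags, c)
print(f"period {fit.period:.1f} s, coherence time {fit.coherence_time:.2g} s")
```

prints:

```
period 38.7 s, coherence time 3.3e+09 s
```

i.e. the deterministic wild-type cell oscillates pole to pole every ~39
seconds and is perfectly periodic — the fitted coherence time is many orders
of magnitude beyond the record length, and the correlation envelope decays
by under 1% over ten periods.  The stochastic sampler
(`minflat.stochsim.simulate`) produces the same oscillation with a finite
coherence time of a few hundred seconds.

The `analysis/` directory contains the numbered study drivers (shape
library, stability limits, deterministic and stochastic runs, sampler
validation, fit-recovery study); each writes its tables under `results/`.
A `minflat` command-line tool exposes config-driven pipeline runs
(`minflat simulate run.yaml`), the shape library (`minflat shapes`) and the
dispersion analysis (`minflat stability slab`).

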