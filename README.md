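# springnet

Phase transitions in cross-linked particle networks: a stochastic
spring-link particle simulator, its macroscopic aggregation–diffusion
limit, and the spectral/bifurcation analysis that predicts where and how
the uniform state destabilises.

## The problem

Many biological systems — adhering cells, transient fiber networks,
protein complexes — consist of agents connected by links that break and
reform quickly.  When the linking/unlinking is much faster than
transport, the particle density f(x, t) of such a system obeys a single
nonlocal equation on the periodic box [-L, L)^d:

    ∂t f = D Δf + ∇·( f ∇(V * f) ),

where D is the noise intensity and V is the compactly supported spring
potential V(x) = (|x| − ℓ)² − (R − ℓ)² for |x| < R (zero outside): links
behave as springs with rest length ℓ, active within a detection radius R.

The uniform density ρ* = (2L)^-d is a steady state.  Fourier mode k
grows at rate λ_k = −(π²|k|²/L²)(D + V̂_k), so lowering the noise below
D_c = −V̂_1 destabilises it and an aggregated state bifurcates.  The
bifurcation is *supercritical* (continuous onset of the order parameter
Q, the first cosine moment of the steady density) or *subcritical*
(discontinuous jump) depending on the spring geometry: in 1D the sign of
2V̂_2 − V̂_1 decides; in 2D a combination V* of the (1,0), (2,0), (1,1)
modes, built from Bessel and Struve functions, plays the same role.

`springnet` computes all of this — closed-form mode coefficients,
critical lengths and noises, amplitude predictions, a positivity-
preserving well-balanced finite-volume solver for the PDE (1D and 2D),
and a JIT-compiled particle simulator with stochastic link dynamics —
and ships experiment drivers that regenerate the reference tables,
bifurcation diagrams, and micro/macro comparisons.

## Worked example

```python
import numpy as np
from springnet import (ModelParams, critical_noise, critical_lengths_1d,
                       bifurcation_type_1d, amplitude_prediction)
from springnet.macro1d import initial_density, run_to_steady

ell_c, ell_star, D_star = critical_lengths_1d(R=0.75, L=3.0)
print(f"ell_c = {ell_c:.4f}, ell* = {ell_star:.4f}, D* = {D_star:.4f}")

p = ModelParams(D=0.0030, ell=0.4725)      # just below threshold
print(f"D_c = {critical_noise(p):.4f}, regime = {bifurcation_type_1d(p).regime}")
print(f"predicted |rho| = {amplitude_prediction(0.001, p).rho_th:.4f}")

res = run_to_steady(initial_density(0.01, 256, p), p)
print(f"solver: Q = {res.Q:.4f}, |rho|_num = {res.rho_num:.4f}, "
      f"T_max = {res.t_max:.0f}")
```

prints

    ell_c = 0.4947, ell* = 0.4530, D* = 0.0074
    D_c = 0.0040, regime = supercritical
    predicted |rho| = 0.3428
    solver: Q = 0.2217, |rho|_num = 0.3304, T_max = 7824

Reading: with spring length 0.4725 the uniform state loses stability at
D_c ≈ 0.0040 through a continuous (supercritical) bifurcation; at
D = 0.0030 the density aggregates into a single bump whose measured
amplitude 0.33 sits close to the weakly nonlinear prediction 0.34, and
the solver reaches stationarity (max residual of D log f + V*f below
1e-7) at t ≈ 7.8e3.

The same surfaces are available from the shell:

    springnet spectral --ell 0.4725 --noise 0.003
    springnet tables --outdir results
    springnet window --ratio 1.0
    springnet micro-run --n-particles 1000 --noise 0.003 --ell 0.4725

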