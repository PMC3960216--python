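# pemrelease

Modelling and bookkeeping tools for drug-release retardation by
polyelectrolyte-multilayer (PEM) coatings on polymer particles.

## The problem

Layer-by-layer (LbL) PEM films assembled on drug-loaded particles (e.g.
BSA-loaded PLGA nano- and microparticles) act as an extra diffusion barrier.
Two questions dominate the analysis of such systems:

1. **How much retardation does the coating provide, and how does it depend on
   particle size?**  Treating the coated particle as two concentric spherical
   conduction regions, the steady-state resistance of a shell bounded by radii
   `r_in < r_out` with diffusivity `D` is

   ```
   R = (r_out − r_in) / (4π · D · r_in · r_out)
   ```

   The core region from an interior reference radius `r₁` to the particle
   surface `r₂` contributes `R_a` (diffusivity `D₁`); the PEM shell of
   thickness `t` (outer radius `r₃ = r₂ + t`) contributes `R_b`, with the
   partition coefficient `K` folded into an effective shell diffusivity
   `K·D₂`.  Under equal driving force the coated/uncoated mass-transfer-rate
   ratio — the **retardation ratio** — is

   ```
   M_T / M₀ = R_a / (R_a + R_b)
   ```

   It is exactly 1 with no coating (`t = 0`) or with a resistance-free core
   (`D₁ = 0`, the capsule limit), and tends to 1 as the particle grows at
   fixed coating: PEM barriers matter on small particles and vanish on large
   ones.

2. **Is an observed release reduction really retardation?**  Release is
   reported as a percentage of measured drug content.  Drug lost during the
   coating procedure shrinks that content, so a smaller absolute release can
   register as a much smaller percentage with no barrier involved: from a
   100 µg load, a 20 µg release reads 20%; lose 15 µg while coating and a
   5 µg release reads 5.9% of the remaining 85 µg.  The `bookkeeping` module
   implements this arithmetic exactly, together with the cumulative-release
   correction for aliquot-and-replenish sampling, drug loading, encapsulation
   efficiency, and per-step coating-loss accounting.

Around these sit a transient two-layer radial diffusion solver (the numerical
oracle for the closed-form ratio and the forward model for fitting), a seeded
generator of study-shaped synthetic data (triplicate release curves with a
burst fraction, layer-by-layer loss runs, alternating ζ-potential sequences),
and least-squares recovery of transport parameters from release curves.

## Worked example

```python
import numpy as np
from pemrelease import CompositeSphere, retardation_ratio, total_resistance
from pemrelease.synthetic_data import SyntheticConfig, generate_release_curves, default_geometry
from pemrelease.fitting import fit_release

# 330 nm particle (r2 = 0.165 um), 20 nm PEM shell at 1% of core permeability
geo = default_geometry()
rb = total_resistance(geo)
print(f"R_a={rb.R_a:.4g}  R_b={rb.R_b:.4g}  ratio={retardation_ratio(geo):.4f}")
# R_a=160.8  R_b=5214  ratio=0.0299      -> strong retardation on the nanoparticle

big = geo.replace(r1=0.75 * 160, r2=160.0)   # same coating on a 160 um particle
print(f"ratio={retardation_ratio(big):.4f}")
# ratio=0.9639                            -> barely any retardation at 160 um

# synthetic noisy triplicate release study, then recover the shell diffusivity
cfg = SyntheticConfig(seed=42, noise_sd=0.03)
curve = generate_release_curves(cfg, coated=True)
print(np.round(curve.mean(), 3))
# [0.395 0.412 0.412 0.412 0.423 0.476 0.567 0.73  0.833]
#  ^ ~40% burst at t=0, then diffusion-limited release over a week (times in h)

fit = fit_release(curve, geo, free=("D2",), bounds={"D2": (1e-8, 1e-3)},
                  grid=cfg.grid, seed=42)
print(fit.estimates)
# {'D2': 9.524e-06, 'burst_fraction': 0.3948}   (true D2 = 1e-05, within 5%)
```

The retardation ratios say that the identical 20 nm coating removes ~97% of
the early mass-transfer rate from a 330 nm particle but only ~4% from a
160 µm particle.  The fit recovers the shell diffusivity from the noisy
triplicates to within a few percent.

The bookkeeping arithmetic of the loss-masquerade illustration:

```python
from pemrelease import percent_release, loss_adjusted_release, render_percent
render_percent(percent_release(20, 100))        # '20.0'
render_percent(loss_adjusted_release(5, 100, 15))  # '5.9'
```

A `pemrelease` command-line interface wraps the same operations
(`ratio`, `sweep`, `simulate`, `generate`, `bookkeep`, `fit`); every run
writes a JSON manifest of its resolved configuration.

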