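# Methods

## Steady-state composite-sphere model

A coated particle is modelled as two concentric spherical conduction regions:
the polymer core from an interior reference radius `r1` to the particle
surface `r2` (diffusivity `D1`), and the PEM shell from `r2` to
`r3 = r2 + t` (diffusivity `D2`, shell/core partition coefficient `K`).  At
steady state the mass-transfer rate under a concentration difference
`C_i − C_0` is `(C_i − C_0)/R_T` with `R_T = R_a + R_b`, where each shell
resistance is `(r_out − r_in)/(4π D r_in r_out)` — the spherical-wall
conduction solution, i.e. the integral of `dr/(4π D r²)` across the shell.
`K` enters only through the effective shell diffusivity `K·D2`; with a
perfect-sink exterior the model cannot distinguish `K` from `D2`
individually, which is why the fitter refuses to free both at once.

The retardation ratio `M_T/M_0 = R_a/(R_a + R_b)` compares coated and
uncoated particles under equal driving force.  It is descriptive of early
time points only: later, the coated particle's interior concentration stays
higher and the true ratio exceeds it.  Limits are handled as exact special
cases rather than floating-point limits: `t = 0` (no coating) and `D1 = 0`
(no core resistance; a capsule) both return exactly 1.

`r1` is a modelling choice, not a physical constant, and the ratio depends on
it, so every API that reports a ratio also carries the `r1` it used.  Size
sweeps default to `r1 = r2/2`; comparisons against the transient solver use
the reservoir radius of the initial condition (below).  The large-particle
limit `ratio → 1` is approached with deficit `≈ (t/r2)·(D1/D2)/K` at
`r1 = r2/2`, so the "within 10⁻³ of 1 at r2/t ≥ 10⁴" behavior quoted in the
tests is the equal-diffusivity case.

All lengths must be in one unit; `CompositeSphere.from_units` normalizes
mixed nm/µm/mm input.  Diffusivities are in (length unit)²/time unit; the
package's defaults use µm and hours.

## Transient two-layer solver

The time-dependent problem solves `∂C/∂t = D(r) (1/r²) ∂/∂r(r² ∂C/∂r)` in
both regions with a zero-flux centre, a perfect sink at the outer surface
(the release medium is large and replenished), and an interface at `r2` that
is flux-continuous with a partition jump `C_shell = K·C_core`.

Discretization: the partition-scaled potential `ψ = C/φ(r)` (`φ = 1` core,
`K` shell) is continuous everywhere, and mass per cell is `φψV`.  A
conservative finite-volume scheme connects neighbouring cell centres through
the *exact* spherical-shell resistance of the two half cells, so the discrete
steady state matches the closed-form series-resistance model to machine
precision, including the interface jump.  Cell widths within each region
shrink geometrically toward the interface and the outer surface
(`grading_ratio`, default 50, is the largest/smallest width ratio) because
that is where early-time boundary layers live.

Time stepping is a θ-scheme: backward Euler by default (unconditionally
stable, monotone), Crank–Nicolson optionally, and an explicit scheme that
refuses to run when the step exceeds its stability limit.  Steps follow a
quadratically graded grid `t_k = t_end (k/N)²`, which resolves the `√t`
early-release singularity without wasting steps late.  Released mass is
accumulated from the outer-boundary flux, making the per-step balance
`remaining + released = initial` an algebraic identity of the scheme; the
solver reports the worst relative violation (round-off, ~1e-13) and the test
suite bounds it at 1e-6.

Accuracy: against the homogeneous-sphere eigenfunction series, a
180+32-cell, 4000-step run is within 7e-4 of the exact fractional-release
curve uniformly in time; halving the resolution changes mid-curve values by
under 1e-3.

Initial conditions: `uniform_core` (the default release scenario),
`uniform_total` (homogeneous sphere, used for analytic checks),
`surface` (a configurable fraction of the load in a thin subsurface band,
emulating the surface segregation that produces burst release), and
`quasi_steady` (below).

## Consistency between the transient and steady-state views

The closed-form ratio assumes both particles see the same concentration
difference between `r1` and the sink.  With a uniformly loaded core that
assumption never coexists cleanly with quasi-steadiness: the bare particle's
near-surface inventory drains on the same clock that establishes the
quasi-steady profile, so the transient rate ratio sweeps from 0 (coated shell
lag) through the closed-form value to above 1 (bare depletion) without
pausing.  `quasi_steady_flux_ratio` therefore realizes the assumption
directly: both runs start from a saturated reservoir inside `r1` with the
steady conduction profile between `r1` and the sink already in place.  At
early times each particle then releases at exactly its quasi-steady rate
under the same driving force, and the ratio of mean **mass** release rates
over a window of 1–10% of the bare reservoir's drainage time constant
(`R_a · V_reservoir`) reproduces `R_a/(R_a + R_b)` to well under the 15%
consistency bound (observed: <1%), drifting upward only as the two reservoirs
drain apart.  Uniform-loading comparisons are retained as qualitative checks
(thicker shells give smaller ratios; vanishing thickness gives 1).

## Measurement bookkeeping

Aliquot-and-replenish sampling: withdrawing `V_aliquot` at each time point
and replacing it with drug-free buffer removes drug mass that later readings
never see.  Cumulative release at point n is
`V_total·C_n + V_aliquot·Σ_{i<n} C_i`, verified property-based against an
explicit withdraw/replenish simulation.  Because published release studies do
not always state whether this correction was applied, the uncorrected
(`V_total·C_n` only) mode is available for sensitivity checks.

Drug loading is `100·(drug mass)/(particle mass)` (w/w) and encapsulation
efficiency `100·(actual)/(intended drug mass)` — the standard definitions,
exposed separately.  `loss_adjusted_release` recomputes a percentage on the
post-loss content basis `content·(1 − loss/100)`, the arithmetic by which
unreported coating loss masquerades as retardation (20% → 5.9% in the
100/20/15/5 µg illustration).  Percentages are full precision internally;
`render_percent` applies one-decimal round-half-away-from-zero at the
reporting layer only.

Coating-loss summaries flag whether the layer-1 wash loss exceeds its
adsorption loss.  The sign of that comparison tracks the build-up pH relative
to the protein's isoelectric point (~4.7 for BSA): below it the positively
charged protein desorbs during washing; above it the protein stays bound to
the polycation and washing removes little.

## Synthetic data

The generator emulates the study conditions the analysis assumes:

* **Release curves**: `burst + (1 − burst)·F_solver(t)` with burst fraction
  0.40 (the immediate release of surface-segregated protein from uncoated
  nanoparticles), triplicates, and a measurement schedule of 0–168 h.  The
  default geometry is a 330 nm particle (`r2 = 0.165` µm) with a 20 nm
  4-layer shell; `D1 = 1e-3` µm²/h puts the core diffusion time `r2²/D1`
  near 27 h (days-scale release, appropriate for a protein in a PLGA
  matrix), and `D2 = 1e-5` µm²/h (1% of core) puts the shell in the
  barrier-dominant regime a retarding PEM occupies.  Noise is multiplicative
  mean-one lognormal per point (assay CV scales with signal), default
  σ = 0.03, with each replicate clipped to monotone non-decreasing.  The
  replicate count (3) follows standard triplicate practice; within-replicate
  noise levels are assumptions, not measured values.
* **Coating runs**: two steps (adsorption, wash) per layer; expected
  per-layer losses decay geometrically (default rate 0.55, matching losses
  concentrated in the first layers); draws are Gamma (non-negative,
  right-skewed, shape 80); the expected grand total equals the published
  per-condition total (pair × build-up pH: 8.0/5.4/6.8/3.7/5.0/3.7%, mean
  5.4%); the layer-1 wash/adsorption ordering is enforced to carry the pH
  signature deterministically.
* **ζ-potential sequences**: strict sign alternation starting positive after
  the polycation layer, magnitudes near 40 mV (PAH/PSS) or 15 mV (PLL/DES)
  with configurable spread, bare particle at −25 mV.

Determinism: all draws derive from `SeedSequence([seed, stream])` with a
fixed stream id per product, so identical configs are byte-identical and
generating one product never perturbs another.

What the generator does **not** emulate: particle aggregation, size
distributions (a single radius stands for the batch), pH-switchable
permeability, matrix degradation, incomplete release from drug–matrix
interaction, or assay-specific artifacts (calibration curvature, complex
formation).  Passing tests therefore demonstrate correctness of the
transport/bookkeeping machinery under the stated statistical structure, not
fidelity to any particular experimental release curve.

## Fitting

`fit_release` minimizes the residual sum of squares between the
burst-plus-diffusion forward model and all replicate points, with bounded
trust-region least squares on log10-scaled diffusivities, five seeded starts
(bounds centre plus four random), best objective winning and ties broken by
the smaller `D2`.  The burst fraction is fixed from the observed t = 0 value
unless freed.  Non-convergence is flagged on the result, never raised.
Uncertainty by replicate bootstrap is available (`n_bootstrap`; each resample
refits from the best point) and is off by default since each resample costs a
full fit.  On the default synthetic conditions, noise-free curves return the
true `D2` within 1%, and 3%-noise triplicates land within 20% in well over
90% of seeded trials; recovery error grows with the noise level.

`empirical_retardation` is the data-side ratio (released fractions or
early-window rates, coated/uncoated) with a replicate-resampling percentile
interval.  It is invariant to a common rescaling of both curves, so the
percent-of-content basis drops out.  On matched synthetic pairs with a fixed
20 nm shell it rises from ~0.04 at `r2 = 0.33` µm to ~0.98 at 160 µm —
the size dependence of release retardation, reproduced end to end.

## Numerical and design choices

* Problem sizes used by the tests (a few hundred cells, a few thousand time
  steps, 100 recovery trials) were chosen so the full suite runs in a few
  minutes while holding the stated tolerances with margin.
* Degenerate inputs are defined values where the physics says so (zero
  driving force → zero rate; infinite resistance → zero rate; `t_end = 0` →
  a single zero point) and errors where it does not (zero total resistance,
  zero content, loss ≥ 100%).
* The solver refuses `D1 = 0` (the capsule limit is an analytic statement,
  handled by the closed form) and explicit stepping beyond its stability
  limit, with guidance to the implicit scheme.

## Known limitations

* The steady-state ratio depends on the arbitrary interior radius `r1`;
  conclusions should be drawn from trends (size, thickness, permeability)
  rather than its absolute value.
* The perfect-sink boundary ignores finite-bath accumulation between
  sampling points; the bookkeeping module's uncorrected mode only brackets,
  not models, that effect.
* Fitting assumes the forward model that generated the data (no model
  error); real curves with matrix erosion or pH-dependent permeability are
  outside its scope.
* `D2` and `K` are only jointly identifiable as `K·D2` from release curves
  under sink conditions.
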