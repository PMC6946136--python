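# Methods

## Model

Two coupled fields on a 2-D lattice: per-lineage biomass `B_i` and a single
limiting resource `R`. Reaction terms are Monod growth with half-saturation
`k` and yield `λ` (resources consumed per unit biomass); transport is
Fickian diffusion with constants `D_B` for cells and `D_R` for the resource.
There is no death, maintenance or active motility; cells move only by
passive diffusion, and the lattice is either a torus (periodic) or a square
with reflecting (zero-gradient, hence mass-conserving) edges.

A "lineage" is whatever the experiment needs to track: a genotype (two
fields suffice for invasion assays) or an individual founder (needed for
territory and drift statistics). Growth depends only on genotype, so
per-founder tracking is pure bookkeeping; a test asserts that summing
founder fields by genotype reproduces the pooled run to 1e-10.

### Nondimensionalization

Characteristic quantities: `R_c = k`, `B_c = k/λ`, `t_c = 1/μ₁`,
`x_c = √(D_R/μ₁)`, with μ₁ the fastest maximum growth rate. In scaled form
the resource diffuses with constant 1, cells with `D_c = D_B/D_R`, and
genotypes grow at relative rates `μ_i,rel = μ_i/μ₁ ≤ 1`. The conversion is
exactly invertible (`to_scaled`/`from_scaled`, round-trip tested to 1e-12),
and a full-model run and the scaled run of its image agree field-by-field
to better than 1e-6 after unit conversion — this is the strongest
correctness check in the suite because it exercises reaction, diffusion,
seeding and the stop rule end to end.

The scaled mean intercolony distance `ζ = IC̄/x_c` summarizes a founder
map: `IC̄` is the mean over colonies of the minimum center-to-center
distance (minimum-image convention on tori). Sweeps that "vary growth rate"
in the scaled model do so by varying the scaled box width `ĥ = dx·√(μ₁/D_R)`
at fixed box count, which is the only way μ₁ enters the dimensionless
system.

## Numerics

- **Operator splitting**, growth then diffusion within each step.
- **Diffusion**: explicit 5-point forward-Euler stencil. The step is bounded
  by `dt ≤ 0.1·dx²/D_max` (`D_max` the largest diffusion constant in play,
  in practice the resource's). The default `StepControl` uses the bound as
  equality; a dt above the bound raises `StabilityError` rather than being
  silently sub-stepped. Under the bound the update is a convex combination
  of neighbor values, so nonnegativity is automatic, and mass conservation
  holds to rounding (≤1e-12 relative) on both boundary types.
- **Reaction**: classical RK4 per box, vectorized over the lattice, with
  substeps chosen so `max(μ)·dt_sub ≤ 0.05` (chemostat dilution counts
  toward the rate). The Monod factor is evaluated with `R` clamped at zero:
  at a depletion front an RK4 stage can overshoot `R` below 0, where the
  raw factor `R/(R+k)` has a pole at `R = −k`; clamping keeps stages
  physical. After integration the resource is *recomputed* from the
  realized biomass gain, `R' = R − λ·ΣΔB` (with the gain proportionally
  capped if it would overdraw the box), so closed-system conservation
  `λ·ΔB_total + ΔR_total = 0` holds to ~1e-14 regardless of integration
  error. An adaptive per-box ODE solver would be the other natural choice;
  fixed-step RK4 with the exact balance correction gives the same
  conservation guarantee at a fraction of the cost, and a grid-refinement
  test (halving dx and dt) shifts final genotype frequencies by <1%.
- **Batch stop rule**: run until >99% of the initial resource is consumed
  (`consumed_frac_stop = 0.99`), with a `max_steps` guard that raises on
  non-terminating configurations (e.g. zero biomass).
- **Well-mixed runs** integrate the mass-action ODE with
  `scipy.solve_ivp` (RK45, rtol 1e-10, terminal event at the consumption
  stop) in relative time τ = μ₁t, making the outcome exactly independent of
  the absolute rate at fixed rate ratios — the property the serial-transfer
  control experiment relies on. Because all genotypes share the Monod
  factor, `ln(B_i(T)/B_i(0))` ratios equal μ ratios; tests verify this to
  1e-6 and check the whole transfer series against an independent
  closed-form recursion.

## Protocols and statistics

- **Serial transfer**: founders carry one biomass unit each, at most one per
  box. The bottleneck is deterministic largest-remainder apportionment of
  49 founders to the final biomass fractions (ties toward the faster
  genotype); each count is within 1 of its quota and counts sum exactly.
  Fresh random positions and a fresh resource field every transfer. The
  transfer count is the number of growth–dilution cycles until the mutant
  fraction reaches the 0.9 threshold. If rounding drives the mutant to zero
  founders the run reports an explicit extinction outcome; at large ζ a
  mutant seeded into a vanishing territory can genuinely finish below half
  a founder quota, so extinction is a real (if rare) outcome of the model,
  not an error.
- **Chemostat**: adds `dR/dt += δ(R_res − R)` and `dB_i/dt −= δB_i` to the
  reaction in every box (dilution is part of the reaction substep, not a
  separate operator); no transfers. Stops on mutant fixation at 0.9,
  washout (total biomass below one founder unit — guaranteed when every
  μ < δ), or a time cap. With uniform biomass every box reduces to the
  textbook chemostat, and the steady state `R* = kδ/(μ−δ)` is reproduced
  to 0.1%.
- **Territories**: discrete Dirichlet tessellation — each lattice box is
  assigned to the nearest founder center, ties to the lowest founder index.
  This matches the lattice world the biomass actually grows on, guarantees
  areas tile the domain exactly, and avoids unbounded-polygon edge cases;
  it is only defined on square (no-flux) domains, which is also where the
  localization sweeps run. Tessellation on a torus is deliberately
  unsupported.
- **Competition localization**: OLS slope (scipy `linregress`) of relative
  biomass on relative territory area; invariant to rescaling either input.
- **Drift**: per map, the population SD across founders of the final
  biomass fraction; averaged over maps per ζ and normalized by the sweep
  maximum. Uses the same equal-growth-rate runs as the localization sweep.
- **Selection assay**: 49 founders (or 9 at desk scale) on an equally
  spaced, translation-symmetric grid on a torus; the center founder is the
  mutant, implemented as mutant relative rate 1 and ancestors 1/1.1 (ζ is
  always defined against the fastest rate). With benefit 1.0 the torus
  symmetry forces a frequency gain of exactly zero, which the suite asserts
  at 1e-9.

## Default conditions

Physical defaults mirror the standard experimental setup: 5 cm torus,
101×101 boxes, `D_R = 1.8e-2 cm²/h` (a small sugar in agar),
`D_B = D_R/1000`, `k = 1`, `λ = 1`, 100 resource units per box, 49 founders,
10% mutant benefit, growth rates 0.01–0.4/h, 20 replicates; config readers
accept cm²/s with explicit unit tags to prevent 3600× errors. The
localization design uses 15 or 49 founders × 10 random maps × 11 length
scales (geometric, ζ ≈ 0.2–20 at 49 founders — the 11 values are not
fixed by the design, only the span of the global-to-local transition).
These live under the `standard` preset.

Tests and the acceptance script run `desk`-scale reductions chosen as the
smallest designs in which every qualitative contrast is still unambiguous:
41×41 lattices with 3 growth rates × 5 replicates for invasion, 15 founders
× 3 maps × 3 length scales (ζ ≈ 0.5–13) for localization/drift, a 9-founder
grid on 45×45 for selection, and 21×21 for the chemostat and equivalence
checks. At the smallest desk-scale ζ (≈0.5) the localization slope is low
(~0.3) but not yet zero; pushing ζ below ~0.3 is where the slope flattens
toward 0, at rapidly growing cost (steps scale as 1/ĥ²).

## What the generator does and does not emulate

Founder maps are uniform random draws without replacement (or exact grids);
the resource starts homogeneous. Real plates have inoculation artifacts,
nutrient gradients, colony height, surfactant effects and multi-resource
co-limitation — none are modeled, and ζ as defined here assumes a single
limiting resource with one diffusion constant. Passing tests therefore
demonstrate the internal consistency of the reaction–diffusion/ζ picture,
not quantitative agreement with any particular wet experiment.

## Known limitations

- Explicit diffusion only; no implicit/ADI or spectral option, by design —
  the simple scheme is the reference behavior the statistics are built on.
- Cost grows as 1/ĥ² for small ζ (well-mixed limit), which bounds how far
  the desk presets push into the global-competition regime.
- The deterministic bottleneck excludes demographic sampling noise; only
  spatially caused drift is present.
- Chemostat runs are open systems: the exact biomass–resource balance
  correction does not apply there, and bookkeeping relies on the RK4
  substeps alone.
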