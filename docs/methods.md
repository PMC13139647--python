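# Methods

This note documents the models, conventions and numerical choices
behind `canopyfill`, and what the synthetic tests do and do not show
about real data.

## Spatial processing

**Geometry.** A plot is an axis-aligned square (default 45 × 45 m). A
2 m edge buffer is removed before any analysis to suppress edge
effects, leaving a 41 × 41 m interior that is divided into four equal
quadrant subplots (SW, SE, NW, NE). All spatial membership tests are
half-open, `[lo, hi)` on x and y: clipping and quadrant assignment are
exact partitions, a point on a midline belongs to the east/north side,
and translating cloud and geometry together never changes an
assignment. Heights are assumed ground-relative; an optional
normalisation subtracts per-cell minimum z on a square horizontal grid
(default 1 m cells) — a deliberately plain lowest-point terrain model
that is biased high wherever a cell lacks a ground return, so it is
off by default and real-data users opt in.

**Voxelisation.** Subplot clouds are counted onto a cubic grid with
edge `e` = 0.40 m, a resolution coarse enough to damp occlusion
speckle but fine enough to resolve crown-scale structure. A point maps
to `floor((p − origin)/e)` per axis; points outside the grid are
dropped and tallied, never fatal, since upstream clipping makes them
rare. Grid dimensions derive from the subplot footprint and the
cloud's maximum height as `n = ceil(extent/e)`, so edge voxels may
overhang the footprint but every horizontal layer contains exactly
`nx·ny` voxels — a constant denominator that makes per-layer occupancy
fractions comparable between layers. Occupancy is binary with a
threshold of one point per voxel (`min_points`, configurable): any
return fills a voxel.

## Canopy boundaries and CSFI

Three boundary heights are derived per subplot from the layer
occupancy profile:

* `H_max`: top face of the highest occupied layer;
* `h10`: scanning from the top layer downward, the top face of the
  first layer whose occupancy reaches the threshold τ = 0.10 (the
  comparison is non-strict, `≥ τ`, and τ is configurable). If no layer
  reaches τ, `h10` is undefined and the definitions that need it are
  flagged invalid rather than raising;
* `LGB`: the lowest green branch. Preferably supplied per subplot from
  field data; otherwise derived from the grid as the bottom face of
  the lowest occupied layer whose bottom face clears a ground-exclusion
  height (default 0.3 m, keeping ground returns and herb-layer hits
  out of the canopy), falling back to 0.

The four canopy-space slabs are total `[LGB, H_max]`, top
`[⅔H_max, H_max]`, mid `[⅓H_max, h10]` and main `[LGB, h10]`, with the
height fractions taken of the subplot's own `H_max`. A grid layer
belongs to a slab when its **centre** height lies in the closed slab
interval — a deterministic snap of fractional boundaries to the voxel
lattice. Degenerate cases (inverted slab, e.g. `h10 ≤ H_max/3` for
mid; undefined `h10`; empty canopy) produce flagged records with a
reason string so batch runs always complete.

CSFI satisfies, and the tests verify, an exact mixture identity: over
a union of disjoint layer ranges it equals the voxel-count-weighted
mean of per-range values. It is also invariant to a common rescaling
of all heights and the voxel edge.

## Productivity

Stem volume treats the stem as a cylinder corrected by a form factor
`f` = 0.4: `V = π(D/100)²/4 · H · f` m³, with D in cm and H in m
(standard forestry units; the conversion is internal). Subplot AWP
sums the annualised increments of trees alive at **both** censuses
(default years 2012 and 2017) and is reported in cm³ yr⁻¹. Trees that
died during the interval are excluded because their terminal volume is
unobserved; with the low mortality typical of the design this choice
barely moves the totals. Negative per-tree increments (measurement
noise) are kept; subplots whose summed AWP is non-positive are flagged
and excluded from the gamma models, whose support is (0, ∞), with the
count logged in the run manifest.

## The gamma mixed model

AWP on CSFI is modelled as gamma with a log link and a plot-level
random intercept:

    y_ij | b_i ~ Gamma(ν, μ_ij),  log μ_ij = x_ij'β + b_i,  b_i ~ N(0, σ²).

Estimation is maximum likelihood with a Laplace approximation to the
random-effect integral. The model has a convenient structure: given
`(β, ν, σ)`, the conditional mode of each `b_i` solves
`ν(A_i e^{-b} − n_i) = b/σ²` with `A_i = Σ_j y_ij e^{-x'β}`, a strictly
concave one-dimensional problem solved by vectorised damped Newton
iteration (tolerance 1e-11 on the scaled gradient). The outer
optimisation over `(β, log σ, log ν)` uses L-BFGS-B with bounds
`log σ ∈ [log 1e-8, log 100]`, `log ν ∈ [log 1e-4, log 1e6]`, and
starting values from a fixed-effects gamma GLM (statsmodels). Wald
standard errors come from the central-difference Hessian of the
marginal negative log-likelihood; p-values are two-sided normal tests
on the link scale, with no multiple-testing correction. Rank-deficient
designs (e.g. constant CSFI) and optimiser failures yield flagged
non-converged fits rather than exceptions.

Two estimation details deserve note. First, on data truly generated
with σ = 0, the free ML estimate of σ is positive for roughly half of
datasets (a boundary MLE); the exact reduction to the fixed-effects
GLM therefore holds at the boundary, and `fixed_sigma=0` pins the
variance component to verify it — the tests check agreement with the
statsmodels GLM to 1e-3 relative. Second, ML (not REML) variance
estimates are slightly downward-biased with 22 groups; the calibration
study below shows the practical effect on inference is small.

Marginal R² follows the Nakagawa decomposition on the link scale:
`R²m = var(Xβ̂) / (var(Xβ̂) + σ̂² + var_res)` with the gamma
observation-level variance `var_res = ψ₁(ν̂)` (trigamma). A lognormal
approximation `log(1 + 1/ν̂)` is available as a switch; the two agree
closely for the shapes seen here (ν ≈ 5).

The reported comparison fits, per canopy definition: an *across* model
(all subplots, CSFI only), mixtures-only and monocultures-only models
(the mixture factor is dropped within a stratum), and an across model
with the CSFI × mixture-type interaction whose interaction p-value is
reported separately. Strata with fewer than two plots are flagged
missing.

## Synthetic data

The generator emulates the study design: 22 plots (two monocultures
per species over six species minus the high-mortality pioneer's two
monocultures, six three-species mixtures each drawing one species per
growth guild, six six-species mixtures), 45 × 45 m plots, 3 m planting
grid (225 positions), four quadrant subplots, species assigned
round-robin within each plot.

Six synthetic species span three guilds (pioneer, intermediate,
shade-tolerant; two each) with heights, diameters and growth rates
plausible for a ~15-year-old tropical plantation (pioneer heights
~11–12 m and growth ~0.8 m yr⁻¹ down to ~6.5 m and ~0.4 m yr⁻¹ for
shade-tolerant species). Crowns are plain vertical ellipsoids set by a
crown-base fraction (0.30–0.48 of height) and a horizontal semi-axis
fraction (0.12–0.18); point clouds are sampled uniformly inside each
crown with Poisson counts at 35–50 points m⁻³, plus optional stem-line
and ground returns. Default between-census mortality is 3%.

AWP has two modes. *Generative* mode draws subplot AWP directly from
the gamma mixed model with chosen truth (defaults β₀ = 12 on the log
scale ≈ 1.6×10⁵ cm³ yr⁻¹ per subplot, β₁ = 3 — the order of magnitude
of the fitted CSFI effects — σ_plot = 0.3, ν = 5) so recovery tests
have known parameters. *Mechanistic* mode computes AWP from the
simulated growth through the productivity module, coupling CSFI and
AWP through stand structure with no scripted effect size. Per-subplot
CSFI drivers for generative studies are truncated-normal draws
(monoculture mean 0.30, mixture mean 0.33, SD 0.07 each by default;
studies of the variance contrast widen the mixture SD).

What the generator does **not** emulate: occlusion and beam geometry
(crown interiors are uniformly filled, so absolute CSFI levels are
optimistic relative to real TLS), branch architecture, allometry
fitted to real species, spatial autocorrelation beyond the plot
intercept, and competition between neighbours. Passing tests therefore
demonstrate correctness of the computational chain and calibration of
the inference under the stated model, not agreement with any field
measurement.

## Verified behaviour

The acceptance suite (also re-runnable via `scripts/acceptance.py`)
verifies, among others: exact agreement of the voxeliser with an
all-pairs brute-force oracle; the hand-built reference grid (bottom
five layers full, top five at 5% occupancy, e = 0.4 m) yielding
H_max = 4.0 m, h10 = 2.0 m and CSFI 0.525 / 0.05 / 1.0 / 1.0 for
total / top / mid / main with the ordering mid ≥ main ≥ total ≥ top;
the CSFI mixture identity to 1e-12; the volume and AWP worked
examples; the GLM reduction to 1e-3; and, at the 22-plot scale over
hundreds of replicates, 95% Wald interval coverage of the CSFI effect
≥ 0.90 and a null rejection rate within [0.03, 0.08]. Simulation sizes
(200 coverage replicates, 500 null replicates, 100 variance-contrast
replicates, five-plot mechanistic runs at reduced point density) were
chosen to bound Monte-Carlo error on those checks while keeping the
default suite quick to run on a laptop.

## Known limitations

* The `h10` boundary is evaluated per layer with a top-down scan;
  other conventions (cumulative profiles, strict inequality) exist in
  the literature and are exposed as configuration where reasonable,
  but the default is this package's declared choice.
* The grid-derived LGB depends on the ground-exclusion height and on
  sampling density near crown bases; field-measured LGB overrides are
  preferred when available.
* The mixed model supports a single random intercept (plot); nested or
  crossed structures and spatial correlation are out of scope.
* Laplace ML can be biased for variance components with few groups;
  no REML correction is implemented.
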