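# Methods

## Scope and intent

`mucofilm` is a conceptual individual-based model of bacterial biofilm
growth in a gut-mucosa-like niche.  It is built to expose how the
*metabolic interaction network* of a community — who eats what, and who
feeds whom — shapes the spatial architecture (intermixing vs.
segregation) and the population dynamics (composition memory,
convergence, invasibility) of the biofilm.  It is not a fitted model of
any particular organism; every species shares one generic parameter set
unless a study varies it deliberately.

## Model structure

A simulation couples four pieces, advanced in a fixed order each growth
timestep (default 0.25 h): pseudo-steady solute transport → Monod growth
→ division → mechanical relaxation.  Planktonic episodes (initial
attachment, scheduled invasions) run between growth steps at a 1 s
motility timestep.

### Agents and mechanics

Bacteria are circles in a 2D box, periodic in x, with continuous
positions, a mass in units of the mean initial cell mass, and radius
r = r₁√m with r₁ = 0.5 μm (constant areal density in the 2D plane; a
cube-root rule is available by configuration).  Agents never die,
detach, or leave; starved cells shrink under maintenance toward a small
floor.

Overlap from growth and division is relieved by a parallel (Jacobi)
shoving scheme: for every overlapping pair the two members each receive
a displacement of half the *overlap* (r_i + r_j − d)/2 along the
center-to-center line, summed over partners, all computed from the same
pre-update positions.  Reading "half" as half the center *distance*
instead makes dense clusters explode and fails to resolve the isolated
pair exactly; the overlap convention resolves an isolated pair in a
single iteration.  Displacements toward the substratum are truncated at
the first contact of the swept circle with the solid block boundary
(closed-form intersection with the radius-dilated rectangles).  The
substratum also acts as a shove partner: a cell whose surface has become
embedded (because it grew while resting on the wall) is pushed out along
the outward normal.  Relaxation alternates shoving and wall constraints
until the worst overlap falls below 10⁻² μm or 50 iterations, whichever
comes first; non-convergence is reported, not fatal.

### Geometry

The substratum is a boolean mask on a 10 μm block lattice: a solid base
one block thick carrying rectangular pillars 80 μm tall, 20 μm wide,
30 μm apart (crypt spacing).  Pillar cross-sections are rectangular
because the lattice cannot express curvature at 10 μm resolution.
Setting pillar height to zero yields the flat control surface.

### Motility and attachment

Planktonic cells run at 10 μm/s for 1 s steps, turning between steps by
a Normal(0, σ) angle with σ chosen so the mean absolute turn is 45°
(an exponential-magnitude variant is available).  A cell whose swept
path touches the substratum or an attached cell stops at first contact
and attaches permanently.  The initial cohort (200 cells by default) is
released uniformly in a band from 200 μm above the pillar tops to just
below the top boundary; on scaled-down domains too short for that band
the release floor is clamped to half the available fluid height.  Cells
still unattached when a 100 s episode ends are kept floating and frozen
— excluded from growth, mechanics, and analysis — rather than deleted;
their count is logged.

### Solute transport

Each solute obeys ∇·(D∇S) + R(S) = 0 per growth timestep
(diffusion is fast relative to biomass change).  Discretization is a
five-point finite-volume stencil on the same block lattice: harmonic
mean face diffusivities, Dirichlet top row (bulk value Sb for nutrients,
0 for by-products — the lumen washes metabolites away), zero-flux
closure at solid faces and the domain floor, periodic side walls.
Host-secretion solutes instead pin their concentration on every
fluid/biofilm block face-adjacent to solid (base and pillar flanks
alike).  D is 0.8·D_bulk in biofilm blocks (any non-solid block holding
at least one attached agent center).

R is assembled per block from resident agents: consumption of solute i
is Σ_k (1/Y)·μmax·S_i/(S_i+Ks)·X_k/V_block, and production adds f_p
times the consumption of the precursor substrate.  The Monod
nonlinearity is handled by Picard iteration with the denominator frozen
at the previous iterate, which keeps every linear system an M-matrix
(hence non-negative solutions) and converges monotonically for these
kinetics; tolerance 10⁻⁶ relative, at most 100 sweeps.  At convergence
the discrete top-boundary influx balances net consumption exactly, which
the test suite audits.

### Growth and division

Per agent, μ is the sum of Monod terms over the species' substrates at
the agent's block concentrations, and mass is updated by explicit Euler:
x ← x + (μ − m)·x·Δt.  Bookkeeping guarantees Σ Δmass = Y × substrate
consumed − maintenance losses at the same concentrations.  A cell
divides when its mass reaches its own threshold, drawn from
Normal(2, 0.2²) truncated to [1.6, 2.4]; the split is exactly 50/50
(an iDynoMiCS-style 50±5% split is available), the daughter is placed
in contact at a uniformly random angle (truncated at walls), and both
cells draw fresh thresholds.  Initial masses come from Normal(1, 0.1²)
truncated at ±2 SD.

### Interaction presets

With kinetic symmetry (same μmax, Ks for every substrate and species):

- **competition** — all species consume the single bulk nutrient A;
- **neutralism** — each species has its own bulk nutrient;
- **commensalism** — species 1 consumes A and excretes C; species 2
  consumes C *and its own bulk nutrient B* (the by-product-only
  recipient is a configuration flag);
- **mutualism** — each species consumes its own bulk nutrient plus the
  partner's by-product, in a ring for >2 species.

Newcomer-invasion presets grow a two-species resident community and
inject 100 competing cells at t = 25 h, released just above the biofilm
surface.  The invader enters a pairwise competitive relationship over a
bulk nutrient: it consumes solute A with baseline kinetics, sharing it
with the green resident (and with everyone in the competition
scenario).  Giving the invader all bulk nutrients instead would hand it
a multi-substrate advantage that reverses the colonization-resistance
contrast; the pairwise wiring matches the interaction definitions used
for the residents.  Five-species
presets assemble a strongly cross-feeding community, a mixed one, and a
purely competitive one.

### The well-mixed ODE twin

The comparison model collapses space to one biomass per species and one
concentration per solute in a fixed biofilm volume V = A·L′
(A = 500 × 1 μm², L′ = 200 μm), fed from the bulk through a
boundary-layer term K(S_b − S)/V with K = D·A/L, L = 400 μm.  Kinetics,
yields and production fractions are identical to the agent model;
biomass is carried as total mass and converted to concentration inside
the right-hand side, avoiding any unit ambiguity.  Integration uses
LSODA with event-style biomass injections between segments.  Initial
biomass equals the mass of the 200-cell inoculum.

## Units and the biomass-substrate conversion

All concentrations live in one arbitrary consistent family in which the
bulk nutrient boundary value is 4.0 and Ks is 0.2; mixing the two
printed unit systems (C-mmol/L and g/L) at face value is deliberate and
documented as unsupported physically.  One knob cannot be avoided: how
much substrate (in concentration × volume units) one unit of cell mass
represents.  Two constraints pin it to an order of magnitude: growth
must be strongly diffusion-limited (growth concentrated at the biofilm
front, little growth inside crypts), which requires per-cell consumption
comparable to the per-column diffusive supply, and mature biofilms must
reach the 50–200 μm thickness regime within 120 h on the full 500 μm
domain.  `biomass_to_substrate` = 3 × 10³ unit·μm³ per unit cell mass
satisfies both (full-size competition reaches ≈50 μm and the
faster-growing cross-feeding scenarios ≈150–200 μm by 120 h) and
corresponds to a cell dry mass of ≈0.1 pg under the glucose-equivalent
reading of the concentration family (4.0 units ≈ 0.12 g/L).  It is
exposed in configuration and is, together with the by-product
stoichiometry f_p = 1 − Y = 0.85, the most influential free parameter
of the model.

Diffusivities default to D = 2.1 × 10⁶ μm²/h (a small molecule in
water) for every solute; per-solute values are configurable.

## Problem sizes used for the quantitative readouts

Full-size runs (500 × 500 μm, 120 h) are expensive, so the shipped
studies use reduced conditions chosen once: the acceptance script runs
each interaction preset on a 250 × 250 μm crypt domain, 200 cells at
50/50, to 72 h or 3500 attached agents, three replicate seeds; the test
suite uses a further-reduced 150 × 250 μm domain with 120 cells and a
1200–1500 agent cutoff.  Scaling down weakens the structural contrast
between interaction types: the cooperative-vs-noncooperative segregation
gap grows with biofilm maturity (thin films are dominated by the founder
patches laid down at attachment), so reduced-scale indices for
commensalism and mutualism sit above the values a mature full-size
biofilm develops.  The studies module exposes the scale as a parameter
so users with more compute can run the full conditions.

## What the synthetic scenarios do and do not emulate

The generator reproduces the *conditions* of the conceptual studies —
symmetric kinetics, 50/50 or skewed inocula, growth-rate asymmetry,
timed invasions — not real gut communities.  Real mucosal biofilms
involve mucus secretion and barrier function, fluid shear and
detachment, cell death and lysis, chemotaxis, and curved crypt
geometry; none of these are modeled, so conclusions transfer only at
the level of mechanism (localized cross-feeding promotes intermixing;
shared-resource competition preserves founder structure), not of
quantitative prediction for any real community.

## Numerical choices and degenerate inputs

- Contact tolerance 10⁻⁶ μm; shoving tolerance 10⁻² μm residual overlap.
- Coincident agent centers are separated along a seeded random direction.
- Negative concentrations from the linear solve are clipped to zero and
  counted (with the M-matrix linearization they do not occur in
  practice).
- Ties at the k-th nearest neighbor are broken by agent id, making the
  segregation index deterministic; the index requires at least k + 1
  attached agents.
- The pillar-height-zero geometry, empty populations, zero-count
  seedings and zero end times are all legal degenerate inputs with
  defined behavior (flat surface, no-op, attachment phase only).
- A run is a pure function of (config, seed); the engine derives
  independent substreams (placement, motility, division, mechanics) from
  the seed so modules can be tested in isolation.

## Known limitations

- Explicit Euler growth at 0.25 h undershoots exponential growth by
  ~0.2% per step; studies comparing against closed forms use a 0.1 h
  step.
- The by-product pool is shared through a continuum field; at the
  default diffusivity its spatial localization around producers is a few
  cell diameters inside dense biofilm, which bounds how sharp the
  cross-feeding intermixing signal can become at reduced problem sizes.
- Blocks are classified biofilm/fluid by agent centers only; a block
  grazed by an agent's rim keeps bulk diffusivity.
- The 2D domain with 1 μm depth makes all densities effectively areal;
  three-dimensional effects (overhangs shading flow, lateral escape
  routes) are absent.
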