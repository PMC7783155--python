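# Methods

## Model

The simulator is a probabilistic cellular automaton for cells migrating
out of a spheroid on a 2-D substrate. State is a binary occupancy lattice
*N* (m × m, one site per 10 μm cell) plus a nonnegative chemoattractant
field *U* on the same lattice. All engine math is dimensionless: one
length unit is one site, one time unit is the assay duration of 24 h, so
the 7-minute step is dt = 7/1440 ≈ 0.004861. We keep the exact fraction
rather than a rounded 0.0048 so that 205 steps correspond exactly to
24 h. The physical step time itself (≈7 min, the time for a cell to move
about its own diameter) is taken as given; it is a calibration input, not
a derived quantity.

### Mechanisms

**Random movement.** A 3×3 Gaussian kernel G with σ = 2 sites,
center forced to zero (the cell is encouraged to leave), renormalized to
sum 1. The weight r ∈ [0, 1] multiplies G and acts as the probability of
attempting a random step.

**Chemotaxis.** The field evolves by
∂u/∂t = D∇²u + c₁n − c₂nu with D = D_chem/D_cell the chemical-to-cell
diffusivity ratio, production proportional to cell occupancy and
degradation to both occupancy and concentration. We discretize with the
explicit 5-point scheme

U′[i,j] = (1−4λ)U[i,j] + λ(U[i±1,j] + U[i,j±1]) + c₁·dt·N[i,j] − c₂·dt·U[i,j]·N[i,j],

λ = D·dt/h². Parameter validation enforces the von Neumann bound
dt ≤ h²/2D (λ ≤ 1/2). Positivity of U is additionally guaranteed when
4λ + c₂·dt ≤ 1, which holds with wide margin at the defaults
(λ ≈ 0.243, c₂·dt ≈ 8.5×10⁻⁵); the property test uses that sufficient
condition. Boundaries are zero-Dirichlet (concentration outside the
lattice is zero); at m = 200 the spheroid never feeds the boundary within
24 h, so the choice is immaterial at reference scale. A cell senses
μx = (U[i,j+1] − U[i,j−1])/(1+3u)² and the analogous μy, with u the
concentration at its *own* site — the saturation denominator models
receptor occupancy at high ambient concentration. The chemotaxis stencil
C is zero except for |μ| at the one cardinal move up the axis of larger
|μ| (exact ties broken uniformly at random); diagonal chemotactic moves
are never generated because gradients are only sampled along the axes.

**Mechanical interaction.** Occupancy is convolved with an all-ones
window of side 2·order+1 (order 1 by default; order 2 widens sensing but
movement is still to adjacent sites only). The 3×3 patch around a cell
counts, at each candidate position, the cells within range; every
candidate's window covers the focal cell, so subtracting 1 everywhere
removes self-interaction. The center is zeroed — the stencil is a pure
movement bias, mirroring G's zero center — and the result normalized to
sum 1 (all-zero for an isolated cell). This construction is attractive:
cells are pulled toward occupied neighborhoods, which reproduces the
pair-migration and pulling seen in spheroid rims.

**Proliferation.** With probability α per step a cell attempts division
instead of moving: the mother stays and a daughter takes a uniformly
chosen free 8-neighbor site (no free site, no division). The biologically
motivated range for α is 0.0007–0.001 per step (the joint probability of
a ~19–30 h cycle per 7-min step times a 15–20% proliferative fraction);
the default is α = 0 because divisions are rare within one 24-h assay.

### Composition and movement

P′ = r·G + c_f·C + q·I, entries clipped at zero (a repellent c_f < 0
suppresses the up-gradient move rather than reversing the stencil), then
normalized **only when the total exceeds 1**. A total below 1 is kept and
the deficit is the probability of staying put. This is the design choice
that makes r a genuine probability of moving: with only random movement
active, a cell moves with probability r, so the effective diffusivity of
the lattice walker is exactly linear in r — the property the drug
protocol relies on. Unconditional normalization would cancel r entirely.

Cells update sequentially in a freshly shuffled order each step. The C
and I kernels are computed from the frozen start-of-step fields for all
cells, but the occupancy check of the actual move sees the live lattice —
the one asymmetry sequential updating introduces. A `synchronous` flag
additionally freezes the occupancy used for *blocking* (conflicts then
resolved in the shuffled order), since the original update order is a
genuinely open choice; the default is sequential because it needs no
conflict-resolution rule beyond volume exclusion itself. The chemical
field updates once per step, after all cells have acted
(`chemo_update_order="before"` flips this; the two differ at O(dt)).

Initial condition: a filled d × d square of cells centered with its
corner at floor((m−d)/2) — the block is exactly centered only when m and
d share parity, a documented convention — and U = 0 everywhere. A disk
initializer is deliberately not provided. One seeded NumPy generator
drives an entire run; cohort replicates derive seeds as base + index, so
every result is bit-reproducible from (params, flags, seed).

## Analysis statistics

* **Mean RRM**: at each time point, the mean over the cells *present* of
  the radial distance from the fixed initial centroid, divided by the
  mean at t₀ (so the first value is exactly 1). The centroid is an input
  measured from the initial spheroid mask, never re-estimated per frame;
  cells lost by tracking simply drop out of later averages.
* **d_cell**: per track, (1/4T) Σ_j [(Δx_j)² + (Δy_j)²] with T the
  track's total duration — unbiased for 2-D Brownian motion with per-step
  displacement variance 4·D·dt. Population-level D_cell is the mean of
  per-track estimates with SEM = sd/√n.
* **Invasion velocity**: OLS slope (free intercept) of the RRM series
  over points with t ≤ 7.5 h, the empirically linear regime.
* **Size split**: small < 100 μm ≤ large (exactly 100 μm is "large").
* **Distribution comparison**: two-sample Kolmogorov–Smirnov with the
  asymptotic p-value (scipy); an exact small-sample computation would be
  the alternative for n ≲ 10.

Track I/O reads and writes TrackMate-spots-style CSV (TRACK_ID,
FRAME/POSITION_T, POSITION_X, POSITION_Y in μm/s), tolerating the
non-numeric label padding rows of newer TrackMate exports; FRAME indices
convert to seconds via the acquisition interval (default 600 s, the
assay's 10-min cadence).

## Synthetic data

`BrownianSpec`/`brownian_tracks` emulate the calibration condition:
isolated cells in a low-density monolayer performing pure 2-D Brownian
motion at D_cell = 0.21 μm²/s, sampled every 10 min for 24 h (144
steps). Each axis increment is N(0, 2·D·dt), i.e. total displacement
variance 4·D·dt per step, matching the 1/4T estimator's convention so
recovery is unbiased. The generator does not emulate microscope noise,
segmentation error, track fragmentation, or interactions — so passing
recovery tests shows estimator correctness, not robustness to real
tracking artifacts. `drug_r_interval` maps a measured diffusivity
fraction f ± s of control onto the r band (f−s, f+s), defaulting to the
migration-inhibitor condition 0.40 ± 0.15 → r ∈ (0.25, 0.55); drug
simulations draw r uniformly from the band per spheroid.

## Study sizes and numerical choices

The emergent-behavior checks run 20 seeds per condition at full reference
scale (m = 200, 205 steps) for spheroid sides d ∈ {5, 10, 16} sites
(50–160 μm): final RRM decreases with size; removing chemotaxis shifts
the final-RRM distribution significantly (KS, α = 0.05) for d = 16 but
not d = 5; and drug-band r lowers mean invasion velocity at every size.
Twenty seeds per arm is enough for the KS contrast while keeping the full
suite around two minutes. The walker-linearity check uses 200 replicates
per r ∈ {0.25, 0.5, 0.75, 1.0} on a 101-site lattice (large enough that
a 205-step walk essentially never reaches the edge).

Degenerate inputs are handled explicitly: an all-zero movement stencil
means "stay with probability 1"; moves off-lattice are cancelled; a track
table whose cells all sit at the centroid at t₀ makes the RRM undefined
and is rejected; gradient reads outside the lattice are zero, consistent
with the field boundary.

## Known limitations

Single chemical species with a fixed attractant sign; 2-D square lattice
only (no hexagonal neighborhoods, no 3-D); no cell death or
migratory/proliferative state switching; no substrate heterogeneity. The
analysis assumes tracking and segmentation were done upstream — the
package quantifies trajectories, it does not produce them from images.
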