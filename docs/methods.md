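# Methods

## Model

The simulator integrates a reaction–diffusion system for the polarity
machinery of a rod-shaped (fission-yeast-like) cell on the closed surface of
a spherocylinder: a cylinder of radius R = 2 μm capped by two hemispheres,
tip-to-tip length L (8 μm by default). Five membrane species are dynamic
fields (molecules/μm²):

* `CD`, `CT` — inactive (GDP-bound) and active (GTP-bound) Cdc42.
* `CGAPI` — a tip-localized GTPase-activating protein (GAP).
* `CGAPIIfast`, `CGAPIIslow` — the fast- and slow-diffusing states of a
  side-localized GAP.

Cdc42-GDP associates with the membrane at a constant flux `jDp` from an
unmodelled cytoplasmic pool, diffuses fast (`DD = 0.2 μm²/s`), and is
activated by membrane GEF at rate `k0p · exp(-s/λ) · CGEF · CD`, where `s`
is the meridian arc-length distance to the nearest tip pole and `λ` (2.5 μm)
restricts activation to the tip regions (`λ = inf` removes the bias).
Cdc42-GTP diffuses slowly (`DT = 0.02 μm²/s`) and is hydrolysed back at rate
`(k1n + k2n·CGAPI + k3n·CGAPIIfast + k8n·CGAPIIslow) · CT`. Both forms
dissociate from the membrane (`rD`, `rT`).

The GEF is a conserved pool of `Ectot` molecules in quasi-static equilibrium
between the cytoplasm (count `Ec`) and the membrane:

    CGEF = (k1p·CT + k2p·CT²) · Ec / V
    Ec   = Ectot / (1 + ∫ (k1p·CT + k2p·CT²)/V da)

The quadratic term is the autocatalytic positive feedback that breaks
symmetry; the shared finite pool is the global coupling through which the
two tips compete. `Ec + ∫ CGEF da = Ectot` holds as an algebraic identity of
the discretization (verified to 1e-12 relative at every step).

GAP_I is recruited by active Cdc42 with a saturating Hill law
`k4n · CT^h/(ksat^h + CT^h)` (h = 2), providing the delayed negative
feedback behind the oscillatory states. GAP_II is recruited at the tip in a
fast-diffusing state (`k5n·CT`), converts spontaneously to a slow state
(`k6n`), and is converted back by active Cdc42 (`k7n·CGAPIIslow·CT`); the
slow form therefore accumulates in a collar around, not on, the active zone.

All rate constants, diffusivities and the geometry default to the reference
parameter set (see `cdc42polar.params.ModelParams`); configs use the same
symbol names (`lambda` for the bias scale).

## Geometry and discretization

Surface points are laid out in rings with equal meridian spacing and ring
populations proportional to the local circumference, giving near-equal-area
cells; the bands between adjacent rings are stitched into triangles and the
triangulation is cleaned by Delaunay edge flips. Node "Voronoi" areas are
barycentric thirds of incident-triangle areas; the Laplace–Beltrami operator
uses half-cotangent edge weights. Consequences, all tested:

* total mesh area matches 2πR(L−2R) + 4πR² within 0.5 % for L up to 35 μm;
* every cell area lies in the reference band 0.017–0.046 μm² at the default
  resolution (`target_cell_area = 0.03 μm²`, the midpoint of that band);
* the weight matrix is symmetric with non-negative off-diagonals, so pure
  diffusion conserves area-weighted mass to machine precision and satisfies
  a discrete maximum principle;
* the explicit-Euler diffusion bound `min_i A_i/(D·Σ_j w_ij)` ≈ 0.024 s is
  more than twice the reference step (0.01 s).

A relaxation stage was considered and rejected: both uniform-Laplacian
smoothing and centroidal (Lloyd) iterations traded area uniformity away for
shape regularity and pushed cells outside the reference area band, while
edge flips fix triangle quality without moving nodes. Arc length `s` is
computed analytically from the axial coordinate (cap: R × polar angle from
the pole; cylinder: πR/2 plus axial distance to the nearer junction), so the
`exp(-s/λ)` bias carries no mesh-resolution bias.

## Time stepping

Forward Euler with dt = 0.01 s. One step adds the diffusive flux and the
reaction terms for all five fields, applies activation noise, then
re-equilibrates the GEF pool to the new Cdc42-GTP field (the quasi-static
assumption; one refresh per step). The hot loop is a fused numba kernel; its
equality with the plain-numpy reaction evaluation (to ~1e-14) is a test.
Concentrations in (−1e−9, 0) are clamped to zero as roundoff; anything lower
aborts with the offending field named. Runs are reproducible: (parameters,
seed) determine the mesh jitter, initial state, noise stream, and therefore
the full trajectory bit-for-bit.

The initial condition is the unpolarized state: `CD = jDp/rD` (80/μm²) with
±1 % uniform relative fluctuations, a random Cdc42-GTP seed uniform in
[0, 0.8]/μm², GAPs at zero. The 1 % amplitude is a package choice (the
reference description says only "small").

## Random activation (`rnoise`)

The equations contain a conversion of Cdc42-GDP to Cdc42-GTP at rate
`rnoise·CD`, described as random activation. How that randomness is realised
is not fully specified, and the choice turns out to matter: it moves the
boundaries between the dynamical states. Four realizations are implemented
(`noise_mode`):

* `langevin` (default) — the deterministic mean conversion `rnoise·CD·dt`
  plus a zero-mean Gaussian exchange with the Poisson-matched standard
  deviation `sqrt(rnoise·CD·dt/a_i)` per node, clipped to the physically
  available molecules (chemical-Langevin treatment). Total Cdc42 is
  conserved exactly by the exchange.
* `stochastic` — whole-molecule Poisson conversion events (per-node Poisson
  thinning realised as one cell-wide event count placed proportionally to
  the per-node rates).
* `deterministic` — the mean term only.
* `off` — no random activation.

The default was selected by a systematic comparison (four published
parameter points × three seeds × all modes): whole-molecule events are
strong enough local kicks (one molecule in a ~0.03 μm² cell is ~33/μm²,
amplified by the quadratic GEF feedback) to destabilize the bipolar
stationary state at large GEF pools and to flip the monopolar state every
few hundred seconds, while the mean term alone locks small-pool cells into
a weakly active symmetric state and no noise at all loses the oscillatory
states entirely. The chemical-Langevin realization is the only one that
reproduces all four canonical states at their reference parameter points;
it is also the most literal reading of equations that print deterministic
±`rnoise·CD` terms.

A side effect of the mean conversion term is a uniform background of active
Cdc42 (~5–15/μm² depending on local hydrolysis) over the whole surface.
This background participates in GEF recruitment and therefore dilutes the
pool available to the tips; see Limitations.

## Observables and classification

Tip traces are area-weighted means of Cdc42-GTP over the two polar caps
within 0.5 μm arc length, sampled every second. Arc-length profiles are
area-weighted bin means (0.25 μm bins) of each species versus distance from
the dominant tip, with the side GAP reported as fast + slow. Decay lengths
come from a nonlinear least-squares fit of `c0·exp(-s/ℓ)` over 0–2 μm from
the dominant tip, on a snapshot taken 20 s after a dominant-tip maximum
occurring after 1000 s of simulation (maxima detected online on the 1-s
trace with a 31-s window and 5 % prominence). Tip-to-side enrichment is the
ratio of mean total Cdc42 (CD+CT) in the dominant tip region to the mean in
a mid-cell band (±1 μm around the meridian midpoint).

States are classified from the paired tip traces. The reference study states
no numeric criteria, so the decision tree is defined operationally; all
thresholds live in `ClassifierConfig`:

* Oscillatory: ≥3 prominent maxima (10 % of the trace mean) on each trace
  with negative zero-lag correlation, or — for relaxation oscillations too
  slow to fit three peaks into the record — ≥3 deep exchanges of tip
  dominance. Oscillatory runs are `BPO` when modulation is deep
  ((max−min)/(max+min) ≥ 0.7) and the cycle-averaged tips are symmetric
  (ratio < 1.5); shallower or asymmetric oscillations are `MPDO` (under
  sustained activation noise a damped oscillatory state appears as small
  persistent anticorrelated fluctuations, which is how `MPDO` manifests at
  the reference point Ectot = 210).
* Stationary: block-mean drift < 2 % over the final 400 s; `MPS` when the
  tip ratio exceeds 1.5 (a rare complete dominance swap still counts as
  monopolar — the two tips are equivalent), `BPS` otherwise, `UNPOLARIZED`
  when the tips are within 1.5× of the surface-mean concentration.
* Oscillation periods are mean inter-peak intervals at 30 % prominence (the
  stricter prominence avoids double-counting ripples on relaxation
  plateaus); the bipolar oscillatory state at the reference point
  (k5n = 0.01/s, Ectot = 500) has a period of ~6 min.

In the unbiased-activation regime (λ = ∞) tip traces are uninformative and
runs are labelled by patch tracking: the area-weighted centroid of the
top-decile active nodes across snapshots. Directed net motion beyond the
patch diameter is a `WAVE`; repeated appearance at distant locations without
directed motion is `PATCH_DYNAMIC`. These thresholds are defined heuristics;
the reference study distinguishes the two regimes only descriptively.

## Experiment drivers and problem sizes

`run_scan` classifies every point of a two-axis parameter grid (default
1200 s per run; optional replicates with a majority label and a coexistence
flag, since near region boundaries different seeds can settle into different
states). `neto_series` models growth across the monopolar-to-bipolar (NETO)
transition: cells of increasing fixed length L with the GEF pool scaled in
proportion to cell volume, anchored at 300 molecules for L = 7 μm and
ksat = 650/μm². `mutant_run` bundles the named perturbations (halved or
absent side-GAP recruitment; unbiased activation with k0p = 0.01 μm²/s).
Default run lengths (800–2000 s) and the default mesh (~3400 nodes at
L = 8 μm) were chosen so that single runs complete in tens of seconds and
the full acceptance suite in minutes on one core; longer runs sharpen the
classification of the slowest oscillations but do not change the reported
quantities materially.

## Limitations

* The realization of random activation is under-determined by the source
  description; state-region boundaries in parameter space shift with the
  choice (documented above). The published phase-diagram structure is
  reproduced topologically, but individual grid cells near boundaries can
  differ, and the oscillation period of the mid-range bipolar states is
  longer here (~10 min) than the 4–6 min of the reference examples.
* The activation background generated by the mean conversion term weakens
  tip zones at low `ksat` (strong tip-GAP feedback): at ksat = 450/μm² the
  oscillatory state has tip amplitudes several-fold lower than the
  monopolar reference state, and the fitted Cdc42-GTP decay lengths sit
  above the published 0.64/0.72 μm values while preserving their ordering
  (halving `k5n` widens the gradient).
* No Cdc42 whole-cell mass conservation (constant cytoplasmic pool), no
  explicit GEF transport, no growth, no cytoskeletal delivery — all by
  design of the source model.
* The synthetic "unpolarized + fluctuations" initial state is the only
  studied initial condition; hysteresis between coexisting states is not
  explored beyond the replicate machinery.
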