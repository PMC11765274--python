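# Methods

`intertrack` simulates the heterogeneous chemical stage of water
radiolysis for *pairs* of ion tracks separated in space by Δx and in
time by Δt, and quantifies how much intertrack reactions change the
radiolytic yields relative to independently evolving tracks.  This note
records the model, the surrogate assumptions, the numerical choices and
their known limitations.

## The three-stage model

Track evolution follows the standard paradigm of radiation damage:

1. **Physical stage** (≲1 fs): the ion and its secondary electrons
   ionise and excite water molecules along the path.
2. **Prechemical stage** (1 fs–1 ps): ionised/excited water dissociates
   into the radiolytic species; sub-excitation electrons thermalise and
   hydrate.
3. **Heterogeneous chemical stage** (1 ps–1 μs): the species diffuse
   and react until the distribution approaches homogeneity.

Stages 1–2 are not transported interaction-by-interaction here.  They
are replaced by a **parametric track surrogate** (`intertrack.track`)
that reproduces their output statistics — the 1-ps species inventory —
because (a) both stages are over before two tracks separated by any
realistic Δt can influence each other, and (b) the intertrack physics
of interest lives entirely in stage 3.

### Track surrogate

* Energy is deposited in **spurs** — localised clusters of primary
  events, the defining structural motif of radiation chemistry.  Spur
  centres follow a Poisson process along the beam axis (+z) over the
  scoring depth with mean count LET·depth / `spur_energy`
  (default 62.5 eV per spur); each spur contains a Poisson number of
  ionisation/excitation events (mean `spur_energy`/`mean_event_energy`
  ≈ 3.7) spread around the centre with a `spur_sigma` = 1 nm Gaussian.
  Each event deposits exactly `mean_event_energy` = 16.7 eV, so the
  event-count mean is LET·depth/16.7 (overdispersed relative to plain
  Poisson by the clustering) and the expected deposited energy is
  exactly LET·depth, with exact per-run energy bookkeeping.
* Transverse spur-centre structure is a two-component radial profile:
  a Gaussian core (`core_sigma`, default 3 nm — the dense ionisation
  column) plus an exponential tail (`tail_fraction` 3%, `tail_scale`
  300 nm) standing in for energetic δ-electrons.  The tail controls
  how much of the track reaches beyond 500 nm (~0.6% with the
  defaults), which in turn controls how far intertrack effects persist
  in Δx.
* Each event is classed ionisation (75%) or excitation (25%) and
  dissociates through configurable branching channels: ionisation →
  OH· + H3O⁺ + e⁻aq; excitation → OH· + H· (50%), H2 + 2 OH· (15%), or
  radiative relaxation with no products (35%).  Products are displaced
  isotropically with per-product Gaussian scales (5 nm for the
  hydrating electron, 0.8 nm otherwise).  These are literature-style
  placeholder ratios, exposed in the config.
* The per-event energy (16.7 eV, i.e. 6 events per 100 eV) is
  calibrated so the 1-ps yields match the standard literature values
  for liquid water (G ≈ 4.5 for e⁻aq and H3O⁺, ≈ 5.7 for OH·, ≈ 0.75
  for H·, per 100 eV).  Both the density calibration and the spur
  clustering matter: the defining intertrack phenomena — in particular
  the delay-dependent sign change of H2O2 — are driven by radical
  densities and by how fast the first track's radical population ages,
  and a sparse or unclustered surrogate visibly suppresses them.

What the surrogate does **not** emulate: electron transport physics
(elastic scattering, cross-section energy dependence), radial dose
profiles beyond the two-component shape, secondary-particle
build-up/back-scatter, multiple ionisation, and LET variation with
depth (the track-segment condition is assumed).  Consequently the
absolute G-value curves are not expected to reproduce any specific
track-structure code; the package's claims are about *relative*
intertrack effects, which are controlled by densities and rate
constants.

## Chemical stage

Seven species are tracked (OH·, e⁻aq, H3O⁺, H·, H2, H2O2, OH⁻) with
literature diffusion coefficients (config units nm²/ps).  The default
reaction set is the closed nine-channel system over these species:
the hydronium–electron recombination H3O⁺ + e⁻aq → H·, the three
H·-consuming channels (e⁻aq + H·, OH· + H·, H· + H·), the
peroxide–electron channel H2O2 + e⁻aq → OH⁻ + OH·, plus OH· + OH· →
H2O2, e⁻aq + OH· → OH⁻, e⁻aq + e⁻aq → H2 + 2 OH⁻ and the
neutralisation H3O⁺ + OH⁻.  The OH· + H2O2 channel is omitted so that
no HO2· needs tracking.  Water is implicit: each channel's solvent
emission count (possibly negative — e.g. e⁻aq + H· consumes a water)
is derived from the oxygen balance and validated against hydrogen and
charge, and logged per reaction so elemental conservation can be
checked exactly on any run.

Every channel is treated as fully diffusion-controlled with the
encounter radius R = k/(4π(D_a + D_b)) (after unit conversion), i.e.
partially diffusion-controlled kinetics are folded into an effective
radius rather than an acceptance probability.  This is the simplest
closure that reproduces the bulk rate constant in the dilute limit.
A convention note: the same closure is applied to identical-reactant
channels; the factor-of-two ambiguity in defining k for A + A
reactions is absorbed into the configured rate constants.

### Propagation

Per step each *active* molecule takes an isotropic Gaussian step of
per-axis standard deviation √(2 D dt), then reacting pairs are
detected and consumed:

* a pair reacts if its end-of-step separation is below the channel
  radius R, or, failing that, with the Brownian-bridge crossing
  probability exp(−(d0−R)(d1−R)/(D_rel dt)) — the chance that the
  inter-particle distance crossed R at some instant during the step.
  The bridge term keeps the capture rate essentially independent of
  the timestep once dt has grown; without it the scheme loses ~7% of
  captures at dt = 10 ps for R ≈ 0.5 nm.
* candidate pairs come from a cKD-tree with a Verlet skin (default
  12 nm): the tree is rebuilt only when twice the largest accumulated
  single-molecule displacement since the last build exceeds the skin,
  which rigorously guarantees no pair can reach contact undetected.
* hits are processed in increasing-distance order and each molecule
  reacts at most once per step (deterministic given positions and the
  random stream); products appear at the pair midpoint (an optional
  Gaussian jitter is configurable, default 0).

The timestep grows from 0.1 ps to 10 ps — 0.1 ps for the first ns of
elapsed time, then one decade of dt per decade of time, capped at
10 ps.  When a delayed track activates, the schedule resets to 0.1 ps
to resolve the fresh track's fast kinetics.

Boundaries are open: by 1 μs the diffusion length (≈0.2 μm for the
fastest species) is small against the 5 μm transverse scale of the
nominal scoring volume, and every molecule continues to count toward
N(t) wherever it drifts.  A cubic periodic box is available
(`box=L`), used by the dilute well-mixed kinetics checks.

## Two-track scheduling

Track 1 starts at (+Δx/2, 0, 0), track 2 at (−Δx/2, 0, 0), both along
+z.  Track 2's inventory is sampled at scheduling time from its own
seed stream (its physical/prechemical stages are independent of track
1) but held *frozen* — excluded from diffusion, reactions and N(t) —
until the global clock reaches Δt (clamped to ≥ 1 ps, the chemical
stage start; Δt ≤ 1 ps means both tracks begin active).  At activation
the deposited energy steps from E1 to E1 + E2, making E(t) a two-step
function, and the yield G(t) = N(t)/E(t) × 100 shows the
characteristic peak (primary species) or drop (secondary species).
The value at the activation instant is a counting identity,

    G(Δt) = (N1(Δt) + N2(1 ps)) / (E1 + E2) × 100,

which the engine satisfies exactly and the test suite asserts to
machine precision.

The **non-interacting (NI) reference** runs the same machinery with
cross-track reactions suppressed, to 1 μs + Δt; the scalar reference
yield averages the two track ages, G_NI = (G_NI(1 μs + Δt) +
G_NI(1 μs))/2.  The intertrack effect of a configuration is

    ΔG_μs = (G_pair(1 μs + Δt) − G_NI) / G_NI,

evaluated per species, with the pair yield read at the nearest logged
time ≤ the target (no interpolation; the logging grid forces exact
points at 1 ps, Δt, 1 μs and Δt + 1 μs).

Replicates use independent child streams spawned from the master seed.
The physical normalisation chooses the replicate count so the total
deposited energy reaches a target (default 2 MeV):
n = ⌈E_target/(LET·depth)⌉.

## Statistics

Per (Δx, Δt) cell, ΔG is the ratio of replicate-mean yields with a
delta-method standard error, and a two-sample Student t-test compares
pair vs NI per-replicate yields at 1 μs + Δt.  Raw per-species
p-values are reported in the grid without multiplicity correction.
When a *family* of species tests must answer one question — "does any
species still differ from NI at this separation?" (the no-effect
boundary in Δx) — the per-Δx family is Holm-corrected at FWER
α = 0.05; with seven species per cell, uncorrected testing would flag
a false boundary in roughly one scan in three.

## Problem sizes and numerical checks

The shipped evaluation protocols use desk-scale track segments:
depth 0.05 μm at LET 30 keV/μm with 30 replicates per cell (the full-
scale setup of 2 μm segments with 2 MeV normalisation is a config change, not
a code change).  Segment length affects replicate statistics and the
absolute yields' late-time dilution, but the per-length track physics
(local densities, hence relative intertrack effects) is unchanged.

The engine's diffusion–reaction coupling is validated against two
closed forms: the ultimate reaction probability R/r0 of an isolated
pair (10⁴ pairs, R = 0.5 nm, r0 = 1 nm), and second-order decay at
rate k[A][B] for a dilute well-mixed system in a periodic box
(k = 10¹⁰ M⁻¹s⁻¹, fitted through the 1/[A] transform, with the first
500 ps discarded to skip the Smoluchowski transient, which is genuine
physics rather than numerical error).  The well-mixed check runs at
constant dt = 0.1 ps; at the operating point chosen the fitted rate
agrees with the configured k to ~1%.

A paired-seed protocol (`protocols.paired_delta_g`) can evaluate ΔG
with the pair and NI arms sharing 1-ps inventories; at desk-scale
molecule counts the gain is modest (reaction-realization noise
dominates over inventory noise), so the shipped evaluations use the
unpaired design.

Known limitations:

* The delay-dependent sign change of the H2O2 intertrack effect (from
  enhancement at short Δt toward depletion at long Δt, driven by the
  second track's solvated electrons consuming the first track's
  peroxide) is reproduced only marginally: at the desk-scale segment
  lengths used here the enhancement decays toward zero by a few
  hundred ns and the long-delay ΔG(H2O2) hovers at zero to slightly
  negative, with the destruction and cross-production terms nearly
  cancelling.  A decisive negative balance at 1 μs-scale delays
  appears to require full-scale segments (μm depths, MeV-scale total
  energy statistics) and the detailed δ-ray radial structure that the
  parametric surrogate replaces.

* With the per-step capture scheme, sub-step structure finer than the
  bridge approximation (multiple crossings, curved-boundary effects)
  is not resolved; residual rate bias at dt = 10 ps is at the few
  percent level for the default radii.
* Species with no channels (H2 by default) still diffuse even though
  their positions only matter for radial statistics.
* No unimolecular decays, no electric-field (Onsager) effects, no
  temperature dependence, and no oxygen or scavenger chemistry; those
  are outside the tracked species set.
* The t-test treats replicates as unpaired (pair and NI samples use
  independent seed streams).
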