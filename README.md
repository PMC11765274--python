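# intertrack

Monte Carlo simulation of **intertrack recombination chemistry** in
water radiolysis: what happens when two ion tracks arrive so close in
space (Δx) and time (Δt) that their radical populations react with each
other before either track has relaxed?

This question sits at the core of the radiation-chemical hypotheses for
the FLASH effect in ultra-high dose-rate radiotherapy (and of
laser-driven, ultra-bunched irradiation in general): at conventional
dose rates tracks are far apart in space-time and evolve independently,
while at ≳40 Gy/s the mean inter-track distances shrink until
cross-track radical-radical reactions can modify the yields of damaging
species.  `intertrack` lets you quantify where in the (Δx, Δt) plane
that happens, for track segments of configurable LET.

## Model in brief

A parametric track surrogate emulates the physical + prechemical stages
and produces the 1-ps inventory of the seven radiolytic species
(OH·, e⁻aq, H3O⁺, H·, H2, H2O2, OH⁻) around a straight ion path, with a
Poisson event count matching LET·depth and a core-plus-tail transverse
profile.  The heterogeneous chemical stage (1 ps – 1 μs) is then
simulated step-by-step: Brownian displacements with per-axis std
√(2 D dt), and bimolecular reactions with Smoluchowski encounter radii

    R = k / (4π (D_a + D_b)),

augmented by a Brownian-bridge crossing test so the capture rate stays
timestep-independent as dt grows from 0.1 ps to 10 ps.  A delayed
second track is sampled immediately but kept frozen until the clock
reaches Δt, at which point the timestep schedule resets and deposited
energy steps up — yields are

    G(t) = N(t) / E(t) × 100   [molecules per 100 eV],

and the intertrack effect at a configuration is the normalised yield
difference one microsecond after the second track,

    ΔG_μs = (G_pair(1 μs + Δt) − G_NI) / G_NI,

against the non-interacting (NI) reference
G_NI = (G_NI(1 μs + Δt) + G_NI(1 μs))/2.  Negative ΔG means depletion
(typical for the primary radicals), positive means enhancement (typical
for the molecular products H2 and H2O2 — though H2O2 famously flips
sign at long delays, when the second track's solvated electrons consume
the peroxide the first track has already built).

See `docs/methods.md` for the full model description, parameter tables
and numerical choices.

## Worked example

Simulate four interacting pairs of LET 30 keV/μm track segments at
Δx = 1 nm, Δt = 1 ps, plus the matching non-interacting references, and
compare the 1-μs yields:

```python
import numpy as np
from intertrack import default_config
from intertrack.track import ParticleSpec
from intertrack.protocols import evaluate_cells

cfg = default_config(particle=ParticleSpec("carbon", 240.0, 30.0, 0.05))
grid, _ = evaluate_cells(cfg, [1.0], dt_ps=1.0, n=8,
                         seed=np.random.SeedSequence(7))
print(grid.table[["species", "delta_g", "se", "p"]].round(3).to_string(index=False))
```

prints (seed 7, eight replicates per arm):

```
species  delta_g    se     p
     OH   -0.241 0.064 0.005
   e_aq   -0.400 0.116 0.007
   H3O+   -0.349 0.090 0.004
      H   -0.301 0.082 0.016
     H2    0.215 0.083 0.019
   H2O2    0.063 0.082 0.447
    OH-   -0.297 0.090 0.011
```

Reading: at essentially zero separation the primary radicals OH·, e⁻aq
and H3O⁺ are depleted by 24–40% relative to independent tracks — the
doubled local density drives extra radical–radical recombination —
while molecular hydrogen is enhanced by ~20% (cross-track e⁻aq and H·
encounters).  The H2O2 enhancement is smaller and, at eight
replicates, not yet significant.  The `p` column is the per-species
Student t-test of pair vs NI replicate yields.

The same sweep is available from the shell:

```bash
intertrack grid --let 30 --depth 0.05 --dx-grid 1,1000 --dt-grid 1 \
    --replicates 8 --seed 7 --out results/
```

which writes `delta_g_grid.csv`, a JSON summary and a reproducibility
manifest (config hash + seed).

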