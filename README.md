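# g4kit

Quantitative analysis of protein–RNA G-quadruplex (rG4) binding and the
liquid-like condensates these interactions drive.

Small, highly charged disordered proteins can bind the stacked G-quartet
face of rG4 structures and, under molecular crowding, co-condense with them
into dynamic droplets.  Characterizing that process quantitatively takes a
chain of unglamorous but exacting computations: counting Hoogsteen hydrogen
bonds to monitor quadruplex integrity in simulation trajectories, mapping
multivalent protein↔RNA contact networks and crowder partitioning,
estimating diffusion constants from mean squared displacements, scoring
sequence preference from bind-n-seq read pools, and extracting dissociation
constants and FRAP recovery halftimes from nonlinear fits.  `g4kit`
packages these stages as a tested Python library for structural biologists
and biophysicists working on ribonucleoprotein condensates.

## The core quantities

- **Hoogsteen bonds / tetrads** — a G-quartet is a cycle of four guanines,
  each donating N1–H···O6 and N2–H···N7 to its neighbor; detection uses a
  3.5 Å donor–acceptor distance and a 30° deviation-from-linearity cutoff.
  An intact n-tetrad core carries exactly 8n bonds.
- **Contacts / multivalency** — molecules are in contact when their
  minimum heavy-atom distance is ≤ 8 Å; crowder proximity uses 6 Å.
  Degree statistics of the bipartite contact graph quantify multivalency.
- **Diffusion** — MSD(t) = 2·dim·D·t for free diffusion, so
  D = MSD(t)/(6t) in 3-D (4t in 2-D); slope fits through the origin and
  per-track estimates mirror single-particle-tracking practice.
- **Enrichment** — the bind-n-seq R statistic is the bound-pool frequency
  of a k-mer over its input-pool frequency; strong G4-forming sequences
  match (G₃₋₆N₀₋₇)₄ under any-decomposition semantics.
- **Fits** — one-site specific binding Y = baseline + Bmax·X/(K_D + X)
  and one-phase association Y = Y0 + (Plateau−Y0)(1 − e^(−Kt)) with
  t½ = ln 2/K, both by Levenberg–Marquardt least squares.

A synthetic-data module generates every input class with known ground
truth — ideal stacked quartets, bead-chain condensate frames with exact
contact counts, Brownian tracks, randomized read pools with controlled
enrichment, noisy model curves — so the whole pipeline runs and is tested
without downloading anything.

## Worked example

```sh
python examples/hoogsteen_and_tetrads.py
```

```
fixture: 280 atoms, 20 guanines on 4 strands
Hoogsteen bonds: 40  (8 per quartet x 5 quartets)
detected tetrads: 5 at stack levels [0, 1, 2, 3, 4]
within-strand stacking register: i -> i+6 (telomeric-repeat-like fold)
```

The fixture is an idealized tetrameric quadruplex of five stacked quartets.
Forty bonds is the intact-core reference: in a trajectory of a
protein-bound quadruplex, counts below 8 per quartet flag tetrad
disruption, and the i → i+6 register identifies the stacking topology of a
telomeric-repeat fold.

```sh
python examples/binding_and_frap_fits.py
```

```
one-site fit: K_D = 0.307 µM (truth 0.300), Bmax = 1.001, baseline = 0.057
  -> half the sites are occupied at X = K_D
one-phase association fit: t_half = 13.02 s (truth 13.00), mobile fraction = 1.01
  -> seconds-scale recovery marks a liquid-like, dynamic droplet
normalized raw trace refit: t_half = 8.00 s (truth 8.00)
```

A sub-micromolar K_D is the regime of specific rG4 binders, and a FRAP
halftime in the tens of seconds distinguishes a reversible liquid droplet
from a gel or aggregate.

The other examples cover condensate contact networks, crowder partitioning
and hollow-core architecture (`condensate_network.py`), diffusion and FRET
distances (`diffusion_and_distances.py`), and bind-n-seq enrichment
(`bind_n_seq.py`).  Each builds its own input, runs one analysis family and
prints what the numbers mean.  The scientific background, parameter
defaults and numerical conventions are documented in `docs/methods.md`.

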