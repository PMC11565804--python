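# Methods

`g4kit` quantifies protein–RNA G-quadruplex (rG4) interactions and the
structure and dynamics of the liquid-like condensates they form.  It covers
five analysis families — quadruplex geometry, condensate interaction
networks, diffusion/distance dynamics, bind-n-seq sequence enrichment, and
binding/FRAP curve fits — plus synthetic-data generators that produce every
input class with known ground truth, so the full pipeline is testable
without any external dataset.

## Coordinate model and units

Coordinates are stored in Å (the native PDB unit) throughout the geometric
modules; the diffusion module converts to µm at its boundary (1 Å = 10⁻⁴
µm) and tracks carry times in seconds.  Trajectories declare a time unit
(`ps` default, matching typical MD snapshot intervals of 100 ps); frames
must share atom count and ordering, and every operation preserves that
ordering.  Molecule identity (`protein`, `rna`, `crowder`, `ion`,
`solvent`) is inferred from residue names through a configurable mapping
whose defaults cover standard amino acids, A/U/G/C ribonucleotides, PEG,
K⁺/Cl⁻ and water — the species of a protein/rG4/PEG/KCl system.  Unknown
residues are an error naming the residue rather than a silent guess.

Two on-disk dialects are supported: multi-model PDB (3-decimal fixed
columns, so a round trip preserves coordinates to 10⁻³ Å) and a CSV
trajectory table (bit-exact round trip, used for diffable fixtures).
Binary MD formats are out of scope; exporting to multi-model PDB from any
MD package is lossless at the precision the analyses need.

## Hoogsteen hydrogen bonds and tetrad detection

A G-quartet is a planar cycle of four guanines, each donating two Hoogsteen
hydrogen bonds to its clockwise neighbor: N1–H···O6 and N2–H···N7.  An
intact quartet therefore carries exactly 8 bonds and an n-tetrad core 8n;
deviations below 8n report quartet disruption (for example by a bound
protein).

Detection follows the convention of the common MD hydrogen-bond tools: a
donor–acceptor pair is a bond when the heavy-atom distance is ≤ `d_max`
(default 3.5 Å, inclusive, no epsilon) and the donor–hydrogen–acceptor
angle deviates from linearity by ≤ `angle_dev_max` (default 30°, i.e.
D–H–A ≥ 150°).  Hydrogens are associated to donors by same-residue
proximity (≤ 1.25 Å); a donor lacking a hydrogen is skipped with a logged
warning when hydrogens are required, and a distance-only mode exists for
hydrogen-free coarse models.  Default donors are guanine N1 and N2 and
default acceptors N7 and O6.  Guanine has no O2 atom; the ribose
2′-hydroxyl can be added through a criteria override but is not part of
the default donor set, which is the set that yields the canonical
8-bonds-per-quartet count.  Neighbor search uses a k-d tree; equivalence
with an all-pairs reference (including ties exactly at the cutoff) is part
of the test contract.  Periodic systems can opt into orthorhombic
minimum-image distances; fixtures are non-periodic.

Tetrads are length-4 directed cycles in the guanine→guanine Hoogsteen
donation graph.  Candidate cycles are canonicalized (rotated to start at
the smallest residue key), sorted, and accepted greedily so each guanine
joins at most one tetrad — a deterministic rule that is invariant under
atom reordering and rigid-body motion.  Stack levels come from projecting
tetrad centroids onto their principal axis; the axis sign (arbitrary from
SVD) is oriented so levels increase with residue numbering.  The stack
report pairs each guanine with the spatially nearest same-strand guanine of
the adjacent quartet and reports the residue-index offset; the telomeric
i → i+6 register appears as a constant offset of 6.

## Ideal quadruplex generator

The fixture replicates a planar guanine template (standard base-frame
coordinates) by 4-fold rotation about the stacking axis.  The template's
rigid in-plane placement (x, y, rotation) is solved numerically: the two
Hoogsteen distances N1···O6′ and N2···N7′ are hard constraints at 2.9 Å
(polished to < 10⁻⁸ Å), and the O6-to-axis radius is a soft target at 2.4 Å
(the K⁺ coordination geometry) that resolves the leftover degree of
freedom.  Amino/imino hydrogens are placed 1.01 Å from their donor along
the donor→acceptor direction, so the angle criterion is met by
construction; the second amino hydrogen takes the other in-plane sp²
direction.  Quartets stack with a rise of 3.4 Å and a twist of 30° per
level (both configurable).  Tetrameric topology assigns one guanine column
per strand; dimeric topology gives each of two strands two opposite
columns, emulating a dimeric fold's strand economy without modeling loops.
The fixture is geometric, not physical: no backbone, no torsional
preferences, no ions.  What it guarantees — and what the tests exploit —
is an exactly known bond and tetrad count.

## Condensate fixtures and interaction networks

The condensate generator places coarse bead-chain molecules (3-bead
protein, 5-bead RNA, 4-bead PEG crowder) so that contact statistics are
exact by construction: every RNA has exactly `contacts_per_rna` proteins at
7 Å minimum atom distance (inside the 8 Å contact cutoff) while all other
protein–RNA pairs exceed 10 Å; a set fraction of crowders sits at 5 Å
(inside the 6 Å proximity cutoff) and the rest far away.  With
`core_inner_radius` set, RNA anchors occupy a spherical shell and one
contact protein per RNA points inward, touching the core surface — a
hollow-core architecture whose core radius equals the parameter exactly.
Optional rigid per-molecule Brownian steps (per-axis variance 2·D·dt) add
frame-to-frame motion.

Analyses on real or synthetic trajectories:

- **Contacts** — molecules are "in contact" when their minimum heavy-atom
  distance is ≤ 8 Å (the atom scope is configurable; heavy-atom minimum
  distance is the prevailing convention).  Degrees of the bipartite
  protein↔RNA graph give per-frame multivalency (mean, max, histogram per
  side).
- **Hydrogen-bond occupancy** — fraction of frames in which a
  (protein-residue, RNA-residue) pair shares ≥ 1 bond under the same
  geometric criteria; sorted descending, equal by contract to a per-frame
  recount.
- **Crowder partitioning** — count of crowder molecules with any atom
  within 6 Å of any protein/RNA atom, one count per molecule per frame.
- **Radial density** — spherical-shell counts and densities about the
  assembly centroid or a given point.  The hollow-core diameter estimator
  (twice the outermost radius, scanning outward, at which shell density is
  still below 10% of the profile peak) is a stated convention, not a
  reconstruction of any particular imaging measure; it is reported
  alongside the raw profile.
- **Conformational clustering** — the Daura/GROMOS procedure with a 0.2 nm
  RMSD cutoff: pairwise RMSD after optimal (Kabsch) superposition on a
  backbone-heavy-atom selection of one molecule (configurable), iterative
  extraction of the frame with the most neighbors as a cluster center, ties
  broken toward the lowest frame index for determinism.  The first center
  is the maximum-population representative conformation.  The O(F²) RMSD
  matrix limits this to the few-thousand-frame trajectories it is meant
  for.

## Diffusion and distances

MSD uses overlapping time windows (time average) pooled over molecules or
tracks (ensemble average); the statistical dependence between lags that
overlapping windows introduce is accepted and the pair counts are reported
per lag.  For free diffusion MSD(t) = 2·dim·D·t, so the point estimate is
D = MSD(t)/(2·dim·t) — the familiar 6t denominator in 3-D, 4t in 2-D —
and the slope estimate is a least-squares line through the origin over a
chosen lag range (an intercept variant absorbs static localization offsets
behind a flag).  Dimensionality is always an explicit argument, never
inferred.  Per-track estimates fit each track's time-averaged MSD over the
first 25% of its lags (≥ 2), the usual single-particle-tracking practice
that avoids the noisy long-lag tail; tracks shorter than 4 points are
skipped with a warning.

End-to-end distances are plain per-frame Euclidean distances between two
(residue, atom) selectors with population mean ± sd.  FRET conversion uses
the Förster forms E = 1/(1 + (r/R0)⁶) and r = R0·(1/E − 1)^(1/6); the
default R0 of 5.4 nm is a typical cyanine donor/acceptor value and is
configurable.  The conversions are exact inverses over the measurable
range; within a condensate the distance reading additionally assumes
orientational averaging, which the package does not model.

## Bind-n-seq enrichment and pattern matching

The R statistic for a k-mer is its frequency among all k-mer instances of
the protein-bound pool divided by its frequency in the input pool (k = 6
by convention; R = 1 means no preference).  k-mers absent from the input
are excluded by default (no smoothing rule is assumed); a ±1 pseudocount is
available behind a flag.  Adapters can be included in the k-mer window and
are included by default in pattern search — they are part of the RNA
presented to the protein — but never in the guanine count of the control
rule, which is defined on the randomized region.

The strong-G4 pattern (G₃₋₆N₀₋₇)₄ is a family of run/loop decompositions,
not a single regex: a greedy scan that commits to maximal G-runs misses
valid splits (e.g. seven consecutive Gs followed by three short runs).
Matching is therefore by existence of any decomposition into `n_runs`
G-runs of `g_run_min..g_run_max` separated by loops of `0..loop_max`
arbitrary nucleotides, implemented as a memoized backtracking scan and
tested against an exhaustive recursive enumerator.  Classification labels
each read `strong_g4` (pattern match), `non_g4_control` (no match, ≥ 8
guanines in the randomized region — the stated threshold appears both as
"> 8" and "≥ 8" in common usage; the ≥ 8 reading is the default and the
threshold is configurable), or `other`.  Pattern enrichment is read-level
(class fraction ratio) while k-mer R is instance-level, matching how the
two statistics are defined.  DNA-letter input is mapped T→U and uppercased.

The pool generator draws a uniform input pool of randomized 40-mers
(n = 10⁵ by default — a desk-scale stand-in for the millions of reads of a
sequencing run) and resamples it with replacement into a bound pool with
per-read weights: the product of enrichment factors of literal motifs
present, optionally times a factor for reads matching the strong-G4
pattern.  The pattern weight emulates a structure-selective binder, which a
fixed substring cannot (a specific 15-mer essentially never occurs in a
uniform random pool).  Factor 1 everywhere reduces the bound pool to a
plain bootstrap of the input.

FOREST normalization subtracts the no-protein control intensity per probe
(negative nets retained — they are informative) and averages probes sharing
a structure across barcodes.

## Curve fits

Two models, fit by Levenberg–Marquardt least squares (lmfit), unweighted by
default (1/Y² weighting behind a flag):

- one-site specific binding Y = baseline + Bmax·X/(K_D + X), reporting K_D
  (µM), Bmax and baseline, with an optional linear nonspecific term behind
  a flag (off by default);
- one-phase association Y = Y0 + (Plateau − Y0)·(1 − e^(−K·t)), reporting
  K, Y0, Plateau, the mobile fraction Plateau − Y0 (meaningful for
  full-scale-normalized input), and the derived halftime t½ = ln 2/K —
  an exact identity in every fit result, never a separately fitted number.

Positivity of K_D and K is enforced by log-parameterization, which also
makes their standard errors approximately log-normal (reported on the
linear scale via the delta method).  Initialization is derivative-free:
K_D starts at the concentration whose signal is nearest half the span, K at
ln 2 over the time nearest half recovery.  Non-convergence is reported
through a flag, not an exception.  FRAP traces are normalized full-scale,
(I(t) − I_bleach)/(I_pre − I_bleach), with the clock re-zeroed at the
first post-bleach point; an unbleached trace is a degenerate input and an
error.

The curve generator evaluates the noiseless model and adds Gaussian noise
with sd equal to `noise_sd` × the noiseless dynamic range (2% is the
default study condition); replicates differ only in noise.  Parameter
recovery contracts — mean fitted K_D within 10% of 0.30 µM and mean t½
within 10% of 13 s over 200 replicates — are part of the test suite, and
`scripts/acceptance.py` recomputes them from scratch.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
hundreds of Brownian tracks of ≤ 100 steps, pools of 10⁴–10⁵ reads,
trajectories of ≤ 12 frames for clustering oracles, 200 fit replicates.
These sizes put every stochastic check 3–4 standard errors away from its
expected value while keeping a full run in tens of seconds.

## Known limitations

- Fixtures are geometric; passing tests demonstrate correctness of the
  detectors and estimators, not force-field realism.  Real trajectories
  add thermal jitter, partial occupancy and topological diversity that the
  generators do not emulate.
- Tetrad detection assumes Hoogsteen donation cycles; mixed or bulged
  quartets that bond through other edges are not classified.
- The hollow-core estimator and the stack-offset report are conventions
  chosen for testability; alternative definitions will differ by up to a
  bin width or a register.
- No spot detection or track linking: the dynamics module consumes
  pre-linked tracks.  No anomalous-diffusion models.
- The clustering implementation materializes the full pairwise RMSD
  matrix; very long trajectories should be strided first (`read_frames`
  preserves file order, so striding is a caller-side slice).
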