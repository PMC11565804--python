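"""Synthetic inputs with known ground truth for every pipeline stage.

Five generator families:

* :func:`build_ideal_g4` — an idealized stacked G-quartet core.  A planar
  guanine template (standard base-frame coordinates) is replicated by 4-fold
  rotation about the stacking axis; the rigid in-plane placement of the
  template is solved numerically so that each guanine's Hoogsteen pair
  distances to its neighbor (N1···O6 and N2···N7) are 2.9 Å with the O6
  carbonyls ringing the axis at the K+-coordination radius.  Amino/imino
  hydrogens are placed along the donor->acceptor vectors, so the default
  hydrogen-bond criteria are satisfied by construction: 8 bonds per tetrad.
* :func:`generate_condensate_frames` — coarse bead-chain protein/RNA/crowder
  mixtures with an exact, constructed contact count per RNA and crowders at
  controlled distances; optional rigid Brownian motion per molecule.
* :func:`simulate_brownian_tracks` — free diffusion with i.i.d. Gaussian
  steps of per-axis variance 2*D*dt.
* :func:`generate_read_pools` — a uniform random 40-mer input pool and a
  bound pool resampled with multiplicative per-motif enrichment weights.
* :func:`generate_curves` — noiseless one-site binding or one-phase
  association values plus Gaussian noise scaled to the dynamic range.

All generators are bit-reproducible given a seed.  Fixtures are geometric,
not physical: no force field, no excluded volume, no RNA backbone torsions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .dynamics import Track
from .enrichment import PatternSpec, ReadPool, normalize_rna
from .fitting import (RecoveryCurve, TitrationCurve, one_phase_association_model,
                      one_site_model)
from .trajectory import AtomRecord, Frame, Trajectory

__all__ = [
    "G4FixtureSpec",
    "PoolSpec",
    "CurveSpec",
    "build_ideal_g4",
    "generate_condensate_frames",
    "simulate_brownian_tracks",
    "generate_read_pools",
    "generate_curves",
]

_LN2 = float(np.log(2.0))

# planar guanine base atoms, standard reference-frame coordinates (Å, z = 0)
_GUANINE_TEMPLATE: dict[str, tuple[float, float]] = {
    "N9": (-1.289, 4.551),
    "C8": (0.023, 4.962),
    "N7": (0.870, 3.969),
    "C5": (0.071, 2.833),
    "C6": (0.424, 1.460),
    "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641),
    "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364),
    "C4": (-1.265, 3.177),
}

_NH_BOND = 1.01          # amino/imino N-H bond length, Å
_HOOGSTEEN_DIST = 2.9    # target N1···O6 / N2···N7 heavy-atom distance, Å
_O6_AXIS_DIST = 2.4      # O6 distance from the stacking axis (K+ site), Å


@dataclass(frozen=True)
class G4FixtureSpec:
    """Parameters of the ideal stacked-quartet fixture.

    ``rise`` is the inter-quartet stacking distance and ``twist`` the helical
    rotation per quartet; ``stack_offset`` is the within-strand residue-index
    step between stacked guanines (6 reproduces the i -> i+6 register of a
    two-quartet-per-repeat telomeric fold).
    """

    n_tetrads: int = 5
    topology: str = "tetrameric"
    rise: float = 3.4
    twist: float = 30.0
    include_hydrogens: bool = True
    include_ribose: bool = False
    stack_offset: int = 6

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.topology not in ("tetrameric", "dimeric"):
            raise ValueError("topology must be 'tetrameric' or 'dimeric'")


@dataclass(frozen=True)
class PoolSpec:
    """Randomized read-pool parameters for bind-n-seq emulation.

    ``enriched_motifs`` weights reads containing a literal subsequence;
    ``pattern_enrichment`` additionally weights reads matching the strong-G4
    run/loop pattern (``pattern_spec``, default (G3-6 N0-7)4), emulating a
    structure-selective binder rather than a sequence-selective one.
    """

    n_reads: int = 100_000
    read_length: int = 40
    enriched_motifs: Mapping[str, float] = field(default_factory=dict)
    pattern_enrichment: float = 1.0
    pattern_spec: "PatternSpec | None" = None
    adapter_5p: str = ""
    adapter_3p: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for motif, factor in self.enriched_motifs.items():
            if factor < 0:
                raise ValueError(f"enrichment factor for {motif!r} must be >= 0")
            if len(motif) > self.read_length:
                raise ValueError(f"motif {motif!r} longer than read_length")
        if self.pattern_enrichment < 0:
            raise ValueError("pattern_enrichment must be >= 0")


@dataclass(frozen=True)
class CurveSpec:
    """Noisy model-curve parameters.

    ``model`` is ``one_site`` (parameters ``K_D``, ``B_max``, ``baseline``)
    or ``one_phase_assoc`` (``t_half``, ``plateau``, ``Y0``).  ``noise_sd``
    is the Gaussian noise standard deviation as a fraction of the noiseless
    dynamic range; replicates differ only by noise.
    """

    model: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    x_values: Sequence[float] | None = None
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("one_site", "one_phase_assoc"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Ideal G-quartet geometry
# ---------------------------------------------------------------------------

def _rot_z(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@lru_cache(maxsize=2)
def _solve_quartet_placement(direction: int = 1) -> tuple[np.ndarray, float]:
    """In-plane placement (tx, ty, theta) of the guanine template so each
    copy under 4-fold rotation donates N1->O6 and N2->N7 to its neighbor."""
    template = np.array([[x, y, 0.0] for x, y in _GUANINE_TEMPLATE.values()])
    names = list(_GUANINE_TEMPLATE)
    i_n1, i_n2, i_n7, i_o6 = (names.index(n) for n in ("N1", "N2", "N7", "O6"))
    rot90 = _rot_z(90.0 * direction)

    def place(params: np.ndarray) -> np.ndarray:
        tx, ty, theta = params
        return template @ _rot_z(np.degrees(theta)).T + np.array([tx, ty, 0.0])

    def residuals(params: np.ndarray) -> np.ndarray:
        g0 = place(params)
        g1 = g0 @ rot90.T
        # the two Hoogsteen distances are hard constraints; the O6-to-axis
        # (K+ coordination) radius is a soft target resolving the leftover
        # degree of freedom
        return np.array([
            np.linalg.norm(g0[i_n1] - g1[i_o6]) - _HOOGSTEEN_DIST,
            np.linalg.norm(g0[i_n2] - g1[i_n7]) - _HOOGSTEEN_DIST,
            0.02 * (np.linalg.norm(g0[i_o6][:2]) - _O6_AXIS_DIST),
        ])

    best = None
    for theta0 in np.linspace(0, 2 * np.pi, 12, endpoint=False):
        sol = least_squares(residuals, x0=[4.0, 0.0, theta0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    # polish the two hard constraints to machine precision from the soft start
    refined = least_squares(lambda p: residuals(p)[:2], x0=best.x,
                            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.abs(refined.fun).max() > 1e-8:
        raise RuntimeError("quartet placement did not converge")
    return place(refined.x), float(refined.cost)


def _quartet_atoms(include_hydrogens: bool) -> list[dict[str, np.ndarray]]:
    """Four placed guanine copies (atom name -> xyz), neighbor of copy i is
    copy (i+1) % 4; hydrogens point at the neighbor's acceptors."""
    for direction in (1, -1):
        try:
            g0, _ = _solve_quartet_placement(direction)
            break
        except RuntimeError:  # pragma: no cover - other chirality
            continue
    names = list(_GUANINE_TEMPLATE)
    copies = [g0 @ _rot_z(90.0 * direction * j).T for j in range(4)]
    quartet = []
    for j in range(4):
        atoms = dict(zip(names, copies[j]))
        if include_hydrogens:
            nb = dict(zip(names, copies[(j + 1) % 4]))
            n1, n2, c2 = atoms["N1"], atoms["N2"], atoms["C2"]
            h1_dir = nb["O6"] - n1
            h21_dir = nb["N7"] - n2
            atoms["H1"] = n1 + _NH_BOND * h1_dir / np.linalg.norm(h1_dir)
            atoms["H21"] = n2 + _NH_BOND * h21_dir / np.linalg.norm(h21_dir)
            # second amino hydrogen: the sp2 direction pointing away from the
            # acceptor (in-plane, ~120° from the C2-N2 bond)
            u = (n2 - c2) / np.linalg.norm(n2 - c2)
            cands = [_rot_z(60.0)[:2, :2] @ u[:2], _rot_z(-60.0)[:2, :2] @ u[:2]]
            h21_u = (h21_dir / np.linalg.norm(h21_dir))[:2]
            pick = cands[int(np.argmin([np.dot(c, h21_u) for c in cands]))]
            atoms["H22"] = n2 + _NH_BOND * np.array([pick[0], pick[1], 0.0])
        quartet.append(atoms)
    return quartet


def build_ideal_g4(spec: G4FixtureSpec | None = None) -> Frame:
    """A single :class:`Frame` holding an ideal stacked G-quartet core.

    Tetrameric topology: four strands, one guanine column each.  Dimeric:
    two strands, each contributing two columns (loop atoms are not modeled).
    Under default criteria each quartet carries exactly 8 Hoogsteen bonds.
    """
    spec = spec or G4FixtureSpec()
    quartet = _quartet_atoms(spec.include_hydrogens)

    if spec.topology == "tetrameric":
        # strand for column j is molecule j+1; one residue per stack level
        column_mol = {j: j + 1 for j in range(4)}
        column_base = {j: 1 for j in range(4)}
    else:
        # two strands, each contributing two opposite columns
        column_mol = {0: 1, 2: 1, 1: 2, 3: 2}
        column_base = {0: 1, 2: 51, 1: 1, 3: 51}

    records: list[tuple[int, int, str, np.ndarray]] = []  # (mol, resid, name, xyz)
    for level in range(spec.n_tetrads):
        rot = _rot_z(spec.twist * level)
        shift = np.array([0.0, 0.0, spec.rise * level])
        for j, atoms in enumerate(quartet):
            resid = column_base[j] + spec.stack_offset * level
            for name, xyz in atoms.items():
                records.append((column_mol[j], resid, name, rot @ xyz + shift))
            if spec.include_ribose:
                n9, c4 = atoms["N9"], atoms["C4"]
                out_dir = (n9 - c4) / np.linalg.norm(n9 - c4)
                records.append((column_mol[j], resid, "C1'",
                                rot @ (n9 + 1.47 * out_dir) + shift))

    records.sort(key=lambda r: (r[0], r[1]))
    atoms = [
        AtomRecord(i + 1, name, name[0], "G", resid, mol, "rna", xyz)
        for i, (mol, resid, name, xyz) in enumerate(records)
    ]
    return Frame(atoms)


# ---------------------------------------------------------------------------
# Condensate fixture
# ---------------------------------------------------------------------------

def _chain(template_z: Sequence[float], center: np.ndarray,
           axis: np.ndarray) -> list[np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    return [center + z * axis for z in template_z]


def _lattice_sites(n: int, spacing: float, origin: np.ndarray) -> list[np.ndarray]:
    if n <= 0:
        return []
    sites = []
    k = 0
    side = max(1, int(np.ceil(n ** (1 / 3))))
    for ix in range(side + 1):
        for iy in range(side + 1):
            for iz in range(side + 1):
                sites.append(origin + spacing * np.array([ix, iy, iz], dtype=float))
                k += 1
                if k >= n:
                    return sites
    return sites


def generate_condensate_frames(
    n_protein: int,
    n_rna: int,
    n_crowder: int = 0,
    contacts_per_rna: int = 3,
    core_inner_radius: float | None = None,
    n_frames: int = 1,
    displacement_D: float = 0.0,
    dt: float = 0.01,
    seed: int = 0,
    crowder_contact_fraction: float = 0.5,
) -> Trajectory:
    """Coarse bead-chain condensate frames with constructed contact counts.

    In frame 0 every RNA has exactly ``contacts_per_rna`` protein molecules
    at minimum inter-atom distance 7 Å (<= the 8 Å contact cutoff) while all
    other protein-RNA pairs are > 10 Å apart; a ``crowder_contact_fraction``
    of the crowders sits 5 Å (< 6 Å) from an RNA, the rest far away.  With
    ``core_inner_radius`` the RNA anchors occupy a spherical shell about the
    origin (a hollow-core architecture); otherwise a sparse lattice.  Each
    subsequent frame displaces every molecule rigidly by Gaussian steps of
    per-axis variance ``2 * displacement_D * dt`` (µm²; coordinates in Å).
    """
    if min(n_protein, n_rna, n_crowder) < 0:
        raise ValueError("molecule counts must be >= 0")
    if contacts_per_rna > 8:
        raise ValueError("placement infeasible: at most 8 contacts per RNA")
    if n_rna and n_protein < n_rna * contacts_per_rna:
        raise ValueError(
            f"need >= {n_rna * contacts_per_rna} proteins for "
            f"{contacts_per_rna} contacts on {n_rna} RNAs"
        )
    rng = np.random.default_rng(seed)

    z_axis = np.array([0.0, 0.0, 1.0])

    # Per-RNA local frames: (site, chain axis, contact-direction basis u1/u2).
    # Sites are kept >= 36 Å apart so that contact proteins of one RNA stay
    # > 10 Å from every other RNA.  In shell mode the chain runs tangentially
    # and the anchor radius carries a margin covering molecule extents, so no
    # atom enters the core.
    frames_of_rna: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    if core_inner_radius is not None:
        # margin equals the protein contact offset: the innermost possible
        # bead (a contact protein pointing at the center) sits exactly at
        # core_inner_radius, so the hollow core has precisely that radius
        margin = 7.0
        for i_rna in range(n_rna):
            for _attempt in range(1000):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                # first anchor sits exactly at R + margin so the innermost
                # contact protein touches the core surface
                r = core_inner_radius + margin + (
                    0.0 if i_rna == 0 else rng.uniform(0.0, 20.0))
                site = r * u
                if all(np.linalg.norm(site - f[0]) >= 36.0 for f in frames_of_rna):
                    t1 = np.cross(u, z_axis if abs(u[2]) < 0.9 else [1.0, 0.0, 0.0])
                    t1 /= np.linalg.norm(t1)
                    t2 = np.cross(u, t1)
                    frames_of_rna.append((site, t1, u, t2))
                    break
            else:
                raise RuntimeError(
                    "placement infeasible: shell too dense for requested RNA count"
                )
    else:
        for site in _lattice_sites(n_rna, 60.0, np.zeros(3)):
            frames_of_rna.append((site, z_axis,
                                  np.array([1.0, 0.0, 0.0]),
                                  np.array([0.0, 1.0, 0.0])))

    all_sites = [f[0] for f in frames_of_rna]
    far_origin = (np.max(np.abs(all_sites), initial=0.0) + 150.0) * np.ones(3)

    protein_z = [-3.8, 0.0, 3.8]
    rna_z = [-10.0, -5.0, 0.0, 5.0, 10.0]
    crowder_z = [-4.5, -1.5, 1.5, 4.5]

    molecules: list[tuple[str, list[np.ndarray]]] = []  # (kind tag, bead coords)

    n_contact_proteins = n_rna * contacts_per_rna
    shell_mode = core_inner_radius is not None
    for site, axis, u1, u2 in frames_of_rna:
        molecules.append(("rna", _chain(rna_z, site, axis)))
        # in shell mode u1 is the outward radial direction; anchor the first
        # contact protein pointing inward so the core surface is populated
        phase = np.pi if shell_mode else rng.uniform(0, 2 * np.pi)
        for c in range(contacts_per_rna):
            a = phase + 2 * np.pi * c / 8.0
            v = np.cos(a) * u1 + np.sin(a) * u2
            molecules.append(("protein", _chain(protein_z, site + 7.0 * v, axis)))

    for p in _lattice_sites(n_protein - n_contact_proteins, 40.0, far_origin):
        molecules.append(("protein", _chain(protein_z, p, z_axis)))

    n_near = int(round(crowder_contact_fraction * n_crowder)) if n_rna else 0
    for c in range(n_near):
        site, axis, u1, u2 = frames_of_rna[c % len(frames_of_rna)]
        a = 2 * np.pi * (c + 0.5) / 8.0
        v = np.cos(a) * u1 + np.sin(a) * u2
        molecules.append(("crowder", _chain(crowder_z, site + 5.0 * v, axis)))
    far_crowder_origin = far_origin + np.array([0.0, 0.0, 500.0])
    for p in _lattice_sites(n_crowder - n_near, 30.0, far_crowder_origin):
        molecules.append(("crowder", _chain(crowder_z, p, z_axis)))

    residue_for = {"protein": "GLY", "rna": "A", "crowder": "PEG"}
    atom_for = {"protein": "CA", "rna": "P", "crowder": "C1"}
    element_for = {"protein": "C", "rna": "P", "crowder": "C"}

    base_atoms: list[AtomRecord] = []
    aid = 0
    for mol_id, (tag, beads) in enumerate(molecules, start=1):
        for bi, xyz in enumerate(beads, start=1):
            aid += 1
            base_atoms.append(AtomRecord(
                aid, atom_for[tag], element_for[tag], residue_for[tag],
                bi, mol_id, tag if tag != "protein" else "protein", xyz,
            ))
    base = Frame(base_atoms)

    sigma = np.sqrt(2.0 * displacement_D * dt) * 1e4  # µm -> Å
    frames = [base]
    offsets = np.zeros((len(molecules), 3))
    for k in range(1, n_frames):
        offsets = offsets + rng.normal(0.0, sigma, size=offsets.shape) if sigma else offsets
        coords = base.coords.copy()
        for mi in range(len(molecules)):
            idx = [i for i, a in enumerate(base.atoms) if a.molecule_id == mi + 1]
            coords[idx] += offsets[mi]
        frames.append(base.with_coords(coords, time=k * dt))
    return Trajectory(frames, dt=dt, time_unit="s")


# ---------------------------------------------------------------------------
# Brownian tracks
# ---------------------------------------------------------------------------

def simulate_brownian_tracks(
    n_tracks: int,
    D: float,
    dim: int = 3,
    dt: float = 0.01,
    n_steps: int = 100,
    seed: int = 0,
) -> list[Track]:
    """Free-diffusion tracks: i.i.d. Gaussian steps, per-axis variance 2*D*dt.

    Positions are in µm and times in seconds; every track starts at the
    origin.  The ensemble MSD at lag ``l*dt`` is ``2*dim*D*l*dt``.
    """
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if D < 0:
        raise ValueError("D must be >= 0")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * D * dt)
    times = np.arange(n_steps) * dt
    tracks = []
    for tid in range(n_tracks):
        steps = rng.normal(0.0, sigma, size=(n_steps - 1, dim)) if sigma else \
            np.zeros((n_steps - 1, dim))
        pos = np.vstack([np.zeros(dim), np.cumsum(steps, axis=0)])
        tracks.append(Track(tid, times, pos))
    return tracks


# ---------------------------------------------------------------------------
# Read pools
# ---------------------------------------------------------------------------

def generate_read_pools(spec: PoolSpec) -> tuple[ReadPool, ReadPool]:
    """(input, bound) pools; bound resamples input with motif weights.

    The input pool is uniform over {A, C, G, U}.  Each read's weight is the
    product of the enrichment factors of the motifs it contains (searched on
    the adapter-extended read); the bound pool draws ``n_reads`` reads with
    replacement with probability proportional to weight.  All factors equal
    to 1 make the bound pool a plain bootstrap of the input pool.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list("ACGU"))
    reads_arr = rng.integers(0, 4, size=(spec.n_reads, spec.read_length))
    reads = ["".join(row) for row in alphabet[reads_arr]]

    motifs = {normalize_rna(m): f for m, f in spec.enriched_motifs.items()}
    a5, a3 = (normalize_rna(spec.adapter_5p) if spec.adapter_5p else "",
              normalize_rna(spec.adapter_3p) if spec.adapter_3p else "")
    weights = np.ones(spec.n_reads)
    if motifs or spec.pattern_enrichment != 1.0:
        from .enrichment import has_strong_g4
        for i, read in enumerate(reads):
            seq = a5 + read + a3
            w = 1.0
            for motif, factor in motifs.items():
                if motif in seq:
                    w *= factor
            if spec.pattern_enrichment != 1.0 and has_strong_g4(seq, spec.pattern_spec):
                w *= spec.pattern_enrichment
            weights[i] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("all read weights are zero; bound pool undefined")
    picks = rng.choice(spec.n_reads, size=spec.n_reads, replace=True,
                       p=weights / total)
    input_pool = ReadPool(reads, "input", spec.adapter_5p, spec.adapter_3p)
    bound_pool = ReadPool([reads[i] for i in picks], "bound",
                          spec.adapter_5p, spec.adapter_3p)
    return input_pool, bound_pool


# ---------------------------------------------------------------------------
# Model curves
# ---------------------------------------------------------------------------

def generate_curves(spec: CurveSpec) -> list[TitrationCurve] | list[RecoveryCurve]:
    """Replicate model curves with Gaussian noise scaled to the dynamic range."""
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.parameters)
    if spec.model == "one_site":
        x = np.asarray(
            spec.x_values if spec.x_values is not None
            else np.logspace(-2, 1, 12)
        , dtype=float)
        if np.any(x <= 0):
            raise ValueError("one_site concentrations must be strictly positive")
        clean = one_site_model(x, p.get("K_D", 1.0), p.get("B_max", 1.0),
                               p.get("baseline", 0.0))
        make = lambda y, r: TitrationCurve(x, y, r)
    else:
        x = np.asarray(
            spec.x_values if spec.x_values is not None
            else np.linspace(0.0, 120.0, 60)
        , dtype=float)
        k = _LN2 / p.get("t_half", 10.0)
        clean = one_phase_association_model(x, k, p.get("plateau", 1.0),
                                            p.get("Y0", 0.0))
        make = lambda y, r: RecoveryCurve(x, y, r)

    sd = spec.noise_sd * float(np.ptp(clean))
    curves = []
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, sd, size=clean.shape) if sd > 0 else 0.0
        curves.append(make(clean + noise, r))
    return curves
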