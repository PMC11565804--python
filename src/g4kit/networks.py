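"""Contact, occupancy, crowder-partitioning, density and clustering analyses
of condensate trajectories.

Molecule-level contact convention: a protein and an RNA are "in contact"
when their minimum heavy-atom pairwise distance is at most the cutoff
(default 8 Å); crowder proximity uses 6 Å and counts each crowder molecule
once per frame.  Conformational clustering follows the Daura (GROMOS)
procedure: pairwise RMSD after optimal least-squares superposition,
iterative extraction of the frame with the most neighbors within the cutoff
(0.2 nm default) as a cluster center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .quadruplex import HBondCriteria, find_hbonds
from .trajectory import AtomRecord, Frame, Trajectory

__all__ = [
    "ContactCriteria",
    "ContactGraph",
    "ClusterResult",
    "contact_graph",
    "multivalency_series",
    "hbond_occupancy",
    "crowder_proximity",
    "radial_density_profile",
    "estimate_core_diameter",
    "kabsch_rmsd",
    "cluster_conformations",
]

_HEAVY = lambda a: not (a.element.upper() == "H" or
                        (not a.element and a.atom_name.startswith("H")))


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoff (Å) and atom scope for molecule-level contacts."""

    cutoff: float = 8.0
    atom_scope: str = "heavy_atoms"  # or "all_atoms"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.atom_scope not in ("heavy_atoms", "all_atoms"):
            raise ValueError("atom_scope must be 'heavy_atoms' or 'all_atoms'")


@dataclass
class ContactGraph:
    """Bipartite protein<->RNA contacts of one frame with edge distances."""

    frame_index: int
    edges: set[tuple[int, int]]          # (protein molecule_id, rna molecule_id)
    min_distance: dict[tuple[int, int], float]
    protein_ids: list[int]
    rna_ids: list[int]

    def degree(self, side: str) -> dict[int, int]:
        ids = self.protein_ids if side == "protein" else self.rna_ids
        pos = 0 if side == "protein" else 1
        deg = {m: 0 for m in ids}
        for e in self.edges:
            deg[e[pos]] += 1
        return deg


@dataclass
class ClusterResult:
    """Daura clustering outcome.

    ``assignments`` maps every frame to a cluster id (0 = most populated);
    ``centers`` maps cluster id to its central frame.
    """

    assignments: dict[int, int]
    centers: dict[int, int]
    rmsd_cutoff_nm: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster_id: int) -> list[int]:
        return sorted(f for f, c in self.assignments.items() if c == cluster_id)


def _molecule_coords(frame: Frame, scope: str) -> dict[int, tuple[str, np.ndarray]]:
    """molecule_id -> (kind, coordinate array) under the atom scope."""
    out: dict[int, tuple[str, list[np.ndarray]]] = {}
    for a in frame.atoms:
        if scope == "heavy_atoms" and not _HEAVY(a):
            continue
        kind, coords = out.setdefault(a.molecule_id, (a.molecule_kind, []))
        coords.append(a.position)
    return {m: (kind, np.array(coords)) for m, (kind, coords) in out.items()}


def contact_graph(frame: Frame, criteria: ContactCriteria | None = None,
                  frame_index: int = 0) -> ContactGraph:
    """Protein-RNA contact edges of one frame.

    An edge exists iff the minimum inter-molecular atom distance is at most
    ``criteria.cutoff``; the per-edge minimum distance is recorded.  A frame
    without proteins or without RNA yields an empty graph with a warning.
    """
    criteria = criteria or ContactCriteria()
    mols = _molecule_coords(frame, criteria.atom_scope)
    proteins = [m for m, (k, _) in mols.items() if k == "protein"]
    rnas = [m for m, (k, _) in mols.items() if k == "rna"]
    if not proteins or not rnas:
        warnings.warn("frame lacks protein or RNA molecules; empty contact graph")
        return ContactGraph(frame_index, set(), {}, proteins, rnas)

    edges: set[tuple[int, int]] = set()
    dists: dict[tuple[int, int], float] = {}
    trees = {m: cKDTree(mols[m][1]) for m in rnas}
    for p in proteins:
        pcoords = mols[p][1]
        for r in rnas:
            d = trees[r].query(pcoords, k=1)[0].min()
            if d <= criteria.cutoff:
                edges.add((p, r))
                dists[(p, r)] = float(d)
    return ContactGraph(frame_index, edges, dists, proteins, rnas)


def multivalency_series(traj: Trajectory, criteria: ContactCriteria | None = None
                        ) -> pd.DataFrame:
    """Per-frame partner-count statistics for both sides of the contact graph.

    Columns: frame, mean/max partners per protein, mean/max partners per RNA,
    and the full degree histograms as dictionaries.
    """
    criteria = criteria or ContactCriteria()
    rows = []
    for i, frame in enumerate(traj.frames):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = contact_graph(frame, criteria, i)
        stats: dict = {"frame": i}
        for side in ("protein", "rna"):
            deg = list(g.degree(side).values())
            hist: dict[int, int] = {}
            for d in deg:
                hist[d] = hist.get(d, 0) + 1
            stats[f"mean_partners_per_{side}"] = float(np.mean(deg)) if deg else 0.0
            stats[f"max_partners_per_{side}"] = int(max(deg)) if deg else 0
            stats[f"{side}_degree_histogram"] = hist
        rows.append(stats)
    return pd.DataFrame(rows)


def hbond_occupancy(
    traj: Trajectory,
    criteria: HBondCriteria | None = None,
    donor_kind: str = "protein",
    acceptor_kind: str = "rna",
) -> pd.DataFrame:
    """Residue-pair hydrogen-bond occupancy over a trajectory.

    Occupancy of a (donor residue, acceptor residue) pair is the fraction of
    frames in which at least one hydrogen bond links the pair, with donors
    drawn from ``donor_kind`` molecules (nitrogen/oxygen atoms) and acceptors
    from ``acceptor_kind``.  The table is sorted by descending occupancy.
    """
    criteria = criteria or HBondCriteria()
    n_frames = len(traj.frames)
    if n_frames == 0:
        raise ValueError("trajectory must hold at least one frame")
    seen: dict[tuple, set[int]] = {}
    labels: dict[tuple, tuple[str, str]] = {}
    for i, frame in enumerate(traj.frames):
        donors = [a for a in frame.atoms
                  if a.molecule_kind == donor_kind and a.element.upper() in ("N", "O")]
        acceptors = [a for a in frame.atoms
                     if a.molecule_kind == acceptor_kind
                     and a.element.upper() in ("N", "O")]
        for b in find_hbonds(frame, criteria, donors, acceptors, i):
            key = ((b.donor.molecule_id, b.donor.residue_id),
                   (b.acceptor.molecule_id, b.acceptor.residue_id))
            seen.setdefault(key, set()).add(i)
            labels[key] = (f"{b.donor.residue_name}{b.donor.residue_id}",
                           f"{b.acceptor.residue_name}{b.acceptor.residue_id}")
    rows = [
        {
            "donor_molecule": k[0][0], "donor_residue": labels[k][0],
            "acceptor_molecule": k[1][0], "acceptor_residue": labels[k][1],
            "occupancy": len(frames) / n_frames, "n_frames": n_frames,
        }
        for k, frames in seen.items()
    ]
    df = pd.DataFrame(rows, columns=["donor_molecule", "donor_residue",
                                     "acceptor_molecule", "acceptor_residue",
                                     "occupancy", "n_frames"])
    return df.sort_values(["occupancy", "donor_molecule", "acceptor_molecule"],
                          ascending=[False, True, True], ignore_index=True)


def crowder_proximity(traj: Trajectory, criteria: ContactCriteria | None = None
                      ) -> pd.Series:
    """Per-frame count of crowder molecules within the cutoff (default 6 Å)
    of any protein or RNA atom; each crowder counts at most once per frame."""
    criteria = criteria or ContactCriteria(cutoff=6.0)
    counts = []
    for frame in traj.frames:
        mols = _molecule_coords(frame, criteria.atom_scope)
        target = [c for m, (k, c) in mols.items() if k in ("protein", "rna")]
        crowders = {m: c for m, (k, c) in mols.items() if k == "crowder"}
        if not crowders or not target:
            counts.append(0)
            continue
        tree = cKDTree(np.vstack(target))
        n = 0
        for coords in crowders.values():
            d, _ = tree.query(coords, k=1)
            if d.min() <= criteria.cutoff:
                n += 1
        counts.append(n)
    return pd.Series(counts, name="crowders_in_contact").rename_axis("frame")


def radial_density_profile(
    frame: Frame,
    species: Sequence[str] = ("protein", "rna"),
    n_bins: int = 20,
    center: np.ndarray | str = "assembly_com",
) -> pd.DataFrame:
    """Spherical-shell atom counts and densities about a center.

    ``center='assembly_com'`` uses the centroid of the selected species.
    Columns: ``r_inner, r_outer, r_mid, count, density`` (atoms/Å³); counts
    sum to the number of selected atoms.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    kinds = set(species)
    coords = np.array([a.position for a in frame.atoms if a.molecule_kind in kinds])
    if coords.size == 0:
        raise ValueError(f"no atoms of species {sorted(kinds)}")
    c = coords.mean(axis=0) if isinstance(center, str) else np.asarray(center, float)
    r = np.linalg.norm(coords - c, axis=1)
    edges = np.linspace(0.0, r.max() * (1 + 1e-9), n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    volume = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return pd.DataFrame({
        "r_inner": edges[:-1], "r_outer": edges[1:],
        "r_mid": 0.5 * (edges[:-1] + edges[1:]),
        "count": counts, "density": counts / volume,
    })


def estimate_core_diameter(profile: pd.DataFrame, threshold_fraction: float = 0.1
                           ) -> float:
    """Hollow-core diameter: twice the outermost radius, scanning outward
    from the center, at which shell density is still below
    ``threshold_fraction`` of the profile's peak.  Returns 0 for a filled
    center.  This is a stated convention, not a unique definition."""
    dens = profile["density"].to_numpy()
    thresh = threshold_fraction * dens.max()
    radius = 0.0
    for _, row in profile.iterrows():
        if row["density"] < thresh:
            radius = row["r_outer"]
        else:
            break
    return 2.0 * radius


# ---------------------------------------------------------------------------
# GROMOS (Daura) clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD (Å) after optimal least-squares rigid superposition of b onto a."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = a - b @ rot
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "P", "C1'"})


def _cluster_selection(traj: Trajectory, atom_indices: Sequence[int] | None,
                       molecule_id: int | None) -> list[int]:
    frame0 = traj.frames[0]
    if atom_indices is not None:
        return list(atom_indices)
    mol = molecule_id if molecule_id is not None else frame0.atoms[0].molecule_id
    idx = [i for i, a in enumerate(frame0.atoms)
           if a.molecule_id == mol and a.atom_name in _BACKBONE_NAMES]
    if not idx:  # bead fixtures may not use backbone names; fall back to heavy
        idx = [i for i, a in enumerate(frame0.atoms)
               if a.molecule_id == mol and _HEAVY(a)]
    return idx


def cluster_conformations(
    traj: Trajectory,
    rmsd_cutoff_nm: float = 0.2,
    atom_indices: Sequence[int] | None = None,
    molecule_id: int | None = None,
) -> ClusterResult:
    """Daura/GROMOS conformational clustering of a trajectory.

    Pairwise RMSD over the selection (default: backbone heavy atoms of the
    first molecule) after optimal superposition; iteratively the frame with
    the most neighbors within the cutoff becomes a cluster center and is
    removed together with its neighbors.  Ties in neighbor count break
    toward the lowest frame index.  The first center is the representative
    conformation of maximum population.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    idx = _cluster_selection(traj, atom_indices, molecule_id)
    if not idx:
        raise ValueError("empty atom selection for clustering")
    cutoff = rmsd_cutoff_nm * 10.0  # nm -> Å
    coords = np.array([f.coords[idx] for f in traj.frames])
    n = len(coords)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(coords[i], coords[j])

    remaining = list(range(n))
    assignments: dict[int, int] = {}
    centers: dict[int, int] = {}
    cid = 0
    while remaining:
        neigh = {
            f: [g for g in remaining if rmsd[f, g] <= cutoff] for f in remaining
        }
        center = max(remaining, key=lambda f: (len(neigh[f]), -f))
        for g in neigh[center]:
            assignments[g] = cid
        centers[cid] = center
        remaining = [f for f in remaining if f not in set(neigh[center])]
        cid += 1
    return ClusterResult(assignments, centers, rmsd_cutoff_nm)
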