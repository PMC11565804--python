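import warnings

import numpy as np
import pytest

from g4kit.networks import (ContactCriteria, cluster_conformations,
                            contact_graph, crowder_proximity,
                            estimate_core_diameter, hbond_occupancy,
                            kabsch_rmsd, multivalency_series,
                            radial_density_profile)
from g4kit.quadruplex import HBondCriteria
from g4kit.synthetic import generate_condensate_frames
from g4kit.trajectory import Frame, Trajectory
from tests.conftest import make_atom


def random_molecule_frame(rng, n_protein=3, n_rna=2, n_crowder=2, spread=25.0):
    atoms = []
    aid = 0
    mol = 0
    for kind, res, name, elem, count in (
        ("protein", "GLY", "CA", "C", n_protein),
        ("rna", "A", "P", "P", n_rna),
        ("crowder", "PEG", "C1", "C", n_crowder),
    ):
        for _ in range(count):
            mol += 1
            center = rng.uniform(0, spread, 3)
            for b in range(3):
                aid += 1
                atoms.append(make_atom(aid, name, b + 1,
                                       center + rng.uniform(-2, 2, 3),
                                       element=elem, residue_name=res,
                                       molecule_id=mol, kind=kind))
    return Frame(atoms)


def brute_force_edges(frame, cutoff):
    mols = {}
    for a in frame.atoms:
        mols.setdefault((a.molecule_kind, a.molecule_id), []).append(a.position)
    edges = set()
    for (k1, m1), c1 in mols.items():
        for (k2, m2), c2 in mols.items():
            if k1 == "protein" and k2 == "rna":
                if min(np.linalg.norm(p - q) for p in c1 for q in c2) <= cutoff:
                    edges.add((m1, m2))
    return edges


@pytest.mark.parametrize("seed", range(5))
def test_contact_graph_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    frame = random_molecule_frame(rng)
    for cutoff in (4.0, 8.0, 15.0):
        g = contact_graph(frame, ContactCriteria(cutoff=cutoff))
        assert g.edges == brute_force_edges(frame, cutoff)


def test_contact_cutoff_monotonicity():
    rng = np.random.default_rng(99)
    frame = random_molecule_frame(rng)
    prev = set()
    for cutoff in (2.0, 5.0, 8.0, 12.0, 20.0):
        edges = contact_graph(frame, ContactCriteria(cutoff=cutoff)).edges
        assert prev <= edges
        prev = edges


def test_constructed_contacts_and_tiny_cutoff(condensate_traj):
    frame = condensate_traj.frames[0]
    g = contact_graph(frame)
    assert set(g.degree("rna").values()) == {3}
    assert all(d <= 8.0 for d in g.min_distance.values())
    tiny = contact_graph(frame, ContactCriteria(cutoff=0.1))
    assert tiny.edges == set()


def test_missing_side_warns_and_returns_empty():
    frame = Frame([make_atom(1, "CA", 1, [0, 0, 0], element="C",
                             residue_name="GLY", kind="protein")])
    with pytest.warns(UserWarning, match="lacks"):
        g = contact_graph(frame)
    assert g.edges == set()


def test_multivalency_static_series_and_bridging(condensate_traj):
    df = multivalency_series(condensate_traj)
    assert len(df) == len(condensate_traj)
    for col in ("mean_partners_per_rna", "max_partners_per_protein"):
        assert df[col].nunique() == 1  # frozen frames -> constant series
    assert df["mean_partners_per_rna"].iloc[0] == pytest.approx(3.0)

    # one protein bead bridging three RNA beads within 8 Å
    atoms = [make_atom(1, "CA", 1, [0, 0, 0], element="C", residue_name="GLY",
                       molecule_id=1, kind="protein")]
    for i, ang in enumerate(np.linspace(0, 2 * np.pi, 3, endpoint=False)):
        atoms.append(make_atom(2 + i, "P", 1, [6 * np.cos(ang), 6 * np.sin(ang), 0],
                               element="P", residue_name="A",
                               molecule_id=2 + i, kind="rna"))
    df1 = multivalency_series(Trajectory([Frame(atoms)]))
    assert df1["max_partners_per_protein"].iloc[0] == 3


def make_bonded_pair_frame(bonded: bool):
    """Protein N donor with hydrogen; RNA O acceptor at 2.9 or 9 Å."""
    d = 2.9 if bonded else 9.0
    return Frame([
        make_atom(1, "N", 1, [0, 0, 0], element="N", residue_name="LYS",
                  molecule_id=1, kind="protein"),
        make_atom(2, "H", 1, [1.0, 0, 0], element="H", residue_name="LYS",
                  molecule_id=1, kind="protein"),
        make_atom(3, "O6", 5, [d, 0, 0], element="O", residue_name="G",
                  molecule_id=2, kind="rna"),
    ])


def test_hbond_occupancy_fractions():
    frames = [make_bonded_pair_frame(i < 5) for i in range(10)]
    table = hbond_occupancy(Trajectory(frames), HBondCriteria())
    assert len(table) == 1
    assert table["occupancy"].iloc[0] == pytest.approx(0.5)

    always = hbond_occupancy(Trajectory([make_bonded_pair_frame(True)] * 10),
                             HBondCriteria())
    assert always["occupancy"].iloc[0] == pytest.approx(1.0)


def test_hbond_occupancy_equals_per_frame_recount():
    rng = np.random.default_rng(4)
    frames = []
    for _ in range(8):
        atoms = []
        for r in range(4):
            base = rng.uniform(0, 10, 3)
            atoms.append(make_atom(3 * r + 1, "N", r + 1, base, element="N",
                                   residue_name="ARG", molecule_id=1, kind="protein"))
            atoms.append(make_atom(3 * r + 2, "H", r + 1, base + [1, 0, 0],
                                   element="H", residue_name="ARG",
                                   molecule_id=1, kind="protein"))
            atoms.append(make_atom(3 * r + 3, "O6", r + 1, rng.uniform(0, 10, 3),
                                   element="O", residue_name="G",
                                   molecule_id=2, kind="rna"))
        frames.append(Frame(atoms))
    traj = Trajectory(frames)
    crit = HBondCriteria()
    table = hbond_occupancy(traj, crit)

    from g4kit.quadruplex import find_hbonds
    expect = {}
    for i, f in enumerate(frames):
        donors = [a for a in f.atoms if a.molecule_kind == "protein"
                  and a.element in "NO"]
        acceptors = [a for a in f.atoms if a.molecule_kind == "rna"
                     and a.element in "NO"]
        pairs = {((b.donor.molecule_id, b.donor.residue_id),
                  (b.acceptor.molecule_id, b.acceptor.residue_id))
                 for b in find_hbonds(f, crit, donors, acceptors)}
        for p in pairs:
            expect[p] = expect.get(p, 0) + 1
    got = {((r.donor_molecule, int(r.donor_residue[3:])),
            (r.acceptor_molecule, int(r.acceptor_residue[1:]))): r.occupancy
           for r in table.itertuples()}
    assert got == {p: n / len(frames) for p, n in expect.items()}


def test_crowder_proximity_thresholds():
    def crowder_at(dist):
        return Frame([
            make_atom(1, "CA", 1, [0, 0, 0], element="C", residue_name="GLY",
                      molecule_id=1, kind="protein"),
            make_atom(2, "C1", 1, [dist, 0, 0], element="C", residue_name="PEG",
                      molecule_id=2, kind="crowder"),
        ])
    assert crowder_proximity(Trajectory([crowder_at(5.0)])).iloc[0] == 1
    assert crowder_proximity(Trajectory([crowder_at(7.0)])).iloc[0] == 0


@pytest.mark.parametrize("seed", range(4))
def test_crowder_proximity_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    frame = random_molecule_frame(rng, n_crowder=5)
    got = crowder_proximity(Trajectory([frame])).iloc[0]
    mols = {}
    for a in frame.atoms:
        mols.setdefault((a.molecule_kind, a.molecule_id), []).append(a.position)
    targets = [p for (k, _), c in mols.items() if k in ("protein", "rna") for p in c]
    expect = sum(
        1 for (k, _), c in mols.items() if k == "crowder"
        and min(np.linalg.norm(p - q) for p in c for q in targets) <= 6.0
    )
    assert got == expect


def test_radial_profile_conserves_counts_and_flags_hollow_core():
    rng = np.random.default_rng(8)
    # uniform solid ball of rna beads
    pts = rng.normal(size=(4000, 3))
    pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 40.0 * rng.uniform(0, 1, (4000, 1)) ** (1 / 3)
    atoms = [make_atom(i + 1, "P", 1, p, element="P", residue_name="A",
                       molecule_id=i + 1, kind="rna") for i, p in enumerate(pts)]
    frame = Frame(atoms)
    prof = radial_density_profile(frame, n_bins=8, center=np.zeros(3))
    assert prof["count"].sum() == 4000
    inner = prof["density"].iloc[1:7]
    assert inner.max() < 2.0 * inner.min()  # flat within sampling noise
    assert estimate_core_diameter(prof) == 0.0

    shell = generate_condensate_frames(n_protein=24, n_rna=8, contacts_per_rna=3,
                                       core_inner_radius=30.0, seed=6)
    sprof = radial_density_profile(shell.frames[0], n_bins=12, center=np.zeros(3))
    assert estimate_core_diameter(sprof) == pytest.approx(60.0, rel=0.2)
    with pytest.raises(ValueError):
        radial_density_profile(frame, n_bins=1)


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------

def reference_daura(rmsd, cutoff):
    """Literal transcription of the iterative max-neighbor extraction."""
    remaining = set(range(len(rmsd)))
    clusters = []
    while remaining:
        best, best_n = None, None
        for f in sorted(remaining):
            neigh = {g for g in remaining if rmsd[f][g] <= cutoff}
            if best_n is None or len(neigh) > len(best_n):
                best, best_n = f, neigh
        clusters.append((best, sorted(best_n)))
        remaining -= best_n
    return clusters


def bead_frame(positions, molecule_id=1):
    return Frame([
        make_atom(i + 1, "CA", i + 1, p, element="C", residue_name="GLY",
                  molecule_id=molecule_id, kind="protein")
        for i, p in enumerate(positions)
    ])


def test_identical_frames_form_one_cluster():
    base = np.random.default_rng(1).uniform(0, 10, (5, 3))
    traj = Trajectory([bead_frame(base)] * 10)
    res = cluster_conformations(traj)
    assert res.n_clusters == 1
    assert res.members(0) == list(range(10))


def test_two_rigid_conformers_split_into_two_clusters():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 10, (6, 3))
    b = a + rng.normal(0, 8, (6, 3))  # far beyond 0.2 nm after superposition
    frames = [bead_frame(a)] * 5 + [bead_frame(b)] * 5
    res = cluster_conformations(Trajectory(frames), rmsd_cutoff_nm=0.2)
    assert res.n_clusters == 2
    assert sorted(len(res.members(c)) for c in res.centers) == [5, 5]


@pytest.mark.parametrize("seed", range(4))
def test_daura_matches_exhaustive_reference_on_small_trajectories(seed):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 10, (5, 3))
    frames = [bead_frame(base + rng.normal(0, 1.2, base.shape)) for _ in range(12)]
    traj = Trajectory(frames)
    res = cluster_conformations(traj, rmsd_cutoff_nm=0.2)

    coords = [f.coords for f in frames]
    rmsd = [[kabsch_rmsd(ci, cj) for cj in coords] for ci in coords]
    ref = reference_daura(rmsd, 2.0)  # 0.2 nm in Å
    assert len(ref) == res.n_clusters
    sizes = []
    for cid, (center, members) in enumerate(ref):
        assert res.centers[cid] == center
        assert res.members(cid) == members
        sizes.append(len(members))
    assert sizes == sorted(sizes, reverse=True)
    # partition: disjoint and complete
    all_members = [m for _, ms in ref for m in ms]
    assert sorted(all_members) == list(range(12))


def test_rmsd_symmetry_and_superposition():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 10, (7, 3))
    theta = 1.1
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    b = a @ rot.T + np.array([3.0, -2.0, 7.0])
    assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
    c = a + rng.normal(0, 1, a.shape)
    assert abs(kabsch_rmsd(a, c) - kabsch_rmsd(c, a)) < 1e-10


def test_cluster_rejects_empty_selection():
    traj = Trajectory([bead_frame(np.zeros((3, 3)) + np.arange(3)[:, None])])
    with pytest.raises(ValueError):
        cluster_conformations(traj, molecule_id=99)
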