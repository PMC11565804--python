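import numpy as np
import pytest

from g4kit.synthetic import G4FixtureSpec, build_ideal_g4, generate_condensate_frames
from g4kit.trajectory import AtomRecord, Frame, Trajectory


@pytest.fixture(scope="session")
def g4_five_tetrads() -> Frame:
    """Idealized five-tetrad tetrameric quadruplex core."""
    return build_ideal_g4(G4FixtureSpec(n_tetrads=5, topology="tetrameric"))


@pytest.fixture(scope="session")
def condensate_traj() -> Trajectory:
    """Small static-ish condensate: 3 RNAs x 3 contacts, crowders, 3 frames."""
    return generate_condensate_frames(
        n_protein=11, n_rna=3, n_crowder=6, contacts_per_rna=3,
        n_frames=3, displacement_D=0.0, seed=7,
    )


def make_atom(atom_id, name, residue_id, pos, *, element=None, residue_name="G",
              molecule_id=1, kind="rna"):
    return AtomRecord(atom_id, name, element or (name[:1] or "X"), residue_name,
                      residue_id, molecule_id, kind, np.asarray(pos, dtype=float))


@pytest.fixture
def linear_hbond_frame():
    """One donor-hydrogen-acceptor triple at 2.9 Å, perfectly linear."""
    atoms = [
        make_atom(1, "N1", 1, [0.0, 0.0, 0.0]),
        make_atom(2, "H1", 1, [1.01, 0.0, 0.0], element="H"),
        make_atom(3, "O6", 2, [2.9, 0.0, 0.0], molecule_id=2),
    ]
    return Frame(atoms)
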