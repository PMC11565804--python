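"""Coordinate data model and trajectory readers/writers.

Atoms, frames and trajectories are the common currency of every geometric
analysis in this package.  Two on-disk dialects are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` blocks, fixed columns), the native
  format of structural ensembles, carrying coordinates at 3-decimal (mÅ)
  precision;
* a plain CSV trajectory dialect (one row per atom per frame) that is
  bit-exact and diff-able, used for fixtures and interchange.

Coordinates are stored in Å throughout; modules that work in µm (diffusion,
single-particle tracking) convert at their own boundary.
"""

from __future__ import annotations

import string
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MOLECULE_KINDS",
    "DEFAULT_KIND_MAP",
    "AtomRecord",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "load_kind_map",
    "read_frames",
    "write_frames",
    "select_atoms",
]

MOLECULE_KINDS = ("protein", "rna", "crowder", "ion", "solvent")

_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()
_RNA_RESIDUES = ["A", "U", "G", "C", "RA", "RU", "RG", "RC"]

#: Default residue-name -> molecule_kind mapping.  Covers exactly the species
#: found in protein/rG4/PEG/KCl/water systems; anything else must be named in
#: a user-supplied mapping.
DEFAULT_KIND_MAP: dict[str, str] = (
    {aa: "protein" for aa in _AMINO_ACIDS}
    | {r: "rna" for r in _RNA_RESIDUES}
    | {"PEG": "crowder"}
    | {"K": "ion", "CL": "ion"}
    | {"HOH": "solvent", "SOL": "solvent", "TIP3": "solvent"}
)

_CSV_COLUMNS = [
    "frame", "time", "atom_id", "atom_name", "element", "residue_name",
    "residue_id", "molecule_id", "molecule_kind", "x", "y", "z",
]

# chain identifiers used when writing PDB; cycled if there are more molecules
_CHAIN_IDS = string.ascii_uppercase + string.digits + string.ascii_lowercase


class TrajectoryError(ValueError):
    """Structural problem in a trajectory file or object."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity, residue/molecule membership and position (Å)."""

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    molecule_id: int
    molecule_kind: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.molecule_kind not in MOLECULE_KINDS:
            raise ValueError(
                f"unknown molecule_kind {self.molecule_kind!r}; "
                f"expected one of {MOLECULE_KINDS}"
            )
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class Frame:
    """An ordered set of atoms at one instant, with an optional box (Å)."""

    atoms: list[AtomRecord]
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TrajectoryError("atom_ids within a frame must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, time: float | None = None) -> "Frame":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TrajectoryError("coordinate array shape mismatch")
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return Frame(atoms, box=self.box, time=self.time if time is None else time)

    def molecule_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.molecule_id, None)
        return list(seen)

    def atoms_of_molecule(self, molecule_id: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.molecule_id == molecule_id]


@dataclass
class Trajectory:
    """Ordered frames with a uniform time step ``dt`` (``time_unit``)."""

    frames: list[Frame]
    dt: float = 1.0
    time_unit: str = "ps"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise TrajectoryError("dt must be positive")
        if self.frames:
            n0 = len(self.frames[0])
            names0 = [a.atom_name for a in self.frames[0].atoms]
            for i, fr in enumerate(self.frames):
                if len(fr) != n0:
                    raise TrajectoryError(
                        f"frame {i} has {len(fr)} atoms, frame 0 has {n0}"
                    )
                if [a.atom_name for a in fr.atoms] != names0:
                    raise TrajectoryError(f"frame {i} atom ordering differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def dt_seconds(self) -> float:
        scale = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9, "ps": 1e-12}
        try:
            return self.dt * scale[self.time_unit]
        except KeyError:  # pragma: no cover - defensive
            raise TrajectoryError(f"unknown time unit {self.time_unit!r}") from None


def load_kind_map(config_path: str | Path) -> dict[str, str]:
    """Read a ``[kinds]`` residue-name -> kind mapping from a TOML config.

    The returned mapping extends (and may override) the built-in defaults.
    """
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    table = cfg.get("kinds", {})
    mapping = dict(DEFAULT_KIND_MAP)
    for res, kind in table.items():
        if kind not in MOLECULE_KINDS:
            raise ValueError(f"config maps {res!r} to unknown kind {kind!r}")
        mapping[res.upper()] = kind
    return mapping


def _kind_of(residue_name: str, kind_map: Mapping[str, str]) -> str:
    try:
        return kind_map[residue_name.upper()]
    except KeyError:
        raise TrajectoryError(
            f"residue {residue_name!r} has no molecule_kind mapping; "
            "supply one via a [kinds] config table"
        ) from None


# ---------------------------------------------------------------------------
# PDB dialect
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str) -> tuple[int, str, str, int, str, np.ndarray, str]:
    atom_id = int(line[6:11])
    atom_name = line[12:16].strip()
    residue_name = line[17:20].strip()
    chain = line[21]
    residue_id = int(line[22:26])
    xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        element = atom_name[0]
    return atom_id, atom_name, residue_name, residue_id, chain, xyz, element


def _read_pdb(path: Path, kind_map: Mapping[str, str]) -> list[Frame]:
    frames: list[Frame] = []
    current: list[AtomRecord] | None = None
    box: np.ndarray | None = None
    saw_model = False
    mol_id = 0
    prev_chain: str | None = None
    prev_resid: int | None = None

    def start_frame() -> list[AtomRecord]:
        nonlocal mol_id, prev_chain, prev_resid
        mol_id = 0
        prev_chain = None
        prev_resid = None
        return []

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            elif rec.startswith("MODEL"):
                saw_model = True
                current = start_frame()
            elif rec.startswith("ENDMDL"):
                if current is None:
                    raise TrajectoryError("ENDMDL without MODEL")
                frames.append(Frame(current, box=box))
                current = None
            elif rec.startswith(("ATOM  ", "HETATM")):
                if current is None:
                    current = start_frame()
                aid, aname, rname, rid, chain, xyz, elem = _parse_pdb_atom(line)
                # a new molecule starts when the chain changes or residue
                # numbering restarts
                if prev_chain is None or chain != prev_chain or rid < (prev_resid or rid):
                    mol_id += 1
                prev_chain, prev_resid = chain, rid
                current.append(
                    AtomRecord(aid, aname, elem, rname, rid, mol_id,
                               _kind_of(rname, kind_map), xyz)
                )
    if current is not None:
        if saw_model:
            raise TrajectoryError("unterminated MODEL block")
        frames.append(Frame(current, box=box))
    return frames


def _format_pdb_atom(a: AtomRecord, chain: str) -> str:
    if np.any(np.abs(a.position) >= 10000) or np.any(a.position <= -1000):
        raise TrajectoryError(
            f"coordinate overflow for atom {a.atom_id}: PDB fixed columns "
            "hold -999.999..9999.999 Å"
        )
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
    record = "ATOM  " if a.molecule_kind in ("protein", "rna") else "HETATM"
    x, y, z = a.position
    return (
        f"{record}{a.atom_id % 100000:5d} {name:<4.4s} {a.residue_name:<3.3s} "
        f"{chain}{a.residue_id % 10000:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
    )


def _write_pdb(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    box = traj.frames[0].box
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    chain_for_mol: dict[int, str] = {}
    for m in traj.frames[0].molecule_ids():
        chain_for_mol[m] = _CHAIN_IDS[len(chain_for_mol) % len(_CHAIN_IDS)]
    for i, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {i:4d}")
        for a in frame.atoms:
            lines.append(_format_pdb_atom(a, chain_for_mol[a.molecule_id]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv_traj(path: Path) -> tuple[list[Frame], float]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"csv_traj missing columns: {missing}")
    frames: list[Frame] = []
    for _, sub in df.groupby("frame", sort=True):
        atoms = [
            AtomRecord(
                int(r.atom_id), str(r.atom_name), str(r.element),
                str(r.residue_name), int(r.residue_id), int(r.molecule_id),
                str(r.molecule_kind), np.array([r.x, r.y, r.z]),
            )
            for r in sub.itertuples(index=False)
        ]
        frames.append(Frame(atoms, time=float(sub["time"].iloc[0])))
    times = df.groupby("frame", sort=True)["time"].first().to_numpy()
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return frames, dt if dt > 0 else 1.0


def _write_csv_traj(traj: Trajectory, path: Path) -> None:
    rows = []
    for i, frame in enumerate(traj.frames):
        t = frame.time if frame.time else i * traj.dt
        for a in frame.atoms:
            rows.append((i, t, a.atom_id, a.atom_name, a.element, a.residue_name,
                         a.residue_id, a.molecule_id, a.molecule_kind,
                         a.position[0], a.position[1], a.position[2]))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_frames(
    path: str | Path,
    format: str = "pdb_multimodel",
    kind_map: Mapping[str, str] | None = None,
    dt: float | None = None,
    time_unit: str = "ps",
) -> Trajectory:
    """Read a trajectory from ``path`` in the named dialect.

    PDB ``MODEL`` blocks map one-to-one to frames; ``molecule_kind`` is
    inferred from the residue name via ``kind_map`` (defaults cover standard
    amino acids, A/U/G/C ribonucleotides, PEG, K+/Cl- and water).  Mismatched
    atom counts across models raise :class:`TrajectoryError`.
    """
    path = Path(path)
    kind_map = dict(DEFAULT_KIND_MAP) if kind_map is None else dict(kind_map)
    if format == "pdb_multimodel":
        frames = _read_pdb(path, kind_map)
        return Trajectory(frames, dt=dt or 1.0, time_unit=time_unit)
    if format == "csv_traj":
        frames, inferred_dt = _read_csv_traj(path)
        return Trajectory(frames, dt=dt or inferred_dt, time_unit=time_unit)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_frames(traj: Trajectory, path: str | Path, format: str = "pdb_multimodel") -> None:
    """Write ``traj`` so that :func:`read_frames` reproduces it.

    PDB coordinates are written at fixed-column 3-decimal precision; the CSV
    dialect round-trips bit-exactly.
    """
    if not traj.frames:
        raise TrajectoryError("cannot write an empty trajectory")
    path = Path(path)
    if format == "pdb_multimodel":
        _write_pdb(traj, path)
    elif format == "csv_traj":
        _write_csv_traj(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def select_atoms(
    frame: Frame,
    by_kind: str | None = None,
    by_residue_name: str | None = None,
    by_atom_name: Iterable[str] | None = None,
    by_molecule_id: int | None = None,
) -> list[AtomRecord]:
    """Atoms matching the conjunction of the provided filters, order preserved."""
    names = set(by_atom_name) if by_atom_name is not None else None
    out = []
    for a in frame.atoms:
        if by_kind is not None and a.molecule_kind != by_kind:
            continue
        if by_residue_name is not None and a.residue_name != by_residue_name:
            continue
        if names is not None and a.atom_name not in names:
            continue
        if by_molecule_id is not None and a.molecule_id != by_molecule_id:
            continue
        out.append(a)
    return out
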