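"""Reading and writing structures, trajectories and collective modes.

Formats
-------
PDB
    Single- and multi-model files, read through :mod:`biotite`.  Chain IDs
    define the default partition.  Coordinates are converted Å -> nm on
    read and nm -> Å on write.  Hydrogens are dropped at load time by
    default (the analyses operate on non-hydrogen atoms); pass
    ``hydrogens=True`` to keep them.
Trajectory container (``.npz``)
    A documented NumPy archive holding ``coords`` (F x N x 3, nm), the
    atom table columns, the partition as JSON and provenance metadata.
    This is the native interchange format between the CLI stages.
Plug-in readers
    :func:`register_trajectory_reader` maps a file extension to a callable
    returning a :class:`~tqcoupling.geometry.Trajectory`, so standard MD
    trajectory formats can be plugged in without new package code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import DataError
from .geometry import (
    ATOMIC_MASSES,
    VDW_RADII_NM,
    AtomTable,
    ChainPartition,
    StructureFrame,
    Trajectory,
)

__all__ = [
    "read_structure",
    "read_trajectory_pdb",
    "write_structure",
    "write_trajectory_pdb",
    "save_trajectory",
    "load_trajectory",
    "register_trajectory_reader",
    "load_radius_table",
    "write_mode_movie",
    "save_mode",
    "load_mode",
]

_ANGSTROM_PER_NM = 10.0


def _atom_table_from_array(
    arr: struc.AtomArray,
    radii: Mapping[str, float] | None,
) -> AtomTable:
    radii = dict(VDW_RADII_NM if radii is None else radii)
    elements = [str(e).upper() for e in arr.element]
    missing = sorted({e for e in elements if e not in radii and e not in ("H", "D")})
    if missing:
        # keep going for exotic elements by falling back to carbon-like size;
        # vdw scoring raises if the fallback sentinel is ever used there.
        for e in missing:
            radii[e] = radii.get("X", 0.170)
    radii.setdefault("H", 0.120)
    radii.setdefault("D", 0.120)
    return AtomTable(
        names=[str(n) for n in arr.atom_name],
        chain_ids=[str(c) for c in arr.chain_id],
        residue_numbers=[int(r) for r in arr.res_id],
        residue_names=[str(r) for r in arr.res_name],
        elements=elements,
        vdw_radii=[radii[e] for e in elements],
        masses=[ATOMIC_MASSES.get(e, 0.0) for e in elements],
    )


def _strip_hydrogens(arr):
    return arr[..., ~np.isin(np.char.upper(arr.element.astype("U2")), ["H", "D"])]


def read_structure(
    path: str | Path,
    model: int = 1,
    hydrogens: bool = False,
    radii: Mapping[str, float] | None = None,
) -> StructureFrame:
    """Read one model of a PDB file as a :class:`StructureFrame` (nm)."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model, altloc="first")
    if not hydrogens:
        arr = _strip_hydrogens(arr)
    if arr.array_length() == 0:
        raise DataError(f"{path}: no atoms after selection")
    atoms = _atom_table_from_array(arr, radii)
    partition = ChainPartition.from_chain_ids(atoms.chain_ids)
    return StructureFrame(coords=arr.coord / _ANGSTROM_PER_NM, atoms=atoms, partition=partition)


def read_trajectory_pdb(
    path: str | Path,
    hydrogens: bool = False,
    radii: Mapping[str, float] | None = None,
    provenance: str = "raw",
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (all models, nm)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(altloc="first")  # AtomArrayStack
    if not hydrogens:
        stack = _strip_hydrogens(stack)
    atoms = _atom_table_from_array(stack[0], radii)
    partition = ChainPartition.from_chain_ids(atoms.chain_ids)
    return Trajectory(
        coords=stack.coord / _ANGSTROM_PER_NM,
        atoms=atoms,
        partition=partition,
        provenance=provenance,
    )


def _to_atom_array(frame: StructureFrame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords * _ANGSTROM_PER_NM
    arr.chain_id = frame.atoms.chain_ids.astype("U4")
    arr.res_id = frame.atoms.residue_numbers
    arr.res_name = frame.atoms.residue_names.astype("U5")
    arr.atom_name = frame.atoms.names.astype("U6")
    arr.element = frame.atoms.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(frame: StructureFrame, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(frame))
    pdb.write(str(path))


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    template = _to_atom_array(traj.frame(0))
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords * _ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# native array container


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Save a trajectory to the documented ``.npz`` container."""
    np.savez_compressed(
        str(path),
        coords=traj.coords,
        names=traj.atoms.names,
        chain_ids=traj.atoms.chain_ids,
        residue_numbers=traj.atoms.residue_numbers,
        residue_names=traj.atoms.residue_names,
        elements=traj.atoms.elements,
        vdw_radii=traj.atoms.vdw_radii,
        masses=traj.atoms.masses,
        partition_json=np.array(json.dumps(traj.partition.to_dict())),
        provenance=np.array(traj.provenance),
        frame_times=(
            traj.frame_times if traj.frame_times is not None else np.array([])
        ),
    )


def _load_container(path: str | Path) -> Trajectory:
    with np.load(str(path), allow_pickle=False) as z:
        atoms = AtomTable(
            names=z["names"],
            chain_ids=z["chain_ids"],
            residue_numbers=z["residue_numbers"],
            residue_names=z["residue_names"],
            elements=z["elements"],
            vdw_radii=z["vdw_radii"],
            masses=z["masses"],
        )
        partition = ChainPartition(
            {k: v for k, v in json.loads(str(z["partition_json"])).items()}
        )
        times = z["frame_times"]
        return Trajectory(
            coords=z["coords"],
            atoms=atoms,
            partition=partition,
            frame_times=None if times.size == 0 else times,
            provenance=str(z["provenance"]),
        )


_TRAJECTORY_READERS: dict[str, Callable[..., Trajectory]] = {}


def register_trajectory_reader(extension: str, reader: Callable[..., Trajectory]) -> None:
    """Register a reader for a file extension (e.g. ``".xtc"``).

    The callable receives the path (plus any keyword arguments given to
    :func:`load_trajectory`) and must return a
    :class:`~tqcoupling.geometry.Trajectory` in nm.
    """
    _TRAJECTORY_READERS[extension.lower().lstrip(".")] = reader


def load_trajectory(path: str | Path, **kwargs) -> Trajectory:
    """Load a trajectory, dispatching on the file extension.

    ``.npz`` (native container) and ``.pdb`` (multi-model) are built in;
    other extensions use readers added via
    :func:`register_trajectory_reader`.
    """
    ext = Path(path).suffix.lower().lstrip(".")
    if ext == "npz":
        return _load_container(path)
    if ext in ("pdb", "pdb1", "ent"):
        return read_trajectory_pdb(path, **kwargs)
    if ext in _TRAJECTORY_READERS:
        return _TRAJECTORY_READERS[ext](path, **kwargs)
    raise DataError(f"no trajectory reader for extension {ext!r}")


def load_radius_table(path: str | Path) -> dict[str, float]:
    """Read an editable two-column radius table (element, radius in nm).

    Lines starting with ``#`` and blank lines are ignored.  The result can
    be passed as ``radii`` to the structure readers, replacing the bundled
    Bondi-style defaults.
    """
    table: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 'ELEMENT radius_nm'")
        try:
            table[parts[0].upper()] = float(parts[1])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: invalid radius {parts[1]!r}") from exc
    if not table:
        raise DataError(f"{path}: empty radius table")
    return table


# ---------------------------------------------------------------------------
# collective modes


def save_mode(mode, path: str | Path) -> None:
    """Write a collective mode as a documented JSON file (vectors in nm)."""
    payload = {
        "role": mode.role,
        "vector": np.asarray(mode.vector).tolist(),
        "origin": np.asarray(mode.origin).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_mode(path: str | Path):
    from .modes import CollectiveMode

    payload = json.loads(Path(path).read_text())
    return CollectiveMode(
        vector=np.asarray(payload["vector"], dtype=np.float64),
        role=payload["role"],
        origin=np.asarray(payload["origin"], dtype=np.float64),
    )


def write_mode_movie(
    origin: StructureFrame,
    mode,
    path: str | Path,
    amplitude: float = 0.5,
    n_steps: int = 21,
) -> None:
    """Write a multi-model PDB interpolating ``origin ± amplitude·mode``."""
    vec = np.asarray(mode.vector, dtype=np.float64).reshape(-1, 3)
    frames = [
        origin.with_coords(origin.coords + a * vec, provenance="backprojected")
        for a in np.linspace(-amplitude, amplitude, n_steps)
    ]
    write_trajectory_pdb(Trajectory.from_frames(frames, provenance="backprojected"), path)
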