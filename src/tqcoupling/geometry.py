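"""Core structural data model and rigid-body superposition kernels.

Conventions used throughout the package:

* All coordinates, radii and translations are in **nanometres** (PDB
  Ångström values are converted on read).
* A conformation of ``N`` atoms is an ``(N, 3)`` float array; a flattened
  configuration vector is a ``(3 N,)`` array in atom-major order.
* Chains (or, more generally, user-defined rigid domains) are described by
  a :class:`ChainPartition`, an ordered, disjoint, covering grouping of
  atom indices.
* Rotations are proper (det = +1); reflections are never produced by the
  superposition kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import DataError, DegenerateGeometryError, UnknownElementError

__all__ = [
    "AtomRecord",
    "AtomTable",
    "ChainPartition",
    "RigidTransform",
    "StructureFrame",
    "Trajectory",
    "kabsch_fit",
    "apply_transform",
    "concatenate_trajectories",
    "count_heavy_atoms",
    "VDW_RADII_NM",
    "ATOMIC_MASSES",
]

# Bondi-style element-wise van der Waals radii (nm).  The table is a
# pragmatic default; analyses that need a specific parameter set can pass
# their own mapping to the readers / builders.
VDW_RADII_NM: dict[str, float] = {
    "H": 0.120, "D": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "F": 0.147, "P": 0.180, "S": 0.180, "CL": 0.175, "BR": 0.185,
    "I": 0.198, "SE": 0.190, "B": 0.192,
    # metals commonly found in protein structures; vdW radii for metals
    # are not well defined, values below are conventional.
    "FE": 0.200, "ZN": 0.139, "MG": 0.173, "NA": 0.227, "K": 0.275,
    "CA": 0.231, "MN": 0.205, "CU": 0.140, "NI": 0.163, "CO": 0.200,
    "LI": 0.182, "CS": 0.343, "HG": 0.155, "CD": 0.158, "MO": 0.200,
    "W": 0.200, "V": 0.200, "AU": 0.166, "PT": 0.175, "X": 0.170,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "SE": 78.971, "B": 10.81,
    "FE": 55.845, "ZN": 65.38, "MG": 24.305, "NA": 22.990, "K": 39.098,
    "CA": 40.078, "MN": 54.938, "CU": 63.546, "NI": 58.693, "CO": 58.933,
    "LI": 6.94, "CS": 132.905, "HG": 200.592, "CD": 112.414, "MO": 95.95,
    "W": 183.84, "V": 50.942, "AU": 196.967, "PT": 195.084, "X": 12.011,
}

#: residue names treated as solvent by the default heavy-atom selection
SOLVENT_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4", "SPC", "DOD"})

#: residue names of free monatomic ions (not prosthetic groups)
ION_RESIDUES = frozenset({
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "CS", "LI", "BR", "IOD",
    "F", "NI", "CU", "CD", "HG", "FE", "FE2", "CO", "SR", "RB",
})


@dataclass(frozen=True)
class AtomRecord:
    """Identity and parameters of a single atom.

    ``residue_id`` is the (chain_id, residue_number, residue_name) triple
    used as the residue key in contact analyses.
    """

    index: int
    name: str
    chain_id: str
    residue_number: int
    residue_name: str
    element: str
    vdw_radius: float
    mass: float

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)

    def __post_init__(self) -> None:
        if not self.vdw_radius > 0:
            raise DataError(f"atom {self.index} ({self.name}): vdw_radius must be > 0")


class AtomTable:
    """Struct-of-arrays atom metadata shared by all frames of a trajectory."""

    def __init__(
        self,
        names: Sequence[str],
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        elements: Sequence[str],
        vdw_radii: Sequence[float],
        masses: Sequence[float],
    ):
        self.names = np.asarray(names, dtype="U6")
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.elements = np.char.upper(np.asarray(elements, dtype="U2"))
        self.vdw_radii = np.asarray(vdw_radii, dtype=np.float64)
        self.masses = np.asarray(masses, dtype=np.float64)
        n = len(self.names)
        for arr_name in ("chain_ids", "residue_numbers", "residue_names",
                         "elements", "vdw_radii", "masses"):
            if len(getattr(self, arr_name)) != n:
                raise DataError(f"AtomTable field {arr_name!r} has inconsistent length")
        if np.any(self.vdw_radii <= 0):
            bad = np.flatnonzero(self.vdw_radii <= 0)[:5].tolist()
            raise DataError(f"non-positive vdW radii at atom indices {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def record(self, i: int) -> AtomRecord:
        return AtomRecord(
            index=int(i),
            name=str(self.names[i]),
            chain_id=str(self.chain_ids[i]),
            residue_number=int(self.residue_numbers[i]),
            residue_name=str(self.residue_names[i]),
            element=str(self.elements[i]),
            vdw_radius=float(self.vdw_radii[i]),
            mass=float(self.masses[i]),
        )

    @property
    def records(self) -> list[AtomRecord]:
        return [self.record(i) for i in range(len(self))]

    def residue_ids(self) -> list[tuple[str, int, str]]:
        return [
            (str(c), int(n), str(r))
            for c, n, r in zip(self.chain_ids, self.residue_numbers, self.residue_names)
        ]

    @classmethod
    def from_elements(
        cls,
        elements: Sequence[str],
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int] | None = None,
        residue_names: Sequence[str] | None = None,
        names: Sequence[str] | None = None,
        radii: Mapping[str, float] | None = None,
        masses: Mapping[str, float] | None = None,
    ) -> "AtomTable":
        """Build a table from element symbols, looking up radii and masses."""
        radii = dict(VDW_RADII_NM if radii is None else radii)
        masses = dict(ATOMIC_MASSES if masses is None else masses)
        elements = [str(e).upper() for e in elements]
        unknown = sorted({e for e in elements if e not in radii})
        if unknown:
            raise UnknownElementError(f"no vdW radius for element(s): {unknown}")
        n = len(elements)
        if residue_numbers is None:
            residue_numbers = list(range(1, n + 1))
        if residue_names is None:
            residue_names = ["UNK"] * n
        if names is None:
            names = elements
        return cls(
            names=names,
            chain_ids=chain_ids,
            residue_numbers=residue_numbers,
            residue_names=residue_names,
            elements=elements,
            vdw_radii=[radii[e] for e in elements],
            masses=[masses.get(e, 0.0) for e in elements],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomTable):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("names", "chain_ids", "residue_numbers", "residue_names",
                      "elements", "vdw_radii", "masses")
        )


class ChainPartition:
    """Ordered, disjoint grouping of atom indices into named rigid domains.

    By default the groups are the protein chains; any grouping (dimers,
    structural domains, ...) can be supplied instead.
    """

    def __init__(self, groups: Mapping[str, Sequence[int]]):
        self._groups: dict[str, np.ndarray] = {
            str(name): np.asarray(idx, dtype=np.intp) for name, idx in groups.items()
        }
        seen: set[int] = set()
        for name, idx in self._groups.items():
            if idx.size == 0:
                raise DataError(f"partition group {name!r} is empty")
            s = set(idx.tolist())
            if len(s) != idx.size:
                raise DataError(f"partition group {name!r} has duplicate indices")
            if seen & s:
                raise DataError(f"partition group {name!r} overlaps another group")
            seen |= s

    @classmethod
    def from_chain_ids(cls, chain_ids: Sequence[str]) -> "ChainPartition":
        chain_ids = np.asarray(chain_ids)
        groups: dict[str, list[int]] = {}
        for i, c in enumerate(chain_ids):
            groups.setdefault(str(c), []).append(i)
        return cls(groups)

    @property
    def names(self) -> list[str]:
        return list(self._groups)

    @property
    def n_groups(self) -> int:
        return len(self._groups)

    def indices(self, name: str) -> np.ndarray:
        return self._groups[name]

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self._groups.items())

    def n_atoms(self) -> int:
        return sum(idx.size for idx in self._groups.values())

    def validate_cover(self, n_atoms: int) -> None:
        covered = np.concatenate([idx for idx in self._groups.values()])
        if covered.size != n_atoms or set(covered.tolist()) != set(range(n_atoms)):
            raise DataError(
                f"partition covers {covered.size} of {n_atoms} atoms; groups must "
                "be disjoint and cover every atom"
            )

    def group_index(self, n_atoms: int) -> np.ndarray:
        """Per-atom integer group label (position of the group in order)."""
        out = np.full(n_atoms, -1, dtype=np.intp)
        for g, (_, idx) in enumerate(self):
            out[idx] = g
        return out

    def to_dict(self) -> dict[str, list[int]]:
        return {name: idx.tolist() for name, idx in self}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChainPartition):
            return NotImplemented
        return self.names == other.names and all(
            np.array_equal(self.indices(n), other.indices(n)) for n in self.names
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t`` (t in nm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=np.float64))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise DataError("RigidTransform needs a 3x3 rotation and a 3-vector translation")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def is_proper(self, tol: float = 1e-8) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < tol
        )


@dataclass
class StructureFrame:
    """A single conformation: coordinates (nm) plus shared atom metadata."""

    coords: np.ndarray
    atoms: AtomTable
    partition: ChainPartition
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DataError("coords must be (N, 3)")
        if len(self.atoms) != self.coords.shape[0]:
            raise DataError("coords and atom table disagree on atom count")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("coords contain non-finite values")
        self.partition.validate_cover(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray, provenance: str | None = None) -> "StructureFrame":
        return StructureFrame(
            coords=np.asarray(coords, dtype=np.float64).reshape(self.coords.shape),
            atoms=self.atoms,
            partition=self.partition,
            provenance=self.provenance if provenance is None else provenance,
        )

    def copy(self) -> "StructureFrame":
        return replace(self, coords=self.coords.copy())


@dataclass
class Trajectory:
    """An ordered series of conformations over one shared atom table.

    ``provenance`` records what the coordinates represent:
    ``raw`` | ``tertiary_only`` | ``quaternary_only`` | ``synthetic`` |
    ``backprojected``.
    """

    coords: np.ndarray  # (F, N, 3), nm
    atoms: AtomTable
    partition: ChainPartition
    frame_times: np.ndarray | None = None  # ns
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("trajectory coords must be (F, N, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise DataError("trajectory coords and atom table disagree on atom count")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
            if self.frame_times.shape != (self.coords.shape[0],):
                raise DataError("frame_times length must equal frame count")
        self.partition.validate_cover(self.coords.shape[1])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureFrame:
        return StructureFrame(
            coords=self.coords[i].copy(),
            atoms=self.atoms,
            partition=self.partition,
            provenance=self.provenance,
        )

    @property
    def flat(self) -> np.ndarray:
        """Frames as (F, 3N) configuration vectors (view when possible)."""
        return self.coords.reshape(self.n_frames, -1)

    @classmethod
    def from_frames(
        cls, frames: Sequence[StructureFrame], provenance: str | None = None
    ) -> "Trajectory":
        if not frames:
            raise DataError("cannot build a trajectory from zero frames")
        first = frames[0]
        for f in frames[1:]:
            if f.atoms != first.atoms:
                raise DataError("all frames must share one atom table")
        return cls(
            coords=np.stack([f.coords for f in frames]),
            atoms=first.atoms,
            partition=first.partition,
            provenance=first.provenance if provenance is None else provenance,
        )


def concatenate_trajectories(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate trajectories sharing one atom table, in the given order."""
    if not trajs:
        raise DataError("nothing to concatenate")
    first = trajs[0]
    for t in trajs[1:]:
        if t.atoms != first.atoms:
            raise DataError("trajectories must share one atom table")
    return Trajectory(
        coords=np.concatenate([t.coords for t in trajs], axis=0),
        atoms=first.atoms,
        partition=first.partition,
        provenance=first.provenance,
    )


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal proper rigid transform mapping ``mobile`` onto ``target``.

    Minimises the weighted RMSD ``sum_i w_i |R x_i + t - y_i|^2`` over
    proper rotations R and translations t (the Kabsch algorithm with the
    determinant correction; a reflection is never returned).

    Parameters
    ----------
    mobile, target : (N, 3) arrays, N >= 3, non-collinear.
    weights : optional non-negative per-atom weights, not all zero.
        Uniform weights reproduce the unweighted fit.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DataError("kabsch_fit: mobile and target must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"kabsch_fit needs >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,):
            raise DataError("weights must be a length-N vector")
        if np.any(w < 0):
            raise DataError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise DataError("weights must not all be zero")
        w = w / total

    mc = w @ mobile
    tc = w @ target
    dm = mobile - mc
    dt = target - tc
    h = (w[:, None] * dm).T @ dt
    u, s, vt = np.linalg.svd(h)
    scale = float(np.sqrt((w @ (dm * dm).sum(axis=1)) * (w @ (dt * dt).sum(axis=1))))
    # The rotation is undetermined if either cloud is (near-)collinear or
    # coincident: the cross-covariance then has rank <= 1.
    if s[1] <= 1e-10 * max(s[0], 1e-300) or scale == 0.0:
        raise DegenerateGeometryError(
            "kabsch_fit: degenerate (collinear or coincident) point cloud"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - r @ mc
    return RigidTransform(r, t)


def apply_transform(
    frame_coords: np.ndarray,
    transform: RigidTransform,
    subset: np.ndarray | Sequence[int] | None = None,
) -> np.ndarray:
    """Apply a rigid transform to a subset of atoms (all atoms by default).

    Coordinates outside ``subset`` are returned unchanged.
    """
    coords = np.asarray(frame_coords, dtype=np.float64).copy()
    if subset is None:
        return transform.apply(coords)
    subset = np.asarray(subset, dtype=np.intp)
    if subset.size == 0:
        raise DataError("apply_transform: subset must be non-empty")
    coords[subset] = transform.apply(coords[subset])
    return coords


def count_heavy_atoms(
    frame: StructureFrame | AtomTable,
    selection: str = "default",
) -> int:
    """Count non-hydrogen atoms under a named selection policy.

    Policies
    --------
    ``default``
        Protein plus prosthetic groups (e.g. heme): every atom except
        solvent residues, free monatomic ions and hydrogen/deuterium.
        This is the selection under which the hemoglobin T-state tetramer
        (PDB 2HHB) counts 4556 atoms.
    ``all``
        Every non-hydrogen atom regardless of residue.
    """
    atoms = frame.atoms if isinstance(frame, StructureFrame) else frame
    known = set(VDW_RADII_NM) | {"D"}
    unknown_mask = ~np.isin(atoms.elements, sorted(known))
    if np.any(unknown_mask):
        offending = [
            f"{atoms.chain_ids[i]}/{atoms.residue_names[i]}{atoms.residue_numbers[i]}/"
            f"{atoms.names[i]} (element {atoms.elements[i]!r})"
            for i in np.flatnonzero(unknown_mask)[:10]
        ]
        raise UnknownElementError("unknown element symbol for atoms: " + ", ".join(offending))
    heavy = ~np.isin(atoms.elements, ["H", "D"])
    if selection == "all":
        return int(heavy.sum())
    if selection == "default":
        resn = np.char.upper(atoms.residue_names)
        excluded = np.isin(resn, sorted(SOLVENT_RESIDUES | ION_RESIDUES))
        return int((heavy & ~excluded).sum())
    raise DataError(f"unknown selection policy {selection!r}")
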