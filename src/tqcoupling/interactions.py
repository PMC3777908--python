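"""Inter-chain van der Waals overlap scoring and contact classification.

For every unordered atom pair on *different* chains the penetration of
the two van der Waals spheres is ``p_ij = max(0, r_i + r_j - d_ij)``;
the summed penetration is a length in nm measuring how sterically
unfavourable a structure is.  Intra-chain pairs are never counted.
A full-dimensional physical structure is expected to score zero; the
backprojected structures of the coupling plane, being two-dimensional
reductions of the motion, generally do not.

Contacts are residue pairs on different chains with any heavy-atom pair
closer than a cutoff (0.3 nm by default).  Profiled along the L-shaped
cQ -> cTew path, contacts fall into mechanistic classes:

* ``pulling``  — present near both end states, broken in the artificial
  off-diagonal intermediate (the elbow): an attractive interaction that
  only survives if local and global motion advance together.
* ``pushing``  — formed only in the elbow: a steric/repulsive clash that
  the coupled motion avoids.
* ``switching`` — a residue trades its contact partner between the two
  end states.
* ``static``   — present along the whole path.
* ``other``    — remaining patterns.

Neighbor search uses a k-d tree; an all-pairs search over the same
distances gives identical results (this equivalence is enforced in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, DataError
from .geometry import ChainPartition, StructureFrame
from .plane import GridPath

__all__ = [
    "OverlapReport",
    "ContactRecord",
    "vdw_overlap",
    "overlap_surface",
    "find_contacts",
    "contact_profile",
    "classify_contacts",
]

ResidueId = tuple[str, int, str]


@dataclass
class OverlapReport:
    """Summed inter-chain vdW sphere penetrations of one structure.

    ``total_overlap`` counts each unordered pair once by default; with
    ``double_count=True`` in :func:`vdw_overlap` every atom accumulates
    the full penetration of each of its pairs (the per-atom accounting),
    which doubles the total.
    """

    total_overlap: float
    per_atom: np.ndarray
    pairs: np.ndarray  # (P, 2) atom indices, i < j
    penetrations: np.ndarray  # (P,)


@dataclass
class ContactRecord:
    """An inter-chain residue pair and its presence along a path."""

    residue_a: ResidueId
    residue_b: ResidueId
    presence: np.ndarray
    contact_class: str = "other"

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool).reshape(-1)
        if self.residue_a[0] == self.residue_b[0]:
            raise DataError("contact residues must lie on distinct chains")


def _inter_chain_pairs(
    coords: np.ndarray,
    group_index: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """Atom pairs (i < j) on different chains closer than ``cutoff``."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    keep = group_index[pairs[:, 0]] != group_index[pairs[:, 1]]
    return pairs[keep]


def vdw_overlap(
    frame: StructureFrame,
    partition: ChainPartition | None = None,
    double_count: bool = False,
) -> OverlapReport:
    """Inter-chain van der Waals overlap of one structure.

    Uses a k-d tree with search radius ``2 * max(radius)`` — no pair with
    a positive penetration can be farther apart than the sum of two
    radii, so the accelerated search is exhaustive for this score.
    """
    if partition is None:
        partition = frame.partition
    if partition.n_groups < 2:
        raise DataError("vdw_overlap needs at least 2 chains")
    radii = frame.atoms.vdw_radii
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[:5]
        names = [
            f"{frame.atoms.chain_ids[i]}/{frame.atoms.names[i]}" for i in bad
        ]
        raise DataError(f"missing or invalid vdW radius for atoms {names}")
    group = partition.group_index(frame.n_atoms)
    pairs = _inter_chain_pairs(frame.coords, group, 2.0 * float(radii.max()))
    per_atom = np.zeros(frame.n_atoms)
    if pairs.shape[0] == 0:
        return OverlapReport(0.0, per_atom, pairs, np.zeros(0))
    d = np.linalg.norm(frame.coords[pairs[:, 0]] - frame.coords[pairs[:, 1]], axis=1)
    pen = radii[pairs[:, 0]] + radii[pairs[:, 1]] - d
    keep = pen > 0
    pairs, pen = pairs[keep], pen[keep]
    np.add.at(per_atom, pairs[:, 0], pen)
    np.add.at(per_atom, pairs[:, 1], pen)
    total = float(per_atom.sum()) if double_count else float(pen.sum())
    return OverlapReport(total, per_atom, pairs, pen)


def overlap_surface(
    grid_structures: list[list[StructureFrame]],
    partition: ChainPartition | None = None,
    double_count: bool = False,
) -> np.ndarray:
    """Total inter-chain overlap (nm) for every cell of a structure grid."""
    return np.array(
        [
            [vdw_overlap(s, partition, double_count).total_overlap for s in row]
            for row in grid_structures
        ]
    )


def find_contacts(
    frame: StructureFrame,
    partition: ChainPartition | None = None,
    cutoff: float = 0.3,
) -> set[tuple[ResidueId, ResidueId]]:
    """Residue pairs on different chains with any atom pair below cutoff.

    Contacts are computed on the atoms present in the frame (heavy atoms
    under the default loaders).  Each pair is reported once, ordered by
    residue id.
    """
    if cutoff <= 0:
        raise ConfigError("contact cutoff must be > 0")
    if partition is None:
        partition = frame.partition
    group = partition.group_index(frame.n_atoms)
    pairs = _inter_chain_pairs(frame.coords, group, cutoff)
    if pairs.shape[0] == 0:
        return set()
    # query_pairs uses strict d < r only at exact ties?  cKDTree includes
    # boundary points; enforce the strict "closer than" criterion here.
    d = np.linalg.norm(frame.coords[pairs[:, 0]] - frame.coords[pairs[:, 1]], axis=1)
    pairs = pairs[d < cutoff]
    rids = frame.atoms.residue_ids()
    out: set[tuple[ResidueId, ResidueId]] = set()
    for i, j in pairs:
        a, b = rids[i], rids[j]
        out.add((a, b) if a <= b else (b, a))
    return out


def contact_profile(
    path: GridPath,
    partition: ChainPartition | None = None,
    cutoff: float = 0.3,
) -> list[ContactRecord]:
    """Presence profile along a path for every contact seen anywhere on it."""
    if len(path) == 0:
        raise DataError("contact_profile needs a non-empty path")
    per_cell = [find_contacts(s, partition, cutoff) for s in path.structures]
    seen: dict[tuple[ResidueId, ResidueId], np.ndarray] = {}
    for k, contacts in enumerate(per_cell):
        for pair in contacts:
            if pair not in seen:
                seen[pair] = np.zeros(len(path), dtype=bool)
            seen[pair][k] = True
    records = [
        ContactRecord(residue_a=a, residue_b=b, presence=pres)
        for (a, b), pres in sorted(seen.items())
    ]
    return records


def _segments(
    length: int,
    corner_index: int,
    end_width: int | None,
    elbow_halfwidth: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = end_width if end_width is not None else min(3, max(1, length // 3))
    lo = max(corner_index - elbow_halfwidth, w)
    hi = min(corner_index + elbow_halfwidth, length - w - 1)
    if 2 * w >= length or lo > hi:
        raise DataError(
            f"path of {length} cells too short for end width {w} and elbow "
            f"halfwidth {elbow_halfwidth}"
        )
    t_seg = np.arange(0, w)
    r_seg = np.arange(length - w, length)
    elbow = np.arange(lo, hi + 1)
    return t_seg, elbow, r_seg


def classify_contacts(
    records: list[ContactRecord],
    path: GridPath,
    end_width: int | None = None,
    elbow_halfwidth: int = 2,
) -> list[ContactRecord]:
    """Assign a mechanistic class to each contact record (in place).

    The path is split into a T-end segment, an elbow segment around the
    corner cell, and an R-end segment; widths are configurable because
    only the qualitative scheme is fixed.  Precedence: static > pulling >
    pushing > switching > other.
    """
    length = len(path)
    t_seg, elbow, r_seg = _segments(length, path.corner_index, end_width, elbow_halfwidth)

    # partner sets per residue at the two ends, for the switching class
    partners_t: dict[ResidueId, set[ResidueId]] = {}
    partners_r: dict[ResidueId, set[ResidueId]] = {}
    for rec in records:
        if rec.presence[t_seg].any():
            partners_t.setdefault(rec.residue_a, set()).add(rec.residue_b)
            partners_t.setdefault(rec.residue_b, set()).add(rec.residue_a)
        if rec.presence[r_seg].any():
            partners_r.setdefault(rec.residue_a, set()).add(rec.residue_b)
            partners_r.setdefault(rec.residue_b, set()).add(rec.residue_a)

    def is_switching_residue(res: ResidueId) -> bool:
        pt, pr = partners_t.get(res), partners_r.get(res)
        return bool(pt) and bool(pr) and pt != pr

    for rec in records:
        at_t = bool(rec.presence[t_seg].any())
        at_r = bool(rec.presence[r_seg].any())
        in_elbow = bool(rec.presence[elbow].any())
        if rec.presence.all():
            rec.contact_class = "static"
        elif at_t and at_r and not in_elbow:
            rec.contact_class = "pulling"
        elif in_elbow and not at_t and not at_r:
            rec.contact_class = "pushing"
        elif (at_t != at_r) and (
            is_switching_residue(rec.residue_a) or is_switching_residue(rec.residue_b)
        ):
            rec.contact_class = "switching"
        else:
            rec.contact_class = "other"
    return records
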