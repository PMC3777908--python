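"""Orthogonal separation of tertiary and quaternary motions.

Given a trajectory, a reference structure and a chain partition, every
frame is split into

* a **tertiary-only** frame: each chain least-squares superposed onto its
  reference chain, so the chains keep all internal fluctuations but share
  the reference centre of mass and orientation, and
* a **quaternary-only** frame: rigid copies of the reference chains posed
  at the per-chain least-squares fit onto the raw frame, so all internal
  coordinates equal the reference in every frame.

The per-frame, per-chain rigid transforms (poses) are stored at
decomposition time; applying the pose of a chain to its tertiary-only
coordinates reproduces the raw frame to machine precision, i.e. the
decomposition is exactly invertible.

At linear order around the reference the two subspaces are orthogonal:
Kabsch optimality makes every tertiary-only displacement exactly
orthogonal to the fitted chain's six rigid-body basis vectors, while the
quaternary-only displacements lie in the span of those vectors.  For a
4-chain system the tertiary subspace has 3N-24 degrees of freedom and the
quaternary subspace 24, of which 6 global ones are removed before any
covariance analysis, leaving 18.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .geometry import (
    ChainPartition,
    RigidTransform,
    StructureFrame,
    Trajectory,
    kabsch_fit,
)

__all__ = [
    "DecomposedTrajectory",
    "decompose",
    "tertiary_only",
    "quaternary_only",
    "recombine",
    "remove_global_fit",
    "chain_rigid_basis",
]


@dataclass
class DecomposedTrajectory:
    """Paired tertiary-only and quaternary-only trajectories plus poses.

    ``pose_rotations[f, c]`` / ``pose_translations[f, c]`` map the
    reference chain ``c`` onto its position in raw frame ``f``.
    """

    tertiary: Trajectory
    quaternary: Trajectory
    pose_rotations: np.ndarray  # (F, C, 3, 3)
    pose_translations: np.ndarray  # (F, C, 3)
    reference: StructureFrame

    def pose(self, frame_index: int, chain: int | str) -> RigidTransform:
        if isinstance(chain, str):
            chain = self.reference.partition.names.index(chain)
        return RigidTransform(
            self.pose_rotations[frame_index, chain],
            self.pose_translations[frame_index, chain],
        )

    @property
    def n_frames(self) -> int:
        return self.tertiary.n_frames


def _check_compatible(
    traj: Trajectory, reference: StructureFrame, partition: ChainPartition
) -> None:
    if traj.n_atoms != reference.n_atoms:
        raise DataError("trajectory and reference disagree on atom count")
    partition.validate_cover(traj.n_atoms)
    for name, idx in partition:
        if idx.size < 3:
            raise DataError(f"chain {name!r} has fewer than 3 atoms; cannot superpose")


def decompose(
    traj: Trajectory,
    reference: StructureFrame | None = None,
    partition: ChainPartition | None = None,
    weights: np.ndarray | None = None,
) -> DecomposedTrajectory:
    """Split a trajectory into tertiary-only and quaternary-only parts.

    ``reference`` defaults to the first frame; ``partition`` defaults to
    the trajectory's own partition.  ``weights`` (e.g. masses) are used
    for the per-chain superpositions; the default is unweighted fitting
    of all atoms.
    """
    if reference is None:
        reference = traj.frame(0)
    if partition is None:
        partition = traj.partition
    _check_compatible(traj, reference, partition)

    f_count, n_atoms = traj.n_frames, traj.n_atoms
    c_count = partition.n_groups
    tert = np.empty_like(traj.coords)
    quat = np.empty_like(traj.coords)
    rot = np.empty((f_count, c_count, 3, 3))
    trans = np.empty((f_count, c_count, 3))

    ref = reference.coords
    for c, (_, idx) in enumerate(partition):
        ref_chain = ref[idx]
        w = None if weights is None else weights[idx]
        for f in range(f_count):
            raw_chain = traj.coords[f, idx]
            to_ref = kabsch_fit(raw_chain, ref_chain, weights=w)
            tert[f, idx] = to_ref.apply(raw_chain)
            pose = to_ref.inverse()
            quat[f, idx] = pose.apply(ref_chain)
            rot[f, c] = pose.rotation
            trans[f, c] = pose.translation

    tertiary = Trajectory(
        coords=tert, atoms=traj.atoms, partition=partition,
        frame_times=traj.frame_times, provenance="tertiary_only",
    )
    quaternary = Trajectory(
        coords=quat, atoms=traj.atoms, partition=partition,
        frame_times=traj.frame_times, provenance="quaternary_only",
    )
    return DecomposedTrajectory(
        tertiary=tertiary,
        quaternary=quaternary,
        pose_rotations=rot,
        pose_translations=trans,
        reference=reference,
    )


def tertiary_only(
    traj: Trajectory,
    reference: StructureFrame | None = None,
    partition: ChainPartition | None = None,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory with every chain superposed onto its reference chain."""
    return decompose(traj, reference, partition, weights).tertiary


def quaternary_only(
    traj: Trajectory,
    reference: StructureFrame | None = None,
    partition: ChainPartition | None = None,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory of rigid reference chains posed at the per-frame fits."""
    return decompose(traj, reference, partition, weights).quaternary


def recombine(decomposed: DecomposedTrajectory, frame_index: int) -> StructureFrame:
    """Reassemble the raw frame from its tertiary part and stored poses.

    Exact by construction: the pose is the stored inverse of the fit used
    to produce the tertiary-only coordinates.
    """
    if not 0 <= frame_index < decomposed.n_frames:
        raise DataError(f"frame index {frame_index} out of range")
    coords = decomposed.tertiary.coords[frame_index].copy()
    for c, (_, idx) in enumerate(decomposed.reference.partition):
        coords[idx] = decomposed.pose(frame_index, c).apply(coords[idx])
    return StructureFrame(
        coords=coords,
        atoms=decomposed.tertiary.atoms,
        partition=decomposed.reference.partition,
        provenance="raw",
    )


def remove_global_fit(
    traj: Trajectory,
    reference: StructureFrame | None = None,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Least-squares fit every frame as a whole onto the reference.

    Removes the six global rigid-body degrees of freedom before any
    covariance analysis.
    """
    if reference is None:
        reference = traj.frame(0)
    if traj.n_atoms != reference.n_atoms:
        raise DataError("trajectory and reference disagree on atom count")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        tr = kabsch_fit(traj.coords[f], reference.coords, weights=weights)
        out[f] = tr.apply(traj.coords[f])
    return Trajectory(
        coords=out, atoms=traj.atoms, partition=traj.partition,
        frame_times=traj.frame_times, provenance=traj.provenance,
    )


def chain_rigid_basis(
    reference: StructureFrame,
    partition: ChainPartition | None = None,
) -> np.ndarray:
    """Orthonormal basis of the per-chain rigid-body subspace.

    Returns a ``(6 C, 3 N)`` array whose rows span, for each chain, the
    three translations and the three infinitesimal rotations about the
    chain centroid, evaluated at the reference geometry.  Rows belonging
    to different chains have disjoint support and are exactly orthogonal.
    """
    if partition is None:
        partition = reference.partition
    n = reference.n_atoms
    rows: list[np.ndarray] = []
    for _, idx in partition:
        chain = reference.coords[idx]
        centered = chain - chain.mean(axis=0)
        block: list[np.ndarray] = []
        for ax in range(3):  # translations
            v = np.zeros((len(idx), 3))
            v[:, ax] = 1.0
            block.append(v)
        for ax in range(3):  # infinitesimal rotations about the centroid
            e = np.zeros(3)
            e[ax] = 1.0
            block.append(np.cross(e, centered))
        # Gram-Schmidt within the chain block (translations are already
        # orthonormal and orthogonal to the centred rotation generators).
        ortho: list[np.ndarray] = []
        for v in block:
            v = v.reshape(-1)
            for u in ortho:
                v = v - (u @ v) * u
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                ortho.append(v / norm)
        for v in ortho:
            full = np.zeros((n, 3))
            full[idx] = v.reshape(-1, 3)
            rows.append(full.reshape(-1))
    return np.array(rows)
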