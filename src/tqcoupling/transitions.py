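"""T -> R transition detection and the crystallographic difference mode.

The difference vector between two end-state structures (after globally
fitting R onto T) is normalised into a collective mode and decomposed —
with the same per-chain machinery used for trajectories — into a
tertiary-only and a quaternary-only component.  Trajectories are
projected onto the full difference vector; a trajectory whose projection
at any time covers at least 80% of the T-to-R distance counts as a
transition.  Among transition trajectories, ones covering a far larger
range than the rest would dominate any covariance analysis despite their
low statistical weight; a configurable median/MAD rule flags them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import quaternary_only, tertiary_only
from .errors import ConfigError, DataError
from .geometry import ChainPartition, StructureFrame, Trajectory, kabsch_fit
from .modes import CollectiveMode

__all__ = [
    "DifferenceMode",
    "TransitionVerdict",
    "tr_difference",
    "detect_transition",
    "flag_outliers",
]


@dataclass
class DifferenceMode:
    """Normalised T->R difference vector and its two components.

    ``span`` is the distance (nm) between the T- and R-state projections
    on the full difference vector, i.e. the norm of the fitted difference.
    A component that vanishes (pure-tertiary or pure-quaternary
    difference) is stored as ``None``.
    """

    full: CollectiveMode
    tertiary_component: CollectiveMode | None
    quaternary_component: CollectiveMode | None
    span: float
    t_state: StructureFrame


@dataclass
class TransitionVerdict:
    """Peak covered fraction of the T-to-R distance for one trajectory."""

    is_transition: bool
    max_fraction: float
    frame_of_max: int


def _single_frame_traj(frame: StructureFrame) -> Trajectory:
    return Trajectory(
        coords=frame.coords[None],
        atoms=frame.atoms,
        partition=frame.partition,
        provenance="raw",
    )


def tr_difference(
    t_state: StructureFrame,
    r_state: StructureFrame,
    partition: ChainPartition | None = None,
    zero_tol: float = 1e-9,
) -> DifferenceMode:
    """Difference mode between two end states, decomposed T/Q-wise.

    The R-state is globally fitted onto the T-state first.  The tertiary
    component is the (normalised) difference between the per-chain-fitted
    R-state and T; the quaternary component is the difference between the
    rigidly re-posed T chains and T.
    """
    if t_state.n_atoms != r_state.n_atoms:
        raise DataError("T- and R-state structures disagree on atom count")
    if partition is None:
        partition = t_state.partition
    fit = kabsch_fit(r_state.coords, t_state.coords)
    r_fitted = r_state.with_coords(fit.apply(r_state.coords))
    d_full = r_fitted.flat - t_state.flat
    span = float(np.linalg.norm(d_full))
    if span <= zero_tol:
        raise DataError("T- and R-state structures are identical: zero difference vector")

    r_traj = _single_frame_traj(r_fitted)
    d_tert = tertiary_only(r_traj, t_state, partition).flat[0] - t_state.flat
    d_quat = quaternary_only(r_traj, t_state, partition).flat[0] - t_state.flat

    def _mode(vec: np.ndarray, role: str) -> CollectiveMode | None:
        norm = np.linalg.norm(vec)
        if norm <= zero_tol * max(span, 1.0):
            return None
        return CollectiveMode(vector=vec, role=role, origin=t_state.flat)

    return DifferenceMode(
        full=CollectiveMode(vector=d_full, role="TR_full", origin=t_state.flat),
        tertiary_component=_mode(d_tert, "TR_tertiary"),
        quaternary_component=_mode(d_quat, "TR_quaternary"),
        span=span,
        t_state=t_state,
    )


def detect_transition(
    traj: Trajectory,
    diff: DifferenceMode,
    threshold: float = 0.8,
) -> TransitionVerdict:
    """Peak covered fraction of the T-to-R distance along a trajectory.

    Every frame is globally fitted onto the T-state internally, so the
    verdict is invariant under rigid motion of the whole trajectory.
    The fraction at frame t is ``(proj(x_t) - proj(T)) / (proj(R) -
    proj(T))`` on the full difference vector; it can exceed 1.
    """
    if not threshold > 0:
        raise ConfigError("transition threshold must be > 0")
    if diff.span <= 0:
        raise DataError("difference mode has zero span")
    t_flat = diff.t_state.flat
    fractions = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fit = kabsch_fit(traj.coords[f], diff.t_state.coords)
        x = fit.apply(traj.coords[f]).reshape(-1)
        fractions[f] = ((x - t_flat) @ diff.full.vector) / diff.span
    imax = int(np.argmax(fractions))
    fmax = float(fractions[imax])
    return TransitionVerdict(
        is_transition=bool(fmax >= threshold),
        max_fraction=fmax,
        frame_of_max=imax,
    )


def flag_outliers(
    verdicts: list[TransitionVerdict],
    k: float = 5.0,
    min_margin: float = 0.05,
) -> list[int]:
    """Indices of transition trajectories covering an outlying range.

    Default rule: among transition trajectories, exclude those whose
    ``max_fraction`` exceeds the median by more than ``k`` times the
    median absolute deviation plus a small absolute margin (the margin
    keeps numerically-identical sets from self-excluding when the MAD is
    zero).  The rule is an explicit, configurable stand-in for a
    qualitative criterion and is logged by the pipeline.
    """
    if len(verdicts) < 3:
        raise DataError("flag_outliers needs at least 3 verdicts")
    trans_idx = [i for i, v in enumerate(verdicts) if v.is_transition]
    if not trans_idx:
        return []
    values = np.array([verdicts[i].max_fraction for i in trans_idx])
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    cut = med + k * mad + min_margin
    return [i for i, v in zip(trans_idx, values) if v > cut]
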