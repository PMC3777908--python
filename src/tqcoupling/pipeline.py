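"""End-to-end orchestration: decompose -> PCA -> FMA -> plane -> contacts.

:func:`run_pipeline` mirrors the analysis order of the coupling method:
separate local from global motions, reduce the quaternary motions to
their principal mode cQ, fit the tertiary coupling mode by PLS-FMA,
span the coupling plane, score vdW overlaps on the backprojected grid
and classify contacts along the cQ->cTew path.  Every stage logs its
parameter set; the outputs are a pure function of (inputs, config,
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tqio
from .decomposition import decompose, remove_global_fit
from .errors import ConfigError, DataError
from .geometry import StructureFrame, Trajectory, kabsch_fit
from .interactions import classify_contacts, contact_profile, overlap_surface
from .modes import (
    CollectiveMode,
    mode_overlap,
    pca,
    pls_fma,
    project,
    select_components,
)
from .plane import build_grid, grid_structures, path_from_anchors, project_plane
from .synthetic import SyntheticSpec, end_states, generate_ensemble
from .transitions import detect_transition, tr_difference

logger = logging.getLogger("tqcoupling")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``traj_path`` + ``t_state_path`` (+ optional ``r_state_path``)
    or ``synthetic`` (keyword arguments for
    :class:`~tqcoupling.synthetic.SyntheticSpec`) must be provided.
    Defaults follow the published analysis parameters: 0.3 nm contact
    cutoff, 80% transition criterion, 20 x 20 grid.
    """

    out_dir: str = "tqcoupling_out"
    traj_path: str | None = None
    t_state_path: str | None = None
    r_state_path: str | None = None
    synthetic: dict | None = None
    seed: int = 0
    contact_cutoff: float = 0.3
    transition_threshold: float = 0.8
    grid_n: int = 20
    k_max: int = 15
    n_components: int | None = None  # None -> cross-validated choice
    #: number of independent synthetic transition trajectories to
    #: concatenate (model half / validation half both then contain full
    #: transitions, as in an ensemble of transition simulations)
    synthetic_segments: int = 2

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "transition_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.grid_n < 2 or self.k_max < 1:
            raise ConfigError("grid_n must be >= 2 and k_max >= 1")
        if self.synthetic is None and (self.traj_path is None or self.t_state_path is None):
            raise ConfigError("provide traj_path and t_state_path, or synthetic")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    config: RunConfig
    reference: StructureFrame
    r_state: StructureFrame | None
    decomposed: object
    pca_result: object
    fma_model: object
    cq: CollectiveMode
    ct: CollectiveMode
    ctew: CollectiveMode
    overlap_matrix: pd.DataFrame
    overlap_grid: np.ndarray
    contacts: list
    verdict: object | None
    k_best: int
    artifacts: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
        logger.info(
            "stage=input synthetic=%s segments=%d",
            dataclasses.asdict(spec), config.synthetic_segments,
        )
        traj, _ = generate_ensemble(spec, config.synthetic_segments)
        t_state, r_state = end_states(spec)
        return traj, t_state, r_state
    logger.info(
        "stage=input traj=%s sha=%s t_state=%s sha=%s",
        config.traj_path, _sha256(config.traj_path),
        config.t_state_path, _sha256(config.t_state_path),
    )
    traj = tqio.load_trajectory(config.traj_path)
    t_state = tqio.read_structure(config.t_state_path)
    r_state = (
        tqio.read_structure(config.r_state_path)
        if config.r_state_path is not None
        else None
    )
    return traj, t_state, r_state


def _mode_overlap_table(modes: dict[str, CollectiveMode | None]) -> pd.DataFrame:
    names = [k for k, v in modes.items() if v is not None]
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            table.loc[a, b] = mode_overlap(modes[a], modes[b])
    return table


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full coupling analysis and write the report bundle.

    Artifacts written to ``config.out_dir``: tertiary/quaternary
    trajectory containers plus a pose table, the cQ/cT/cTew mode vectors,
    a per-frame projection table with split-half correlations, the mutual
    mode-overlap matrix, the vdW overlap grid and the classified contact
    table.  Any stage failure aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "input"
    try:
        traj, t_state, r_state = _load_inputs(config)

        stage = "decompose"
        logger.info("stage=decompose frames=%d atoms=%d", traj.n_frames, traj.n_atoms)
        dec = decompose(traj, t_state)
        tqio.save_trajectory(dec.tertiary, out / "tertiary.npz")
        tqio.save_trajectory(dec.quaternary, out / "quaternary.npz")
        artifacts["tertiary"] = out / "tertiary.npz"
        artifacts["quaternary"] = out / "quaternary.npz"
        pose_rows = []
        from scipy.spatial.transform import Rotation

        for f in range(dec.n_frames):
            for c, name in enumerate(t_state.partition.names):
                quat = Rotation.from_matrix(dec.pose_rotations[f, c]).as_quat()
                pose_rows.append(
                    [f, name, *quat, *dec.pose_translations[f, c]]
                )
        pd.DataFrame(
            pose_rows,
            columns=["frame", "chain", "qx", "qy", "qz", "qw", "tx", "ty", "tz"],
        ).to_csv(out / "poses.csv", index=False)
        artifacts["poses"] = out / "poses.csv"

        stage = "pca"
        quat_fit = remove_global_fit(dec.quaternary, t_state)
        pca_res = pca(quat_fit)
        logger.info(
            "stage=pca first_mode_variance_fraction=%.3f",
            float(pca_res.explained_fraction[0]),
        )
        cq = CollectiveMode(pca_res.eigenvectors[0], role="cQ", origin=t_state.flat)

        stage = "fma"
        target = project(quat_fit, cq)
        if config.n_components is None:
            k_best, cv_curve = select_components(dec.tertiary, target, config.k_max)
        else:
            k_best, cv_curve = config.n_components, np.array([])
        model = pls_fma(dec.tertiary, target, k_best, refit_on_full=True)
        logger.info(
            "stage=fma k_best=%d fit_r=%.3f cv_r=%.3f", k_best, model.fit_r, model.cv_r
        )
        ct, ctew = model.mode_cT, model.mode_cTew
        for name, mode in (("cq", cq), ("ct", ct), ("ctew", ctew)):
            tqio.save_mode(mode, out / f"{name}.json")
            artifacts[name] = out / f"{name}.json"

        pred = model.predict(dec.tertiary)
        proj_df = pd.DataFrame(
            {
                "frame": np.arange(traj.n_frames),
                "target_cq_nm": target.values,
                "fma_model_nm": pred,
                "half": np.where(np.arange(traj.n_frames) < model.split_point, "fit", "validation"),
            }
        )
        proj_path = out / "projections.csv"
        with open(proj_path, "w") as fh:
            fh.write(f"# fit_r={model.fit_r:.6f} cv_r={model.cv_r:.6f} k={k_best}\n")
            proj_df.to_csv(fh, index=False)
        artifacts["projections"] = proj_path

        stage = "difference_modes"
        verdict = None
        modes_table: dict[str, CollectiveMode | None] = {
            "cQ": cq, "cT": ct, "cTew": ctew,
        }
        if r_state is not None:
            diff = tr_difference(t_state, r_state)
            modes_table.update(
                {
                    "T-R full": diff.full,
                    "T-R tertiary": diff.tertiary_component,
                    "T-R quaternary": diff.quaternary_component,
                }
            )
            verdict = detect_transition(traj, diff, config.transition_threshold)
            logger.info(
                "stage=transition max_fraction=%.3f is_transition=%s",
                verdict.max_fraction, verdict.is_transition,
            )
            pd.DataFrame(
                [[verdict.max_fraction, verdict.is_transition, verdict.frame_of_max]],
                columns=["max_fraction", "is_transition", "frame_of_max"],
            ).to_csv(out / "verdicts.csv", index=False)
            artifacts["verdicts"] = out / "verdicts.csv"
        overlap_tbl = _mode_overlap_table(modes_table)
        overlap_tbl.to_csv(out / "mode_overlaps.csv")
        artifacts["mode_overlaps"] = out / "mode_overlaps.csv"

        stage = "plane"
        anchors = {"T": t_state}
        if r_state is not None:
            # anchor the R-state after globally fitting it onto T
            r_fit = kabsch_fit(r_state.coords, t_state.coords)
            anchors["R"] = r_state.with_coords(r_fit.apply(r_state.coords))
        projection = project_plane(traj, cq, ctew, t_state, anchors=anchors)
        grid = build_grid(projection, config.grid_n)
        cells = grid_structures(grid, t_state)
        surface = overlap_surface(cells, t_state.partition)
        pd.DataFrame(surface).to_csv(out / "overlap_grid.csv", index=False)
        artifacts["overlap_grid"] = out / "overlap_grid.csv"
        plane_df = pd.DataFrame(projection.points, columns=["cq_nm", "ctew_nm"])
        plane_df.to_csv(out / "plane_projections.csv", index=False)
        artifacts["plane_projections"] = out / "plane_projections.csv"

        stage = "contacts"
        contacts = []
        if r_state is not None:
            path = path_from_anchors(grid, projection, t_state)
            records = contact_profile(path, t_state.partition, config.contact_cutoff)
            contacts = classify_contacts(records, path)
            rows = [
                [
                    rec.residue_a[0], rec.residue_a[1], rec.residue_a[2],
                    rec.residue_b[0], rec.residue_b[1], rec.residue_b[2],
                    "".join("1" if p else "0" for p in rec.presence),
                    rec.contact_class,
                ]
                for rec in contacts
            ]
            pd.DataFrame(
                rows,
                columns=["chain_a", "res_a", "name_a", "chain_b", "res_b",
                         "name_b", "presence", "class"],
            ).to_csv(out / "contacts.csv", index=False)
            artifacts["contacts"] = out / "contacts.csv"
            logger.info("stage=contacts path_cells=%d records=%d", len(path), len(contacts))

        (out / "config.json").write_text(config.to_json())
        artifacts["config"] = out / "config.json"
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        if isinstance(exc, (ConfigError, DataError)):
            raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
        raise DataError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        reference=t_state,
        r_state=r_state,
        decomposed=dec,
        pca_result=pca_res,
        fma_model=model,
        cq=cq,
        ct=ct,
        ctew=ctew,
        overlap_matrix=overlap_tbl,
        overlap_grid=surface,
        contacts=contacts,
        verdict=verdict,
        k_best=k_best,
        artifacts=artifacts,
    )
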