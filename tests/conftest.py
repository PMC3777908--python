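"""Shared fixtures: small synthetic systems and a full analysis chain."""

from __future__ import annotations

import numpy as np
import pytest

import tqcoupling as tq
from tqcoupling.synthetic import generate_ensemble


def make_frame(coords, chain_of, radii=0.15, elements=None):
    """Small ad-hoc structure: coords (N,3) nm, chain label per atom."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    chain_of = list(chain_of)
    elements = ["C"] * n if elements is None else list(elements)
    atoms = tq.AtomTable(
        names=["CA"] * n,
        chain_ids=chain_of,
        residue_numbers=list(range(1, n + 1)),
        residue_names=["UNK"] * n,
        elements=elements,
        vdw_radii=[radii] * n if np.isscalar(radii) else list(radii),
        masses=[12.0] * n,
    )
    return tq.StructureFrame(
        coords=coords,
        atoms=atoms,
        partition=tq.ChainPartition.from_chain_ids(chain_of),
    )


@pytest.fixture(scope="session")
def small_spec():
    return tq.SyntheticSpec(seed=11, n_frames=120, atoms_per_chain=20)


@pytest.fixture(scope="session")
def small_system(small_spec):
    traj, truth = tq.generate(small_spec)
    ref = tq.make_reference(small_spec)
    return {"spec": small_spec, "traj": traj, "truth": truth, "ref": ref}


@pytest.fixture(scope="session")
def ensemble_system():
    """Two concatenated 1000-frame transition trajectories of one system,
    decomposed, with PCA, the cQ target and a cross-validated FMA model —
    the full analysis chain computed once for the whole session."""
    spec = tq.SyntheticSpec(seed=1, n_frames=1000)
    traj, truths = generate_ensemble(spec, 2)
    ref = tq.make_reference(spec)
    t_state, r_state = tq.end_states(spec)
    dec = tq.decompose(traj, ref)
    qfit = tq.remove_global_fit(dec.quaternary, ref)
    pca_res = tq.pca(qfit)
    cq = tq.CollectiveMode(pca_res.eigenvectors[0], role="cQ", origin=ref.flat)
    target = tq.project(qfit, cq)
    k_best, cv_curve = tq.select_components(dec.tertiary, target, k_max=10)
    model = tq.pls_fma(dec.tertiary, target, k_best, refit_on_full=True)
    return {
        "spec": spec,
        "traj": traj,
        "truths": truths,
        "ref": ref,
        "t_state": t_state,
        "r_state": r_state,
        "dec": dec,
        "qfit": qfit,
        "pca": pca_res,
        "cq": cq,
        "target": target,
        "k_best": k_best,
        "cv_curve": cv_curve,
        "model": model,
    }


@pytest.fixture(scope="session")
def ensemble_plane(ensemble_system):
    """Plane projection, 20x20 grid and T->R path on the ensemble system."""
    s = ensemble_system
    projection = tq.project_plane(
        s["traj"], s["cq"], s["model"].mode_cTew, s["t_state"],
        anchors={"T": s["t_state"], "R": s["r_state"]},
    )
    grid = tq.build_grid(projection, 20)
    cells = tq.grid_structures(grid, s["t_state"])
    path = tq.path_from_anchors(grid, projection, s["t_state"])
    return {"projection": projection, "grid": grid, "cells": cells, "path": path}
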