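"""vdW overlap scoring, contact detection and mechanistic classification."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import tqcoupling as tq
from tqcoupling.errors import DataError
from tqcoupling.interactions import ContactRecord
from tqcoupling.plane import GridPath

from conftest import make_frame


def brute_force_overlap(frame, double_count=False):
    """All-pairs O(N^2) oracle for the inter-chain penetration sum."""
    group = frame.partition.group_index(frame.n_atoms)
    r = frame.atoms.vdw_radii
    d = cdist(frame.coords, frame.coords)
    total = 0.0
    for i in range(frame.n_atoms):
        for j in range(i + 1, frame.n_atoms):
            if group[i] == group[j]:
                continue
            pen = r[i] + r[j] - d[i, j]
            if pen > 0:
                total += 2 * pen if double_count else pen
    return total


def brute_force_contacts(frame, cutoff):
    """All-pairs oracle for residue contacts below the cutoff."""
    group = frame.partition.group_index(frame.n_atoms)
    rids = frame.atoms.residue_ids()
    d = cdist(frame.coords, frame.coords)
    out = set()
    for i in range(frame.n_atoms):
        for j in range(i + 1, frame.n_atoms):
            if group[i] != group[j] and d[i, j] < cutoff:
                a, b = rids[i], rids[j]
                out.add((a, b) if a <= b else (b, a))
    return out


def _random_touching_frame(seed, n=500):
    """Two random blobs close enough to interpenetrate."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.4, (n // 2, 3))
    b = rng.normal(0, 0.4, (n - n // 2, 3)) + np.array([0.7, 0.0, 0.0])
    return make_frame(np.vstack([a, b]), "A" * (n // 2) + "B" * (n - n // 2))


class TestVdwOverlap:
    def test_two_atom_penetration_arithmetic(self):
        frame = make_frame([[0, 0, 0], [0.20, 0, 0]], "AB", radii=0.15)
        rep = tq.vdw_overlap(frame)
        assert rep.total_overlap == pytest.approx(0.10, abs=1e-12)
        assert rep.per_atom[0] == pytest.approx(0.10, abs=1e-12)
        assert rep.per_atom[1] == pytest.approx(0.10, abs=1e-12)

    def test_clash_free_frame_scores_exactly_zero(self):
        frame = make_frame([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]], "ABB", radii=0.15)
        assert tq.vdw_overlap(frame).total_overlap == 0.0

    def test_intra_chain_pairs_never_counted(self):
        # both atoms of chain A overlap each other, not chain B
        frame = make_frame([[0, 0, 0], [0.1, 0, 0], [5.0, 0, 0]], "AAB", radii=0.15)
        assert tq.vdw_overlap(frame).total_overlap == 0.0

    def test_rigid_motion_leaves_total_unchanged(self):
        frame = _random_touching_frame(0, n=60)
        base = tq.vdw_overlap(frame).total_overlap
        rot = Rotation.from_rotvec([0.4, -1.0, 0.2]).as_matrix()
        moved = frame.with_coords(frame.coords @ rot.T + np.array([3.0, -1.0, 2.0]))
        assert tq.vdw_overlap(moved).total_overlap == pytest.approx(base, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        frame = _random_touching_frame(seed, n=500)
        assert tq.vdw_overlap(frame).total_overlap == pytest.approx(
            brute_force_overlap(frame), abs=1e-12
        )

    def test_double_count_mode_doubles_pair_total(self):
        frame = _random_touching_frame(2, n=100)
        single = tq.vdw_overlap(frame).total_overlap
        double = tq.vdw_overlap(frame, double_count=True).total_overlap
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_total_decreases_when_a_pair_separates(self):
        frame = make_frame([[0, 0, 0], [0.2, 0, 0], [0, 0.22, 0]], "ABB", radii=0.15)
        base = tq.vdw_overlap(frame).total_overlap
        wider = frame.with_coords(
            np.array([[0, 0, 0], [0.25, 0, 0], [0, 0.22, 0]])
        )
        assert tq.vdw_overlap(wider).total_overlap < base

    def test_single_chain_raises(self):
        frame = make_frame(np.eye(3), "AAA")
        with pytest.raises(DataError):
            tq.vdw_overlap(frame)


class TestOverlapSurface:
    def test_shape_matches_grid(self, ensemble_plane, ensemble_system):
        surf = tq.overlap_surface(ensemble_plane["cells"], ensemble_system["t_state"].partition)
        assert surf.shape == (20, 20)
        assert np.all(surf >= 0)

    def test_clash_free_grid_is_all_zero(self, toy_grid_structures):
        surf = tq.overlap_surface(toy_grid_structures)
        assert np.array_equal(surf, np.zeros_like(surf))

    def test_off_diagonal_corner_exceeds_diagonal(self, ensemble_plane, ensemble_system):
        """Overlap is minimal along the coupled (diagonal) motion and grows
        when the quaternary closing advances without the tertiary
        contraction (below-diagonal side)."""
        surf = tq.overlap_surface(ensemble_plane["cells"], ensemble_system["t_state"].partition)
        diag = np.array([surf[i, i] for i in range(20)])
        corner = surf[19, 0]
        assert np.all(corner > diag)  # sign test over 20 diagonal cells
        assert corner > 0


@pytest.fixture()
def toy_grid_structures():
    frame = make_frame([[0, 0, 0], [2.0, 0, 0]], "AB", radii=0.15)
    return [[frame, frame], [frame, frame]]


class TestFindContacts:
    def test_pair_inside_cutoff_detected(self):
        frame = make_frame([[0, 0, 0], [0.25, 0, 0]], "AB")
        contacts = tq.find_contacts(frame, cutoff=0.3)
        assert contacts == {(("A", 1, "UNK"), ("B", 2, "UNK"))}

    def test_pair_outside_cutoff_absent(self):
        frame = make_frame([[0, 0, 0], [0.35, 0, 0]], "AB")
        assert tq.find_contacts(frame, cutoff=0.3) == set()

    def test_invariant_under_rigid_motion(self):
        frame = _random_touching_frame(3, n=80)
        base = tq.find_contacts(frame, cutoff=0.3)
        rot = Rotation.from_euler("y", 70, degrees=True).as_matrix()
        moved = frame.with_coords(frame.coords @ rot.T + 1.0)
        assert tq.find_contacts(moved, cutoff=0.3) == base

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        frame = _random_touching_frame(seed, n=500)
        assert tq.find_contacts(frame, cutoff=0.3) == brute_force_contacts(frame, 0.3)


def _fake_path(length, corner):
    return GridPath(
        cells=[(min(i, corner), max(0, i - corner)) for i in range(length)],
        cell_coords=np.zeros((length, 2)),
        structures=[],
        corner_index=corner,
    )


def _record(pattern, res_a=("A", 1, "UNK"), res_b=("B", 1, "UNK")):
    return ContactRecord(
        residue_a=res_a, residue_b=res_b,
        presence=np.array([c == "1" for c in pattern]),
    )


class TestContactProfileAndClasses:
    def test_profile_lengths_and_reporting(self, ensemble_plane, ensemble_system):
        path = ensemble_plane["path"]
        records = tq.contact_profile(path, ensemble_system["t_state"].partition, 0.3)
        assert all(len(r.presence) == len(path) for r in records)
        assert all(r.presence.any() for r in records)  # never-seen pairs absent
        assert all(r.residue_a[0] != r.residue_b[0] for r in records)

    def test_always_present_is_static(self):
        path = _fake_path(7, 3)
        (rec,) = tq.classify_contacts([_record("1111111")], path)
        assert rec.contact_class == "static"

    def test_ends_only_pattern_is_pulling(self):
        path = _fake_path(7, 3)
        (rec,) = tq.classify_contacts([_record("1100011")], path)
        assert rec.contact_class == "pulling"

    def test_elbow_only_pattern_is_pushing(self):
        path = _fake_path(7, 3)
        (rec,) = tq.classify_contacts([_record("0011100")], path)
        assert rec.contact_class == "pushing"

    def test_partner_change_is_switching(self):
        path = _fake_path(7, 3)
        recs = [
            _record("1100000", ("A", 1, "UNK"), ("B", 1, "UNK")),
            _record("0000011", ("A", 1, "UNK"), ("B", 2, "UNK")),
        ]
        out = tq.classify_contacts(recs, path)
        assert [r.contact_class for r in out] == ["switching", "switching"]

    def test_isolated_one_sided_contact_is_other(self):
        path = _fake_path(7, 3)
        (rec,) = tq.classify_contacts([_record("1100000")], path)
        assert rec.contact_class == "other"

    def test_classification_invariant_under_path_reversal(self):
        """Reversing the path (swapping the T and R ends) preserves every
        class: pulling stays pulling, pushing stays pushing, the switching
        partners swap roles."""
        length, corner = 17, 8
        path = _fake_path(length, corner)
        rev_path = _fake_path(length, length - 1 - corner)
        recs = [
            _record("1" * 3 + "0" * 11 + "1" * 3, ("A", 1, "UNK"), ("B", 1, "UNK")),
            _record("0" * 7 + "111" + "0" * 7, ("A", 2, "UNK"), ("B", 2, "UNK")),
            _record("11" + "0" * 15, ("A", 3, "UNK"), ("B", 3, "UNK")),
            _record("0" * 15 + "11", ("A", 3, "UNK"), ("B", 4, "UNK")),
        ]
        fwd = tq.classify_contacts([ContactRecord(r.residue_a, r.residue_b, r.presence.copy()) for r in recs], path)
        rev = tq.classify_contacts(
            [ContactRecord(r.residue_a, r.residue_b, r.presence[::-1].copy()) for r in recs],
            rev_path,
        )
        assert [r.contact_class for r in fwd] == [r.contact_class for r in rev]
        assert [r.contact_class for r in fwd] == ["pulling", "pushing", "switching", "switching"]

    def test_too_short_path_raises(self):
        with pytest.raises(DataError, match="too short"):
            tq.classify_contacts([_record("11")], _fake_path(2, 1))
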