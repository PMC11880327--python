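"""Superposition, loop RMSD and the spline up-sampled distance."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tcrloops.geometry import (
    DistanceMatrix,
    GeometryError,
    LoopLengthError,
    UnderdeterminedError,
    loop_rmsd,
    pairwise_distance_matrix,
    superpose_by_anchors,
    upsampled_distance,
)

from conftest import make_loop, random_loop


def _rigidly_moved(loop, rotation: Rotation, translation):
    """Apply one rigid transform to anchors and loop alike."""
    moved = make_loop([r.backbone["CA"] for r in loop.loop_residues],
                      region=loop.region_name)
    for part in ("loop_residues", "anchor_residues"):
        for res_src, res_dst in zip(getattr(loop, part), getattr(moved, part)):
            for atom, coord in res_src.backbone.items():
                res_dst.backbone[atom] = rotation.apply(coord) + translation
    return moved


class TestSuperposition:
    def test_identity_for_identical_anchors(self):
        a = make_loop([(235 + i, 0, 3) for i in range(4)])
        sup = superpose_by_anchors(a, a)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(sup.translation, 0, atol=1e-10)
        assert sup.anchor_rmsd == pytest.approx(0, abs=1e-10)

    def test_recovers_exact_rigid_motion(self):
        reference = make_loop([(235 + i, 0, 3) for i in range(4)])
        rot = Rotation.from_euler("z", 90, degrees=True)
        mobile = _rigidly_moved(reference, rot, np.array([5.0, 0.0, 0.0]))
        sup = superpose_by_anchors(mobile, reference)
        assert sup.anchor_rmsd == pytest.approx(0, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        # transform inverts the motion: mobile anchors land on the reference
        for res_m, res_r in zip(mobile.anchor_residues, reference.anchor_residues):
            moved = sup.apply(np.array([res_m.backbone["CA"]]))[0]
            assert np.allclose(moved, res_r.backbone["CA"], atol=1e-6)

    def test_anchor_rmsd_matches_numeric_optimiser(self, rng):
        """Brute-force oracle: minimise anchor squared error over rotation
        vectors + translation with a generic optimiser."""
        reference = make_loop([(235 + i, 0, 3) for i in range(3)])
        mobile = make_loop([(235 + i, 0, 3) for i in range(3)])
        # displace one anchor atom of the mobile copy by 1 A
        mobile.anchor_residues[2].backbone["CA"] = (
            mobile.anchor_residues[2].backbone["CA"] + np.array([0, 1.0, 0])
        )
        sup = superpose_by_anchors(mobile, reference)

        pm = np.array([r.backbone[a] for r in mobile.anchor_residues
                       for a in ("N", "CA", "C", "O")])
        pr = np.array([r.backbone[a] for r in reference.anchor_residues
                       for a in ("N", "CA", "C", "O")])

        def cost(params):
            rot = Rotation.from_rotvec(params[:3])
            return np.mean(np.sum((rot.apply(pm) + params[3:] - pr) ** 2, axis=1))

        best = min(
            minimize(cost, np.concatenate([rng.normal(scale=0.1, size=3),
                                           rng.normal(scale=0.5, size=3)]),
                     method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000}).fun
            for _ in range(5)
        )
        assert sup.anchor_rmsd == pytest.approx(np.sqrt(best), abs=1e-4)

    def test_superposition_is_a_local_optimum(self, rng):
        a = random_loop(rng, 8)
        b = random_loop(rng, 8)
        sup = superpose_by_anchors(a, b)
        pm = np.array([r.backbone[at] for r in a.anchor_residues
                       for at in ("N", "CA", "C", "O")])
        pr = np.array([r.backbone[at] for r in b.anchor_residues
                       for at in ("N", "CA", "C", "O")])
        base = np.sum((sup.apply(pm) - pr) ** 2)
        for _ in range(100):
            perturbation = Rotation.from_rotvec(rng.normal(scale=1e-3, size=3))
            rotated = (perturbation.as_matrix() @ sup.rotation @ pm.T).T
            # re-centre optimally for the perturbed rotation
            shift = (pr - rotated).mean(axis=0)
            assert np.sum((rotated + shift - pr) ** 2) >= base - 1e-9

    def test_too_few_anchor_atoms_raises(self):
        a = make_loop([(240, 0, 3)])
        for res in a.anchor_residues[1:]:
            for atom in ("N", "CA", "C", "O"):
                res.backbone[atom] = None
        for atom in ("C", "O"):  # leave only two atoms in total
            a.anchor_residues[0].backbone[atom] = None
        with pytest.raises(UnderdeterminedError):
            superpose_by_anchors(a, make_loop([(240, 0, 3)]))

    def test_region_mismatch_raises(self):
        with pytest.raises(GeometryError):
            superpose_by_anchors(make_loop([(240, 0, 3)], region="CDR3"),
                                 make_loop([(70, 0, 3)], region="CDR1"))


class TestLoopRmsd:
    def test_identical_loops_zero(self):
        a = make_loop([(235 + 2 * i, 0, 4) for i in range(5)])
        assert loop_rmsd(a, a).value == pytest.approx(0, abs=1e-12)

    def test_uniform_translation_gives_exact_displacement(self):
        ca = [(235 + 2 * i, 0, 4) for i in range(5)]
        a = make_loop(ca)
        b = make_loop([(x, y, z + 2.0) for x, y, z in ca])
        dist = loop_rmsd(a, b)
        assert dist.value == pytest.approx(2.0, abs=1e-9)
        assert dist.kind == "rmsd_equal_length"

    def test_matches_hand_computed_arithmetic(self):
        ca_a = [(230.0, 0.0, 0.0), (234.0, 1.0, 2.0), (238.0, -1.0, 1.0)]
        ca_b = [(230.5, 0.0, 0.0), (234.0, 2.0, 2.0), (238.0, -1.0, 2.5)]
        a, b = make_loop(ca_a), make_loop(ca_b)
        # identical anchors so the superposition is the identity; every one
        # of the residue's four atoms shares its CA displacement
        sq = [0.5**2, 1.0**2, 1.5**2]
        expected = np.sqrt(sum(4 * s for s in sq) / 12)
        assert loop_rmsd(a, b).value == pytest.approx(expected, abs=1e-6)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(LoopLengthError):
            loop_rmsd(make_loop([(235, 0, 3), (237, 0, 3)]),
                      make_loop([(235, 0, 3), (236, 0, 3), (237, 0, 3)]))


class TestUpsampledDistance:
    def test_equal_length_equivalence(self, rng):
        for _ in range(25):
            length = int(rng.integers(3, 15))
            a, b = random_loop(rng, length), random_loop(rng, length)
            assert upsampled_distance(a, b).value == pytest.approx(
                loop_rmsd(a, b).value, abs=1e-9
            )

    def test_self_distance_zero_after_deletion(self, rng):
        full = random_loop(rng, 8)
        shorter = make_loop(
            [r.backbone["CA"] for i, r in enumerate(full.loop_residues) if i != 4]
        )
        assert upsampled_distance(shorter, shorter).value == pytest.approx(0, abs=1e-12)

    def test_matches_dense_resampling_oracle(self, rng):
        from tcrloops.geometry import _backbone_trace, _resample_trace, superpose_by_anchors

        from conftest import smooth_loop

        for _ in range(10):
            # two conformations of the same underlying smooth curve, about
            # an Angstrom apart: the regime the up-sampled distance serves
            amps = rng.normal(scale=2.0, size=(2, 3))
            a = smooth_loop(rng, 4, amplitudes=amps)
            b = smooth_loop(rng, 5, amplitudes=amps + rng.normal(scale=0.4, size=(2, 3)))
            value = upsampled_distance(a, b).value
            sup = superpose_by_anchors(a, b)
            dense_a = _resample_trace(sup.apply(_backbone_trace(a)), 1000)
            dense_b = _resample_trace(_backbone_trace(b), 1000)
            oracle = np.sqrt(np.mean(np.sum((dense_a - dense_b) ** 2, axis=1)))
            assert value == pytest.approx(oracle, abs=0.05)

    def test_too_short_loop_rejected(self):
        with pytest.raises(GeometryError):
            upsampled_distance(make_loop([(240, 0, 3)]), make_loop([(239, 0, 3), (241, 0, 3)]))


class TestDistanceProperties:
    def test_symmetry_both_kinds(self, rng):
        a, b = random_loop(rng, 9), random_loop(rng, 9)
        assert loop_rmsd(a, b).value == pytest.approx(loop_rmsd(b, a).value, abs=1e-9)
        c = random_loop(rng, 11)
        assert upsampled_distance(a, c).value == pytest.approx(
            upsampled_distance(c, a).value, abs=1e-9
        )

    def test_rigid_motion_invariance(self, rng):
        a = random_loop(rng, 7)
        b = random_loop(rng, 7)
        rot = Rotation.from_euler("xyz", [31.0, -54.0, 12.0], degrees=True)
        moved_b = _rigidly_moved(b, rot, np.array([3.0, -7.0, 11.0]))
        assert loop_rmsd(a, moved_b).value == pytest.approx(
            loop_rmsd(a, b).value, abs=1e-6
        )
        c = random_loop(rng, 9)
        assert upsampled_distance(moved_b, c).value == pytest.approx(
            upsampled_distance(b, c).value, abs=1e-6
        )


class TestPairwiseMatrix:
    def test_identical_loops_give_zero_matrix(self):
        a = make_loop([(235 + 2 * i, 0, 4) for i in range(5)])
        matrix = pairwise_distance_matrix([a, a, a], ids=["x", "y", "z"])
        assert np.allclose(matrix.values, 0, atol=1e-12)

    def test_translated_copy_pattern(self):
        ca = [(235 + 2 * i, 0, 4) for i in range(5)]
        a = make_loop(ca)
        b = make_loop([(x, y, z + 2.0) for x, y, z in ca])
        matrix = pairwise_distance_matrix([a, b, a])
        expected = np.array([[0, 2, 0], [2, 0, 2], [0, 2, 0]], dtype=float)
        assert np.allclose(matrix.values, expected, atol=1e-9)

    def test_planted_two_cluster_separation(self, rng):
        ca = [(235 + 2 * i, 0, 4) for i in range(5)]
        near = [make_loop(np.asarray(ca) + rng.normal(scale=0.05, size=(5, 3)))
                for _ in range(5)]
        far = [make_loop(np.asarray(ca) + np.array([0, 8.0, 0])
                         + rng.normal(scale=0.05, size=(5, 3)))
               for _ in range(5)]
        matrix = pairwise_distance_matrix(near + far)
        within = [matrix.values[i, j] for i in range(5) for j in range(5) if i != j]
        within += [matrix.values[i, j] for i in range(5, 10) for j in range(5, 10) if i != j]
        between = [matrix.values[i, j] for i in range(5) for j in range(5, 10)]
        assert max(within) < min(between)

    def test_mixed_region_rejected(self):
        with pytest.raises(GeometryError):
            pairwise_distance_matrix(
                [make_loop([(240, 0, 3)], region="CDR3"),
                 make_loop([(70, 0, 3)], region="CDR1")]
            )

    def test_csv_round_trip_is_bit_exact(self, tmp_path, rng):
        loops = [random_loop(rng, 6) for _ in range(4)]
        matrix = pairwise_distance_matrix(loops, ids=list("abcd"))
        path = tmp_path / "d.csv"
        matrix.to_csv(path)
        reread = DistanceMatrix.from_csv(path)
        assert reread.ids == matrix.ids
        assert np.array_equal(reread.values, matrix.values)
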