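import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lhlkit import geometry as geo
from lhlkit import structure_io as sio
from lhlkit import synthetic_data as synth

from conftest import build_structure
from oracles import (
    oracle_lhl_rmsd,
    oracle_pairwise_helix_rmsd,
    oracle_superpose_bruteforce,
    oracle_superpose_rmsd,
)


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


def translate_structure(s, shift, only=None):
    """Copy of s with residues in ``only`` (or all) translated by shift."""
    residues = []
    for r in s.residues:
        move = only is None or r.index in only
        residues.append(sio.Residue(
            index=r.index, aa=r.aa,
            coords={k: (v + shift if move else v.copy())
                    for k, v in r.coords.items()},
        ))
    return sio.BackboneStructure(id=s.id + "_t", residues=residues)


class TestSuperpose:
    def test_identical_sets_zero_rmsd_identity(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        tf, rmsd = geo.superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-8)

    def test_recovers_known_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, (12, 3))
        R, t = random_rigid(rng)
        tf, rmsd = geo.superpose(pts, pts @ R.T + t)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-6)
        np.testing.assert_allclose(tf.translation, t, atol=1e-6)

    def test_matches_bruteforce_on_hand_built_sets(self):
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 4.0]])
        b = np.array([[0.2, 0.1, 0], [2.9, -0.3, 0.4],
                      [-0.1, 2.2, 0.1], [1.3, 0.8, 3.7]])
        _, rmsd = geo.superpose(a, b)
        assert rmsd == pytest.approx(oracle_superpose_bruteforce(a, b),
                                     abs=1e-4)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-5, 5, (8, 3))
        b = a + rng.normal(0, 0.5, a.shape)
        _, rmsd0 = geo.superpose(a, b)
        R, t = random_rigid(rng)
        _, rmsd1 = geo.superpose(a @ R.T + t, b @ R.T + t)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_rejects_mismatched_or_tiny_inputs(self):
        with pytest.raises(ValueError):
            geo.superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            geo.superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_no_reflection(self):
        # a mirrored point set must not be matched by an improper rotation
        rng = np.random.default_rng(3)
        a = rng.uniform(-5, 5, (6, 3))
        mirrored = a * np.array([-1.0, 1.0, 1.0])
        tf, rmsd = geo.superpose(a, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-8)
        assert rmsd > 0.1


class TestHelixVector:
    def test_planted_centroid_and_axis(self, cohort_factory):
        for _, s, ann, truths in cohort_factory(3, seed=5, with_truth=True):
            for truth in truths:
                hv = geo.helix_vector(s, truth.helix_range)
                assert np.linalg.norm(hv.centroid - truth.centroid) < 0.5
                angle = math.degrees(math.acos(
                    np.clip(hv.direction @ truth.direction, -1, 1)))
                assert angle < 10.0

    def test_translation_equivariance(self, small_cohort):
        _, s, ann = small_cohort[0]
        shift = np.array([3.0, -2.0, 5.0])
        s2 = translate_structure(s, shift)
        h = ann.helices[0]
        v1, v2 = geo.helix_vector(s, h), geo.helix_vector(s2, h)
        np.testing.assert_allclose(v2.centroid, v1.centroid + shift, atol=1e-8)
        np.testing.assert_allclose(v2.direction, v1.direction, atol=1e-8)

    def test_rotation_equivariance(self, small_cohort):
        _, s, ann = small_cohort[0]
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        residues = [
            sio.Residue(index=r.index, aa=r.aa,
                        coords={k: R @ v for k, v in r.coords.items()})
            for r in s.residues
        ]
        s2 = sio.BackboneStructure(id="rot", residues=residues)
        h = ann.helices[0]
        v1, v2 = geo.helix_vector(s, h), geo.helix_vector(s2, h)
        np.testing.assert_allclose(v2.direction, R @ v1.direction, atol=1e-6)


class TestTrimToCommon:
    @pytest.mark.parametrize("long,short,expected_long", [
        ((1, 10), (1, 10), (1, 10)),     # equal: unchanged
        ((1, 12), (21, 30), (2, 11)),    # even trim: central window
        ((1, 11), (21, 30), (1, 10)),    # odd trim: N-terminal kept
        ((5, 19), (1, 4), (10, 13)),     # large asymmetric case
    ])
    def test_trimming_rule(self, long, short, expected_long):
        out_long, out_short = geo.trim_to_common(long, short)
        assert out_long == expected_long
        assert out_short == short

    def test_shorter_never_modified_equal_lengths_always(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = int(rng.integers(1, 50))
            b = int(rng.integers(1, 50))
            ra = (a, a + int(rng.integers(0, 20)))
            rb = (b, b + int(rng.integers(0, 20)))
            oa, ob = geo.trim_to_common(ra, rb)
            assert oa[1] - oa[0] == ob[1] - ob[0]
            shorter = ra if ra[1] - ra[0] <= rb[1] - rb[0] else rb
            assert shorter in (oa, ob)


class TestPairwiseHelixRmsd:
    def test_self_is_zero_and_symmetric(self, small_cohort):
        _, s1, a1 = small_cohort[0]
        _, s2, a2 = small_cohort[1]
        assert geo.pairwise_helix_rmsd(s1, a1, s1, a1) == pytest.approx(
            0.0, abs=1e-8)
        d12 = geo.pairwise_helix_rmsd(s1, a1, s2, a2)
        d21 = geo.pairwise_helix_rmsd(s2, a2, s1, a1)
        assert d12 == pytest.approx(d21, abs=1e-6)

    def test_rigid_helix_translation_recovered_exactly(self, small_cohort):
        _, s, ann = small_cohort[0]
        helix_residues = set()
        for a, b in ann.helices:
            helix_residues.update(range(a, b + 1))
        s2 = translate_structure(s, np.array([0.0, 0.0, 3.0]),
                                 only=helix_residues)
        d = geo.pairwise_helix_rmsd(s, ann, s2, ann)
        assert d == pytest.approx(3.0, abs=1e-6)

    def test_unequal_helix_lengths_match_oracle(self, cohort_factory):
        cohort = cohort_factory(4, seed=17)
        (_, s1, a1), (_, s2, a2) = cohort[0], cohort[1]
        assert (
            (a1.helices[0][1] - a1.helices[0][0])
            != (a2.helices[0][1] - a2.helices[0][0])
            or (a1.helices[1][1] - a1.helices[1][0])
            != (a2.helices[1][1] - a2.helices[1][0])
        ), "fixture should plant unequal helix lengths"
        d = geo.pairwise_helix_rmsd(s1, a1, s2, a2)
        assert d == pytest.approx(
            oracle_pairwise_helix_rmsd(s1, a1, s2, a2), abs=1e-6)

    def test_sheet_size_mismatch_rejected(self, small_cohort, scaffold):
        _, s1, a1 = small_cohort[0]
        sc, _ = scaffold
        bad = sio.SegmentAnnotation(
            structure_id=a1.structure_id,
            sheet_residues=frozenset(list(a1.sheet_residues)[:-1]),
            helices=a1.helices, reshaped_lhls=a1.reshaped_lhls,
        )
        with pytest.raises(sio.StructureError, match="sheet size"):
            geo.pairwise_helix_rmsd(s1, a1, s1, bad)


class TestLhlRmsd:
    def test_identical_is_zero(self, small_cohort):
        _, s, ann = small_cohort[0]
        assert geo.lhl_rmsd(s, s, ann) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_lhl_displacement_exact(self, small_cohort):
        _, s, ann = small_cohort[0]
        moved = translate_structure(
            s, np.array([2.0, 0.0, 0.0]), only=ann.lhl_residues)
        assert geo.lhl_rmsd(moved, s, ann) == pytest.approx(2.0, abs=1e-6)

    def test_random_perturbation_matches_oracle(self, small_cohort):
        rng = np.random.default_rng(4)
        _, s, ann = small_cohort[0]
        lhl = ann.lhl_residues
        residues = [
            sio.Residue(
                index=r.index, aa=r.aa,
                coords={k: v + (rng.normal(0, 0.3, 3) if r.index in lhl
                                else 0.0)
                        for k, v in r.coords.items()})
            for r in s.residues
        ]
        pred = sio.BackboneStructure(id="pert", residues=residues)
        assert geo.lhl_rmsd(pred, s, ann) == pytest.approx(
            oracle_lhl_rmsd(pred, s, ann), abs=1e-8)


class TestEnsembleLhlRmsd:
    def test_selectors(self, small_cohort):
        _, s, ann = small_cohort[0]
        ens = synth.make_prediction_ensemble(
            s, ann, target_rmsds=[1.0, 2.0, 3.0], plddts=[70, 90, 80], seed=0)
        assert geo.ensemble_lhl_rmsd(ens, s, ann, "lowest") == pytest.approx(
            1.0, rel=0.05)
        assert geo.ensemble_lhl_rmsd(ens, s, ann, "rank1") == pytest.approx(
            2.0, rel=0.05)

    def test_design_itself_gives_zero(self, small_cohort):
        _, s, ann = small_cohort[0]
        ens = sio.PredictionEnsemble(design_id=s.id, members=[(s, 90.0)])
        assert geo.ensemble_lhl_rmsd(ens, s, ann, "lowest") == pytest.approx(
            0.0, abs=1e-10)

    def test_unknown_selector(self, small_cohort):
        _, s, ann = small_cohort[0]
        ens = sio.PredictionEnsemble(design_id=s.id, members=[(s, 90.0)])
        with pytest.raises(ValueError):
            geo.ensemble_lhl_rmsd(ens, s, ann, "best")


class TestBiasStatistics:
    def test_predictions_equal_to_designs(self, cohort_factory):
        cohort = cohort_factory(4, seed=21)
        pairs = [(s, a) for _, s, a in cohort]
        reference = pairs[0]
        frac, frac_margin = geo.bias_statistics(
            pairs[1:], pairs[1:], reference)
        assert (frac, frac_margin) == (0.0, 0.0)

    def test_planted_reference_like_fraction_recovered(self, cohort_factory):
        diverse = cohort_factory(6, seed=22)
        regular = cohort_factory(1, seed=23, regime="regular")
        reference = (regular[0][1], regular[0][2])
        designs = [(s, a) for _, s, a in diverse]
        # plant: half the predictions are the reference itself
        predictions = [
            reference if i % 2 == 0 else designs[i]
            for i in range(len(designs))
        ]
        frac, frac_margin = geo.bias_statistics(
            designs, predictions, reference)
        assert frac == pytest.approx(0.5)
        assert frac_margin <= frac

    def test_margin_fraction_never_exceeds_closer_fraction(self,
                                                           cohort_factory):
        diverse = cohort_factory(5, seed=24)
        regular = cohort_factory(5, seed=25, regime="regular")
        reference = cohort_factory(1, seed=26, regime="regular")[0]
        designs = [(s, a) for _, s, a in diverse]
        predictions = [(s, a) for _, s, a in regular]
        for margin in (0.0, 0.5, 1.0, 2.0):
            frac, frac_margin = geo.bias_statistics(
                designs, predictions, (reference[1], reference[2]),
                margin=margin)
            assert frac_margin <= frac


class TestBins:
    def make_vector(self, centroid, direction):
        d = np.asarray(direction, float)
        return geo.HelixVector(
            centroid=np.asarray(centroid, float),
            direction=d / np.linalg.norm(d),
            helix_range=(1, 10), n_residues=10)

    @pytest.mark.parametrize("centroid,direction,expected", [
        ((0.1, 0.1, 0.1), (1, 1, 1), (0, 0, 0, "+", "+", "+")),
        ((-0.1, 3.9, 2.0), (1, -1, 1), (-1, 1, 1, "+", "-", "+")),
        ((5.0, -3.2, 0.0), (-1, -1, -1), (2, -2, 0, "-", "-", "-")),
    ])
    def test_floor_and_sign_convention(self, centroid, direction, expected):
        v = self.make_vector(centroid, direction)
        assert geo.bin_index(v) == expected

    def test_zero_direction_component_is_plus(self):
        v = self.make_vector((0.5, 0.5, 0.5), (0, 0, 1))
        assert geo.bin_index(v)[3:] == ("+", "+", "+")

    def test_occupancy_full_empty_partial(self):
        universe = [
            self.make_vector((0.5, 0.5, 0.5), (1, 1, 1)),
            self.make_vector((2.5, 0.5, 0.5), (1, 1, 1)),
            self.make_vector((4.5, 0.5, 0.5), (1, 1, 1)),
        ]
        assert geo.bin_occupancy(universe, universe) == 1.0
        assert geo.bin_occupancy([], universe) == 0.0
        assert geo.bin_occupancy(universe[:2], universe) == pytest.approx(2 / 3)

    def test_occupancy_monotone_in_subset(self):
        rng = np.random.default_rng(0)
        universe = [
            self.make_vector(rng.uniform(-5, 5, 3), rng.normal(size=3))
            for _ in range(30)
        ]
        prev = 0.0
        for k in range(0, 31, 5):
            occ = geo.bin_occupancy(universe[:k], universe)
            assert occ >= prev
            assert 0.0 <= occ <= 1.0
            prev = occ

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            geo.bin_occupancy([], [])


class TestSheetFace:
    def test_opposite_faces_have_opposite_signs(self, cohort_factory,
                                                scaffold):
        sc, sc_ann = scaffold
        _, s, ann, truths = cohort_factory(1, seed=31, with_truth=True)[0]
        sheet = ann.sheet_residues
        face = geo.sheet_face(s, ann.helices[0], sheet)
        # mirror the whole first LHL across the sheet plane (z -> -z)
        lhl = set(range(ann.reshaped_lhls[0][0], ann.reshaped_lhls[0][1] + 1))
        residues = [
            sio.Residue(index=r.index, aa=r.aa,
                        coords={k: (v * np.array([1, 1, -1.0])
                                    if r.index in lhl else v.copy())
                                for k, v in r.coords.items()})
            for r in s.residues
        ]
        mirrored = sio.BackboneStructure(id="mir", residues=residues)
        assert geo.sheet_face(mirrored, ann.helices[0], sheet) == -face

    def test_in_plane_centroid_maps_to_plus(self, scaffold):
        sc, sc_ann = scaffold
        # helix centered exactly in the sheet plane
        helix = synth.ideal_helix(8)
        centroid = synth._backbone_centroid(helix)
        moved = [
            {k: v - centroid + np.array([30.0, 0.0, 0.0]) for k, v in c.items()}
            for c in helix
        ]
        residues = list(sc.residues) + [
            sio.Residue(index=sc.residues[-1].index + 1 + i, aa="A",
                        coords=c)
            for i, c in enumerate(moved)
        ]
        s = sio.BackboneStructure(id="flat", residues=residues)
        start = sc.residues[-1].index + 1
        # project the helix onto the plane z-offset of the sheet centroid
        plane_c, normal = geo._sheet_plane(s, sc_ann.sheet_residues)
        hv = geo.helix_vector(s, (start, start + 7))
        offset = float(normal @ (hv.centroid - plane_c))
        shifted = [
            sio.Residue(index=r.index, aa=r.aa,
                        coords={k: v - offset * normal
                                if r.index >= start else v.copy()
                                for k, v in r.coords.items()})
            for r in s.residues
        ]
        s2 = sio.BackboneStructure(id="flat2", residues=shifted)
        assert geo.sheet_face(s2, (start, start + 7),
                              sc_ann.sheet_residues) == 1

    def test_collinear_sheet_rejected(self):
        coords = []
        for i in range(4):
            base = np.array([3.8 * i, 0.0, 0.0])
            coords.append({"N": base, "CA": base + [1.4, 0, 0],
                           "C": base + [2.4, 0, 0], "O": base + [2.4, 1, 0]})
        s = build_structure(coords)
        with pytest.raises(sio.StructureError):
            geo._sheet_plane(s, {1, 2, 3, 4})


class TestShellResidues:
    @pytest.fixture()
    def toy(self, cohort_factory):
        return cohort_factory(1, seed=41)[0]

    def test_lhl_residues_always_in_shell1(self, toy):
        _, s, ann = toy
        shell1 = geo.shell_residues(s, ann, shell=1)
        assert ann.lhl_residues <= shell1

    def test_shell1_subset_of_shell2(self, toy):
        _, s, ann = toy
        shell1 = geo.shell_residues(s, ann, shell=1)
        shell2 = geo.shell_residues(s, ann, shell=2)
        assert shell1 <= shell2

    def test_distant_residue_excluded(self, toy):
        _, s, ann = toy
        lhl_cas = np.array([s.ca(i) for i in sorted(ann.lhl_residues)])
        shell1 = geo.shell_residues(s, ann, shell=1)
        for r in s.residues:
            dmin = np.linalg.norm(lhl_cas - r.coords["CA"], axis=1).min()
            if dmin > 10.0:
                assert r.index not in shell1

    def test_orientation_gate(self):
        # one LHL residue at origin; two neighbours 8 A away, CB toward and
        # away from it respectively — only the former joins shell 1
        def res(idx, ca, cb):
            ca = np.asarray(ca, float)
            return sio.Residue(index=idx, aa="A", coords={
                "N": ca + [-1.0, 0, 0], "CA": ca, "C": ca + [1.0, 0, 0],
                "O": ca + [1.0, 1.0, 0], "CB": np.asarray(cb, float),
            })
        target = res(1, [0, 0, 0], [0, 1, 0])
        toward = res(10, [8.0, 0, 0], [7.0, 0, 0])      # CB points at target
        away = res(20, [0, 8.0, 0], [0, 9.0, 0])        # CB points away
        s = sio.BackboneStructure(id="toy", residues=[target, toward, away])
        ann = sio.SegmentAnnotation(structure_id="toy",
                                    reshaped_lhls=[(1, 1)])
        shell1 = geo.shell_residues(s, ann, shell=1)
        assert 10 in shell1 and 20 not in shell1


class TestMinHelixLengthFilter:
    @pytest.mark.parametrize("lengths,expected", [
        ((7, 9), True),     # boundary inclusive
        ((6, 12), False),
        ((8, 8), True),
    ])
    def test_boundary(self, lengths, expected):
        helices, lhls, pos = [], [], 1
        for L in lengths:
            lhls.append((pos, pos + L + 3))
            helices.append((pos + 2, pos + 2 + L - 1))
            pos += L + 10
        ann = sio.SegmentAnnotation(structure_id="x", helices=helices,
                                    reshaped_lhls=lhls)
        assert geo.min_helix_length_filter(ann) is expected

    def test_lhl_without_helix_fails(self):
        ann = sio.SegmentAnnotation(structure_id="x", helices=[(3, 12)],
                                    reshaped_lhls=[(1, 15), (20, 35)])
        assert geo.min_helix_length_filter(ann) is False
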