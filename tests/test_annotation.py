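"""Backbone dihedrals, geometric turn assignment and type classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaturn.annotation import (
    IDEAL_TURN_ANGLES,
    TURN_TYPES,
    BackboneStructure,
    Residue,
    TurnRecord,
    UndefinedAngleError,
    assign_beta_turns,
    classify_turn_type,
    dihedral_angle,
    labels_from_turns,
    phi_psi,
)
from betaturn.synthetic import EXTENDED_ANGLES, build_backbone


def oracle_torsion(p1, p2, p3, p4):
    """Independent vector-algebra torsion: plane normals for the magnitude,
    a signed determinant for the IUPAC sign."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    mag = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    sign = np.sign(np.dot(np.cross(n1, n2), p3 - p2))
    return sign * mag if sign != 0 else mag


class TestDihedralAngle:
    def test_planar_cis_is_zero(self):
        # eclipsed: p1 and p4 on the same side of the p2-p3 axis
        assert dihedral_angle((1, 1, 0), (0, 0, 0), (0, 0, 1), (1, 1, 1)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert abs(dihedral_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1))) == pytest.approx(180.0)

    @pytest.mark.parametrize("theta", [30.0, 90.0, 150.0])
    def test_matches_vector_oracle(self, theta):
        rad = math.radians(theta)
        pts = ((1, 0, 0), (0, 0, 0), (0, 0, 1), (math.cos(rad), math.sin(rad), 1))
        got = dihedral_angle(*pts)
        want = oracle_torsion(*pts)
        assert got == pytest.approx(want, abs=1e-9)
        assert abs(got) == pytest.approx(theta, abs=1e-9)

    def test_random_points_match_oracle(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            assert dihedral_angle(*pts) == pytest.approx(oracle_torsion(*pts), abs=1e-8)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedAngleError):
            dihedral_angle((0, 0, 0), (0, 0, 1), (0, 0, 2), (1, 0, 3))

    def test_range_half_open(self):
        # exactly anti-periplanar must report +180, never -180
        val = dihedral_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1))
        assert val == pytest.approx(180.0)
        assert val > 0


class TestPhiPsi:
    def test_boundary_values_undefined(self):
        st3 = build_backbone([EXTENDED_ANGLES] * 3)
        angles = phi_psi(st3)
        assert angles[0][0] is None and angles[-1][1] is None
        assert angles[1][0] is not None and angles[1][1] is not None

    def test_single_residue_all_undefined(self):
        st1 = build_backbone([EXTENDED_ANGLES])
        assert phi_psi(st1) == [(None, None)]

    @pytest.mark.parametrize("phi,psi", [(-120.0, 120.0), (-57.0, -47.0), (-60.0, -30.0)])
    def test_builder_round_trip(self, phi, psi):
        st = build_backbone([(phi, psi)] * 8)
        for got_phi, got_psi in phi_psi(st)[1:-1]:
            assert got_phi == pytest.approx(phi, abs=0.5)
            assert got_psi == pytest.approx(psi, abs=0.5)


class TestClassifyTurnType:
    def test_all_ideal_quadruples_round_trip(self):
        for ttype, ideal in IDEAL_TURN_ANGLES.items():
            assert classify_turn_type(*ideal) == ttype

    def test_type_iv_average_angles_fall_through(self):
        assert classify_turn_type(-61, 10, -53, 17) == "IV"

    def test_single_deviation_within_45_tolerated(self):
        assert classify_turn_type(-60, -30, -61, 0) == "I"  # phi2 off by 29
        assert classify_turn_type(-60, -30, -90, 44) == "I"  # one angle in (30, 45]

    def test_two_moderate_deviations_rejected(self):
        # two angles in (30, 45] must not match any specific type
        assert classify_turn_type(-60 + 35, -30 - 35, -90, 0) == "IV"

    def test_mirror_types_distinguished(self):
        assert classify_turn_type(60, 30, 90, 0) == "I'"
        assert classify_turn_type(60, -120, -80, 0) == "II'"

    @given(st.sampled_from(sorted(IDEAL_TURN_ANGLES)),
           st.integers(min_value=-2, max_value=2))
    @settings(max_examples=50, deadline=None)
    def test_circular_invariance(self, ttype, wraps):
        phi1, psi1, phi2, psi2 = IDEAL_TURN_ANGLES[ttype]
        assert classify_turn_type(phi1 + 360 * wraps, psi1, phi2, psi2) == \
            classify_turn_type(phi1, psi1, phi2, psi2)


def _tetrapeptide(central_psi1):
    """6-mer whose end-CA separation varies with one central torsion."""
    angles = [list(EXTENDED_ANGLES) for _ in range(6)]
    angles[2] = [-60.0, central_psi1]
    angles[3] = [-90.0, 0.0]
    return build_backbone(angles)


class TestAssignBetaTurns:
    def test_compact_window_assigned(self):
        st = _tetrapeptide(-30.0)  # ideal type I geometry, d ~ 4.9 A
        cas = st.ca_coords()
        assert np.linalg.norm(cas[1] - cas[4]) < 7.0
        turns = assign_beta_turns(st, [0] * 6)
        assert TurnRecord(start=2, type="I") in turns

    def test_distance_above_cutoff_rejected(self):
        st = _tetrapeptide(140.0)  # opened-up geometry
        cas = st.ca_coords()
        assert np.linalg.norm(cas[1] - cas[4]) > 7.0
        assert assign_beta_turns(st, [0] * 6) == []

    def test_helix_masked_window_rejected(self):
        st = _tetrapeptide(-30.0)
        mask = [0, 1, 1, 1, 1, 0]  # all four window residues helical
        assert assign_beta_turns(st, mask) == []

    def test_single_masked_residue_rejects_window(self):
        st = _tetrapeptide(-30.0)
        mask = [0, 0, 0, 1, 0, 0]
        starts = [t.start for t in assign_beta_turns(st, mask)]
        assert 2 not in starts

    def test_short_chain_no_turns(self):
        st = build_backbone([EXTENDED_ANGLES] * 3)
        assert assign_beta_turns(st, [0] * 3) == []

    def test_mask_length_checked(self):
        st = build_backbone([EXTENDED_ANGLES] * 5)
        with pytest.raises(ValueError):
            assign_beta_turns(st, [0] * 4)

    def test_threshold_boundary_by_bisection(self):
        """The assignment boundary sits at 7.00 +/- 0.01 A."""
        def separation(psi):
            st = _tetrapeptide(psi)
            cas = st.ca_coords()
            return float(np.linalg.norm(cas[1] - cas[4]))

        def assigned(psi):
            return any(t.start == 2 for t in
                       assign_beta_turns(_tetrapeptide(psi), [0] * 6))

        lo, hi = -30.0, 140.0  # separation increases monotonically with psi here
        assert assigned(lo) and not assigned(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if assigned(mid):
                lo = mid
            else:
                hi = mid
        assert separation(lo) == pytest.approx(7.0, abs=0.01)
        # monotone: assigned below the boundary, never above
        for psi in np.linspace(-30, lo - 1e-6, 25):
            assert assigned(float(psi))
        for psi in np.linspace(hi + 1e-6, 140, 25):
            assert not assigned(float(psi))


class TestLabelsFromTurns:
    def test_single_turn_window(self):
        labels = labels_from_turns([TurnRecord(5, "I")], 20)
        assert list(np.flatnonzero(labels["turn"])) == [4, 5, 6, 7]
        assert list(np.flatnonzero(labels["I"])) == [4, 5, 6, 7]
        for ch in ("II", "IV", "VIII", "NS"):
            assert not labels[ch].any()

    @pytest.mark.parametrize("ttype", ["I'", "II'", "VIa1", "VIa2", "VIb"])
    def test_rare_types_map_to_ns(self, ttype):
        labels = labels_from_turns([TurnRecord(3, ttype)], 10)
        assert labels["NS"].sum() == 4
        for ch in ("I", "II", "IV", "VIII"):
            assert not labels[ch].any()

    def test_overlapping_turns_union_semantics(self):
        turns = [TurnRecord(5, "I"), TurnRecord(7, "II")]
        labels = labels_from_turns(turns, 20)
        # brute-force membership oracle
        for pos in range(20):
            in_first = 4 <= pos <= 7
            in_second = 6 <= pos <= 9
            assert labels["turn"][pos] == int(in_first or in_second)
            assert labels["I"][pos] == int(in_first)
            assert labels["II"][pos] == int(in_second)

    def test_out_of_range_turn_rejected(self):
        with pytest.raises(ValueError):
            labels_from_turns([TurnRecord(18, "I")], 20)

    def test_type_channels_imply_turn_channel(self, rng):
        starts = sorted(rng.choice(np.arange(1, 40), size=6, replace=False))
        turns = [TurnRecord(int(s), str(rng.choice(TURN_TYPES))) for s in starts]
        labels = labels_from_turns(turns, 50)
        labels.validate()
        for ch in ("I", "II", "IV", "VIII", "NS"):
            assert np.all(labels[ch] <= labels["turn"])

    def test_disjoint_turns_count_exactly(self):
        turns = [TurnRecord(1, "I"), TurnRecord(10, "II"), TurnRecord(20, "VIII")]
        labels = labels_from_turns(turns, 30)
        assert labels["turn"].sum() == 4 * len(turns)


class TestBackboneStructure:
    def test_chain_break_rejected(self):
        r1 = Residue(1, "A", np.zeros(3), np.zeros(3), np.array([1.5, 0, 0]))
        r2 = Residue(2, "A", np.array([9, 0, 0.0]), np.array([10, 0, 0.0]),
                     np.array([11, 0, 0.0]))
        with pytest.raises(ValueError, match="chain break"):
            BackboneStructure("A", [r1, r2])

    def test_indices_strictly_increasing(self):
        r1 = Residue(2, "A", np.zeros(3), np.zeros(3), np.array([1.5, 0, 0]))
        r2 = Residue(2, "A", np.array([1, 1, 0.0]), np.array([2, 1, 0.0]),
                     np.array([3, 1, 0.0]))
        with pytest.raises(ValueError, match="strictly increasing"):
            BackboneStructure("A", [r1, r2])
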