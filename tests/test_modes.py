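"""Fingerprinting, mode classification, transitions and the A/B switch."""

import numpy as np
import pytest

from habind.errors import SchemaError, TopologyError
from habind.modes import (
    MODES,
    FingerprintVector,
    ModeAssignment,
    ReferenceFingerprints,
    ab_form,
    classify,
    detect_transitions,
    dihedral,
    fingerprint,
    reference_table,
)

from conftest import make_model, make_traj


class TestReferenceData:
    def test_reference_set_has_39_residues_and_three_modes(self):
        refs = ReferenceFingerprints.from_package_data()
        assert len(refs.residues) == 39
        assert set(refs.columns) == set(MODES)

    def test_key_residue_is_saturated_in_the_crystallographic_mode(self):
        df = reference_table().set_index("resid")
        assert df.loc[41, "crystallographic"] == 100.0
        assert df.loc[41, "parallel"] == 100.0
        assert df.loc[41, "upright"] == pytest.approx(92.2)

    def test_percentages_and_errors_in_range(self):
        df = reference_table()
        for m in MODES:
            assert df[m].between(0, 100).all()
            assert (df[f"{m}_se"] >= 0).all()


class TestClassify:
    def test_reference_column_classifies_as_itself_with_similarity_one(self):
        refs = ReferenceFingerprints.from_package_data()
        for mode in MODES:
            asg = classify(refs.vector(mode), refs)
            assert asg.label == mode
            assert asg.similarities[mode] == pytest.approx(1.0)

    def test_all_zero_fingerprint_is_unbound(self):
        refs = ReferenceFingerprints.from_package_data()
        fp = FingerprintVector(residues=refs.residues,
                               values=np.zeros(len(refs.residues)))
        assert classify(fp, refs).label == "unbound"

    def test_cosine_is_scale_invariant(self):
        refs = ReferenceFingerprints.from_package_data()
        base = refs.vector("parallel")
        for c in (0.2, 0.5, 0.93):
            scaled = FingerprintVector(residues=base.residues,
                                       values=base.values * c)
            asg = classify(scaled, refs)
            assert asg.label == "parallel"
            assert asg.similarities["parallel"] == pytest.approx(1.0)

    def test_residue_order_mismatch_is_schema_error(self):
        refs = ReferenceFingerprints.from_package_data()
        fp = FingerprintVector(residues=refs.residues[::-1].copy(),
                               values=np.ones(len(refs.residues)))
        with pytest.raises(SchemaError):
            classify(fp, refs)

    def test_noisy_references_recover_their_source_label(self):
        # +/-10% uniform multiplicative noise, clipped to [0, 100]
        refs = ReferenceFingerprints.from_package_data()
        rng = np.random.default_rng(2024)
        correct = total = 0
        for mode in MODES:
            col = refs.columns[mode]
            for _ in range(100):
                noisy = np.clip(col * rng.uniform(0.9, 1.1, col.shape), 0, 100)
                fp = FingerprintVector(residues=refs.residues, values=noisy)
                total += 1
                correct += classify(fp, refs).label == mode
        assert correct / total >= 0.95


class TestFingerprint:
    def _bound_model(self):
        # pseudo-residues 41 and 76 near the chain; 25 far away
        coords = [[0.0, 0, 0], [0.5, 0, 0],       # polymer NAG, GCU
                  [0.0, 0.4, 0], [0.5, 0.4, 0],   # residues 41, 76 (bound)
                  [0.0, 3.0, 0]]                  # residue 25 (unbound)
        return make_model(coords, resids=[1, 2, 41, 76, 25],
                          resnames=["NAG", "GCU", "ARG", "THR", "ASN"],
                          chains=["P", "P", "A", "A", "A"],
                          roles={"P": "polymer", "A": "protein"})

    def test_bound_residues_score_100_others_0(self):
        model = self._bound_model()
        traj = make_traj(model, np.repeat(model.coords[None], 4, axis=0))
        fp = fingerprint(traj, np.array([0, 1]))
        vals = dict(zip(fp.residues, fp.values))
        assert vals[41] == 100.0 and vals[76] == 100.0
        assert vals[25] == 0.0 and vals[150] == 0.0

    def test_single_frame_window_is_binary(self):
        model = self._bound_model()
        traj = make_traj(model, model.coords[None])
        fp = fingerprint(traj, np.array([0, 1]), window=(0, 1))
        assert set(np.unique(fp.values)) <= {0.0, 100.0}

    def test_concatenated_windows_average_by_frame_count(self):
        model = self._bound_model()
        far = model.coords + np.array([0, 0, 0]) * 0  # frame variants
        near = model.coords.copy()
        away = model.coords.copy()
        away[2:, 1] += 5.0   # protein detached
        frames = np.stack([near, near, near, away])   # 3 bound + 1 not
        traj = make_traj(model, frames)
        full = fingerprint(traj, np.array([0, 1]))
        w1 = fingerprint(traj, np.array([0, 1]), window=(0, 3))
        w2 = fingerprint(traj, np.array([0, 1]), window=(3, 4))
        expected = (3 * w1.values + 1 * w2.values) / 4
        np.testing.assert_allclose(full.values, expected)

    def test_empty_window_rejected(self):
        model = self._bound_model()
        traj = make_traj(model, model.coords[None])
        with pytest.raises(IndexError):
            fingerprint(traj, np.array([0, 1]), window=(1, 1))


class TestTransitions:
    def _asg(self, labels):
        return [ModeAssignment(label=l, similarities={}) for l in labels]

    def test_two_long_runs_give_two_segments(self):
        labels = ["parallel"] * 6 + ["upright"] * 6
        segs = detect_transitions(self._asg(labels), min_segment=5)
        assert segs == [((0, 6), "parallel"), ((6, 12), "upright")]

    def test_single_window_flicker_absorbed(self):
        labels = ["parallel", "parallel", "upright", "parallel", "parallel"]
        segs = detect_transitions(self._asg(labels), min_segment=2)
        assert segs == [((0, 5), "parallel")]

    def test_constant_labels_one_segment(self):
        segs = detect_transitions(self._asg(["upright"] * 9))
        assert segs == [((0, 9), "upright")]

    def test_empty_sequence(self):
        assert detect_transitions([]) == []


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([2.0, 1, 0])]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        p = [np.array([1.0, 1, 0]), np.array([0.0, 0, 0]),
             np.array([1.0, 0, 0]), np.array([2.0, -1, 0])]
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-9)

    def test_matches_mdanalysis_on_random_quadruples(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(8)
        for _ in range(50):
            pts = rng.normal(0, 1, (4, 3))
            mine = dihedral(*pts)
            ref = np.degrees(calc_dihedrals(pts[0][None], pts[1][None],
                                            pts[2][None], pts[3][None]))[0]
            # same magnitude and sign convention (reference runs in float32)
            assert mine == pytest.approx(float(ref), abs=1e-3)


class TestAbForm:
    def _complex_model(self, phi_negative, with_ligand_contact):
        """Backbone C(41)-N(42)-CA(42)-C(42) with controllable phi, plus an
        R41 side-chain nitrogen near/far from a ligand oxygen."""
        z = -0.1 if phi_negative else 0.1
        lig_y = -0.3 if with_ligand_contact else -2.0
        coords = [
            [0.10, 0.14, z],      # C of residue 41 (sets phi sign)
            [0.0, 0.0, 0.0],      # N 42
            [0.145, 0.0, 0.0],    # CA 42
            [0.2, -0.14, 0.0],    # C 42
            [0.0, -0.12, 0.0],    # NH1 of R41 side chain
            [0.0, lig_y, 0.0],    # ligand O
        ]
        return make_model(
            coords,
            resids=[41, 42, 42, 42, 41, 1],
            resnames=["ARG", "TYR", "TYR", "TYR", "ARG", "NAG"],
            chains=["A"] * 5 + ["P"],
            names=["C", "N", "CA", "C", "NH1", "O3"],
            elements=["C", "N", "C", "C", "N", "O"],
            roles={"A": "protein", "P": "polymer"})

    def test_b_form_requires_phi_basin_and_hbond(self):
        model = self._complex_model(phi_negative=True, with_ligand_contact=True)
        traj = make_traj(model, model.coords[None])
        states = ab_form(traj, np.array([5]))
        assert states[0].state == "B"
        assert states[0].phi < 0
        assert states[0].r41_hbonds >= 1

    def test_phi_in_b_basin_without_hbond_is_a_form(self):
        model = self._complex_model(phi_negative=True, with_ligand_contact=False)
        traj = make_traj(model, model.coords[None])
        states = ab_form(traj, np.array([5]))
        assert states[0].state == "A"
        assert states[0].r41_hbonds == 0

    def test_phi_in_a_basin_is_a_form_even_with_hbond(self):
        model = self._complex_model(phi_negative=False, with_ligand_contact=True)
        traj = make_traj(model, model.coords[None])
        assert ab_form(traj, np.array([5]))[0].state == "A"

    def test_never_b_when_ligand_absent_from_selection(self):
        # ligand-free frames cannot satisfy the hydrogen-bond conjunct
        model = self._complex_model(phi_negative=True, with_ligand_contact=False)
        frames = np.repeat(model.coords[None], 5, axis=0)
        traj = make_traj(model, frames)
        assert all(s.state == "A" for s in ab_form(traj, np.array([5])))

    def test_missing_backbone_is_topology_error(self):
        model = make_model([[0, 0, 0]], resids=[41], resnames=["ARG"],
                           names=["CB"], chains=["A"],
                           roles={"A": "protein"})
        traj = make_traj(model, model.coords[None])
        with pytest.raises(TopologyError):
            ab_form(traj, np.array([0]))


class TestTransitionProperties:
    """Segment structure invariants under arbitrary label sequences."""

    from hypothesis import given, settings, strategies as st

    @given(labels=st.lists(st.sampled_from(["crystallographic", "parallel",
                                            "upright", "unbound"]),
                           min_size=1, max_size=60),
           min_segment=st.integers(min_value=1, max_value=6))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_segments_partition_the_series(self, labels, min_segment):
        segs = detect_transitions(
            [ModeAssignment(label=l, similarities={}) for l in labels],
            min_segment=min_segment)
        # contiguous cover of [0, len) with no empty or touching-equal runs
        assert segs[0][0][0] == 0 and segs[-1][0][1] == len(labels)
        for (a, b), (c, d) in zip((s[0] for s in segs),
                                  (s[0] for s in segs[1:])):
            assert b == c
        for (s, e), _ in segs:
            assert e > s
        for ((_, _), la), ((_, _), lb) in zip(segs, segs[1:]):
            assert la != lb
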