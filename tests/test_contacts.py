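"""Contact kernels and statistics against brute-force enumeration."""

import math

import numpy as np
import pytest

from habind.contacts import (
    ContactParams,
    HBondCriteria,
    ResidueContactSeries,
    contact_contour,
    contact_count_profile,
    contact_count_series,
    hydrogen_bonds,
    min_distance,
    replica_binding_table,
    residue_binding_percent,
    residue_contact_series,
)
from habind.errors import SchemaError, SelectionError
from habind.model_io import assign_ha_numbering

from conftest import make_model, make_traj


def brute_min_distance(xa, xb, box=None):
    """O(N^2) minimum distance, scanning all 27 periodic images."""
    best = math.inf
    shifts = [np.zeros(3)] if box is None else [
        np.array([i, j, k]) * box
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for a in xa:
        for b in xb:
            for s in shifts:
                best = min(best, float(np.linalg.norm(a - (b + s))))
    return best


def brute_pair_count(xa, xb, cutoff, box=None):
    count = 0
    for a in xa:
        for b in xb:
            if box is None:
                d = np.linalg.norm(a - b)
            else:
                d = min(np.linalg.norm(a - (b + np.array([i, j, k]) * box))
                        for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1))
            if d <= cutoff:
                count += 1
    return count


class TestMinDistance:
    def test_simple_pair(self):
        model = make_model([[0, 0, 0], [0, 0, 0.5]])
        d = min_distance(model, np.array([0]), np.array([1]),
                         model.coords)
        assert d == pytest.approx(0.5)

    def test_minimum_image_in_periodic_box(self):
        model = make_model([[0, 0, 0.1], [0, 0, 3.9]], box=[4.0, 4.0, 4.0])
        d = min_distance(model, np.array([0]), np.array([1]), model.coords,
                         ContactParams(periodic=True), box=model.box)
        assert d == pytest.approx(0.2, abs=1e-6)

    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_brute_force_on_random_points(self, periodic):
        rng = np.random.default_rng(42)
        box = np.array([3.0, 3.0, 3.0]) if periodic else None
        xa = rng.uniform(0, 3, (50, 3))
        xb = rng.uniform(0, 3, (50, 3))
        model = make_model(np.vstack([xa, xb]), box=box)
        d = min_distance(model, np.arange(50), np.arange(50, 100),
                         model.coords, ContactParams(periodic=periodic),
                         box=box)
        assert d == pytest.approx(brute_min_distance(xa, xb, box), abs=1e-6)

    def test_empty_selection_rejected(self):
        model = make_model([[0, 0, 0]])
        with pytest.raises(SelectionError):
            min_distance(model, np.array([], dtype=int), np.array([0]),
                         model.coords)


class TestBindingPercent:
    def _series(self, pattern):
        return ResidueContactSeries(residues=np.array([41]),
                                    contacts=np.array(pattern)[:, None],
                                    times=np.arange(len(pattern), dtype=float))

    def test_three_of_four_frames(self):
        assert residue_binding_percent(
            self._series([True, True, True, False]), 41) == pytest.approx(75.0)

    def test_bounds(self):
        assert residue_binding_percent(self._series([False] * 5), 41) == 0.0
        assert residue_binding_percent(self._series([True] * 5), 41) == 100.0

    def test_boundary_distance_is_inclusive(self):
        # one ligand atom at exactly the 0.6 nm cutoff in every frame
        model = make_model([[0, 0, 0], [0, 0, 0.6]],
                           resids=[41, 1], resnames=["ARG", "NAG"],
                           chains=["A", "P"],
                           roles={"A": "protein", "P": "polymer"})
        traj = make_traj(model, np.repeat(model.coords[None], 3, axis=0))
        series = residue_contact_series(traj, [41], np.array([1]))
        assert residue_binding_percent(series, 41) == 100.0

    def test_unknown_residue_is_key_error(self):
        with pytest.raises(KeyError):
            residue_binding_percent(self._series([True]), 99)


class TestReplicaTable:
    def _series_with_percent(self, pct, n_frames=1000):
        n_on = int(round(pct / 100 * n_frames))
        pattern = [True] * n_on + [False] * (n_frames - n_on)
        return ResidueContactSeries(residues=np.array([25]),
                                    contacts=np.array(pattern)[:, None],
                                    times=np.arange(n_frames, dtype=float))

    def test_identical_replicas_have_zero_se(self):
        t = replica_binding_table([self._series_with_percent(100)] * 3)
        assert t.mean[0] == 100.0 and t.se[0] == 0.0

    def test_two_replica_arithmetic(self):
        t = replica_binding_table([self._series_with_percent(51.9),
                                   self._series_with_percent(52.7)])
        assert t.mean[0] == pytest.approx(52.3)
        assert t.se[0] == pytest.approx(0.4)

    def test_single_replica_se_is_undefined_sentinel(self):
        t = replica_binding_table([self._series_with_percent(80)])
        assert t.mean[0] == pytest.approx(80.0)
        assert np.isnan(t.se[0])

    def test_residue_set_mismatch_is_schema_error(self):
        a = self._series_with_percent(50)
        b = ResidueContactSeries(residues=np.array([26]),
                                 contacts=np.zeros((10, 1), bool),
                                 times=np.arange(10, dtype=float))
        with pytest.raises(SchemaError):
            replica_binding_table([a, b])


class TestContactCounts:
    def _two_ligand_model(self):
        # residue 41 atom permanently within cutoff of exactly 2 ligand atoms
        return make_model([[0, 0, 0], [0.3, 0, 0], [0, 0.3, 0], [2, 2, 2]],
                          resids=[41, 1, 2, 3],
                          resnames=["ARG", "NAG", "GCU", "NAG"],
                          chains=["A", "P", "P", "P"],
                          roles={"A": "protein", "P": "polymer"})

    def test_constant_pair_count(self):
        model = self._two_ligand_model()
        traj = make_traj(model, np.repeat(model.coords[None], 4, axis=0))
        prof = contact_count_profile(traj, [41], np.array([1, 2, 3]))
        assert prof["mean_contacts"].iloc[0] == pytest.approx(2.0)

    def test_no_contacts_gives_zero(self):
        model = self._two_ligand_model()
        far = model.coords + np.array([[0, 0, 0], [10, 0, 0],
                                       [10, 0, 0], [10, 0, 0]])
        traj = make_traj(model, far[None])
        prof = contact_count_profile(traj, [41], np.array([1, 2, 3]))
        assert prof["mean_contacts"].iloc[0] == 0.0

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(7)
        n_prot, n_lig, n_frames = 6, 8, 20
        model = make_model(
            rng.uniform(0, 2, (n_prot + n_lig, 3)),
            resids=list(range(1, n_prot + 1)) + list(range(1, n_lig + 1)),
            resnames=["ALA"] * n_prot + ["NAG"] * n_lig,
            chains=["A"] * n_prot + ["P"] * n_lig,
            roles={"A": "protein", "P": "polymer"})
        frames = rng.uniform(0, 2, (n_frames, n_prot + n_lig, 3))
        traj = make_traj(model, frames)
        lig = np.arange(n_prot, n_prot + n_lig)
        series = contact_count_series(traj, np.arange(n_prot), lig)
        expected = [brute_pair_count(f[:n_prot], f[n_prot:], 0.6)
                    for f in frames]
        assert list(series.counts) == expected

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(3)
        model = make_model(rng.uniform(0, 2, (10, 3)),
                           resids=[1] * 5 + [1, 2, 3, 4, 5],
                           resnames=["ALA"] * 5 + ["NAG"] * 5,
                           chains=["A"] * 5 + ["P"] * 5,
                           roles={"A": "protein", "P": "polymer"})
        traj = make_traj(model, rng.uniform(0, 2, (5, 10, 3)))
        lig = np.arange(5, 10)
        counts = [contact_count_series(traj, np.arange(5), lig,
                                       ContactParams(cutoff=c)).counts
                  for c in (0.3, 0.6, 0.9)]
        assert np.all(counts[0] <= counts[1])
        assert np.all(counts[1] <= counts[2])

    def test_time_independent_summary_invariant_to_frame_order(self):
        rng = np.random.default_rng(11)
        model = make_model(rng.uniform(0, 2, (6, 3)),
                           resids=[41, 42, 1, 2, 3, 4],
                           resnames=["ARG", "TYR", "NAG", "GCU", "NAG", "GCU"],
                           chains=["A", "A", "P", "P", "P", "P"],
                           roles={"A": "protein", "P": "polymer"})
        frames = rng.uniform(0, 2, (12, 6, 3))
        lig = np.array([2, 3, 4, 5])
        t1 = make_traj(model, frames)
        t2 = make_traj(model, frames[::-1].copy())
        s1 = residue_contact_series(t1, [41, 42], lig)
        s2 = residue_contact_series(t2, [41, 42], lig)
        assert residue_binding_percent(s1, 41) == residue_binding_percent(s2, 41)
        assert residue_binding_percent(s1, 42) == residue_binding_percent(s2, 42)


class TestContour:
    def _chain_model(self, n_mono=8):
        xs = np.arange(n_mono) * 0.5
        coords = [[x, 0, 0] for x in xs] + [[0.5, 0.4, 0]]
        return make_model(
            coords,
            resids=list(range(1, n_mono + 1)) + [41],
            resnames=["NAG" if i % 2 == 0 else "GCU"
                      for i in range(n_mono)] + ["ARG"],
            chains=["P"] * n_mono + ["A"],
            roles={"P": "polymer", "A": "protein"})

    def test_nonzero_rows_track_the_protein(self):
        model = self._chain_model()
        rmap = assign_ha_numbering(model, None, 41)
        traj = make_traj(model, np.repeat(model.coords[None], 3, axis=0))
        contour = contact_contour(traj, rmap, np.array([8]))
        touched = contour.mono_indices[contour.matrix.any(axis=1)]
        assert touched.size > 0
        assert np.all(np.abs(touched) <= 1.0)  # protein sits at disacc 0

    def test_band_shifts_with_protein_translation(self):
        model = self._chain_model()
        rmap = assign_ha_numbering(model, None, 41)
        f0 = model.coords.copy()
        f1 = model.coords.copy()
        f1[8, 0] += 2.0  # +2 nm = +2 disaccharides = +4 monosaccharides
        traj = make_traj(model, np.stack([f0, f1]))
        contour = contact_contour(traj, rmap, np.array([8]))
        c0 = contour.mono_indices[contour.matrix[:, 0] > 0].mean()
        c1 = contour.mono_indices[contour.matrix[:, 1] > 0].mean()
        assert c1 - c0 == pytest.approx(4.0, abs=0.5)

    def test_row_sum_equals_total_pair_count(self):
        rng = np.random.default_rng(5)
        model = self._chain_model()
        rmap = assign_ha_numbering(model, None, 41)
        frames = model.coords[None] + rng.normal(0, 0.3, (6, 9, 3))
        traj = make_traj(model, frames)
        contour = contact_contour(traj, rmap, np.array([8]))
        totals = contact_count_series(traj, np.arange(8), np.array([8]))
        assert list(contour.matrix.sum(axis=0)) == list(totals.counts)


class TestHydrogenBonds:
    def test_collinear_pair_within_criteria_reported(self):
        # N-H...O collinear at 0.29 nm donor-acceptor distance
        model = make_model([[0, 0, 0], [0.1, 0, 0], [0.29, 0, 0]],
                           names=["N", "H", "O"], elements=["N", "H", "O"])
        hb = hydrogen_bonds(model, model.coords, donors=np.array([0]),
                            acceptors=np.array([2]), hydrogens={0: [1]})
        assert len(hb) == 1
        assert hb[0].angle == pytest.approx(180.0)

    def test_long_pair_not_reported(self):
        model = make_model([[0, 0, 0], [0.1, 0, 0], [0.40, 0, 0]],
                           names=["N", "H", "O"], elements=["N", "H", "O"])
        assert hydrogen_bonds(model, model.coords, np.array([0]),
                              np.array([2]), hydrogens={0: [1]}) == []

    def test_bent_geometry_fails_angle_criterion(self):
        model = make_model([[0, 0, 0], [0.1, 0, 0], [0.1, 0.25, 0]],
                           names=["N", "H", "O"], elements=["N", "H", "O"])
        hb = hydrogen_bonds(model, model.coords, np.array([0]), np.array([2]),
                            hydrogens={0: [1]})
        assert hb == []  # ~90 degrees at H

    def test_random_set_matches_exhaustive_check(self):
        rng = np.random.default_rng(19)
        n = 12
        coords = rng.uniform(0, 1.2, (n, 3))
        model = make_model(coords, elements=["N"] * 6 + ["O"] * 6)
        donors, acceptors = np.arange(6), np.arange(6, 12)
        crit = HBondCriteria()
        found = {(h.donor, h.acceptor)
                 for h in hydrogen_bonds(model, coords, donors, acceptors,
                                         criteria=crit)}
        expected = {(int(d), int(a)) for d in donors for a in acceptors
                    if np.linalg.norm(coords[d] - coords[a]) <= crit.distance}
        assert found == expected
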