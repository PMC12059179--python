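"""Contact-analysis observables against brute-force and arithmetic oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ktrkit import contacts
from ktrkit.contacts import (ContactSpec, NativeContactSet,
                             build_native_contacts, fraction_native_contacts,
                             lipid_contacts, q_timeseries, terminus_length,
                             z_distance_distribution)

from conftest import brute_force_pairs, make_trajectory


def two_atom_traj(distance):
    frames = [[[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]]
    return make_trajectory(frames, residue_index=[7, 50],
                           segment=["tail", "partner"])


class TestBuildNativeContacts:
    @pytest.mark.parametrize("d, expected", [(4.4, 1), (4.6, 0)])
    def test_cutoff_is_strict(self, d, expected):
        traj = two_atom_traj(d)
        ncs = build_native_contacts(traj, ContactSpec())
        assert len(ncs) == expected

    def test_matches_brute_force_on_random_frame(self, rng):
        xyz = rng.uniform(0, 15, size=(50, 3))
        n_tail = 25
        traj = make_trajectory([xyz],
                               residue_index=[7] * n_tail + [50] * 25,
                               segment=["tail"] * n_tail + ["partner"] * 25)
        ncs = build_native_contacts(traj, ContactSpec())
        oracle = brute_force_pairs(xyz[:n_tail], xyz[n_tail:], 4.5)
        got = sorted(zip(ncs.atom_i, ncs.atom_j))
        want = sorted((i, j + n_tail) for i, j, _ in oracle)
        assert got == want
        assert np.allclose(sorted(ncs.r0), sorted(d for *_, d in oracle))

    def test_empty_group_raises(self):
        traj = two_atom_traj(4.0)
        spec = ContactSpec(group_a=range(90, 99))
        with pytest.raises(ValueError, match="non-empty"):
            build_native_contacts(traj, spec)


class TestFractionNativeContacts:
    spec = ContactSpec()

    def test_half_at_padded_distance(self):
        """A contact at exactly lam * r0 contributes exactly 1/2."""
        ncs = NativeContactSet(atom_i=[0], atom_j=[1], r0=[4.0])
        xyz = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])  # lam*r0 = 6
        assert fraction_native_contacts(xyz, ncs, self.spec) == pytest.approx(0.5)

    def test_native_frame_value(self):
        # r = r0 = 4: exponent 5*(4 - 6) = -10
        ncs = NativeContactSet(atom_i=[0], atom_j=[1], r0=[4.0])
        xyz = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        expected = 1.0 / (1.0 + np.exp(-10.0))
        assert fraction_native_contacts(xyz, ncs, self.spec) == pytest.approx(
            expected, abs=1e-12)

    def test_broken_contact_value(self):
        # r = 10, r0 = 4: exponent +20
        ncs = NativeContactSet(atom_i=[0], atom_j=[1], r0=[4.0])
        xyz = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        expected = 1.0 / (1.0 + np.exp(20.0))
        q = fraction_native_contacts(xyz, ncs, self.spec)
        assert q == pytest.approx(expected, rel=1e-9)
        assert q < 1e-8

    def test_empty_set_raises(self):
        ncs = NativeContactSet(atom_i=[], atom_j=[], r0=[])
        with pytest.raises(ValueError, match="empty"):
            fraction_native_contacts(np.zeros((2, 3)), ncs, self.spec)


class TestQTimeseries:
    def test_constant_on_repeated_reference(self, rng):
        xyz = rng.uniform(0, 10, size=(20, 3))
        traj = make_trajectory(np.repeat(xyz[None], 5, axis=0),
                               residue_index=[7] * 10 + [50] * 10,
                               segment=["tail"] * 10 + ["partner"] * 10)
        spec = ContactSpec()
        ncs = build_native_contacts(traj, spec)
        q = q_timeseries(traj, ncs, spec)
        assert len(q.value) == 5
        assert np.allclose(q.value, q.value[0])
        assert q.value[0] > 0.95

    def test_translated_tail_breaks_contacts(self):
        xyz = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        frames = np.repeat(xyz[None], 3, axis=0)
        frames[1, 0, 2] += 50.0
        traj = make_trajectory(frames, residue_index=[7, 50],
                               segment=["tail", "partner"])
        spec = ContactSpec()
        ncs = build_native_contacts(traj, spec)
        q = q_timeseries(traj, ncs, spec)
        assert q.value[1] < 0.01
        assert np.all((q.value > 0) & (q.value < 1))


class TestLipidContacts:
    spec = ContactSpec()

    @pytest.mark.parametrize("dz, expected", [(3.4, 1), (3.6, 0)])
    def test_cutoff(self, dz, expected):
        frames = [[[0.0, 0, 0], [0.0, 0, dz]]]
        traj = make_trajectory(frames, residue_index=[2, 1000],
                               segment=["tail", "lipid-phosphate"])
        ts, per = lipid_contacts(traj, [2], self.spec)
        assert ts.value[0] == expected

    def test_pair_counted_once_per_frame(self):
        # two atoms of one residue both touch the same lipid molecule
        frames = [[[0.0, 0, 0], [1.0, 0, 0], [0.5, 0, 3.0], [0.5, 0, 3.2]]]
        traj = make_trajectory(
            frames, residue_index=[2, 2, 1000, 1000],
            segment=["tail", "tail", "lipid-phosphate", "lipid-acyl"])
        ts, _ = lipid_contacts(traj, [2], self.spec)
        assert ts.value[0] == 1

    def test_matches_brute_force(self, rng):
        n_res, n_lip = 5, 20
        res_xyz = rng.uniform(0, 12, size=(n_res * 2, 3))
        lip_xyz = rng.uniform(0, 12, size=(n_lip * 2, 3))
        traj = make_trajectory(
            [np.vstack([res_xyz, lip_xyz])],
            residue_index=(list(np.repeat(np.arange(2, 2 + n_res), 2))
                           + list(np.repeat(np.arange(1000, 1000 + n_lip), 2))),
            segment=["tail"] * (n_res * 2) + ["lipid-phosphate"] * (n_lip * 2))
        ts, _ = lipid_contacts(traj, range(2, 2 + n_res), self.spec)
        count = 0
        for r in range(n_res):
            for m in range(n_lip):
                ra = res_xyz[2 * r:2 * r + 2]
                la = lip_xyz[2 * m:2 * m + 2]
                if any(np.linalg.norm(a - b) <= 3.5 for a in ra for b in la):
                    count += 1
        assert ts.value[0] == count

    def test_no_lipids_raises(self):
        traj = two_atom_traj(4.0)
        with pytest.raises(ValueError, match="lipid"):
            lipid_contacts(traj, [7], self.spec)


def membrane_traj(bead_z, plane_z=0.0, shift=np.zeros(3)):
    """Tail beads at given z values below a 4-phosphate plane."""
    phos = np.array([[x, y, plane_z] for x in (-5, 5) for y in (-5, 5)])
    tail = np.array([[i * 2.0, 0.0, z] for i, z in enumerate(bead_z)])
    xyz = np.vstack([tail, phos]) + shift
    return make_trajectory(
        [xyz], residue_index=list(range(2, 2 + len(bead_z))) + [1000] * 4,
        segment=["tail"] * len(bead_z) + ["lipid-phosphate"] * 4)


class TestZDistribution:
    def test_spike_at_zero(self):
        traj = membrane_traj([0.0, 0.0, 0.0])
        _, _, samples = z_distance_distribution(traj, range(2, 5))
        assert np.allclose(samples, 0.0)

    def test_translation_invariance(self):
        a = membrane_traj([-10.0, -20.0])
        b = membrane_traj([-10.0, -20.0], shift=np.array([3.0, -2.0, 7.0]))
        *_, sa = z_distance_distribution(a, range(2, 4))
        *_, sb = z_distance_distribution(b, range(2, 4))
        assert np.allclose(sa, sb)

    def test_mean_of_two_levels(self):
        traj = membrane_traj([-10.0, -20.0])
        *_, samples = z_distance_distribution(traj, range(2, 4))
        assert samples.mean() == pytest.approx(-15.0)

    def test_no_phosphates_raises(self):
        traj = two_atom_traj(4.0)
        with pytest.raises(ValueError, match="phosphate"):
            z_distance_distribution(traj, [7])


class TestTerminusLength:
    def test_extended_chain(self):
        tail = np.column_stack([np.arange(20) * 3.8, np.zeros(20),
                                np.zeros(20)])
        traj = make_trajectory([tail], residue_index=range(2, 22),
                               segment=["tail"] * 20)
        ts = terminus_length(traj, range(2, 22))
        assert ts.value[0] == pytest.approx(19 * 3.8)

    def test_coincident_ends_zero(self):
        tail = np.zeros((3, 3))
        tail[1] = [1.0, 1.0, 0.0]
        traj = make_trajectory([tail], residue_index=[2, 3, 4],
                               segment=["tail"] * 3)
        assert terminus_length(traj, range(2, 5)).value[0] == 0.0

    def test_rotation_invariance(self, rng):
        tail = rng.normal(size=(10, 3)) * 5
        R = Rotation.from_euler("xyz", [31, -47, 112], degrees=True)
        t1 = make_trajectory([tail], residue_index=range(2, 12),
                             segment=["tail"] * 10)
        t2 = make_trajectory([R.apply(tail)], residue_index=range(2, 12),
                             segment=["tail"] * 10)
        l1 = terminus_length(t1, range(2, 12)).value[0]
        l2 = terminus_length(t2, range(2, 12)).value[0]
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_short_range_raises(self):
        traj = two_atom_traj(4.0)
        with pytest.raises(ValueError, match="2 residues"):
            terminus_length(traj, [7])
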