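import numpy as np
import pytest

from dimerscope import interface as iface
from dimerscope import trajectory_io as tio
from dimerscope.structure_metrics import sasa


def atom(name, element, res_name="ALA", res_seq=1, chain="A"):
    return tio.AtomRecord(1, name, element, res_name, res_seq, chain)


class TestClassifyContact:
    def test_canonical_donor_acceptor_pair_is_hydrogen_bond(self):
        asn = atom("ND2", "N", "ASN", 226, "A")
        thr = atom("OG1", "O", "THR", 264, "B")
        assert iface.classify_contact(asn, [0, 0, 0], thr, [2.9, 0, 0]) == "hydrogen_bond"

    def test_carbon_to_oxygen_between_cutoffs_is_carbon_hydrogen(self):
        c = atom("CB", "C")
        o = atom("O", "O", res_seq=2, chain="B")
        assert iface.classify_contact(c, [0, 0, 0], o, [3.6, 0, 0]) == "carbon_hydrogen"

    def test_carbon_pair_boundaries(self):
        c1, c2 = atom("CB", "C"), atom("CG", "C", "LEU", 3, "B")
        assert iface.classify_contact(c1, [0, 0, 0], c2, [4.0, 0, 0]) == "van_der_waals"
        assert iface.classify_contact(c1, [0, 0, 0], c2, [4.6, 0, 0]) is None

    def test_priority_is_unique_and_ordered(self):
        # donor/acceptor N-O pair inside every cutoff: must be typed H-bond
        asn = atom("ND2", "N", "ASN", 1, "A")
        ser = atom("OG", "O", "SER", 2, "B")
        assert iface.classify_contact(asn, [0, 0, 0], ser, [3.4, 0, 0]) == "hydrogen_bond"
        # same elements but acceptor-acceptor at H-bond range: falls to vdW
        bb_o1 = atom("O", "O", "GLY", 1, "A")
        bb_o2 = atom("O", "O", "GLY", 2, "B")
        assert iface.classify_contact(bb_o1, [0, 0, 0], bb_o2, [3.2, 0, 0]) == "van_der_waals"

    def test_explicit_donor_hydrogen_geometry(self):
        hd21 = atom("HD21", "H", "ASN", 226, "A")
        og1 = atom("OG1", "O", "THR", 264, "B")
        assert iface.classify_contact(hd21, [0, 0, 0], og1, [2.0, 0, 0]) == "hydrogen_bond"
        assert iface.classify_contact(hd21, [0, 0, 0], og1, [2.8, 0, 0]) is None
        hb2 = atom("HB2", "H", "ALA", 3, "A")  # carbon-attached
        assert iface.classify_contact(hb2, [0, 0, 0], og1, [2.8, 0, 0]) == "carbon_hydrogen"


class TestInterfaceSnapshot:
    def test_separated_chains_have_empty_interface(self, dimer):
        traj, _, _ = dimer
        far = tio.Trajectory(
            atoms=traj.atoms,
            frames=traj.frames.copy(),
            times=traj.times.copy(),
        )
        b_idx = [i for i, a in enumerate(far.atoms) if a.chain_id == "B"]
        far.frames[:, b_idx, :] += 500.0
        snap = iface.interface_snapshot(far, 0, "A", "B")
        assert snap.residues_a == set() and snap.residues_b == set()
        assert abs(snap.interface_area) < 1e-6
        assert snap.contacts == []

    def test_interface_residues_match_generator_ground_truth(self, dimer):
        traj, truth, _ = dimer
        for frame in (0, 30, 59):
            snap = iface.interface_snapshot(traj, frame, "A", "B", compute_area=False)
            assert {r for _, r in snap.residues_a} == truth.interface_residues_per_frame[frame]["A"]
            assert {r for _, r in snap.residues_b} == truth.interface_residues_per_frame[frame]["B"]

    def test_interface_area_equals_half_delta_sasa(self, dimer):
        traj, _, _ = dimer
        snap = iface.interface_snapshot(traj, 0, "A", "B", sasa_points=240)
        coords = traj.frames[0]
        heavy = [i for i, a in enumerate(traj.atoms) if not a.is_hydrogen]
        ia = [i for i in heavy if traj.atoms[i].chain_id == "A"]
        ib = [i for i in heavy if traj.atoms[i].chain_id == "B"]
        s_a = sasa(coords[ia], [traj.atoms[i] for i in ia], n_points=240).total
        s_b = sasa(coords[ib], [traj.atoms[i] for i in ib], n_points=240).total
        s_ab = sasa(
            coords[ia + ib], [traj.atoms[i] for i in ia + ib], n_points=240
        ).total
        assert snap.interface_area == pytest.approx(0.5 * (s_a + s_b - s_ab), abs=1e-6)
        assert 0 <= snap.pct_interface_a <= 100
        assert 0 <= snap.pct_interface_b <= 100

    def test_swapping_chain_labels_swaps_residue_sets(self, dimer):
        traj, _, _ = dimer
        ab = iface.interface_snapshot(traj, 10, "A", "B", compute_area=False)
        ba = iface.interface_snapshot(traj, 10, "B", "A", compute_area=False)
        assert ab.residues_a == ba.residues_b
        assert ab.residues_b == ba.residues_a
        assert len(ab.contacts) == len(ba.contacts)

    def test_missing_chain_rejected(self, dimer):
        traj, _, _ = dimer
        with pytest.raises(KeyError):
            iface.interface_snapshot(traj, 0, "A", "Z")


class TestHotSpots:
    def _snap(self, res_a, res_b):
        return iface.InterfaceSnapshot(
            time=0.0,
            residues_a={("ALA", r) for r in res_a},
            residues_b={("ALA", r) for r in res_b},
            contacts=[],
            interface_area=0.0,
            pct_interface_a=0.0,
            pct_interface_b=0.0,
        )

    def test_consensus_is_chainwise_intersection(self):
        snaps = [self._snap({1, 2}, {7}), self._snap({1}, {7, 8}), self._snap({1, 3}, {7})]
        hs = iface.hotspot_consensus(snaps)
        assert hs.residues_a == {("ALA", 1)}
        assert hs.residues_b == {("ALA", 7)}

    def test_disjoint_snapshots_give_empty_consensus(self):
        hs = iface.hotspot_consensus([self._snap({1}, {2}), self._snap({3}, {4})])
        assert hs.residues_a == set() and hs.residues_b == set()

    def test_empty_snapshot_list_rejected(self):
        with pytest.raises(ValueError):
            iface.hotspot_consensus([])

    def test_consensus_monotone_under_added_snapshots(self):
        snaps = [self._snap({1, 2, 3}, {5}), self._snap({1, 2}, {5}), self._snap({2}, {5, 6})]
        prev = iface.hotspot_consensus(snaps[:1])
        for k in (2, 3):
            cur = iface.hotspot_consensus(snaps[:k])
            assert cur.residues_a <= prev.residues_a
            assert cur.residues_b <= prev.residues_b
            prev = cur

    def test_transient_contact_excluded_from_consensus(self, dimer):
        """Residue 12's contact exists only in the first half of the run, so
        snapshots spanning both halves keep residue 7 but drop residue 12."""
        traj, truth, _ = dimer
        times = [0.0, 20.0, 40.0, 59.0]
        _, hs, _ = iface.snapshot_report(traj, times, compute_area=False)
        res_a = {r for _, r in hs.residues_a}
        assert 7 in res_a
        assert 12 not in res_a
        # consensus can only be a superset of the all-frame persistent truth
        assert truth.true_interface_residues["A"] <= res_a


class TestGlycans:
    def test_glycan_contacts_typed_and_span_labeled(self, dimer):
        traj, _, _ = dimer
        contacts = iface.glycan_interactions(traj, 0, [("A", 500)])
        assert contacts, "glycan stand-in should touch nearby residues"
        for c in contacts:
            assert c.kind in {"hydrogen_bond", "carbon_hydrogen", "van_der_waals"}
            chain_partner = c.atom_b.split(":")[0]
            assert c.span == ("intra_chain" if chain_partner == "A" else "inter_chain")

    def test_far_glycan_has_no_contacts(self, dimer):
        traj, _, _ = dimer
        moved = tio.Trajectory(traj.atoms, traj.frames.copy(), traj.times.copy())
        gly = [i for i, a in enumerate(moved.atoms) if a.res_seq == 500]
        moved.frames[:, gly, :] += 300.0
        assert iface.glycan_interactions(moved, 0, [("A", 500)]) == []

    def test_unknown_glycan_residue_rejected(self, dimer):
        traj, _, _ = dimer
        with pytest.raises(KeyError):
            iface.glycan_interactions(traj, 0, [("A", 999)])


class TestSnapshotReport:
    def test_single_time_single_row(self, dimer):
        traj, _, _ = dimer
        table, _, snaps = iface.snapshot_report(traj, [0.0], compute_area=False)
        assert len(table) == 1 and len(snaps) == 1

    def test_seven_snapshot_series(self, dimer):
        traj, _, _ = dimer
        times = list(np.linspace(0, 59, 7))
        table, _, snaps = iface.snapshot_report(traj, times, compute_area=False)
        assert len(table) == 7
        for row, snap in zip(table.itertuples(index=False), snaps):
            assert row.n_residues_a == len(snap.residues_a)
            assert row.n_residues_b == len(snap.residues_b)

    def test_time_outside_span_rejected(self, dimer):
        traj, _, _ = dimer
        with pytest.raises(ValueError, match="outside"):
            iface.snapshot_report(traj, [1000.0], compute_area=False)
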