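import math

import numpy as np
import pytest

from pinmap.interface import (VDW_RADII, buried_surface_area, classify_contacts,
                              hydrophobic_clusters, interface_residues,
                              interface_report, partition_from_chains,
                              pin_residues, shrake_rupley_sasa)
from pinmap.structio import Atom, Chain, Residue, StructureModel
from pinmap.superpose import RigidTransform, apply_transform
from pinmap.synthetic import build_pin_pocket_fixture

from conftest import res_pairs


def atom_model(atoms_by_chain):
    """{chain: [(res_seq, res_name, [(atom, element, xyz), ...])]}"""
    chains = []
    for chain_id, residues in atoms_by_chain.items():
        rs = []
        for res_seq, res_name, atoms in residues:
            rs.append(Residue(res_name, res_seq, "", [
                Atom(name, elem, np.asarray(xyz, float), 90.0)
                for name, elem, xyz in atoms]))
        chains.append(Chain(chain_id, rs))
    return StructureModel("fixture", chains, "synthetic")


def single_atom_model(element="C", xyz=(0.0, 0.0, 0.0), chain="A", res=1):
    return atom_model({chain: [(res, "ALA", [("CA", element, xyz)])]})


class TestShrakeRupley:
    def test_single_sphere_closed_form(self):
        model = single_atom_model()
        sasa = shrake_rupley_sasa(model)
        exact = 4.0 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert sasa.total == pytest.approx(exact, rel=0.005)

    def test_disjoint_spheres_additive(self):
        model = atom_model({"A": [
            (1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))]),
            (2, "ALA", [("CA", "C", (100.0, 0.0, 0.0))]),
        ]})
        sasa = shrake_rupley_sasa(model)
        single = shrake_rupley_sasa(single_atom_model()).total
        assert sasa.total == pytest.approx(2.0 * single, rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        model = atom_model({"A": [
            (1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))]),
            (2, "ALA", [("CA", "C", (d, 0.0, 0.0))]),
        ]})
        sasa = shrake_rupley_sasa(model)
        R = VDW_RADII["C"] + 1.4
        # each sphere loses a cap of height h = R - d/2
        h = R - d / 2.0
        exact = 2.0 * (4.0 * math.pi * R * R - 2.0 * math.pi * R * h)
        assert sasa.total == pytest.approx(exact, rel=0.005)

    def test_total_equals_sum_of_atoms(self, complex_bundle):
        model, _, _ = complex_bundle
        sasa = shrake_rupley_sasa(model)
        assert sasa.total == pytest.approx(sum(sasa.per_atom.values()),
                                           abs=1e-6)

    def test_unknown_element_without_radius(self):
        model = single_atom_model(element="FE")
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(model, radii={"C": 1.7})
        # an override unblocks it
        result = shrake_rupley_sasa(model, radii={"FE": 1.5})
        assert result.total > 0

    def test_agrees_with_independent_reference(self, rng):
        """Cross-check against biotite's Shrake-Rupley on random clusters,
        with a shared radius table so only the algorithms differ."""
        import biotite.structure as struc

        for _ in range(5):
            n = int(rng.integers(6, 15))
            coords = rng.uniform(0, 8, size=(n, 3))
            elements = rng.choice(["C", "N", "O", "S"], size=n)
            model = atom_model({"A": [
                (i + 1, "ALA", [("CA", el, xyz)])
                for i, (el, xyz) in enumerate(zip(elements, coords))]})
            mine = shrake_rupley_sasa(model, n_points=3000)

            arr = struc.AtomArray(n)
            arr.coord = coords.astype(np.float32)
            arr.chain_id = np.array(["A"] * n)
            arr.res_id = np.arange(1, n + 1)
            arr.res_name = np.array(["ALA"] * n)
            arr.atom_name = np.array(["CA"] * n)
            arr.element = elements
            ref = struc.sasa(arr, probe_radius=1.4, point_number=5000,
                             vdw_radii=np.array([VDW_RADII[e] for e in elements]))
            for i in range(n):
                mine_i = mine.per_residue[("A", i + 1, "")]
                assert mine_i == pytest.approx(float(ref[i]),
                                               rel=0.02, abs=0.1)


class TestBuriedSurfaceArea:
    def test_separated_molecules_bury_nothing(self):
        model = atom_model({
            "A": [(1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))])],
            "B": [(1, "ALA", [("CA", "C", (100.0, 0.0, 0.0))])],
        })
        part = partition_from_chains(["A"], ["B"])
        assert buried_surface_area(model, part) == (0.0, 0.0)

    def test_bsa_identity(self, complex_bundle, dimer_partition):
        from pinmap.interface import _split, _union_model

        model, _, _ = complex_bundle
        bsa1, bsa2 = buried_surface_area(model, dimer_partition)
        g1, g2 = _split(model, dimer_partition)
        s1 = shrake_rupley_sasa(g1).total
        s2 = shrake_rupley_sasa(g2).total
        s12 = shrake_rupley_sasa(_union_model(g1, g2)).total
        assert bsa1 + bsa2 == pytest.approx(s1 + s2 - s12, abs=1e-3)
        assert bsa1 > 0 and bsa2 > 0

    def test_matches_generator_regression(self, complex_bundle, dimer_partition):
        model, _, truth = complex_bundle
        bsa = buried_surface_area(model, dimer_partition)
        assert bsa[0] == pytest.approx(truth.bsa[0], abs=1e-6)
        assert bsa[1] == pytest.approx(truth.bsa[1], abs=1e-6)

    def test_overlapping_partition_rejected(self, complex_bundle):
        model, _, _ = complex_bundle
        part = partition_from_chains(["A", "B"], ["B", "C"])
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area(model, part)


def salt_pair_model(distance):
    """A Lys sidechain N on chain A facing a Glu carboxylate O on chain B."""
    return atom_model({
        "A": [(10, "LYS", [("CA", "C", (0.0, 0.0, 0.0)),
                           ("CB", "C", (1.5, 0.0, 0.0)),
                           ("NZ", "N", (3.0, 0.0, 0.0))])],
        "B": [(5, "GLU", [("CA", "C", (3.0 + distance + 3.0, 0.0, 0.0)),
                          ("CB", "C", (3.0 + distance + 1.5, 0.0, 0.0)),
                          ("OE1", "O", (3.0 + distance, 0.0, 0.0))])],
    })


class TestClassifyContacts:
    def test_salt_bridge_at_cutoff_distance(self):
        model = salt_pair_model(3.40)
        contacts = classify_contacts(model, partition_from_chains(["A"], ["B"]))
        salt = [c for c in contacts if c.kind == "salt_bridge"]
        assert len(salt) == 1
        assert salt[0].distance == pytest.approx(3.40, abs=1e-9)
        # NZ-OE1 also satisfies the hydrogen-bond distance but is reported
        # once, under the higher-priority kind
        assert not any(c.kind == "hydrogen_bond"
                       and c.atom_a.atom_name == "NZ" for c in contacts)

    def test_beyond_cutoffs_nothing_reported(self):
        model = salt_pair_model(4.10)
        contacts = classify_contacts(model, partition_from_chains(["A"], ["B"]))
        assert contacts == []

    def test_pin_pocket_fixture_counts(self):
        model, truth = build_pin_pocket_fixture()
        contacts = classify_contacts(model, partition_from_chains(["A"], ["B"]))
        hydro = [c for c in contacts if c.kind == "hydrophobic"]
        pairs = {(c.atom_a.res_key, c.atom_b.res_key) for c in hydro}
        assert len(pairs) == truth["n_hydrophobic_pairs"]

    def test_symmetric_in_group_order(self, complex_bundle):
        model, _, _ = complex_bundle
        fwd = classify_contacts(model, partition_from_chains(["A", "B"], ["C"]))
        rev = classify_contacts(model, partition_from_chains(["C"], ["A", "B"]))
        fwd_pairs = {(c.atom_a.res_key, c.atom_b.res_key, c.kind) for c in fwd}
        rev_pairs = {(c.atom_b.res_key, c.atom_a.res_key, c.kind) for c in rev}
        assert fwd_pairs == rev_pairs

    def test_invariant_under_rigid_motion(self, rng):
        model, _ = build_pin_pocket_fixture()
        part = partition_from_chains(["A"], ["B"])
        base = res_pairs(classify_contacts(model, part))
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = apply_transform(model, RigidTransform(rot, rng.normal(size=3) * 30))
        assert res_pairs(classify_contacts(moved, part)) == base

    def test_every_contact_satisfies_its_cutoff(self, complex_contacts):
        cutoffs = {"salt_bridge": 4.0, "hydrogen_bond": 3.5, "hydrophobic": 4.5}
        assert complex_contacts  # non-empty on the default complex
        for c in complex_contacts:
            assert c.distance <= cutoffs[c.kind] + 1e-9


class TestInterfaceResidues:
    def test_separated_molecules_empty(self):
        model = atom_model({
            "A": [(1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))])],
            "B": [(1, "ALA", [("CA", "C", (100.0, 0.0, 0.0))])],
        })
        out = interface_residues(model, partition_from_chains(["A"], ["B"]))
        assert out == {}

    def test_span_bounds_are_min_max(self, complex_bundle, dimer_partition):
        model, _, _ = complex_bundle
        out = interface_residues(model, dimer_partition)
        for chain, info in out.items():
            assert info["span"] == (min(info["residues"]), max(info["residues"]))


class TestClustersAndPins:
    def test_no_hydrophobic_contacts_no_clusters(self):
        model = salt_pair_model(3.4)
        contacts = classify_contacts(model, partition_from_chains(["A"], ["B"]))
        assert hydrophobic_clusters(contacts) == []

    def test_clusters_partition_hydrophobic_residues(self, complex_contacts):
        clusters = hydrophobic_clusters(complex_contacts, side="b")
        nodes = {c.atom_b.res_key for c in complex_contacts
                 if c.kind == "hydrophobic"}
        seen = set()
        for cluster in clusters:
            assert not (cluster.members & seen)  # disjoint
            seen |= cluster.members
        assert seen == nodes  # covering

    def test_designed_pin_detected(self):
        model, truth = build_pin_pocket_fixture()
        part = partition_from_chains(["A"], ["B"])
        pins = pin_residues(model, part, partner_min=4)
        assert [(p.residue[0], p.residue[1]) for p in pins] == [truth["pin"]]
        assert pins[0].buried_fraction >= 0.75

    def test_partner_min_monotonicity(self):
        model, truth = build_pin_pocket_fixture()
        part = partition_from_chains(["A"], ["B"])
        assert pin_residues(model, part, partner_min=6) == []

    def test_exposed_residue_is_not_a_pin(self, complex_report):
        # every reported pin must be heavily buried with several partners
        for pin in complex_report.pins:
            assert pin.buried_fraction >= 0.75
            assert pin.n_partners >= 4


class TestInterfaceReport:
    def test_pocket_members_belong_to_clusters(self, complex_report):
        cluster_members = set().union(*(c.members for c in complex_report.clusters))
        for pin in complex_report.pins:
            assert set(pin.pocket) <= cluster_members

    def test_contact_residues_are_interfacial(self, complex_report):
        iface = {(chain, res) for chain, info in complex_report.interface.items()
                 for res in info["residues"]}
        for c in complex_report.contacts:
            assert (c.atom_a.chain_id, c.atom_a.res_seq) in iface
            assert (c.atom_b.chain_id, c.atom_b.res_seq) in iface

    def test_serialization_round_trip(self, complex_report, tmp_path):
        import json

        complex_report.to_json(tmp_path / "rep.json")
        with open(tmp_path / "rep.json") as fh:
            data = json.load(fh)
        assert data["bsa_group1_A2"] > 0
        assert data["asymmetric"] is True
        complex_report.to_tsv(tmp_path / "contacts.tsv")
        lines = (tmp_path / "contacts.tsv").read_text().splitlines()
        assert len(lines) == len(complex_report.contacts) + 1
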