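"""Inter-chain contacts, interface qualification and mutation mapping."""

import numpy as np
import pytest

from ppiscreen.interfaces import (
    ComplexStructure,
    MutationRecord,
    Residue,
    interface_residues,
    load_structure,
    map_mutations,
    qualify_interfaces,
    residue_contacts,
)
from ppiscreen.simulate import (
    SimulationConfig,
    gen_random_complex,
    gen_toy_complex,
    structure_to_pdb,
)


def single_residue(number, name="ALA", ca=(0, 0, 0), cb=None):
    atoms = {"CA": np.array(ca, dtype=float)}
    if cb is not None:
        atoms["CB"] = np.array(cb, dtype=float)
    return Residue(number=number, name=name, atoms=atoms)


def two_residue_structure(separation):
    return ComplexStructure(
        chains={
            "A": [single_residue(1, cb=(0, 0, 0))],
            "B": [single_residue(1, ca=(separation, 0, 0), cb=(separation, 0, 0))],
        }
    )


class TestResidueContacts:
    def test_cutoff_is_strict(self):
        assert len(residue_contacts(two_residue_structure(7.9))) == 1
        assert len(residue_contacts(two_residue_structure(8.0))) == 0

    def test_constructed_count_is_exact(self):
        cfg = SimulationConfig(n_interchain_contacts=10, n_chain_residues=30)
        contacts = residue_contacts(gen_toy_complex(cfg))
        assert len(contacts) == 10
        assert {(c.res_a, c.res_b) for c in contacts} == {(i, i) for i in range(1, 11)}

    def test_matches_brute_force_scan(self):
        cfg = SimulationConfig(seed=13, n_chain_residues=15)
        st = gen_random_complex(cfg)
        contacts = {(c.res_a, c.res_b) for c in residue_contacts(st)}
        expected = set()
        for ra in st.chains["A"]:
            for rb in st.chains["B"]:
                xa = np.vstack(list(ra.atoms.values()))
                xb = np.vstack(list(rb.atoms.values()))
                d = min(
                    float(np.linalg.norm(xa[i] - xb[j]))
                    for i in range(len(xa))
                    for j in range(len(xb))
                )
                if d < 8.0:
                    expected.add((ra.number, rb.number))
        assert contacts == expected

    def test_single_chain_warns_and_returns_empty(self):
        st = ComplexStructure(chains={"A": [single_residue(1)]})
        with pytest.warns(UserWarning):
            assert residue_contacts(st) == []

    def test_cutoff_monotonicity(self):
        cfg = SimulationConfig(seed=21, n_chain_residues=20)
        st = gen_random_complex(cfg)
        at6 = {(c.res_a, c.res_b) for c in residue_contacts(st, cutoff=6.0)}
        at8 = {(c.res_a, c.res_b) for c in residue_contacts(st, cutoff=8.0)}
        assert at6 <= at8

    def test_heavy_atom_mode_is_superset_of_cbeta(self):
        cfg = SimulationConfig(seed=22, n_chain_residues=20)
        st = gen_random_complex(cfg)
        heavy = {(c.res_a, c.res_b) for c in residue_contacts(st, atom_mode="min_heavy_atom")}
        cbeta = {(c.res_a, c.res_b) for c in residue_contacts(st, atom_mode="c_beta")}
        assert cbeta <= heavy


class TestQualifyInterfaces:
    @pytest.mark.parametrize("n_contacts,expected", [(10, True), (9, False)])
    def test_minimum_contact_rule(self, n_contacts, expected):
        cfg = SimulationConfig(n_interchain_contacts=n_contacts)
        [iface] = qualify_interfaces(residue_contacts(gen_toy_complex(cfg)))
        assert iface.qualifies is expected
        assert iface.n_contacts == n_contacts

    def test_three_chain_grouping(self):
        # chains A and B overlap heavily; C touches A at one residue only
        a = [single_residue(i + 1, ca=(i * 10.0, 0, 0)) for i in range(12)]
        b = [single_residue(i + 1, ca=(i * 10.0, 5, 0)) for i in range(12)]
        c = [single_residue(1, ca=(0, -5, 0))]
        ifaces = qualify_interfaces(
            residue_contacts(ComplexStructure(chains={"A": a, "B": b, "C": c}))
        )
        by_pair = {f.chain_pair: f for f in ifaces}
        assert by_pair[("A", "B")].qualifies and by_pair[("A", "B")].n_contacts == 12
        assert not by_pair[("A", "C")].qualifies and by_pair[("A", "C")].n_contacts == 1
        assert ("B", "C") not in by_pair

    def test_empty_contacts(self):
        assert qualify_interfaces([]) == []

    def test_contact_bookkeeping(self):
        cfg = SimulationConfig(seed=30, n_chain_residues=25)
        contacts = residue_contacts(gen_random_complex(cfg))
        ifaces = qualify_interfaces(contacts)
        assert sum(f.n_contacts for f in ifaces) == len(contacts)


class TestInterfaceResidues:
    def test_union_per_chain(self):
        cfg = SimulationConfig(n_interchain_contacts=10)
        [iface] = qualify_interfaces(residue_contacts(gen_toy_complex(cfg)))
        residues = interface_residues(iface)
        assert residues == {"A": set(range(1, 11)), "B": set(range(1, 11))}


class TestMapMutations:
    @pytest.fixture
    def toy_interface(self):
        cfg = SimulationConfig(n_interchain_contacts=10)
        st = gen_toy_complex(cfg)
        [iface] = qualify_interfaces(residue_contacts(st))
        return st, iface

    def test_interface_mutation_matched_and_consistent(self, toy_interface):
        st, iface = toy_interface
        mut = MutationRecord("GENE1", 5, "A", "V")  # toy residues are all ALA
        [m] = map_mutations([mut], iface, {"GENE1": ("A", 0)}, structure=st)
        assert m.matched and m.ref_consistent

    def test_non_interface_position_not_matched(self, toy_interface):
        st, iface = toy_interface
        [m] = map_mutations([MutationRecord("GENE1", 25, "A", "V")], iface, {"GENE1": ("A", 0)}, structure=st)
        assert not m.matched

    def test_reference_mismatch_flagged_not_dropped(self, toy_interface):
        st, iface = toy_interface
        [m] = map_mutations([MutationRecord("GENE1", 5, "W", "V")], iface, {"GENE1": ("A", 0)}, structure=st)
        assert m.matched and m.ref_consistent is False and "mismatch" in m.note

    def test_offset_applied(self, toy_interface):
        st, iface = toy_interface
        # canonical position 105 with offset -100 lands on structure residue 5
        [m] = map_mutations([MutationRecord("GENE1", 105, "A", "V")], iface, {"GENE1": ("A", -100)}, structure=st)
        assert m.matched

    def test_unmapped_gene_skipped_with_notice(self, toy_interface):
        st, iface = toy_interface
        [m] = map_mutations([MutationRecord("OTHER", 5, "A", "V")], iface, {"GENE1": ("A", 0)})
        assert not m.matched and "chain map" in m.note

    def test_invalid_amino_acid_code_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord("G", 5, "B", "V")
        with pytest.raises(ValueError):
            MutationRecord("G", 5, "A", "A")


def test_pdb_roundtrip_preserves_contacts(tmp_path):
    cfg = SimulationConfig(seed=17, n_chain_residues=25)
    st = gen_random_complex(cfg)
    path = tmp_path / "complex.pdb"
    structure_to_pdb(st, path)
    reloaded = load_structure(path)
    original = {(c.res_a, c.res_b) for c in residue_contacts(st)}
    after = {(c.res_a, c.res_b) for c in residue_contacts(reloaded)}
    assert original == after
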