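import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppidisp.interactome import (
    AlignmentRecord,
    ChainStructure,
    Interactome,
    InvalidInputError,
    PPIRecord,
    Protein,
    annotate_ppi_template,
    compute_interface,
    count_mutually_exclusive,
    interface_overlap,
    read_fasta,
    read_interactome_tsv,
    read_pdb_chains,
    write_fasta,
    write_interactome_tsv,
)


def single_atom_chain(chain_id, xyz, position=1):
    return ChainStructure(chain_id, [(position, np.array([xyz]))])


def brute_force_interface(chain_a, chain_b, cutoff):
    """O(n^2) all-atom-pairs reference scan."""
    iface_a, iface_b = set(), set()
    for pos_a, atoms_a in chain_a.residues:
        for pos_b, atoms_b in chain_b.residues:
            for xa in atoms_a:
                for xb in atoms_b:
                    if math.dist(xa, xb) <= cutoff:
                        iface_a.add(pos_a)
                        iface_b.add(pos_b)
    return iface_a, iface_b


def random_chain(rng, chain_id, n_residues, max_atoms=3, scale=10.0):
    residues = [
        (pos, rng.uniform(0, scale, size=(rng.integers(1, max_atoms + 1), 3)))
        for pos in range(1, n_residues + 1)
    ]
    return ChainStructure(chain_id, residues)


class TestComputeInterface:
    def test_beyond_cutoff_empty(self):
        a = single_atom_chain("A", (0.0, 0.0, 0.0))
        b = single_atom_chain("B", (6.0, 0.0, 0.0))
        assert compute_interface(a, b) == (set(), set())

    def test_boundary_inclusive_at_exact_cutoff(self):
        # 3-4-5 triangle: distance exactly 5.0
        a = single_atom_chain("A", (0.0, 0.0, 0.0))
        b = single_atom_chain("B", (3.0, 4.0, 0.0))
        assert compute_interface(a, b) == ({1}, {1})

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a = random_chain(rng, "A", int(rng.integers(1, 11)))
            b = random_chain(rng, "B", int(rng.integers(1, 11)))
            assert compute_interface(a, b) == brute_force_interface(a, b, 5.0)

    def test_shrinking_cutoff_monotone(self, rng):
        a = random_chain(rng, "A", 10)
        b = random_chain(rng, "B", 10)
        previous = None
        for cutoff in (8.0, 5.0, 3.0, 1.0):
            ia, ib = compute_interface(a, b, cutoff)
            if previous is not None:
                assert ia <= previous[0] and ib <= previous[1]
            previous = (ia, ib)

    def test_symmetric_emptiness(self, rng):
        for _ in range(10):
            a = random_chain(rng, "A", 5)
            b = random_chain(rng, "B", 5)
            ia, ib = compute_interface(a, b)
            assert bool(ia) == bool(ib)

    def test_invalid_cutoff(self):
        a = single_atom_chain("A", (0, 0, 0))
        with pytest.raises(InvalidInputError):
            compute_interface(a, a, distance_cutoff=0.0)

    def test_empty_chain_rejected(self):
        a = single_atom_chain("A", (0, 0, 0))
        with pytest.raises(InvalidInputError):
            compute_interface(a, ChainStructure("B", []))


class TestChainStructure:
    def test_positions_must_increase(self):
        with pytest.raises(InvalidInputError):
            ChainStructure("A", [(2, np.zeros((1, 3))), (1, np.zeros((1, 3)))])

    def test_residue_needs_atoms(self):
        with pytest.raises(InvalidInputError):
            ChainStructure("A", [(1, np.zeros((0, 3)))])


class TestAnnotateTemplate:
    def setup_method(self):
        self.prot_a = Protein("PA", "A" * 50)
        self.prot_b = Protein("PB", "C" * 50)
        self.iface = (set(range(1, 11)), set(range(1, 11)))

    @staticmethod
    def identity_alignment(protein_id, chain_id, n=50, e_value=1e-10):
        return AlignmentRecord(
            protein_id, chain_id, e_value, {i: i for i in range(1, n + 1)}
        )

    def test_half_coverage_boundary_annotated(self):
        # residue maps cover exactly 5 of 10 interface residues per side
        alns = [
            AlignmentRecord("PA", "X", 1e-10, {i: i for i in range(1, 6)}),
            AlignmentRecord("PB", "Y", 1e-10, {i: i for i in range(1, 6)}),
        ]
        ppi = annotate_ppi_template(
            (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y"), "tmpl"
        )
        assert ppi is not None
        assert ppi.interface_a == frozenset(range(1, 6))

    def test_below_threshold_none(self):
        alns = [
            AlignmentRecord("PA", "X", 1e-10, {i: i for i in range(1, 5)}),  # 4/10
            AlignmentRecord("PB", "Y", 1e-10, {i: i for i in range(1, 11)}),
        ]
        assert (
            annotate_ppi_template(
                (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y")
            )
            is None
        )

    def test_identity_alignment_preserves_interface(self):
        alns = [
            self.identity_alignment("PA", "X"),
            self.identity_alignment("PB", "Y"),
        ]
        ppi = annotate_ppi_template(
            (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y"), "tmpl"
        )
        assert ppi.interface_a == frozenset(self.iface[0])
        assert ppi.interface_b == frozenset(self.iface[1])
        assert ppi.template == ("tmpl", ("X", "Y"))

    def test_both_partners_same_chain_only_none(self):
        alns = [
            self.identity_alignment("PA", "X"),
            self.identity_alignment("PB", "X"),
        ]
        assert (
            annotate_ppi_template(
                (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y")
            )
            is None
        )

    def test_e_value_filter(self):
        alns = [
            self.identity_alignment("PA", "X", e_value=1e-3),  # above cutoff
            self.identity_alignment("PB", "Y"),
        ]
        assert (
            annotate_ppi_template(
                (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y")
            )
            is None
        )

    def test_zero_threshold_annotates_any_alignment_pair(self):
        alns = [
            AlignmentRecord("PA", "X", 1e-10, {40: 40}),  # covers none of iface
            AlignmentRecord("PB", "Y", 1e-10, {40: 40}),
        ]
        assert (
            annotate_ppi_template(
                (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y"),
                coverage_threshold=0.0,
            )
            is not None
        )

    def test_threshold_above_one_annotates_none(self):
        alns = [
            self.identity_alignment("PA", "X"),
            self.identity_alignment("PB", "Y"),
        ]
        assert (
            annotate_ppi_template(
                (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y"),
                coverage_threshold=1.001,
            )
            is None
        )

    def test_chain_swap_assignment(self):
        # PA aligns to Y and PB to X: annotation still found
        alns = [
            self.identity_alignment("PA", "Y"),
            self.identity_alignment("PB", "X"),
        ]
        ppi = annotate_ppi_template(
            (self.prot_a, self.prot_b), self.iface, alns, ("X", "Y"), "t"
        )
        assert ppi is not None and ppi.template == ("t", ("Y", "X"))


def hub_interactome(n_partners, shared=True):
    hub_iface = frozenset(range(1, 5))
    proteins = [Protein("H", "A" * 40)] + [
        Protein(f"P{i}", "A" * 40) for i in range(n_partners)
    ]
    ppis = []
    for i in range(n_partners):
        iface = hub_iface if shared else frozenset(range(1 + 4 * i, 5 + 4 * i))
        ppis.append(
            PPIRecord("H", f"P{i}", interface_a=iface, interface_b=frozenset({1, 2}))
        )
    return Interactome(proteins, ppis)


class TestMutualExclusivity:
    def test_single_ppi_is_zero(self):
        inter = hub_interactome(1)
        assert count_mutually_exclusive(inter, inter.ppis[0]) == (0, "0")

    def test_six_identical_interfaces_ge5(self):
        inter = hub_interactome(6)
        for ppi in inter.ppis:
            assert count_mutually_exclusive(inter, ppi) == (5, ">=5")

    def test_disjoint_interfaces_zero(self):
        inter = hub_interactome(3, shared=False)
        for ppi in inter.ppis:
            assert count_mutually_exclusive(inter, ppi) == (0, "0")

    def test_bin_1_4(self):
        inter = hub_interactome(3)
        for ppi in inter.ppis:
            assert count_mutually_exclusive(inter, ppi) == (2, "1-4")

    def test_symmetric_under_partner_relabel(self):
        inter = hub_interactome(4)
        flipped = Interactome(
            list(inter.proteins.values()),
            [
                PPIRecord(p.partner_b, p.partner_a, p.interface_b, p.interface_a)
                for p in inter.ppis
            ],
        )
        for orig, flip in zip(inter.ppis, flipped.ppis):
            assert (
                count_mutually_exclusive(inter, orig)[0]
                == count_mutually_exclusive(flipped, flip)[0]
            )

    def test_empty_interface_contributes_zero(self):
        proteins = [Protein(p, "A" * 20) for p in ("X", "Y", "Z")]
        ppis = [
            PPIRecord("X", "Y", frozenset(), frozenset({1})),
            PPIRecord("X", "Z", frozenset({1, 2}), frozenset({1})),
        ]
        inter = Interactome(proteins, ppis)
        assert count_mutually_exclusive(inter, inter.ppis[0])[0] == 0

    def test_overlap_definition(self):
        assert interface_overlap({1, 2, 3, 4}, {3, 4}) == 1.0  # smaller set fully in
        assert interface_overlap({1, 2}, {3, 4}) == 0.0
        assert interface_overlap(set(), {1}) == 0.0


class TestInteractomeModel:
    def test_duplicate_pairs_collapsed_first_wins(self):
        proteins = [Protein("A", "AAAA"), Protein("B", "CCCC")]
        ppis = [
            PPIRecord("A", "B", frozenset({1}), frozenset({1}), delta_g=-10.0),
            PPIRecord("B", "A", frozenset({2}), frozenset({2}), delta_g=-30.0),
        ]
        inter = Interactome(proteins, ppis)
        assert len(inter) == 1
        assert inter.ppis[0].delta_g == -10.0

    def test_unknown_partner_rejected(self):
        with pytest.raises(InvalidInputError):
            Interactome([Protein("A", "AAAA")], [PPIRecord("A", "B")])

    def test_interface_out_of_bounds_rejected(self):
        proteins = [Protein("A", "AAAA"), Protein("B", "CCCC")]
        with pytest.raises(InvalidInputError):
            Interactome(proteins, [PPIRecord("A", "B", frozenset({5}), frozenset())])

    def test_homodimer_allowed(self):
        inter = Interactome(
            [Protein("A", "AAAA")],
            [PPIRecord("A", "A", frozenset({1}), frozenset({2}))],
        )
        assert inter.ppis[0].is_homodimer
        assert inter.ppis[0].interface_of("A") == frozenset({1, 2})

    def test_protein_validation(self):
        with pytest.raises(InvalidInputError):
            Protein("A", "")
        with pytest.raises(InvalidInputError):
            Protein("A", "AZB")  # Z not standard


class TestIO:
    def test_pdb_first_model_atoms_only(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  GLY B   1       3.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    4  O   HOH A   2      50.000  50.000  50.000  1.00  0.00           O\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      5  CA  ALA A   9      99.000  99.000  99.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "END\n"
        )
        chains = read_pdb_chains(pdb)
        assert set(chains) == {"A", "B"}
        assert chains["A"].positions == [1]  # HETATM excluded, model 2 ignored
        assert len(chains["A"].residues[0][1]) == 2
        ia, ib = compute_interface(chains["A"], chains["B"])
        assert (ia, ib) == ({1}, {1})

    def test_interactome_tsv_round_trip(self, tmp_path, small_bundle):
        inter = small_bundle.interactome
        path = tmp_path / "interactome.tsv"
        write_interactome_tsv(inter, path)
        back = read_interactome_tsv(path, inter.proteins, name=inter.name)
        assert len(back) == len(inter)
        for orig, rt in zip(inter.ppis, back.ppis):
            assert orig.partners() == rt.partners()
            assert orig.interface_a == rt.interface_a
            assert orig.interface_b == rt.interface_b
            assert orig.delta_g == rt.delta_g
            assert orig.template == rt.template

    def test_fasta_round_trip(self, tmp_path):
        proteins = [Protein("p1", "ACDEF"), Protein("p2", "GHIKX")]
        path = tmp_path / "p.fasta"
        write_fasta(proteins, path)
        back = read_fasta(path)
        assert {p.id: p.sequence for p in proteins} == {
            k: v.sequence for k, v in back.items()
        }


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0, 12, allow_nan=False, width=32),
            st.floats(0, 12, allow_nan=False, width=32),
            st.floats(0, 12, allow_nan=False, width=32),
        ),
        min_size=1,
        max_size=8,
    ),
    st.lists(
        st.tuples(
            st.floats(0, 12, allow_nan=False, width=32),
            st.floats(0, 12, allow_nan=False, width=32),
            st.floats(0, 12, allow_nan=False, width=32),
        ),
        min_size=1,
        max_size=8,
    ),
)
def test_interface_property_matches_oracle(coords_a, coords_b):
    a = ChainStructure("A", [(i + 1, np.array([c])) for i, c in enumerate(coords_a)])
    b = ChainStructure("B", [(i + 1, np.array([c])) for i, c in enumerate(coords_b)])
    assert compute_interface(a, b) == brute_force_interface(a, b, 5.0)
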