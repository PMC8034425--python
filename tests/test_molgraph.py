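"""Molecular graph construction: formulas, molfile parsing, perception."""

import pytest
from hypothesis import given, settings, strategies as st

from screenkit.molgraph import (
    Atom,
    Bond,
    FormulaError,
    MolfileError,
    MoleculeGraph,
    format_formula,
    parse_formula,
    perceive,
    read_molfile,
    read_sdf,
)

from conftest import benzene_ring, make_mol


class TestParseFormula:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C19H11F4NO2", {"C": 19, "H": 11, "F": 4, "N": 1, "O": 2}),
            ("H2O", {"H": 2, "O": 1}),
            ("C", {"C": 1}),
            ("CH3Cl", {"C": 1, "H": 3, "Cl": 1}),
        ],
    )
    def test_counts(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx2", "C19Q", "c2h6"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_roundtrip_hill_order(self):
        assert format_formula(parse_formula("C19H11F4NO2")) == "C19H11F4NO2"

    @given(
        counts=st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "F", "S", "Cl", "Br"]),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_format_parse_identity(self, counts):
        assert parse_formula(format_formula(counts)) == counts


class TestReadMolfile:
    def test_benzene_fixture(self, benzene):
        assert len(benzene.atoms) == 6
        assert len(benzene.bonds) == 6
        assert all(a.element == "C" for a in benzene.atoms)

    def test_nsc765598_heavy_atoms_match_formula(self, nsc765598):
        heavy = parse_formula("C19H11F4NO2")
        heavy.pop("H")
        assert len(nsc765598.atoms) == sum(heavy.values()) == 26
        counts = nsc765598.formula_counts(with_implicit_h=False)
        assert counts == heavy

    def test_count_mismatch_is_error(self):
        text = "\n".join(
            [
                "bad", "", "",
                "  5  0  0  0  0  0  0  0  0  0999 V2000",
                "    0.0000    0.0000    0.0000 C   0  0",
                "    0.0000    0.0000    0.0000 C   0  0",
                "    0.0000    0.0000    0.0000 C   0  0",
                "    0.0000    0.0000    0.0000 C   0  0",
                "M  END",
            ]
        )
        # the declared 5th atom line is actually "M  END"
        with pytest.raises(MolfileError, match="line 9"):
            read_molfile(text)

    def test_v3000_rejected(self):
        text = "\n".join(
            ["m", "", "", "  0  0  0     0  0            999 V3000"]
        )
        with pytest.raises(MolfileError, match="V3000"):
            read_molfile(text)

    def test_charge_block_applied(self):
        text = "\n".join(
            [
                "oxide", "", "",
                "  1  0  0  0  0  0  0  0  0  0999 V2000",
                "    0.0000    0.0000    0.0000 O   0  0",
                "M  CHG  1   1  -1",
                "M  END",
            ]
        )
        mol = read_molfile(text)
        assert mol.atoms[0].formal_charge == -1

    def test_sdf_iterates_records_in_order(self):
        rec = "\n".join(
            [
                "one", "", "",
                "  1  0  0  0  0  0  0  0  0  0999 V2000",
                "    0.0000    0.0000    0.0000 C   0  0",
                "M  END",
            ]
        )
        rec2 = rec.replace("one", "two").replace(" C ", " N ")
        mols = list(read_sdf(rec + "\n$$$$\n" + rec2 + "\n$$$$\n"))
        assert [m.name for m in mols] == ["one", "two"]
        assert [m.atoms[0].element for m in mols] == ["C", "N"]


class TestGraphInvariants:
    def test_self_bond_rejected(self):
        with pytest.raises(MolfileError, match="self-bond"):
            MoleculeGraph("x", [Atom("C")], [Bond(0, 0, 1)])

    def test_duplicate_bond_rejected(self):
        with pytest.raises(MolfileError, match="duplicate"):
            MoleculeGraph(
                "x", [Atom("C"), Atom("C")], [Bond(0, 1, 1), Bond(1, 0, 1)]
            )

    def test_dangling_bond_rejected(self):
        with pytest.raises(MolfileError, match="missing atom"):
            MoleculeGraph("x", [Atom("C")], [Bond(0, 1, 1)])


class TestImplicitH:
    def test_benzene_one_h_per_carbon(self, benzene):
        assert [a.implicit_h for a in benzene.atoms] == [1] * 6

    def test_carbonyl_carbon_fully_substituted(self):
        # C(=O)(C)(N): the central carbon has no room for hydrogen
        mol = make_mol(
            "amide-core",
            ["C", "O", "C", "N"],
            [(0, 1, 2), (0, 2, 1), (0, 3, 1)],
        )
        assert mol.atoms[0].implicit_h == 0

    def test_nsc765598_total_h_matches_formula(self, nsc765598):
        assert sum(a.implicit_h for a in nsc765598.atoms) == 11

    def test_charged_atoms(self):
        ammonium = make_mol("ammonium", ["N"], [], charges={0: 1})
        assert ammonium.atoms[0].implicit_h == 4
        oxide = make_mol("methoxide", ["C", "O"], [(0, 1, 1)], charges={1: -1})
        assert oxide.atoms[1].implicit_h == 0

    def test_overvalent_floors_at_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="screenkit.molgraph"):
            mol = make_mol(
                "overvalent",
                ["C", "O", "O", "O"],
                [(0, 1, 2), (0, 2, 2), (0, 3, 2)],
            )
        assert mol.atoms[0].implicit_h == 0
        assert "valence" in caplog.text


class TestRingPerception:
    def test_benzene_all_in_ring(self, benzene):
        assert all(a.in_ring for a in benzene.atoms)
        assert all(b.in_ring for b in benzene.bonds)

    def test_biphenyl_link_not_in_ring(self, biphenyl):
        link = next(b for b in biphenyl.bonds if b.pair() == frozenset((0, 6)))
        assert not link.in_ring
        assert sum(b.in_ring for b in biphenyl.bonds) == 12

    def test_hexane_acyclic(self, hexane):
        assert not any(a.in_ring for a in hexane.atoms)
        assert not any(b.in_ring for b in hexane.bonds)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance(self, nsc765598, seed):
        """Relabeling atoms must not change which bonds are in rings."""
        import numpy as np

        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(nsc765598.atoms))
        atoms = [Atom(element=nsc765598.atoms[i].element) for i in np.argsort(perm)]
        bonds = [
            Bond(int(perm[b.a]), int(perm[b.b]), b.order)
            for b in nsc765598.bonds
        ]
        permuted = perceive(MoleculeGraph("perm", atoms, bonds))
        original_pairs = {
            frozenset((perm[b.a], perm[b.b]))
            for b in nsc765598.bonds
            if b.in_ring
        }
        permuted_pairs = {b.pair() for b in permuted.bonds if b.in_ring}
        assert original_pairs == permuted_pairs


class TestAromaticity:
    def test_benzene_aromatic(self, benzene):
        assert sum(a.aromatic for a in benzene.atoms) == 6

    def test_cyclohexane_not_aromatic(self, cyclohexane):
        assert not any(a.aromatic for a in cyclohexane.atoms)

    def test_nsc765598_three_benzenoid_rings(self, nsc765598):
        assert sum(a.aromatic for a in nsc765598.atoms) == 18

    def test_pyridine_nitrogen_aromatic(self):
        ring = benzene_ring()
        mol = make_mol("pyridine", ["N"] + ["C"] * 5, ring)
        assert mol.atoms[0].aromatic

    def test_aromatic_implies_in_ring(self, nsc765598, benzene):
        for mol in (nsc765598, benzene):
            assert all(a.in_ring for a in mol.atoms if a.aromatic)
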