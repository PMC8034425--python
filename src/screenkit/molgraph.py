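"""Minimal small-molecule graphs: V2000 molfile input, formulas, perception.

The molecule model is deliberately small: heavy atoms with formal charges,
bonds of integer order 1-3, and three derived annotations (implicit hydrogen
counts, ring membership, benzenoid aromaticity). That is exactly what the
graph-derivable drug-likeness descriptors need; stereochemistry, tautomers
and non-benzenoid aromaticity are out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: Elements the parser accepts, with default (neutral, lowest) valences.
DEFAULT_VALENCE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "S": 2, "P": 3,
    "Cl": 1, "Br": 1, "I": 1, "H": 1,
}

KNOWN_ELEMENTS = frozenset(DEFAULT_VALENCE)


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


class MolfileError(ValueError):
    """Raised for structurally invalid molfile input (with line context)."""


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False
    in_ring: bool = False


@dataclass
class Bond:
    a: int
    b: int
    order: int
    in_ring: bool = False
    aromatic: bool = False

    def pair(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


@dataclass
class MoleculeGraph:
    """A heavy-atom molecular graph with derived annotations.

    ``rings`` holds the perceived minimum cycle basis as ordered atom-index
    tuples once :func:`perceive_rings` has run.
    """

    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    rings: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise MolfileError(
                    f"bond ({bond.a}, {bond.b}) references a missing atom"
                )
            if bond.a == bond.b:
                raise MolfileError(f"self-bond on atom {bond.a}")
            if bond.pair() in seen:
                raise MolfileError(f"duplicate bond ({bond.a}, {bond.b})")
            seen.add(bond.pair())

    # -- convenience views -------------------------------------------------

    def bond_orders_at(self, i: int) -> list[int]:
        return [b.order for b in self.bonds if i in (b.a, b.b)]

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in (b.a, b.b))

    def neighbors(self, i: int) -> list[int]:
        return [b.b if b.a == i else b.a for b in self.bonds if i in (b.a, b.b)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((b.a, b.b) for b in self.bonds)
        return g

    def formula_counts(self, with_implicit_h: bool = True) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
        if with_implicit_h:
            n_h = sum(a.implicit_h for a in self.atoms)
            if n_h:
                counts["H"] = counts.get("H", 0) + n_h
        return counts


# ---------------------------------------------------------------------------
# Molecular formulas

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    ``"C19H11F4NO2"`` -> ``{"C": 19, "H": 11, "F": 4, "N": 1, "O": 2}``.
    A missing count means 1.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        symbol, digits = m.groups()
        if symbol not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Canonical Hill-order string: C first, H second, others alphabetical."""
    for symbol, n in counts.items():
        if symbol not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {symbol!r}")
        if not (isinstance(n, int) and n >= 1):
            raise FormulaError(f"count for {symbol} must be a positive integer")
    order = [s for s in ("C", "H") if s in counts]
    order += sorted(s for s in counts if s not in ("C", "H"))
    return "".join(f"{s}{counts[s] if counts[s] > 1 else ''}" for s in order)


# ---------------------------------------------------------------------------
# MDL molfile (V2000) input

def read_molfile(text: str, name: str | None = None) -> MoleculeGraph:
    """Read a single MDL V2000 molfile (or SDF record) into a graph.

    Coordinates are discarded; ``M  CHG`` blocks are applied. V3000 input is
    rejected. Errors carry the 1-based line number of the offending line.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile too short: missing counts line (line 4)")
    counts_line = lines[3]
    if "V3000" in counts_line:
        raise MolfileError("V3000 molfiles are not supported; supply V2000")
    try:
        n_atoms = int(counts_line[0:3])
        n_bonds = int(counts_line[3:6])
    except ValueError as exc:
        raise MolfileError(f"bad counts line (line 4): {counts_line!r}") from exc

    atom_start = 4
    bond_start = atom_start + n_atoms
    if len(lines) < bond_start + n_bonds:
        raise MolfileError(
            f"truncated molfile: counts line declares {n_atoms} atoms and "
            f"{n_bonds} bonds but only {len(lines)} lines are present"
        )

    atoms: list[Atom] = []
    for idx in range(n_atoms):
        lineno = atom_start + idx + 1
        line = lines[atom_start + idx]
        fields = line.split()
        if len(fields) < 4:
            raise MolfileError(f"bad atom line {lineno}: {line!r}")
        element = fields[3]
        if element not in KNOWN_ELEMENTS:
            raise MolfileError(
                f"unknown element {element!r} on atom line {lineno}"
            )
        atoms.append(Atom(element=element))

    bonds: list[Bond] = []
    for idx in range(n_bonds):
        lineno = bond_start + idx + 1
        line = lines[bond_start + idx]
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError) as exc:
            raise MolfileError(f"bad bond line {lineno}: {line!r}") from exc
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise MolfileError(
                f"bond line {lineno} references atom outside 1..{n_atoms}"
            )
        if order not in (1, 2, 3):
            raise MolfileError(
                f"unsupported bond order {order} on line {lineno}"
            )
        bonds.append(Bond(a=a - 1, b=b - 1, order=order))

    for offset, line in enumerate(lines[bond_start + n_bonds:]):
        if line.startswith("M  CHG"):
            fields = line.split()
            n_entries = int(fields[2])
            for k in range(n_entries):
                atom_idx = int(fields[3 + 2 * k]) - 1
                charge = int(fields[4 + 2 * k])
                atoms[atom_idx].formal_charge = charge
        if line.startswith("M  END"):
            break

    mol_name = name if name is not None else (lines[0].strip() or "unnamed")
    return MoleculeGraph(name=mol_name, atoms=atoms, bonds=bonds)


def read_sdf(text: str) -> Iterator[MoleculeGraph]:
    """Iterate the records of a (multi-record) SDF string in order."""
    for record in text.split("$$$$"):
        if record.strip():
            yield read_molfile(record.lstrip("\n"))


def load_fixture(name: str) -> MoleculeGraph:
    """Load a packaged structure fixture (e.g. ``"nsc765598"``), perceived."""
    text = (resources.files("screenkit.data") / f"{name}.mol").read_text()
    return perceive(read_molfile(text))


# ---------------------------------------------------------------------------
# Perception passes

def assign_implicit_h(mol: MoleculeGraph) -> MoleculeGraph:
    """Fill ``implicit_h`` from default valences, bond orders and charge.

    implicit_h = max(0, default_valence + formal_charge - sum(bond orders)).
    The additive charge adjustment covers the common organic cases
    (N+ tetravalent, O- monovalent); over-valent atoms floor at 0 with a
    logged warning rather than raising.
    """
    for i, atom in enumerate(mol.atoms):
        used = sum(mol.bond_orders_at(i))
        target = DEFAULT_VALENCE[atom.element] + atom.formal_charge
        h = target - used
        if h < 0:
            logger.warning(
                "atom %d (%s) in %s exceeds its default valence "
                "(%d bonds vs %d); implicit H floored at 0",
                i, atom.element, mol.name, used, target,
            )
            h = 0
        atom.implicit_h = h
    return mol


def _ordered_ring(ring_nodes: list[int], adjacency: dict[int, set[int]]) -> tuple[int, ...] | None:
    """Order a cycle-basis node set by traversal; None if not a simple ring."""
    members = set(ring_nodes)
    if any(len(adjacency[n] & members) != 2 for n in members):
        return None
    start = min(members)
    order = [start]
    prev = None
    while len(order) < len(members):
        current = order[-1]
        nxt = [n for n in adjacency[current] & members if n != prev]
        if not nxt:
            return None
        # deterministic tie-break on the first step of the walk
        order.append(min(nxt))
        prev = current
    return tuple(order)


def perceive_rings(mol: MoleculeGraph) -> MoleculeGraph:
    """Mark atoms/bonds lying on any cycle of a minimum cycle basis.

    Ties in the basis are irrelevant for membership: an edge is in-ring
    exactly when it is not a bridge of the graph.
    """
    g = mol.to_networkx()
    basis = nx.minimum_cycle_basis(g) if g.number_of_edges() else []
    adjacency = {i: set(mol.neighbors(i)) for i in range(len(mol.atoms))}

    rings: list[tuple[int, ...]] = []
    for ring_nodes in basis:
        ordered = _ordered_ring(ring_nodes, adjacency)
        if ordered is not None:
            rings.append(ordered)
    mol.rings = sorted(rings, key=lambda r: (len(r), r))

    bridges = set(frozenset(e) for e in nx.bridges(g))
    for atom in mol.atoms:
        atom.in_ring = False
    for bond in mol.bonds:
        # a non-bridge edge always lies on some cycle
        bond.in_ring = bond.pair() not in bridges
        if bond.in_ring:
            mol.atoms[bond.a].in_ring = True
            mol.atoms[bond.b].in_ring = True
    return mol


def perceive_aromatic(mol: MoleculeGraph) -> MoleculeGraph:
    """Flag benzenoid rings: 6-membered C/N rings with alternating 1/2 bonds.

    This intentionally skips Hueckel electron counting and five-membered
    heteroaromatics; it is sufficient for benzenoid drug-like scaffolds.
    """
    if not mol.rings and any(b.in_ring for b in mol.bonds):
        raise ValueError("rings must be perceived before aromaticity")
    bond_by_pair = {b.pair(): b for b in mol.bonds}
    for atom in mol.atoms:
        atom.aromatic = False
    for bond in mol.bonds:
        bond.aromatic = False
    for ring in mol.rings:
        if len(ring) != 6:
            continue
        if any(mol.atoms[i].element not in ("C", "N") for i in ring):
            continue
        orders = [
            bond_by_pair[frozenset((ring[k], ring[(k + 1) % 6]))].order
            for k in range(6)
        ]
        if orders in ([1, 2, 1, 2, 1, 2], [2, 1, 2, 1, 2, 1]):
            for k in range(6):
                mol.atoms[ring[k]].aromatic = True
                bond_by_pair[frozenset((ring[k], ring[(k + 1) % 6]))].aromatic = True
    return mol


def perceive(mol: MoleculeGraph) -> MoleculeGraph:
    """Run the full perception pipeline: implicit H, rings, aromaticity."""
    return perceive_aromatic(perceive_rings(assign_implicit_h(mol)))
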