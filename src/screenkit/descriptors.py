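"""Graph-derivable drug-likeness descriptors and the Lipinski verdict.

Covers molecular weight (from formula counts), Lipinski H-bond donor and
acceptor counts, Ertl topological polar surface area (TPSA), fraction of
sp3 carbons, rotatable-bond count, and the rule-of-five check. Lipophilicity
(logP) and molar refractivity come from external predictors and are consumed
as inputs, never computed here.

Conventions (each chosen to match standard reporting for the benzenoid
amide scaffolds this package was built around):

* acceptors are Lipinski N+O counts (halogens excluded);
* the rotatable-bond rule counts acyclic single bonds between two
  non-terminal heavy atoms, *including* amide C-N bonds;
* atomic masses are IUPAC standard atomic weights at 3 decimals, with the
  final molecular weight rounded half-up to 2 decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .molgraph import MoleculeGraph

logger = logging.getLogger(__name__)

#: IUPAC standard atomic weights, 3 decimal places.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.060, "Cl": 35.450, "Br": 79.904, "I": 126.904,
}


class DescriptorError(ValueError):
    """Raised when an atom environment cannot be classified."""


@dataclass
class DescriptorSet:
    """Computed graph descriptors plus externally supplied logP / MR."""

    mw: float
    n_hbd: int
    n_hba: int
    tpsa: float
    frac_csp3: float
    n_rotatable: int
    logp: float | None = None
    molar_refractivity: float | None = None


@dataclass
class LipinskiVerdict:
    violations: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Molecular weight

def molecular_weight(formula_counts: dict[str, int]) -> float:
    """Sum of count x standard atomic weight, rounded half-up to 2 decimals."""
    total = Decimal("0")
    for symbol, count in formula_counts.items():
        if symbol not in ATOMIC_MASS:
            raise DescriptorError(f"no atomic mass for element {symbol!r}")
        total += Decimal(str(ATOMIC_MASS[symbol])) * count
    return float(total.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# H-bond donors / acceptors (Lipinski definitions)

def count_hbd(mol: MoleculeGraph) -> int:
    """Hydrogens on N or O (implicit H must be assigned)."""
    return sum(a.implicit_h for a in mol.atoms if a.element in ("N", "O"))


def count_hba(mol: MoleculeGraph) -> int:
    """Lipinski acceptor count: number of N plus number of O atoms."""
    return sum(1 for a in mol.atoms if a.element in ("N", "O"))


# ---------------------------------------------------------------------------
# Ertl TPSA

# Published Ertl fragment contributions (A^2) for N and O environments.
# Keyed by (element, formal_charge, aromatic, n_H, sorted non-aromatic bond
# orders). Aromatic ring bonds are counted separately, so e.g. pyridine N is
# ("N", 0, True, 0, ()).
_TPSA_CONTRIB: dict[tuple, float] = {
    # --- nitrogen, neutral, non-aromatic
    ("N", 0, False, 0, (1, 1, 1)): 3.24,    # tertiary amine
    ("N", 0, False, 0, (1, 2)): 12.36,      # imine-type =N-
    ("N", 0, False, 0, (3,)): 23.79,        # nitrile
    ("N", 0, False, 0, (1, 2, 2)): 11.68,
    ("N", 0, False, 0, (2, 3)): 13.60,
    ("N", 0, False, 1, (1, 1)): 12.03,      # secondary amine / amide N-H
    ("N", 0, False, 1, (2,)): 23.85,        # =N-H
    ("N", 0, False, 2, (1,)): 26.02,        # primary amine / amide NH2
    # --- nitrogen, charged
    ("N", 1, False, 0, (1, 1, 1, 1)): 0.00,
    ("N", 1, False, 0, (1, 1, 2)): 3.01,
    ("N", 1, False, 1, (1, 1, 1)): 4.44,
    ("N", 1, False, 1, (1, 2)): 13.97,
    ("N", 1, False, 2, (1, 1)): 16.61,
    ("N", 1, False, 2, (2,)): 25.59,
    ("N", 1, False, 3, (1,)): 27.64,
    # --- nitrogen, aromatic (two in-ring bonds absorbed by the flag)
    ("N", 0, True, 0, ()): 12.89,           # pyridine-type n
    ("N", 0, True, 0, (1,)): 4.93,          # substituted pyrrole-type n
    ("N", 0, True, 1, ()): 15.79,           # n-H
    ("N", 1, True, 1, ()): 14.14,
    # --- oxygen
    ("O", 0, False, 0, (1, 1)): 9.23,       # ether
    ("O", 0, False, 0, (2,)): 17.07,        # carbonyl / doubly bonded O
    ("O", 0, False, 1, (1,)): 20.23,        # hydroxyl
    ("O", -1, False, 0, (1,)): 23.06,       # oxide anion
    ("O", 0, True, 0, ()): 13.14,           # aromatic o (furan-type)
}


def _tpsa_key(mol: MoleculeGraph, i: int) -> tuple:
    atom = mol.atoms[i]
    plain_orders = sorted(
        b.order for b in mol.bonds if i in (b.a, b.b) and not b.aromatic
    )
    return (
        atom.element,
        atom.formal_charge,
        atom.aromatic,
        atom.implicit_h,
        tuple(plain_orders),
    )


def tpsa(mol: MoleculeGraph) -> float:
    """Topological polar surface area: sum of Ertl N/O fragment contributions.

    Implicit H and ring/aromatic perception must have run. A polar atom whose
    environment matches no published class raises (it never silently
    contributes zero).
    """
    total = 0.0
    for i, atom in enumerate(mol.atoms):
        if atom.element not in ("N", "O"):
            continue
        key = _tpsa_key(mol, i)
        try:
            total += _TPSA_CONTRIB[key]
        except KeyError:
            raise DescriptorError(
                f"no TPSA fragment class for atom {i} with environment "
                f"(element={key[0]}, charge={key[1]}, aromatic={key[2]}, "
                f"n_H={key[3]}, bond_orders={key[4]})"
            ) from None
    return round(total, 2)


# ---------------------------------------------------------------------------
# Hybridization / flexibility

def fraction_csp3(mol: MoleculeGraph) -> float:
    """Share of carbons bearing only single bonds and no aromatic flag."""
    carbons = [i for i, a in enumerate(mol.atoms) if a.element == "C"]
    if not carbons:
        return 0.0
    sp3 = sum(
        1
        for i in carbons
        if not mol.atoms[i].aromatic
        and all(o == 1 for o in mol.bond_orders_at(i))
    )
    return round(sp3 / len(carbons), 2)


def rotatable_bonds(mol: MoleculeGraph) -> int:
    """Acyclic single bonds between two non-terminal heavy atoms.

    Terminal means heavy-atom degree 1. Amide C-N bonds are counted.
    """
    return sum(
        1
        for b in mol.bonds
        if b.order == 1
        and not b.in_ring
        and mol.degree(b.a) >= 2
        and mol.degree(b.b) >= 2
    )


# ---------------------------------------------------------------------------
# Rule of five

def lipinski(d: DescriptorSet) -> LipinskiVerdict:
    """Rule-of-five check: MW < 500, HBD < 5, HBA < 10, logP < 5, MR in 40-130.

    logP / molar refractivity rules are skipped (with a logged note) when the
    externally supplied values are absent.
    """
    verdict = LipinskiVerdict()
    if d.mw >= 500:
        verdict.violations.append(f"molecular weight {d.mw:.2f} >= 500")
    if d.n_hbd >= 5:
        verdict.violations.append(f"H-bond donors {d.n_hbd} >= 5")
    if d.n_hba >= 10:
        verdict.violations.append(f"H-bond acceptors {d.n_hba} >= 10")
    if d.logp is None:
        verdict.skipped.append("logP (not supplied)")
        logger.info("Lipinski logP rule skipped: no value supplied")
    elif d.logp >= 5:
        verdict.violations.append(f"logP {d.logp:.2f} >= 5")
    if d.molar_refractivity is None:
        verdict.skipped.append("molar refractivity (not supplied)")
        logger.info("Lipinski molar-refractivity rule skipped: no value supplied")
    elif not 40 <= d.molar_refractivity <= 130:
        verdict.violations.append(
            f"molar refractivity {d.molar_refractivity:.2f} outside [40, 130]"
        )
    return verdict


def compute_descriptors(
    mol: MoleculeGraph,
    logp: float | None = None,
    molar_refractivity: float | None = None,
) -> DescriptorSet:
    """All graph descriptors for a perceived molecule in one call."""
    return DescriptorSet(
        mw=molecular_weight(mol.formula_counts()),
        n_hbd=count_hbd(mol),
        n_hba=count_hba(mol),
        tpsa=tpsa(mol),
        frac_csp3=fraction_csp3(mol),
        n_rotatable=rotatable_bonds(mol),
        logp=logp,
        molar_refractivity=molar_refractivity,
    )
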