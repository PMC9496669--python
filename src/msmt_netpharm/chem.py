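"""Physicochemical descriptors and rule-based drug-likeness verdicts.

RDKit handles SMILES parsing and atom typing; every descriptor on top of the
parsed structure is computed natively here:

* molecular weight — periodic-table sum including implicit hydrogens;
* HBA / HBD — Lipinski's simple counts (N+O atoms; H on N/O), the convention
  required to reproduce the reported values (e.g. three acceptors for equol);
* MlogP — the Moriguchi 1992 thirteen-descriptor regression for the
  octanol-water partition coefficient;
* TPSA — Ertl 2000 fragment contributions over N/O environments;
* Lipinski rule-of-five violation count over {MW<=500, HBA<=10, HBD<=5,
  MlogP<=4.15} and the Abbott bioavailability score (discrete levels
  0.11/0.17/0.55/0.56/0.85).

Descriptors are computed on the neutral parent structure: protonation-state
charges are neutralized; net-neutral zwitterions (N-oxides, betaines) are
kept as-is; molecules that stay net-charged are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import GetPeriodicTable

__all__ = [
    "Molecule",
    "DescriptorReport",
    "UnsupportedElementError",
    "parse_molecule",
    "molecular_weight",
    "count_hba",
    "count_hbd",
    "mlogp",
    "tpsa",
    "lipinski_report",
    "read_smiles_table",
    "report_table",
]

log = logging.getLogger(__name__)

_PT = GetPeriodicTable()

#: elements inside the Moriguchi parameterization
_MLOGP_ELEMENTS = {"H", "C", "N", "O", "F", "Cl", "Br", "I", "S", "P"}

#: weight of each carbon/halogen atom in the Moriguchi CX term
_CX_WEIGHT = {"C": 1.0, "F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


class UnsupportedElementError(ValueError):
    """Raised when a descriptor is undefined for an element in the molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed structure plus its bookkeeping identity."""

    name: str
    mol: Chem.Mol
    smiles: str
    pubchem_cid: Optional[int] = None
    was_neutralized: bool = False
    input_net_charge: int = 0

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def formula(self) -> str:
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        return CalcMolFormula(self.mol)


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Neutralize trivial protonation-state charges ([O-] -> OH, [NH3+] ->
    NH2 ...).  Charges that cannot be removed (quaternary N, N-oxide O-) are
    kept; the caller decides whether the remaining net charge is acceptable."""
    mol = Chem.RWMol(mol)
    changed = False
    for atom in mol.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        if charge < 0 and atom.GetSymbol() in {"O", "N", "S"}:
            # protonate anionic heteroatom unless it balances an adjacent
            # cation (zwitterion such as an N-oxide or a nitro group)
            if any(nb.GetFormalCharge() > 0 for nb in atom.GetNeighbors()):
                continue
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            changed = True
        elif charge > 0 and atom.GetSymbol() == "N" and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            changed = True
    out = mol.GetMol()
    if changed:
        Chem.SanitizeMol(out)
    return out, changed


def parse_molecule(smiles: str, name: str, pubchem_cid: Optional[int] = None) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Aromaticity perception and implicit-hydrogen assignment are performed by
    RDKit sanitization.  Invalid SMILES raise ``ValueError`` naming the
    molecule; molecules with residual net formal charge after trivial
    neutralization are rejected.
    """
    if not smiles or not smiles.strip():
        raise ValueError(f"{name}: empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"{name}: invalid SMILES {smiles!r}")
    input_charge = Chem.GetFormalCharge(mol)
    mol, changed = _neutralize(mol)
    if changed:
        log.info("%s: charged input neutralized for descriptor computation", name)
    if Chem.GetFormalCharge(mol) != 0:
        raise ValueError(
            f"{name}: net formal charge {Chem.GetFormalCharge(mol)} cannot be "
            f"trivially neutralized"
        )
    return Molecule(name=name, mol=mol, smiles=smiles, pubchem_cid=pubchem_cid,
                    was_neutralized=changed, input_net_charge=input_charge)


# ---------------------------------------------------------------------------
# simple additive descriptors


def molecular_weight(mol: Molecule) -> float:
    """Sum of standard atomic weights over all atoms, implicit H included."""
    weight = 0.0
    for atom in mol.mol.GetAtoms():
        weight += _PT.GetAtomicWeight(atom.GetAtomicNum())
        weight += atom.GetTotalNumHs() * _PT.GetAtomicWeight(1)
    return weight


def count_hba(mol: Molecule) -> int:
    """Lipinski hydrogen-bond acceptors: the count of N and O atoms."""
    return sum(1 for a in mol.mol.GetAtoms() if a.GetAtomicNum() in (7, 8))


def count_hbd(mol: Molecule) -> int:
    """Lipinski hydrogen-bond donors: hydrogens attached to N or O (each
    attached H counts once)."""
    return sum(a.GetTotalNumHs() for a in mol.mol.GetAtoms()
               if a.GetAtomicNum() in (7, 8))


# ---------------------------------------------------------------------------
# Moriguchi octanol-water partition coefficient (MlogP)

# regression coefficients of the published thirteen-descriptor model
_MLOGP_COEF = {
    "intercept": -1.014,
    "CX": 1.244,   # applied to CX**0.6
    "NO": -1.017,  # applied to NO**0.9
    "PRX": 0.406,
    "UB": -0.145,  # applied to UB**0.8
    "HB": 0.511,
    "POL": 0.268,
    "AMP": -2.215,
    "ALK": 0.912,
    "RNG": -0.392,
    "QN": -3.684,
    "NO2": 0.474,
    "NCS": 1.582,
    "BLM": 0.773,
}

_SMARTS = {
    "amide": Chem.MolFromSmarts("[NX3][CX3]=[OX1]"),
    "sulfonamide": Chem.MolFromSmarts("[NX3][SX4](=[OX1])=[OX1]"),
    "nitro": Chem.MolFromSmarts("[NX3](=O)[OX1]"),
    "alpha_amino_acid": Chem.MolFromSmarts("[NX3;!$(N-C=O)][CX4][CX3](=O)[OX2H1]"),
    "aminobenzoic": Chem.MolFromSmarts("[NX3H2]c1ccccc1[CX3](=O)[OX2H1]"),
    "pyridine_cooh": Chem.MolFromSmarts("[nX2]1ccccc1[CX3](=O)[OX2H1]"),
    "quaternary_n": Chem.MolFromSmarts("[NX4+]"),
    "n_oxide": Chem.MolFromSmarts("[NX4+][OX1-]"),
    "isothiocyanate": Chem.MolFromSmarts("[NX2]=C=[SX1]"),
    "thiocyanate": Chem.MolFromSmarts("[SX2]C#[NX1]"),
    "beta_lactam": Chem.MolFromSmarts("[NX3R]1[CX3R](=O)[CX4R][CX4R]1"),
}


def mlogp_descriptors(mol: Molecule) -> dict[str, float]:
    """The thirteen Moriguchi structural descriptors.

    Definitions the 1992 publication states only in words are fixed as
    follows (see the package methods note for the anchoring): UB counts
    non-aromatic double and triple bonds, nitro N-O doubles excluded; POL
    counts acyl-type polar substituents attached to aromatic rings
    (attachment carbon/sulfur multiply bonded to N or O, nitro excluded);
    RNG flags the presence of any ring; HB flags an ortho-arranged
    intramolecular donor/acceptor pair on an aromatic ring.
    """
    m = mol.mol
    for atom in m.GetAtoms():
        if atom.GetSymbol() not in _MLOGP_ELEMENTS:
            raise UnsupportedElementError(
                f"{mol.name}: element {atom.GetSymbol()} outside the MlogP "
                f"parameterization"
            )

    desc = dict.fromkeys(_MLOGP_COEF, 0.0)
    desc.pop("intercept")

    # CX: weighted carbon + halogen count
    desc["CX"] = sum(_CX_WEIGHT.get(a.GetSymbol(), 0.0) for a in m.GetAtoms())
    # NO: nitrogen + oxygen count
    desc["NO"] = float(sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8)))

    # PRX: N/O proximity — 2 per bonded pair, 1 per pair separated by one
    # C/S/P atom, with a -1 correction per carboxamide/sulfonamide group
    hetero = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    prx = 0.0
    for i, ai in enumerate(hetero):
        for aj in hetero[i + 1:]:
            path = Chem.GetShortestPath(m, ai, aj)
            if len(path) == 2:
                prx += 2.0
            elif len(path) == 3 and m.GetAtomWithIdx(path[1]).GetSymbol() in {"C", "S", "P"}:
                prx += 1.0
    prx -= len(m.GetSubstructMatches(_SMARTS["amide"]))
    prx -= len(m.GetSubstructMatches(_SMARTS["sulfonamide"]))
    desc["PRX"] = max(prx, 0.0)

    # UB: non-aromatic unsaturated bonds, nitro bonds excluded
    nitro_atoms = {idx for match in m.GetSubstructMatches(_SMARTS["nitro"]) for idx in match}
    ub = 0
    for bond in m.GetBonds():
        if bond.GetIsAromatic():
            continue
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
            if {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()} <= nitro_atoms:
                continue
            ub += 1
    desc["UB"] = float(ub)

    desc["HB"] = 1.0 if _has_intramolecular_hbond(m) else 0.0
    desc["POL"] = float(_aromatic_polar_substituents(m))
    desc["AMP"] = _amphoteric(m)
    desc["ALK"] = 1.0 if _is_alkane_like(m) else 0.0
    desc["RNG"] = 1.0 if m.GetRingInfo().NumRings() > 0 else 0.0

    n_ox = len(m.GetSubstructMatches(_SMARTS["n_oxide"]))
    quat = len(m.GetSubstructMatches(_SMARTS["quaternary_n"])) - n_ox
    desc["QN"] = quat * 1.0 + n_ox * 0.5
    desc["NO2"] = float(len(m.GetSubstructMatches(_SMARTS["nitro"])))
    desc["NCS"] = (len(m.GetSubstructMatches(_SMARTS["isothiocyanate"])) * 1.0
                   + len(m.GetSubstructMatches(_SMARTS["thiocyanate"])) * 0.5)
    desc["BLM"] = 1.0 if m.HasSubstructMatch(_SMARTS["beta_lactam"]) else 0.0
    return desc


def _has_intramolecular_hbond(m: Chem.Mol) -> bool:
    """Ortho donor/acceptor pair on an aromatic ring (salicyl/catechol-type)."""
    for bond in m.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if not (a.GetIsAromatic() and b.GetIsAromatic()):
            continue
        if _aromatic_donor_substituent(a) and _aromatic_acceptor_substituent(b):
            return True
        if _aromatic_donor_substituent(b) and _aromatic_acceptor_substituent(a):
            return True
    return False


def _aromatic_donor_substituent(ring_atom: Chem.Atom) -> bool:
    for nb in ring_atom.GetNeighbors():
        if nb.GetIsAromatic():
            continue
        if nb.GetAtomicNum() in (7, 8) and nb.GetTotalNumHs() > 0:
            return True
    return False


def _aromatic_acceptor_substituent(ring_atom: Chem.Atom) -> bool:
    for nb in ring_atom.GetNeighbors():
        if nb.GetIsAromatic():
            continue
        if nb.GetAtomicNum() in (7, 8):
            return True
        if nb.GetAtomicNum() in (6, 16):
            for nb2 in nb.GetNeighbors():
                if nb2.GetIdx() == ring_atom.GetIdx():
                    continue
                bond = nb.GetOwningMol().GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx())
                if nb2.GetAtomicNum() in (7, 8) and bond.GetBondTypeAsDouble() >= 2:
                    return True
    return False


def _aromatic_polar_substituents(m: Chem.Mol) -> int:
    """Acyl-type polar substituents on aromatic rings: a non-ring attachment
    C or S that is double- or triple-bonded to N or O (C=O, C#N, S=O...),
    nitro excluded (it has its own regression term)."""
    count = 0
    for atom in m.GetAtoms():
        if not atom.GetIsAromatic():
            continue
        for nb in atom.GetNeighbors():
            if nb.GetIsAromatic() or nb.IsInRing():
                continue
            if nb.GetSymbol() not in {"C", "S"}:
                continue
            for nb2 in nb.GetNeighbors():
                if nb2.GetIdx() == atom.GetIdx():
                    continue
                bond = m.GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx())
                if nb2.GetAtomicNum() in (7, 8) and bond.GetBondTypeAsDouble() >= 2:
                    count += 1
                    break
    return count


def _amphoteric(m: Chem.Mol) -> float:
    if m.HasSubstructMatch(_SMARTS["alpha_amino_acid"]):
        return 1.0
    if m.HasSubstructMatch(_SMARTS["aminobenzoic"]) or m.HasSubstructMatch(_SMARTS["pyridine_cooh"]):
        return 0.5
    return 0.0


def _is_alkane_like(m: Chem.Mol) -> bool:
    """Hydrocarbon (C/H only) with no aromatic system, no triple bond and at
    most one double bond: alkane, alkene, cycloalkane, cycloalkene."""
    if any(a.GetAtomicNum() not in (1, 6) for a in m.GetAtoms()):
        return False
    if any(a.GetIsAromatic() for a in m.GetAtoms()):
        return False
    doubles = sum(1 for b in m.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE)
    triples = sum(1 for b in m.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE)
    return triples == 0 and doubles <= 1


def mlogp(mol: Molecule) -> float:
    """Moriguchi 1992 regression estimate of log P (unrounded; reports print
    one decimal)."""
    d = mlogp_descriptors(mol)
    value = _MLOGP_COEF["intercept"]
    value += _MLOGP_COEF["CX"] * d["CX"] ** 0.6
    value += _MLOGP_COEF["NO"] * d["NO"] ** 0.9
    value += _MLOGP_COEF["UB"] * d["UB"] ** 0.8
    for term in ("PRX", "HB", "POL", "AMP", "ALK", "RNG", "QN", "NO2", "NCS", "BLM"):
        value += _MLOGP_COEF[term] * d[term]
    return value


# ---------------------------------------------------------------------------
# Ertl topological polar surface area

# fragment contributions (A^2) keyed by the N/O environment signature:
# (symbol, aromatic, charge, nH, n_single, n_double, n_triple, n_aromatic,
#  in_3ring); attached hydrogens count toward n_single
_TPSA_FRAGMENTS = {
    # nitrogen
    ("N", False, 0, 0, 3, 0, 0, 0, False): 3.24,   # N(-*)(-*)-*
    ("N", False, 0, 0, 1, 1, 0, 0, False): 12.36,  # N(-*)=*
    ("N", False, 0, 0, 0, 0, 1, 0, False): 23.79,  # N#*
    ("N", False, 0, 0, 1, 2, 0, 0, False): 11.68,  # N(-*)(=*)=*
    ("N", False, 0, 0, 0, 1, 1, 0, False): 13.60,  # N(=*)#*
    ("N", False, 0, 0, 3, 0, 0, 0, True): 3.01,    # three-ring N(-*)(-*)-*
    ("N", False, 0, 1, 3, 0, 0, 0, False): 12.03,  # NH(-*)-*
    ("N", False, 0, 1, 3, 0, 0, 0, True): 21.94,   # three-ring NH(-*)-*
    ("N", False, 0, 1, 1, 1, 0, 0, False): 23.85,  # NH=*
    ("N", False, 0, 2, 3, 0, 0, 0, False): 26.02,  # NH2-*
    ("N", False, 1, 0, 4, 0, 0, 0, False): 0.00,   # N+(-*)(-*)(-*)-*
    ("N", False, 1, 0, 2, 1, 0, 0, False): 3.01,   # N+(-*)(-*)=*
    ("N", False, 1, 0, 1, 0, 1, 0, False): 4.36,   # N+(-*)#*
    ("N", False, 1, 1, 4, 0, 0, 0, False): 4.44,   # NH+(-*)(-*)-*
    ("N", False, 1, 1, 2, 1, 0, 0, False): 13.97,  # NH+(-*)=*
    ("N", False, 1, 2, 4, 0, 0, 0, False): 16.61,  # NH2+(-*)-*
    ("N", False, 1, 2, 2, 1, 0, 0, False): 25.59,  # NH2+=*
    ("N", False, 1, 3, 4, 0, 0, 0, False): 27.64,  # NH3+-*
    ("N", True, 0, 0, 0, 0, 0, 2, False): 12.89,   # n(:*):*
    ("N", True, 0, 0, 0, 0, 0, 3, False): 4.41,    # n(:*)(:*):*
    ("N", True, 0, 0, 1, 0, 0, 2, False): 4.93,    # n(-*)(:*):*
    ("N", True, 0, 0, 0, 1, 0, 2, False): 8.39,    # n(=*)(:*):*
    ("N", True, 0, 1, 1, 0, 0, 2, False): 15.79,   # nH(:*):*
    ("N", True, 1, 0, 0, 0, 0, 3, False): 4.10,    # n+(:*)(:*):*
    ("N", True, 1, 0, 1, 0, 0, 2, False): 3.88,    # n+(-*)(:*):*
    ("N", True, 1, 1, 1, 0, 0, 2, False): 14.14,   # nH+(:*):*
    # oxygen
    ("O", False, 0, 0, 2, 0, 0, 0, False): 9.23,   # O(-*)-*
    ("O", False, 0, 0, 2, 0, 0, 0, True): 12.53,   # three-ring O(-*)-*
    ("O", False, 0, 0, 0, 1, 0, 0, False): 17.07,  # O=*
    ("O", False, 0, 1, 2, 0, 0, 0, False): 20.23,  # OH-*
    ("O", False, -1, 0, 1, 0, 0, 0, False): 23.06, # O- -*
    ("O", True, 0, 0, 0, 0, 0, 2, False): 13.14,   # o(:*):*
}


def _tpsa_signature(atom: Chem.Atom):
    n_single = n_double = n_triple = n_arom = 0
    for bond in atom.GetBonds():
        if bond.GetIsAromatic():
            n_arom += 1
        elif bond.GetBondType() == Chem.BondType.SINGLE:
            n_single += 1
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            n_double += 1
        elif bond.GetBondType() == Chem.BondType.TRIPLE:
            n_triple += 1
    n_h = atom.GetTotalNumHs()
    return (
        atom.GetSymbol(),
        atom.GetIsAromatic(),
        atom.GetFormalCharge(),
        n_h,
        n_single + n_h,  # attached hydrogens are single bonds in the table
        n_double,
        n_triple,
        n_arom,
        atom.IsInRingSize(3),
    )


def tpsa(mol: Molecule) -> float:
    """Ertl fragment-contribution TPSA in A^2 (N/O environments).

    Environments absent from the published fragment table fall back to a
    generic valence-based contribution with a logged warning.
    """
    total = 0.0
    # charge-separated nitro groups score as the hypervalent N(=O)=O form
    # the fragment table was parameterized on
    nitro_atoms: dict[int, float] = {}
    for n_idx, *_rest in mol.mol.GetSubstructMatches(_SMARTS["nitro"]):
        nitro_atoms[n_idx] = 11.68
        for nb in mol.mol.GetAtomWithIdx(n_idx).GetNeighbors():
            if nb.GetAtomicNum() == 8:
                nitro_atoms[nb.GetIdx()] = 17.07
    for atom in mol.mol.GetAtoms():
        if atom.GetAtomicNum() not in (7, 8):
            continue
        if atom.GetIdx() in nitro_atoms:
            total += nitro_atoms[atom.GetIdx()]
            continue
        signature = _tpsa_signature(atom)
        if signature in _TPSA_FRAGMENTS:
            total += _TPSA_FRAGMENTS[signature]
        else:
            heavy_degree = atom.GetDegree()
            n_h = atom.GetTotalNumHs()
            if atom.GetAtomicNum() == 7:
                generic = 30.5 - (heavy_degree + n_h) * 8.2 + n_h * 1.5
            else:
                generic = 28.5 - (heavy_degree + n_h) * 8.6 + n_h * 1.5
            generic = max(generic, 0.0)
            log.warning(
                "%s: N/O environment %s not in the TPSA fragment table; "
                "generic contribution %.2f used", mol.name, signature, generic,
            )
            total += generic
    return total


# ---------------------------------------------------------------------------
# rule verdicts

_ANIONIC_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=O)[OX2H1]",            # carboxylic acid
        "[CX3](=O)[OX1-]",             # carboxylate
        "[SX4](=O)(=O)[OX2H1,OX1-]",   # sulfonic acid
        "[SX3](=O)[OX2H1,OX1-]",       # sulfinic acid
        "[PX4](=O)([OX2H1,OX1-])[OX2H1,OX1-]",  # phosphonic/phosphoric
        "c1nn[nH1]n1",                 # tetrazole
        "[SX4](=O)(=O)[NX3H1][CX3]=O", # acylsulfonamide
    )
]


@dataclass
class DescriptorReport:
    """The seven reported physicochemical quantities plus rule verdicts.

    Verdict comparisons use unrounded values; the ``*_display`` fields carry
    the report precision (MW two decimals, MlogP one, TPSA two).
    """

    name: str
    pubchem_cid: Optional[int]
    mw: float
    hba: int
    hbd: int
    mlogp: float
    tpsa: float
    lipinski_violations: int
    bioavailability_score: float
    tpsa_pass: bool
    ro5_pass: bool  # the "<=1 violation" aggregation column
    anionic: bool

    @property
    def mw_display(self) -> float:
        return round(self.mw, 2)

    @property
    def mlogp_display(self) -> float:
        return round(self.mlogp, 1)

    @property
    def tpsa_display(self) -> float:
        return round(self.tpsa, 2)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "pubchem_cid": self.pubchem_cid,
            "mw": self.mw_display,
            "hba": self.hba,
            "hbd": self.hbd,
            "mlogp": self.mlogp_display,
            "tpsa": self.tpsa_display,
            "lipinski_violations": self.lipinski_violations,
            "bioavailability_score": self.bioavailability_score,
            "tpsa_pass": self.tpsa_pass,
            "ro5_pass": self.ro5_pass,
        }


def _is_anionic(m: Chem.Mol) -> bool:
    return any(m.HasSubstructMatch(patt) for patt in _ANIONIC_SMARTS)


def lipinski_report(
    mol: Molecule,
    mw_limit: float = 500.0,
    mw_inclusive: bool = True,
) -> DescriptorReport:
    """Full descriptor suite plus rule-of-five and bioavailability verdicts.

    Violations are counted against {MW<=500, HBA<=10, HBD<=5, MlogP<=4.15}
    (set ``mw_inclusive=False`` for a strict MW<500 boundary; the boundary
    case is logged either way).  The Abbott bioavailability score is 0.55
    for rule-compliant compounds that are not anions; anions score by TPSA
    band (<=75: 0.85, <=150: 0.56, >150: 0.11); non-anionic rule failures
    score 0.17.
    """
    mw = molecular_weight(mol)
    hba = count_hba(mol)
    hbd = count_hbd(mol)
    logp = mlogp(mol)
    psa = tpsa(mol)

    mw_ok = mw <= mw_limit if mw_inclusive else mw < mw_limit
    if mw == mw_limit:
        log.info("%s: molecular weight exactly at the %g boundary", mol.name, mw_limit)
    violations = sum(
        not ok for ok in (mw_ok, hba <= 10, hbd <= 5, logp <= 4.15)
    )
    ro5_pass = violations <= 1
    anionic = _is_anionic(mol.mol) or mol.input_net_charge < 0
    if anionic:
        score = 0.85 if psa <= 75 else (0.56 if psa <= 150 else 0.11)
    else:
        score = 0.55 if ro5_pass else 0.17
    return DescriptorReport(
        name=mol.name,
        pubchem_cid=mol.pubchem_cid,
        mw=mw,
        hba=hba,
        hbd=hbd,
        mlogp=logp,
        tpsa=psa,
        lipinski_violations=violations,
        bioavailability_score=score,
        tpsa_pass=psa < 140,
        ro5_pass=ro5_pass,
        anionic=anionic,
    )


# ---------------------------------------------------------------------------
# file interfaces


def read_smiles_table(path: str | Path) -> list[Molecule]:
    """Read ``name<TAB>cid<TAB>smiles`` (``#`` comments, optional header)."""
    path = Path(path)
    molecules = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0].lower() == "name":
                continue
            if len(fields) != 3:
                raise ValueError(
                    f"{path.name} line {lineno}: expected 3 columns, got {len(fields)}"
                )
            name, cid, smiles = fields
            molecules.append(parse_molecule(smiles, name, int(cid) if cid else None))
    return molecules


def report_table(reports: Iterable[DescriptorReport]):
    """Reports as a pandas frame mirroring the published table columns."""
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in reports])
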