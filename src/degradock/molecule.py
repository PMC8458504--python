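"""Molecular graphs, SMILES/SDF I/O and the drug-likeness descriptor panel.

Molecules are RDKit ``Mol`` objects (hydrogen-implicit graphs with optional 3D
conformers).  On top of RDKit's primitives this module implements the
screen's descriptor panel: Ertl TPSA, Wildman-Crippen logP, Delaney ESOL
solubility, Lipinski rule-of-five accounting, the Abbott/Martin
bioavailability score, and the six-axis bioavailability radar.

Hydrogen-bond counting rules
----------------------------
* donors: N or O atoms bearing at least one hydrogen;
* acceptors: every O atom, plus N atoms that are neither amide/imide
  nitrogens (N bonded to a carbonyl carbon) nor pyrrole-type aromatic
  nitrogens (three-coordinate aromatic N donating its lone pair to the ring).

This acceptor rule reproduces the reference count of 4 for the screen's lead
compound (three oxygens plus its single tertiary amine; the two imide
nitrogens are excluded).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, TextIO

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors
from rdkit import RDLogger

from . import config

RDLogger.DisableLog("rdApp.*")

Molecule = Chem.Mol

#: SMILES of the lead spiro-hydantoin compound (built by hand from its
#: published IUPAC name: an 8-(2,3-dihydro-1H-inden-2-yl)-1-isobutyl-
#: 3-(4-methoxybenzyl)-1,3,8-triazaspiro[4.5]decane-2,4-dione).
LEAD_COMPOUND_SMILES = "CC(C)CN1C(=O)N(Cc2ccc(OC)cc2)C(=O)C11CCN(CC1)C1Cc2ccccc2C1"
LEAD_COMPOUND_NAME = "SMC13"


class MoleculeParseError(ValueError):
    """Raised for malformed SMILES or SDF input."""


def parse_smiles(text: str, name: str | None = None) -> Molecule:
    """Parse a SMILES string into a sanitized molecule.

    Aromaticity is perceived and implicit hydrogens are filled to standard
    valence.  Raises :class:`MoleculeParseError` on malformed input.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise MoleculeParseError(f"malformed SMILES: {text!r}")
    if name is not None:
        mol.SetProp("_Name", name)
    return mol


def mol_name(m: Molecule, default: str = "") -> str:
    return m.GetProp("_Name") if m.HasProp("_Name") else default


def read_sdf(source) -> list[Molecule]:
    """Read all records of a V2000 SDF file (path or file-like object)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    mols: list[Molecule] = []
    # SDMolSupplier over the raw text keeps record indices for error messages
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=True, removeHs=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise MoleculeParseError(f"unreadable SDF record at index {idx}")
        mols.append(mol)
    return mols


def write_sdf(molecules: Iterable[Molecule], dest) -> None:
    """Write molecules as V2000 SDF (coordinates kept to 4 decimals)."""
    own = not hasattr(dest, "write")
    fh: TextIO = open(dest, "w") if own else dest
    try:
        writer = Chem.SDWriter(fh)
        writer.SetForceV3000(False)
        for mol in molecules:
            writer.write(mol)
        writer.close()
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Individual descriptors
# ---------------------------------------------------------------------------

def molecular_weight(m: Molecule) -> float:
    """Average molecular weight (g/mol) including implicit hydrogens."""
    if m.GetNumAtoms() == 0:
        return 0.0
    return float(Descriptors.MolWt(m))


def tpsa(m: Molecule) -> float:
    """Ertl topological polar surface area (A^2), N/O contributions."""
    return float(Descriptors.TPSA(m))


def count_h_bond_donors(m: Molecule) -> int:
    """Number of N/O atoms bearing at least one hydrogen."""
    n = 0
    for atom in m.GetAtoms():
        if atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() >= 1:
            n += 1
    return n


def _is_amide_or_imide_n(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        if nb.GetAtomicNum() != 6:
            continue
        for bond in nb.GetBonds():
            other = bond.GetOtherAtom(nb)
            if other.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def count_h_bond_acceptors(m: Molecule) -> int:
    """All oxygens plus non-amide, non-pyrrole-type nitrogens."""
    n = 0
    for atom in m.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 8:
            n += 1
        elif z == 7:
            if atom.GetIsAromatic() and atom.GetTotalDegree() == 3:
                continue  # pyrrole-type: lone pair is part of the ring sextet
            if _is_amide_or_imide_n(atom):
                continue
            n += 1
    return n


def logp(m: Molecule) -> float:
    """Wildman-Crippen octanol/water partition coefficient."""
    return float(Crippen.MolLogP(m))


def rotatable_bonds(m: Molecule) -> int:
    """Non-ring single bonds between non-terminal heavy atoms, amides excluded."""
    return int(rdMolDescriptors.CalcNumRotatableBonds(
        m, rdMolDescriptors.NumRotatableBondsOptions.Strict))


def aromatic_proportion(m: Molecule) -> float:
    heavy = m.GetNumHeavyAtoms()
    if heavy == 0:
        return 0.0
    arom = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
    return arom / heavy


def logs_esol(m: Molecule) -> float:
    """Delaney ESOL aqueous solubility estimate (log mol/L)."""
    if m.GetNumAtoms() == 0:
        return 0.0
    return (0.16
            - 0.63 * logp(m)
            - 0.0062 * molecular_weight(m)
            + 0.066 * rotatable_bonds(m)
            - 0.74 * aromatic_proportion(m))


def lipinski_violations(m: Molecule) -> int:
    """Rule-of-five violations: MW>500, logP>5, HBD>5, HBA>10."""
    v = 0
    if molecular_weight(m) > 500.0:
        v += 1
    if logp(m) > 5.0:
        v += 1
    if count_h_bond_donors(m) > 5:
        v += 1
    if count_h_bond_acceptors(m) > 10:
        v += 1
    return v


_ACID_SMARTS = [
    Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),        # carboxylic acid
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1]"),    # sulfonic acid
    Chem.MolFromSmarts("[PX4](=O)([OX2H1])"),      # phosphonic/phosphoric acid
    Chem.MolFromSmarts("[SX4](=O)(=O)[NX3H1][CX3]=O"),  # acyl sulfonamide
]


def is_anionic_at_ph7(m: Molecule) -> bool:
    """Net negative formal charge, or an acid group deprotonated at pH 7."""
    if Chem.GetFormalCharge(m) < 0:
        return True
    return any(m.HasSubstructMatch(p) for p in _ACID_SMARTS if p is not None)


def bioavailability_score(m: Molecule) -> float:
    """Abbott bioavailability score (Martin 2005 rule table).

    Anions at physiological pH are bucketed by TPSA; everything else scores
    0.55 with at most one rule-of-five violation, 0.17 otherwise.
    """
    if is_anionic_at_ph7(m):
        t = tpsa(m)
        if t > 150.0:
            return 0.11
        if t >= 75.0:
            return 0.56
        return 0.85
    return 0.55 if lipinski_violations(m) <= 1 else 0.17


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSet:
    """Drug-likeness panel of one molecule (SwissADME-style)."""

    name: str
    molecular_weight: float
    tpsa: float
    hbd: int
    hba: int
    logp: float
    logs_esol: float
    rotatable_bonds: int
    lipinski_violations: int
    bioavailability_score: float
    drug_like: bool
    radar: dict[str, float] = field(default_factory=dict)

    def radar_in_range(self) -> dict[str, bool]:
        out = {}
        for axis, value in self.radar.items():
            lo, hi = config.RADAR_RANGES[axis]
            out[axis] = lo <= value <= hi
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    TSV_COLUMNS = (
        "name", "molecular_weight", "tpsa", "hbd", "hba", "logp", "logs_esol",
        "rotatable_bonds", "lipinski_violations", "bioavailability_score",
        "drug_like",
    )

    def to_tsv_row(self) -> str:
        vals = [
            self.name,
            f"{self.molecular_weight:.1f}",
            f"{self.tpsa:.2f}",
            str(self.hbd),
            str(self.hba),
            f"{self.logp:.2f}",
            f"{self.logs_esol:.2f}",
            str(self.rotatable_bonds),
            str(self.lipinski_violations),
            f"{self.bioavailability_score:.2f}",
            "yes" if self.drug_like else "no",
        ]
        return "\t".join(vals)


def fraction_csp3(m: Molecule) -> float:
    return float(rdMolDescriptors.CalcFractionCSP3(m)) if m.GetNumAtoms() else 0.0


def descriptor_panel(m: Molecule) -> DescriptorSet:
    """Compute the full panel.  MW is reported to 1 decimal, TPSA to 2."""
    mw = round(molecular_weight(m), 1)
    t = round(tpsa(m), 2)
    lp = logp(m)
    ls = logs_esol(m)
    rb = rotatable_bonds(m)
    viol = lipinski_violations(m)
    return DescriptorSet(
        name=mol_name(m),
        molecular_weight=mw,
        tpsa=t,
        hbd=count_h_bond_donors(m),
        hba=count_h_bond_acceptors(m),
        logp=lp,
        logs_esol=ls,
        rotatable_bonds=rb,
        lipinski_violations=viol,
        bioavailability_score=bioavailability_score(m),
        drug_like=viol <= 1,
        radar={
            "LIPO": lp,
            "SIZE": mw,
            "POLAR": t,
            "INSOLU": ls,
            "INSATU": fraction_csp3(m),
            "FLEX": float(rb),
        },
    )


def molecular_formula(m: Molecule) -> str:
    return rdMolDescriptors.CalcMolFormula(m)
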