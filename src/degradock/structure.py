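"""Receptor structure handling: PDB I/O, virtual mutagenesis, sites, clashes.

Structures are ``gemmi.Structure`` objects.  The module adds the operations a
surrogate-receptor workflow needs: deleting chains or residue ranges (e.g. a
bound chaperone peptide and linker), applying point mutations with idealized
side-chain rebuilds, defining a degradation site from tagged residues, and
distance/clash utilities with Bondi van der Waals radii.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import config
from .geometry import place_atom

ProteinStructure = gemmi.Structure

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


class PDBFormatError(ValueError):
    """Raised when a PDB record cannot be parsed (message carries the line number)."""


class StructureError(ValueError):
    """Raised for selections or mutations that do not match the structure."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtext = line[lo:hi].strip()
            try:
                float(fieldtext)
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: non-numeric {what} coordinate {fieldtext!r}"
                ) from None


def read_pdb(source) -> ProteinStructure:
    """Parse ATOM/HETATM/TER/END records from a path, text, or file object.

    Alternative locations are resolved by keeping altLoc 'A' or blank.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = str(source)
        if "\n" in source:
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    st.remove_alternative_conformations()
    st.setup_entities()
    return st


def write_pdb(structure: ProteinStructure, dest) -> None:
    """Serialize to PDB (coordinates to 3 decimals, original ordering)."""
    text = structure.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def pdb_string(structure: ProteinStructure) -> str:
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Coordinate access
# ---------------------------------------------------------------------------

def structure_coords(structure: ProteinStructure) -> tuple[np.ndarray, list[str]]:
    """All atom coordinates (n, 3) and their element symbols."""
    coords, elements = [], []
    for chain in structure[0]:
        for res in chain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name.upper())
    if not coords:
        return np.zeros((0, 3)), []
    return np.asarray(coords, dtype=float), elements


def get_residue(structure: ProteinStructure, chain_id: str, res_seq: int) -> gemmi.Residue:
    model = structure[0]
    for chain in model:
        if chain.name != chain_id:
            continue
        for res in chain:
            if res.seqid.num == res_seq:
                return res
    raise StructureError(f"residue {chain_id}:{res_seq} not found")


def residue_coords(res: gemmi.Residue) -> np.ndarray:
    return np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res], dtype=float)


# ---------------------------------------------------------------------------
# Deletion
# ---------------------------------------------------------------------------

def _parse_selection(sel) -> tuple[str, int | None, int | None]:
    """'B' -> whole chain; 'A:10-12' -> range; 'A:10' -> single residue."""
    if isinstance(sel, tuple):
        return sel if len(sel) == 3 else (sel[0], sel[1], sel[1])
    if ":" not in sel:
        return sel, None, None
    chain, rng = sel.split(":", 1)
    if "-" in rng:
        lo, hi = rng.split("-", 1)
        return chain, int(lo), int(hi)
    return chain, int(rng), int(rng)


def delete_components(structure: ProteinStructure, selections) -> ProteinStructure:
    """Return a copy lacking exactly the selected chains/residue ranges."""
    if isinstance(selections, (str, tuple)):
        selections = [selections]
    out = structure.clone()
    model = out[0]
    removed = 0
    for sel in selections:
        chain_id, lo, hi = _parse_selection(sel)
        chain = None
        for c in model:
            if c.name == chain_id:
                chain = c
                break
        if chain is None:
            raise StructureError(f"selection {sel!r}: chain {chain_id!r} not found")
        if lo is None:
            removed += len(chain)
            model.remove_chain(chain_id)
            continue
        idx = [i for i, r in enumerate(chain) if lo <= r.seqid.num <= hi]
        if not idx:
            raise StructureError(f"selection {sel!r} matches no residues")
        for i in reversed(idx):
            del chain[i]
        removed += len(idx)
    if removed == 0:
        raise StructureError("selection matched nothing")
    out.setup_entities()
    return out


# ---------------------------------------------------------------------------
# Virtual mutagenesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """One point substitution, e.g. MutationSpec('A', 71, 'V', 'A')."""

    chain: str
    position: int
    from_res: str
    to_res: str

    @classmethod
    def parse(cls, text: str, chain: str = "A") -> "MutationSpec":
        """Parse compact notation like 'V71A' (optionally 'A:V71A')."""
        if ":" in text:
            chain, text = text.split(":", 1)
        return cls(chain, int(text[1:-1]), text[0].upper(), text[-1].upper())


# Side-chain templates as internal coordinates built outward from the
# backbone.  Each entry: (atom, element, (ref_a, ref_b, ref_c), bond A,
# angle deg at ref_c, torsion deg about ref_b-ref_c).  Single canonical
# rotamer (chi1 trans, aliphatic chains extended).
_T = {
    "ALA": [],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 111.0, -60.0),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 114.0, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.52, 111.0, -60.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 111.0, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 111.0, -60.0),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.0, 180.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, -90.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.47, 111.0, 180.0),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.46, 111.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.41, 111.0, 180.0)],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.81, 111.0, 180.0)],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.41, 109.5, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.52, 111.0, -60.0),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("SD", "S", ("CA", "CB", "CG"), 1.81, 111.0, 180.0),
        ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.0, 180.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 119.0, 0.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 119.0, 180.0),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 112.0, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.23, 121.0, 0.0),
        ("ND2", "N", ("CA", "CB", "CG"), 1.33, 117.0, 180.0),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 119.0, 0.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 119.0, 180.0),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.0, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.23, 121.0, 0.0),
        ("NE2", "N", ("CB", "CG", "CD"), 1.33, 117.0, 180.0),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.36, 131.0, -90.0),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
        ("NE2", "N", ("CG", "ND1", "CE1"), 1.32, 108.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, -90.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.36, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.50, 114.0, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.37, 127.0, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.43, 127.0, -90.0),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.0, 180.0),
        ("CE2", "C", ("CG", "CD1", "NE1"), 1.37, 109.0, 0.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.0, 180.0),
        ("CZ2", "C", ("CD1", "NE1", "CE2"), 1.40, 130.0, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 119.0, 180.0),
        ("CH2", "C", ("NE1", "CE2", "CZ2"), 1.37, 122.0, 180.0),
    ],
    "GLY": [],
}

SUPPORTED_TARGETS = frozenset(AA_3TO1[k] for k in _T)


def _atom_pos(res: gemmi.Residue, name: str) -> np.ndarray:
    for atom in res:
        if atom.name == name:
            return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    raise StructureError(f"atom {name} missing in residue {res.name} {res.seqid.num}")


def _build_cb(res: gemmi.Residue) -> np.ndarray:
    # tetrahedral CB from backbone frame (L-amino-acid chirality)
    return place_atom(_atom_pos(res, "C"), _atom_pos(res, "N"),
                      _atom_pos(res, "CA"), 1.53, 110.5, 123.0)


def apply_mutations(structure: ProteinStructure, specs) -> ProteinStructure:
    """Apply point substitutions, rebuilding side chains from ideal templates.

    Backbone atoms (N, CA, C, O and CB where kept) retain their coordinates
    exactly; side chains beyond CB are rebuilt in a single canonical rotamer.
    Truncating substitutions (e.g. V->A) delete atoms only.
    """
    if isinstance(specs, MutationSpec):
        specs = [specs]
    out = structure.clone()
    for spec in specs:
        to3 = AA_1TO3.get(spec.to_res)
        if to3 is None or to3 not in _T:
            raise StructureError(f"unsupported target residue {spec.to_res!r}")
        res = get_residue(out, spec.chain, spec.position)
        cur1 = AA_3TO1.get(res.name)
        if cur1 != spec.from_res:
            raise StructureError(
                f"{spec.chain}:{spec.position} is {res.name} "
                f"({cur1}), expected {spec.from_res}")
        keep = set(BACKBONE_ATOMS)
        if to3 != "GLY":
            keep.add("CB")
        for i in reversed(range(len(res))):
            if res[i].name not in keep:
                del res[i]
        if to3 != "GLY" and not any(a.name == "CB" for a in res):
            cb = _build_cb(res)
            atom = gemmi.Atom()
            atom.name = "CB"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*cb)
            atom.occ = 1.0
            res.add_atom(atom)
        placed = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
        for name, elem, (ra, rb, rc), bond, angle, torsion in _T[to3]:
            pos = place_atom(placed[ra], placed[rb], placed[rc], bond, angle, torsion)
            placed[name] = pos
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            res.add_atom(atom)
        res.name = to3
    return out


# ---------------------------------------------------------------------------
# Distances and clashes
# ---------------------------------------------------------------------------

def vdw_radius(element: str) -> float:
    return config.BONDI_RADII.get(element.upper(), config.BONDI_DEFAULT)


def find_clashes(coords_a, coords_b, tolerance: float = config.CLASH_TOLERANCE,
                 elements_a=None, elements_b=None) -> list[tuple[int, int]]:
    """Atom pairs closer than r_vdw(i) + r_vdw(j) - tolerance (Bondi radii).

    Elements default to carbon when not supplied.  The returned pair list is
    exhaustive and sorted; indices refer to the two input arrays.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both coordinate sets must be non-empty")
    ra = np.array([vdw_radius(e) for e in elements_a] if elements_a is not None
                  else [config.BONDI_RADII["C"]] * len(A))
    rb = np.array([vdw_radius(e) for e in elements_b] if elements_b is not None
                  else [config.BONDI_RADII["C"]] * len(B))
    cutoff = ra.max() + rb.max() - tolerance
    tree_b = cKDTree(B)
    pairs: list[tuple[int, int]] = []
    for i, neighbours in enumerate(cKDTree(A).query_ball_tree(tree_b, cutoff)):
        for j in neighbours:
            if np.linalg.norm(A[i] - B[j]) < ra[i] + rb[j] - tolerance:
                pairs.append((i, j))
    pairs.sort()
    return pairs


@dataclass
class SiteDefinition:
    """A set of tagged residues with a geometric centroid and radius."""

    residues: list[tuple[str, int]]
    centroid: np.ndarray
    radius: float


def define_site(structure: ProteinStructure, residues, radius: float = 8.0) -> SiteDefinition:
    """Site from (chain, resSeq) pairs; centroid is the pooled atom mean."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    residues = [tuple(r) for r in residues]
    coords = []
    for chain_id, seq in residues:
        res = get_residue(structure, chain_id, seq)
        coords.append(residue_coords(res))
    all_coords = np.vstack(coords)
    return SiteDefinition(residues=residues,
                          centroid=all_coords.mean(axis=0),
                          radius=float(radius))


def site_atom_coords(structure: ProteinStructure, site: SiteDefinition) -> np.ndarray:
    coords = [residue_coords(get_residue(structure, c, s)) for c, s in site.residues]
    return np.vstack(coords)


def min_site_distance(ligand_coords, structure: ProteinStructure,
                      site: SiteDefinition) -> float:
    """Minimum distance between any ligand heavy atom and any site-residue atom."""
    L = np.asarray(ligand_coords, dtype=float)
    if len(L) == 0:
        raise ValueError("ligand has no atoms")
    S = site_atom_coords(structure, site)
    d = np.linalg.norm(L[:, None, :] - S[None, :, :], axis=-1)
    return float(d.min())
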