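"""3D conformer generation: seeded embedding, force-field cleanup, RMSD pruning.

Up to ``max_n`` conformers are generated per molecule (default 10).  Geometries
come from seeded distance-geometry embedding with experimental-torsion
preferences (so acyclic torsions land near the staggered set), are then
relaxed with the package's Dreiding-style force field, and finally deduplicated
by greedy lowest-energy-first RMSD pruning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import config, forcefield
from .geometry import superpose_rmsd


class EmbeddingError(RuntimeError):
    """Raised when no 3D geometry could be generated for a molecule."""


@dataclass
class Conformer:
    """One rigid 3D geometry of a ligand (heavy atoms).

    ``mol`` is None for synthetic pseudo-ligands that exist only as an atom
    cloud; real molecules keep a reference to their RDKit graph.
    """

    elements: list[str]
    coords: np.ndarray
    energy: float = 0.0
    mol: Chem.Mol | None = field(default=None, repr=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) != len(self.elements):
            raise ValueError("coordinate count does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centered_coords(self) -> np.ndarray:
        return self.coords - self.coords.mean(axis=0)


def _embed_raw(mol_h: Chem.Mol, n: int, seed: int, random_coords: bool) -> list[int]:
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1) or 1
    params.useRandomCoords = random_coords
    params.pruneRmsThresh = -1.0
    params.numThreads = 1
    return list(AllChem.EmbedMultipleConfs(mol_h, numConfs=n, params=params))


def embed_conformers(mol: Chem.Mol, max_n: int = config.MAX_CONFORMERS,
                     seed: int = 0) -> list[Conformer]:
    """Generate at most ``max_n`` cleaned, deduplicated conformers.

    Deterministic for a fixed seed.  Raises :class:`EmbeddingError` if no
    geometry can be produced within the retry budget.
    """
    if mol.GetNumAtoms() == 0:
        raise EmbeddingError("cannot embed an empty molecule")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    mol_h = Chem.AddHs(Chem.Mol(mol))
    n_embed = max(max_n + 2, 4)
    conf_ids = _embed_raw(mol_h, n_embed, seed, random_coords=False)
    if not conf_ids:
        conf_ids = _embed_raw(mol_h, n_embed, seed + 7919, random_coords=True)
    if not conf_ids:
        raise EmbeddingError(f"embedding failed for molecule {name or Chem.MolToSmiles(mol)!r}")

    heavy = [a.GetIdx() for a in mol_h.GetAtoms() if a.GetAtomicNum() > 1]
    elements = [mol_h.GetAtomWithIdx(i).GetSymbol() for i in heavy]
    top = forcefield.build_topology(mol)
    out: list[Conformer] = []
    for cid in conf_ids:
        pos = mol_h.GetConformer(cid).GetPositions()[heavy]
        coords, energy = forcefield.minimize(top, pos, max_steps=150)
        out.append(Conformer(elements=elements, coords=coords,
                             energy=energy, mol=mol, name=name))
    return prune_by_rmsd(out, config.CONFORMER_PRUNE_RMSD)[:max_n]


def minimize_conformer(conf: Conformer, max_steps: int = 200) -> Conformer:
    """Relax a conformer with the Dreiding-style force field.

    The returned energy is never above the input conformer's energy.
    """
    if conf.mol is None:
        raise ValueError("cannot minimize a pseudo-ligand without a molecular graph")
    top = forcefield.build_topology(conf.mol)
    coords, energy = forcefield.minimize(top, conf.coords, max_steps=max_steps)
    return Conformer(elements=conf.elements, coords=coords, energy=energy,
                     mol=conf.mol, name=conf.name)


def prune_by_rmsd(conformers: list[Conformer],
                  threshold: float = config.CONFORMER_PRUNE_RMSD) -> list[Conformer]:
    """Greedy lowest-energy-first deduplication.

    Every discarded conformer is within ``threshold`` superposition-RMSD of a
    kept one.
    """
    if not conformers:
        raise ValueError("no conformers to prune")
    ordered = sorted(conformers, key=lambda c: c.energy)
    kept: list[Conformer] = []
    for cand in ordered:
        if all(superpose_rmsd(cand.coords, k.coords) >= threshold for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def conformers_to_multimodel_pdb(conformers: list[Conformer], dest) -> None:
    """Write conformers as a multi-model PDB (HETATM records, ligand LIG)."""
    own = not hasattr(dest, "write")
    fh = open(dest, "w") if own else dest
    try:
        for imodel, conf in enumerate(conformers, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            for i, (el, xyz) in enumerate(zip(conf.elements, conf.coords), start=1):
                name = f"{el}{i}"[:4]
                fh.write(
                    f"HETATM{i:5d} {name:<4s} LIG A   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def conformers_to_sdf(conformers: list[Conformer], dest) -> None:
    """Write real-molecule conformers as SDF records (one per geometry)."""
    from .molecule import write_sdf
    mols = []
    for conf in conformers:
        if conf.mol is None:
            raise ValueError("pseudo-ligands cannot be written as SDF")
        m = Chem.Mol(conf.mol)
        m.RemoveAllConformers()
        c = Chem.Conformer(m.GetNumAtoms())
        for i, xyz in enumerate(conf.coords):
            c.SetAtomPosition(i, tuple(float(v) for v in xyz))
        m.AddConformer(c, assignId=True)
        mols.append(m)
    if hasattr(dest, "write"):
        write_sdf(mols, dest)
    else:
        with open(dest, "w") as fh:
            write_sdf(mols, fh)
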