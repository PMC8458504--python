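"""Shared fixtures: tiny synthetic structures and molecules built in memory."""

from __future__ import annotations

import numpy as np
import pytest

import degradock as dd


def _residue_block(lines, serial_start, res_name, chain, seq, atoms):
    out = []
    serial = serial_start
    for name, element, (x, y, z) in atoms:
        out.append(
            f"ATOM  {serial:5d}  {name:<3s} {res_name} {chain}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")
        serial += 1
    lines.extend(out)
    return serial


def make_structure_from_atoms(coords, elements):
    """One-chain structure with one pseudo-atom per residue (test helper)."""
    lines = []
    serial = 1
    for i, (xyz, el) in enumerate(zip(coords, elements), start=1):
        serial = _residue_block(lines, serial, "GLY", "A", i,
                                [("CA", el, tuple(xyz))])
    lines.append("END")
    return dd.read_pdb("\n".join(lines) + "\n")


def backbone(x0: float) -> list:
    """Idealized-ish backbone + CB atom records offset along x."""
    return [
        ("N", "N", (x0 + 0.0, 0.0, 0.0)),
        ("CA", "C", (x0 + 1.458, 0.0, 0.0)),
        ("C", "C", (x0 + 2.009, 1.420, 0.0)),
        ("O", "O", (x0 + 1.251, 2.390, 0.0)),
        ("CB", "C", (x0 + 1.988, -0.773, -1.208)),
    ]


@pytest.fixture(scope="session")
def surrogate_pdb_text() -> str:
    """Two-chain fixture: chain A carries V71/A72/L74/R81, chain B a peptide.

    Side-chain atoms beyond CB are placed at plausible (not ideal) positions;
    the mutation machinery only requires backbone + CB to be present.
    """
    lines = []
    serial = 1
    defs = [
        ("VAL", 71, [("CG1", "C", (1.3, -2.1, -1.1)), ("CG2", "C", (3.5, -0.9, -1.2))]),
        ("ALA", 72, []),
        ("GLY", 73, None),  # GLY: no CB
        ("LEU", 74, [("CG", "C", (1.9, -1.0, -2.6)),
                     ("CD1", "C", (3.0, -1.9, -3.2)), ("CD2", "C", (0.8, -0.4, -3.5))]),
        ("SER", 75, [("OG", "O", (2.2, -2.0, -1.3))]),
        ("ARG", 81, [("CG", "C", (3.1, -0.4, -2.0)), ("CD", "C", (3.8, -1.5, -2.8)),
                     ("NE", "N", (5.0, -1.0, -3.4)), ("CZ", "C", (5.9, -1.8, -3.9)),
                     ("NH1", "N", (5.7, -3.1, -3.9)), ("NH2", "N", (7.0, -1.3, -4.4))]),
    ]
    for i, (res, seq, side) in enumerate(defs):
        x0 = 8.0 * i
        atoms = backbone(x0)
        if side is None:
            atoms = atoms[:4]  # GLY has no CB
        else:
            atoms = atoms + [(n, e, (x0 + dx, dy, dz)) for n, e, (dx, dy, dz) in side]
        serial = _residue_block(lines, serial, res, "A", seq, atoms)
    lines.append("TER")
    for j in range(3):  # chain B: the chaperone-peptide stand-in
        serial = _residue_block(lines, serial, "GLY", "B", j + 1,
                                [("CA", "C", (4.0 * j, 20.0, 5.0))])
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def surrogate_structure(surrogate_pdb_text):
    return dd.read_pdb(surrogate_pdb_text)


@pytest.fixture(scope="session")
def lead_mol():
    return dd.parse_smiles(dd.LEAD_COMPOUND_SMILES, name="SMC13")


@pytest.fixture(scope="session")
def compact_receptor():
    """Small knob-free toy receptor with a compact cognate ligand."""
    rec = dd.make_toy_receptor(pocket_radius=4.5, seed=11)
    lig = dd.make_cognate_ligand(4.5, seed=12, name="compact")
    planted = dd.plant_cognate_ligand(rec, lig, seed=13)
    return rec, lig, planted
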