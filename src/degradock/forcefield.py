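"""Dreiding-style force field used for conformer cleanup and pose refinement.

Energy terms: harmonic bonds and angles plus a 12-6 Lennard-Jones nonbonded
term (1-2 and 1-3 pairs excluded).  Equilibrium bond lengths come from
covalent-radii sums scaled by bond order; equilibrium angles from the central
atom's hybridization; LJ minimum-energy distances from Bondi radii sums.
Constants live in :mod:`degradock.config`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import config


class MinimizationError(RuntimeError):
    """Raised when the energy turns non-finite during minimization."""


def _covalent(elem: str) -> float:
    return config.COVALENT_RADII.get(elem.upper(), config.COVALENT_DEFAULT)


@dataclass
class Topology:
    """Bonded terms of one molecule (heavy atoms only)."""

    elements: list[str]
    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray        # (nb,)
    angles: np.ndarray         # (na, 3) int, middle atom is the vertex
    angle_theta0: np.ndarray   # (na,) radians
    nb_pairs: np.ndarray       # (np, 2) int, pairs with LJ interactions
    nb_rmin: np.ndarray        # (np,)


_HYB_ANGLE = {
    Chem.HybridizationType.SP: 180.0,
    Chem.HybridizationType.SP2: 120.0,
    Chem.HybridizationType.SP3: 109.47,
}


def build_topology(mol: Chem.Mol) -> Topology:
    """Bond/angle/nonbonded term lists for the heavy-atom graph of ``mol``."""
    n = mol.GetNumAtoms()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds, r0 = [], []
    adjacency = [set() for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        scale = config.FF_ORDER_SCALE.get(order, 1.0)
        bonds.append((i, j))
        r0.append((_covalent(elements[i]) + _covalent(elements[j])) * scale)
        adjacency[i].add(j)
        adjacency[j].add(i)
    angles, theta0 = [], []
    for j in range(n):
        nbrs = sorted(adjacency[j])
        ideal = _HYB_ANGLE.get(mol.GetAtomWithIdx(j).GetHybridization(), 109.47)
        if mol.GetAtomWithIdx(j).GetIsAromatic():
            ideal = 120.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
                theta0.append(np.deg2rad(ideal))
    excluded = {tuple(sorted(b)) for b in bonds}
    for i, j, k in angles:
        excluded.add(tuple(sorted((i, k))))
    nb_pairs, nb_rmin = [], []
    radii = [config.BONDI_RADII.get(e.upper(), config.BONDI_DEFAULT) for e in elements]
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            nb_pairs.append((i, j))
            nb_rmin.append(radii[i] + radii[j])
    return Topology(
        elements=elements,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_r0=np.array(r0),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_theta0=np.array(theta0),
        nb_pairs=np.array(nb_pairs, dtype=int).reshape(-1, 2),
        nb_rmin=np.array(nb_rmin),
    )


def energy_and_gradient(top: Topology, coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Total energy (kcal/mol) and its analytic gradient, shape (n, 3)."""
    X = np.asarray(coords, dtype=float)
    grad = np.zeros_like(X)
    energy = 0.0

    if len(top.bonds):
        vec = X[top.bonds[:, 0]] - X[top.bonds[:, 1]]
        r = np.linalg.norm(vec, axis=1)
        dr = r - top.bond_r0
        energy += float(config.FF_BOND_K * (dr * dr).sum())
        f = (2.0 * config.FF_BOND_K * dr / np.maximum(r, 1e-8))[:, None] * vec
        np.add.at(grad, top.bonds[:, 0], f)
        np.add.at(grad, top.bonds[:, 1], -f)

    if len(top.angles):
        i, j, k = top.angles.T
        u = X[i] - X[j]
        v = X[k] - X[j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip((u * v).sum(1) / np.maximum(nu * nv, 1e-8), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dt = theta - top.angle_theta0
        energy += float(config.FF_ANGLE_K * (dt * dt).sum())
        sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 1e-8))
        coef = 2.0 * config.FF_ANGLE_K * dt / sin_t
        du = (u / (nu * nu)[:, None]) * cos_t[:, None] - v / (nu * nv)[:, None]
        dv = (v / (nv * nv)[:, None]) * cos_t[:, None] - u / (nu * nv)[:, None]
        np.add.at(grad, i, -coef[:, None] * du)
        np.add.at(grad, k, -coef[:, None] * dv)
        np.add.at(grad, j, coef[:, None] * (du + dv))

    if len(top.nb_pairs):
        vec = X[top.nb_pairs[:, 0]] - X[top.nb_pairs[:, 1]]
        r = np.maximum(np.linalg.norm(vec, axis=1), 0.3)
        s = top.nb_rmin / r
        s6 = s ** 6
        energy += float((config.FF_LJ_EPS * (s6 * s6 - 2.0 * s6)).sum())
        dEdr = config.FF_LJ_EPS * 12.0 * (s6 - s6 * s6) / r
        f = (dEdr / r)[:, None] * vec
        np.add.at(grad, top.nb_pairs[:, 0], f)
        np.add.at(grad, top.nb_pairs[:, 1], -f)

    return energy, grad


def minimize(top: Topology, coords: np.ndarray, max_steps: int = 200,
             gtol: float = 1e-3) -> tuple[np.ndarray, float]:
    """Steepest descent with backtracking line search.

    Energy never increases relative to the input; terminates on the step
    budget or when the gradient norm falls below ``gtol``.
    """
    X = np.asarray(coords, dtype=float).copy()
    energy, grad = energy_and_gradient(top, X)
    if not np.isfinite(energy):
        raise MinimizationError("non-finite energy at step 0")
    step = 1e-3
    for it in range(max_steps):
        gnorm = np.linalg.norm(grad)
        if gnorm < gtol:
            break
        direction = -grad / gnorm
        accepted = False
        for _ in range(30):
            X_new = X + step * direction
            e_new, g_new = energy_and_gradient(top, X_new)
            if not np.isfinite(e_new):
                raise MinimizationError(f"non-finite energy at step {it}")
            if e_new <= energy:
                X, energy, grad = X_new, e_new, g_new
                step = min(step * 1.6, 0.5)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return X, float(energy)


# ---------------------------------------------------------------------------
# Intermolecular term for rigid pose refinement
# ---------------------------------------------------------------------------

def interaction_energy(lig_coords: np.ndarray, lig_elements,
                       rec_coords: np.ndarray, rec_elements) -> float:
    """Pairwise 12-6 LJ energy between a ligand and (fixed) receptor atoms."""
    L = np.asarray(lig_coords, dtype=float)
    R = np.asarray(rec_coords, dtype=float)
    rl = np.array([config.BONDI_RADII.get(e.upper(), config.BONDI_DEFAULT)
                   for e in lig_elements])
    rr = np.array([config.BONDI_RADII.get(e.upper(), config.BONDI_DEFAULT)
                   for e in rec_elements])
    d = np.maximum(np.linalg.norm(L[:, None, :] - R[None, :, :], axis=-1), 0.5)
    rmin = rl[:, None] + rr[None, :]
    s6 = (rmin / d) ** 6
    return float((config.FF_LJ_EPS * (s6 * s6 - 2.0 * s6)).sum())
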