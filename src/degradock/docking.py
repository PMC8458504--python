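"""Rigid patch-style docking into a defined site.

Poses are enumerated as seeded uniform rotations crossed with translations on
a 1 A grid inside the site sphere, scored by a geometric contact/clash score
(contacts in the 3.0-4.5 A shell, clashes below 3.0 A, composite =
contacts - 5 x clashes), clustered greedily at 4 A ligand RMSD in the common
receptor frame, and optionally refined by rigid-body 6-DOF minimization of a
Lennard-Jones interaction energy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from . import config, forcefield
from .conformers import Conformer
from .geometry import (quaternion_to_matrix, random_unit_quaternions,
                       rmsd_no_superposition, rotvec_to_matrix)
from .structure import ProteinStructure, SiteDefinition, structure_coords


@dataclass
class Pose:
    """One rigid placement of a ligand conformer against the receptor."""

    conformer: Conformer
    quaternion: np.ndarray          # (w, x, y, z)
    translation: np.ndarray         # target position of the ligand centroid
    coords: np.ndarray              # transformed ligand coordinates
    contacts: int | None = None
    clashes: int | None = None
    score: float | None = None

    def recompute_coords(self) -> np.ndarray:
        R = quaternion_to_matrix(self.quaternion)
        return self.conformer.centered_coords() @ R.T + self.translation


@dataclass
class DockingResult:
    """Clustered poses of one molecule, ordered by non-increasing score."""

    name: str
    poses: list[Pose] = field(default_factory=list)
    cluster_sizes: list[int] = field(default_factory=list)

    @property
    def best_pose(self) -> Pose | None:
        return self.poses[0] if self.poses else None


# ---------------------------------------------------------------------------
# Receptor context
# ---------------------------------------------------------------------------

@dataclass
class ReceptorContext:
    """Receptor atoms cached as arrays for repeated scoring.

    ``near_*`` restrict to atoms that can possibly interact with a ligand
    whose centroid stays inside the site sphere; using them is exact for
    contact/clash counting because the cutoff radius includes the maximum
    ligand extent plus the 4.5 A interaction shell.
    """

    coords: np.ndarray
    elements: list[str]
    site: SiteDefinition
    near_coords: np.ndarray
    near_elements: list[str]

    @classmethod
    def build(cls, structure: ProteinStructure, site: SiteDefinition,
              max_ligand_extent: float = 8.0) -> "ReceptorContext":
        coords, elements = structure_coords(structure)
        cutoff = site.radius + max_ligand_extent + config.CONTACT_SHELL[1] + 0.1
        d = np.linalg.norm(coords - site.centroid, axis=1)
        mask = d <= cutoff
        return cls(coords=coords, elements=elements, site=site,
                   near_coords=coords[mask],
                   near_elements=[e for e, m in zip(elements, mask) if m])


def grid_points(radius: float, spacing: float = config.GRID_SPACING) -> np.ndarray:
    """Integer-lattice offsets (spacing-scaled) with norm <= radius."""
    n = int(np.floor(radius / spacing))
    pts = [np.array([i, j, k], dtype=float) * spacing
           for i, j, k in itertools.product(range(-n, n + 1), repeat=3)
           if (i * i + j * j + k * k) * spacing * spacing <= radius * radius]
    return np.array(pts).reshape(-1, 3)


# ---------------------------------------------------------------------------
# Sampling and scoring
# ---------------------------------------------------------------------------

def sample_poses(structure: ProteinStructure, site: SiteDefinition,
                 conformers: list[Conformer], n_orientations: int = 8,
                 seed: int = 0) -> list[Pose]:
    """Enumerate rotation x grid-translation poses (unscored).

    Deterministic for a fixed seed; ligand centroids never leave the site
    sphere by construction.
    """
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = grid_points(site.radius)
    poses: list[Pose] = []
    for conf in conformers:
        quats = random_unit_quaternions(n_orientations, rng)
        centered = conf.centered_coords()
        for q in quats:
            R = quaternion_to_matrix(q)
            rotated = centered @ R.T
            for off in offsets:
                t = site.centroid + off
                poses.append(Pose(conformer=conf, quaternion=q.copy(),
                                  translation=t, coords=rotated + t))
    return poses


def _count_pairs(lig: np.ndarray, rec: np.ndarray) -> tuple[int, int]:
    d = np.linalg.norm(lig[:, None, :] - rec[None, :, :], axis=-1)
    lo, hi = config.CONTACT_SHELL
    contacts = int(((d >= lo) & (d <= hi)).sum())
    clashes = int((d < config.CLASH_DISTANCE).sum())
    return contacts, clashes


def score_pose(structure_or_context, pose: Pose) -> Pose:
    """Fill in contact count, clash count and the composite score."""
    if isinstance(structure_or_context, ReceptorContext):
        rec = structure_or_context.coords
    else:
        rec, _ = structure_coords(structure_or_context)
    pose.contacts, pose.clashes = _count_pairs(pose.coords, rec)
    pose.score = (config.CONTACT_WEIGHT * pose.contacts
                  - config.CLASH_WEIGHT * pose.clashes)
    return pose


def score_poses_batch(context: ReceptorContext, conf: Conformer,
                      quats: np.ndarray, targets: np.ndarray,
                      chunk: int = 40000) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized contact/clash counts for all (rotation, translation) combos.

    Returns (contacts, clashes) arrays of shape (len(quats) * len(targets),),
    rotation-major ordering.
    """
    from scipy.spatial.distance import cdist
    rec = context.near_coords
    centered = conf.centered_coords()
    n_atoms = centered.shape[0]
    n_t = len(targets)
    all_contacts = np.empty(len(quats) * n_t, dtype=np.int32)
    all_clashes = np.empty(len(quats) * n_t, dtype=np.int32)
    lo, hi = config.CONTACT_SHELL
    for iq, q in enumerate(quats):
        rotated = centered @ quaternion_to_matrix(q).T      # (n_atoms, 3)
        base = iq * n_t
        step = max(1, chunk // max(1, n_atoms))
        for start in range(0, n_t, step):
            t = targets[start:start + step]                 # (m, 3)
            lig = (rotated[None, :, :] + t[:, None, :]).reshape(-1, 3)
            d = cdist(lig, rec).reshape(len(t), n_atoms, -1)
            all_contacts[base + start:base + start + len(t)] = \
                ((d >= lo) & (d <= hi)).sum(axis=(1, 2))
            all_clashes[base + start:base + start + len(t)] = \
                (d < config.CLASH_DISTANCE).sum(axis=(1, 2))
    return all_contacts, all_clashes


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_poses(poses: list[Pose],
                  rmsd_threshold: float = config.POSE_CLUSTER_RMSD,
                  name: str = "") -> DockingResult:
    """Greedy best-score-first clustering at ``rmsd_threshold`` ligand RMSD.

    Poses share the receptor frame, so RMSD is computed without
    re-superposition.  Cluster representatives end up pairwise farther apart
    than the threshold and ordered by non-increasing composite score.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    scored = [p for p in poses if p.score is not None]
    if len(scored) != len(poses):
        raise ValueError("cluster_poses requires scored poses")
    ordered = sorted(scored, key=lambda p: -p.score)
    reps: list[Pose] = []
    sizes: list[int] = []
    for pose in ordered:
        assigned = False
        for idx, rep in enumerate(reps):
            if (pose.conformer.n_atoms == rep.conformer.n_atoms and
                    rmsd_no_superposition(pose.coords, rep.coords) <= rmsd_threshold):
                sizes[idx] += 1
                assigned = True
                break
        if not assigned:
            reps.append(pose)
            sizes.append(1)
    if not name and reps:
        name = reps[0].conformer.name
    return DockingResult(name=name, poses=reps, cluster_sizes=sizes)


# ---------------------------------------------------------------------------
# Rigid refinement
# ---------------------------------------------------------------------------

def refine_pose(structure_or_context, pose: Pose, max_steps: int = 60) -> Pose:
    """Rigid-body 6-DOF LJ minimization around the current placement.

    Keeps the refined pose only when its composite score did not decrease;
    the ligand centroid is constrained to site radius + 2 A when a receptor
    context (with a site) is available.
    """
    if isinstance(structure_or_context, ReceptorContext):
        ctx = structure_or_context
        rec_coords, rec_elements = ctx.near_coords, ctx.near_elements
        site = ctx.site
    else:
        rec_coords, rec_elements = structure_coords(structure_or_context)
        ctx = None
        site = None
    base = score_pose(structure_or_context, pose)
    centroid0 = base.coords.mean(axis=0)
    centered = base.coords - centroid0
    lig_elements = base.conformer.elements

    def objective(x: np.ndarray) -> float:
        R = rotvec_to_matrix(x[:3])
        lig = centered @ R.T + centroid0 + x[3:]
        e = forcefield.interaction_energy(lig, lig_elements, rec_coords, rec_elements)
        if site is not None:
            excess = np.linalg.norm(lig.mean(axis=0) - site.centroid) - (site.radius + 2.0)
            if excess > 0:
                e += 100.0 * excess * excess
        return e

    try:
        res = scipy_minimize(objective, np.zeros(6), method="Powell",
                             options={"maxiter": max_steps, "xtol": 1e-3})
    except Exception:
        return base
    R = rotvec_to_matrix(res.x[:3])
    new_coords = centered @ R.T + centroid0 + res.x[3:]
    refined = Pose(conformer=base.conformer, quaternion=base.quaternion,
                   translation=new_coords.mean(axis=0), coords=new_coords)
    refined = score_pose(structure_or_context, refined)
    if refined.score is None or refined.score < base.score:
        return base
    return refined


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def poses_to_pdb(structure: ProteinStructure, poses: list[Pose], dest) -> None:
    """Receptor plus ligand placements as a multi-model PDB."""
    from .structure import pdb_string
    receptor_records = [line for line in pdb_string(structure).splitlines()
                        if line.startswith(("ATOM", "HETATM", "TER"))]
    own = not hasattr(dest, "write")
    fh = open(dest, "w") if own else dest
    try:
        for imodel, pose in enumerate(poses, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            fh.write("\n".join(receptor_records) + "\n")
            for i, (el, xyz) in enumerate(zip(pose.conformer.elements,
                                              pose.coords), start=1):
                name = f"{el}{i}"[:4]
                fh.write(
                    f"HETATM{i:5d} {name:<4s} LIG L   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {el:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# High-level per-ligand docking (pipeline fast path)
# ---------------------------------------------------------------------------

def dock_ligand(context: ReceptorContext, conformers: list[Conformer],
                n_orientations: int = 8, seed: int = 0, keep_top: int = 100,
                refine: bool = False,
                rmsd_threshold: float = config.POSE_CLUSTER_RMSD) -> DockingResult:
    """Sample, score, cluster (and optionally refine) poses for one ligand.

    Equivalent to sample_poses + score_pose on every pose, but scores the
    rotation x grid ensemble with vectorized batch counting and materializes
    Pose objects only for the ``keep_top`` best placements before clustering.
    """
    rng = np.random.default_rng(seed)
    targets = context.site.centroid + grid_points(context.site.radius)
    best: list[tuple[float, int, int, int, np.ndarray, np.ndarray]] = []
    for conf_idx, conf in enumerate(conformers):
        quats = random_unit_quaternions(n_orientations, rng)
        contacts, clashes = score_poses_batch(context, conf, quats, targets)
        scores = (config.CONTACT_WEIGHT * contacts
                  - config.CLASH_WEIGHT * clashes).astype(float)
        order = np.argsort(-scores, kind="stable")[:keep_top]
        n_t = len(targets)
        for flat in order:
            iq, it = divmod(int(flat), n_t)
            best.append((float(scores[flat]), int(contacts[flat]),
                         int(clashes[flat]), conf_idx, quats[iq], targets[it]))
    best.sort(key=lambda rec: -rec[0])
    poses: list[Pose] = []
    for score, n_contact, n_clash, conf_idx, q, t in best[:keep_top]:
        conf = conformers[conf_idx]
        R = quaternion_to_matrix(q)
        coords = conf.centered_coords() @ R.T + t
        poses.append(Pose(conformer=conf, quaternion=q, translation=t,
                          coords=coords, contacts=n_contact, clashes=n_clash,
                          score=score))
    if not poses:
        return DockingResult(name=conformers[0].name if conformers else "")
    result = cluster_poses(poses, rmsd_threshold)
    if refine and result.poses:
        result.poses[0] = refine_pose(context, result.poses[0])
    return result
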