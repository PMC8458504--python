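"""Interaction-fingerprint featurization of docking models.

Each scored pose becomes a fixed-length named vector: protein-ligand
heavy-atom contact counts binned by protein atom class {C, N, O, S, other} x
ligand atom class {C, N, O, other} x distance shell {[0,2.5), [2.5,3.5),
[3.5,4.5)}, followed by coarse summaries: donor/acceptor heavy-atom pair
count (N/O vs N/O within 3.5 A), hydrophobic C-C contacts within 4.5 A,
buried-ligand fraction, the docking composite score and the ligand
heavy-atom count.
"""

from __future__ import annotations

import numpy as np

from .docking import Pose, ReceptorContext
from .structure import ProteinStructure, structure_coords

PROTEIN_CLASSES = ("C", "N", "O", "S", "X")
LIGAND_CLASSES = ("C", "N", "O", "X")
DISTANCE_BINS = ((0.0, 2.5), (2.5, 3.5), (3.5, 4.5))
_BIN_LABELS = ("0_2.5", "2.5_3.5", "3.5_4.5")

HBOND_DISTANCE = 3.5
HYDROPHOBIC_DISTANCE = 4.5
BURIAL_DISTANCE = 4.5

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"cnt_{p}{l}_{b}"
    for p in PROTEIN_CLASSES for l in LIGAND_CLASSES for b in _BIN_LABELS
) + ("hbond_pairs", "hydrophobic_contacts", "buried_fraction",
     "composite_score", "ligand_heavy_atoms")

N_FEATURES = len(FEATURE_NAMES)


def _atom_class(element: str, classes: tuple[str, ...]) -> int:
    el = element.upper()
    if el in classes:
        return classes.index(el)
    return len(classes) - 1  # "X"


def featurize_pose(structure_or_context, pose: Pose) -> np.ndarray:
    """Deterministic feature vector of one scored pose (length 65)."""
    if pose.score is None:
        raise ValueError("featurize_pose requires a scored pose")
    if isinstance(structure_or_context, ReceptorContext):
        rec_coords = structure_or_context.coords
        rec_elements = structure_or_context.elements
    else:
        rec_coords, rec_elements = structure_coords(structure_or_context)
    lig = pose.coords
    lig_elements = pose.conformer.elements

    d = np.linalg.norm(rec_coords[None, :, :] - lig[:, None, :], axis=-1)
    # (ligand, receptor) distance matrix
    pclass = np.array([_atom_class(e, PROTEIN_CLASSES) for e in rec_elements])
    lclass = np.array([_atom_class(e, LIGAND_CLASSES) for e in lig_elements])

    vec = np.zeros(N_FEATURES)
    nb = len(DISTANCE_BINS)
    for b, (lo, hi) in enumerate(DISTANCE_BINS):
        mask = (d >= lo) & (d < hi)
        li, ri = np.nonzero(mask)
        if len(li):
            flat = (pclass[ri] * len(LIGAND_CLASSES) + lclass[li]) * nb + b
            np.add.at(vec, flat, 1)

    polar_rec = np.isin([e.upper() for e in rec_elements], ("N", "O"))
    polar_lig = np.isin([e.upper() for e in lig_elements], ("N", "O"))
    vec[60] = int((d[np.ix_(polar_lig, polar_rec)] <= HBOND_DISTANCE).sum())

    carbon_rec = np.array([e.upper() == "C" for e in rec_elements])
    carbon_lig = np.array([e.upper() == "C" for e in lig_elements])
    vec[61] = int((d[np.ix_(carbon_lig, carbon_rec)] <= HYDROPHOBIC_DISTANCE).sum())

    contacted = (d <= BURIAL_DISTANCE).any(axis=1)
    vec[62] = contacted.sum() / max(1, len(lig))
    vec[63] = float(pose.score)
    vec[64] = float(len(lig))
    return vec


def feature_matrix_tsv(features: np.ndarray, dest) -> None:
    """Write a feature matrix with the canonical header as TSV."""
    own = not hasattr(dest, "write")
    fh = open(dest, "w") if own else dest
    try:
        fh.write("\t".join(FEATURE_NAMES) + "\n")
        for row in np.atleast_2d(features):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")
    finally:
        if own:
            fh.close()
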