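"""Package-wide constants and defaults.

All tunable parameters of the screen live here so that every stage reads the
same values and the pipeline can hash its effective configuration.  Distances
are in Angstrom throughout.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Screen-defining defaults
# ---------------------------------------------------------------------------

#: Maximum number of 3D conformers generated per molecule.
MAX_CONFORMERS = 10

#: Greedy pose-clustering RMSD threshold (ligand RMSD in the receptor frame).
POSE_CLUSTER_RMSD = 4.0

#: Number of trees in the random-forest binder classifier.
N_TREES = 500

#: Degradation-site proximity cutoff: a candidate passes iff the minimum
#: heavy-atom distance between its pose and any atom of the tagged site
#: residues is <= this value (inclusive comparison).
SITE_CUTOFF = 5.0

# ---------------------------------------------------------------------------
# Docking score
# ---------------------------------------------------------------------------

#: Protein-ligand heavy-atom pairs with distance in this closed-open shell
#: count as favourable contacts.
CONTACT_SHELL = (3.0, 4.5)

#: Pairs closer than this are steric clashes for the docking score (for a
#: carbon-carbon pair this coincides with the Bondi-radii clash rule at the
#: default 0.4 A tolerance: 1.70 + 1.70 - 0.40 = 3.00).
CLASH_DISTANCE = 3.0

CONTACT_WEIGHT = 1.0
CLASH_WEIGHT = 5.0

#: Translation grid spacing for pose sampling.
GRID_SPACING = 1.0

# ---------------------------------------------------------------------------
# Geometry tables
# ---------------------------------------------------------------------------

#: Bondi van der Waals radii (A).  Atoms missing from the table fall back to
#: the generic radius.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
BONDI_DEFAULT = 1.70

#: Crystallographic clash-tolerance convention.
CLASH_TOLERANCE = 0.4

#: Single-bond covalent radii (A) used for force-field equilibrium lengths.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
}
COVALENT_DEFAULT = 0.77

# ---------------------------------------------------------------------------
# Dreiding-style force-field constants
# ---------------------------------------------------------------------------

#: Harmonic bond force constant, kcal/mol/A^2.
FF_BOND_K = 300.0
#: Harmonic angle force constant, kcal/mol/rad^2.
FF_ANGLE_K = 50.0
#: Lennard-Jones well depth, kcal/mol (uniform).
FF_LJ_EPS = 0.1
#: Bond-order scale factors applied to the covalent-radii sum.
FF_ORDER_SCALE = {1.0: 1.00, 1.5: 0.95, 2.0: 0.91, 3.0: 0.85}

# ---------------------------------------------------------------------------
# Descriptor panel (SwissADME-style bioavailability radar axis ranges)
# ---------------------------------------------------------------------------

#: axis -> (lower, upper) of the "drug-like" zone.
RADAR_RANGES = {
    "LIPO": (-0.7, 5.0),     # Wildman-Crippen logP
    "SIZE": (150.0, 500.0),  # molecular weight, g/mol
    "POLAR": (20.0, 130.0),  # Ertl TPSA, A^2
    "INSOLU": (-6.0, 0.0),   # ESOL logS
    "INSATU": (0.25, 1.0),   # fraction of sp3 carbons
    "FLEX": (0.0, 9.0),      # rotatable bonds
}

#: Conformer RMSD dedup threshold.
CONFORMER_PRUNE_RMSD = 0.5
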