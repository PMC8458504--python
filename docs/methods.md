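# Methods

This note documents the models and procedures implemented in degradock, the
parameters that matter, the synthetic data the tests run on, and the
limitations of both.

## Problem setting

The screen looks for small molecules that bind a protein surface adjacent to
designated ubiquitylation lysines (a "degradation site"), the surface
normally occupied by a chaperone peptide. The pipeline is: prepare a
surrogate receptor → generate ligand conformers → dock rigidly into the
site → featurize each docking model → score with a random-forest binder
classifier → discard candidates far from the degradation site → rank.

## Receptor preparation

Structures are read and written as PDB through gemmi; alternative locations
are resolved by keeping altLoc 'A' or blank. Component deletion removes
whole chains or residue ranges and leaves every other atom untouched.

Virtual mutagenesis substitutes residue identities while keeping all
backbone atoms (N, CA, C, O, and CB where retained) bit-identical. Side
chains beyond CB are rebuilt from idealized internal-coordinate templates
(bond lengths from standard covalent geometry, one canonical rotamer:
chi1 trans, aliphatic chains extended, rings planar) using natural-extension
(NeRF) placement. No rotamer search is performed — downstream scoring is
deliberately coarse, so a single rotamer is adequate. Seventeen target
residue types are supported; proline (backbone-coupled) is rejected
explicitly, and glycine targets simply truncate the side chain.

## Conformers

Up to `MAX_CONFORMERS = 10` conformers per molecule. Geometries come from
seeded distance-geometry embedding with experimental-torsion preferences
(RDKit ETKDGv3), which places acyclic torsions near the staggered
{±60°, 180°} set. Each geometry is then relaxed with the package's
Dreiding-style force field and the set is deduplicated by greedy
lowest-energy-first pruning at 0.5 Å superposition RMSD (Kabsch, no
symmetry correction). Embedding is bit-reproducible for a fixed seed.

The force field has three terms: harmonic bonds (k = 300 kcal/mol/Å²,
equilibrium lengths from covalent-radii sums scaled by bond order),
harmonic angles (k = 50 kcal/mol/rad², equilibria from hybridization), and
a 12-6 Lennard-Jones nonbonded term (ε = 0.1 kcal/mol, minimum-energy
distance from Bondi radii sums; 1-2 and 1-3 pairs excluded). Minimization
is steepest descent with a backtracking line search, which guarantees the
energy never rises above the input; it stops at the step budget or when
the gradient norm falls below 1e-3. There are no torsional terms — torsion
quality is inherited from the embedding, not imposed by the minimizer.

## Docking

Docking is rigid and exhaustive over a seeded ensemble: `n_orientations`
uniform random rotations (Shoemake quaternions) crossed with translations on
a 1 Å integer grid covering the site sphere; ligand centroids never leave
the sphere. The score is geometric:

    contacts  = protein–ligand heavy-atom pairs with 3.0 Å ≤ d ≤ 4.5 Å
    clashes   = pairs with d < 3.0 Å
    composite = 1.0 · contacts − 5.0 · clashes

The flat 3.0 Å clash distance coincides with the Bondi-radii clash rule for
a carbon–carbon pair at the default 0.4 Å tolerance (1.70 + 1.70 − 0.40);
the full per-element vdW rule is used everywhere clashes are inspected
structurally (`find_clashes`, interface checks). Contact/clash weights and
the shell are configuration constants, not fitted quantities.

Poses are clustered greedily, best score first, at `POSE_CLUSTER_RMSD =
4.0 Å` ligand RMSD computed in the common receptor frame (poses are
alternative placements at one site, so no re-superposition). Optional
refinement minimizes the intermolecular LJ energy over the 6 rigid-body
degrees of freedom (Powell), keeps the result only if the composite score
did not decrease, and constrains the centroid to site radius + 2 Å.

The library-screening fast path (`dock_ligand`) scores the full
rotation × grid ensemble with vectorized batch counting and materializes
only the best ~100 placements before clustering; it is exactly equivalent
to scoring every sampled pose and keeping the top ones.

Pose-recovery behaviour: for a compact molded binder the top-ranked cluster
re-finds the planted placement within 2 Å across seeds. The contact score
is nearly rotation-invariant for quasi-isotropic ligands, so recovery is
assessed with compact binders whose orientational degeneracy lies within
that tolerance; orientation of strongly anisotropic ligands is keyed only
through clashes.

## Featurization and classification

Each scored pose becomes a fixed-order vector of 65 named features:
60 contact counts binned by protein atom class {C, N, O, S, other} ×
ligand atom class {C, N, O, other} × distance shell {[0,2.5), [2.5,3.5),
[3.5,4.5)} Å, then donor/acceptor heavy-atom pairs (N/O–N/O within 3.5 Å),
hydrophobic C–C contacts within 4.5 Å, the buried-ligand fraction
(ligand atoms with any protein atom within 4.5 Å, over ligand heavy atoms),
the docking composite score, and the ligand heavy-atom count. Every entry
is computable by exhaustive pair enumeration, which the tests exploit as an
oracle.

The classifier is a 500-tree random forest (bagged CART, Gini impurity,
√F candidate features per split, grown to purity, seeded). Training
delegates to scikit-learn; the fitted trees are immediately exported to
plain arrays, and **prediction is the package's own traversal**: the binder
score is the fraction of trees whose leaf majority class is "binder",
identical to a hand tally of per-tree votes. The exported model serializes
to versioned JSON and round-trips to bit-identical predictions.

Training pairs follow the screen's design: positives are the best redocked
pose of each cognate receptor–ligand pair; negatives re-dock the same
ligands into deranged (never cognate) receptors, sampled with a seed, with
exact class balance.

## Site filter and ranking

A candidate passes iff the minimum distance between its best pose's heavy
atoms and any atom of the tagged site residues is ≤ 5.0 Å — the comparison
is inclusive at exactly 5.0, and all atoms of the site residues count (not
only side-chain termini). Failures are retained, flagged, and logged with
the rule name. Passing candidates are ranked by classifier score; ties
break by higher docking contact count, then lexicographic molecule id, so
reports are byte-identical across reruns.

## Descriptor panel

Molecular weight (IUPAC atomic weights), Ertl TPSA (N/O fragment
contributions), H-bond donors (N/O bearing ≥1 H) and acceptors (all O,
plus N excluding amide/imide and pyrrole-type aromatic N — a rule chosen
because it reproduces the reference acceptor count of 4 for a
C28H35N3O3 lead with two imide N, one amine N, two carbonyl O and one
ether O), Wildman–Crippen logP, Delaney ESOL logS, strict rotatable-bond
counting (non-ring single bonds between non-terminal heavy atoms, amides
excluded), Lipinski violations (MW > 500, logP > 5, HBD > 5, HBA > 10) and
the Abbott/Martin bioavailability score: anions at pH 7 bucket by TPSA
(> 150 → 0.11; 75–150 → 0.56; < 75 → 0.85), everything else scores 0.55
with ≤ 1 violation and 0.17 otherwise. The radar axes use SwissADME's
default ranges (LIPO −0.7–5, SIZE 150–500 g/mol, POLAR 20–130 Å²,
INSOLU −6–0, INSATU 0.25–1 Csp3 fraction, FLEX 0–9 rotatable bonds).

Two caveats: reference logP values of this kind are typically multi-model
consensi, so the single Wildman–Crippen model is checked only within a
±1.5 sanity band; and the provenance of reference logS values is generally
model-specific, so ESOL is reported as-is rather than matched.

## Binding isotherm

The default model is the ligand-excess 1:1 hyperbola
`s(c) = s_u + (s_b − s_u)·c/(c + Kd)` — appropriate when the titrated
compound vastly exceeds the fluorescent target; a ligand-depletion
quadratic form is available via `model="quadratic"`. Fitting is nonlinear
least squares on **log10 Kd** (far better conditioned than fitting Kd
directly at nanomolar scale), multistarted from 12 log-spaced guesses
across the measured range; the lowest-RSS converged fit wins. The Kd
standard error comes from the linearized covariance via the delta method.
Preconditions: ≥ 4 points, a non-flat curve; the titration should span the
transition (the default design, 18 two-fold dilutions from 200 µM, reaches
1.526 nM and covers any Kd from low-nanomolar to mid-micromolar).

## Synthetic benchmark: what it emulates and what it does not

The toy receptor is a pseudo-atom shell (one atom per residue) with one
concave spherical pocket open to one side; the two lining residues at the
mouth rim are tagged LYS 76/81 to emulate a degradation site. Pockets wider
than 7 Å carry a central knob so that every pocket admits a shell-shaped
ligand of one specific radius: the cognate ligand sits 3.5 Å (mid contact
shell) from both wall and knob, while a one-size-class (1 Å) mismatch
drives it into clash distance of one of them. This keys
receptor–ligand complementarity in both directions — a smaller ligand hits
the knob, a larger one the wall — which is what makes randomly re-paired
complexes genuinely negative.

The benchmark uses 4 training and 4 test receptors cycling through pocket
radii {7, 8, 9, 10} Å with 3 molded cognate ligands each (12 positives +
12 balanced negatives per split; test receptors are freshly generated and
never appear in training), one screen receptor (8 Å pocket) with a planted
molded binder, and 99 decoys — random chain/ring drug-like molecules
(8–24 heavy atoms, ≥ 80 % Lipinski-compliant) assembled atom-by-atom with
seeded valence-respecting growth. A master seed spawns per-component child
seeds through `numpy.random.SeedSequence`, so adding fixtures never
perturbs existing ones and every artifact regenerates byte-identically.

Desk-scale problem sizes used throughout the tests: 6 orientations ×
~120 grid points per conformer, 2 conformers per decoy, 500-tree forests;
a full benchmark run (generation, training, held-out evaluation, 100-way
screen) takes tens of seconds per master seed.

What passing these tests shows: every stage is wired correctly, the
geometry kernels match brute-force enumeration, the classifier learns a
real complementarity signal from docking-derived features, and the
end-to-end screen enriches a planted binder under controlled conditions.
What it does not show: performance on real proteins and chemistry. The toy
receptors have no side chains, electrostatics, solvation or flexibility;
the decoys are topologically simple; and the complementarity signal is
far cleaner than experimental binding data. The synthetic benchmark is a
correctness and sensitivity harness, not a claim of real-world enrichment.

## Numerical and design choices

* Clash tolerance 0.4 Å (crystallographic convention); Bondi radii table in
  `config.py`; atoms missing from tables fall back to carbon-like values.
* Site centroid = pooled mean over all atoms of the named residues;
  default site radius 8 Å for the degradation site, 3 Å for the docking
  sampling sphere (the pocket-center region where ligand centroids are
  physically plausible).
* Pose RMSD without superposition; conformer RMSD with superposition.
* Greedy clustering and pruning are stable-sorted, so ties resolve
  deterministically.
* Degenerate inputs raise typed errors (`PDBFormatError`, `StructureError`,
  `FixtureError`, `FitError`, `SchemaError`, `EmbeddingError`) naming the
  offending record, residue or parameter.
* All randomness flows through explicit integer seeds; nothing reads global
  RNG state.

## Known limitations

* The docking score has no electrostatics, desolvation or directional
  H-bond term; H-bonding enters only as a distance-based feature.
* Side-chain rebuilds use a single rotamer and ideal geometry; clashes
  introduced by a rebuilt rotamer are not resolved.
* The conformer force field has no torsional or electrostatic terms.
* The forest is target-agnostic (one global model), matching a
  train-once-score-library design; per-target fine-tuning is out of scope.
* The quadratic binding model assumes a known target concentration; Hill
  cooperativity and kinetic (association/dissociation) analyses are out of
  scope.
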