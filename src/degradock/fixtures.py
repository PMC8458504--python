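"""Deterministic synthetic fixtures: toy receptors, cognate complexes, decoys.

Every stage of the screen is testable without downloads.  A toy receptor is a
pseudo-atom (one atom per residue) shell with a single concave pocket; two
rim residues are tagged as lysines emulating a ubiquitylation degradation
site.  Cognate ligands are synthetic atom-cloud blobs molded to their
pocket's size so that the cognate gap falls mid contact shell; re-pairing a
ligand with a different-sized pocket destroys that complementarity, which is
what the binder classifier learns to detect.  Decoy libraries are random
chain-like drug-like molecules assembled atom-by-atom.

Seeding: a master seed spawns per-component child seeds through
``numpy.random.SeedSequence`` so adding fixtures never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from rdkit import Chem

from .conformers import Conformer
from .docking import Pose, ReceptorContext, dock_ligand, score_pose
from .geometry import fibonacci_sphere, quaternion_to_matrix, random_unit_quaternions
from .structure import ProteinStructure, SiteDefinition, define_site

#: gap between a cognate ligand's surface and the pocket wall (and knob), mid
#: contact shell
COGNATE_GAP = 3.5

#: wall-to-knob separation of every pocket; the cognate ligand shell sits
#: midway, COGNATE_GAP from both surfaces
ANNULUS_WIDTH = 2 * COGNATE_GAP

#: pocket (cavity) radii cycled over benchmark receptors; 1 A spacing
#: guarantees that any deranged pairing is at least one size class off, which
#: produces clashes against either the knob (pocket too small a class) or the
#: wall (too large)
POCKET_RADII = (7.0, 8.0, 9.0, 10.0)

SITE_RESSEQ = (76, 81)


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


def child_seed(master_seed: int, *ids: int) -> int:
    """Stable, collision-resistant child seed below 2**31."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(i) for i in ids))
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


@dataclass
class BenchmarkSpec:
    """Study conditions of the synthetic screen benchmark."""

    n_train_receptors: int = 4
    n_test_receptors: int = 4
    n_cognate_ligands: int = 3       # per receptor
    n_decoys: int = 99
    screen_pocket_radius: float = 8.0
    shell_radius_pad: float = 4.0
    noise_sigma: float = 0.0
    n_orientations: int = 6
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train_receptors, self.n_test_receptors,
               self.n_cognate_ligands, self.n_decoys) < 1:
            raise FixtureError("all benchmark counts must be >= 1")


# ---------------------------------------------------------------------------
# Toy receptor
# ---------------------------------------------------------------------------

@dataclass
class ToyReceptor:
    """Synthetic pseudo-atom receptor with one concave pocket."""

    structure: ProteinStructure
    pocket_center: np.ndarray
    pocket_radius: float
    site_residues: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", s) for s in SITE_RESSEQ])

    def docking_site(self, radius: float = 3.0) -> SiteDefinition:
        """Sampling site centred on the pocket (grid extent = radius)."""
        return SiteDefinition(residues=list(self.site_residues),
                              centroid=self.pocket_center.copy(),
                              radius=float(radius))

    def degradation_site(self, radius: float = 8.0) -> SiteDefinition:
        return define_site(self.structure, self.site_residues, radius)


def _sphere_points(radius: float, spacing: float, rng: np.random.Generator,
                   cone_cos: float) -> np.ndarray:
    """Points on a sphere (seeded random orientation), opening cone removed."""
    n = max(8, int(4.0 * np.pi * radius * radius / (spacing * spacing)))
    pts = fibonacci_sphere(n)
    R = quaternion_to_matrix(random_unit_quaternions(1, rng)[0])
    pts = pts @ R.T
    keep = pts[:, 2] < cone_cos  # remove the cap around +z (pocket mouth)
    return pts[keep] * radius


def make_toy_receptor(pocket_radius: float = 7.5, seed: int = 0,
                      noise_sigma: float = 0.0,
                      shell_radius_pad: float = 4.0) -> ToyReceptor:
    """Pseudo-protein shell with a concave keyed pocket and two site residues.

    The pocket is a spherical cavity lining centred at the origin and open
    toward +z.  Pockets wider than ANNULUS_WIDTH carry a central knob whose
    radius keeps the wall-to-knob gap constant, so each pocket size admits a
    shell ligand of one specific radius; a sparse outer layer provides bulk.
    The two lining residues closest to the mouth rim are tagged LYS 76 and
    LYS 81.  Deterministic for a fixed seed; ``noise_sigma`` jitters every
    pseudo-atom.
    """
    if pocket_radius < 2.0:
        raise FixtureError("pocket radius must be at least 2 A")
    if shell_radius_pad <= 0:
        raise FixtureError("outer shell must lie outside the pocket lining")
    rng = np.random.default_rng(seed)
    lining = _sphere_points(pocket_radius, 3.0, rng, cone_cos=np.cos(np.deg2rad(55)))
    parts = [lining]
    knob_radius = pocket_radius - ANNULUS_WIDTH
    if knob_radius > -0.5:
        parts.append(np.zeros((1, 3)))  # knob centre
        if knob_radius >= 0.7:
            n_knob = max(6, int(4.0 * np.pi * knob_radius ** 2 / (1.7 * 1.7)))
            knob = fibonacci_sphere(n_knob) * knob_radius
            R = quaternion_to_matrix(random_unit_quaternions(1, rng)[0])
            parts.append(knob @ R.T)
    outer = _sphere_points(pocket_radius + shell_radius_pad, 5.0, rng,
                           cone_cos=np.cos(np.deg2rad(70)))
    parts.append(outer)
    coords = np.vstack(parts)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    # seeded element pattern: mostly carbon with polar sprinkling
    elements = rng.choice(["C", "C", "C", "C", "N", "O"], size=len(coords))

    # two rim (highest-z) lining atoms become the degradation-site lysines
    rim_order = np.argsort(-lining[:, 2])
    site_idx = {int(rim_order[0]), int(rim_order[1])}

    st = gemmi.Structure()
    st.name = f"toy_receptor_seed{seed}"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    seq = 1
    site_ids = iter(SITE_RESSEQ)
    for i, (xyz, el) in enumerate(zip(coords, elements)):
        is_site = i in site_idx
        res = gemmi.Residue()
        res.name = "LYS" if is_site else "GLY"
        if is_site:
            res.seqid = gemmi.SeqId(str(next(site_ids)))
        else:
            while seq in SITE_RESSEQ:
                seq += 1
            res.seqid = gemmi.SeqId(str(seq))
            seq += 1
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element(str(el))
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return ToyReceptor(structure=st, pocket_center=np.zeros(3),
                       pocket_radius=float(pocket_radius))


# ---------------------------------------------------------------------------
# Cognate ligands and planting
# ---------------------------------------------------------------------------

def make_cognate_ligand(pocket_radius: float, seed: int = 0,
                        name: str = "cognate") -> Conformer:
    """Synthetic ligand molded to a keyed pocket (atom cloud, no bond graph).

    A spherical shell of radius pocket_radius - COGNATE_GAP: centred in its
    cognate pocket it sits COGNATE_GAP from both wall and knob (mid contact
    shell on both sides), while a one-size-class mismatch drives it into
    clash distance of one of them.  Pockets without a knob get a compact
    ligand (centre atom plus small shell).
    """
    r_lig = pocket_radius - COGNATE_GAP
    if r_lig < 0.2:
        raise FixtureError(f"pocket radius {pocket_radius} too small for a ligand")
    rng = np.random.default_rng(seed)
    pts = []
    hollow = pocket_radius - ANNULUS_WIDTH > -0.5  # pocket has a knob
    if not hollow:
        pts.append(np.zeros(3))
    if r_lig >= 0.7:
        n_shell = max(4, int(4.0 * np.pi * r_lig * r_lig / (1.8 * 1.8)))
        shell = fibonacci_sphere(min(n_shell, 40)) * r_lig
        R = quaternion_to_matrix(random_unit_quaternions(1, rng)[0])
        pts.extend(shell @ R.T)
    coords = np.array(pts) + rng.normal(0.0, 0.1, (len(pts), 3))
    elements = [str(e) for e in
                rng.choice(["C", "C", "C", "N", "O"], size=len(coords))]
    return Conformer(elements=elements, coords=coords, energy=0.0,
                     mol=None, name=name)


def plant_cognate_ligand(receptor: ToyReceptor, ligand: Conformer,
                         seed: int = 0, min_contacts: int = 5,
                         max_tries: int = 64) -> Pose:
    """Place a ligand in the pocket with >= min_contacts and zero clashes.

    Seeded rotations (plus small centre jitters) are tried until the
    constraint holds; the best-contact placement wins ties.
    """
    rng = np.random.default_rng(seed)
    context = ReceptorContext.build(receptor.structure, receptor.docking_site())
    centered = ligand.centered_coords()
    best: Pose | None = None
    for trial in range(max_tries):
        q = random_unit_quaternions(1, rng)[0]
        jitter = rng.normal(0.0, 0.3, 3) if trial else np.zeros(3)
        t = receptor.pocket_center + jitter
        coords = centered @ quaternion_to_matrix(q).T + t
        pose = score_pose(context, Pose(conformer=ligand, quaternion=q,
                                        translation=t, coords=coords))
        if pose.clashes == 0 and pose.contacts >= min_contacts:
            if best is None or pose.score > best.score:
                best = pose
            if trial >= 8 and best is not None:
                break
    if best is None:
        raise FixtureError(
            f"could not plant ligand {ligand.name!r} "
            f"(pocket {receptor.pocket_radius} A) within {max_tries} tries")
    return best


# ---------------------------------------------------------------------------
# Decoy library
# ---------------------------------------------------------------------------

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_molecule(rng: np.random.Generator) -> Chem.Mol | None:
    rw = Chem.RWMol()
    n_atoms = int(rng.integers(8, 18))
    elems = rng.choice(["C", "C", "C", "C", "C", "C", "N", "O"], size=n_atoms)
    idx0 = rw.AddAtom(Chem.Atom(str(elems[0])))
    open_valence = {idx0: _MAX_VALENCE[str(elems[0])]}
    for el in elems[1:]:
        el = str(el)
        hosts = [i for i, v in open_valence.items() if v >= 1]
        if not hosts:
            break
        host = hosts[int(rng.integers(len(hosts)))]
        new = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(host, new, Chem.BondType.SINGLE)
        open_valence[host] -= 1
        open_valence[new] = _MAX_VALENCE[el] - 1
    # sprinkle in up to two phenyl rings for aromatic variety
    for _ in range(int(rng.integers(0, 3))):
        hosts = [i for i, v in open_valence.items()
                 if v >= 1 and rw.GetAtomWithIdx(i).GetSymbol() == "C"]
        if not hosts:
            break
        host = hosts[int(rng.integers(len(hosts)))]
        ring = [rw.AddAtom(Chem.Atom("C")) for _ in range(6)]
        for k in range(6):
            rw.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
            rw.GetAtomWithIdx(ring[k]).SetIsAromatic(True)
        rw.AddBond(host, ring[0], Chem.BondType.SINGLE)
        open_valence[host] -= 1
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def make_decoy_library(n: int, seed: int = 0) -> list[Chem.Mol]:
    """n random valid drug-like molecules (chain/ring assembly, seeded)."""
    if n < 1:
        raise FixtureError("n must be >= 1")
    mols: list[Chem.Mol] = []
    attempt = 0
    while len(mols) < n:
        rng = np.random.default_rng(child_seed(seed, 17, attempt))
        attempt += 1
        mol = _random_molecule(rng)
        if mol is None:
            continue
        mol.SetProp("_Name", f"decoy_{len(mols):04d}")
        mols.append(mol)
        if attempt > 50 * n:
            raise FixtureError("decoy generation stalled")
    return mols


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------

@dataclass
class CognateComplex:
    """A receptor with its molded ligand and the planted reference pose."""

    receptor: ToyReceptor
    ligand: Conformer
    planted: Pose


@dataclass
class ScreenBenchmark:
    """Labeled train/test complexes plus a decoy screen with a planted binder."""

    spec: BenchmarkSpec
    train_complexes: list[CognateComplex]
    test_complexes: list[CognateComplex]
    screen_receptor: ToyReceptor
    planted_ligand: Conformer
    decoys: list[Chem.Mol]


def _make_complexes(spec: BenchmarkSpec, split_id: int, n_receptors: int
                    ) -> list[CognateComplex]:
    out = []
    for r in range(n_receptors):
        radius = POCKET_RADII[r % len(POCKET_RADII)]
        receptor = make_toy_receptor(
            pocket_radius=radius,
            seed=child_seed(spec.master_seed, split_id, r),
            noise_sigma=spec.noise_sigma,
            shell_radius_pad=spec.shell_radius_pad)
        for l in range(spec.n_cognate_ligands):
            lig = make_cognate_ligand(
                radius, seed=child_seed(spec.master_seed, split_id, r, 100 + l),
                name=f"cognate_s{split_id}_r{r}_l{l}")
            planted = plant_cognate_ligand(
                receptor, lig, seed=child_seed(spec.master_seed, split_id, r, 200 + l))
            out.append(CognateComplex(receptor=receptor, ligand=lig, planted=planted))
    return out


def make_screen_benchmark(spec: BenchmarkSpec) -> ScreenBenchmark:
    """Assemble the full labeled benchmark from a spec (seed-reproducible)."""
    train = _make_complexes(spec, 1, spec.n_train_receptors)
    test = _make_complexes(spec, 2, spec.n_test_receptors)
    screen_receptor = make_toy_receptor(
        pocket_radius=spec.screen_pocket_radius,
        seed=child_seed(spec.master_seed, 3, 0),
        noise_sigma=spec.noise_sigma,
        shell_radius_pad=spec.shell_radius_pad)
    planted_ligand = make_cognate_ligand(
        spec.screen_pocket_radius, seed=child_seed(spec.master_seed, 3, 1),
        name="planted_binder")
    # the planting must be feasible; raises if not
    plant_cognate_ligand(screen_receptor, planted_ligand,
                         seed=child_seed(spec.master_seed, 3, 2))
    decoys = make_decoy_library(spec.n_decoys, seed=child_seed(spec.master_seed, 4))
    return ScreenBenchmark(spec=spec, train_complexes=train, test_complexes=test,
                           screen_receptor=screen_receptor,
                           planted_ligand=planted_ligand, decoys=decoys)


# ---------------------------------------------------------------------------
# Training pairs
# ---------------------------------------------------------------------------

def derange_receptors(n: int, cognate_of: list[int], rng: np.random.Generator,
                      n_receptors: int, max_tries: int = 2000) -> list[int]:
    """Assign each complex a non-cognate receptor index (seeded)."""
    if n_receptors < 2:
        raise FixtureError("derangement needs at least 2 distinct receptors")
    for _ in range(max_tries):
        perm = rng.permutation(n_receptors)
        assignment = [int(perm[cognate_of[i]]) for i in range(n)]
        if all(assignment[i] != cognate_of[i] for i in range(n)):
            return assignment
    raise FixtureError("no derangement found")


def build_training_set(complexes: list[CognateComplex], seed: int = 0,
                       n_orientations: int = 8,
                       site_radius: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Features and labels from cognate (redocked) and deranged pairings.

    Positives are the best redocked pose of each cognate pair; negatives are
    the best pose of the same ligand docked into a deranged (non-cognate)
    receptor.  Class balance is exact.
    """
    from .features import featurize_pose

    receptors: list[ToyReceptor] = []
    cognate_of: list[int] = []
    for cx in complexes:
        try:
            idx = next(i for i, r in enumerate(receptors) if r is cx.receptor)
        except StopIteration:
            receptors.append(cx.receptor)
            idx = len(receptors) - 1
        cognate_of.append(idx)
    if len(receptors) < 2 or len(complexes) < 2:
        raise FixtureError("need >= 2 distinct receptors and ligands")

    contexts = [ReceptorContext.build(r.structure, r.docking_site(site_radius))
                for r in receptors]
    rng = np.random.default_rng(seed)
    negative_receptor = derange_receptors(len(complexes), cognate_of, rng,
                                          len(receptors))
    X, y = [], []
    for i, cx in enumerate(complexes):
        pos_result = dock_ligand(contexts[cognate_of[i]], [cx.ligand],
                                 n_orientations=n_orientations,
                                 seed=child_seed(seed, 5, i))
        X.append(featurize_pose(contexts[cognate_of[i]], pos_result.best_pose))
        y.append(1)
        neg_ctx = contexts[negative_receptor[i]]
        neg_result = dock_ligand(neg_ctx, [cx.ligand],
                                 n_orientations=n_orientations,
                                 seed=child_seed(seed, 6, i))
        X.append(featurize_pose(neg_ctx, neg_result.best_pose))
        y.append(0)
    return np.array(X), np.array(y)
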