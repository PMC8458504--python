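"""End-to-end screen orchestration.

``run_screen`` executes prep -> conformers -> docking -> featurization ->
classification -> site filter -> ranking -> descriptors for a ligand library
against one receptor, producing a :class:`ScreenReport` with per-candidate
verdicts, provenance (config hash, seed, stage log) and serializable output.
``run_benchmark_screen`` wires the synthetic benchmark through the same path:
it trains the binder classifier on the benchmark's cognate/deranged pairs and
screens the planted binder among decoys.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import config
from .conformers import Conformer, EmbeddingError, embed_conformers
from .docking import ReceptorContext, dock_ligand
from .features import featurize_pose
from .fixtures import (BenchmarkSpec, ScreenBenchmark, build_training_set,
                       child_seed, make_screen_benchmark)
from .forest import TrainedForest, train_forest
from .molecule import descriptor_panel
from .sitefilter import (CandidateVerdict, apply_site_filter,
                         interface_clash_check, rank_candidates, report_tsv)
from .structure import ProteinStructure, SiteDefinition, min_site_distance


@dataclass
class ScreenConfig:
    """Effective parameters of one screen run (defaults are the pinned ones)."""

    max_conformers: int = config.MAX_CONFORMERS
    n_orientations: int = 8
    cluster_rmsd: float = config.POSE_CLUSTER_RMSD
    n_trees: int = config.N_TREES
    site_cutoff: float = config.SITE_CUTOFF
    docking_site_radius: float = 3.0
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ScreenReport:
    """Ranked verdicts plus provenance for one screen run."""

    verdicts: list[CandidateVerdict]
    config_hash: str
    seed: int
    n_screened: int
    n_skipped: int
    log: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def rank_of(self, molecule_id: str) -> int | None:
        for v in self.verdicts:
            if v.molecule_id == molecule_id:
                return v.rank
        return None

    def to_json(self) -> str:
        # wall-clock timings are provenance, not results: they live in a
        # sidecar so that identical config + seeds give byte-identical reports
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_screened": self.n_screened,
            "n_skipped": self.n_skipped,
            "log": self.log,
            "candidates": [v.to_dict() for v in self.verdicts],
        }, sort_keys=True, default=_json_default)

    def write(self, out_dir, overwrite: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        existing = out / "screen_report.json"
        if existing.exists() and not overwrite:
            prior = json.loads(existing.read_text()).get("config_hash")
            if prior != self.config_hash:
                raise FileExistsError(
                    f"{existing} holds a report for config {prior}; refusing "
                    f"to overwrite with config {self.config_hash} "
                    f"(pass overwrite=True)")
        (out / "screen_report.json").write_text(self.to_json())
        (out / "timings.json").write_text(
            json.dumps({k: round(v, 3) for k, v in self.timings.items()}))
        with open(out / "screen_report.tsv", "w") as fh:
            report_tsv(self.verdicts, fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"unserializable {type(obj)}")


def _ligand_conformers(entry, cfg: ScreenConfig, seed: int) -> tuple[str, list[Conformer]]:
    """Accept either a prepared Conformer (pseudo-ligand) or an RDKit Mol."""
    if isinstance(entry, Conformer):
        return entry.name, [entry]
    mol: Chem.Mol = entry
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"
    confs = embed_conformers(mol, max_n=cfg.max_conformers, seed=seed)
    return name, confs


def run_screen(structure: ProteinStructure, docking_site: SiteDefinition,
               degradation_site: SiteDefinition, ligands,
               classifier: TrainedForest, cfg: ScreenConfig | None = None,
               interface_coords=None, interface_elements=None) -> ScreenReport:
    """Screen a ligand library against one receptor.

    ``ligands`` is a list of RDKit molecules and/or prepared conformers.
    Every candidate appears exactly once in the report; per-molecule failures
    are logged and skipped without aborting the screen.
    """
    cfg = cfg or ScreenConfig()
    t0 = time.perf_counter()
    log: list[str] = []
    context = ReceptorContext.build(structure, docking_site)
    verdicts: list[CandidateVerdict] = []
    n_skipped = 0
    timings = {"dock": 0.0, "classify": 0.0}
    for idx, entry in enumerate(ligands):
        seed_i = child_seed(cfg.seed, 11, idx)
        try:
            name, confs = _ligand_conformers(entry, cfg, seed_i)
        except EmbeddingError as exc:
            log.append(f"skip\t{getattr(entry, 'name', idx)}\tembedding failure: {exc}")
            n_skipped += 1
            continue
        td = time.perf_counter()
        result = dock_ligand(context, confs, n_orientations=cfg.n_orientations,
                             seed=seed_i, rmsd_threshold=cfg.cluster_rmsd)
        timings["dock"] += time.perf_counter() - td
        best = result.best_pose
        if best is None:
            log.append(f"skip\t{name}\tno poses sampled")
            n_skipped += 1
            continue
        tc = time.perf_counter()
        vec = featurize_pose(context, best)
        score = classifier.classify(vec)
        timings["classify"] += time.perf_counter() - tc
        dist = min_site_distance(best.coords, structure, degradation_site)
        clashes = 0
        if interface_coords is not None and len(interface_coords):
            clashes = interface_clash_check(best.coords, best.conformer.elements,
                                            interface_coords, interface_elements)
        desc = None
        if isinstance(entry, Chem.Mol):
            desc = descriptor_panel(entry)
        verdicts.append(CandidateVerdict(
            molecule_id=name, classifier_score=float(score),
            min_site_distance=float(dist), interface_clashes=clashes,
            contacts=int(best.contacts or 0), descriptors=desc))
    if verdicts:
        apply_site_filter(verdicts, cfg.site_cutoff)
        for v in verdicts:
            if not v.site_pass:
                log.append(f"discard\t{v.molecule_id}\t>{cfg.site_cutoff:g} A site filter")
        verdicts = rank_candidates(verdicts)
    else:
        log.append("warning\tempty library: report has 0 candidates")
    timings["total"] = time.perf_counter() - t0
    return ScreenReport(verdicts=verdicts, config_hash=cfg.content_hash(),
                        seed=cfg.seed, n_screened=len(verdicts),
                        n_skipped=n_skipped, log=log, timings=timings)


# ---------------------------------------------------------------------------
# Benchmark wiring
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkOutcome:
    """Joined result of training, held-out evaluation and the decoy screen."""

    report: ScreenReport
    classifier: TrainedForest
    planted_rank: int | None
    planted_passes_filter: bool
    holdout_auc: float
    benchmark: ScreenBenchmark


def _auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count half)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def run_benchmark_screen(master_seed: int = 0,
                         spec: BenchmarkSpec | None = None,
                         cfg: ScreenConfig | None = None) -> BenchmarkOutcome:
    """Full synthetic-benchmark exercise for one master seed.

    Builds the benchmark, trains the binder forest on the training split,
    measures held-out AUC on the disjoint test split, then screens the
    planted binder among the decoys through :func:`run_screen`.
    """
    spec = spec or BenchmarkSpec(master_seed=master_seed)
    if spec.master_seed != master_seed:
        spec.master_seed = master_seed
    cfg = cfg or ScreenConfig(max_conformers=2, n_orientations=6, seed=master_seed)
    bench = make_screen_benchmark(spec)

    X_train, y_train = build_training_set(
        bench.train_complexes, seed=child_seed(master_seed, 21),
        n_orientations=spec.n_orientations,
        site_radius=cfg.docking_site_radius)
    classifier = train_forest(X_train, y_train, n_trees=cfg.n_trees,
                              seed=child_seed(master_seed, 22))

    X_test, y_test = build_training_set(
        bench.test_complexes, seed=child_seed(master_seed, 23),
        n_orientations=spec.n_orientations,
        site_radius=cfg.docking_site_radius)
    scores = classifier.classify_many(X_test)
    auc = _auc(scores[y_test == 1], scores[y_test == 0])

    receptor = bench.screen_receptor
    report = run_screen(
        receptor.structure,
        receptor.docking_site(cfg.docking_site_radius),
        receptor.degradation_site(),
        [bench.planted_ligand] + list(bench.decoys),
        classifier, cfg)
    planted_rank = report.rank_of(bench.planted_ligand.name)
    planted_pass = any(v.site_pass and v.molecule_id == bench.planted_ligand.name
                       for v in report.verdicts)
    return BenchmarkOutcome(report=report, classifier=classifier,
                            planted_rank=planted_rank,
                            planted_passes_filter=planted_pass,
                            holdout_auc=auc, benchmark=bench)
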