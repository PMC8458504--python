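"""Post-classification candidate verification and ranking.

Candidates are kept when the best docking pose lies within the
degradation-site proximity cutoff (inclusive at the default 5.0 A), checked
against chaperone-interface coordinates for steric clashes, and ranked by
classifier score with deterministic tie-breaking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import config
from .molecule import DescriptorSet
from .structure import find_clashes


@dataclass
class CandidateVerdict:
    """Screen outcome for one molecule."""

    molecule_id: str
    classifier_score: float
    min_site_distance: float
    site_pass: bool = False
    interface_clashes: int = 0
    contacts: int = 0
    rank: int | None = None
    descriptors: DescriptorSet | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def apply_site_filter(verdicts: list[CandidateVerdict],
                      cutoff: float = config.SITE_CUTOFF) -> list[CandidateVerdict]:
    """Set pass flags: pass iff min site distance <= cutoff (inclusive).

    Failing candidates are retained with the flag false and an explanatory
    note.  Raising the cutoff can only increase the number of passers.
    """
    for v in verdicts:
        v.site_pass = v.min_site_distance <= cutoff
        if not v.site_pass:
            v.notes.append(
                f"discarded: pose {v.min_site_distance:.2f} A from degradation "
                f"site (> {cutoff:g} A)")
    return verdicts


def interface_clash_check(pose_coords, pose_elements, interface_coords,
                          interface_elements=None,
                          tolerance: float = config.CLASH_TOLERANCE) -> int:
    """Number of vdW clashes between a pose and chaperone-interface atoms."""
    interface_coords = np.asarray(interface_coords, dtype=float)
    if interface_coords.size == 0:
        raise ValueError("interface coordinate set is empty")
    pairs = find_clashes(pose_coords, interface_coords, tolerance,
                         elements_a=pose_elements, elements_b=interface_elements)
    return len(pairs)


def rank_candidates(verdicts: list[CandidateVerdict]) -> list[CandidateVerdict]:
    """Order passing candidates by classifier score (desc).

    Ties break by higher contact count, then lexicographic molecule id.
    Non-passing candidates follow, unranked, in the same deterministic order.
    """
    if not verdicts:
        raise ValueError("no candidates to rank")
    key = lambda v: (-v.classifier_score, -v.contacts, v.molecule_id)
    passing = sorted([v for v in verdicts if v.site_pass], key=key)
    failing = sorted([v for v in verdicts if not v.site_pass], key=key)
    for i, v in enumerate(passing, start=1):
        v.rank = i
    for v in failing:
        v.rank = None
    return passing + failing


def report_tsv(verdicts: list[CandidateVerdict], dest) -> None:
    cols = ("rank", "molecule_id", "classifier_score", "min_site_distance",
            "site_pass", "interface_clashes", "contacts")
    own = not hasattr(dest, "write")
    fh = open(dest, "w") if own else dest
    try:
        fh.write("\t".join(cols) + "\n")
        for v in verdicts:
            fh.write("\t".join([
                "" if v.rank is None else str(v.rank),
                v.molecule_id,
                f"{v.classifier_score:.4f}",
                f"{v.min_site_distance:.3f}",
                "pass" if v.site_pass else "fail",
                str(v.interface_clashes),
                str(v.contacts),
            ]) + "\n")
    finally:
        if own:
            fh.close()


def report_json(verdicts: list[CandidateVerdict]) -> str:
    return json.dumps([v.to_dict() for v in verdicts], sort_keys=True)
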