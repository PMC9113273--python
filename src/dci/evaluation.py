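"""Scoring predicted communities against an external domain annotation.

A structural domain counts as *recovered* when some community overlaps it
with Jaccard index at least a threshold (default 0.5) and that community is
not claimed by another domain with larger overlap.  Assignment is greedy by
descending Jaccard with deterministic tie-breaking, so each community can
recover at most one domain.

Also provides the C-alpha RMSD after optimal (Kabsch) superposition, used
to quantify how far apart two conformations of the same protein are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ParseError
from .structure_io import CalphaModel, ResidueKey

__all__ = [
    "DomainAnnotation",
    "DomainRecord",
    "domain_recovery",
    "parse_domain_table",
    "recovery_table",
    "superposed_rmsd",
    "paired_coordinates",
]


@dataclass
class DomainAnnotation:
    """Named, non-overlapping residue sets (e.g. structural domains)."""

    domains: list[tuple[str, frozenset[ResidueKey]]]

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for name, members in self.domains:
            overlap = seen & members
            if overlap:
                raise ValueError(
                    f"domain {name!r} overlaps a previous domain at "
                    f"{sorted(str(r) for r in overlap)[:3]}"
                )
            seen |= members


@dataclass
class DomainRecord:
    """Recovery outcome for one annotated domain."""

    name: str
    best_community: int | None  # 1-based community label, None if unmatched
    jaccard: float
    recovered: bool


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def domain_recovery(
    labels: Sequence[int],
    model: CalphaModel,
    annotation: DomainAnnotation,
    threshold: float = 0.5,
) -> tuple[list[DomainRecord], list[ResidueKey]]:
    """Match communities to annotated domains and flag recoveries.

    Annotated residues absent from the model are reported in the returned
    skipped list (second element) and excluded from the overlap
    computation; they are not fatal.

    Greedy assignment: all (domain, community) pairs are ranked by
    descending Jaccard (ties broken by annotation order, then community
    label); each domain and each community is used at most once.  A domain
    is recovered when its assigned pair's Jaccard >= threshold.
    """
    labels = list(labels)
    if len(labels) != len(model):
        raise ValueError("labels length does not match model size")
    model_keys = set(model.residues)

    community_members: dict[int, set[ResidueKey]] = {}
    for key, lab in zip(model.residues, labels):
        community_members.setdefault(int(lab), set()).add(key)
    communities = {lab: frozenset(m) for lab, m in community_members.items()}

    skipped: list[ResidueKey] = []
    trimmed: list[tuple[str, frozenset[ResidueKey]]] = []
    for name, members in annotation.domains:
        missing = members - model_keys
        skipped.extend(sorted(missing))
        trimmed.append((name, frozenset(members & model_keys)))

    candidates = []
    for d_idx, (name, members) in enumerate(trimmed):
        for lab, com in sorted(communities.items()):
            candidates.append((_jaccard(members, com), d_idx, lab))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    assigned_domain: dict[int, tuple[int, float]] = {}
    used_communities: set[int] = set()
    for jac, d_idx, lab in candidates:
        if d_idx in assigned_domain or lab in used_communities or jac == 0.0:
            continue
        assigned_domain[d_idx] = (lab, jac)
        used_communities.add(lab)

    records = []
    for d_idx, (name, _) in enumerate(trimmed):
        if d_idx in assigned_domain:
            lab, jac = assigned_domain[d_idx]
            records.append(DomainRecord(name, lab, jac, jac >= threshold))
        else:
            records.append(DomainRecord(name, None, 0.0, False))
    return records, skipped


def parse_domain_table(text: str) -> DomainAnnotation:
    """Parse a domain annotation TSV.

    Columns: domain_name, chain, start_resnum, end_resnum.  Multiple rows
    with the same name contribute to one domain.  A header line is
    detected and skipped.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    groups: dict[str, set[ResidueKey]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"domain table line {lineno}: expected 4 columns")
        if lineno == 1 and parts[0].lower() in ("domain", "domain_name", "name"):
            continue
        name = parts[0]
        try:
            start, end = int(parts[2]), int(parts[3])
        except ValueError as exc:
            raise ParseError(f"domain table line {lineno}: {exc}") from exc
        if name not in groups:
            groups[name] = set()
            order.append(name)
        for num in range(start, end + 1):
            groups[name].add(ResidueKey(parts[1], num))
    return DomainAnnotation([(name, frozenset(groups[name])) for name in order])


def recovery_table(records: list[DomainRecord]) -> str:
    lines = ["domain\tbest_community\tjaccard\trecovered"]
    for rec in records:
        com = "" if rec.best_community is None else str(rec.best_community)
        lines.append(f"{rec.name}\t{com}\t{rec.jaccard:.4f}\t{int(rec.recovered)}")
    return "\n".join(lines) + "\n"


def paired_coordinates(
    model_a: CalphaModel, model_b: CalphaModel
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the residues the two models share, in model_a order."""
    shared = [key for key in model_a.residues if key in model_b]
    if len(shared) < 3:
        raise ValueError("models share fewer than 3 residues")
    a = np.array([model_a.coordinates[model_a.index_of(k)] for k in shared])
    b = np.array([model_b.coordinates[model_b.index_of(k)] for k in shared])
    return a, b


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """C-alpha RMSD after optimal rigid-body (Kabsch) superposition."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need two equal-shape (N, 3) coordinate arrays")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rotation, _ = Rotation.align_vectors(a0, b0)
    diff = a0 - rotation.apply(b0)
    return float(np.sqrt((diff ** 2).sum() / len(a)))
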