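"""Indication mapping onto MeSH, identifier currency, and export aggregation.

Free-text therapeutic claims map onto MeSH descriptor headings restricted
to the disease-relevant branches of the MeSH tree — C (Diseases),
E (Analytical, Diagnostic and Therapeutic Techniques, and Equipment) and
F (Psychiatry and Psychology) — plus a small allowlist of specific terms
outside those branches.  Supplementary concept records (C-numbers) are
never mapped.  Where matched descriptors are related by tree ancestry,
only the most specific is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from drugcure.hierarchy import HierarchyLink, families
from drugcure.trials import DrugIndication, match_normalize

MESH_ID_RE = re.compile(r"^[DC]\d{6,9}$")

DEFAULT_ALLOWED_BRANCHES = frozenset({"C", "E", "F"})

#: Specific descriptors outside C/E/F that are still mappable
#: (e.g. "Skin Aging" under G13).
DEFAULT_ALLOWLIST = frozenset({"D015595"})


@dataclass
class MeshDescriptor:
    mesh_id: str  # D-number (descriptor) or C-number (SCR)
    heading: str
    tree_numbers: list[str] = field(default_factory=list)
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not MESH_ID_RE.match(self.mesh_id):
            raise ValueError(f"bad MeSH id {self.mesh_id!r}")

    @property
    def is_scr(self) -> bool:
        return self.mesh_id.startswith("C")

    @property
    def branches(self) -> set[str]:
        return {t[0] for t in self.tree_numbers}


@dataclass
class MechanismEntry:
    molregno: int
    mechanism_of_action: str
    action_type: str
    tid: Optional[int] = None  # NULL for nonmolecular mechanisms
    site_id: Optional[int] = None
    variant_id: Optional[int] = None  # -1 = undefined mutation
    comments: str = ""


def load_mesh_vocabulary(path) -> list[MeshDescriptor]:
    """Read a MeSH-like vocabulary file: tab-separated
    (mesh_id, heading, tree_numbers ';'-joined, synonyms '|'-joined)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            mesh_id, heading = fields[0], fields[1]
            trees = fields[2].split(";") if len(fields) > 2 and fields[2] else []
            syns = fields[3].split("|") if len(fields) > 3 and fields[3] else []
            out.append(MeshDescriptor(mesh_id, heading, trees, syns))
    return out


def tree_ancestor(a: MeshDescriptor, b: MeshDescriptor) -> bool:
    """True iff ``a`` is a tree ancestor of ``b``: some tree number of ``b``
    extends one of ``a``'s with a dot segment."""
    for ta in a.tree_numbers:
        for tb in b.tree_numbers:
            if tb.startswith(ta + "."):
                return True
    return False


def map_indication_text(
    text: str,
    mesh_vocabulary: Sequence[MeshDescriptor],
    allowed_branches: frozenset[str] = DEFAULT_ALLOWED_BRANCHES,
    allowlist: frozenset[str] = DEFAULT_ALLOWLIST,
) -> list[str]:
    """Map a free-text therapeutic claim to MeSH descriptor ids.

    Candidate descriptors are those whose heading or synonym occurs in the
    text (case-insensitive, punctuation-insensitive), restricted to allowed
    branches (or the allowlist) with SCR records excluded.  Among
    candidates related by tree ancestry only the most specific survives;
    unrelated equally-specific candidates are all kept.
    """
    norm = match_normalize(text)
    candidates: list[MeshDescriptor] = []
    for desc in mesh_vocabulary:
        if desc.is_scr:
            continue
        if desc.mesh_id not in allowlist and not (
            desc.branches & allowed_branches
        ):
            continue
        terms = [desc.heading] + desc.synonyms
        if any(match_normalize(t) in norm for t in terms if t):
            candidates.append(desc)
    keep = []
    for desc in candidates:
        if any(o is not desc and tree_ancestor(desc, o) for o in candidates):
            continue  # a matched descendant is more specific
        keep.append(desc.mesh_id)
    return sorted(keep)


def refresh_identifiers(
    rows: Sequence[DrugIndication],
    downgraded: Optional[dict[str, str]] = None,
    merged: Optional[dict[str, str]] = None,
    removed: Iterable[str] = (),
) -> tuple[list[DrugIndication], list[tuple[DrugIndication, str]]]:
    """Bring indication identifiers up to date with an ontology release.

    Downgraded identifiers are rewritten automatically; merged or removed
    identifiers need a curator's eye and are queued instead (with the
    suggested replacement where one exists).  Returns (updated rows,
    manual queue of (row, reason)).
    """
    downgraded = downgraded or {}
    merged = merged or {}
    removed = set(removed)
    queue: list[tuple[DrugIndication, str]] = []
    updated: list[DrugIndication] = []
    for row in rows:
        ids = [row.efo_id, row.mesh_id]
        queued = False
        for ident in ids:
            if ident in merged:
                queue.append((row, f"{ident} merged into {merged[ident]}"))
                queued = True
            elif ident in removed:
                queue.append((row, f"{ident} removed from ontology"))
                queued = True
        if queued:
            continue
        if row.efo_id in downgraded:
            row.efo_id = downgraded[row.efo_id]
        if row.mesh_id in downgraded:
            row.mesh_id = downgraded[row.mesh_id]
        updated.append(row)
    return updated, queue


@dataclass
class ExportRow:
    molregno: int
    mesh_id: str
    mechanism_of_action: str
    action_type: str
    max_phase_for_ind: float


def aggregate_for_export(
    links: dict[int, HierarchyLink],
    mechanisms: Sequence[MechanismEntry],
    indications: Sequence[DrugIndication],
) -> list[ExportRow]:
    """Aggregate mechanisms and indications upward for delivery.

    Annotation on a salt form propagates to both the salt and its parent;
    annotation on the parent alone stays on the parent.  Only compounds
    that end up with *both* a mechanism and an indication are exported.
    """
    mech_by_mol: dict[int, list[MechanismEntry]] = {}
    for m in mechanisms:
        mech_by_mol.setdefault(m.molregno, []).append(m)
    ind_by_mol: dict[int, list[DrugIndication]] = {}
    for i in indications:
        ind_by_mol.setdefault(i.molregno, []).append(i)

    def lift(by_mol: dict[int, list]) -> dict[int, list]:
        lifted: dict[int, list] = {k: list(v) for k, v in by_mol.items()}
        for parent, members in families(links).items():
            for member in members:
                if member == parent:
                    continue
                for item in by_mol.get(member, []):
                    lifted.setdefault(parent, [])
                    if item not in lifted[parent]:
                        lifted[parent].append(item)
        return lifted

    mech_lifted = lift(mech_by_mol)
    ind_lifted = lift(ind_by_mol)
    rows: list[ExportRow] = []
    for molregno in sorted(set(mech_lifted) & set(ind_lifted)):
        for mech in mech_lifted[molregno]:
            for ind in ind_lifted[molregno]:
                rows.append(
                    ExportRow(
                        molregno=molregno,
                        mesh_id=ind.mesh_id,
                        mechanism_of_action=mech.mechanism_of_action,
                        action_type=mech.action_type,
                        max_phase_for_ind=ind.max_phase_for_ind,
                    )
                )
    return rows
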