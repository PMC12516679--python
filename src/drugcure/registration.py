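"""Compound registration: standardize, match-or-register, provenance, conflicts.

An incoming compound with a structure is standardized and compared against
the registry by full 27-character standard InChIKey: an exact key match maps
to the existing molregno, otherwise a new molregno is registered.  A
structureless (biotherapeutic or name-only) compound merges only on an exact
normalized-name match; ambiguity or conflicting structural evidence goes to
a curation queue, never to an automatic merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

from drugcure import chem
from drugcure.core import (
    CompoundRecordEntry,
    MissingEntryError,
    MoleculeEntry,
    Registry,
    StructureRecord,
    SynonymEntry,
    SRC_NAMES,
    lookup_by_inchikey,
    lookup_by_name,
    normalize_name,
)

StructureParseError = chem.StructureParseError


@dataclass
class IncomingCompound:
    """One compound arriving from a source feed."""

    src_id: int
    pref_name: Optional[str] = None
    synonyms: list[SynonymEntry] = field(default_factory=list)
    structure_raw: Optional[str] = None  # molfile V2000 or SMILES
    bio_sequence: Optional[str] = None
    bio_component_type: Optional[str] = None
    source_name: str = ""
    extraction_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.structure_raw is None and not (self.pref_name or self.synonyms):
            raise ValueError("incoming compound needs a structure or a name")
        if not self.source_name:
            self.source_name = SRC_NAMES.get(self.src_id, str(self.src_id))


@dataclass
class RegistrationOutcome:
    decision: str  # matched_existing | registered_new | queued_for_review
    molregno: Optional[int] = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.decision in ("matched_existing", "registered_new"):
            assert self.molregno is not None
        if self.decision == "queued_for_review":
            assert self.reasons


@dataclass
class ConflictReport:
    kind: str  # name_shared_structure_differs | structure_shared_names_differ
    name: Optional[str]
    molregnos: tuple[int, ...]
    detail: str = ""


def standardize_structure(raw: str, penalty_checker=None) -> StructureRecord:
    """Standardize a raw molfile or SMILES into a :class:`StructureRecord`.

    Runs a checker (built-in simplified scorer by default: valence errors,
    kekulization failures, other sanitization warnings) and the standardizer
    (functional-group normalization), then generates the standardized
    molfile, canonical SMILES, standard InChI and standard InChIKey.  A
    penalty above 5 does not raise — the record is marked reviewable and
    still carries whatever identifiers could be generated.
    """
    mol = chem.parse_structure(raw, sanitize=False)
    penalty = (penalty_checker or chem.sanitize_penalty)(mol)
    mol = chem.safe_sanitize(mol)
    if penalty <= 5:
        mol = chem.cleanup(mol)
    molfile, smiles, std_inchi, key = chem.identifiers(mol)
    return StructureRecord(
        molfile=molfile,
        canonical_smiles=smiles,
        std_inchi=std_inchi,
        std_inchikey=key,
        penalty=penalty,
    )


def register_compound(registry: Registry, incoming: IncomingCompound) -> RegistrationOutcome:
    """Match an incoming compound to an existing molregno or register it new.

    With a structure, identity is decided by exact standard-InChIKey match.
    Without one (biotherapeutics, name-only sources), a unique exact
    normalized-name match merges; multiple matches, or a name match onto an
    entry that holds a structure (evidence the incoming record lacks), are
    queued for manual review.  Conflicts never raise.
    """
    if incoming.structure_raw is not None:
        try:
            structure = standardize_structure(incoming.structure_raw)
        except StructureParseError as exc:
            return RegistrationOutcome(
                decision="queued_for_review", reasons=[f"parse error: {exc}"]
            )
        if structure.std_inchikey:
            existing = lookup_by_inchikey(registry, structure.std_inchikey)
            if existing is not None:
                _merge_names(registry, existing, incoming)
                attach_source_record(
                    registry,
                    existing,
                    incoming.src_id,
                    incoming.source_name,
                    incoming.extraction_date,
                )
                return RegistrationOutcome("matched_existing", molregno=existing)
        molregno = registry.next_molregno()
        entry = MoleculeEntry(
            molregno=molregno,
            pref_name=incoming.pref_name,
            structure=structure,
        )
        registry.add_entry(entry)
        for syn in incoming.synonyms:
            registry.add_synonym(molregno, syn.name, syn.syn_type)
        attach_source_record(
            registry, molregno, incoming.src_id, incoming.source_name,
            incoming.extraction_date,
        )
        return RegistrationOutcome("registered_new", molregno=molregno)

    # structureless: exact-name path
    names = [incoming.pref_name] if incoming.pref_name else []
    names += [s.name for s in incoming.synonyms]
    matches: set[int] = set()
    for name in names:
        matches |= lookup_by_name(registry, name)
    if len(matches) > 1:
        return RegistrationOutcome(
            decision="queued_for_review",
            reasons=[f"name matches {len(matches)} existing compounds: "
                     f"{sorted(matches)}"],
        )
    if len(matches) == 1:
        molregno = next(iter(matches))
        entry = registry.get(molregno)
        if entry.structure is not None:
            # a structureless feed naming a structured compound is evidence
            # of a possible form mismatch (parent vs salt, biologic
            # generation) — curator decides
            return RegistrationOutcome(
                decision="queued_for_review",
                reasons=[
                    f"name matches structured compound {molregno}; "
                    "structureless record cannot confirm identity"
                ],
            )
        _merge_names(registry, molregno, incoming)
        attach_source_record(
            registry, molregno, incoming.src_id, incoming.source_name,
            incoming.extraction_date,
        )
        return RegistrationOutcome("matched_existing", molregno=molregno)

    molregno = registry.next_molregno()
    entry = MoleculeEntry(
        molregno=molregno,
        pref_name=incoming.pref_name,
        bio_sequence=incoming.bio_sequence,
        bio_component_type=incoming.bio_component_type,
    )
    registry.add_entry(entry)
    for syn in incoming.synonyms:
        registry.add_synonym(molregno, syn.name, syn.syn_type)
    attach_source_record(
        registry, molregno, incoming.src_id, incoming.source_name,
        incoming.extraction_date,
    )
    return RegistrationOutcome("registered_new", molregno=molregno)


def _merge_names(registry: Registry, molregno: int, incoming: IncomingCompound) -> None:
    entry = registry.get(molregno)
    if incoming.pref_name and not entry.pref_name:
        entry.pref_name = incoming.pref_name
        registry._index_name(incoming.pref_name, molregno)
    elif incoming.pref_name and normalize_name(incoming.pref_name) != normalize_name(
        entry.pref_name or ""
    ):
        registry.add_synonym(molregno, incoming.pref_name)
    for syn in incoming.synonyms:
        registry.add_synonym(molregno, syn.name, syn.syn_type)
    if incoming.bio_sequence and not entry.bio_sequence:
        entry.bio_sequence = incoming.bio_sequence
        entry.bio_component_type = incoming.bio_component_type


def attach_source_record(
    registry: Registry,
    molregno: int,
    src_id: int,
    source_name: str = "",
    extraction_date: Optional[date] = None,
) -> int:
    """Append a provenance row; identical (molregno, src, name) rows dedup."""
    if molregno not in registry:
        raise MissingEntryError(molregno)
    source_name = source_name or SRC_NAMES.get(src_id, str(src_id))
    for rec in registry.records:
        if (
            rec.molregno == molregno
            and rec.src_id == src_id
            and rec.source_name == source_name
        ):
            return rec.record_id
    rec = CompoundRecordEntry(
        record_id=registry.next_record_id(),
        molregno=molregno,
        src_id=src_id,
        source_name=source_name,
        extraction_date=extraction_date,
    )
    registry.records.append(rec)
    return rec.record_id


def remove_source_records(registry: Registry, molregno: int, src_id: int) -> int:
    """Source downgrade: delete all provenance rows for one (compound, source).

    Returns the number of rows removed.  Used when a compound drops out of a
    feed (e.g. delisted from the approved-products file).
    """
    if molregno not in registry:
        raise MissingEntryError(molregno)
    before = len(registry.records)
    registry.records = [
        r
        for r in registry.records
        if not (r.molregno == molregno and r.src_id == src_id)
    ]
    return before - len(registry.records)


def reconcile_conflicts(registry: Registry) -> list[ConflictReport]:
    """Report cross-source identity conflicts; pure report, no mutation.

    Two kinds are detected: the same (normalized) name attached to entries
    with different InChIKeys, and the same InChIKey family carrying
    inconsistent preferred names (possible only via legacy/manual edits,
    since the index forbids live duplicates).
    """
    reports: list[ConflictReport] = []
    name_to_ids: dict[str, set[int]] = {}
    for name, molregno in registry.iter_names():
        name_to_ids.setdefault(name, set()).add(molregno)
    for name, ids in sorted(name_to_ids.items()):
        if len(ids) < 2:
            continue
        keys = {
            registry.get(m).structure.std_inchikey
            for m in ids
            if registry.get(m).structure is not None
        }
        if len(keys) > 1:
            reports.append(
                ConflictReport(
                    kind="name_shared_structure_differs",
                    name=name,
                    molregnos=tuple(sorted(ids)),
                    detail=f"{len(keys)} distinct InChIKeys",
                )
            )
    # same connectivity (first InChIKey block), different preferred names
    block_to_ids: dict[str, set[int]] = {}
    for entry in registry:
        if entry.structure is not None and entry.structure.std_inchikey:
            block_to_ids.setdefault(
                entry.structure.std_inchikey[:14], set()
            ).add(entry.molregno)
    for block, ids in sorted(block_to_ids.items()):
        if len(ids) < 2:
            continue
        prefs = {
            normalize_name(registry.get(m).pref_name)
            for m in ids
            if registry.get(m).pref_name
        }
        if len(prefs) > 1:
            shared = set.intersection(
                *(
                    {n for n, mm in registry.iter_names() if mm == m}
                    for m in ids
                )
            )
            if not shared:
                reports.append(
                    ConflictReport(
                        kind="structure_shared_names_differ",
                        name=None,
                        molregnos=tuple(sorted(ids)),
                        detail=f"connectivity block {block}",
                    )
                )
    return reports
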