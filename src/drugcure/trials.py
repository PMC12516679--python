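"""Clinical-trials pipeline: filter trials, map interventions and conditions,
disentangle multi-drug/multi-condition trials, flag redundant conditions,
and derive drug–indication rows.

Mapping is deliberately conservative: only a curated-dictionary hit or an
exact normalized-name match is ever assigned automatically.  Substring
("partial") matches merely generate candidate lists for a manual review
queue — names shorter than four characters and blocklisted names (which
commonly mis-match as substrings) are excluded from candidate generation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

from drugcure.core import Registry, normalize_name
from drugcure.ontology import Ontology

NCT_RE = re.compile(r"^NCT\d+$")

VALID_PHASES = {
    "early_phase1",
    "phase1",
    "phase1_2",
    "phase2",
    "phase2_3",
    "phase3",
    "phase4",
    "not_applicable",
}

#: trial phase -> max_phase_for_ind contribution (phase4 handled separately)
PHASE_FOR_IND = {
    "early_phase1": 0.5,
    "phase1": 1.0,
    "phase1_2": 1.0,
    "phase2": 2.0,
    "phase2_3": 2.0,
    "phase3": 3.0,
    "phase4": 4.0,
}

ABSENT = "ABSENT"
NOT_DRUG = "NOT_DRUG"
NOT_SPECIFIED_DRUGS = "NOT_SPECIFIED_DRUGS"
NOT_CONDITION = "NOT_CONDITION"

_PUNCT_RE = re.compile(r"[^\w\s]")


def match_normalize(text: str) -> str:
    """Lowercase, punctuation-stripped, whitespace-collapsed matching form."""
    return re.sub(r"\s+", " ", _PUNCT_RE.sub(" ", normalize_name(text))).strip()


@dataclass
class TrialRecord:
    nct_id: str
    study_type: str  # interventional | observational | ...
    phase: str
    overall_status: str = ""
    intervention_names: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    last_update: Optional[date] = None

    def __post_init__(self) -> None:
        if not NCT_RE.match(self.nct_id):
            raise ValueError(f"bad trial id {self.nct_id!r}")


@dataclass
class InterventionMapping:
    nct_id: str
    intervention_name: str
    outcome: object  # molregno (int) | ABSENT | NOT_DRUG | NOT_SPECIFIED_DRUGS
    method: str = "exact_auto"  # exact_auto | dictionary | manual
    not_for_automatic_mapping: bool = False


@dataclass
class ConditionMapping:
    nct_id: str
    condition: str
    outcome: object  # term_id (str) | ABSENT | NOT_CONDITION
    method: str = "exact_auto"
    is_indication: int = 0  # 1 confirmed, 0 rejected; other codes opaque
    redundant: bool = False
    not_for_automatic_mapping: bool = False


@dataclass
class DrugIndication:
    molregno: int
    mesh_id: str
    efo_id: Optional[str]
    max_phase_for_ind: float
    nct_ids: list[str] = field(default_factory=list)


def parse_trial_feed(feed: str | list) -> list[TrialRecord]:
    """Parse a ClinicalTrials.gov API v2-style JSON feed (subset).

    Accepts the JSON text or the already-decoded list of study objects with
    protocolSection -> identificationModule / designModule /
    armsInterventionsModule / conditionsModule / statusModule.
    """
    studies = json.loads(feed) if isinstance(feed, str) else feed
    records = []
    for study in studies:
        proto = study.get("protocolSection", study)
        ident = proto.get("identificationModule", {})
        design = proto.get("designModule", {})
        arms = proto.get("armsInterventionsModule", {})
        cond = proto.get("conditionsModule", {})
        status = proto.get("statusModule", {})
        phases = design.get("phases", [])
        phase = _phase_code(phases)
        update = status.get("lastUpdatePostDateStruct", {}).get("date")
        records.append(
            TrialRecord(
                nct_id=ident.get("nctId", ""),
                study_type=str(design.get("studyType", "")).lower(),
                phase=phase,
                overall_status=status.get("overallStatus", ""),
                intervention_names=[
                    iv.get("name", "") for iv in arms.get("interventions", [])
                ],
                conditions=list(cond.get("conditions", [])),
                last_update=date.fromisoformat(update) if update else None,
            )
        )
    return records


def _phase_code(phases: Sequence[str]) -> str:
    mapped = []
    for p in phases:
        code = str(p).strip().lower().replace("early phase 1", "early_phase1")
        code = code.replace("phase ", "phase").replace("na", "not_applicable") \
            if code in ("na", "n/a") else code.replace("phase ", "phase")
        code = {
            "early_phase1": "early_phase1",
            "phase1": "phase1",
            "phase2": "phase2",
            "phase3": "phase3",
            "phase4": "phase4",
            "not_applicable": "not_applicable",
        }.get(code, code)
        mapped.append(code)
    if not mapped:
        return "not_applicable"
    if set(mapped) == {"phase1", "phase2"}:
        return "phase1_2"
    if set(mapped) == {"phase2", "phase3"}:
        return "phase2_3"
    return mapped[0]


def filter_trials(
    feed: Iterable[TrialRecord],
    window: Optional[tuple[date, date]] = None,
) -> list[TrialRecord]:
    """Keep interventional trials with an exact phase, updated in-window."""
    kept = []
    for t in feed:
        if t.study_type != "interventional":
            continue
        if t.phase == "not_applicable" or t.phase not in VALID_PHASES:
            continue
        if window is not None:
            if t.last_update is None or not (window[0] <= t.last_update <= window[1]):
                continue
        kept.append(t)
    return kept


def _candidates(
    text: str,
    names: Iterable[tuple[str, object]],
    blocklist: frozenset[str],
) -> list[tuple[str, object]]:
    """All dictionary names of length >= 4, not blocklisted, occurring as a
    substring of the normalized text."""
    norm = match_normalize(text)
    out = []
    seen = set()
    for name, target in names:
        n = match_normalize(name)
        if len(n) < 4 or n in blocklist:
            continue
        if n in norm and (n, target) not in seen:
            seen.add((n, target))
            out.append((n, target))
    return sorted(out, key=lambda x: (-len(x[0]), x[0], str(x[1])))


def map_intervention(
    nct_id: str,
    name: str,
    registry: Registry,
    dictionary: Optional[dict[str, object]] = None,
    blocklist: Iterable[str] = (),
) -> tuple[InterventionMapping, list[tuple[str, object]]]:
    """Map one intervention name to a molregno or a sentinel outcome.

    Stage 1: curated dictionary hit on the normalized name (reused unless
    the entry is marked not-for-automatic-mapping).  Stage 2: exact match
    against a pref_name or synonym.  Stage 3: no auto-assignment — return
    ABSENT plus substring-match candidates for manual resolution.
    """
    dictionary = dictionary or {}
    blockset = frozenset(match_normalize(b) for b in blocklist)
    norm = match_normalize(name)
    if norm in dictionary:
        entry = dictionary[norm]
        target, nfam = entry if isinstance(entry, tuple) else (entry, False)
        if not nfam:
            return (
                InterventionMapping(nct_id, name, target, method="dictionary"),
                [],
            )
    exact = {m for n, m in registry.iter_names() if match_normalize(n) == norm}
    if len(exact) == 1:
        return (
            InterventionMapping(nct_id, name, exact.pop(), method="exact_auto"),
            [],
        )
    cands = _candidates(name, registry.iter_names(), blockset)
    return InterventionMapping(nct_id, name, ABSENT, method="manual"), cands


def map_condition(
    nct_id: str,
    condition: str,
    ontology: Ontology,
    dictionary: Optional[dict[str, object]] = None,
    blocklist: Iterable[str] = (),
) -> tuple[ConditionMapping, list[tuple[str, object]]]:
    """Map one trial condition to an ontology term id or a sentinel.

    Same three-stage procedure as intervention mapping, over ontology term
    names and synonyms; the blocklist prevents known incorrect substring
    matches (e.g. a broad term inside a more specific condition string).
    """
    dictionary = dictionary or {}
    blockset = frozenset(match_normalize(b) for b in blocklist)
    norm = match_normalize(condition)
    if norm in dictionary:
        entry = dictionary[norm]
        target, nfam = entry if isinstance(entry, tuple) else (entry, False)
        if not nfam:
            return (
                ConditionMapping(nct_id, condition, target, method="dictionary"),
                [],
            )
    names = _ontology_names(ontology)
    exact = {t for n, t in names if match_normalize(n) == norm}
    if len(exact) == 1:
        return (
            ConditionMapping(nct_id, condition, exact.pop(), method="exact_auto"),
            [],
        )
    cands = _candidates(condition, names, blockset)
    return ConditionMapping(nct_id, condition, ABSENT, method="manual"), cands


def _ontology_names(ontology: Ontology) -> list[tuple[str, str]]:
    names = []
    for tid in ontology.graph.nodes:
        term = ontology.terms[tid]
        names.append((term.name, tid))
        for syn in term.synonyms:
            names.append((syn, tid))
    return names


def disentangle_trial(
    trial: TrialRecord,
    drug_mappings: Sequence[InterventionMapping],
    condition_mappings: Sequence[ConditionMapping],
    ontology: Ontology,
    threshold: float = 0.85,
) -> tuple[list[ConditionMapping], bool]:
    """Assign is_indication for one trial's mapped conditions.

    A single mapped condition applies to every mapped drug.  With multiple
    conditions, all of them are confirmed only when every pairwise semantic
    similarity reaches the threshold (the conditions then describe one
    disease); otherwise the trial is queued for manual category assignment
    and — until reviewed — is excluded from output.  Returns (updated
    condition mappings, queued_for_manual).
    """
    mapped_terms = [
        c for c in condition_mappings if isinstance(c.outcome, str) and c.outcome in ontology
    ]
    mapped_drugs = [d for d in drug_mappings if isinstance(d.outcome, int)]
    if not mapped_terms or not mapped_drugs:
        return list(condition_mappings), False
    if len(mapped_terms) == 1:
        mapped_terms[0].is_indication = 1
        return list(condition_mappings), False
    for i, a in enumerate(mapped_terms):
        for b in mapped_terms[i + 1 :]:
            if ontology.similarity(a.outcome, b.outcome) < threshold:
                return list(condition_mappings), True
    for c in mapped_terms:
        c.is_indication = 1
    return list(condition_mappings), False


def flag_redundant_conditions(
    condition_mappings: Sequence[ConditionMapping], ontology: Ontology
) -> list[ConditionMapping]:
    """Mark less-specific conditions of one trial as redundant.

    A mapped term is redundant iff another mapped term of the same trial is
    its strict transitive descendant — the deepest term(s) carry the signal.
    At least one term always stays non-redundant.
    """
    terms = [
        c for c in condition_mappings if isinstance(c.outcome, str) and c.outcome in ontology
    ]
    ids = {c.outcome for c in terms}
    for c in terms:
        others = ids - {c.outcome}
        c.redundant = any(ontology.is_descendant(o, c.outcome) for o in others)
    return list(condition_mappings)


def derive_indications(
    trials: Sequence[TrialRecord],
    intervention_mappings: Sequence[InterventionMapping],
    condition_mappings: Sequence[ConditionMapping],
    efo_to_mesh: dict[str, str],
    regulatory_approved_pairs: Iterable[tuple[int, str]] = (),
) -> list[DrugIndication]:
    """Turn confirmed trial mappings into drug–indication rows.

    Per (drug, condition, trial): the phase code maps onto
    max_phase_for_ind; a Phase 4 trial is kept only when the (drug, EFO
    condition) pair holds regulatory approval — a trial registry cannot
    certify approval for an unapproved indication.  EFO terms translate to
    MeSH; pairs with no MeSH equivalent are dropped.  Duplicates collapse
    to the maximum phase, accumulating trial references.
    """
    approved = set(regulatory_approved_pairs)
    by_trial_drugs: dict[str, list[int]] = {}
    for m in intervention_mappings:
        if isinstance(m.outcome, int):
            by_trial_drugs.setdefault(m.nct_id, []).append(m.outcome)
    by_trial_conds: dict[str, list[ConditionMapping]] = {}
    for c in condition_mappings:
        if isinstance(c.outcome, str) and c.is_indication == 1 and not c.redundant:
            by_trial_conds.setdefault(c.nct_id, []).append(c)

    rows: dict[tuple[int, str], DrugIndication] = {}
    for trial in trials:
        phase = PHASE_FOR_IND.get(trial.phase)
        if phase is None:
            continue
        for drug in by_trial_drugs.get(trial.nct_id, []):
            for cond in by_trial_conds.get(trial.nct_id, []):
                efo = cond.outcome
                if phase == 4.0 and (drug, efo) not in approved:
                    continue  # Phase 4 without regulatory approval: dropped
                mesh = efo_to_mesh.get(efo)
                if mesh is None:
                    continue  # no MeSH equivalent: pair not incorporated
                key = (drug, mesh)
                row = rows.get(key)
                if row is None:
                    rows[key] = DrugIndication(
                        molregno=drug,
                        mesh_id=mesh,
                        efo_id=efo,
                        max_phase_for_ind=phase,
                        nct_ids=[trial.nct_id],
                    )
                else:
                    row.max_phase_for_ind = max(row.max_phase_for_ind, phase)
                    if trial.nct_id not in row.nct_ids:
                        row.nct_ids.append(trial.nct_id)
    return sorted(rows.values(), key=lambda r: (r.molregno, r.mesh_id))
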