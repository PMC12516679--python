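"""Rule-based molecule-level annotations.

All the drug-property rules applied per drug form: preferred-name choice,
molecule type, inorganic/polymer flags, chirality, therapeutic flag,
maximum clinical phase, availability type, withdrawal eligibility, first
approval year, USAN year validation and USAN stem mapping.  Family-level
aggregation of the results lives in :mod:`drugcure.hierarchy`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from drugcure import chem
from drugcure.core import (
    SRC_ATC,
    SRC_EMA,
    SRC_FDA_NEW_DRUGS,
    SRC_FDA_ORANGE_BOOK,
    SRC_INN,
    SRC_USAN,
    SRC_WITHDRAWN,
    StructureRecord,
    normalize_name,
)

ORGANIC_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)

#: Trial-phase evidence -> max_phase contribution.
TRIAL_PHASE_EVIDENCE = {
    "phase3": 3.0,
    "phase2": 2.0,
    "phase2_3": 2.0,
    "phase1": 1.0,
    "phase1_2": 1.0,
    "early_phase1": 0.5,
}

_GREEK_SPELL = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
    "ε": "epsilon", "κ": "kappa", "λ": "lambda", "ω": "omega",
}

#: SMARTS substructure rules for biotherapeutic molecule types; a hit
#: assigns the category when it does not conflict with the name suffix.
DEFAULT_SUBSTRUCTURE_RULES: tuple[tuple[str, str], ...] = (
    # pyranose-pyranose glycosidic repeat
    ("oligosaccharide", "C1OC(CO)C(O)C(O)C1OC2OC(CO)C(O)C(O)C2"),
    # two phosphodiester-linked riboses
    ("oligonucleotide", "OP(=O)(O)OCC1OC(C(O)C1O)OP(=O)(O)O"),
)

POLYMER_NAME_KEYWORDS = ("polymer", "poly(", "polyethylene", "polyvinyl")
POLYMER_SMARTS = "COCCOCCOCCOC"  # PEG-like repeat unit


@dataclass
class ApprovalEvent:
    agency: str
    year: int
    region: str = ""
    human_use: bool = True
    molregno: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2100:
            raise ValueError(f"implausible approval year {self.year}")


@dataclass
class WithdrawalEvent:
    year: int
    region: str
    reason_text: str = ""
    all_doses: bool = False
    all_populations: bool = False
    all_indications: bool = False
    basis: str = "safety"  # safety | efficacy | drug_interaction_safety | suspended
    corroborated: bool = False
    warning_class: str = ""
    granular_efo: str = ""


# ---------------------------------------------------------------------------
# config loading


def _read_tsv(name: str, path=None) -> list[list[str]]:
    if path is None:
        text = (resources.files("drugcure") / "data" / name).read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_diagnostic_phrases(path=None) -> list[str]:
    return [row[0].strip().lower() for row in _read_tsv("diagnostic_phrases.tsv", path)]


def load_type_suffixes(path=None) -> dict[str, str]:
    return {row[0].strip().lower(): row[1].strip() for row in _read_tsv("type_suffixes.tsv", path)}


@dataclass
class UsanStem:
    stem: str
    kind: str  # prefix | infix | suffix
    definition: str

    @property
    def core(self) -> str:
        return self.stem.strip("-").lower()


def load_usan_stems(path=None) -> list[UsanStem]:
    return [UsanStem(r[0], r[1], r[2]) for r in _read_tsv("usan_stems.tsv", path)]


# ---------------------------------------------------------------------------
# preferred name


def choose_pref_name(
    sources: Sequence[tuple[str, str]], approved: bool
) -> str:
    """Choose the preferred name from per-source candidates.

    ``sources`` is a list of (source tag, name) pairs with tags like
    "FDA", "EMA", "USAN", "INN", "GSRS".  Approved drugs take the
    regulator's name; otherwise USAN is used first, then INN, then the
    fallback dictionary (GSRS-like) name.  Greek letters are written out
    in full in English.
    """
    if not sources:
        raise ValueError("no name sources supplied")
    by_src = {}
    for src, name in sources:
        by_src.setdefault(src.upper(), name)
    name = None
    if approved:
        for reg in ("FDA", "EMA", "FDA_ORANGE_BOOK", "FDA_NEW_DRUGS", "PMDA", "MHRA"):
            if reg in by_src:
                name = by_src[reg]
                break
    if name is None:
        for src in ("USAN", "INN", "GSRS"):
            if src in by_src:
                name = by_src[src]
                break
    if name is None:
        name = sources[0][1]
    for greek, latin in _GREEK_SPELL.items():
        name = name.replace(greek, latin).replace(greek.upper(), latin)
    return name


# ---------------------------------------------------------------------------
# molecule type and flags


def assign_molecule_type(
    name: Optional[str],
    structure: Optional[StructureRecord] = None,
    suffix_table: Optional[dict[str, str]] = None,
    substructure_rules: Iterable[tuple[str, str]] = DEFAULT_SUBSTRUCTURE_RULES,
) -> tuple[str, bool]:
    """Assign the molecule_type category; returns (category, needs_review).

    Name suffixes drive biotherapeutic categories (-mab antibody, -ase
    enzyme, ...); substructure patterns assign oligosaccharide /
    oligonucleotide for structured biologics.  When suffix and substructure
    evidence disagree the category is "unknown" and the compound is routed
    to review.  A structured compound with no biologic evidence defaults to
    "small molecule"; no evidence at all gives "unknown".
    """
    if suffix_table is None:
        suffix_table = load_type_suffixes()
    suffix_type: Optional[str] = None
    if name:
        stem_word = normalize_name(name).split()[0] if name.strip() else ""
        for suffix in sorted(suffix_table, key=len, reverse=True):
            if stem_word.endswith(suffix):
                suffix_type = suffix_table[suffix]
                break
    substructure_type: Optional[str] = None
    if structure is not None and structure.canonical_smiles:
        mol = Chem.MolFromSmiles(structure.canonical_smiles)
        if mol is not None:
            for category, smarts in substructure_rules:
                patt = Chem.MolFromSmarts(smarts)
                if patt is not None and mol.HasSubstructMatch(patt):
                    substructure_type = category
                    break
    if suffix_type and substructure_type and suffix_type != substructure_type:
        return "unknown", True
    if substructure_type:
        return substructure_type, False
    if suffix_type:
        return suffix_type, False
    if structure is not None:
        return "small molecule", False
    return "unknown", False


def compute_inorganic_flag(structure: StructureRecord) -> bool:
    """True iff no atom belongs to the common organic element set.

    The rule is applied literally to the element set {H, C, N, O, P, S, F,
    Cl, Br, I}; note that it classifies simple halide salts such as NaCl as
    organic because they contain a listed halogen (documented limitation).
    """
    mol = Chem.MolFromSmiles(structure.canonical_smiles)
    if mol is None:
        return False
    mol = Chem.AddHs(mol)
    elements = {atom.GetSymbol() for atom in mol.GetAtoms()}
    return not (elements & ORGANIC_ELEMENTS)


def compute_polymer_flag(
    name: Optional[str],
    structure: Optional[StructureRecord] = None,
    keywords: Sequence[str] = POLYMER_NAME_KEYWORDS,
    repeat_smarts: str = POLYMER_SMARTS,
) -> bool:
    """True on a repeat-unit substructure hit or a polymer name keyword."""
    if name:
        low = name.lower()
        if any(k in low for k in keywords):
            return True
    if structure is not None and structure.canonical_smiles:
        mol = Chem.MolFromSmiles(structure.canonical_smiles)
        patt = Chem.MolFromSmarts(repeat_smarts)
        if mol is not None and patt is not None and mol.HasSubstructMatch(patt):
            return True
    return False


# ---------------------------------------------------------------------------
# chirality

_NAME_STEREO_RE = re.compile(r"(\(±\)|±|\bRS\b|\bSR\b|\bDL\b|\bD/L\b)", re.I)


def assign_chirality(
    structure: Optional[StructureRecord],
    name: Optional[str] = None,
    is_biotherapeutic: bool = False,
) -> tuple[int, list[str]]:
    """Chirality category: 2 achiral, 1 single stereoisomer, 0 mixture,
    -1 unknown.  Returns (code, review notes).

    Decision tree: a structureless biotherapeutic is a single stereoisomer
    (amino acids / nucleotides have defined configuration); a structure
    with no potential stereocenters is achiral; a structure superimposable
    on its mirror image (identical standard InChI — the meso / internal
    mirror-symmetry test) is achiral even when stereocenters are drawn;
    fully assigned stereocenters give a single stereoisomer; present but
    undrawn or partially drawn stereo gives a mixture; no structure and no
    biologic evidence is unknown.  Name patterns (±, RS, D/L) only add a
    review note, never decide the category.
    """
    notes: list[str] = []
    if name and _NAME_STEREO_RE.search(name):
        notes.append(f"name suggests stereo mixture: {name!r}")
    if structure is None:
        return (1, notes) if is_biotherapeutic else (-1, notes)
    mol = Chem.MolFromSmiles(structure.canonical_smiles)
    if mol is None:
        return -1, notes + ["structure not parseable from canonical SMILES"]
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    if not centers:
        return 2, notes
    iso = Chem.MolToSmiles(mol)
    if "@" in iso:  # mirror test is informative only with drawn stereo
        self_inchi = chem.inchi_of_smiles(iso)
        mirror_inchi = chem.inchi_of_smiles(chem.mirror_smiles(iso))
        if self_inchi is not None and self_inchi == mirror_inchi:
            return 2, notes  # superimposable on its mirror image
    if all(tag != "?" for _, tag in centers):
        return 1, notes
    return 0, notes


# ---------------------------------------------------------------------------
# therapeutic flag


def assign_therapeutic_flag(
    indication_text: str, phrases: Optional[Sequence[str]] = None
) -> tuple[bool, list[str]]:
    """False iff the indication text matches a diagnostic-use phrase.

    Returns (flag, matched phrases); matches are surfaced so a curator can
    review borderline wording.  Empty text defaults to therapeutic.
    """
    if phrases is None:
        phrases = load_diagnostic_phrases()
    low = (indication_text or "").lower()
    hits = [p for p in phrases if p in low]
    return (not hits), hits


# ---------------------------------------------------------------------------
# maximum phase


def resolve_max_phase(
    drug_sources: Iterable[int],
    family_sources: Iterable[int] = (),
    trial_phases: Iterable[str] = (),
    approvals: Iterable[ApprovalEvent] = (),
) -> tuple[Optional[float], bool]:
    """Resolve the maximum clinical development phase for one drug form.

    Returns (max_phase, needs_review).  Category 4 requires a human-use
    regulatory approval source (FDA Orange Book, FDA new drugs, withdrawn
    drugs, or EMA backed by a human-use approval) or an ATC source with no
    other regulatory source anywhere in the compound family.  Trial phases
    and name applications contribute 3 / 2 / 1 / 0.5 (INN counts as phase 2
    evidence, USAN as phase 1).  A Phase 4 trial alone cannot certify
    approval: it contributes phase 3 plus a review flag.  A drug source
    with no phase evidence at all (e.g. veterinary-only EMA) gives -1;
    no drug source and no trial evidence gives NULL (research compound).
    """
    drug_sources = set(drug_sources)
    family_sources = set(family_sources) | drug_sources
    trial_phases = list(trial_phases)
    approvals = list(approvals)
    review = False

    human_approval = any(a.human_use for a in approvals)
    regulatory = {SRC_FDA_ORANGE_BOOK, SRC_FDA_NEW_DRUGS, SRC_WITHDRAWN}
    if drug_sources & regulatory:
        return 4.0, review
    if SRC_EMA in drug_sources and human_approval:
        return 4.0, review
    if SRC_ATC in drug_sources and not (
        family_sources & (regulatory | {SRC_EMA})
    ):
        return 4.0, review

    evidence: list[float] = []
    for phase in trial_phases:
        if phase == "phase4":
            evidence.append(3.0)
            review = True
        elif phase in TRIAL_PHASE_EVIDENCE:
            evidence.append(TRIAL_PHASE_EVIDENCE[phase])
    if SRC_INN in drug_sources:
        evidence.append(2.0)
    if SRC_USAN in drug_sources:
        evidence.append(1.0)
    if evidence:
        return max(evidence), review
    if drug_sources:
        return -1.0, review  # drug source but no assignable phase evidence
    return None, review


# ---------------------------------------------------------------------------
# availability type


def assign_availability_type(
    is_orange_book: bool,
    marketing_status: Optional[str],
    withdrawn_flag: bool,
    has_drug_source: bool,
) -> Optional[int]:
    """Availability code: 2 OTC, 1 prescription, 0 discontinued, -1 unknown,
    -2 withdrawn, NULL for research compounds.

    -2 requires the withdrawn flag together with a discontinued marketing
    status (Orange Book drugs) or an uncurated status (non-Orange-Book
    drugs); a drug still marketed in one region keeps its marketing code
    even when withdrawn elsewhere.
    """
    if not has_drug_source:
        return None
    if withdrawn_flag:
        if is_orange_book and marketing_status == "discontinued":
            return -2
        if not is_orange_book:
            return -2
    if is_orange_book:
        return {"otc": 2, "rx": 1, "discontinued": 0}.get(marketing_status, -1)
    return -1


# ---------------------------------------------------------------------------
# withdrawal


def evaluate_withdrawal(
    events: Sequence[WithdrawalEvent],
) -> tuple[bool, Optional[int], list[str]]:
    """Decide withdrawn-drug eligibility from curated withdrawal events.

    A drug is withdrawn iff at least one event withdraws all doses, all
    populations and all indications on a safety basis (including
    safety-related drug–drug interactions, and suspensions corroborated by
    additional references).  Efficacy-only withdrawals never qualify.
    Returns (eligible, earliest qualifying year, qualifying regions).
    """
    qualifying = []
    for ev in events:
        if not (ev.all_doses and ev.all_populations and ev.all_indications):
            continue
        if ev.basis in ("safety", "drug_interaction_safety"):
            qualifying.append(ev)
        elif ev.basis == "suspended" and ev.corroborated:
            qualifying.append(ev)
    if not qualifying:
        return False, None, []
    year = min(ev.year for ev in qualifying)
    countries = sorted({ev.region for ev in qualifying if ev.region})
    return True, year, countries


# ---------------------------------------------------------------------------
# approval years


def compute_first_approval(approvals: Sequence[ApprovalEvent]) -> Optional[int]:
    """Earliest year over human-use approvals; withdrawal/reapproval cycles
    do not reset it (the earliest approval stands)."""
    years = [a.year for a in approvals if a.human_use]
    return min(years) if years else None


def validate_usan_year(
    usan_year: Optional[int], first_approval: Optional[int]
) -> Optional[str]:
    """Warn when the USAN application postdates first approval.

    A USAN is granted during clinical development, so it should precede
    approval; a later year signals a curation error to check.
    """
    if usan_year is None or first_approval is None:
        return None
    if usan_year > first_approval:
        return (
            f"usan_year {usan_year} is later than first_approval "
            f"{first_approval}"
        )
    return None


# ---------------------------------------------------------------------------
# USAN stems


def map_usan_stem(
    name: str, stem_table: Optional[Sequence[UsanStem]] = None
) -> Optional[tuple[str, Optional[str], str]]:
    """Map a USAN name onto its name stem; longest matching stem wins.

    Returns (stem, substem, definition) or None.  Prefix stems match at the
    start of the name, suffix stems at the end, infix stems anywhere.
    """
    if stem_table is None:
        stem_table = load_usan_stems()
    low = normalize_name(name)
    matches: list[UsanStem] = []
    for st in stem_table:
        core = st.core
        if st.kind == "suffix" and low.endswith(core):
            matches.append(st)
        elif st.kind == "prefix" and low.startswith(core):
            matches.append(st)
        elif st.kind == "infix" and core in low:
            matches.append(st)
    if not matches:
        return None
    best = max(matches, key=lambda s: len(s.core))
    return best.stem, None, best.definition
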