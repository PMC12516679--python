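"""Domain types shared across the pipeline, and the in-memory compound registry.

The registry is the analog of a ``molecule_dictionary`` plus
``compound_records`` and ``molecule_synonyms``: one entry per unique
compound (keyed by an integer ``molregno``), an InChIKey index over
structured entries, and a normalized-name index over preferred names and
synonyms.  NULL-valued drug properties are represented as Python ``None``
throughout; exports render them explicitly (``\\N``), never as empty strings.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Iterator, Optional

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: InChIKey middle block of any structure without a stereo layer.
STEREO_FREE_BLOCK = "UHFFFAOYSA"

#: Source identifiers for drug and clinical-candidate feeds.
SRC_CANDIDATES = 8
SRC_FDA_ORANGE_BOOK = 9
SRC_FDA_NEW_DRUGS = 12
SRC_USAN = 13
SRC_WITHDRAWN = 36
SRC_ATC = 41
SRC_BNF = 42
SRC_PRODRUG_ACTIVE = 53
SRC_INN = 63
SRC_EMA = 66

VALID_SRC_IDS = frozenset(
    {
        SRC_CANDIDATES,
        SRC_FDA_ORANGE_BOOK,
        SRC_FDA_NEW_DRUGS,
        SRC_USAN,
        SRC_WITHDRAWN,
        SRC_ATC,
        SRC_BNF,
        SRC_PRODRUG_ACTIVE,
        SRC_INN,
        SRC_EMA,
    }
)

SRC_NAMES = {
    SRC_CANDIDATES: "CANDIDATES",
    SRC_FDA_ORANGE_BOOK: "FDA_ORANGE_BOOK",
    SRC_FDA_NEW_DRUGS: "FDA_NEW_DRUGS",
    SRC_USAN: "USAN",
    SRC_WITHDRAWN: "WITHDRAWN",
    SRC_ATC: "ATC",
    SRC_BNF: "BNF",
    SRC_PRODRUG_ACTIVE: "PRODRUG_ACTIVE",
    SRC_INN: "INN",
    SRC_EMA: "EMA",
}

#: Sources that by themselves certify human regulatory approval.
REGULATORY_SRC_IDS = frozenset(
    {SRC_FDA_ORANGE_BOOK, SRC_FDA_NEW_DRUGS, SRC_WITHDRAWN, SRC_EMA}
)

_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "κ": "kappa",
    "λ": "lambda",
    "ω": "omega",
}

_WS_RE = re.compile(r"\s+")


class MalformedInchikeyError(ValueError):
    """Raised when an InChIKey does not match the 27-character layout."""


class MissingEntryError(KeyError):
    """Raised when a molregno is not present in the registry."""


def normalize_name(name: str) -> str:
    """Normalize a compound name for indexing and matching.

    Lowercases, trims, collapses internal whitespace and writes Greek
    letters out in full ("α" -> "alpha"), so that e.g. "Interferon α-2b"
    and "interferon alpha-2b" index identically.
    """
    s = unicodedata.normalize("NFC", name)
    for greek, latin in _GREEK.items():
        s = s.replace(greek, latin).replace(greek.upper(), latin)
    s = _WS_RE.sub(" ", s.strip())
    return s.lower()


@dataclass
class StructureRecord:
    """A standardized chemical structure and its identifiers."""

    molfile: str
    canonical_smiles: str
    std_inchi: str
    std_inchikey: str
    penalty: int = 0

    def __post_init__(self) -> None:
        if self.std_inchikey and not INCHIKEY_RE.match(self.std_inchikey):
            raise MalformedInchikeyError(self.std_inchikey)
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")

    @property
    def has_stereo(self) -> bool:
        return bool(self.std_inchikey) and not self.std_inchikey[15:25].startswith(
            STEREO_FREE_BLOCK
        )

    @property
    def reviewable(self) -> bool:
        """True when the checker penalty exceeds the inclusion threshold (5)."""
        return self.penalty > 5


@dataclass
class SynonymEntry:
    """One synonym, research code, or trade name of a compound."""

    molregno: int
    name: str
    syn_type: str = "synonym"  # synonym | trade_name | research_code
    normalized: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("synonym name must be non-empty")
        if not self.normalized:
            self.normalized = normalize_name(self.name)


@dataclass
class CompoundRecordEntry:
    """One (compound, source) provenance row — a compound_records analog."""

    record_id: int
    molregno: int
    src_id: int
    source_name: str
    extraction_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.src_id not in VALID_SRC_IDS:
            raise ValueError(f"unknown src_id {self.src_id}")


@dataclass
class MoleculeEntry:
    """One registered compound with its drug-property fields.

    Enumerated codes follow the conventions of a drug-dictionary table:
    ``max_phase`` in {4, 3, 2, 1, 0.5, -1, None}; ``chirality`` in
    {2 achiral, 1 single stereoisomer, 0 mixture, -1 unknown};
    ``prodrug``/``first_in_class``/``orphan`` in {1, 0, -1};
    ``availability_type`` in {2 OTC, 1 prescription, 0 discontinued,
    -1 unknown, -2 withdrawn, None}.  ``None`` means "not a drug or
    clinical candidate" wherever the field admits it.
    """

    molregno: int
    pref_name: Optional[str] = None
    max_phase: Optional[float] = None
    molecule_type: Optional[str] = None
    chirality: int = -1
    prodrug: int = -1
    first_in_class: int = -1
    oral: bool = False
    parenteral: bool = False
    topical: bool = False
    availability_type: Optional[int] = None
    therapeutic_flag: bool = False
    withdrawn_flag: bool = False
    black_box_warning: bool = False
    dosed_ingredient: bool = False
    first_approval: Optional[int] = None
    usan_year: Optional[int] = None
    usan_stem: Optional[str] = None
    usan_substem: Optional[str] = None
    usan_stem_definition: Optional[str] = None
    orphan: int = -1
    veterinary: int = 0
    inorganic_flag: bool = False
    polymer_flag: bool = False
    structure: Optional[StructureRecord] = None
    bio_sequence: Optional[str] = None
    bio_component_type: Optional[str] = None  # protein | nucleic acid
    synonyms: list[SynonymEntry] = field(default_factory=list)
    max_phase_review: bool = False

    @property
    def is_biotherapeutic(self) -> bool:
        return self.structure is None and (
            self.bio_sequence is not None
            or self.molecule_type
            in {
                "antibody",
                "antibody drug conjugate",
                "cell-based",
                "enzyme",
                "gene",
                "oligosaccharide",
                "oligonucleotide",
                "protein",
            }
        )


class Registry:
    """In-memory compound registry with InChIKey and name indexes.

    Invariants: the InChIKey index maps each key to exactly one molregno,
    and the id counter is strictly increasing, so registration is
    deterministic given input order.
    """

    def __init__(self, start_molregno: int = 1) -> None:
        self.entries: dict[int, MoleculeEntry] = {}
        self.records: list[CompoundRecordEntry] = []
        self._by_inchikey: dict[str, int] = {}
        self._by_name: dict[str, set[int]] = {}
        self._next_molregno = start_molregno
        self._next_record_id = 1

    # -- id management -------------------------------------------------

    def next_molregno(self) -> int:
        n = self._next_molregno
        self._next_molregno += 1
        return n

    def next_record_id(self) -> int:
        n = self._next_record_id
        self._next_record_id += 1
        return n

    # -- entry management ----------------------------------------------

    def add_entry(self, entry: MoleculeEntry) -> MoleculeEntry:
        if entry.molregno in self.entries:
            raise ValueError(f"molregno {entry.molregno} already registered")
        self.entries[entry.molregno] = entry
        if entry.structure is not None and entry.structure.std_inchikey:
            key = entry.structure.std_inchikey
            if key in self._by_inchikey:
                raise ValueError(
                    f"InChIKey {key} already mapped to molregno "
                    f"{self._by_inchikey[key]}"
                )
            self._by_inchikey[key] = entry.molregno
        if entry.pref_name:
            self._index_name(entry.pref_name, entry.molregno)
        for syn in entry.synonyms:
            self._index_name(syn.name, entry.molregno)
        return entry

    def add_synonym(self, molregno: int, name: str, syn_type: str = "synonym") -> None:
        entry = self.get(molregno)
        syn = SynonymEntry(molregno=molregno, name=name, syn_type=syn_type)
        if any(s.normalized == syn.normalized for s in entry.synonyms):
            return
        entry.synonyms.append(syn)
        self._index_name(name, molregno)

    def _index_name(self, name: str, molregno: int) -> None:
        self._by_name.setdefault(normalize_name(name), set()).add(molregno)

    def get(self, molregno: int) -> MoleculeEntry:
        try:
            return self.entries[molregno]
        except KeyError:
            raise MissingEntryError(molregno) from None

    def __contains__(self, molregno: int) -> bool:
        return molregno in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[MoleculeEntry]:
        return iter(self.entries.values())

    # -- source records ------------------------------------------------

    def records_for(self, molregno: int) -> list[CompoundRecordEntry]:
        return [r for r in self.records if r.molregno == molregno]

    def sources_for(self, molregno: int) -> set[int]:
        return {r.src_id for r in self.records if r.molregno == molregno}

    # -- name iteration (used by the trials mapper) ---------------------

    def iter_names(self) -> Iterable[tuple[str, int]]:
        """Yield (normalized name, molregno) over pref_names and synonyms."""
        for entry in self.entries.values():
            if entry.pref_name:
                yield normalize_name(entry.pref_name), entry.molregno
            for syn in entry.synonyms:
                yield syn.normalized, entry.molregno


def lookup_by_inchikey(registry: Registry, inchikey: str) -> Optional[int]:
    """Return the unique molregno whose structure has this standard InChIKey.

    Raises :class:`MalformedInchikeyError` for a key that does not match the
    27-character layout.
    """
    if not INCHIKEY_RE.match(inchikey):
        raise MalformedInchikeyError(inchikey)
    return registry._by_inchikey.get(inchikey)


def lookup_by_name(registry: Registry, name: str) -> set[int]:
    """Case-insensitive, whitespace-normalized match over pref_name + synonyms.

    May return more than one id where legacy duplicate names remain; the
    caller decides whether ambiguity goes to a curation queue.
    """
    return set(registry._by_name.get(normalize_name(name), set()))
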