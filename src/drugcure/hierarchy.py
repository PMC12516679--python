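"""Molecule hierarchy: parent derivation, family grouping, prodrug links,
and upward aggregation of drug properties.

Every drug form belongs to a family with one parent — the form left after
salts, solvents and isotope labels are stripped.  The ``active_molregno``
points at the pharmacologically active ingredient and differs from the
parent only for prodrugs.  Manually fixed links always win over automatic
derivation (tautomer problems, structureless biotherapeutic families).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from rdkit import Chem

from drugcure import chem
from drugcure.core import MissingEntryError, MoleculeEntry, Registry, StructureRecord
from drugcure.registration import standardize_structure

#: max_phase ordering used for family aggregation: NULL (None) is ignored,
#: -1 (unknown) sits below 0.5.
PHASE_ORDER = {4.0: 6, 3.0: 5, 2.0: 4, 1.0: 3, 0.5: 2, -1.0: 1}


class DegenerateStructureError(ValueError):
    """Raised when every fragment of a structure is a dictionary fragment."""


@dataclass
class HierarchyLink:
    """molregno / parent_molregno / active_molregno triple."""

    molregno: int
    parent_molregno: int
    active_molregno: int
    manually_fixed: bool = False


def load_fragment_dictionary(path=None) -> set[str]:
    """Load the salt/solvent dictionary as a set of InChIKey first blocks.

    The shipped list holds ~30 common counterions and solvents; it is a
    plain editable text file (one SMILES + name per line, tab-separated).
    """
    if path is None:
        text = (
            resources.files("drugcure") / "data" / "salt_fragments.tsv"
        ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    blocks: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split("\t")[0]
        ik = _connectivity_block(smiles)
        if ik:
            blocks.add(ik)
    return blocks


def _connectivity_block(smiles: str) -> Optional[str]:
    """First (connectivity) InChIKey block of a SMILES, charge-normalized."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    from rdkit.Chem.MolStandardize import rdMolStandardize

    try:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception:
        pass
    std_inchi = chem.inchi_of_smiles(Chem.MolToSmiles(mol))
    if std_inchi is None:
        return None
    from rdkit.Chem.inchi import InchiToInchiKey

    key = InchiToInchiKey(std_inchi)
    return key[:14] if key else None


def derive_parent(
    structure: StructureRecord, fragment_dictionary: Optional[set[str]] = None
) -> StructureRecord:
    """Strip salts/solvents/isotopes from a structure to obtain its parent.

    Fragments whose charge-normalized connectivity appears in the fragment
    dictionary are removed, isotope labels are cleared to natural abundance,
    and trivially protonatable/deprotonatable charges on what remains are
    neutralized.  A neutral, unlabeled, single-fragment input is a fixed
    point.  If *every* fragment is a dictionary fragment there is no parent
    to derive and :class:`DegenerateStructureError` is raised.
    """
    if fragment_dictionary is None:
        fragment_dictionary = load_fragment_dictionary()
    mol = Chem.MolFromSmiles(structure.canonical_smiles)
    if mol is None:
        mol = chem.parse_structure(structure.molfile)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    kept: list[Chem.Mol] = []
    for frag in frags:
        frag = chem.safe_sanitize(frag)
        block = _connectivity_block(Chem.MolToSmiles(frag))
        if block is not None and block in fragment_dictionary:
            continue
        kept.append(frag)
    if not kept:
        raise DegenerateStructureError(
            "all fragments are salt/solvent dictionary entries"
        )
    combined = kept[0]
    for frag in kept[1:]:
        combined = Chem.CombineMols(combined, frag)
    combined = Chem.RWMol(combined)
    for atom in combined.GetAtoms():
        atom.SetIsotope(0)
    from rdkit.Chem.MolStandardize import rdMolStandardize

    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    try:
        mol = rdMolStandardize.Uncharger().uncharge(mol)
    except Exception:
        pass
    return standardize_structure(Chem.MolToSmiles(mol))


def build_families(
    registry: Registry,
    manual_overrides: Iterable[HierarchyLink] = (),
    fragment_dictionary: Optional[set[str]] = None,
) -> dict[int, HierarchyLink]:
    """Assign every registry entry to a family via a hierarchy link.

    Salt forms whose stripped parent structure is not registered get a
    *virtual parent*: a new entry holding only the parent structure, with no
    compound_records rows of its own.  Manual overrides always win over the
    automatic derivation and are flagged ``manually_fixed``.
    """
    if fragment_dictionary is None:
        fragment_dictionary = load_fragment_dictionary()
    overrides = {link.molregno: link for link in manual_overrides}
    for link in overrides.values():
        for ref in (link.molregno, link.parent_molregno, link.active_molregno):
            if ref not in registry:
                raise MissingEntryError(ref)
        link.manually_fixed = True

    links: dict[int, HierarchyLink] = {}
    for molregno in sorted(registry.entries):
        if molregno in links:
            continue
        if molregno in overrides:
            links[molregno] = overrides[molregno]
            continue
        entry = registry.get(molregno)
        parent = molregno
        if entry.structure is not None and entry.structure.std_inchikey:
            try:
                parent_structure = derive_parent(entry.structure, fragment_dictionary)
            except DegenerateStructureError:
                parent_structure = entry.structure
            if parent_structure.std_inchikey != entry.structure.std_inchikey:
                from drugcure.core import lookup_by_inchikey

                existing = lookup_by_inchikey(
                    registry, parent_structure.std_inchikey
                )
                if existing is not None:
                    parent = existing
                else:
                    parent = registry.next_molregno()
                    registry.add_entry(
                        MoleculeEntry(molregno=parent, structure=parent_structure)
                    )
        links[molregno] = HierarchyLink(
            molregno=molregno, parent_molregno=parent, active_molregno=parent
        )
    # parents are their own parents (self-links for any virtual parent too)
    for link in list(links.values()):
        p = link.parent_molregno
        if p not in links:
            links[p] = HierarchyLink(molregno=p, parent_molregno=p, active_molregno=p)
    return links


def families(links: dict[int, HierarchyLink]) -> dict[int, list[int]]:
    """Group molregnos by parent: {parent_molregno: [member molregnos]}."""
    fams: dict[int, list[int]] = {}
    for link in links.values():
        fams.setdefault(link.parent_molregno, []).append(link.molregno)
    for members in fams.values():
        members.sort()
    return fams


def set_active_ingredient(
    links: dict[int, HierarchyLink],
    prodrug_annotations: Iterable[tuple[int, int]],
    registry: Optional[Registry] = None,
) -> dict[int, HierarchyLink]:
    """Record the pharmacologically active ingredient of each prodrug.

    The active_molregno is set on the prodrug form and on every other
    drug/candidate member of its family (they all metabolize to the same
    active species).  The schema allows a single active ingredient per
    prodrug; two distinct actives raise a constraint error.
    """
    actives: dict[int, int] = {}
    for prodrug, active in prodrug_annotations:
        if prodrug not in links:
            raise MissingEntryError(prodrug)
        if prodrug in actives and actives[prodrug] != active:
            raise ValueError(
                f"prodrug {prodrug} annotated with two distinct active "
                f"ingredients ({actives[prodrug]}, {active})"
            )
        actives[prodrug] = active
    fams = families(links)
    for prodrug, active in actives.items():
        parent = links[prodrug].parent_molregno
        for member in fams[parent]:
            if (
                member != prodrug
                and registry is not None
                and registry.get(member).max_phase is None
            ):
                continue  # research-only member: not curated as a drug form
            links[member].active_molregno = active
    return links


def aggregate_family_properties(
    registry: Registry, links: dict[int, HierarchyLink]
) -> Registry:
    """Aggregate drug-form properties onto each family's parent form.

    max_phase: maximum over members in the order 4 > 3 > 2 > 1 > 0.5 > -1
    (NULL ignored); boolean flags OR upward; first_approval and usan_year
    take the earliest year; dosed_ingredient is deliberately NOT aggregated
    (it distinguishes whether the parent itself is administered); chirality
    is copied to the parent only when uniform across annotated members.
    """
    for parent, members in families(links).items():
        parent_entry = registry.get(parent)
        phases = [
            registry.get(m).max_phase
            for m in members
            if registry.get(m).max_phase is not None
        ]
        if phases:
            best = max(phases, key=lambda p: PHASE_ORDER[p])
            if parent_entry.max_phase is None or PHASE_ORDER[best] > PHASE_ORDER.get(
                parent_entry.max_phase, 0
            ):
                parent_entry.max_phase = best
        for flag in (
            "oral",
            "parenteral",
            "topical",
            "therapeutic_flag",
            "withdrawn_flag",
            "black_box_warning",
            "inorganic_flag",
            "polymer_flag",
        ):
            if any(getattr(registry.get(m), flag) for m in members):
                setattr(parent_entry, flag, True)
        years = [
            registry.get(m).first_approval
            for m in members
            if registry.get(m).first_approval is not None
        ]
        if years:
            parent_entry.first_approval = min(years)
        usan_years = [
            registry.get(m).usan_year
            for m in members
            if registry.get(m).usan_year is not None
        ]
        if usan_years:
            parent_entry.usan_year = min(usan_years)
        chis = {
            registry.get(m).chirality
            for m in members
            if registry.get(m).chirality != -1
        }
        if len(chis) == 1 and parent_entry.chirality == -1:
            parent_entry.chirality = chis.pop()
    return registry


def propagate_prodrug(
    registry: Registry, links: dict[int, HierarchyLink]
) -> Registry:
    """Flag every drug/candidate form of a prodrug family as a prodrug.

    All forms metabolize to the same active ingredient, so the flag applies
    family-wide — but only to members curated as drugs or clinical
    candidates (max_phase not NULL); research-only members are untouched.
    """
    for parent, members in families(links).items():
        if any(registry.get(m).prodrug == 1 for m in members):
            for m in members:
                entry = registry.get(m)
                if entry.max_phase is not None:
                    entry.prodrug = 1
    return registry
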