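"""RDKit helpers shared by registration and hierarchy.

Thin wrappers around parsing, standardization and identifier generation so
the rest of the package never touches RDKit objects directly.
"""

from __future__ import annotations

from typing import Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")


class StructureParseError(ValueError):
    """Raised when a structure cannot be parsed at all."""


def parse_structure(raw: str, sanitize: bool = True) -> Chem.Mol:
    """Parse a raw molfile (V2000) or SMILES string into an RDKit Mol.

    Multi-line input containing "V2000" is treated as a molfile; anything
    else as SMILES.  Raises :class:`StructureParseError` with the offending
    input when nothing parses.
    """
    raw = raw.rstrip()
    if "\n" in raw or "V2000" in raw:
        mol = Chem.MolFromMolBlock(raw, sanitize=sanitize, removeHs=sanitize)
        kind = "molfile"
    else:
        mol = Chem.MolFromSmiles(raw, sanitize=sanitize)
        kind = "SMILES"
    if mol is None:
        first_line = raw.splitlines()[0] if raw else ""
        raise StructureParseError(f"unparseable {kind}: {first_line!r}")
    return mol


def sanitize_penalty(mol: Chem.Mol) -> int:
    """Simplified checker score for a parsed (unsanitized) molecule.

    Valence violations and kekulization failures score 6 (above the
    inclusion threshold of 5, so the record is routed to review); a clean
    molecule scores 0.  The checker contract is pluggable — this built-in
    scorer covers the failure modes RDKit can detect without external rules.
    """
    problems = Chem.DetectChemistryProblems(mol)
    penalty = 0
    for p in problems:
        if p.GetType() in ("AtomValenceException", "KekulizeException"):
            penalty = max(penalty, 6)
        else:
            penalty = max(penalty, 2)
    return penalty


def safe_sanitize(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize as far as possible, skipping operations that raise."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            catchErrors=True,
        )
    return mol


def cleanup(mol: Chem.Mol) -> Chem.Mol:
    """Standardizer pass: functional-group normalization + metal handling."""
    try:
        return rdMolStandardize.Cleanup(mol)
    except Exception:
        return mol


def identifiers(mol: Chem.Mol) -> tuple[str, str, str, str]:
    """Return (molfile, canonical SMILES, standard InChI, standard InChIKey).

    InChI fields are empty strings when generation fails (e.g. a structure
    with unresolvable valence that is only kept for the review queue).
    """
    try:
        molfile = Chem.MolToMolBlock(mol, kekulize=True)
    except Exception:
        molfile = Chem.MolToMolBlock(mol, kekulize=False)
    smiles = Chem.MolToSmiles(mol)
    try:
        std_inchi = inchi.MolToInchi(mol) or ""
    except Exception:
        std_inchi = ""
    key = inchi.InchiToInchiKey(std_inchi) if std_inchi else ""
    return molfile, smiles, std_inchi, key or ""


def mirror_smiles(isomeric_smiles: str) -> str:
    """SMILES of the mirror image: invert every tetrahedral stereo tag."""
    return (
        isomeric_smiles.replace("@@", "\x00")
        .replace("@", "@@")
        .replace("\x00", "@")
    )


def inchi_of_smiles(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        return inchi.MolToInchi(mol) or None
    except Exception:
        return None
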