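"""Shared fixtures: small registries, a seven-term ontology, helpers."""

from __future__ import annotations

import io
import math

import pytest

from drugcure.core import Registry
from drugcure.ontology import load_ontology
from drugcure.registration import IncomingCompound, register_compound

#: Seven-term diamond-free tree for hand-checkable information content:
#: root R with children A and B; A has leaves a1, a2; B has leaves b1, b2.
SEVEN_TERM_OBO = """format-version: 1.2
ontology: seven

[Term]
id: S:R
name: root

[Term]
id: S:A
name: branch a
is_a: S:R

[Term]
id: S:B
name: branch b
is_a: S:R

[Term]
id: S:a1
name: leaf a1
is_a: S:A

[Term]
id: S:a2
name: leaf a2
is_a: S:A

[Term]
id: S:b1
name: leaf b1
is_a: S:B

[Term]
id: S:b2
name: leaf b2
is_a: S:B
"""


@pytest.fixture
def seven_term_ontology():
    return load_ontology(io.StringIO(SEVEN_TERM_OBO))


#: Explicit parent lists for independent-closure oracles on the same tree.
SEVEN_TERM_PARENTS = {
    "S:R": [],
    "S:A": ["S:R"],
    "S:B": ["S:R"],
    "S:a1": ["S:A"],
    "S:a2": ["S:A"],
    "S:b1": ["S:B"],
    "S:b2": ["S:B"],
}


def closure_descendants(parents: dict[str, list[str]]) -> dict[str, set[str]]:
    """Brute-force transitive closure: iterate until fixpoint."""
    desc: dict[str, set[str]] = {t: set() for t in parents}
    changed = True
    while changed:
        changed = False
        for child, ps in parents.items():
            for p in ps:
                new = ({child} | desc[child]) - desc[p]
                if new:
                    desc[p] |= new
                    changed = True
    return desc


def oracle_lin(parents: dict[str, list[str]], a: str, b: str) -> float:
    """Direct Lin formula evaluation on enumerated descendant counts."""
    desc = closure_descendants(parents)
    n = len(parents)
    ic = {t: -math.log((len(d) + 1) / n) for t, d in desc.items()}

    def ancestors(t: str) -> set[str]:
        out: set[str] = set()
        stack = list(parents[t])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(parents[p])
        return out

    if a == b:
        return 1.0
    common = (ancestors(a) | {a}) & (ancestors(b) | {b})
    if not common:
        return 0.0
    mica = max(ic[t] for t in common)
    denom = ic[a] + ic[b]
    return 2 * mica / denom if denom else 0.0


@pytest.fixture
def small_registry() -> Registry:
    """Three structured drugs + one structureless biotherapeutic."""
    reg = Registry()
    for src, name, smi in [
        (9, "aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
        (13, "ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        (66, "caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ]:
        register_compound(
            reg, IncomingCompound(src_id=src, pref_name=name, structure_raw=smi)
        )
    register_compound(
        reg,
        IncomingCompound(src_id=63, pref_name="vonicogase",
                         bio_sequence="MKTAYIAKQR", bio_component_type="protein"),
    )
    return reg
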