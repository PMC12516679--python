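# drugcure

A rule-based curation engine for drug and clinical-candidate data, modeled
on the workflow that large medicinal-chemistry databases use to maintain a
nonredundant dictionary of drugs, salts, and clinical candidates across
many regulatory and registry feeds.

It is written for data engineers and cheminformaticians who need to merge
compound records from heterogeneous sources (approved-product lists,
generic-name applications, trial registries) into a single coherent set of
compounds with curated drug properties — and who need every automatic
decision to be rule-driven, logged, and reviewable.

## What it does

**Compound registration.** Incoming structures (molfile V2000 or SMILES)
are standardized with RDKit and identified by their full 27-character
standard InChIKey. An exact key match maps the record onto the existing
compound id (*molregno*); otherwise a new id is registered. Structureless
biotherapeutics merge only on an exact normalized-name match; anything
ambiguous goes to a curation queue. A simplified checker scores structures;
a penalty > 5 routes the record to manual review.

**Molecule hierarchy.** Each compound belongs to a family with one parent —
the form left after salts, solvents, and isotope labels are stripped
(configurable fragment dictionary, ~30 common counterions/solvents).
Prodrugs carry an *active_molregno* pointing at the pharmacologically
active ingredient. Drug properties aggregate upward onto the parent:

- `max_phase`: max over members in the order 4 > 3 > 2 > 1 > 0.5 > −1
  (NULL ignored); boolean flags OR upward; `first_approval` and
  `usan_year` take the earliest year; `dosed_ingredient` is deliberately
  **not** aggregated.
- the `prodrug` flag propagates to every drug/candidate form of the family.

**Drug-property classifiers.** `max_phase` resolution from sources and
trial phases (regulatory source → 4; Phase 3 → 3; Phase 2 or INN → 2;
Phase 1 or USAN → 1; Early Phase 1 → 0.5; drug source without phase
evidence → −1); chirality (2 achiral / 1 single stereoisomer / 0 mixture /
−1 unknown, with a meso test by InChI equality of the molecule and its
mirror image); availability type (2 OTC / 1 Rx / 0 discontinued / −1
unknown / −2 withdrawn); withdrawal eligibility (all doses ∧ all
populations ∧ all indications ∧ safety basis; efficacy never qualifies);
therapeutic flag; molecule type from name suffixes and substructure rules;
inorganic/polymer flags; preferred-name choice; USAN stems.

**Clinical-trials pipeline.** Interventional trials with an exact phase are
filtered from a ClinicalTrials.gov-style JSON feed; interventions map to
compounds and conditions to disease-ontology terms. Only dictionary hits
or exact name matches auto-assign — substring matches merely generate
review candidates (names < 4 characters and blocklisted names excluded).
Multi-condition trials are disentangled with Lin semantic similarity,
IC(t) = −ln((|descendants(t)|+1)/N), at a 0.85 threshold; less-specific
conditions of a trial are flagged redundant; confirmed (drug, condition)
pairs become indication rows with `max_phase_for_ind` (Phase 4 only with
regulatory approval for the pair), translated from ontology terms to MeSH
descriptors restricted to the C/E/F branches.

## Worked example

```python
from drugcure.core import Registry
from drugcure.registration import IncomingCompound, register_compound
from drugcure import hierarchy, classifiers

reg = Registry()
salt = "CC(=O)Oc1ccccc1C(=O)O.OS(=O)(=O)O"
for src in (9, 66, 13):  # Orange Book, EMA, USAN
    out = register_compound(reg, IncomingCompound(
        src_id=src, pref_name="examplat sulfate", structure_raw=salt))
    print(f"src {src}: {out.decision} -> molregno {out.molregno}")

links = hierarchy.build_families(reg)
for e in reg:
    e.max_phase, _ = classifiers.resolve_max_phase(reg.sources_for(e.molregno))
hierarchy.aggregate_family_properties(reg, links)
for e in reg:
    print(f"molregno {e.molregno}: max_phase {e.max_phase}, "
          f"key {e.structure.std_inchikey}")
```

prints

```
src 9: registered_new -> molregno 1
src 66: matched_existing -> molregno 1
src 13: matched_existing -> molregno 1
molregno 1: max_phase 4.0, key KNAVFBMJUPIBOI-UHFFFAOYSA-N
molregno 2: max_phase 4.0, key BSYNRYMUTXBXSQ-UHFFFAOYSA-N
```

The same salt submitted from three feeds registers once (molregno 1) with
three provenance rows. Hierarchy building strips the sulfate counterion and
creates the parent as a *virtual* compound (molregno 2, no provenance rows
of its own). The salt's regulatory sources give it `max_phase` 4, and
family aggregation lifts the parent to 4 as well.

A command-line interface wraps the same flow:

```bash
drugcure demo --seed 1 --out demo_out
# demo: 23 compounds, 23 hierarchy links, 12 trials, 4 indication rows -> demo_out
```

which generates the synthetic fixture bundle, runs the full pipeline, and
writes `molecule_dictionary.csv`, `compound_records.csv`,
`molecule_hierarchy.csv`, `drug_indication.csv` plus the manual review
queues (nulls are exported as a literal `\N`; `--format sqlite` writes a
single-file database instead).

## Layout

- `drugcure.core` — domain types, the in-memory registry, name/key indexes
- `drugcure.registration` — standardization, match-vs-register, provenance
- `drugcure.hierarchy` — parent derivation, families, prodrugs, aggregation
- `drugcure.classifiers` — all rule-based drug-property annotations
- `drugcure.ontology` — OBO loading, descendant queries, Lin similarity
- `drugcure.trials` — trial filtering, mapping, disentanglement, indications
- `drugcure.indications` — MeSH mapping, identifier refresh, export rollup
- `drugcure.fixtures` — seeded synthetic inputs and the expected manifest
- `drugcure.export` / `drugcure.cli` — orchestration, tables, quality report

See `docs/methods.md` for the full account of the rules, their parameters,
and the design decisions behind them.
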