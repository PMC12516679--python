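"""Synthetic fixtures: every input the pipeline consumes, generated locally.

The generator emulates the shape of the real feeds — drug-source records
for registration, a ClinicalTrials.gov-style JSON feed, a small disease
ontology in OBO format, a MeSH-like vocabulary — plus reconstructions of
the worked curation scenarios (family aggregation onto a parent, prodrug
propagation, earliest-approval-year, redundant trial conditions, meso
chirality, withdrawal rules, availability types) with their expected
outcomes recorded in a manifest.  Everything is seeded and regenerating
with the same seed is byte-identical.  Stand-in structures are simple
SMILES: what the fixtures assert is rule behavior, not real-compound
chemistry.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

from drugcure.core import (
    SRC_ATC,
    SRC_CANDIDATES,
    SRC_EMA,
    SRC_FDA_NEW_DRUGS,
    SRC_FDA_ORANGE_BOOK,
    SRC_INN,
    SRC_USAN,
    SRC_WITHDRAWN,
)

#: Drug-like parent scaffolds (deliberately simple, pairwise-distinct).
BASE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin-like
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen-like
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine-like
    "NC(=O)c1ccc(O)cc1",              # amide phenol
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",     # lidocaine-like
    "OCC(O)C(O)C(O)C(O)CO",           # sugar alcohol
    "Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1",  # sulfonamide
    "CC(N)Cc1ccccc1",                 # amphetamine-like
    "OC(=O)c1cc(O)c(O)cc1",           # catechol acid
    "CN1CCC(CC1)Oc1ccccc1",           # aryl ether amine
    "CC(=O)Nc1ccc(O)cc1",             # acetaminophen-like
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",   # naproxen-like
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",  # thiazide-like
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",  # penicillin-like
    "OC(=O)CCc1ccccc1",               # phenylpropanoate
    "CNCC(O)c1ccc(O)c(O)c1",          # adrenaline-like
    "Clc1ccccc1C(=O)NCCN",            # chloro benzamide amine
    "CCOC(=O)c1ccccc1N",              # anthranilate ester
    "CN(C)CCCN1c2ccccc2Sc2ccccc21",   # phenothiazine-like
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc32)CC1",  # piperazine tricyclic
]

#: Counterion SMILES used to build salt forms.
COUNTERIONS = ["Cl", "Br", "CS(=O)(=O)O", "OS(=O)(=O)O", "CC(=O)O",
               "OC(=O)/C=C/C(=O)O"]

#: Name fragments for deterministic pseudo-names.
_SYLLABLES = ["va", "lo", "mi", "ter", "zan", "bre", "cu", "dor", "fex",
              "gal", "het", "jun", "kel", "nor", "pra", "quo", "rit", "sol"]
_SALT_SUFFIX = {
    "Cl": "hydrochloride",
    "Br": "hydrobromide",
    "CS(=O)(=O)O": "mesylate",
    "OS(=O)(=O)O": "sulfate",
    "CC(=O)O": "acetate",
    "OC(=O)/C=C/C(=O)O": "fumarate",
}

_BIO_SUFFIXES = ["mab", "ase", "cept"]


@dataclass
class FamilySpec:
    """Ground truth for one generated compound family."""

    parent_name: str
    parent_smiles: Optional[str]
    salt_names: list[str] = field(default_factory=list)
    salt_smiles: list[str] = field(default_factory=list)
    src_ids: list[int] = field(default_factory=list)
    is_biotherapeutic: bool = False
    research_only: bool = False


@dataclass
class FixtureBundle:
    """All generated inputs plus the expected-output manifest."""

    seed: int
    families: list[FamilySpec] = field(default_factory=list)
    trial_feed: list[dict] = field(default_factory=list)
    ontology_obo: str = ""
    mesh_vocabulary: str = ""
    efo_to_mesh: dict[str, str] = field(default_factory=dict)
    intervention_dictionary: dict[str, object] = field(default_factory=dict)
    blocklist: list[str] = field(default_factory=list)
    #: scenario inputs keyed by drug-form name: approval events as
    #: (agency, year, region) and withdrawal events as keyword dicts
    approval_events: dict[str, list[tuple]] = field(default_factory=dict)
    withdrawal_events: dict[str, list[dict]] = field(default_factory=dict)
    meso_smiles: str = ""
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        """Serialize the bundle into the file formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "trials.json").write_text(
            json.dumps(self.trial_feed, indent=1, sort_keys=True), "utf-8"
        )
        (outdir / "ontology.obo").write_text(self.ontology_obo, "utf-8")
        (outdir / "mesh_vocabulary.tsv").write_text(self.mesh_vocabulary, "utf-8")
        lines = ["# source feed: src_id\tpref_name\tsmiles"]
        for fam in self.families:
            # first form carries the family's drug sources; the remaining
            # forms enter as clinical-candidate records (src 8)
            forms = list(zip(fam.salt_names, fam.salt_smiles)) + [
                (fam.parent_name, fam.parent_smiles or "")
            ]
            for i, (name, smiles) in enumerate(forms):
                srcs = fam.src_ids if i == 0 else (
                    [SRC_CANDIDATES] if fam.src_ids else []
                )
                for src in srcs:
                    lines.append(f"{src}\t{name}\t{smiles}")
        (outdir / "source_feed.tsv").write_text("\n".join(lines) + "\n", "utf-8")
        (outdir / "efo_to_mesh.tsv").write_text(
            "".join(f"{k}\t{v}\n" for k, v in sorted(self.efo_to_mesh.items())),
            "utf-8",
        )
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True), "utf-8"
        )
        return outdir


def _pseudo_name(rng: random.Random, n: int = 3) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n))


def gen_registry_fixture(seed: int, n_families: int = 10) -> FixtureBundle:
    """Generate compound families with recorded ground-truth hierarchy.

    Each family holds a parent scaffold plus 0–3 salt forms built by
    attaching counterions; roughly one in five families is a structureless
    biotherapeutic, and one in six a research-only entry (no drug source).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = random.Random(seed)
    bundle = FixtureBundle(seed=seed)
    bases = list(BASE_SMILES)
    drug_srcs = [SRC_FDA_ORANGE_BOOK, SRC_EMA, SRC_USAN, SRC_INN, SRC_ATC,
                 SRC_CANDIDATES]
    for i in range(n_families):
        name = _pseudo_name(rng) + rng.choice(["in", "ol", "one", "ide"])
        if rng.random() < 0.2:
            bio = name[:-2] + rng.choice(_BIO_SUFFIXES)
            bundle.families.append(
                FamilySpec(
                    parent_name=bio,
                    parent_smiles=None,
                    src_ids=[rng.choice([SRC_USAN, SRC_INN, SRC_EMA])],
                    is_biotherapeutic=True,
                )
            )
            continue
        smiles = bases[i % len(bases)]
        n_salts = rng.randint(0, 3)
        salts, salt_names = [], []
        for ion in rng.sample(COUNTERIONS, n_salts):
            salts.append(f"{smiles}.{ion}")
            salt_names.append(f"{name} {_SALT_SUFFIX[ion]}")
        research = rng.random() < 1 / 6
        bundle.families.append(
            FamilySpec(
                parent_name=name,
                parent_smiles=smiles,
                salt_names=salt_names,
                salt_smiles=salts,
                src_ids=[] if research else rng.sample(
                    drug_srcs, rng.randint(1, 2)
                ),
                research_only=research,
            )
        )
    return bundle


FIXTURE_OBO = """format-version: 1.2
ontology: fixture-disease

[Term]
id: FIX:0000001
name: disease

[Term]
id: FIX:0000002
name: cancer
is_a: FIX:0000001 ! disease

[Term]
id: FIX:0000003
name: hematologic malignancies
synonym: "hematologic cancer" EXACT []
is_a: FIX:0000002 ! cancer

[Term]
id: FIX:0000004
name: leukemia
is_a: FIX:0000003 ! hematologic malignancies

[Term]
id: FIX:0000005
name: myeloid leukemia
is_a: FIX:0000004 ! leukemia

[Term]
id: FIX:0000007
name: plasma cell neoplasm
is_a: FIX:0000003 ! hematologic malignancies

[Term]
id: FIX:0000006
name: multiple myeloma
is_a: FIX:0000007 ! plasma cell neoplasm

[Term]
id: FIX:0000008
name: nervous system disease
is_a: FIX:0000001 ! disease

[Term]
id: FIX:0000009
name: fatigue
is_a: FIX:0000008 ! nervous system disease

[Term]
id: FIX:0000010
name: solid tumor
synonym: "unspecified adult solid tumor" EXACT []
is_a: FIX:0000002 ! cancer

[Term]
id: FIX:0000011
name: lung cancer
is_a: FIX:0000010 ! solid tumor

[Term]
id: FIX:0000012
name: small cell lung cancer
is_a: FIX:0000011 ! lung cancer

[Term]
id: FIX:0000013
name: non small cell lung cancer
is_a: FIX:0000011 ! lung cancer

[Term]
id: FIX:0000014
name: bipolar depression
is_a: FIX:0000008 ! nervous system disease

[Term]
id: FIX:0000015
name: seizures
is_a: FIX:0000008 ! nervous system disease

[Term]
id: FIX:0000016
name: endothelial dysfunction
is_a: FIX:0000001 ! disease
"""

FIXTURE_MESH = """# mesh_id\theading\ttree_numbers\tsynonyms
D009369\tNeoplasms\tC04\t
D008545\tMelanoma\tC04.557.465\ttumor melanoma
D007938\tLeukemia\tC04.557.337\t
D007951\tLeukemia, Myeloid\tC04.557.337.539\tmyeloid leukemia
D009101\tMultiple Myeloma\tC04.557.595\tplasma cell myeloma
D005221\tFatigue\tF02.830\t
D003865\tDepressive Disorder, Major\tF03.600.300\tmajor depressive disorder
D012640\tSeizures\tC10.597.742\t
D001424\tBacterial Infections\tC01.252\t
D015595\tSkin Aging\tG13.500\t
C536494\tUveal melanoma\t\tuveal melanoma
"""

#: EFO-like term -> MeSH descriptor equivalences for the fixture ontology.
FIXTURE_EFO_TO_MESH = {
    "FIX:0000004": "D007938",
    "FIX:0000005": "D007951",
    "FIX:0000006": "D009101",
    "FIX:0000007": "D009101",
    "FIX:0000009": "D005221",
    "FIX:0000014": "D003865",
    "FIX:0000015": "D012640",
    # FIX:0000016 (endothelial dysfunction) deliberately has no equivalent
}


def _study(nct: str, stype: str, phases: list[str], interventions: list[str],
           conditions: list[str], update: str) -> dict:
    return {
        "protocolSection": {
            "identificationModule": {"nctId": nct},
            "designModule": {"studyType": stype, "phases": phases},
            "armsInterventionsModule": {
                "interventions": [{"name": n} for n in interventions]
            },
            "conditionsModule": {"conditions": conditions},
            "statusModule": {
                "overallStatus": "Completed",
                "lastUpdatePostDateStruct": {"date": update},
            },
        }
    }


def gen_trials_feed(seed: int, n_trials: int = 12,
                    drug_names: Optional[list[str]] = None) -> list[dict]:
    """Generate a ClinicalTrials.gov v2-style JSON feed.

    Mixes exact-name, partial-name, placebo, non-specific and absent
    interventions; single- and multi-condition trials including descendant
    chains and sub-threshold condition pairs; all phase values including a
    filtered "not applicable" study and an observational study.
    """
    rng = random.Random(seed)
    names = drug_names or [_pseudo_name(rng) + "in" for _ in range(8)]
    conditions_pool = [
        ["leukemia"],
        ["multiple myeloma", "plasma cell neoplasm"],
        ["fatigue", "unspecified adult solid tumor"],
        ["leukemia", "hematologic malignancies", "myeloid leukemia", "cancer"],
        ["non small cell lung cancer"],
        ["seizures"],
    ]
    phases = [["Phase 1"], ["Phase 2"], ["Phase 3"], ["Phase 4"],
              ["Early Phase 1"], ["Phase 1", "Phase 2"], ["Phase 2", "Phase 3"]]
    feed = []
    for i in range(n_trials):
        nct = f"NCT{90000000 + seed % 1000 * 1000 + i:08d}"
        name = rng.choice(names)
        kind = i % 6
        if kind == 0:
            interventions = [name]                       # exact match
        elif kind == 1:
            interventions = [f"{name.title()} 60 mg"]     # partial match
        elif kind == 2:
            interventions = ["Placebo", name]
        elif kind == 3:
            interventions = ["Antibiotics"]               # non-specific
        elif kind == 4:
            interventions = ["zz-unregistered-agent"]     # absent
        else:
            interventions = [name, rng.choice(names)]
        feed.append(
            _study(
                nct,
                "interventional",
                rng.choice(phases),
                interventions,
                rng.choice(conditions_pool),
                f"2024-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
            )
        )
    # always include records that must be filtered out
    feed.append(
        _study(f"NCT{80000000 + seed % 10000:08d}", "interventional",
               ["NA"], [names[0]], ["leukemia"], "2024-06-15")
    )
    feed.append(
        _study(f"NCT{81000000 + seed % 10000:08d}", "observational",
               ["Phase 2"], [names[0]], ["leukemia"], "2024-06-16")
    )
    return feed


def gen_paper_examples() -> FixtureBundle:
    """Reconstruct the worked curation scenarios with expected outcomes.

    The manifest records, for each scenario, the rule outcome the pipeline
    must reproduce: parent aggregation to phase 4, family-wide prodrug
    flags, earliest approval year 1963, three-of-four redundant trial
    conditions, meso chirality code 2, withdrawal eligibility, and the
    availability-type codes.
    """
    bundle = FixtureBundle(seed=0)
    bundle.ontology_obo = FIXTURE_OBO
    bundle.mesh_vocabulary = FIXTURE_MESH
    bundle.efo_to_mesh = dict(FIXTURE_EFO_TO_MESH)
    bundle.intervention_dictionary = {
        "placebo": "NOT_DRUG",
        "antibiotics": "NOT_SPECIFIED_DRUGS",
        "antidepressants": "NOT_SPECIFIED_DRUGS",
        "corticosteroids": "NOT_SPECIFIED_DRUGS",
    }
    bundle.blocklist = ["astat", "siran"]

    # approved salt + phase-1 parent (aggregation scenario)
    bundle.families.append(
        FamilySpec(
            parent_name="mitrelvat",
            parent_smiles=BASE_SMILES[0],
            salt_names=["mitrelvat sulfate"],
            salt_smiles=[BASE_SMILES[0] + ".OS(=O)(=O)O"],
            src_ids=[SRC_FDA_ORANGE_BOOK, SRC_EMA],
        )
    )
    # prodrug family: parent + two salts + research member
    bundle.families.append(
        FamilySpec(
            parent_name="tenovir disoproxil",
            parent_smiles=BASE_SMILES[1],
            salt_names=["tenovir disoproxil fumarate", "tenovir disoproxil mesylate"],
            salt_smiles=[
                BASE_SMILES[1] + ".OC(=O)/C=C/C(=O)O",
                BASE_SMILES[1] + ".CS(=O)(=O)O",
            ],
            src_ids=[SRC_FDA_ORANGE_BOOK],
        )
    )
    # withdrawn-and-reapproved drug (first_approval scenario)
    bundle.families.append(
        FamilySpec(
            parent_name="fenflurine",
            parent_smiles=BASE_SMILES[7],
            salt_names=["fenflurine hydrochloride"],
            salt_smiles=[BASE_SMILES[7] + ".Cl"],
            src_ids=[SRC_FDA_ORANGE_BOOK, SRC_WITHDRAWN],
        )
    )
    bundle.approval_events = {
        "fenflurine hydrochloride": [
            ("FR", 1963, "France"),
            ("FDA", 1973, "United States"),
            ("FDA", 2020, "United States"),
        ],
    }
    bundle.withdrawal_events = {
        "fenflurine hydrochloride": [
            dict(year=1997, region="United States",
                 reason_text="valvular heart disease", all_doses=True,
                 all_populations=True, all_indications=True, basis="safety"),
        ],
    }
    bundle.meso_smiles = "OC(=O)[C@H](O)[C@H](O)C(O)=O"
    bundle.manifest = {
        "parent_aggregated_max_phase": 4.0,
        "prodrug_flag_count": 3,
        "first_approval_year": 1963,
        "redundant_condition_count": 3,
        "kept_condition": "FIX:0000005",
        "meso_chirality": 2,
        "withdrawal_eligible": True,
        "availability_withdrawn_discontinued": -2,
        "availability_ema_only": -1,
        "usan_only_max_phase": 1.0,
        "inn_only_max_phase": 2.0,
        "early_phase1_max_phase": 0.5,
        "veterinary_ema_max_phase": -1.0,
    }
    return bundle


def evaluate_manifest(bundle: FixtureBundle, workdir: str | Path) -> dict:
    """Run the pipeline on a bundle and recompute every manifest quantity.

    Writes the bundle to ``workdir``, executes the full pipeline on the
    generated files, then applies the scenario-specific curation steps
    (prodrug annotation, approval/withdrawal events, chirality of the meso
    input, redundancy flagging of the nested-condition trial) and returns
    the computed values under the same keys as the manifest.
    """
    from drugcure import classifiers, hierarchy
    from drugcure.core import lookup_by_name
    from drugcure.export import run_pipeline
    from drugcure.ontology import load_ontology
    from drugcure.registration import standardize_structure
    from drugcure.trials import ConditionMapping, flag_redundant_conditions, map_condition

    fixture_dir = bundle.write(Path(workdir) / "fixtures")
    config = {
        "source_feed": str(fixture_dir / "source_feed.tsv"),
        "trials": str(fixture_dir / "trials.json"),
        "ontology": str(fixture_dir / "ontology.obo"),
        "efo_to_mesh": str(fixture_dir / "efo_to_mesh.tsv"),
        "dictionary": bundle.intervention_dictionary,
        "blocklist": bundle.blocklist,
    }
    result = run_pipeline(config)
    registry, links = result.registry, result.links
    computed: dict = {}

    # family aggregation: the approved salt lifts its parent to phase 4
    (salt_id,) = lookup_by_name(registry, "mitrelvat sulfate")
    computed["parent_aggregated_max_phase"] = registry.get(
        links[salt_id].parent_molregno
    ).max_phase

    # prodrug propagation across the three drug forms of one family
    (fum_id,) = lookup_by_name(registry, "tenovir disoproxil fumarate")
    registry.get(fum_id).prodrug = 1
    hierarchy.propagate_prodrug(registry, links)
    parent = links[fum_id].parent_molregno
    computed["prodrug_flag_count"] = sum(
        1
        for m, link in links.items()
        if link.parent_molregno == parent and registry.get(m).prodrug == 1
    )

    # earliest approval year across approval/withdrawal/reapproval events
    events = [
        classifiers.ApprovalEvent(agency=a, year=y, region=r)
        for a, y, r in bundle.approval_events["fenflurine hydrochloride"]
    ]
    computed["first_approval_year"] = classifiers.compute_first_approval(events)

    # withdrawal eligibility from the curated event
    w_events = [
        classifiers.WithdrawalEvent(**kw)
        for kw in bundle.withdrawal_events["fenflurine hydrochloride"]
    ]
    eligible, _, _ = classifiers.evaluate_withdrawal(w_events)
    computed["withdrawal_eligible"] = eligible

    # redundancy over the nested four-condition trial
    ontology = load_ontology(str(fixture_dir / "ontology.obo"))
    cmaps = []
    for cond in ["leukemia", "hematologic malignancies", "myeloid leukemia",
                 "cancer"]:
        mapping, _ = map_condition("NCT99999999", cond, ontology)
        cmaps.append(mapping)
    flag_redundant_conditions(cmaps, ontology)
    computed["redundant_condition_count"] = sum(1 for c in cmaps if c.redundant)
    kept = [c.outcome for c in cmaps if not c.redundant]
    computed["kept_condition"] = kept[0] if len(kept) == 1 else None

    # meso chirality
    code, _ = classifiers.assign_chirality(
        standardize_structure(bundle.meso_smiles)
    )
    computed["meso_chirality"] = code

    # availability types
    computed["availability_withdrawn_discontinued"] = (
        classifiers.assign_availability_type(True, "discontinued", eligible, True)
    )
    computed["availability_ema_only"] = classifiers.assign_availability_type(
        False, None, False, True
    )

    # max_phase source rules
    from drugcure.core import SRC_EMA, SRC_INN, SRC_USAN

    computed["usan_only_max_phase"] = classifiers.resolve_max_phase({SRC_USAN})[0]
    computed["inn_only_max_phase"] = classifiers.resolve_max_phase({SRC_INN})[0]
    computed["early_phase1_max_phase"] = classifiers.resolve_max_phase(
        set(), trial_phases=["early_phase1"]
    )[0]
    computed["veterinary_ema_max_phase"] = classifiers.resolve_max_phase(
        {SRC_EMA},
        approvals=[classifiers.ApprovalEvent("EMA", 2019, human_use=False)],
    )[0]
    return computed
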