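"""Trial filtering, intervention/condition mapping, disentanglement,
redundancy flagging and indication derivation."""

import io
from datetime import date

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from drugcure.core import Registry
from drugcure.fixtures import FIXTURE_OBO
from drugcure.ontology import load_ontology
from drugcure.registration import IncomingCompound, register_compound
from drugcure.trials import (
    ABSENT,
    NOT_CONDITION,
    NOT_DRUG,
    NOT_SPECIFIED_DRUGS,
    ConditionMapping,
    InterventionMapping,
    TrialRecord,
    derive_indications,
    disentangle_trial,
    filter_trials,
    flag_redundant_conditions,
    map_condition,
    map_intervention,
    match_normalize,
    parse_trial_feed,
)


@pytest.fixture(scope="module")
def ontology():
    return load_ontology(io.StringIO(FIXTURE_OBO))


@pytest.fixture
def registry():
    reg = Registry()
    for name, smi in [
        ("atorvastatin", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        ("modafinil", "CC(=O)Oc1ccccc1C(=O)O"),
        ("lanoconazole", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ]:
        out = register_compound(
            reg, IncomingCompound(src_id=13, pref_name=name, structure_raw=smi)
        )
        if name == "lanoconazole":
            reg.add_synonym(out.molregno, "astat")
    return reg


def _trial(nct="NCT00000001", stype="interventional", phase="phase2",
           interventions=(), conditions=(), update=date(2024, 6, 1)):
    return TrialRecord(
        nct_id=nct, study_type=stype, phase=phase,
        intervention_names=list(interventions), conditions=list(conditions),
        last_update=update,
    )


class TestFilter:
    def test_observational_dropped(self):
        assert filter_trials([_trial(stype="observational")]) == []

    def test_not_applicable_phase_dropped(self):
        assert filter_trials([_trial(phase="not_applicable")]) == []

    def test_interventional_in_window_kept(self):
        window = (date(2024, 1, 1), date(2024, 12, 31))
        assert len(filter_trials([_trial()], window)) == 1

    def test_out_of_window_dropped(self):
        window = (date(2023, 1, 1), date(2023, 12, 31))
        assert filter_trials([_trial()], window) == []

    def test_feed_parsing_round_trip(self):
        from drugcure.fixtures import gen_trials_feed

        feed = gen_trials_feed(3, 6, ["drugone"])
        records = parse_trial_feed(feed)
        assert len(records) == 8  # 6 + the two always-filtered studies
        kept = filter_trials(records)
        assert all(t.study_type == "interventional" for t in kept)
        assert all(t.phase != "not_applicable" for t in kept)


class TestInterventionMapping:
    def test_exact_name_auto_maps(self, registry):
        mapping, cands = map_intervention("NCT1", "Modafinil", registry)
        assert isinstance(mapping.outcome, int)
        assert mapping.method == "exact_auto"
        assert cands == []

    def test_blocked_substring_excluded_but_valid_candidate_kept(self, registry):
        """'astat' (a synonym that would substring-match 'Atorvastatin') is
        blocklisted; 'atorvastatin' itself remains a candidate."""
        mapping, cands = map_intervention(
            "NCT1", "Atorvastatin 60 mg", registry, blocklist=["astat"]
        )
        assert mapping.outcome == ABSENT  # partial matches never auto-assign
        names = [n for n, _ in cands]
        assert "atorvastatin" in names
        assert "astat" not in names

    def test_placebo_via_dictionary(self, registry):
        mapping, _ = map_intervention(
            "NCT1", "Placebo", registry, dictionary={"placebo": NOT_DRUG}
        )
        assert mapping.outcome == NOT_DRUG and mapping.method == "dictionary"

    def test_nonspecific_class_name(self, registry):
        mapping, _ = map_intervention(
            "NCT1", "Antibiotics", registry,
            dictionary={"antibiotics": NOT_SPECIFIED_DRUGS},
        )
        assert mapping.outcome == NOT_SPECIFIED_DRUGS

    def test_not_for_automatic_mapping_entry_skipped(self, registry):
        mapping, _ = map_intervention(
            "NCT1", "study drug", registry,
            dictionary={"study drug": (1, True)},
        )
        assert mapping.outcome == ABSENT

    @settings(deadline=None, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.text(alphabet="abcdefgh in60mg", min_size=0, max_size=40))
    def test_candidates_equal_brute_force_scan(self, registry, text):
        """Candidate generation equals scanning every registry name of
        length >= 4 for substring occurrence in the normalized text."""
        mapping, cands = map_intervention("NCT1", text, registry)
        if mapping.outcome != ABSENT:
            return  # exact match short-circuits candidate generation
        norm = match_normalize(text)
        expected = {
            (match_normalize(n), m)
            for n, m in registry.iter_names()
            if len(match_normalize(n)) >= 4 and match_normalize(n) in norm
        }
        assert set(cands) == expected


class TestConditionMapping:
    def test_exact_name_auto_maps(self, ontology):
        mapping, _ = map_condition("NCT1", "Leukemia", ontology)
        assert mapping.outcome == "FIX:0000004"

    def test_substring_never_auto_maps(self, ontology):
        """'non small cell lung cancer' is an exact term here; but a text
        containing 'small cell lung cancer' as a fragment must not
        auto-map to the fragment term."""
        mapping, cands = map_condition(
            "NCT1", "advanced small cell lung cancer stage III", ontology
        )
        assert mapping.outcome == ABSENT
        assert any(t == "FIX:0000012" for _, t in cands)

    def test_exact_full_string_wins_over_fragment(self, ontology):
        mapping, _ = map_condition("NCT1", "non small cell lung cancer", ontology)
        assert mapping.outcome == "FIX:0000013"

    def test_not_condition_via_dictionary(self, ontology):
        mapping, _ = map_condition(
            "NCT1", "Colonoscopy", ontology,
            dictionary={"colonoscopy": NOT_CONDITION},
        )
        assert mapping.outcome == NOT_CONDITION


class TestDisentangle:
    def test_similar_conditions_all_confirmed(self, ontology):
        """Two sibling conditions above the similarity threshold are both
        confirmed for the trial's drugs."""
        trial = _trial(conditions=["multiple myeloma", "plasma cell neoplasm"])
        imaps = [InterventionMapping(trial.nct_id, "d", 1)]
        cmaps = [
            ConditionMapping(trial.nct_id, "multiple myeloma", "FIX:0000006"),
            ConditionMapping(trial.nct_id, "plasma cell neoplasm", "FIX:0000007"),
        ]
        sim = ontology.similarity("FIX:0000006", "FIX:0000007")
        assert sim >= 0.85  # fixture built so the siblings clear threshold
        updated, queued = disentangle_trial(trial, imaps, cmaps, ontology)
        assert not queued
        assert all(c.is_indication == 1 for c in updated)

    def test_dissimilar_conditions_queued(self, ontology):
        trial = _trial(conditions=["fatigue", "solid tumor"])
        imaps = [InterventionMapping(trial.nct_id, "d", 1)]
        cmaps = [
            ConditionMapping(trial.nct_id, "fatigue", "FIX:0000009"),
            ConditionMapping(trial.nct_id, "solid tumor", "FIX:0000010"),
        ]
        assert ontology.similarity("FIX:0000009", "FIX:0000010") < 0.85
        updated, queued = disentangle_trial(trial, imaps, cmaps, ontology)
        assert queued
        assert all(c.is_indication == 0 for c in updated)

    def test_one_condition_three_drugs(self, ontology):
        trial = _trial(conditions=["leukemia"])
        imaps = [InterventionMapping(trial.nct_id, f"d{i}", i) for i in (1, 2, 3)]
        cmaps = [ConditionMapping(trial.nct_id, "leukemia", "FIX:0000004")]
        updated, queued = disentangle_trial(trial, imaps, cmaps, ontology)
        assert not queued and updated[0].is_indication == 1
        rows = derive_indications(
            [trial], imaps, updated, {"FIX:0000004": "D007938"}
        )
        assert len(rows) == 3  # one (drug, condition) pair per drug


class TestRedundancy:
    def test_three_of_four_nested_conditions_redundant(self, ontology):
        """Leukemia / hematologic malignancies / myeloid leukemia / cancer:
        the deepest term survives, the three ancestors are redundant."""
        cmaps = [
            ConditionMapping("NCT1", "leukemia", "FIX:0000004"),
            ConditionMapping("NCT1", "hematologic malignancies", "FIX:0000003"),
            ConditionMapping("NCT1", "myeloid leukemia", "FIX:0000005"),
            ConditionMapping("NCT1", "cancer", "FIX:0000002"),
        ]
        flag_redundant_conditions(cmaps, ontology)
        redundant = [c for c in cmaps if c.redundant]
        kept = [c for c in cmaps if not c.redundant]
        assert len(redundant) == 3
        assert [c.outcome for c in kept] == ["FIX:0000005"]

    def test_unrelated_conditions_not_redundant(self, ontology):
        cmaps = [
            ConditionMapping("NCT1", "fatigue", "FIX:0000009"),
            ConditionMapping("NCT1", "leukemia", "FIX:0000004"),
        ]
        flag_redundant_conditions(cmaps, ontology)
        assert not any(c.redundant for c in cmaps)

    def test_matches_all_pairs_ancestor_oracle(self, ontology):
        import itertools

        terms = ["FIX:0000002", "FIX:0000003", "FIX:0000004", "FIX:0000005",
                 "FIX:0000010", "FIX:0000011"]
        cmaps = [ConditionMapping("NCT1", t, t) for t in terms]
        flag_redundant_conditions(cmaps, ontology)
        for c in cmaps:
            expected = any(
                other != c.outcome and c.outcome != other
                and other in ontology.descendants(c.outcome)
                for other in terms
            )
            assert c.redundant == expected
        assert not all(c.redundant for c in cmaps)


class TestDeriveIndications:
    E2M = {"FIX:0000004": "D007938", "FIX:0000014": "D003865"}

    def test_phase4_without_approval_dropped(self):
        trial = _trial(phase="phase4", conditions=["bipolar depression"])
        imaps = [InterventionMapping(trial.nct_id, "oxc", 7)]
        cmaps = [ConditionMapping(trial.nct_id, "bipolar depression",
                                  "FIX:0000014", is_indication=1)]
        rows = derive_indications([trial], imaps, cmaps, self.E2M)
        assert rows == []

    def test_phase4_with_approval_kept(self):
        trial = _trial(phase="phase4", conditions=["bipolar depression"])
        imaps = [InterventionMapping(trial.nct_id, "oxc", 7)]
        cmaps = [ConditionMapping(trial.nct_id, "bipolar depression",
                                  "FIX:0000014", is_indication=1)]
        rows = derive_indications(
            [trial], imaps, cmaps, self.E2M,
            regulatory_approved_pairs=[(7, "FIX:0000014")],
        )
        assert len(rows) == 1 and rows[0].max_phase_for_ind == 4.0

    def test_no_mesh_equivalent_dropped(self):
        """A condition with no MeSH equivalent cannot be incorporated."""
        trial = _trial(conditions=["endothelial dysfunction"])
        imaps = [InterventionMapping(trial.nct_id, "poli", 9)]
        cmaps = [ConditionMapping(trial.nct_id, "endothelial dysfunction",
                                  "FIX:0000016", is_indication=1)]
        rows = derive_indications([trial], imaps, cmaps, self.E2M)
        assert rows == []

    def test_duplicate_pairs_collapse_to_max_phase(self):
        t2 = _trial(nct="NCT00000002", phase="phase2", conditions=["leukemia"])
        t3 = _trial(nct="NCT00000003", phase="phase3", conditions=["leukemia"])
        imaps = [InterventionMapping(t.nct_id, "d", 5) for t in (t2, t3)]
        cmaps = [ConditionMapping(t.nct_id, "leukemia", "FIX:0000004",
                                  is_indication=1) for t in (t2, t3)]
        rows = derive_indications([t2, t3], imaps, cmaps, self.E2M)
        assert len(rows) == 1
        assert rows[0].max_phase_for_ind == 3.0
        assert set(rows[0].nct_ids) == {"NCT00000002", "NCT00000003"}

    def test_redundant_conditions_excluded(self):
        trial = _trial(conditions=["leukemia"])
        imaps = [InterventionMapping(trial.nct_id, "d", 5)]
        cmaps = [ConditionMapping(trial.nct_id, "leukemia", "FIX:0000004",
                                  is_indication=1, redundant=True)]
        assert derive_indications([trial], imaps, cmaps, self.E2M) == []
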