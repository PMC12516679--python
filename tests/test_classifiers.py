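"""Rule-based drug-property annotations."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from drugcure.classifiers import (
    ApprovalEvent,
    WithdrawalEvent,
    assign_availability_type,
    assign_chirality,
    assign_molecule_type,
    assign_therapeutic_flag,
    choose_pref_name,
    compute_first_approval,
    compute_inorganic_flag,
    compute_polymer_flag,
    evaluate_withdrawal,
    map_usan_stem,
    resolve_max_phase,
    validate_usan_year,
)
from drugcure.core import (
    SRC_ATC,
    SRC_EMA,
    SRC_FDA_ORANGE_BOOK,
    SRC_INN,
    SRC_USAN,
    SRC_WITHDRAWN,
)
from drugcure.registration import standardize_structure


class TestPrefName:
    def test_approved_takes_regulator_name(self):
        name = choose_pref_name([("FDA", "X mesylate"), ("USAN", "X")], approved=True)
        assert name == "X mesylate"

    def test_unapproved_usan_beats_inn(self):
        assert choose_pref_name([("INN", "y"), ("USAN", "z")], approved=False) == "z"

    def test_greek_letters_written_out(self):
        assert "alpha" in choose_pref_name([("USAN", "interferon α")], approved=False)

    def test_empty_sources_raise(self):
        with pytest.raises(ValueError):
            choose_pref_name([], approved=False)


class TestMoleculeType:
    @pytest.mark.parametrize(
        "name,expected",
        [("vofatamab", "antibody"), ("ranpirnase", "enzyme")],
    )
    def test_suffix_rules_for_structureless_biologics(self, name, expected):
        category, review = assign_molecule_type(name, None)
        assert category == expected and not review

    def test_structured_default_small_molecule(self):
        rec = standardize_structure("CC(=O)Oc1ccccc1C(=O)O")
        category, review = assign_molecule_type("asprinol", rec)
        assert category == "small molecule"

    def test_no_evidence_unknown(self):
        category, _ = assign_molecule_type("plainname", None)
        assert category == "unknown"


class TestInorganicFlag:
    def test_elemental_iron_true(self):
        assert compute_inorganic_flag(standardize_structure("[Fe]")) is True

    def test_water_false(self):
        assert compute_inorganic_flag(standardize_structure("O")) is False

    @pytest.mark.parametrize("smiles", [
        "[Na+].[Cl-]", "O=[Ti]=O", "[Au]", "[Li+].[Li+].O=C([O-])[O-]",
        "c1ccccc1", "N", "S", "[Pt]",
    ])
    def test_agrees_with_element_set_oracle(self, smiles):
        """Oracle: explicit element-set intersection with the organic list."""
        from rdkit import Chem

        rec = standardize_structure(smiles)
        mol = Chem.AddHs(Chem.MolFromSmiles(rec.canonical_smiles))
        elements = {a.GetSymbol() for a in mol.GetAtoms()}
        organic = {"H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
        assert compute_inorganic_flag(rec) == (not (elements & organic))


class TestPolymerFlag:
    def test_name_keyword(self):
        assert compute_polymer_flag("poly(ethylene glycol) 3350", None) is True

    def test_aspirin_false(self):
        rec = standardize_structure("CC(=O)Oc1ccccc1C(=O)O")
        assert compute_polymer_flag("aspirin", rec) is False

    def test_repeat_unit_substructure_hit(self):
        rec = standardize_structure("COCCOCCOCCOCCOC")
        assert compute_polymer_flag("macrogol-like", rec) is True


class TestChirality:
    def test_meso_structure_is_achiral(self):
        """Two stereocenters, superimposable mirror image -> category 2."""
        rec = standardize_structure("OC(=O)[C@H](O)[C@H](O)C(O)=O")
        code, _ = assign_chirality(rec)
        assert code == 2

    def test_fully_specified_single_enantiomer(self):
        rec = standardize_structure("C[C@H](N)C(=O)O")  # L-alanine-like
        code, _ = assign_chirality(rec)
        assert code == 1

    def test_undrawn_stereocenters_are_mixture(self):
        """Two stereocenters with no stereobonds drawn -> category 0."""
        rec = standardize_structure("OC(=O)C(O)C(O)c1ccccc1")
        code, _ = assign_chirality(rec)
        assert code == 0

    def test_no_stereocenters_achiral(self):
        code, _ = assign_chirality(standardize_structure("c1ccccc1"))
        assert code == 2

    def test_structureless_biotherapeutic_single_stereoisomer(self):
        code, _ = assign_chirality(None, "rasburicase", is_biotherapeutic=True)
        assert code == 1

    def test_no_structure_no_biologic_unknown(self):
        code, _ = assign_chirality(None, "mystery")
        assert code == -1

    def test_name_pattern_only_annotates(self):
        rec = standardize_structure("C[C@H](N)C(=O)O")
        code, notes = assign_chirality(rec, name="(±)-something")
        assert code == 1  # structure decides; name only adds a note
        assert notes


class TestTherapeuticFlag:
    def test_therapeutic_indication(self):
        flag, hits = assign_therapeutic_flag("indicated for colorectal neoplasms")
        assert flag is True and not hits

    def test_diagnostic_phrases_clear_flag(self):
        flag, hits = assign_therapeutic_flag(
            "radioactive diagnostic agent used in gamma imaging"
        )
        assert flag is False and hits

    def test_empty_text_defaults_true(self):
        assert assign_therapeutic_flag("")[0] is True


class TestMaxPhase:
    def test_usan_only_is_phase_1(self):
        phase, _ = resolve_max_phase({SRC_USAN})
        assert phase == 1.0

    def test_inn_only_is_phase_2(self):
        phase, _ = resolve_max_phase({SRC_INN})
        assert phase == 2.0

    def test_early_phase1_trial_is_0_5(self):
        phase, _ = resolve_max_phase(set(), trial_phases=["early_phase1"])
        assert phase == 0.5

    def test_veterinary_only_ema_is_unknown(self):
        phase, _ = resolve_max_phase(
            {SRC_EMA}, approvals=[ApprovalEvent("EMA", 2019, human_use=False)]
        )
        assert phase == -1.0

    def test_orange_book_is_phase_4(self):
        phase, _ = resolve_max_phase({SRC_FDA_ORANGE_BOOK})
        assert phase == 4.0

    def test_atc_without_other_regulatory_is_phase_4(self):
        phase, _ = resolve_max_phase({SRC_ATC})
        assert phase == 4.0

    def test_atc_with_family_ema_defers(self):
        """An ATC-listed parent whose family holds an EMA source gets no
        automatic 4 from the ATC rule; evidence decides."""
        phase, _ = resolve_max_phase({SRC_ATC}, family_sources={SRC_EMA})
        assert phase == -1.0

    def test_phase4_trial_alone_gives_3_with_review(self):
        phase, review = resolve_max_phase(set(), trial_phases=["phase4"])
        assert phase == 3.0 and review

    def test_no_evidence_is_null(self):
        phase, _ = resolve_max_phase(set())
        assert phase is None

    @settings(deadline=None, max_examples=40)
    @given(st.permutations(["phase3", "phase1", "early_phase1", "phase2_3"]))
    def test_order_invariance(self, phases):
        base, _ = resolve_max_phase(set(), trial_phases=sorted(phases))
        shuffled, _ = resolve_max_phase(set(), trial_phases=list(phases))
        assert base == shuffled


class TestAvailability:
    def test_withdrawn_discontinued_is_minus_2(self):
        assert assign_availability_type(True, "discontinued", True, True) == -2

    def test_ema_only_prescription_unknown(self):
        assert assign_availability_type(False, None, False, True) == -1

    def test_withdrawn_elsewhere_keeps_marketing_code(self):
        """Withdrawn in one region but still an Orange Book prescription
        drug keeps code 1."""
        assert assign_availability_type(True, "rx", True, True) == 1

    def test_research_compound_null(self):
        assert assign_availability_type(False, None, False, False) is None

    def test_total_over_input_cross_product(self):
        """The function is total: every input combination yields a value in
        the documented code set."""
        codes = {2, 1, 0, -1, -2, None}
        for ob, status, wd, has in itertools.product(
            [True, False], ["otc", "rx", "discontinued", None],
            [True, False], [True, False],
        ):
            assert assign_availability_type(ob, status, wd, has) in codes


def _event(**kw):
    defaults = dict(year=2003, region="Canada", all_doses=True,
                    all_populations=True, all_indications=True, basis="safety")
    defaults.update(kw)
    return WithdrawalEvent(**defaults)


class TestWithdrawal:
    def test_single_region_safety_withdrawal_eligible(self):
        eligible, year, countries = evaluate_withdrawal([_event()])
        assert eligible and year == 2003 and countries == ["Canada"]

    def test_not_all_indications_ineligible(self):
        assert evaluate_withdrawal([_event(all_indications=False)])[0] is False

    def test_efficacy_basis_never_qualifies(self):
        assert evaluate_withdrawal([_event(basis="efficacy")])[0] is False

    def test_suspension_needs_corroboration(self):
        assert evaluate_withdrawal([_event(basis="suspended")])[0] is False
        assert evaluate_withdrawal(
            [_event(basis="suspended", corroborated=True)]
        )[0] is True

    def test_drug_interaction_safety_qualifies(self):
        assert evaluate_withdrawal(
            [_event(basis="drug_interaction_safety")]
        )[0] is True

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(1950, 2024), min_size=1, max_size=6))
    def test_all_efficacy_lists_never_eligible(self, years):
        events = [_event(year=y, basis="efficacy") for y in years]
        assert evaluate_withdrawal(events)[0] is False


class TestApprovalYears:
    def test_earliest_year_survives_withdrawal_and_reapproval(self):
        """France 1963, US 1973, reapproval 2020 -> 1963."""
        approvals = [
            ApprovalEvent("FR", 1963, "France"),
            ApprovalEvent("FDA", 1973, "United States"),
            ApprovalEvent("FDA", 2020, "United States"),
        ]
        assert compute_first_approval(approvals) == 1963

    def test_no_approvals_none(self):
        assert compute_first_approval([]) is None

    def test_single_event(self):
        assert compute_first_approval([ApprovalEvent("EMA", 2011)]) == 2011

    def test_veterinary_approvals_ignored(self):
        assert compute_first_approval(
            [ApprovalEvent("EMA", 1990, human_use=False)]
        ) is None

    @pytest.mark.parametrize(
        "usan,approval,warns",
        [(2015, 2018, False), (2019, 2018, True), (None, 2018, False),
         (2015, None, False)],
    )
    def test_usan_year_validation(self, usan, approval, warns):
        warning = validate_usan_year(usan, approval)
        assert (warning is not None) == warns


class TestUsanStem:
    def test_tide_suffix_is_peptide_stem(self):
        result = map_usan_stem("teriparatide")
        assert result is not None
        stem, _, definition = result
        assert stem == "-tide" and "peptide" in definition

    def test_no_stem_none(self):
        assert map_usan_stem("xyzzyplugh") is None

    def test_longest_match_wins(self):
        """Oracle: enumerate all matching stems and take the longest."""
        from drugcure.classifiers import load_usan_stems

        name = "trametinib"  # matches both -tinib and -metinib
        stems = load_usan_stems()
        matching = [s for s in stems
                    if s.kind == "suffix" and name.endswith(s.core)]
        assert len(matching) >= 2
        best = max(matching, key=lambda s: len(s.core))
        assert map_usan_stem(name, stems)[0] == best.stem == "-metinib"
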