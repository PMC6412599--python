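import dataclasses

import pytest

from adviceaudit.rulesets import (
    DecisionNode,
    Edge,
    GuidelineRuleset,
    RulesetEvaluationError,
    build_dutch_tree,
    derive_stage,
    dutch_advice,
    evaluate_ruleset,
    is_high_risk_stage_ii,
    load_nccn_template,
    load_ruleset,
    save_ruleset,
    validate_ruleset,
)
from adviceaudit.types import (
    AdviceCategory,
    Differentiation,
    MsiStatus,
    NodesExamined,
    PNStage,
    PTStage,
    Stage,
    TreatmentAdvice,
    default_catalogue,
)

from conftest import make_case

R, C, NR = AdviceCategory.R, AdviceCategory.C, AdviceCategory.NR

CHEMO_CODES = ("CAPE_MONO", "FU_LV_MONO", "CAPOX", "FOLFOX", "OTHER_SYSTEMIC")


class TestDeriveStage:
    @pytest.mark.parametrize(
        "pt, pn, expected",
        [
            (PTStage.T2, PNStage.N0, Stage.I),
            (PTStage.T1, PNStage.N0, Stage.I),
            (PTStage.T3, PNStage.N0, Stage.II),
            (PTStage.T4, PNStage.N0, Stage.II),
            (PTStage.T1, PNStage.N2, Stage.III),
            (PTStage.T4, PNStage.N1, Stage.III),
        ],
    )
    def test_tnm_mapping(self, pt, pn, expected):
        assert derive_stage(make_case(pt_stage=pt, pn_stage=pn)) is expected

    def test_total_partition_over_factorial(self, factorial_cases):
        stages = {derive_stage(c) for c in factorial_cases}
        assert stages == set(Stage)


class TestHighRiskStageII:
    def test_pt4_is_high_risk(self):
        assert is_high_risk_stage_ii(make_case(pt_stage=PTStage.T4))

    def test_no_features_is_low_risk(self):
        assert not is_high_risk_stage_ii(make_case())

    def test_few_nodes_examined_is_high_risk(self):
        assert is_high_risk_stage_ii(make_case(nodes_examined=NodesExamined.LT10))

    @pytest.mark.parametrize(
        "override",
        [
            {"differentiation": Differentiation.POOR_UNDIFF},
            {"vascular_invasion": True},
            {"obstruction_or_perforation": True},
        ],
    )
    def test_each_single_feature_is_high_risk(self, override):
        assert is_high_risk_stage_ii(make_case(**override))

    def test_rejects_non_stage_ii(self):
        with pytest.raises(ValueError, match="stage-II"):
            is_high_risk_stage_ii(make_case(pn_stage=PNStage.N1))


def advice_dict(advice: TreatmentAdvice) -> dict:
    return {code: cat for code, cat in advice.items}


class TestDutchAdvice:
    def test_stage_i_observation_only(self):
        advice = advice_dict(dutch_advice(make_case(pt_stage=PTStage.T1)))
        assert advice["OBSERVATION"] is R
        assert all(advice[code] is NR for code in CHEMO_CODES)

    def test_stage_ii_low_risk_observation_only(self):
        advice = advice_dict(dutch_advice(make_case()))
        assert advice["OBSERVATION"] is R
        assert all(advice[code] is NR for code in CHEMO_CODES)

    def test_stage_ii_high_risk_mss_doublets_considered(self):
        advice = advice_dict(dutch_advice(make_case(pt_stage=PTStage.T4)))
        assert advice["OBSERVATION"] is R
        assert advice["CAPOX"] is C and advice["FOLFOX"] is C
        assert advice["CAPE_MONO"] is NR and advice["FU_LV_MONO"] is NR
        assert advice["OTHER_SYSTEMIC"] is NR

    def test_stage_ii_high_risk_msi_observation_only(self):
        advice = advice_dict(
            dutch_advice(make_case(pt_stage=PTStage.T4, msi_status=MsiStatus.MSI))
        )
        assert advice["OBSERVATION"] is R
        assert all(advice[code] is NR for code in CHEMO_CODES)

    def test_stage_ii_high_risk_contraindicated_observation_only(self):
        advice = advice_dict(
            dutch_advice(make_case(pt_stage=PTStage.T4, oxaliplatin_contraindicated=True))
        )
        assert advice["OBSERVATION"] is R
        assert all(advice[code] is NR for code in CHEMO_CODES)

    def test_stage_iii_doublets_recommended(self):
        advice = advice_dict(dutch_advice(make_case(pn_stage=PNStage.N1)))
        assert advice["CAPOX"] is R and advice["FOLFOX"] is R
        assert advice["OBSERVATION"] is NR
        assert advice["CAPE_MONO"] is NR and advice["FU_LV_MONO"] is NR

    def test_stage_iii_contraindicated_mss_monotherapy(self):
        advice = advice_dict(
            dutch_advice(
                make_case(pn_stage=PNStage.N2, oxaliplatin_contraindicated=True)
            )
        )
        assert advice["CAPE_MONO"] is R and advice["FU_LV_MONO"] is R
        assert advice["CAPOX"] is NR and advice["FOLFOX"] is NR
        assert advice["OBSERVATION"] is NR

    def test_stage_iii_contraindicated_msi_no_chemo(self):
        advice = advice_dict(
            dutch_advice(
                make_case(
                    pn_stage=PNStage.N1,
                    oxaliplatin_contraindicated=True,
                    msi_status=MsiStatus.MSI,
                )
            )
        )
        assert advice["OBSERVATION"] is R
        assert all(advice[code] is NR for code in CHEMO_CODES)

    def test_totality_over_factorial(self, factorial_cases, catalogue):
        assert all(
            dutch_advice(case).is_total_over(catalogue) for case in factorial_cases
        )

    def test_age_does_not_alter_advice(self):
        young = dutch_advice(make_case(age=45, pt_stage=PTStage.T4))
        old = dutch_advice(make_case(age=75, pt_stage=PTStage.T4))
        assert young.items == old.items

    @pytest.mark.parametrize(
        "feature",
        [
            {"pt_stage": PTStage.T4},
            {"nodes_examined": NodesExamined.LT10},
            {"differentiation": Differentiation.POOR_UNDIFF},
            {"vascular_invasion": True},
            {"obstruction_or_perforation": True},
        ],
    )
    def test_monotone_risk(self, feature):
        """Adding one high-risk feature to a stage-II MSS case never demotes
        a chemotherapy option from C/R to NR."""
        rank = {NR: 0, C: 1, R: 2}
        base = advice_dict(dutch_advice(make_case()))
        risky = advice_dict(dutch_advice(make_case(**feature)))
        for code in CHEMO_CODES:
            assert rank[risky[code]] >= rank[base[code]]


def _single_leaf_tree(catalogue) -> GuidelineRuleset:
    advice = TreatmentAdvice.of({"OBSERVATION": R}, catalogue)
    return GuidelineRuleset(name="degenerate", root="leaf", nodes={}, leaves={"leaf": advice})


class TestEvaluateRuleset:
    def test_single_leaf_tree_returns_its_advice(self, catalogue):
        tree = _single_leaf_tree(catalogue)
        result = evaluate_ruleset(tree, make_case())
        assert result == tree.leaves["leaf"]

    def test_missing_branch_raises_defect_error(self, catalogue):
        advice = TreatmentAdvice.of({}, catalogue)
        tree = GuidelineRuleset(
            name="gappy",
            root="n0",
            nodes={
                "n0": DecisionNode(
                    "n0", "msi_status", (Edge((MsiStatus.MSS,), "leaf"),)
                )
            },
            leaves={"leaf": advice},
        )
        with pytest.raises(RulesetEvaluationError, match="no edge"):
            evaluate_ruleset(tree, make_case(msi_status=MsiStatus.MSI))

    def test_packaged_tree_equals_oracle_everywhere(self, dutch_tree, factorial_cases):
        for case in factorial_cases:
            assert evaluate_ruleset(dutch_tree, case).items == dutch_advice(case).items


class TestValidateRuleset:
    def test_packaged_dutch_tree_is_clean(self, dutch_tree):
        assert validate_ruleset(dutch_tree) == []

    def test_built_tree_is_clean(self):
        assert validate_ruleset(build_dutch_tree()) == []

    def test_nccn_template_is_clean(self):
        assert validate_ruleset(load_nccn_template()) == []

    def test_overlap_defect(self, catalogue):
        advice = TreatmentAdvice.of({}, catalogue)
        tree = GuidelineRuleset(
            name="overlapping",
            root="n0",
            nodes={
                "n0": DecisionNode(
                    "n0",
                    "msi_status",
                    (
                        Edge((MsiStatus.MSS, MsiStatus.MSI), "leaf"),
                        Edge((MsiStatus.MSI,), "leaf"),
                    ),
                )
            },
            leaves={"leaf": advice},
        )
        kinds = [d.kind for d in validate_ruleset(tree)]
        assert kinds == ["overlap"]

    def test_gap_defect(self, catalogue):
        advice = TreatmentAdvice.of({}, catalogue)
        tree = GuidelineRuleset(
            name="gappy",
            root="n0",
            nodes={
                "n0": DecisionNode("n0", "msi_status", (Edge((MsiStatus.MSS,), "leaf"),))
            },
            leaves={"leaf": advice},
        )
        defects = validate_ruleset(tree)
        assert [d.kind for d in defects] == ["gap"]
        assert "MSI" in defects[0].detail

    def test_cycle_defect(self, catalogue):
        tree = GuidelineRuleset(
            name="cyclic",
            root="n0",
            nodes={
                "n0": DecisionNode(
                    "n0", "vascular_invasion",
                    (Edge((False,), "n1"), Edge((True,), "n1")),
                ),
                "n1": DecisionNode(
                    "n1", "perineural_invasion",
                    (Edge((False,), "n0"), Edge((True,), "n0")),
                ),
            },
            leaves={},
        )
        assert any(d.kind == "cycle" for d in validate_ruleset(tree))

    def test_dangling_target_defect(self, catalogue):
        tree = GuidelineRuleset(
            name="dangling",
            root="n0",
            nodes={
                "n0": DecisionNode(
                    "n0", "vascular_invasion",
                    (Edge((False,), "nowhere"), Edge((True,), "nowhere")),
                )
            },
            leaves={},
        )
        assert any(d.kind == "dangling" for d in validate_ruleset(tree))

    def test_continuous_field_node_is_bad_field(self, catalogue):
        advice = TreatmentAdvice.of({}, catalogue)
        tree = GuidelineRuleset(
            name="age-branching",
            root="n0",
            nodes={"n0": DecisionNode("n0", "age", (Edge((45,), "leaf"),))},
            leaves={"leaf": advice},
        )
        assert any(d.kind == "bad-field" for d in validate_ruleset(tree))


class TestRulesetIO:
    def test_json_round_trip(self, tmp_path, dutch_tree, factorial_cases):
        path = tmp_path / "tree.json"
        save_ruleset(dutch_tree, path)
        loaded = load_ruleset(path)
        assert loaded.name == dutch_tree.name
        for case in factorial_cases[:64]:
            assert evaluate_ruleset(loaded, case) == evaluate_ruleset(dutch_tree, case)

    def test_loading_invalid_tree_raises(self, tmp_path, catalogue):
        tree = GuidelineRuleset(
            name="gappy",
            root="n0",
            nodes={
                "n0": DecisionNode("n0", "msi_status", (Edge((MsiStatus.MSS,), "leaf"),))
            },
            leaves={"leaf": TreatmentAdvice.of({}, catalogue)},
        )
        path = tmp_path / "bad.json"
        save_ruleset(tree, path)
        import adviceaudit.types as t

        with pytest.raises(t.FormatError, match="gap"):
            load_ruleset(path)

    def test_nccn_template_is_distinct_file(self, dutch_tree):
        template = load_nccn_template()
        assert template.name != dutch_tree.name
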