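import pytest

from adviceaudit.types import (
    Differentiation,
    MsiStatus,
    NodesExamined,
    PatientCase,
    PNStage,
    PTStage,
    ResectionMargin,
)


BASE_CASE_KWARGS = dict(
    case_id="case_0001",
    age=60,
    functional_status=0,
    pt_stage=PTStage.T3,
    pn_stage=PNStage.N0,
    nodes_examined=NodesExamined.GE10,
    differentiation=Differentiation.WELL_MODERATE,
    vascular_invasion=False,
    obstruction_or_perforation=False,
    msi_status=MsiStatus.MSS,
    oxaliplatin_contraindicated=False,
    serious_liver_disease=False,
    serious_kidney_disease=False,
    resection_margin=ResectionMargin.NEGATIVE,
    perineural_invasion=False,
)


def make_case(**overrides) -> PatientCase:
    """A valid stage-II non-high-risk case, with overrides."""
    kwargs = dict(BASE_CASE_KWARGS)
    kwargs.update(overrides)
    return PatientCase(**kwargs)


@pytest.fixture
def case_factory():
    return make_case


@pytest.fixture
def catalogue():
    from adviceaudit.types import default_catalogue

    return default_catalogue()


@pytest.fixture
def matrix():
    from adviceaudit.concordance import default_matrix

    return default_matrix()


@pytest.fixture(scope="session")
def dutch_tree():
    from adviceaudit.rulesets import load_dutch_tree

    return load_dutch_tree()


@pytest.fixture(scope="session")
def factorial_cases():
    """The 9216 cases of the default FULL_FACTORIAL plan (session-cached)."""
    from adviceaudit.casegen import default_plan, enumerate_cases

    return enumerate_cases(default_plan())
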