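"""Declarative guideline decision trees plus the hard-coded Dutch oracle.

Two independent routes produce guideline advice:

* :func:`dutch_advice` — a hard-coded implementation of the Dutch adjuvant
  colon-cancer rules (stage I observation, high-risk stage II with MSS and
  no oxaliplatin contraindication, stage III doublets with a monotherapy
  fallback).
* :func:`evaluate_ruleset` — a generic interpreter for declarative
  :class:`GuidelineRuleset` trees loaded from JSON; the packaged Dutch tree
  must agree with the oracle case-by-case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .types import (
    AdviceCategory,
    AdviceSource,
    Catalogue,
    Differentiation,
    FIELD_DOMAINS,
    FormatError,
    MsiStatus,
    NodesExamined,
    PatientCase,
    PNStage,
    PTStage,
    Stage,
    TreatmentAdvice,
    default_catalogue,
    value_from_str,
    value_to_str,
)

__all__ = [
    "DecisionNode",
    "Edge",
    "GuidelineRuleset",
    "RulesetDefect",
    "RulesetEvaluationError",
    "derive_stage",
    "is_high_risk_stage_ii",
    "dutch_advice",
    "evaluate_ruleset",
    "validate_ruleset",
    "build_dutch_tree",
    "load_dutch_tree",
    "load_ruleset",
    "save_ruleset",
]


def derive_stage(case: PatientCase) -> Stage:
    """TNM stage group: node-positive = III, else T1/T2 = I, T3/T4 = II."""
    if case.pn_stage in (PNStage.N1, PNStage.N2):
        return Stage.III
    if case.pt_stage in (PTStage.T1, PTStage.T2):
        return Stage.I
    return Stage.II


def is_high_risk_stage_ii(case: PatientCase) -> bool:
    """True iff a stage-II case carries at least one high-risk feature.

    High-risk features: pT4 tumor, fewer than 10 examined regional lymph
    nodes, poor/undifferentiated histology, (extramural) vascular invasion,
    or presentation with obstruction/perforation.

    Raises:
        ValueError: if the case is not stage II.
    """
    if derive_stage(case) is not Stage.II:
        raise ValueError(
            f"is_high_risk_stage_ii requires a stage-II case, "
            f"got stage {derive_stage(case).value} ({case.case_id})"
        )
    return (
        case.pt_stage is PTStage.T4
        or case.nodes_examined is NodesExamined.LT10
        or case.differentiation.value == "POOR_UNDIFF"
        or case.vascular_invasion
        or case.obstruction_or_perforation
    )


# Leaf advice profiles, keyed for reuse between the oracle and the tree
# builder. Options not listed are NR-coerced by TreatmentAdvice.of.
_OBSERVATION_ONLY: dict[str, AdviceCategory] = {"OBSERVATION": AdviceCategory.R}
_STAGE_II_CONSIDER = {
    "OBSERVATION": AdviceCategory.R,
    "CAPOX": AdviceCategory.C,
    "FOLFOX": AdviceCategory.C,
}
_STAGE_III_DOUBLET = {"CAPOX": AdviceCategory.R, "FOLFOX": AdviceCategory.R}
_STAGE_III_MONO = {"CAPE_MONO": AdviceCategory.R, "FU_LV_MONO": AdviceCategory.R}


def dutch_advice(
    case: PatientCase, catalogue: Catalogue | None = None
) -> TreatmentAdvice:
    """Hard-coded Dutch adjuvant colon-cancer oracle.

    Stage I and non-high-risk stage II: observation only. High-risk stage II
    with an MSS tumor and no oxaliplatin contraindication: doublets for
    consideration. Stage III: oxaliplatin doublets recommended; with
    oxaliplatin contraindicated, fluoropyrimidine monotherapy if MSS, and
    observation only if MSI.
    """
    catalogue = catalogue or default_catalogue()
    stage = derive_stage(case)
    if stage is Stage.I:
        profile = _OBSERVATION_ONLY
    elif stage is Stage.II:
        if (
            is_high_risk_stage_ii(case)
            and case.msi_status is MsiStatus.MSS
            and not case.oxaliplatin_contraindicated
        ):
            profile = _STAGE_II_CONSIDER
        else:
            profile = _OBSERVATION_ONLY
    else:  # stage III
        if not case.oxaliplatin_contraindicated:
            profile = _STAGE_III_DOUBLET
        elif case.msi_status is MsiStatus.MSS:
            profile = _STAGE_III_MONO
        else:
            profile = _OBSERVATION_ONLY
    return TreatmentAdvice.of(profile, catalogue, source=AdviceSource.GUIDELINE)


@dataclass(frozen=True)
class Edge:
    """One outgoing branch of a decision node, labeled by a value set."""

    values: tuple[object, ...]
    target: str


@dataclass(frozen=True)
class DecisionNode:
    node_id: str
    field: str
    edges: tuple[Edge, ...]


@dataclass(frozen=True)
class GuidelineRuleset:
    """A declarative decision tree mapping patient cases to advice."""

    name: str
    root: str
    nodes: Mapping[str, DecisionNode]
    leaves: Mapping[str, TreatmentAdvice]


@dataclass(frozen=True)
class RulesetDefect:
    """One structural violation found by :func:`validate_ruleset`."""

    kind: str  # overlap | gap | dangling | cycle | unreachable-leaf | bad-field
    node_id: str
    detail: str


class RulesetEvaluationError(RuntimeError):
    """A case value matched no edge — the ruleset is defective."""


def validate_ruleset(ruleset: GuidelineRuleset) -> list[RulesetDefect]:
    """Check edge partitions, acyclicity, and that every path ends in a leaf.

    Returns one defect record per violation; an empty list means valid.
    """
    defects: list[RulesetDefect] = []
    targets = set(ruleset.nodes) | set(ruleset.leaves)
    if ruleset.root not in targets:
        defects.append(RulesetDefect("dangling", ruleset.root, "root is undefined"))

    for node in ruleset.nodes.values():
        domain = FIELD_DOMAINS.get(node.field)
        if domain is None:
            defects.append(
                RulesetDefect(
                    "bad-field",
                    node.node_id,
                    f"field {node.field!r} has no finite domain",
                )
            )
            continue
        seen: dict[object, int] = {}
        for i, edge in enumerate(node.edges):
            if edge.target not in targets:
                defects.append(
                    RulesetDefect(
                        "dangling", node.node_id, f"edge target {edge.target!r} undefined"
                    )
                )
            for value in edge.values:
                if value not in domain:
                    defects.append(
                        RulesetDefect(
                            "bad-field",
                            node.node_id,
                            f"value {value!r} outside domain of {node.field}",
                        )
                    )
                elif value in seen:
                    defects.append(
                        RulesetDefect(
                            "overlap",
                            node.node_id,
                            f"value {value!r} on edges {seen[value]} and {i}",
                        )
                    )
                else:
                    seen[value] = i
        uncovered = [v for v in domain if v not in seen]
        if uncovered:
            defects.append(
                RulesetDefect(
                    "gap",
                    node.node_id,
                    f"uncovered {node.field} values: "
                    + ", ".join(value_to_str(v) for v in uncovered),
                )
            )

    # Cycle detection over node->node edges (leaves are terminal).
    color: dict[str, int] = {}  # 0 unvisited implicit, 1 in stack, 2 done

    def visit(node_id: str, path: tuple[str, ...]) -> None:
        if node_id in ruleset.leaves or node_id not in ruleset.nodes:
            return
        state = color.get(node_id, 0)
        if state == 1:
            defects.append(
                RulesetDefect("cycle", node_id, "cycle via " + " -> ".join(path))
            )
            return
        if state == 2:
            return
        color[node_id] = 1
        for edge in ruleset.nodes[node_id].edges:
            visit(edge.target, path + (edge.target,))
        color[node_id] = 2

    visit(ruleset.root, (ruleset.root,))
    return defects


def evaluate_ruleset(ruleset: GuidelineRuleset, case: PatientCase) -> TreatmentAdvice:
    """Follow edges from the root by matching case field values.

    Raises:
        RulesetEvaluationError: if a case value matches no edge (a ruleset
            defect that validation would have reported).
    """
    current = ruleset.root
    steps = 0
    limit = len(ruleset.nodes) + 1
    while current not in ruleset.leaves:
        node = ruleset.nodes.get(current)
        if node is None:
            raise RulesetEvaluationError(
                f"{ruleset.name}: node {current!r} is neither a node nor a leaf"
            )
        value = getattr(case, node.field)
        nxt = next((e.target for e in node.edges if value in e.values), None)
        if nxt is None:
            raise RulesetEvaluationError(
                f"{ruleset.name}: node {current!r} has no edge for "
                f"{node.field}={value_to_str(value)} (case {case.case_id})"
            )
        current = nxt
        steps += 1
        if steps > limit:
            raise RulesetEvaluationError(f"{ruleset.name}: cycle at {current!r}")
    return ruleset.leaves[current]


def build_dutch_tree(catalogue: Catalogue | None = None) -> GuidelineRuleset:
    """Construct the Dutch adjuvant colon-cancer rules as a declarative tree."""
    catalogue = catalogue or default_catalogue()

    def advice(profile: Mapping[str, AdviceCategory]) -> TreatmentAdvice:
        return TreatmentAdvice.of(profile, catalogue, source=AdviceSource.GUIDELINE)

    leaves = {
        "leaf_observation": advice(_OBSERVATION_ONLY),
        "leaf_ii_consider": advice(_STAGE_II_CONSIDER),
        "leaf_iii_doublet": advice(_STAGE_III_DOUBLET),
        "leaf_iii_mono": advice(_STAGE_III_MONO),
    }
    n = {}

    def node(node_id: str, fld: str, *edges: tuple[Sequence[object], str]) -> str:
        n[node_id] = DecisionNode(
            node_id, fld, tuple(Edge(tuple(vals), tgt) for vals, tgt in edges)
        )
        return node_id

    node(
        "nodal_status",
        "pn_stage",
        ((PNStage.N0,), "t_stage"),
        ((PNStage.N1, PNStage.N2), "iii_oxali"),
    )
    node(
        "t_stage",
        "pt_stage",
        ((PTStage.T1, PTStage.T2), "leaf_observation"),
        ((PTStage.T3,), "ii_nodes"),
        ((PTStage.T4,), "ii_msi"),
    )
    # Stage II high-risk feature chain: any feature routes into ii_msi.
    node(
        "ii_nodes",
        "nodes_examined",
        ((NodesExamined.LT10,), "ii_msi"),
        ((NodesExamined.GE10,), "ii_diff"),
    )
    node(
        "ii_diff",
        "differentiation",
        ((Differentiation.POOR_UNDIFF,), "ii_msi"),
        ((Differentiation.WELL_MODERATE,), "ii_vasc"),
    )
    node(
        "ii_vasc",
        "vascular_invasion",
        ((True,), "ii_msi"),
        ((False,), "ii_obstr"),
    )
    node(
        "ii_obstr",
        "obstruction_or_perforation",
        ((True,), "ii_msi"),
        ((False,), "leaf_observation"),
    )
    node(
        "ii_msi",
        "msi_status",
        ((MsiStatus.MSI,), "leaf_observation"),
        ((MsiStatus.MSS,), "ii_oxali"),
    )
    node(
        "ii_oxali",
        "oxaliplatin_contraindicated",
        ((True,), "leaf_observation"),
        ((False,), "leaf_ii_consider"),
    )
    node(
        "iii_oxali",
        "oxaliplatin_contraindicated",
        ((False,), "leaf_iii_doublet"),
        ((True,), "iii_msi"),
    )
    node(
        "iii_msi",
        "msi_status",
        ((MsiStatus.MSS,), "leaf_iii_mono"),
        ((MsiStatus.MSI,), "leaf_observation"),
    )
    return GuidelineRuleset(
        name="dutch-adjuvant-colon", root="nodal_status", nodes=n, leaves=leaves
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization


def ruleset_to_dict(ruleset: GuidelineRuleset) -> dict:
    return {
        "name": ruleset.name,
        "root": ruleset.root,
        "nodes": {
            node.node_id: {
                "field": node.field,
                "edges": [
                    {"values": [value_to_str(v) for v in e.values], "target": e.target}
                    for e in node.edges
                ],
            }
            for node in ruleset.nodes.values()
        },
        "leaves": {
            leaf_id: {code: cat.value for code, cat in advice.items}
            for leaf_id, advice in ruleset.leaves.items()
        },
    }


def ruleset_from_dict(
    raw: Mapping, catalogue: Catalogue | None = None
) -> GuidelineRuleset:
    catalogue = catalogue or default_catalogue()
    for key in ("name", "root", "nodes", "leaves"):
        if key not in raw:
            raise FormatError(f"ruleset file missing key {key!r}")
    nodes: dict[str, DecisionNode] = {}
    for node_id, spec in raw["nodes"].items():
        fld = spec.get("field")
        if fld not in FIELD_DOMAINS and fld != "age":
            raise FormatError(f"node {node_id!r}: unknown field {fld!r}")
        edges = tuple(
            Edge(
                values=tuple(value_from_str(fld, str(v)) for v in e["values"]),
                target=str(e["target"]),
            )
            for e in spec.get("edges", [])
        )
        nodes[node_id] = DecisionNode(node_id, fld, edges)
    leaves = {
        leaf_id: TreatmentAdvice.of(cats, catalogue, source=AdviceSource.GUIDELINE)
        for leaf_id, cats in raw["leaves"].items()
    }
    return GuidelineRuleset(
        name=str(raw["name"]), root=str(raw["root"]), nodes=nodes, leaves=leaves
    )


def save_ruleset(ruleset: GuidelineRuleset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ruleset_to_dict(ruleset), indent=2) + "\n")


def load_ruleset(
    path: str | Path, catalogue: Catalogue | None = None, validate: bool = True
) -> GuidelineRuleset:
    """Load a ruleset JSON file; by default reject structurally invalid trees."""
    raw = json.loads(Path(path).read_text())
    ruleset = ruleset_from_dict(raw, catalogue)
    if validate:
        defects = validate_ruleset(ruleset)
        if defects:
            lines = "; ".join(f"{d.kind}@{d.node_id}: {d.detail}" for d in defects)
            raise FormatError(f"{path}: invalid ruleset: {lines}")
    return ruleset


def _packaged(name: str) -> Path:
    return Path(str(resources.files("adviceaudit").joinpath("data", name)))


def load_dutch_tree(catalogue: Catalogue | None = None) -> GuidelineRuleset:
    """Load the packaged declarative Dutch tree fixture."""
    return load_ruleset(_packaged("dutch_tree.json"), catalogue)


def load_nccn_template(catalogue: Catalogue | None = None) -> GuidelineRuleset:
    """Load the editable NCCN-style ruleset template (same shape, own file)."""
    return load_ruleset(_packaged("nccn_template.json"), catalogue)
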