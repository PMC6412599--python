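"""Decision-point plans and synthetic patient-case enumeration.

An :class:`EnumerationPlan` lists one :class:`DecisionPointSpec` per patient
field: either a set of tested values or a constant. ``enumerate_cases``
expands the plan into a deterministic full factorial, or deduplicates it to
one representative per distinct (guideline advice, stage) path signature.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Callable, Mapping, Sequence

import yaml

from .rulesets import derive_stage, dutch_advice
from .types import (
    CASE_FIELDS,
    Differentiation,
    FormatError,
    MsiStatus,
    NodesExamined,
    PatientCase,
    PNStage,
    PTStage,
    ResectionMargin,
    Stage,
    TreatmentAdvice,
    value_from_str,
    value_to_str,
)

__all__ = [
    "DecisionPointKind",
    "EnumerationMode",
    "DecisionPointSpec",
    "EnumerationPlan",
    "default_plan",
    "enumerate_cases",
    "count_by_stage",
    "load_plan",
    "save_plan",
]


class DecisionPointKind(str, enum.Enum):
    CATEGORICAL = "CATEGORICAL"
    CONTINUOUS = "CONTINUOUS"


class EnumerationMode(str, enum.Enum):
    FULL_FACTORIAL = "FULL_FACTORIAL"
    PATH_DEDUP = "PATH_DEDUP"


@dataclass(frozen=True)
class DecisionPointSpec:
    """One decision point: either tested over values or held constant."""

    name: str
    kind: DecisionPointKind
    tested_values: tuple[object, ...] = ()
    held_constant: bool = False
    constant_value: object | None = None

    def __post_init__(self) -> None:
        if self.name not in CASE_FIELDS:
            raise ValueError(f"unknown decision point {self.name!r}")
        if self.held_constant:
            if self.constant_value is None:
                raise ValueError(f"{self.name}: held_constant requires constant_value")
        elif not self.tested_values:
            raise ValueError(f"{self.name}: tested_values must be non-empty")

    @property
    def values(self) -> tuple[object, ...]:
        return (self.constant_value,) if self.held_constant else self.tested_values


@dataclass(frozen=True)
class EnumerationPlan:
    points: tuple[DecisionPointSpec, ...]
    mode: EnumerationMode = EnumerationMode.FULL_FACTORIAL
    guideline_point_names: frozenset[str] = frozenset()
    advisor_point_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [p.name for p in self.points]
        if sorted(names) != sorted(CASE_FIELDS):
            missing = set(CASE_FIELDS) - set(names)
            extra = set(names) - set(CASE_FIELDS)
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(
                f"plan must cover every case field exactly once "
                f"(missing={sorted(missing)}, extra={sorted(extra)}, "
                f"duplicated={sorted(dupes)})"
            )
        for attr in ("guideline_point_names", "advisor_point_names"):
            unknown = getattr(self, attr) - set(names)
            if unknown:
                raise ValueError(f"{attr} contains unknown points: {sorted(unknown)}")

    def point(self, name: str) -> DecisionPointSpec:
        for p in self.points:
            if p.name == name:
                return p
        raise KeyError(name)


#: Decision points attributed to the Dutch guideline (9 names).
GUIDELINE_POINT_NAMES = frozenset(
    {
        "age",
        "pt_stage",
        "pn_stage",
        "nodes_examined",
        "differentiation",
        "vascular_invasion",
        "obstruction_or_perforation",
        "msi_status",
        "oxaliplatin_contraindicated",
    }
)

#: The advisor's minimum variable set (13 names: every field except the
#: oxaliplatin contraindication, which only the guideline asks about).
ADVISOR_POINT_NAMES = frozenset(CASE_FIELDS) - {"oxaliplatin_contraindicated"}


def default_plan(mode: EnumerationMode = EnumerationMode.FULL_FACTORIAL) -> EnumerationPlan:
    """The packaged enumeration plan.

    Tests age at 3 purposively sampled levels (45/60/75), every categorical
    guideline point at all values, and the advisor-only comorbidity flags;
    holds resection margin, perineural invasion, and functional status at
    normal/absent. Factorial size: 3 * 4 * 3 * 2**8 = 9216.
    """
    cat = DecisionPointKind.CATEGORICAL
    cont = DecisionPointKind.CONTINUOUS
    points = (
        DecisionPointSpec("age", cont, tested_values=(45, 60, 75)),
        DecisionPointSpec("pt_stage", cat, tested_values=tuple(PTStage)),
        DecisionPointSpec("pn_stage", cat, tested_values=tuple(PNStage)),
        DecisionPointSpec("nodes_examined", cat, tested_values=tuple(NodesExamined)),
        DecisionPointSpec("differentiation", cat, tested_values=tuple(Differentiation)),
        DecisionPointSpec("vascular_invasion", cat, tested_values=(False, True)),
        DecisionPointSpec(
            "obstruction_or_perforation", cat, tested_values=(False, True)
        ),
        DecisionPointSpec("msi_status", cat, tested_values=tuple(MsiStatus)),
        DecisionPointSpec(
            "oxaliplatin_contraindicated", cat, tested_values=(False, True)
        ),
        DecisionPointSpec("serious_liver_disease", cat, tested_values=(False, True)),
        DecisionPointSpec("serious_kidney_disease", cat, tested_values=(False, True)),
        DecisionPointSpec(
            "resection_margin",
            cat,
            held_constant=True,
            constant_value=ResectionMargin.NEGATIVE,
        ),
        DecisionPointSpec(
            "perineural_invasion", cat, held_constant=True, constant_value=False
        ),
        DecisionPointSpec(
            "functional_status", cont, held_constant=True, constant_value=0
        ),
    )
    return EnumerationPlan(
        points=points,
        mode=mode,
        guideline_point_names=GUIDELINE_POINT_NAMES,
        advisor_point_names=ADVISOR_POINT_NAMES,
    )


AdviceFn = Callable[[PatientCase], TreatmentAdvice]


def enumerate_cases(
    plan: EnumerationPlan, advice_fn: AdviceFn | None = None
) -> list[PatientCase]:
    """Expand a plan into synthetic patient cases.

    FULL_FACTORIAL: the Cartesian product of tested values across
    non-constant points, in deterministic lexicographic order of the plan's
    value lists, constants filled in; case ids are zero-padded ordinals.

    PATH_DEDUP: the factorial set reduced to one representative per distinct
    (guideline advice, stage) signature, keeping the lexicographically first
    member. ``advice_fn`` supplies the guideline route (default:
    :func:`dutch_advice`).
    """
    tested = [p for p in plan.points if not p.held_constant]
    constants = {p.name: p.constant_value for p in plan.points if p.held_constant}
    combos = list(product(*(p.tested_values for p in tested)))
    width = max(1, len(str(len(combos))))
    cases = []
    for i, combo in enumerate(combos, start=1):
        kwargs = dict(zip((p.name for p in tested), combo))
        kwargs.update(constants)
        cases.append(PatientCase(case_id=f"case_{i:0{width}d}", **kwargs))

    if plan.mode is EnumerationMode.FULL_FACTORIAL:
        return cases

    advice_fn = advice_fn or dutch_advice
    seen: set[tuple] = set()
    kept = []
    for case in cases:
        signature = (derive_stage(case), advice_fn(case).items)
        if signature not in seen:
            seen.add(signature)
            kept.append(case)
    return kept


def count_by_stage(cases: Sequence[PatientCase]) -> dict[Stage, int]:
    """Partition a case list by derived stage; all three keys always present."""
    counts = {stage: 0 for stage in Stage}
    for case in cases:
        counts[derive_stage(case)] += 1
    return counts


# ---------------------------------------------------------------------------
# Plan files (YAML or JSON, chosen by extension)


def _plan_to_dict(plan: EnumerationPlan) -> dict:
    points = []
    for p in plan.points:
        entry: dict = {"name": p.name, "kind": p.kind.value}
        if p.held_constant:
            entry["held_constant"] = True
            entry["constant_value"] = value_to_str(p.constant_value)
        else:
            entry["tested_values"] = [value_to_str(v) for v in p.tested_values]
        points.append(entry)
    return {
        "mode": plan.mode.value,
        "points": points,
        "guideline_point_names": sorted(plan.guideline_point_names),
        "advisor_point_names": sorted(plan.advisor_point_names),
    }


def _plan_from_dict(raw: Mapping) -> EnumerationPlan:
    try:
        points = []
        for entry in raw["points"]:
            name = entry["name"]
            if entry.get("held_constant"):
                points.append(
                    DecisionPointSpec(
                        name=name,
                        kind=DecisionPointKind(entry["kind"]),
                        held_constant=True,
                        constant_value=value_from_str(
                            name, str(entry["constant_value"])
                        ),
                    )
                )
            else:
                points.append(
                    DecisionPointSpec(
                        name=name,
                        kind=DecisionPointKind(entry["kind"]),
                        tested_values=tuple(
                            value_from_str(name, str(v))
                            for v in entry["tested_values"]
                        ),
                    )
                )
        return EnumerationPlan(
            points=tuple(points),
            mode=EnumerationMode(raw.get("mode", "FULL_FACTORIAL")),
            guideline_point_names=frozenset(raw.get("guideline_point_names", ())),
            advisor_point_names=frozenset(raw.get("advisor_point_names", ())),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"invalid enumeration plan: {exc}") from exc


def save_plan(plan: EnumerationPlan, path: str | Path) -> None:
    path = Path(path)
    payload = _plan_to_dict(plan)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_plan(path: str | Path, mode: EnumerationMode | None = None) -> EnumerationPlan:
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    plan = _plan_from_dict(raw)
    if mode is not None:
        plan = replace(plan, mode=mode)
    return plan
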