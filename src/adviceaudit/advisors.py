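"""Advisor contract: black-box advice per case, mock and recorded backends.

The proprietary system under audit cannot be redistributed, so two stand-ins
implement the same ``advise(case)`` contract:

* :class:`MockAdvisor` — evaluates a backing ruleset and optionally perturbs
  each option's category with configured shift probabilities, reproducibly
  seeded per (seed, case_id, option code).
* :class:`RecordedAdvisor` — replays externally captured advice loaded from
  CSV/JSON keyed by case id.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

from .rulesets import GuidelineRuleset, evaluate_ruleset
from .types import (
    AdviceCategory,
    AdviceSource,
    CATEGORIES,
    Catalogue,
    FormatError,
    PatientCase,
    TreatmentAdvice,
    default_catalogue,
)

__all__ = [
    "Advisor",
    "MissingAdviceError",
    "PerturbationConfig",
    "MockAdvisor",
    "RecordedAdviceStore",
    "RecordedAdvisor",
    "mock_advise",
    "load_recorded",
    "save_recorded",
]


class MissingAdviceError(KeyError):
    """A recorded advisor has no entry for the requested case."""


@runtime_checkable
class Advisor(Protocol):
    """Anything that can produce total ADVISOR-sourced advice for a case."""

    def advise(self, case: PatientCase) -> TreatmentAdvice: ...


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-option category-shift probabilities for the mock advisor.

    ``shift_probabilities`` maps ordered (from, to) category pairs to a
    probability; for each "from" category the outgoing mass must sum to at
    most 1 (the residual is "no change"). Each option draws independently
    from a stream seeded by (seed, case_id, option code), so outcomes do not
    depend on the order cases are processed.
    """

    shift_probabilities: Mapping[tuple[AdviceCategory, AdviceCategory], float] = field(
        default_factory=dict
    )
    per_option: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for (src, dst), p in self.shift_probabilities.items():
            if src == dst:
                raise ValueError(f"shift ({src.value}->{dst.value}) must move category")
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"shift probability for ({src.value}->{dst.value}) "
                    f"must be in [0, 1], got {p}"
                )
        for src in CATEGORIES:
            total = sum(
                p for (s, _), p in self.shift_probabilities.items() if s == src
            )
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"outgoing shift probabilities from {src.value} sum to "
                    f"{total} > 1"
                )

    @classmethod
    def of(
        cls,
        shifts: Mapping[str, float] | None = None,
        per_option: bool = True,
        seed: int = 0,
    ) -> "PerturbationConfig":
        """Build from string keys like ``{"R->C": 0.3}``."""
        parsed: dict[tuple[AdviceCategory, AdviceCategory], float] = {}
        for key, p in (shifts or {}).items():
            try:
                src, dst = (AdviceCategory(part.strip()) for part in key.split("->"))
            except ValueError as exc:
                raise FormatError(f"invalid shift key {key!r}") from exc
            parsed[(src, dst)] = float(p)
        return cls(shift_probabilities=parsed, per_option=per_option, seed=seed)


def _shift_category(
    category: AdviceCategory,
    config: PerturbationConfig,
    rng: random.Random,
) -> AdviceCategory:
    """Apply at most one category shift, sampled from the config."""
    u = rng.random()
    cumulative = 0.0
    for dst in CATEGORIES:
        p = config.shift_probabilities.get((category, dst), 0.0)
        cumulative += p
        if u < cumulative:
            return dst
    return category


def mock_advise(
    ruleset: GuidelineRuleset,
    config: PerturbationConfig,
    case: PatientCase,
    catalogue: Catalogue | None = None,
) -> TreatmentAdvice:
    """Evaluate the backing ruleset, then perturb each option independently."""
    catalogue = catalogue or default_catalogue()
    base = evaluate_ruleset(ruleset, case)
    perturbed = {}
    for code, category in base.items:
        # String seeding is deterministic across processes and independent
        # of case processing order.
        rng = random.Random(f"{config.seed}:{case.case_id}:{code}")
        perturbed[code] = _shift_category(category, config, rng)
    return TreatmentAdvice.of(perturbed, catalogue, source=AdviceSource.ADVISOR)


@dataclass(frozen=True)
class MockAdvisor:
    """Ruleset-backed advisor with optional category perturbation."""

    ruleset: GuidelineRuleset
    config: PerturbationConfig = field(default_factory=PerturbationConfig)
    catalogue: Catalogue = field(default_factory=default_catalogue)

    def advise(self, case: PatientCase) -> TreatmentAdvice:
        return mock_advise(self.ruleset, self.config, case, self.catalogue)


@dataclass(frozen=True)
class RecordedAdviceStore:
    """Externally captured advice keyed by case id."""

    entries: Mapping[str, TreatmentAdvice]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self.entries


@dataclass(frozen=True)
class RecordedAdvisor:
    store: RecordedAdviceStore

    def advise(self, case: PatientCase) -> TreatmentAdvice:
        try:
            return self.store.entries[case.case_id]
        except KeyError:
            raise MissingAdviceError(
                f"no recorded advice for case {case.case_id!r}"
            ) from None


def load_recorded(
    path: str | Path, catalogue: Catalogue | None = None
) -> RecordedAdviceStore:
    """Load recorded advice from CSV (case_id, option_code, category) or JSON.

    Options absent for a known case id are coerced to NR; duplicate
    (case_id, option_code) pairs and unknown option codes are format errors.
    """
    catalogue = catalogue or default_catalogue()
    path = Path(path)
    codes = {o.code for o in catalogue}
    by_case: dict[str, dict[str, AdviceCategory]] = {}
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: advice JSON must map case_id to categories")
        for case_id, cats in raw.items():
            if not isinstance(cats, dict):
                raise FormatError(f"{path}: entry for {case_id!r} must be a mapping")
            by_case[str(case_id)] = {}
            for code, cat in cats.items():
                if code not in codes:
                    raise FormatError(f"{path}: unknown option code {code!r}")
                try:
                    by_case[str(case_id)][code] = AdviceCategory(cat)
                except ValueError as exc:
                    raise FormatError(f"{path}: invalid category {cat!r}") from exc
    else:
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            expected = {"case_id", "option_code", "category"}
            if reader.fieldnames is None or not expected <= set(reader.fieldnames):
                raise FormatError(
                    f"{path}: advice CSV needs columns {sorted(expected)}"
                )
            for lineno, row in enumerate(reader, start=2):
                case_id = row["case_id"].strip()
                code = row["option_code"].strip()
                if code not in codes:
                    raise FormatError(
                        f"{path}:{lineno}: unknown option code {code!r}"
                    )
                try:
                    category = AdviceCategory(row["category"].strip())
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: invalid category {row['category']!r}"
                    ) from exc
                case_entries = by_case.setdefault(case_id, {})
                if code in case_entries:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate ({case_id}, {code}) pair"
                    )
                case_entries[code] = category
    entries = {
        case_id: TreatmentAdvice.of(cats, catalogue, source=AdviceSource.ADVISOR)
        for case_id, cats in by_case.items()
    }
    return RecordedAdviceStore(entries=entries)


def save_recorded(store: RecordedAdviceStore, path: str | Path) -> None:
    """Write a store back out in normalized form (sorted case ids)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            case_id: {code: cat.value for code, cat in advice.items}
            for case_id, advice in sorted(store.entries.items())
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["case_id", "option_code", "category"])
        for case_id, advice in sorted(store.entries.items()):
            for code, category in advice.items:
                writer.writerow([case_id, code, category.value])
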