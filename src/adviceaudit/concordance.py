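"""Concordance scoring: cross-tabulation matrix, case scores, safety flags.

Each treatment option contributes one cell of a 3x3 (guideline category x
advisor category) score matrix; per-option scores sum to an overall case
score in [-2k, +2k] for a k-option catalogue. Cases where the advisor
recommends (red) or suggests for consideration (orange) a chemotherapy the
guideline marks not recommended are flagged, red taking precedence.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .types import (
    AdviceCategory,
    CATEGORIES,
    Catalogue,
    FormatError,
    Stage,
    TreatmentAdvice,
    default_catalogue,
)

__all__ = [
    "Flag",
    "ScoreMatrix",
    "CaseResult",
    "default_matrix",
    "score_case",
    "assign_flag",
    "aggregate",
    "load_matrix",
    "save_matrix",
    "write_results_csv",
    "read_results_csv",
]


class Flag(str, enum.Enum):
    RED = "RED"
    ORANGE = "ORANGE"
    NONE = "NONE"


@dataclass(frozen=True)
class ScoreMatrix:
    """Total mapping (guideline category, advisor category) -> integer score.

    Invariants enforced at construction: scores lie in [-2, +2], agreement
    (diagonal) cells equal +2, and the extreme disagreement cells (R, NR)
    and (NR, R) equal -2.
    """

    cells: Mapping[tuple[AdviceCategory, AdviceCategory], int]

    def __post_init__(self) -> None:
        expected = {(g, a) for g in CATEGORIES for a in CATEGORIES}
        if set(self.cells) != expected:
            raise ValueError("score matrix must cover all 9 category pairs")
        for pair, score in self.cells.items():
            if not isinstance(score, int) or not -2 <= score <= 2:
                raise ValueError(f"cell {pair}: score {score!r} outside [-2, 2]")
        for cat in CATEGORIES:
            if self.cells[(cat, cat)] != 2:
                raise ValueError(f"diagonal cell ({cat.value},{cat.value}) must be +2")
        for pair in ((AdviceCategory.R, AdviceCategory.NR), (AdviceCategory.NR, AdviceCategory.R)):
            if self.cells[pair] != -2:
                raise ValueError(
                    f"cell ({pair[0].value},{pair[1].value}) must be -2"
                )

    def __call__(self, guideline: AdviceCategory, advisor: AdviceCategory) -> int:
        return self.cells[(guideline, advisor)]


def default_matrix() -> ScoreMatrix:
    """Default cross-tabulation: +2 agreement, +-1 adjacent, -2 R/NR swap."""
    R, C, NR = AdviceCategory.R, AdviceCategory.C, AdviceCategory.NR
    return ScoreMatrix(
        cells={
            (R, R): 2, (C, C): 2, (NR, NR): 2,
            (R, C): 1, (C, R): 1,
            (C, NR): -1, (NR, C): -1,
            (R, NR): -2, (NR, R): -2,
        }
    )


@dataclass(frozen=True)
class CaseResult:
    """Per-case concordance outcome; ``flag`` is None until assigned."""

    case_id: str
    per_option_scores: Mapping[str, int]
    overall_score: int
    flag: Flag | None = None
    stage: Stage | None = None

    def __post_init__(self) -> None:
        if self.overall_score != sum(self.per_option_scores.values()):
            raise ValueError("overall_score must equal the sum of option scores")


def _require_total(advice: TreatmentAdvice, catalogue: Catalogue, label: str) -> None:
    if not advice.is_total_over(catalogue):
        raise ValueError(
            f"{label} advice is not total over the catalogue "
            f"({[c for c, _ in advice.items]})"
        )


def score_case(
    guideline: TreatmentAdvice,
    advisor: TreatmentAdvice,
    matrix: ScoreMatrix | None = None,
    catalogue: Catalogue | None = None,
    *,
    case_id: str = "",
    stage: Stage | None = None,
) -> CaseResult:
    """Cross-tabulate the two advices option-by-option and sum the scores."""
    matrix = matrix or default_matrix()
    catalogue = catalogue or default_catalogue()
    _require_total(guideline, catalogue, "guideline")
    _require_total(advisor, catalogue, "advisor")
    g = guideline.categories
    a = advisor.categories
    per_option = {o.code: matrix(g[o.code], a[o.code]) for o in catalogue}
    return CaseResult(
        case_id=case_id,
        per_option_scores=per_option,
        overall_score=sum(per_option.values()),
        stage=stage,
    )


def assign_flag(
    guideline: TreatmentAdvice,
    advisor: TreatmentAdvice,
    catalogue: Catalogue | None = None,
) -> Flag:
    """Red/orange safety flag; red takes precedence when both apply.

    Only chemotherapy options can trigger flags: RED when the advisor
    recommends a guideline-NR chemotherapy, ORANGE when it suggests one for
    consideration.
    """
    catalogue = catalogue or default_catalogue()
    _require_total(guideline, catalogue, "guideline")
    _require_total(advisor, catalogue, "advisor")
    g = guideline.categories
    a = advisor.categories
    orange = False
    for option in catalogue:
        if not option.is_chemotherapy or g[option.code] is not AdviceCategory.NR:
            continue
        if a[option.code] is AdviceCategory.R:
            return Flag.RED
        if a[option.code] is AdviceCategory.C:
            orange = True
    return Flag.ORANGE if orange else Flag.NONE


def _round_half_up_percent(count: int, total: int) -> int:
    return int(math.floor(count * 100.0 / total + 0.5))


def aggregate(results: Sequence[CaseResult]) -> dict:
    """Summarize results: score extremes/median, per-stage histograms, flags.

    The median of an even count is the lower middle value; this convention
    is recorded in the output metadata. Flag percentages are integers,
    rounded half-up, and may sum to 100 +- 1.
    """
    n = len(results)
    summary: dict = {"n": n, "median_convention": "lower_middle"}
    scores = sorted(r.overall_score for r in results)
    if n:
        summary["score_min"] = scores[0]
        summary["score_max"] = scores[-1]
        summary["score_median"] = scores[(n - 1) // 2]
    else:
        summary["score_min"] = summary["score_max"] = summary["score_median"] = None

    histogram: dict[str, dict[int, int]] = {stage.value: {} for stage in Stage}
    histogram["unknown"] = {}
    for r in results:
        key = r.stage.value if r.stage is not None else "unknown"
        histogram[key][r.overall_score] = histogram[key].get(r.overall_score, 0) + 1
    if not histogram["unknown"]:
        del histogram["unknown"]
    summary["histogram_by_stage"] = {
        stage: dict(sorted(hist.items())) for stage, hist in histogram.items()
    }

    flag_counts = {flag.value: 0 for flag in Flag}
    for r in results:
        flag_counts[(r.flag or Flag.NONE).value] += 1
    summary["flag_counts"] = flag_counts
    summary["flag_percentages"] = (
        {k: _round_half_up_percent(v, n) for k, v in flag_counts.items()} if n else None
    )
    return summary


# ---------------------------------------------------------------------------
# File formats


def load_matrix(path: str | Path) -> ScoreMatrix:
    """Load a 3x3 matrix from JSON: {"R": {"R": 2, "C": 1, "NR": -2}, ...}."""
    raw = json.loads(Path(path).read_text())
    try:
        cells = {
            (AdviceCategory(g), AdviceCategory(a)): int(raw[g][a])
            for g in ("R", "C", "NR")
            for a in ("R", "C", "NR")
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed score matrix: {exc}") from exc
    return ScoreMatrix(cells=cells)


def save_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    payload = {
        g.value: {a.value: matrix(g, a) for a in CATEGORIES} for g in CATEGORIES
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_results_csv(
    results: Sequence[CaseResult], catalogue: Catalogue, path: str | Path
) -> None:
    columns = ["case_id", "stage", *(o.code for o in catalogue), "overall_score", "flag"]
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for r in results:
            writer.writerow(
                [
                    r.case_id,
                    r.stage.value if r.stage else "",
                    *(r.per_option_scores[o.code] for o in catalogue),
                    r.overall_score,
                    (r.flag or Flag.NONE).value,
                ]
            )


def read_results_csv(path: str | Path, catalogue: Catalogue) -> list[CaseResult]:
    results = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            per_option = {o.code: int(row[o.code]) for o in catalogue}
            results.append(
                CaseResult(
                    case_id=row["case_id"],
                    per_option_scores=per_option,
                    overall_score=int(row["overall_score"]),
                    flag=Flag(row["flag"]),
                    stage=Stage(row["stage"]) if row.get("stage") else None,
                )
            )
    return results
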