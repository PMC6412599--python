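"""End-to-end pipeline and CLI: generate, advise, score, report, run.

``run_evaluation`` wires the whole audit together — enumerate cases from a
plan, obtain guideline and advisor advice, cross-tabulate, flag, and write
cases/advice/results CSVs plus per-case analysis tables and a summary JSON.
All stages are deterministic for a given seed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import click
import yaml

from . import casegen
from .advisors import (
    Advisor,
    MockAdvisor,
    PerturbationConfig,
    RecordedAdviceStore,
    RecordedAdvisor,
    load_recorded,
    save_recorded,
)
from .casegen import EnumerationMode, EnumerationPlan, default_plan, load_plan
from .concordance import (
    CaseResult,
    Flag,
    ScoreMatrix,
    aggregate,
    assign_flag,
    default_matrix,
    load_matrix,
    read_results_csv,
    score_case,
    write_results_csv,
)
from .rulesets import (
    GuidelineRuleset,
    derive_stage,
    evaluate_ruleset,
    load_dutch_tree,
    load_ruleset,
)
from .types import (
    AdviceSource,
    Catalogue,
    PatientCase,
    TreatmentAdvice,
    default_catalogue,
    load_catalogue,
    read_cases_csv,
    write_cases_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisRow", "RunConfig", "run_evaluation", "render_case_table", "cli"]


@dataclass(frozen=True)
class AnalysisRow:
    """One line of a per-case analysis table (one row per catalogue option)."""

    option_label: str
    guideline_category: str
    advisor_category: str
    score: int
    comment: str = ""


def render_case_table(
    case: PatientCase,
    guideline: TreatmentAdvice,
    advisor: TreatmentAdvice,
    result: CaseResult,
    catalogue: Catalogue | None = None,
) -> list[AnalysisRow]:
    """Exactly one row per catalogue option, in catalogue order."""
    catalogue = catalogue or default_catalogue()
    g = guideline.categories
    a = advisor.categories
    rows = []
    for option in catalogue:
        score = result.per_option_scores[option.code]
        comment = ""
        if g[option.code] != a[option.code]:
            comment = (
                f"advisor says {a[option.code].value}, "
                f"guideline says {g[option.code].value}"
            )
        rows.append(
            AnalysisRow(
                option_label=option.label,
                guideline_category=g[option.code].value,
                advisor_category=a[option.code].value,
                score=score,
                comment=comment,
            )
        )
    return rows


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full audit run; None fields use packaged defaults."""

    out_dir: str | Path = "audit_out"
    plan_path: str | Path | None = None
    ruleset_path: str | Path | None = None
    advisor_kind: str = "mock"  # "mock" | "recorded"
    advisor_ruleset_path: str | Path | None = None
    recorded_path: str | Path | None = None
    perturb_path: str | Path | None = None
    matrix_path: str | Path | None = None
    catalogue_path: str | Path | None = None
    mode: EnumerationMode | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.advisor_kind not in ("mock", "recorded"):
            raise ValueError(f"advisor_kind must be mock or recorded: {self.advisor_kind!r}")
        if self.advisor_kind == "recorded" and self.recorded_path is None:
            raise ValueError("recorded advisor requires recorded_path")


def _load_perturbation(path: str | Path | None, seed: int) -> PerturbationConfig:
    if path is None:
        return PerturbationConfig.of(seed=seed)
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return PerturbationConfig.of(
        shifts=raw.get("shifts", {}),
        per_option=bool(raw.get("per_option", True)),
        seed=int(raw.get("seed", seed)),
    )


def _build_advisor(
    config: RunConfig, guideline: GuidelineRuleset, catalogue: Catalogue
) -> Advisor:
    if config.advisor_kind == "recorded":
        return RecordedAdvisor(load_recorded(config.recorded_path, catalogue))
    backing = (
        load_ruleset(config.advisor_ruleset_path, catalogue)
        if config.advisor_ruleset_path
        else guideline
    )
    perturb = _load_perturbation(config.perturb_path, config.seed)
    return MockAdvisor(ruleset=backing, config=perturb, catalogue=catalogue)


def _write_analysis_tables(
    path: Path,
    cases: Sequence[PatientCase],
    guideline_advice: dict[str, TreatmentAdvice],
    advisor_advice: dict[str, TreatmentAdvice],
    results: dict[str, CaseResult],
    catalogue: Catalogue,
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["case_id", "treatment_option", "guideline", "advisor", "score", "comment"]
        )
        for case in cases:
            rows = render_case_table(
                case,
                guideline_advice[case.case_id],
                advisor_advice[case.case_id],
                results[case.case_id],
                catalogue,
            )
            for row in rows:
                writer.writerow(
                    [
                        case.case_id,
                        row.option_label,
                        row.guideline_category,
                        row.advisor_category,
                        row.score,
                        row.comment,
                    ]
                )


def run_evaluation(config: RunConfig) -> dict:
    """Run all pipeline stages and write the results bundle to out_dir.

    Returns a dict with the enumerated cases, per-case results, and the
    aggregate summary (also written as ``summary.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    catalogue = (
        load_catalogue(config.catalogue_path)
        if config.catalogue_path
        else default_catalogue()
    )
    matrix = load_matrix(config.matrix_path) if config.matrix_path else default_matrix()
    plan = (
        load_plan(config.plan_path, mode=config.mode)
        if config.plan_path
        else default_plan(mode=config.mode or EnumerationMode.FULL_FACTORIAL)
    )
    guideline_tree = (
        load_ruleset(config.ruleset_path, catalogue)
        if config.ruleset_path
        else load_dutch_tree(catalogue)
    )
    advisor = _build_advisor(config, guideline_tree, catalogue)

    logger.info("enumerating cases (%s)", plan.mode.value)
    cases = casegen.enumerate_cases(
        plan, advice_fn=lambda c: evaluate_ruleset(guideline_tree, c)
    )
    logger.info("%d cases enumerated", len(cases))

    guideline_advice: dict[str, TreatmentAdvice] = {}
    advisor_advice: dict[str, TreatmentAdvice] = {}
    results: dict[str, CaseResult] = {}
    final: list[CaseResult] = []
    for case in cases:
        logger.debug("evaluating %s", case.case_id)
        g = evaluate_ruleset(guideline_tree, case)
        a = advisor.advise(case)
        scored = score_case(
            g, a, matrix, catalogue, case_id=case.case_id, stage=derive_stage(case)
        )
        result = CaseResult(
            case_id=scored.case_id,
            per_option_scores=scored.per_option_scores,
            overall_score=scored.overall_score,
            flag=assign_flag(g, a, catalogue),
            stage=scored.stage,
        )
        guideline_advice[case.case_id] = g
        advisor_advice[case.case_id] = a
        results[case.case_id] = result
        final.append(result)

    summary = aggregate(final)
    summary["mode"] = plan.mode.value
    summary["seed"] = config.seed
    summary["stage_counts"] = {
        stage.value: count
        for stage, count in casegen.count_by_stage(cases).items()
    }

    write_cases_csv(cases, out_dir / "cases.csv")
    save_recorded(
        RecordedAdviceStore(entries=guideline_advice), out_dir / "guideline_advice.csv"
    )
    save_recorded(
        RecordedAdviceStore(entries=advisor_advice), out_dir / "advisor_advice.csv"
    )
    write_results_csv(final, catalogue, out_dir / "results.csv")
    _write_analysis_tables(
        out_dir / "analysis_tables.csv",
        cases,
        guideline_advice,
        advisor_advice,
        results,
        catalogue,
    )
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("results written to %s", out_dir)
    return {"cases": cases, "results": final, "summary": summary}


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--quiet", is_flag=True, help="Suppress progress logging.")
def cli(quiet: bool) -> None:
    """Audit a black-box treatment advisor against a guideline ruleset."""
    logging.basicConfig(
        level=logging.WARNING if quiet else logging.INFO,
        format="%(levelname)s %(message)s",
    )


_mode_option = click.option(
    "--mode",
    type=click.Choice([m.value for m in EnumerationMode]),
    default=EnumerationMode.FULL_FACTORIAL.value,
    show_default=True,
)


@cli.command()
@click.option("--plan", "plan_path", type=click.Path(exists=True), default=None)
@_mode_option
@click.option("--out", "out_path", type=click.Path(), required=True)
@click.option("--summary", "summary_path", type=click.Path(), default=None)
def generate(plan_path, mode, out_path, summary_path) -> None:
    """Enumerate synthetic cases from a plan into a cases CSV."""
    mode_enum = EnumerationMode(mode)
    plan = load_plan(plan_path, mode=mode_enum) if plan_path else default_plan(mode_enum)
    cases = casegen.enumerate_cases(plan)
    write_cases_csv(cases, out_path)
    counts = {s.value: c for s, c in casegen.count_by_stage(cases).items()}
    if summary_path:
        Path(summary_path).write_text(
            json.dumps({"n_cases": len(cases), "stage_counts": counts}, indent=2) + "\n"
        )
    click.echo(f"{len(cases)} cases -> {out_path} (stages: {counts})")


@cli.command()
@click.option("--cases", "cases_path", type=click.Path(exists=True), required=True)
@click.option("--ruleset", "ruleset_path", type=click.Path(exists=True), default=None,
              help="Guideline ruleset JSON (default: packaged Dutch tree).")
@click.option("--advisor", "advisor_kind",
              type=click.Choice(["guideline", "mock", "recorded"]), default="guideline",
              show_default=True)
@click.option("--recorded", "recorded_path", type=click.Path(exists=True), default=None)
@click.option("--perturb", "perturb_path", type=click.Path(exists=True), default=None)
@click.option("--catalogue", "catalogue_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def advise(cases_path, ruleset_path, advisor_kind, recorded_path, perturb_path,
           catalogue_path, seed, out_path) -> None:
    """Produce an advice CSV for each case (guideline, mock, or recorded)."""
    catalogue = load_catalogue(catalogue_path) if catalogue_path else default_catalogue()
    tree = (
        load_ruleset(ruleset_path, catalogue) if ruleset_path else load_dutch_tree(catalogue)
    )
    cases = read_cases_csv(cases_path)
    entries: dict[str, TreatmentAdvice] = {}
    if advisor_kind == "guideline":
        for case in cases:
            entries[case.case_id] = evaluate_ruleset(tree, case)
    else:
        if advisor_kind == "recorded":
            if not recorded_path:
                raise click.UsageError("--advisor recorded requires --recorded")
            advisor: Advisor = RecordedAdvisor(load_recorded(recorded_path, catalogue))
        else:
            advisor = MockAdvisor(
                ruleset=tree,
                config=_load_perturbation(perturb_path, seed),
                catalogue=catalogue,
            )
        for case in cases:
            entries[case.case_id] = advisor.advise(case)
    save_recorded(RecordedAdviceStore(entries=entries), out_path)
    click.echo(f"advice for {len(entries)} cases -> {out_path}")


@cli.command()
@click.option("--cases", "cases_path", type=click.Path(exists=True), required=True)
@click.option("--guideline", "guideline_path", type=click.Path(exists=True), required=True)
@click.option("--advisor", "advisor_path", type=click.Path(exists=True), required=True)
@click.option("--matrix", "matrix_path", type=click.Path(exists=True), default=None)
@click.option("--catalogue", "catalogue_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def score(cases_path, guideline_path, advisor_path, matrix_path, catalogue_path,
          out_path) -> None:
    """Cross-tabulate two advice CSVs into a per-case results CSV."""
    catalogue = load_catalogue(catalogue_path) if catalogue_path else default_catalogue()
    matrix = load_matrix(matrix_path) if matrix_path else default_matrix()
    cases = read_cases_csv(cases_path)
    g_store = load_recorded(guideline_path, catalogue)
    a_store = load_recorded(advisor_path, catalogue)
    results = []
    for case in cases:
        g = g_store.entries[case.case_id].with_source(AdviceSource.GUIDELINE)
        a = a_store.entries[case.case_id]
        scored = score_case(
            g, a, matrix, catalogue, case_id=case.case_id, stage=derive_stage(case)
        )
        results.append(
            CaseResult(
                case_id=scored.case_id,
                per_option_scores=scored.per_option_scores,
                overall_score=scored.overall_score,
                flag=assign_flag(g, a, catalogue),
                stage=scored.stage,
            )
        )
    write_results_csv(results, catalogue, out_path)
    click.echo(f"{len(results)} results -> {out_path}")


@cli.command()
@click.option("--results", "results_path", type=click.Path(exists=True), required=True)
@click.option("--catalogue", "catalogue_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def report(results_path, catalogue_path, out_path) -> None:
    """Aggregate a results CSV into a summary JSON."""
    catalogue = load_catalogue(catalogue_path) if catalogue_path else default_catalogue()
    results = read_results_csv(results_path, catalogue)
    summary = aggregate(results)
    Path(out_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    click.echo(f"summary for {len(results)} results -> {out_path}")


@cli.command()
@click.option("--plan", "plan_path", type=click.Path(exists=True), default=None)
@click.option("--ruleset", "ruleset_path", type=click.Path(exists=True), default=None)
@click.option("--advisor", "advisor_kind", type=click.Choice(["mock", "recorded"]),
              default="mock", show_default=True)
@click.option("--advisor-ruleset", "advisor_ruleset_path", type=click.Path(exists=True),
              default=None, help="Backing ruleset for the mock advisor.")
@click.option("--recorded", "recorded_path", type=click.Path(exists=True), default=None)
@click.option("--perturb", "perturb_path", type=click.Path(exists=True), default=None)
@click.option("--matrix", "matrix_path", type=click.Path(exists=True), default=None)
@click.option("--catalogue", "catalogue_path", type=click.Path(exists=True), default=None)
@_mode_option
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def run(plan_path, ruleset_path, advisor_kind, advisor_ruleset_path, recorded_path,
        perturb_path, matrix_path, catalogue_path, mode, seed, out_dir) -> None:
    """Run the full pipeline: generate, advise, score, flag, report."""
    config = RunConfig(
        out_dir=out_dir,
        plan_path=plan_path,
        ruleset_path=ruleset_path,
        advisor_kind=advisor_kind,
        advisor_ruleset_path=advisor_ruleset_path,
        recorded_path=recorded_path,
        perturb_path=perturb_path,
        matrix_path=matrix_path,
        catalogue_path=catalogue_path,
        mode=EnumerationMode(mode),
        seed=seed,
    )
    bundle = run_evaluation(config)
    summary = bundle["summary"]
    click.echo(
        f"{summary['n']} cases scored; flags: {summary['flag_counts']}; "
        f"median {summary['score_median']} -> {out_dir}"
    )


if __name__ == "__main__":
    cli()
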