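# adviceaudit

Systematically audit a "black-box" treatment-advice system against an
executable clinical-guideline ruleset. The pipeline enumerates synthetic
patient cases from decision points, obtains a guideline recommendation and a
(black-box or mock) advisor recommendation per case, scores their agreement
with a cross-tabulation matrix (per-option scores −2..+2, overall case score
−12..+12 for the default 6-option catalogue), assigns red/orange safety
flags (red: the advisor *recommends* a chemotherapy the guideline marks not
recommended; orange: it suggests it *for consideration*; red takes
precedence), and aggregates results by tumor stage.

## Modules

| Module | Purpose |
| --- | --- |
| `adviceaudit.types` | Domain types: `PatientCase`, treatment catalogue, `TreatmentAdvice` (R/C/NR), case CSV dialect |
| `adviceaudit.rulesets` | Declarative decision trees + validator/interpreter; hard-coded Dutch adjuvant colon-cancer oracle and its packaged declarative equivalent |
| `adviceaudit.casegen` | Decision-point plans, full-factorial / path-deduplicated case enumeration, per-stage counts |
| `adviceaudit.advisors` | Advisor contract: perturbable ruleset-backed mock and recorded-advice replay (CSV/JSON) |
| `adviceaudit.concordance` | Score matrix, per-case scoring, flag assignment, aggregation |
| `adviceaudit.report_io` | End-to-end pipeline, artifact I/O, and the `adviceaudit` CLI |

Packaged fixtures live in `src/adviceaudit/data/`: the Dutch decision tree,
an editable NCCN-style ruleset template, the default score matrix, the
default enumeration plan (age tested at 45/60/75; resection margin,
perineural invasion, and functional status held at normal/absent; 9
guideline decision points, 13 advisor variables, 8 shared, 14 unique), and
the default treatment catalogue.

## CLI

```sh
# full pipeline: enumerate, advise, score, flag, report
adviceaudit run --mode PATH_DEDUP --seed 1 --out audit_out/

# or stage by stage
adviceaudit generate --mode FULL_FACTORIAL --out cases.csv
adviceaudit advise --cases cases.csv --out guideline.csv
adviceaudit advise --cases cases.csv --advisor mock --perturb perturb.yaml \
    --seed 1 --out advisor.csv
adviceaudit score --cases cases.csv --guideline guideline.csv \
    --advisor advisor.csv --out results.csv
adviceaudit report --results results.csv --out summary.json
```

Externally captured black-box advice can be replayed with
`--advisor recorded --recorded advice.csv` (columns: `case_id`,
`option_code`, `category`; options absent for a case are treated as NR).
A perturbation file (`{"shifts": {"R->C": 0.3}}`, YAML or JSON) makes the
mock advisor emulate a discordant black box, reproducibly seeded per
(seed, case, option). Custom rulesets, matrices, catalogues, and plans are
plain JSON/YAML files swapped in via the corresponding flags.

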