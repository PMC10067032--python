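"""End-to-end runs: simulate a trial, analyse it, render a report.

Every run writes a config JSON sidecar and logs the master seed, so any
output file is traceable to the configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DATASET_COLUMNS, SimConfig, read_dataset, simulate_trial, write_dataset
from .models import ModelSpec, arm_difference, fit_multilevel_ordinal, fit_random_intercept, wald_test
from .woa import GROUPINGS, TRUNCATION_POLICIES, analysis_records, build_woa_table, summarize

log = logging.getLogger("advicetrial")


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")

#: Moderator analyses, one interaction model per moderator.
MODERATOR_TERMS = ("profession", "total_experience", "palliative_experience", "strength")


@dataclass
class RunConfig:
    """Configuration of a full simulate-and-analyse run."""

    sim: SimConfig = field(default_factory=SimConfig)
    truncation_policy: str = "clamp"
    output_dir: Path = Path("advicetrial_output")
    fit_ordinal: bool = True

    def __post_init__(self) -> None:
        if self.truncation_policy not in TRUNCATION_POLICIES:
            raise ValueError(f"invalid truncation policy {self.truncation_policy!r}")
        self.output_dir = Path(self.output_dir)


def run_simulate(config: RunConfig) -> Path:
    """Generate and write a synthetic trial dataset; returns the CSV path."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    df = simulate_trial(config.sim)
    path = out / "dataset.csv"
    write_dataset(df, path, config.sim)
    completers = df.groupby("participant_id")["completed"].all()
    by_arm = df.drop_duplicates("participant_id")["arm"].value_counts()
    log.info("simulated %d participants (seed=%d): %s; completers=%d",
             config.sim.n_participants, config.sim.seed,
             by_arm.to_dict(), int(completers.sum()))
    return path


def run_analyze(dataset: str | Path, config: RunConfig) -> dict:
    """Score WOA, summarise, and fit the multilevel models.

    Writes woa.csv, summary CSVs, and fit JSONs under the output directory;
    returns the results as a dict.  Raises on schema mismatch; fit
    convergence failures are recorded, never silenced.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    df = read_dataset(dataset)
    woa_table = build_woa_table(df, policy=config.truncation_policy)
    woa_table.to_csv(out / "woa.csv", index=False)

    records = analysis_records(woa_table)
    summaries = {}
    for name in GROUPINGS:
        tab = summarize(records, name)
        tab.to_csv(out / f"summary_{name}.csv", index=False)
        summaries[name] = tab

    results: dict = {
        "n_enrolled": int(df["participant_id"].nunique()),
        "n_analysed": int(records["participant_id"].nunique()),
        "n_records_analysed": int(len(records)),
        "n_excluded_tie": int((woa_table["reason"] == "tie").sum()),
        "n_excluded_incomplete": int(
            woa_table.loc[woa_table["reason"] == "incomplete", "participant_id"].nunique()
        ),
        "truncation_policy": config.truncation_policy,
    }

    est, ci, p = arm_difference(records)
    primary = fit_random_intercept(records, ModelSpec(fixed_effects=["arm"]))
    results["arm_difference"] = {"estimate": est, "ci95": list(ci), "p": p}
    results["primary_fit"] = primary.to_dict()

    moderators = {}
    for term in MODERATOR_TERMS:
        spec = ModelSpec(fixed_effects=["arm", term, f"arm:{term}"])
        fit = fit_random_intercept(records, spec)
        stat, dof, pval = wald_test(fit, [f"arm:{term}"])
        moderators[term] = {
            "fit": fit.to_dict(),
            "interaction_wald": {"statistic": stat, "df": dof, "p": pval},
        }
    results["moderators"] = moderators

    if config.fit_ordinal:
        ordinal = fit_multilevel_ordinal(records, ModelSpec(response="bin", fixed_effects=["arm"]))
        results["ordinal_fit"] = ordinal.to_dict()

    converged = primary.converged and all(
        m["fit"]["converged"] for m in moderators.values()
    )
    results["all_converged"] = bool(converged)
    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=_json_default) + "\n"
    )
    log.info("analysis written to %s (arm difference %.3f, p=%.3g)", out, est, p)
    return results


def run_report(results_dir: str | Path) -> str:
    """Render a markdown report from a results directory.

    Deterministic: identical inputs produce byte-identical text.
    """
    results_dir = Path(results_dir)
    path = results_dir / "results.json"
    missing = [str(p) for p in (path,) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing result files: {missing}")
    res = json.loads(path.read_text())

    lines = ["# Advice-taking trial analysis", ""]
    lines.append(f"Participants enrolled: {res['n_enrolled']}; "
                 f"analysed (per protocol): {res['n_analysed']}; "
                 f"records analysed: {res['n_records_analysed']} "
                 f"(ties excluded: {res['n_excluded_tie']}).")
    ad = res["arm_difference"]
    lines.append("")
    lines.append(
        f"**Arm difference (clinician - algorithm) in mean WOA: "
        f"{ad['estimate']:+.3f} (95% CI {ad['ci95'][0]:.3f}, "
        f"{ad['ci95'][1]:.3f}; p = {ad['p']:.2g})**"
    )
    lines.append("")
    lines.append("## Moderator interactions (one model per moderator)")
    lines.append("")
    lines.append("| moderator | Wald chi2 | df | p |")
    lines.append("|---|---|---|---|")
    for term, m in res["moderators"].items():
        w = m["interaction_wald"]
        lines.append(f"| arm x {term} | {w['statistic']:.2f} | {w['df']} | {w['p']:.3g} |")
    if "ordinal_fit" in res:
        of = res["ordinal_fit"]
        arm_coef = of["beta"].get("arm[CLINICIAN]")
        lin = ad["estimate"]
        concord = (arm_coef is not None and arm_coef * lin > 0) or (
            arm_coef == 0 and lin == 0
        )
        lines.append("")
        lines.append("## Ordinal sensitivity analysis")
        lines.append("")
        lines.append(
            f"Proportional-odds arm effect: {arm_coef:+.3f} "
            f"(sigma_u^2 = {of['sigma_u2']:.3f}); "
            + ("sign concordant with the linear model."
               if concord else "sign NOT concordant with the linear model.")
        )
    bad = [k for k in ("primary_fit",) if not res[k]["converged"]] + [
        f"moderator:{t}" for t, m in res["moderators"].items()
        if not m["fit"]["converged"]
    ]
    if bad or not res.get("all_converged", True):
        lines.append("")
        lines.append(f"**WARNING: non-convergence in {bad or 'some fits'}**")
    lines.append("")
    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    return text
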