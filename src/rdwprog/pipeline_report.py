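"""End-to-end pipeline: simulate (or load) -> fit -> compare -> trajectories -> association.

Produces a ReportBundle mirroring the four analysis tables — baseline
characteristics by ICU survival, odds-ratio tables for the base and
enhanced models, discrimination/reclassification comparisons for all three
outcomes, and the trajectory-class mortality table with the combined
late-upward vs late-downward test — plus a provenance block (config, seed,
package version) sufficient to regenerate every number. The JSON report
carries full precision; the text report rounds to the conventional display
precision (AUC 3 dp, OR 2 dp, percentages 1 dp). Stage timings go to the
log, never into the report, so identical (config, seed) runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_data import (
    CohortTable,
    RDWSeries,
    read_cohort,
    read_rdw_long,
    write_cohort,
    write_rdw_long,
)
from .contingency import (
    ContingencyTable,
    chi_square_test,
    fisher_exact_2x2,
    fisher_exact_rxc,
    late_direction_table,
)
from .errors import ConfigError, PipelineError
from .model_comparison import ComparisonResult, compare_models
from .risk_models import ModelSpec, fit_logistic, odds_ratios
from .synthetic_cohort import GeneratorConfig, generate_cohort
from .trajectory import CLASSES, classify_cohort

log = logging.getLogger("rdwprog.pipeline")

OUTCOME_LABELS = {
    "icu": "ICU mortality",
    "hospital": "In-hospital mortality",
    "day90": "90-day mortality",
}


@dataclass(frozen=True)
class ReportBundle:
    """All pipeline outputs: four analysis tables plus provenance."""

    baseline: dict
    odds_ratio_tables: dict
    comparisons: dict
    trajectory_table: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "odds_ratios": self.odds_ratio_tables,
            "comparisons": self.comparisons,
            "trajectories": self.trajectory_table,
            "provenance": self.provenance,
        }


def baseline_table(cohort: CohortTable) -> dict:
    """Baseline characteristics split by ICU survival status.

    Continuous covariates as mean (SD); sex and comorbidity category as
    n (%). The SD of a single-patient group is reported as None rather
    than raising or printing zero.
    """
    frame = cohort.to_frame()
    groups = {
        "survivors": frame[~frame["icu_death"]],
        "nonsurvivors": frame[frame["icu_death"]],
        "all": frame,
    }

    def mean_sd(g: pd.DataFrame, col: str):
        if len(g) == 0:
            return {"mean": None, "sd": None, "n": 0}
        sd = float(g[col].std(ddof=1)) if len(g) > 1 else None
        return {"mean": float(g[col].mean()), "sd": sd, "n": int(len(g))}

    def count_pct(g: pd.DataFrame, mask: pd.Series):
        k = int(mask.sum())
        return {"n": k, "pct": 100.0 * k / len(g) if len(g) else None}

    out: dict = {}
    for name, g in groups.items():
        block = {
            "n": int(len(g)),
            "age": mean_sd(g, "age"),
            "rdw_baseline": mean_sd(g, "rdw_baseline"),
            "pf_ratio": mean_sd(g, "pf_ratio"),
            "sofa": mean_sd(g, "sofa"),
            "male": count_pct(g, g["sex"] == "male") if len(g) else {"n": 0, "pct": None},
            "female": count_pct(g, g["sex"] == "female") if len(g) else {"n": 0, "pct": None},
            "comorbidity": {
                cat: count_pct(g, g["comorbidity_category"] == cat) if len(g) else
                {"n": 0, "pct": None}
                for cat in ("0", "1", "2", "3plus")
            },
        }
        out[name] = block
    return out


def _or_table_dict(cohort: CohortTable, outcome: str) -> dict:
    out = {}
    for label, include in (("base", False), ("enhanced", True)):
        fit = fit_logistic(cohort, ModelSpec(outcome=outcome, include_rdw=include))
        tab = odds_ratios(fit)
        out[label] = {
            term: {
                "or": float(row["or"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
            }
            for term, row in tab.iterrows()
        }
        out[label]["converged"] = fit.converged
        out[label]["n"] = fit.n_used
    return out


def _comparison_dict(c: ComparisonResult) -> dict:
    return {
        "auc": {
            "base": c.delong.auc_base,
            "enhanced": c.delong.auc_new,
            "delta": c.delong.delta,
            "ci": list(c.delong.ci),
            "p": c.delong.p,
        },
        "nri": {
            "total": c.nri.total,
            "event_component": c.nri.event_component,
            "nonevent_component": c.nri.nonevent_component,
            "ci": list(c.nri.ci),
            "p": c.nri.p,
        },
        "idi": {
            "total": c.idi.total,
            "mean_base_events": c.idi.mean_base_events,
            "mean_new_events": c.idi.mean_new_events,
            "mean_base_nonevents": c.idi.mean_base_nonevents,
            "mean_new_nonevents": c.idi.mean_new_nonevents,
            "ci": list(c.idi.ci),
            "p": c.idi.p,
        },
        "n_events": c.n_events,
        "n_nonevents": c.n_nonevents,
    }


def trajectory_table(
    cohort: CohortTable,
    series: tuple[RDWSeries, ...],
    alpha: float = 0.05,
    min_obs: int = 4,
    rxc_method: str = "exact",
    seed: int = 0,
) -> dict:
    """Trajectory-class mortality table with association tests.

    In-hospital deaths are cross-tabulated against the five trajectory
    classes (chi-square and R x C Fisher), and the combined late-upward
    (up + convex) vs late-downward (down + concave) groups are compared
    with both the 2x2 Fisher exact test and the uncorrected chi-square.
    """
    summary = classify_cohort(series, alpha=alpha, min_obs=min_obs)
    hosp = {r.patient_id: r.hosp_death for r in cohort}
    tab = summary.table
    tab = tab[tab["trajectory_class"] != "excluded"].copy()
    tab["hosp_death"] = tab["patient_id"].map(hosp)
    if tab["hosp_death"].isna().any():
        missing = tab.loc[tab["hosp_death"].isna(), "patient_id"].tolist()[:5]
        raise ConfigError(
            f"RDW series patients missing from the cohort table: {missing}"
        )

    classes = {}
    counts_grid = []
    for cls in CLASSES:
        sub = tab[tab["trajectory_class"] == cls]
        died = int(sub["hosp_death"].sum())
        total = int(len(sub))
        classes[cls] = {
            "n": total,
            "deaths": died,
            "mortality_pct": 100.0 * died / total if total else None,
        }
        counts_grid.append([died, total - died])

    out: dict = {
        "classes": classes,
        "n_classified": int(len(tab)),
        "n_excluded": int(summary.n_excluded),
    }
    grid = np.asarray(counts_grid)
    if np.all(grid.sum(axis=1) > 0) and np.all(grid.sum(axis=0) > 0):
        five = ContingencyTable.from_array(
            grid, row_labels=CLASSES, col_labels=("died", "survived")
        )
        out["five_class_test"] = {
            "chi_square": chi_square_test(five).__dict__,
            "fisher": {
                "p": fisher_exact_rxc(five, method=rxc_method, seed=seed).p,
                "method": rxc_method,
            },
        }
    up = tab[tab["late_direction"] == "late_up"]
    down = tab[tab["late_direction"] == "late_down"]
    if len(up) and len(down):
        two = late_direction_table(
            int(up["hosp_death"].sum()), len(up),
            int(down["hosp_death"].sum()), len(down),
        )
        fisher = fisher_exact_2x2(two)
        out["combined_test"] = {
            "late_up": {"n": int(len(up)), "deaths": int(up["hosp_death"].sum()),
                        "mortality_pct": 100.0 * up["hosp_death"].mean()},
            "late_down": {"n": int(len(down)), "deaths": int(down["hosp_death"].sum()),
                          "mortality_pct": 100.0 * down["hosp_death"].mean()},
            "fisher_p": fisher.p,
            "chi_square_p": chi_square_test(two).p
            if min(two.to_array().sum(axis=0).min(), two.to_array().sum(axis=1).min()) > 0
            else None,
        }
    return out


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def run_pipeline(
    config: str | Path | Mapping,
    out_dir: str | Path | None = None,
    quiet: bool = False,
) -> ReportBundle:
    """Run simulate/load -> fit -> compare -> trajectories -> association.

    ``config`` is a path to (or mapping of) a pipeline configuration with
    either a ``generator`` block (simulate mode) or ``cohort_csv`` +
    ``rdw_csv`` paths (user mode). Writes ``report.json`` and
    ``report.txt`` (and, in simulate mode, the generated CSVs plus a
    provenance JSON) into ``out_dir`` when given.
    """
    t0 = time.perf_counter()
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = dict(config)

    def stage(name):
        if not quiet:
            log.info("stage %-12s t=%.2fs", name, time.perf_counter() - t0)

    if "generator" in config:
        gen_dict = dict(config["generator"])
        gen = GeneratorConfig.from_dict(gen_dict)
        stage("simulate")
        try:
            cohort, series = generate_cohort(gen)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("simulate", exc) from exc
        prov_inputs = {"mode": "simulate", "generator": gen.to_dict()}
    elif "cohort_csv" in config and "rdw_csv" in config:
        stage("load")
        try:
            cohort = read_cohort(config["cohort_csv"])
            series = read_rdw_long(config["rdw_csv"])
        except Exception as exc:
            raise PipelineError("load", exc) from exc
        prov_inputs = {
            "mode": "user",
            "cohort_csv": str(config["cohort_csv"]),
            "rdw_csv": str(config["rdw_csv"]),
        }
    else:
        raise ConfigError(
            "config needs either a 'generator' block or 'cohort_csv' + 'rdw_csv'",
            field="generator",
        )

    alpha = float(config.get("alpha", 0.05))
    min_obs = int(config.get("min_obs", 4))
    seed = int(config.get("seed", config.get("generator", {}).get("seed", 0)))
    rxc_method = str(config.get("rxc_method", "exact"))

    stage("baseline")
    try:
        baseline = baseline_table(cohort)
    except Exception as exc:
        raise PipelineError("baseline", exc) from exc

    stage("fit")
    ors = {}
    comparisons = {}
    for outcome in ("icu", "hospital", "day90"):
        try:
            ors[outcome] = _or_table_dict(cohort, outcome)
            comparisons[outcome] = _comparison_dict(compare_models(cohort, outcome))
        except Exception as exc:
            raise PipelineError(f"fit/compare ({outcome})", exc) from exc

    stage("trajectories")
    try:
        traj = trajectory_table(
            cohort, series, alpha=alpha, min_obs=min_obs,
            rxc_method=rxc_method, seed=seed,
        )
    except Exception as exc:
        raise PipelineError("trajectories", exc) from exc

    bundle = ReportBundle(
        baseline=baseline,
        odds_ratio_tables=ors,
        comparisons=comparisons,
        trajectory_table=traj,
        provenance={
            "inputs": prov_inputs,
            "seed": seed,
            "alpha": alpha,
            "min_obs": min_obs,
            "version": __version__,
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stage("write")
        if prov_inputs["mode"] == "simulate":
            write_cohort(cohort, out_dir / "cohort.csv")
            write_rdw_long(series, out_dir / "rdw_long.csv")
            (out_dir / "provenance.json").write_text(
                json.dumps(bundle.provenance, indent=2, sort_keys=True)
            )
        (out_dir / "report.json").write_text(
            json.dumps(bundle.to_dict(), indent=2, sort_keys=True)
        )
        (out_dir / "report.txt").write_text(render_text_report(bundle))
    stage("done")
    return bundle


def _fmt(x, nd):
    return "NA" if x is None else f"{x:.{nd}f}"


def render_text_report(bundle: ReportBundle) -> str:
    """Human-readable report at display precision."""
    lines: list[str] = []
    b = bundle.baseline
    lines.append("=== Baseline characteristics by ICU survival ===")
    lines.append(
        f"{'':28s}{'Survivors':>14s}{'Nonsurvivors':>14s}{'All':>14s}"
    )
    lines.append(
        f"{'n':28s}{b['survivors']['n']:>14d}{b['nonsurvivors']['n']:>14d}"
        f"{b['all']['n']:>14d}"
    )
    for key, label in (
        ("age", "Age, mean (SD)"),
        ("rdw_baseline", "RDW %, mean (SD)"),
        ("pf_ratio", "PaO2/FiO2, mean (SD)"),
        ("sofa", "SOFA, mean (SD)"),
    ):
        row = [
            f"{_fmt(b[g][key]['mean'], 1)} ({_fmt(b[g][key]['sd'], 1)})"
            for g in ("survivors", "nonsurvivors", "all")
        ]
        lines.append(f"{label:28s}{row[0]:>14s}{row[1]:>14s}{row[2]:>14s}")
    for key, label in (("male", "Male, n (%)"), ("female", "Female, n (%)")):
        row = [
            f"{b[g][key]['n']} ({_fmt(b[g][key]['pct'], 1)})"
            for g in ("survivors", "nonsurvivors", "all")
        ]
        lines.append(f"{label:28s}{row[0]:>14s}{row[1]:>14s}{row[2]:>14s}")

    lines.append("")
    lines.append("=== Odds ratios (95% CI) ===")
    for outcome, tabs in bundle.odds_ratio_tables.items():
        lines.append(f"-- {OUTCOME_LABELS[outcome]} --")
        terms = [t for t in tabs["enhanced"] if t not in ("converged", "n")]
        lines.append(f"{'term':16s}{'base':>22s}{'enhanced':>22s}")
        for term in terms:
            cells = []
            for label in ("base", "enhanced"):
                if term in tabs[label]:
                    e = tabs[label][term]
                    cells.append(
                        f"{e['or']:.2f} ({e['ci_low']:.2f}, {e['ci_high']:.2f})"
                    )
                else:
                    cells.append("-")
            lines.append(f"{term:16s}{cells[0]:>22s}{cells[1]:>22s}")

    lines.append("")
    lines.append("=== Added value of RDW (base vs enhanced) ===")
    for outcome, c in bundle.comparisons.items():
        a, nri, idi_ = c["auc"], c["nri"], c["idi"]
        lines.append(f"-- {OUTCOME_LABELS[outcome]} --")
        lines.append(
            f"AUC {a['base']:.3f} -> {a['enhanced']:.3f}, delta {a['delta']:.3f} "
            f"({a['ci'][0]:.3f}, {a['ci'][1]:.3f}), p={a['p']:.3g}"
        )
        lines.append(
            f"NRI {nri['total']:.3f} ({nri['ci'][0]:.3f}, {nri['ci'][1]:.3f}), "
            f"p={nri['p']:.3g} [events {100 * nri['event_component']:.0f}%, "
            f"non-events {100 * nri['nonevent_component']:.0f}%]"
        )
        lines.append(
            f"IDI {idi_['total']:.3f} ({idi_['ci'][0]:.3f}, {idi_['ci'][1]:.3f}), "
            f"p={idi_['p']:.3g}"
        )

    lines.append("")
    lines.append("=== RDW trajectory classes and in-hospital mortality ===")
    t = bundle.trajectory_table
    lines.append(f"{'class':10s}{'n':>6s}{'deaths':>8s}{'mortality %':>13s}")
    for cls, e in t["classes"].items():
        lines.append(
            f"{cls:10s}{e['n']:>6d}{e['deaths']:>8d}{_fmt(e['mortality_pct'], 1):>13s}"
        )
    lines.append(f"excluded (<min measurements): {t['n_excluded']}")
    if "five_class_test" in t:
        f5 = t["five_class_test"]
        lines.append(
            f"5-class: chi2={f5['chi_square']['statistic']:.2f} "
            f"(df {f5['chi_square']['df']}), p={f5['chi_square']['p']:.2f}; "
            f"Fisher p={f5['fisher']['p']:.2f}"
        )
    if "combined_test" in t:
        ct = t["combined_test"]
        lines.append(
            f"late-up {ct['late_up']['deaths']}/{ct['late_up']['n']} "
            f"({ct['late_up']['mortality_pct']:.0f}%) vs late-down "
            f"{ct['late_down']['deaths']}/{ct['late_down']['n']} "
            f"({ct['late_down']['mortality_pct']:.0f}%): "
            f"Fisher p={ct['fisher_p']:.3f}, chi2 p={ct['chi_square_p']:.3f}"
        )
    lines.append("")
    lines.append(f"rdwprog {bundle.provenance['version']}, seed {bundle.provenance['seed']}")
    return "\n".join(lines) + "\n"
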