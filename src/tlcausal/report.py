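"""Roadmap orchestration: diagnostics -> estimation -> sensitivity.

`run_roadmap` walks the staged procedure on a cohort and returns a single
structured report (a plain dict, JSON-serializable): the configuration
echo, cohort summary, identifiability diagnostics, the targeted estimates
with super-learner summaries, and the causal-gap sensitivity block. In
strict-positivity mode an empty treated/control cell in any declared
stratification aborts estimation (raising
:class:`IdentifiabilityError`); in permissive mode the report records the
flags and estimation proceeds under truncation.

A minimal structural schema ships with the module and every emitted
report validates against it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, RunConfig, read_cohort, resolve_ps_bound
from .diagnostics import (
    DoseGroupSpec,
    crude_dose_proportions,
    positivity_table,
    ps_cstat,
    ps_overlap_summary,
)
from .simulate import SimConfig, generate_cohort
from .tmle import TMLE

__all__ = [
    "IdentifiabilityError",
    "run_roadmap",
    "load_run_spec",
    "validate_report",
    "REPORT_SCHEMA",
]


class IdentifiabilityError(RuntimeError):
    """Hard positivity failure in strict mode: estimation was not attempted."""


# Structural schema: required key -> expected type (dict means nested block).
REPORT_SCHEMA: dict[str, Any] = {
    "config": dict,
    "seed": int,
    "version": str,
    "cohort": {
        "n": int,
        "n_events": int,
        "n_treated": int,
        "n_control": int,
    },
    "diagnostics": {
        "positivity": dict,
        "any_empty_cells": bool,
    },
    "estimation": dict,   # empty when aborted
    "sensitivity": dict,  # empty when aborted
}


def validate_report(report: Mapping, schema: Mapping | None = None, path: str = "") -> None:
    """Raise ValueError when the report does not match the shipped schema."""
    if schema is None:
        schema = REPORT_SCHEMA
    for key, expected in schema.items():
        here = f"{path}.{key}" if path else key
        if key not in report:
            raise ValueError(f"report missing required key {here!r}")
        value = report[key]
        if isinstance(expected, dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"report key {here!r} must be a mapping")
            validate_report(value, expected, here)
        elif not isinstance(value, expected):
            raise ValueError(
                f"report key {here!r} must be {expected.__name__}, "
                f"got {type(value).__name__}"
            )


def _categorical_columns(cohort: Cohort, max_levels: int = 10) -> list[str]:
    cols = []
    for c in cohort.w.columns:
        if cohort.w[c].nunique() <= max_levels:
            cols.append(c)
    return cols


def _diagnose(cohort: Cohort, config: RunConfig) -> dict:
    block: dict[str, Any] = {"positivity": {}, "any_empty_cells": False}
    for col in _categorical_columns(cohort):
        table = positivity_table(cohort.w[col].to_numpy(), cohort.a)
        flags = table.empty_cell_flags()
        block["positivity"][col] = {
            "categories": [str(l) for l in table.labels],
            "control": table.control.tolist(),
            "treated": table.treated.tolist(),
            "zero_treated": [str(l) for l in flags["zero_treated"]],
            "zero_control": [str(l) for l in flags["zero_control"]],
        }
        if table.has_empty_cells:
            block["any_empty_cells"] = True
    if cohort.dose is not None:
        spec = DoseGroupSpec(cut_points=tuple(config.dose_cut_points))
        dose_df = crude_dose_proportions(cohort.dose, cohort.y, spec)
        block["dose_groups"] = dose_df.where(pd.notna(dose_df), None).to_dict("records")
        block["dose_non_monotonic"] = bool(dose_df.attrs["non_monotonic"])
    return block


def run_roadmap(
    cohort: Cohort,
    config: RunConfig,
    seed: int | None = None,
    strict_positivity: bool | None = None,
) -> dict:
    """Execute the staged analysis and return the structured report."""
    if seed is None:
        seed = config.seed
    if strict_positivity is None:
        strict_positivity = config.strict_positivity

    report: dict[str, Any] = {
        "config": {
            f.name: (list(v) if isinstance(v := getattr(config, f.name), (tuple, list))
                     else v)
            for f in dataclasses.fields(config)
        },
        "seed": int(seed),
        "version": __version__,
        "cohort": {
            "n": cohort.n,
            "n_events": cohort.n_events,
            "n_treated": cohort.n_treated,
            "n_control": cohort.n - cohort.n_treated,
        },
        "estimation": {},
        "sensitivity": {},
    }
    diag = _diagnose(cohort, config)
    report["diagnostics"] = diag

    if strict_positivity and diag["any_empty_cells"]:
        empty = {c: v for c, v in diag["positivity"].items()
                 if v["zero_treated"] or v["zero_control"]}
        report["aborted"] = (
            "strict positivity: empty treated/control cells in "
            + ", ".join(sorted(empty))
        )
        validate_report(report)
        return report

    model = TMLE(cohort, config)
    res = model.fit(seed=seed)
    est_block = res.to_dict()
    if res.nuisances_initial.outcome_fit is not None:
        est_block["outcome_sl"] = res.nuisances_initial.outcome_fit.summary_dict()
    if res.nuisances_initial.ps_fit is not None:
        est_block["ps_sl"] = res.nuisances_initial.ps_fit.summary_dict()
        g_raw = res.nuisances_initial.g_raw
        bound = res.nuisances_initial.bound
        est_block["ps_cstat"] = ps_cstat(g_raw, cohort.a)
        est_block["ps_overlap"] = ps_overlap_summary(
            g_raw, cohort.a, bins=10, bound=bound
        )
    report["estimation"] = est_block

    sens = res.sensitivity()
    report["sensitivity"] = sens.to_dict()
    report["_results"] = res  # live object for callers; stripped before writing
    report["_sensitivity_table"] = sens.table
    validate_report(report)
    return report


def write_report_outputs(report: dict, outdir: str | Path) -> None:
    """Write report.json plus the figure-backing CSV tables and the
    per-subject influence-curve audit file."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = report.pop("_results", None)
    sens_table = report.pop("_sensitivity_table", None)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    if res is not None:
        pd.DataFrame({
            "ic_rd": res.ic,
            "ic_psi1": res.ic1,
            "ic_psi0": res.ic0,
        }).to_csv(outdir / "ic_values.csv", index=False)
        overlap = report["estimation"].get("ps_overlap")
        if overlap:
            edges = overlap["bin_edges"]
            pd.DataFrame({
                "bin_lower": edges[:-1],
                "bin_upper": edges[1:],
                "treated_proportion": overlap["treated_proportions"],
                "control_proportion": overlap["control_proportions"],
            }).to_csv(outdir / "fig3_table.csv", index=False)
    if "dose_groups" in report.get("diagnostics", {}):
        pd.DataFrame(report["diagnostics"]["dose_groups"]).to_csv(
            outdir / "fig2_table.csv", index=False
        )
    if sens_table is not None:
        sens_table.to_csv(outdir / "fig4_table.csv", index=False)


def load_run_spec(path: str | Path) -> tuple[RunConfig, Path | None, SimConfig | None]:
    """Parse a run configuration file.

    Top-level keys: ``run`` (RunConfig fields), and either ``input`` (a
    cohort CSV path, relative to the config file) or ``simulate``
    (SimConfig fields).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    run_cfg = RunConfig(**(raw.get("run") or {}))
    input_path = raw.get("input")
    if input_path is not None:
        input_path = (path.parent / input_path).resolve()
    sim_cfg = None
    if raw.get("simulate") is not None:
        sim_cfg = SimConfig(**raw["simulate"])
    if input_path is None and sim_cfg is None:
        raise ValueError("config must provide an 'input' path or a 'simulate' block")
    return run_cfg, input_path, sim_cfg


def resolve_cohort(run_cfg: RunConfig, input_path: Path | None,
                   sim_cfg: SimConfig | None) -> Cohort:
    if input_path is not None:
        return read_cohort(input_path, run_cfg)
    cohort, _ = generate_cohort(sim_cfg, compute_truth=False)
    return cohort
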