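"""Identifiability and positivity diagnostics.

Pre-fit: per-stratum treated/control counts with empty-cell flags, and
order-respecting category collapsing (the remedy for sparse strata).
Post-fit: propensity-score discrimination (C-statistic), per-arm overlap
summaries, crude dose-group event proportions, and a main-terms logistic
dose model kept only as a baseline comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .cohort import Cohort, DEFAULT_DOSE_CUTS

__all__ = [
    "StratumTable",
    "DoseGroupSpec",
    "positivity_table",
    "collapse_categories",
    "ps_cstat",
    "ps_overlap_summary",
    "crude_dose_proportions",
    "assign_dose_groups",
    "baseline_logistic_or",
]


@dataclass
class StratumTable:
    """Treated/control counts per ordered category."""

    labels: list
    control: np.ndarray
    treated: np.ndarray

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=int)
        self.treated = np.asarray(self.treated, dtype=int)
        if not (len(self.labels) == len(self.control) == len(self.treated)):
            raise ValueError("labels, control and treated must share length")
        if (self.control < 0).any() or (self.treated < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.control.sum() + self.treated.sum())

    def empty_cell_flags(self) -> dict[str, list]:
        """Categories violating positivity in-sample."""
        zero_treated = [l for l, t in zip(self.labels, self.treated) if t == 0]
        zero_control = [l for l, c in zip(self.labels, self.control) if c == 0]
        return {"zero_treated": zero_treated, "zero_control": zero_control}

    @property
    def has_empty_cells(self) -> bool:
        flags = self.empty_cell_flags()
        return bool(flags["zero_treated"] or flags["zero_control"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.labels, "control": self.control, "treated": self.treated}
        )


def positivity_table(values: Sequence, a: np.ndarray,
                     labels: Sequence | None = None) -> StratumTable:
    """Cross-tabulate a categorical covariate against treatment arm.

    ``labels`` fixes the category order (and includes empty categories);
    otherwise categories appear in sorted order of observed values.
    """
    values = np.asarray(values, dtype=object)
    a = np.asarray(a)
    if len(values) != len(a):
        raise ValueError("values and a must share length")
    if labels is None:
        labels = sorted(set(values.tolist()))
    control = np.array([int(np.sum((values == l) & (a == 0))) for l in labels])
    treated = np.array([int(np.sum((values == l) & (a == 1))) for l in labels])
    return StratumTable(labels=list(labels), control=control, treated=treated)


def collapse_categories(table: StratumTable, mapping: Mapping) -> StratumTable:
    """Merge categories per ``mapping`` (old label -> new label).

    Only order-respecting collapses are allowed: the old labels mapped to
    a common new label must be contiguous in the table's ordering. Counts
    are summed within new labels; totals are preserved.
    """
    missing = [l for l in table.labels if l not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover labels {missing}")
    new_order: list = []
    positions: dict = {}
    for i, old in enumerate(table.labels):
        new = mapping[old]
        if new not in positions:
            positions[new] = [i]
            new_order.append(new)
        else:
            positions[new].append(i)
    for new, idxs in positions.items():
        if max(idxs) - min(idxs) + 1 != len(idxs):
            raise ValueError(f"non-contiguous merge for new label {new!r}")
    control = np.array([table.control[positions[l]].sum() for l in new_order])
    treated = np.array([table.treated[positions[l]].sum() for l in new_order])
    return StratumTable(labels=new_order, control=control, treated=treated)


def ps_cstat(g: np.ndarray, a: np.ndarray) -> float:
    """Concordance (AUC) of the propensity score against treatment.

    The probability that a random treated subject's score exceeds a random
    control subject's, with ties counted 1/2 (Mann–Whitney convention).
    """
    a = np.asarray(a)
    if a.sum() == 0 or a.sum() == len(a):
        raise ValueError("both arms must be non-empty to compute a C-statistic")
    return float(roc_auc_score(a, np.asarray(g, dtype=float)))


def ps_overlap_summary(g: np.ndarray, a: np.ndarray, bins: int = 10,
                       bound: float | None = None) -> dict:
    """Per-arm propensity histograms on a shared [0, 1] grid plus ranges.

    Reports the shared-bin overlap mass (sum of per-bin minima of the two
    arm proportions), per-arm min/max, and — when a truncation ``bound``
    is given — how many scores fall at or beyond it, with a
    ``truncation_no_impact`` flag when none do.
    """
    if bins < 2:
        raise ValueError("bins must be at least 2")
    g = np.asarray(g, dtype=float)
    a = np.asarray(a)
    edges = np.linspace(0.0, 1.0, bins + 1)
    out: dict = {"bin_edges": edges.tolist()}
    props = {}
    for arm, name in ((1, "treated"), (0, "control")):
        vals = g[a == arm]
        hist, _ = np.histogram(vals, bins=edges)
        p = hist / max(len(vals), 1)
        props[name] = p
        out[f"{name}_proportions"] = p.tolist()
        out[f"{name}_min"] = float(vals.min()) if len(vals) else float("nan")
        out[f"{name}_max"] = float(vals.max()) if len(vals) else float("nan")
    out["overlap_mass"] = float(np.minimum(props["treated"], props["control"]).sum())
    if bound is not None:
        n_extreme = int(np.sum((g <= bound) | (g >= 1.0 - bound)))
        out["bound"] = float(bound)
        out["n_at_or_beyond_bound"] = n_extreme
        out["truncation_no_impact"] = n_extreme == 0
    return out


@dataclass(frozen=True)
class DoseGroupSpec:
    """Seven total-dose categories: 0 (untreated) and six half-open
    intervals (0,10], (10,20], ..., (40,50], (50, inf) on the 72 mg/24 h
    scale."""

    cut_points: Sequence[float] = DEFAULT_DOSE_CUTS

    def __post_init__(self) -> None:
        cuts = list(self.cut_points)
        if sorted(cuts) != cuts or len(set(cuts)) != len(cuts) or any(c <= 0 for c in cuts):
            raise ValueError("cut points must be positive and strictly increasing")

    @property
    def n_groups(self) -> int:
        return len(self.cut_points) + 2

    @property
    def labels(self) -> list[str]:
        cuts = list(self.cut_points)
        labels = ["0"]
        lo = 0.0
        for c in cuts:
            labels.append(f">{lo:g}-{c:g}")
            lo = c
        labels.append(f">{lo:g}")
        return labels


def assign_dose_groups(dose: np.ndarray, spec: DoseGroupSpec | None = None) -> np.ndarray:
    """Map non-negative doses to group indices 0..k+1 (group 0 iff dose=0,
    right-closed intervals above)."""
    if spec is None:
        spec = DoseGroupSpec()
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise ValueError("dose must be non-negative")
    cuts = np.asarray(spec.cut_points, dtype=float)
    # side='left' makes intervals right-closed: dose exactly at a cut stays below
    group = 1 + np.searchsorted(cuts, dose, side="left")
    group[dose == 0.0] = 0
    return group.astype(int)


def crude_dose_proportions(dose: np.ndarray, y: np.ndarray,
                           spec: DoseGroupSpec | None = None) -> pd.DataFrame:
    """Crude event proportion per dose group (the figure-backing table for
    the dose–response plot). Empty groups are reported with n=0 and NaN
    proportion; a ``non_monotonic`` attribute flags any non-monotone
    pattern across non-empty groups."""
    if spec is None:
        spec = DoseGroupSpec()
    y = np.asarray(y)
    group = assign_dose_groups(dose, spec)
    rows = []
    for k in range(spec.n_groups):
        mask = group == k
        n_k = int(mask.sum())
        events = int(y[mask].sum())
        rows.append({
            "group": k,
            "label": spec.labels[k],
            "n": n_k,
            "events": events,
            "proportion": events / n_k if n_k > 0 else float("nan"),
        })
    df = pd.DataFrame(rows)
    p = df.loc[df["n"] > 0, "proportion"].to_numpy()
    non_mono = bool(len(p) > 2 and not (np.all(np.diff(p) >= 0) or np.all(np.diff(p) <= 0)))
    df.attrs["non_monotonic"] = non_mono
    return df


def baseline_logistic_or(
    cohort: Cohort,
    covariate_cols: Sequence[str] | None = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Main-terms logistic model of the outcome on continuous total dose
    plus covariates; returns the exponentiated dose coefficient (odds
    ratio per dose unit) with its Wald CI.

    Provided only as a baseline comparison: a continuous main-terms dose
    term imposes a monotonic log-linear dose–response, and any covariates
    measured after the outcome should be excluded (a cause must precede
    its effect) — ``covariate_cols`` controls exactly which enter.
    """
    if cohort.dose is None:
        raise ValueError("cohort has no dose column")
    cols = list(covariate_cols) if covariate_cols is not None else list(cohort.w.columns)
    x = pd.DataFrame({"dose": cohort.dose})
    for c in cols:
        x[c] = cohort.w[c].to_numpy(dtype=float)
    x = sm.add_constant(x)
    try:
        fit = sm.Logit(cohort.y, x).fit(disp=0)
    except Exception as exc:  # perfect separation and friends
        raise RuntimeError(f"baseline logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise RuntimeError("baseline logistic fit is separated (infinite SEs)")
    beta = float(fit.params["dose"])
    ci = fit.conf_int(alpha=1 - level).loc["dose"]
    return float(np.exp(beta)), (float(np.exp(ci[0])), float(np.exp(ci[1])))
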