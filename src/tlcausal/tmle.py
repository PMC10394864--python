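"""Targeted minimum loss-based estimation of a binary point-treatment effect.

The estimand is the marginal risk difference

    psi_obs = E[ E(Y | A=1, W) - E(Y | A=0, W) ],

with risk-ratio and odds-ratio contrasts derived from the same targeted
arm means. The estimator is the standard two-stage TMLE for the ATE:

1. Initial outcome regression Qbar(A, W) and propensity score
   g(W) = P(A=1 | W) are fitted by super learning; g is truncated to
   [bound, 1 - bound].
2. A one-parameter logistic fluctuation with clever covariate
   H(A, W) = A/g - (1-A)/(1-g) updates Qbar so that the efficient
   influence function estimating equation is solved, i.e. the empirical
   mean of

       IC_i = H(A_i, W_i) (Y_i - Qbar*(A_i, W_i))
              + Qbar*(1, W_i) - Qbar*(0, W_i) - RD

   is (numerically) zero. The influence-curve standard error is
   sd(IC) / sqrt(n), and Wald confidence intervals follow (on the log
   scale for RR/OR).

A fully stratified g-computation plug-in (`gcomp_oracle`) is provided for
discrete covariates; with saturated nuisance fits TMLE reproduces it
exactly, which anchors the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import Cohort, RunConfig, resolve_ps_bound
from .superlearner import SuperLearner

__all__ = [
    "TMLE",
    "TMLEResults",
    "NuisanceFits",
    "PositivityError",
    "fit_nuisances",
    "fluctuate",
    "estimate",
    "wald_ci",
    "gcomp_oracle",
    "effect_on_scale",
]

_Q_EPS = 1e-9  # bound on outcome-regression probabilities before logit


class PositivityError(ValueError):
    """The treated/control contrast is undefined in some stratum (or globally)."""


@dataclass
class NuisanceFits:
    """Initial nuisance estimates used by the targeting step.

    qbar_aw, qbar1, qbar0 : outcome-regression predictions at the observed
        treatment, at A=1 and at A=0 (probabilities).
    g_raw, g : propensity P(A=1|W) before and after two-sided truncation
        to [bound, 1 - bound].
    """

    qbar_aw: np.ndarray
    qbar1: np.ndarray
    qbar0: np.ndarray
    g_raw: np.ndarray
    g: np.ndarray
    bound: float
    outcome_fit: SuperLearner | None = None
    ps_fit: SuperLearner | None = None

    def __post_init__(self) -> None:
        for name in ("qbar_aw", "qbar1", "qbar0", "g_raw"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                arr = np.clip(arr, _Q_EPS, 1.0 - _Q_EPS)
            setattr(self, name, arr)
        self.g = np.clip(np.asarray(self.g, dtype=float), self.bound, 1.0 - self.bound)


def fit_nuisances(
    cohort: Cohort, config: RunConfig, seed: int | None = None
) -> NuisanceFits:
    """Fit the outcome regression on (W, A) and the propensity on W by
    super learning; truncate g at the resolved bound."""
    if seed is None:
        seed = config.seed
    a = cohort.a.astype(float)
    if a.min() == a.max():
        raise PositivityError("treatment is constant: the contrast is undefined")
    w = cohort.w.to_numpy(dtype=float)
    xa = np.column_stack([a, w])

    sl_q = SuperLearner(list(config.outcome_library), v=min(config.v_folds, cohort.n),
                        seed=seed)
    sl_q.fit(xa, cohort.y)
    qbar_aw = sl_q.predict_proba(xa)
    qbar1 = sl_q.predict_proba(np.column_stack([np.ones_like(a), w]))
    qbar0 = sl_q.predict_proba(np.column_stack([np.zeros_like(a), w]))

    sl_g = SuperLearner(list(config.ps_library), v=min(config.v_folds, cohort.n),
                        seed=seed + 1)
    sl_g.fit(w, a)
    g_raw = sl_g.predict_proba(w)

    bound = resolve_ps_bound(config, cohort.n)
    return NuisanceFits(
        qbar_aw=qbar_aw, qbar1=qbar1, qbar0=qbar0, g_raw=g_raw, g=g_raw,
        bound=bound, outcome_fit=sl_q, ps_fit=sl_g,
    )


def _solve_epsilon(
    h: np.ndarray, y: np.ndarray, offset_logit_q: np.ndarray,
    tol: float = 1e-12, max_iter: int = 100,
) -> float:
    """One-parameter offset-logistic MLE by safeguarded Newton iterations.

    Solves the score equation sum_i H_i (Y_i - expit(logit Q_i + eps H_i)) = 0.
    """
    eps = 0.0
    for _ in range(max_iter):
        q = expit(offset_logit_q + eps * h)
        score = float(np.sum(h * (y - q)))
        info = float(np.sum(h * h * q * (1.0 - q)))
        if abs(score) < tol * max(1.0, len(y)):
            return eps
        if info <= 0.0:
            break
        step = score / info
        eps += np.clip(step, -5.0, 5.0)
    q = expit(offset_logit_q + eps * h)
    if abs(float(np.sum(h * (y - q)))) > 1e-6 * len(y):
        raise RuntimeError(
            "fluctuation MLE did not converge; "
            f"residual score {float(np.sum(h * (y - q))):.3e}"
        )
    return eps


def fluctuate(nuisances: NuisanceFits, cohort: Cohort) -> tuple[NuisanceFits, float]:
    """Targeting step: update Qbar along the clever-covariate fluctuation.

    Returns the updated nuisance fits (Qbar*, with Qbar*(1,W) and
    Qbar*(0,W) shifted by eps/g and -eps/(1-g) on the logit scale) and the
    fitted fluctuation coefficient eps.
    """
    a = cohort.a.astype(float)
    y = cohort.y.astype(float)
    g = nuisances.g
    h = a / g - (1.0 - a) / (1.0 - g)
    h1 = 1.0 / g
    h0 = -1.0 / (1.0 - g)
    lq = logit(np.clip(nuisances.qbar_aw, _Q_EPS, 1 - _Q_EPS))
    eps = _solve_epsilon(h, y, lq)
    updated = replace(
        nuisances,
        qbar_aw=expit(lq + eps * h),
        qbar1=expit(logit(np.clip(nuisances.qbar1, _Q_EPS, 1 - _Q_EPS)) + eps * h1),
        qbar0=expit(logit(np.clip(nuisances.qbar0, _Q_EPS, 1 - _Q_EPS)) + eps * h0),
        outcome_fit=nuisances.outcome_fit,
        ps_fit=nuisances.ps_fit,
    )
    return updated, eps


def wald_ci(psi: float, sigma: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval psi +/- z_{(1+level)/2} * sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    return (psi - z * sigma, psi + z * sigma)


def effect_on_scale(
    psi1: float, psi0: float, ic1: np.ndarray, ic0: np.ndarray, scale: str,
    level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Effect estimate, influence-curve SE and CI on the requested scale.

    RD is psi1 - psi0 on the identity scale. RR and OR use delta-method
    standard errors on the log scale; the CI is computed on the log scale
    and exponentiated.
    """
    n = len(ic1)
    if scale == "RD":
        est = psi1 - psi0
        ic = ic1 - ic0
        se = float(np.std(ic, ddof=0) / np.sqrt(n))
        return est, se, wald_ci(est, se, level)
    if not (0.0 < psi0 < 1.0 and 0.0 < psi1 < 1.0):
        raise ValueError("arm means must lie strictly in (0,1) for RR/OR")
    if scale == "RR":
        est = psi1 / psi0
        ic_log = ic1 / psi1 - ic0 / psi0
    elif scale == "OR":
        est = (psi1 / (1 - psi1)) / (psi0 / (1 - psi0))
        ic_log = ic1 / (psi1 * (1 - psi1)) - ic0 / (psi0 * (1 - psi0))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    se_log = float(np.std(ic_log, ddof=0) / np.sqrt(n))
    lo, hi = wald_ci(np.log(est), se_log, level)
    return float(est), se_log, (float(np.exp(lo)), float(np.exp(hi)))


class TMLE:
    """Targeted maximum likelihood model for a binary point treatment.

    Parameters
    ----------
    cohort : Cohort
        Validated (Y, A, W) data.
    config : RunConfig, optional
        Analysis settings (scale, folds, truncation bound, libraries).
    nuisances : NuisanceFits, optional
        Precomputed initial fits; when given, super learning is skipped.
        This is how externally supplied (e.g. saturated or known-design)
        nuisance estimates enter.

    Examples
    --------
    >>> model = TMLE(cohort, config)
    >>> res = model.fit()
    >>> res.estimate, res.se, res.conf_int()
    """

    def __init__(
        self,
        cohort: Cohort,
        config: RunConfig | None = None,
        nuisances: NuisanceFits | None = None,
    ):
        self.cohort = cohort
        self.config = config if config is not None else RunConfig()
        self.nuisances = nuisances

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "y",
        treatment: str = "a",
        covariates: list[str] | None = None,
        config: RunConfig | None = None,
    ) -> "TMLE":
        if covariates is None:
            covariates = [c for c in df.columns if c not in (outcome, treatment)]
        cohort = Cohort(
            y=df[outcome].to_numpy(),
            a=df[treatment].to_numpy(),
            w=df[covariates].copy(),
        )
        return cls(cohort, config=config)

    def fit(self, seed: int | None = None) -> "TMLEResults":
        initial = self.nuisances
        if initial is None:
            initial = fit_nuisances(self.cohort, self.config, seed=seed)
        a = self.cohort.a.astype(float)
        if a.min() == a.max():
            raise PositivityError("treatment is constant: the contrast is undefined")
        targeted, eps = fluctuate(initial, self.cohort)
        y = self.cohort.y.astype(float)
        g = targeted.g
        psi1 = float(np.mean(targeted.qbar1))
        psi0 = float(np.mean(targeted.qbar0))
        ic1 = (a / g) * (y - targeted.qbar_aw) + targeted.qbar1 - psi1
        ic0 = ((1 - a) / (1 - g)) * (y - targeted.qbar_aw) + targeted.qbar0 - psi0
        return TMLEResults(
            model=self,
            psi1=psi1,
            psi0=psi0,
            ic1=ic1,
            ic0=ic0,
            epsilon=eps,
            nuisances_initial=initial,
            nuisances_targeted=targeted,
        )


class TMLEResults:
    """Targeted estimates with influence-curve inference.

    Attributes
    ----------
    psi1, psi0 : targeted counterfactual arm means E[Y_1], E[Y_0]
    estimate : effect on the configured scale (RD by default)
    se : influence-curve standard error on the estimation scale
         (identity for RD, log for RR/OR)
    ic : per-subject influence-curve contributions for the RD
    epsilon : fitted fluctuation coefficient
    """

    def __init__(self, model, psi1, psi0, ic1, ic0, epsilon,
                 nuisances_initial, nuisances_targeted):
        self.model = model
        self.psi1 = psi1
        self.psi0 = psi0
        self.ic1 = ic1
        self.ic0 = ic0
        self.epsilon = epsilon
        self.nuisances_initial = nuisances_initial
        self.nuisances_targeted = nuisances_targeted
        self.level = model.config.level
        self.scale = model.config.scale
        self.n = model.cohort.n

    # --- RD-scale quantities -------------------------------------------------
    @property
    def rd(self) -> float:
        return self.psi1 - self.psi0

    @property
    def ic(self) -> np.ndarray:
        return self.ic1 - self.ic0

    @property
    def se_rd(self) -> float:
        return float(np.std(self.ic, ddof=0) / np.sqrt(self.n))

    # --- configured-scale quantities -----------------------------------------
    def _on_scale(self, scale: str | None = None):
        scale = scale or self.scale
        return effect_on_scale(
            self.psi1, self.psi0, self.ic1, self.ic0, scale, self.level
        )

    @property
    def estimate(self) -> float:
        return self._on_scale()[0]

    @property
    def se(self) -> float:
        return self._on_scale()[1]

    def conf_int(self, scale: str | None = None) -> tuple[float, float]:
        return self._on_scale(scale)[2]

    def effects_table(self) -> pd.DataFrame:
        """RD, RR and OR estimates with SEs and confidence intervals."""
        rows = []
        for scale in ("RD", "RR", "OR"):
            est, se, ci = self._on_scale(scale)
            rows.append({"scale": scale, "estimate": est,
                         "se": se, "ci_lower": ci[0], "ci_upper": ci[1]})
        return pd.DataFrame(rows).set_index("scale")

    def sensitivity(self, null: float | None = None, delta_grid=None,
                    z_compat: float | None = None):
        """Causal-gap sensitivity analysis of this result (see
        :mod:`tlcausal.sensitivity`)."""
        from .sensitivity import causal_gap_scan

        est, se, _ = self._on_scale()
        if self.scale in ("RR", "OR"):
            est = float(np.log(est))
            null_ = 0.0 if null is None else float(np.log(null))
        else:
            null_ = self.model.config.null_value if null is None else null
        return causal_gap_scan(
            est, se, null=null_, level=self.level, delta_grid=delta_grid,
            z_compat=z_compat,
        )

    def summary(self) -> str:
        est, se, ci = self._on_scale()
        bound = self.nuisances_targeted.bound
        n_trunc = int(np.sum(
            (self.nuisances_targeted.g_raw < bound)
            | (self.nuisances_targeted.g_raw > 1 - bound)
        ))
        lines = [
            "        Targeted Maximum Likelihood Estimation",
            "=" * 58,
            f"N subjects:        {self.n:>8d}    Events:   {self.model.cohort.n_events:>6d}",
            f"Treated:           {self.model.cohort.n_treated:>8d}    Scale:    {self.scale:>6s}",
            f"PS bound:          {bound:>8.4f}    (reported as {round(bound, 2):.2f})",
            f"PS values truncated: {n_trunc:>6d}    epsilon:  {self.epsilon:>8.5f}",
            "-" * 58,
            f"E[Y1] (targeted):  {self.psi1:>8.4f}",
            f"E[Y0] (targeted):  {self.psi0:>8.4f}",
            f"{self.scale} estimate:       {est:>8.4f}",
            f"SE (influence curve): {se:>8.4f}"
            + ("  [log scale]" if self.scale in ("RR", "OR") else ""),
            f"{100 * self.level:.0f}% CI:            [{ci[0]:.4f}, {ci[1]:.4f}]",
            "=" * 58,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "psi1": self.psi1,
            "psi0": self.psi0,
            "epsilon": float(self.epsilon),
            "level": self.level,
            "ps_bound": float(self.nuisances_targeted.bound),
            "ps_bound_2dp": round(float(self.nuisances_targeted.bound), 2),
            "effects": {},
        }
        for scale in ("RD", "RR", "OR"):
            est, se, ci = self._on_scale(scale)
            out["effects"][scale] = {
                "estimate": float(est), "se": float(se),
                "ci_lower": float(ci[0]), "ci_upper": float(ci[1]),
            }
        return out


def estimate(cohort: Cohort, config: RunConfig,
             nuisances: NuisanceFits | None = None,
             seed: int | None = None) -> TMLEResults:
    """Functional entry point: fit TMLE on a cohort."""
    return TMLE(cohort, config, nuisances=nuisances).fit(seed=seed)


def gcomp_oracle(cohort: Cohort, max_strata: int = 32) -> float:
    """Fully stratified g-computation plug-in for discrete covariates.

    Computes sum_w phat(w) * [ybar(A=1, w) - ybar(A=0, w)]. Every stratum
    must contain both treated and untreated subjects; an empty cell raises
    a :class:`PositivityError` naming the stratum.
    """
    w = cohort.w
    keys = pd.MultiIndex.from_frame(w).to_numpy() if w.shape[1] > 1 else w.iloc[:, 0].to_numpy()
    strata, inverse = np.unique(np.asarray(keys, dtype=object), return_inverse=True)
    if len(strata) > max_strata:
        raise ValueError(f"too many strata ({len(strata)} > {max_strata})")
    n = cohort.n
    rd = 0.0
    for s_idx, s in enumerate(strata):
        mask = inverse == s_idx
        a = cohort.a[mask]
        y = cohort.y[mask]
        if a.sum() == 0 or a.sum() == len(a):
            raise PositivityError(f"stratum {s!r} has an empty treated or control cell")
        rd += (mask.mean()) * (y[a == 1].mean() - y[a == 0].mean())
    return float(rd)


def saturated_nuisances(cohort: Cohort, bound: float = 1e-6) -> NuisanceFits:
    """Saturated (nonparametric MLE) nuisance fits on discrete covariates:
    within-stratum arm means for Qbar and within-stratum treatment rates
    for g. Intended for tests and small discrete toys."""
    w = cohort.w
    keys = pd.MultiIndex.from_frame(w).to_numpy() if w.shape[1] > 1 else w.iloc[:, 0].to_numpy()
    strata, inverse = np.unique(np.asarray(keys, dtype=object), return_inverse=True)
    n = cohort.n
    qbar_aw = np.empty(n)
    qbar1 = np.empty(n)
    qbar0 = np.empty(n)
    g = np.empty(n)
    for s_idx in range(len(strata)):
        mask = inverse == s_idx
        a = cohort.a[mask]
        y = cohort.y[mask]
        if a.sum() == 0 or a.sum() == len(a):
            raise PositivityError(
                f"stratum {strata[s_idx]!r} has an empty treated or control cell"
            )
        m1 = y[a == 1].mean()
        m0 = y[a == 0].mean()
        qbar1[mask] = m1
        qbar0[mask] = m0
        qbar_aw[mask] = np.where(a == 1, m1, m0)
        g[mask] = a.mean()
    return NuisanceFits(
        qbar_aw=qbar_aw, qbar1=qbar1, qbar0=qbar0, g_raw=g, g=g, bound=bound
    )
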