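"""Synthetic point-treatment cohorts with known causal truth.

The generator emulates a perinatal observational cohort: ~225 subjects,
ten baseline covariates (age, height, weight, BMI and six binary
indicators), a logistic treatment-assignment mechanism, and a logistic
binary-outcome mechanism with a treatment main effect. Three departures
from the clean observational setting can be injected, each controllable:

- measured confounding (covariates entering both mechanisms),
- a latent Bernoulli confounder U entering both linear predictors, which
  creates a known, sign-interpretable causal gap between the W-adjusted
  statistical estimand and the true marginal risk difference,
- a contraindication stratum: a fixed fraction of subjects whose
  treatment probability is structurally zero (a positivity violation
  invisible in W).

Counterfactual truth (E[Y_1], E[Y_0], the true risk difference, and the
injected causal gap) is computed by Monte-Carlo integration over fresh
covariate draws, with conditional expectations over U taken analytically.

Continuous covariates enter the linear predictors standardized by fixed
constants (not sample moments), so coefficients are on a common O(1)
scale and the Monte-Carlo oracle integrates the exact same mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_cohort",
    "true_effect_oracle",
    "generate_dose_cohort",
    "default_sim_config",
]

# fixed standardization constants for continuous covariates
_STD = {
    "age": (31.0, 5.0),
    "height": (158.0, 5.5),
    "weight": (55.0, 8.0),
    "bmi": (22.0, 3.0),
}

_BINARY_COVARIATES = (
    ("first_pregnancy", 0.45),
    ("single_placenta", 0.35),
    ("art", 0.30),
    ("magnesium", 0.25),
    ("corticosteroid", 0.30),
)

# dose-category bounds on the 72 mg/24 h scale; category 0 is dose = 0
_DOSE_GROUP_BOUNDS = ((0.0, 10.0), (10.0, 20.0), (20.0, 30.0),
                      (30.0, 40.0), (40.0, 50.0), (50.0, 80.0))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort mechanism.

    ``propensity_coefs`` and ``outcome_coefs`` map standardized covariate
    names (``age_z``, ``height_z``, ``weight_z``, ``bmi_z``, the binary
    indicator names, ``obesity``, plus ``intercept``, ``a`` and ``u``) to
    linear-predictor weights on the logit scale.
    """

    n: int = 225
    propensity_coefs: Mapping[str, float] = field(default_factory=dict)
    outcome_coefs: Mapping[str, float] = field(default_factory=dict)
    contraindication_fraction: float = 0.0
    confounder_strength: float = 0.0
    u_prevalence: float = 0.5
    dose_targets: Sequence[float] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.25)
    dose_group_probs: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 <= self.contraindication_fraction < 1.0:
            raise ValueError("contraindication fraction must lie in [0, 1)")
        if not 0.0 < self.u_prevalence < 1.0:
            raise ValueError("u prevalence must lie in (0, 1)")
        if len(self.dose_targets) != 7:
            raise ValueError("dose_targets must give 7 group event rates")
        if any(not 0.0 < t < 1.0 for t in self.dose_targets):
            raise ValueError("dose-group event-rate targets must lie in (0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Known counterfactual truth for a simulation mechanism.

    ``delta`` is the injected causal gap: the large-sample difference
    between the W-adjusted statistical estimand and the true marginal risk
    difference. It is 0 when no latent confounder is injected.
    """

    psi1: float
    psi0: float
    rd: float
    delta: float
    mc_se: float = 0.0
    psi_stat: float = float("nan")
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "true_psi1": self.psi1,
            "true_psi0": self.psi0,
            "true_rd": self.rd,
            "injected_delta": self.delta,
            "statistical_estimand": self.psi_stat,
            "mc_se": self.mc_se,
            "warnings": list(self.warnings),
        }


def default_sim_config(**overrides) -> SimConfig:
    """Default mechanism: ~36% treated, ~17% marginal event rate, true
    risk difference near 0.21, measured confounding through BMI, age and
    co-medication indicators."""
    propensity = {
        "intercept": -0.70,
        "age_z": 0.30,
        "bmi_z": 0.40,
        "magnesium": 0.50,
        "corticosteroid": 0.40,
        "first_pregnancy": -0.30,
    }
    outcome = {
        "intercept": -2.60,
        "a": 1.50,
        "age_z": 0.20,
        "bmi_z": 0.50,
        "obesity": 0.30,
        "magnesium": 0.40,
        "corticosteroid": 0.30,
    }
    base = dict(propensity_coefs=propensity, outcome_coefs=outcome)
    base.update(overrides)
    return SimConfig(**base)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(np.round(rng.normal(31.0, 5.0, n)), 16, 45)
    height = rng.normal(158.0, 5.5, n)
    # weight correlated with height (r ~ 0.5)
    weight = 55.0 + 0.5 * 8.0 / 5.5 * (height - 158.0) \
        + rng.normal(0.0, 8.0 * np.sqrt(1 - 0.25), n)
    weight = np.clip(weight, 35.0, 110.0)
    bmi = weight / (height / 100.0) ** 2
    df = pd.DataFrame({
        "age": age,
        "height": np.round(height, 1),
        "weight": np.round(weight, 1),
        "bmi": np.round(bmi, 2),
        "obesity": (bmi >= 25.0).astype(int),
    })
    for name, p in _BINARY_COVARIATES:
        df[name] = rng.binomial(1, p, n)
    return df


def _design(w: pd.DataFrame) -> pd.DataFrame:
    """Standardized design frame referenced by coefficient names."""
    d = pd.DataFrame(index=w.index)
    for col, (center, scale) in _STD.items():
        if col in w.columns:
            d[f"{col}_z"] = (w[col] - center) / scale
    for col in w.columns:
        if col not in _STD:
            d[col] = w[col]
    return d


def _linpred(d: pd.DataFrame, coefs: Mapping[str, float],
             a: np.ndarray | float = 0.0, u: np.ndarray | float = 0.0,
             u_strength: float = 0.0) -> np.ndarray:
    lp = np.full(len(d), float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name in ("intercept", "a", "u"):
            continue
        if name not in d.columns:
            raise ValueError(f"coefficient names unknown covariate {name!r}")
        lp = lp + beta * d[name].to_numpy(dtype=float)
    lp = lp + float(coefs.get("a", 0.0)) * np.asarray(a, dtype=float)
    u_coef = float(coefs.get("u", u_strength))
    lp = lp + u_coef * np.asarray(u, dtype=float)
    return lp


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("covariates", "u", "contraindication", "treatment",
             "outcome", "dose", "oracle")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {k: np.random.default_rng(c) for k, c in zip(names, children)}


def generate_cohort(
    config: SimConfig,
    compute_truth: bool = True,
    mc_size: int = 100_000,
    return_latent: bool = False,
):
    """Draw one cohort; return it with the mechanism's counterfactual truth.

    Reproducible bit-for-bit given the config (including seed). Covariate,
    latent-confounder, treatment and outcome draws come from separate
    child streams of the root seed, so changing one stage does not perturb
    the others. With ``return_latent`` a third element exposes the latent
    draws (U, true propensity, contraindication mask) for audits.
    """
    rngs = _streams(config.seed)
    w = _draw_covariates(config.n, rngs["covariates"])
    d = _design(w)
    u = rngs["u"].binomial(1, config.u_prevalence, config.n)

    g = expit(_linpred(d, config.propensity_coefs, u=u,
                       u_strength=config.confounder_strength))
    k_contra = int(np.floor(config.contraindication_fraction * config.n))
    contra = np.zeros(config.n, dtype=bool)
    if k_contra > 0:
        idx = rngs["contraindication"].choice(config.n, size=k_contra, replace=False)
        contra[idx] = True
        g = np.where(contra, 0.0, g)
    a = rngs["treatment"].binomial(1, g)

    py = expit(_linpred(d, config.outcome_coefs, a=a, u=u,
                        u_strength=config.confounder_strength))
    y = rngs["outcome"].binomial(1, py)

    msgs: list[str] = []
    if a.sum() == 0 or a.sum() == config.n:
        msgs.append("degenerate treatment draw: single-arm cohort")
        warnings.warn(msgs[-1], stacklevel=2)

    cohort = Cohort(y=y, a=a, w=w)
    if compute_truth:
        truth = true_effect_oracle(config, mc_size=mc_size)
        truth = replace(truth, warnings=truth.warnings + tuple(msgs))
    else:
        truth = SimTruth(float("nan"), float("nan"), float("nan"),
                         float("nan"), warnings=tuple(msgs))
    if return_latent:
        return cohort, truth, {"u": u, "propensity": g, "contraindicated": contra}
    return cohort, truth


def true_effect_oracle(config: SimConfig, mc_size: int = 100_000) -> SimTruth:
    """Monte-Carlo oracle for the mechanism's counterfactual truth.

    E[Y_1] and E[Y_0] integrate the outcome mechanism over fresh covariate
    draws under forced A=1 and A=0, taking the expectation over the latent
    confounder U analytically. The injected causal gap delta is
    psi_stat - rd, where psi_stat = E_W[E(Y|A=1,W) - E(Y|A=0,W)] uses the
    U-posterior given (A, W) — the estimand a W-adjusted estimator targets.
    """
    if mc_size < 10_000:
        raise ValueError("mc_size must be at least 10^4")
    rng = _streams(config.seed)["oracle"]
    w = _draw_covariates(mc_size, rng)
    d = _design(w)
    pu = config.u_prevalence
    s = config.confounder_strength

    def q(a_val: float, u_val: float) -> np.ndarray:
        return expit(_linpred(d, config.outcome_coefs, a=a_val, u=u_val,
                              u_strength=s))

    # counterfactual means: U marginal
    p1 = (1 - pu) * q(1, 0) + pu * q(1, 1)
    p0 = (1 - pu) * q(0, 0) + pu * q(0, 1)
    psi1 = float(p1.mean())
    psi0 = float(p0.mean())
    rd = psi1 - psi0
    mc_se = float(np.std(p1 - p0, ddof=0) / np.sqrt(mc_size))

    # W-adjusted statistical estimand: condition U on (A, W)
    g0 = expit(_linpred(d, config.propensity_coefs, u=0, u_strength=s))
    g1 = expit(_linpred(d, config.propensity_coefs, u=1, u_strength=s))
    c = config.contraindication_fraction
    # contraindication is drawn independently of (W, U): it scales
    # P(A=1|W,U) by (1-c), which cancels for A=1 and tilts the A=0 mixture
    w1_num = pu * g1
    w1 = w1_num / ((1 - pu) * g0 + w1_num)
    w0_num = pu * (c + (1 - c) * (1 - g1))
    w0 = w0_num / ((1 - pu) * (c + (1 - c) * (1 - g0)) + w0_num)
    e_y_a1 = (1 - w1) * q(1, 0) + w1 * q(1, 1)
    e_y_a0 = (1 - w0) * q(0, 0) + w0 * q(0, 1)
    psi_stat = float((e_y_a1 - e_y_a0).mean())

    return SimTruth(psi1=psi1, psi0=psi0, rd=rd,
                    delta=psi_stat - rd, mc_se=mc_se, psi_stat=psi_stat)


def generate_dose_cohort(config: SimConfig) -> Cohort:
    """Draw a cohort with a total-dose column and a crude dose–response
    following the configured per-group event-rate targets.

    Treated subjects are spread over the six positive dose categories
    (uniform doses within each category); the outcome is drawn from the
    group-level target rates, producing the configured crude pattern —
    non-monotonic by default (rising toward the 41–50 group, then
    falling). Empty groups at small n are flagged with a warning.
    """
    rngs = _streams(config.seed)
    w = _draw_covariates(config.n, rngs["covariates"])
    d = _design(w)
    u = rngs["u"].binomial(1, config.u_prevalence, config.n)
    g = expit(_linpred(d, config.propensity_coefs, u=u,
                       u_strength=config.confounder_strength))
    a = rngs["treatment"].binomial(1, g)

    probs = (np.full(6, 1.0 / 6.0) if config.dose_group_probs is None
             else np.asarray(config.dose_group_probs, dtype=float))
    if len(probs) != 6 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("dose_group_probs must be 6 probabilities summing to 1")

    dose = np.zeros(config.n)
    group = np.zeros(config.n, dtype=int)
    treated = np.flatnonzero(a == 1)
    if len(treated) > 0:
        grp = rngs["dose"].choice(np.arange(1, 7), size=len(treated), p=probs)
        group[treated] = grp
        lo = np.array([_DOSE_GROUP_BOUNDS[k - 1][0] for k in grp])
        hi = np.array([_DOSE_GROUP_BOUNDS[k - 1][1] for k in grp])
        udraw = rngs["dose"].uniform(size=len(treated))
        # doses in the half-open interval (lo, hi]
        dose[treated] = hi - udraw * (hi - lo)

    targets = np.asarray(config.dose_targets, dtype=float)
    y = rngs["outcome"].binomial(1, targets[group])

    present = np.unique(group)
    missing = sorted(set(range(7)) - set(present.tolist()))
    if missing:
        warnings.warn(f"empty dose groups at n={config.n}: {missing}", stacklevel=2)

    return Cohort(y=y, a=a, w=w, dose=dose)
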