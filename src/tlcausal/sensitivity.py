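"""Non-parametric sensitivity analysis for unexplained assumption violations.

The causal gap is delta = psi_stat - psi_causal: the discrepancy between
the statistical estimand and the causal parameter when consistency,
positivity or no-unmeasured-confounding fail. For a hypothesized delta the
bias-corrected estimate is psi_hat - delta, and the confidence bounds
shift by the same amount. Two closed-form thresholds summarize robustness:

- the *G-value*, min(|psi - z sigma - null|, |psi + z sigma - null|): the
  smallest |delta| that negates the finding (moves the null just inside a
  CI that excluded it, or just outside one that included it);
- the *reversal threshold*: the delta at which the entire shifted CI lands
  on the other side of the null.

For ratio scales (RR/OR) all arithmetic is on the log scale with null
log(1) = 0. The exact normal quantile is used by default; ``z_compat``
forces a fixed quantile (e.g. 1.96) for arithmetic parity with published
two-decimal tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SensitivityResult",
    "causal_gap_scan",
    "g_value",
    "flip_thresholds",
]


def _zq(level: float, z_compat: float | None) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if z_compat is not None:
        return float(z_compat)
    return float(norm.ppf(0.5 + level / 2.0))


def g_value(psi: float, sigma: float, null: float = 0.0, level: float = 0.95,
            z_compat: float | None = None) -> float:
    """Smallest causal gap (in absolute value) that negates the finding."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = _zq(level, z_compat)
    return float(min(abs(psi - z * sigma - null), abs(psi + z * sigma - null)))


def flip_thresholds(psi: float, sigma: float, null: float = 0.0,
                    level: float = 0.95, z_compat: float | None = None
                    ) -> tuple[float, float]:
    """Signed gap thresholds under the shift convention psi - delta.

    ``delta_nullify``: the delta at which the nearer CI bound touches the
    null (|delta_nullify| equals the G-value when the CI excludes the
    null). ``delta_reverse``: the delta at which the farther bound crosses
    the null, i.e. the whole CI lands on the other side.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = _zq(level, z_compat)
    lo, hi = psi - z * sigma, psi + z * sigma
    # shifting by delta moves both bounds down; which bound is "nearer"
    # depends on the side of the null the estimate sits on
    if psi >= null:
        return (lo - null, hi - null)
    return (hi - null, lo - null)


@dataclass
class SensitivityResult:
    """Causal-gap scan output.

    ``table`` carries one row per grid delta: the shifted estimate and CI
    and the gap in SE units. ``delta_nullify``/``delta_reverse`` are the
    closed-form flip thresholds; ``g_value`` is their magnitude gate.
    """

    psi: float
    sigma: float
    null: float
    level: float
    table: pd.DataFrame
    g_value: float
    delta_nullify: float
    delta_reverse: float

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "sigma": self.sigma,
            "null": self.null,
            "level": self.level,
            "g_value": self.g_value,
            "g_value_se_units": self.g_value / self.sigma,
            "delta_nullify": self.delta_nullify,
            "delta_reverse": self.delta_reverse,
        }


def causal_gap_scan(
    psi: float,
    sigma: float,
    null: float = 0.0,
    level: float = 0.95,
    delta_grid: np.ndarray | None = None,
    z_compat: float | None = None,
) -> SensitivityResult:
    """Scan hypothetical causal gaps and report shifted estimates and CIs.

    The default grid is 81 equally spaced points spanning +/- 4 SE units
    around zero. At delta = 0 the shifted quantities equal the originals;
    shifted bounds decrease strictly in delta (psi - delta convention).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = _zq(level, z_compat)
    if delta_grid is None:
        delta_grid = np.linspace(-4.0 * sigma, 4.0 * sigma, 81)
    delta_grid = np.asarray(delta_grid, dtype=float)
    lo, hi = psi - z * sigma, psi + z * sigma
    shifted = psi - delta_grid
    table = pd.DataFrame({
        "delta": delta_grid,
        "delta_se_units": delta_grid / sigma,
        "shifted_estimate": shifted,
        "shifted_ci_lower": lo - delta_grid,
        "shifted_ci_upper": hi - delta_grid,
        "ci_includes_null": (lo - delta_grid <= null) & (null <= hi - delta_grid),
    })
    d_null, d_rev = flip_thresholds(psi, sigma, null, level, z_compat)
    return SensitivityResult(
        psi=psi, sigma=sigma, null=null, level=level, table=table,
        g_value=g_value(psi, sigma, null, level, z_compat),
        delta_nullify=d_null, delta_reverse=d_rev,
    )
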