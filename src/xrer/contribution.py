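"""Attributable-fraction estimators for risk-region variants.

Two complementary summaries of how much of a case cohort the rare damaging
risk-region variants explain:

* the percentage of cases attributable to >= 1 such variant: carrier
  percentage in cases minus carrier percentage in controls, with a
  per-group percentile bootstrap CI floored at 0;
* the percentage of such variants that carry risk: the relative excess of
  the mean per-sample variant count in cases over controls,
  100 * (mean_case - mean_ctrl) / mean_case, with the CI propagated from
  the two-sample mean-difference interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CarrierSummary:
    pct_cases_carrier: float
    pct_controls_carrier: float
    attributable_pct: float
    ci95: tuple

    def __post_init__(self):
        assert 0 <= self.pct_cases_carrier <= 100
        assert 0 <= self.pct_controls_carrier <= 100


def carrier_difference(pct_cases: float, pct_controls: float) -> float:
    """Point estimate: percent of cases attributable to >= 1 variant."""
    return pct_cases - pct_controls


def attributable_cases(case_carrier, control_carrier, n_boot: int = 10_000,
                       seed: int = 0, floor: bool = True) -> CarrierSummary:
    """Excess carrier percentage in cases, with a percentile bootstrap CI.

    ``case_carrier`` / ``control_carrier`` are per-individual booleans
    (carries >= 1 rare damaging risk-region variant). Resampling is done
    within each group; the lower CI bound is floored at 0.
    """
    case = np.asarray(case_carrier, dtype=float)
    ctrl = np.asarray(control_carrier, dtype=float)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both groups must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    pc, pt = 100 * case.mean(), 100 * ctrl.mean()
    boot = 100 * (
        case[rng.integers(0, len(case), size=(n_boot, len(case)))].mean(axis=1)
        - ctrl[rng.integers(0, len(ctrl), size=(n_boot, len(ctrl)))].mean(axis=1)
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    if floor:
        lo = max(lo, 0.0)
    return CarrierSummary(pc, pt, pc - pt, (float(lo), float(hi)))


def variants_carrying_risk(case_counts, control_counts, floor: bool = True):
    """Percentage of case variants in excess of the control rate.

    Point estimate 100 * (mean_case - mean_ctrl) / mean_case; the CI comes
    from the Welch two-sample mean-difference interval divided by mean_case.
    Returns (percentage, (lo, hi)); (nan, (nan, nan)) when cases carry no
    variants at all.
    """
    case = np.asarray(case_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both groups must be non-empty")
    mc, mt = case.mean(), ctrl.mean()
    if mc == 0:
        return float("nan"), (float("nan"), float("nan"))
    est = 100.0 * (mc - mt) / mc
    v1 = case.var(ddof=1) / len(case)
    v2 = ctrl.var(ddof=1) / len(ctrl)
    se = np.sqrt(v1 + v2)
    denom = v1**2 / (len(case) - 1) + v2**2 / (len(ctrl) - 1)
    df = (v1 + v2) ** 2 / denom if denom > 0 else len(case) + len(ctrl) - 2
    tcrit = stats.t.ppf(0.975, df)
    lo = 100.0 * (mc - mt - tcrit * se) / mc
    hi = 100.0 * (mc - mt + tcrit * se) / mc
    if floor:
        lo = max(lo, 0.0)
    return float(est), (float(lo), float(hi))
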