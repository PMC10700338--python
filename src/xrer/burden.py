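"""Group-level enrichment statistics.

All exact 2x2 comparisons report the conditional maximum-likelihood odds
ratio (the noncentral-hypergeometric convention of R's ``fisher.test``) with
its exact 95% CI and a one-sided upper-tail p-value inclusive of the
observed table. Synonymous counts serve as the normalizer: a damaging-vs-
synonymous table contrasts mutation *rates* while cancelling platform and
ancestry effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from dataclasses import dataclass
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .intervals import Interval


@dataclass
class CountTable2x2:
    """Counts in R's column-major ``matrix(c(a, b, c, d), ncol=2)`` layout.

    Column 1 = (a, b), column 2 = (c, d); e.g. a=Dam_case, b=Syn_case,
    c=Dam_ctrl, d=Syn_ctrl.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=int)

    def transpose_groups(self) -> "CountTable2x2":
        return CountTable2x2(self.c, self.d, self.a, self.b, self.label)


@dataclass
class BurdenResult:
    odds_ratio: float
    ci95: tuple
    p_one_sided: float
    table: CountTable2x2
    label: str = ""

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "a": self.table.a, "b": self.table.b,
            "c": self.table.c, "d": self.table.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci95[0], "ci_high": self.ci95[1],
            "p_one_sided": self.p_one_sided,
        }


def exact_tail_p(table: CountTable2x2, alternative: str = "greater") -> float:
    """One-sided exact hypergeometric tail, inclusive of the observed table."""
    return float(stats.fisher_exact(table.as_array(), alternative=alternative)[1])


def fisher_burden(table: CountTable2x2, alternative: str = "greater") -> BurdenResult:
    """One-sided exact test with conditional-MLE odds ratio and exact CI."""
    arr = table.as_array()
    res = _odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(0.95)
    p = exact_tail_p(table, alternative)
    return BurdenResult(float(res.statistic), (float(ci.low), float(ci.high)),
                        float(p), table, table.label)


def poisson_rate_test(count_case: int, n_case: float, count_ctrl: int, n_ctrl: float,
                      alternative: str = "greater"):
    """Exact conditional comparison of two Poisson rates.

    Conditional on the total count, the case count is binomial with success
    probability n_case*RR / (n_case*RR + n_ctrl); the returned p-value and
    CI are the exact binomial ones mapped to the rate-ratio scale.

    Returns (rate ratio, (lo, hi), p).
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("denominators must be positive")
    total = count_case + count_ctrl
    if total == 0:
        raise ValueError("no events in either group")
    rr = (count_case / n_case) / (count_ctrl / n_ctrl) if count_ctrl else np.inf
    p0 = n_case / (n_case + n_ctrl)
    bt = stats.binomtest(count_case, total, p0, alternative=alternative)
    ci = bt.proportion_ci(0.95, method="exact")

    def to_rr(pi):
        if pi >= 1.0:
            return np.inf
        return (pi / (1 - pi)) * (n_ctrl / n_case)

    return float(rr), (float(to_rr(ci.low)), float(to_rr(ci.high))), float(bt.pvalue)


def transmission_burden(t_case: int, u_case: int, t_ctrl: int, u_ctrl: int,
                        label: str = "") -> BurdenResult:
    """Transmitted/untransmitted contrast, cases versus controls.

    Laid out as ``matrix(c(T_case, T_ctrl, U_case, U_ctrl), ncol=2)`` so an
    OR > 1 means excess transmission in cases.
    """
    return fisher_burden(CountTable2x2(t_case, t_ctrl, u_case, u_ctrl, label))


def transmission_burden_by(records_case: pd.DataFrame, records_ctrl: pd.DataFrame,
                           by: str | None = None, classes: dict | None = None) -> pd.DataFrame:
    """Batch transmission tests per variant class (and optionally per stratum).

    ``classes`` maps a test label to the variant classes pooled for it
    (default: LGD, Mis3, damaging = LGD+Mis3, synonymous).
    """
    if classes is None:
        classes = {"LGD": ["LGD"], "Mis3": ["Mis3"],
                   "damaging": ["LGD", "Mis3"], "synonymous": ["synonymous"]}
    rows = []
    strata = [None] if by is None else sorted(
        set(records_case[by].dropna()) | set(records_ctrl[by].dropna())
    )
    for stratum in strata:
        rc = records_case if stratum is None else records_case[records_case[by] == stratum]
        rt = records_ctrl if stratum is None else records_ctrl[records_ctrl[by] == stratum]
        for name, cls in classes.items():
            c = rc[rc["vclass"].isin(cls)]
            t = rt[rt["vclass"].isin(cls)]
            tc = int((c["transmission"] == "transmitted").sum())
            uc = int((c["transmission"] == "untransmitted").sum())
            tt = int((t["transmission"] == "transmitted").sum())
            ut = int((t["transmission"] == "untransmitted").sum())
            label = name if stratum is None else f"{name}|{stratum}"
            if tc + uc + tt + ut == 0:
                continue
            rows.append(transmission_burden(tc, uc, tt, ut, label).as_row())
    return pd.DataFrame(rows)


def poisson_regression_burden(dam_counts, phenotypes, syn_counts,
                              min_group: int = 100, reference: str = "control"):
    """Log-linear burden model ``#dam ~ phenotype + offset(log #syn)``.

    Samples with zero synonymous count get offset log(0.5). Phenotype groups
    smaller than ``min_group`` are dropped (with the dropped labels reported).
    Returns (per-phenotype DataFrame with RR, CI, p; dropped group list).
    """
    df = pd.DataFrame({
        "dam": np.asarray(dam_counts, dtype=float),
        "phen": pd.Series(phenotypes).astype(str).to_numpy(),
        "syn": np.asarray(syn_counts, dtype=float),
    })
    sizes = df["phen"].value_counts()
    dropped = sorted(sizes[sizes < min_group].index)
    df = df[~df["phen"].isin(dropped)]
    if reference not in set(df["phen"]):
        raise ValueError(f"reference group {reference!r} missing or too small")
    levels = [reference] + sorted(set(df["phen"]) - {reference})
    X = pd.get_dummies(pd.Categorical(df["phen"], categories=levels), drop_first=True).astype(float)
    X = sm.add_constant(X)
    offset = np.log(np.where(df["syn"] > 0, df["syn"], 0.5))
    model = sm.GLM(df["dam"].to_numpy(), X, family=sm.families.Poisson(), offset=offset)
    try:
        fit = model.fit()
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"Poisson regression failed to converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError("Poisson regression failed to converge")
    ci = fit.conf_int()
    rows = []
    for lev in levels[1:]:
        rows.append({
            "phenotype": lev,
            "rate_ratio": float(np.exp(fit.params[lev])),
            "ci_low": float(np.exp(ci.loc[lev, 0])),
            "ci_high": float(np.exp(ci.loc[lev, 1])),
            "p": float(fit.pvalues[lev]),
            "n": int((df["phen"] == lev).sum()),
        })
    return pd.DataFrame(rows), dropped


def _sample_or(tc, uc, tt, ut):
    if uc * tt == 0:
        return np.inf if tc * ut > 0 else np.nan
    return (tc * ut) / (uc * tt)


def sliding_window_scan(records_case: pd.DataFrame, records_ctrl: pd.DataFrame,
                        span: Interval, width: int = 5_000_000, step: int = 20_000,
                        flag_or: float = 1.2, classes=("LGD", "Mis3")) -> pd.DataFrame:
    """Per-window transmission contrast of cases versus controls.

    Windows with sample OR above ``flag_or`` are flagged regardless of the
    p-value; empty windows are skipped.
    """
    if width < step:
        raise ValueError("window width must be >= step")
    case = records_case[records_case["vclass"].isin(classes)]
    ctrl = records_ctrl[records_ctrl["vclass"].isin(classes)]

    def tallies(df):
        pos = df["pos"].to_numpy(float)
        t = (df["transmission"] == "transmitted").to_numpy()
        return pos, t

    cpos, ct = tallies(case)
    tpos, tt_ = tallies(ctrl)
    rows = []
    starts = np.arange(span[0], span[1] - width + step, step)
    # cumulative tallies over sorted positions make each window O(log n)
    order_c = np.argsort(cpos)
    order_t = np.argsort(tpos)
    cpos_s, ct_s = cpos[order_c], ct[order_c]
    tpos_s, tt_s = tpos[order_t], tt_[order_t]
    cum_ct = np.concatenate([[0], np.cumsum(ct_s)])
    cum_tt = np.concatenate([[0], np.cumsum(tt_s)])
    for s in starts:
        e = s + width
        i0, i1 = np.searchsorted(cpos_s, [s, e])
        j0, j1 = np.searchsorted(tpos_s, [s, e])
        tc = int(cum_ct[i1] - cum_ct[i0]); uc = int((i1 - i0) - tc)
        tt = int(cum_tt[j1] - cum_tt[j0]); ut = int((j1 - j0) - tt)
        if tc + uc + tt + ut == 0:
            continue
        orr = _sample_or(tc, uc, tt, ut)
        p = stats.fisher_exact([[tc, uc], [tt, ut]], alternative="greater")[1]
        rows.append({"start": int(s), "end": int(e), "T_case": tc, "U_case": uc,
                     "T_ctrl": tt, "U_ctrl": ut, "odds_ratio": orr, "p": p,
                     "flagged": bool(np.isfinite(orr) and orr > flag_or or orr == np.inf)})
    return pd.DataFrame(rows)


def permutation_overlap(set_a: set, set_b: set, universe: list, n_perm: int = 100_000,
                        seed: int = 0):
    """Permutation enrichment of the overlap of two gene sets within a universe.

    p = (#permutations with overlap >= observed) / n_perm; fold = observed /
    mean permuted overlap.
    """
    universe = list(universe)
    uni = set(universe)
    if not (set_a <= uni and set_b <= uni):
        raise ValueError("gene sets must be subsets of the universe")
    rng = np.random.default_rng(seed)
    in_a = np.isin(np.array(universe), list(set_a))
    k = len(set_b)
    observed = len(set_a & set_b)
    n = len(universe)
    hits = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        hits[i] = int(in_a[rng.choice(n, size=k, replace=False)].sum())
    p = float((hits >= observed).mean())
    fold = observed / hits.mean() if hits.mean() > 0 else np.inf
    return float(fold), p, observed


def nested_regression_ftest(proband_counts, sibling_counts, recomb_rate):
    """Does log recombination rate add predictive value for per-gene case counts?

    Compares ``#case ~ #ctrl`` against ``#case ~ #ctrl + log(rate)`` with a
    nested-model F-test. Returns (F, p).
    """
    rate = np.asarray(recomb_rate, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("recombination rates must be positive for the log transform")
    y = np.asarray(proband_counts, dtype=float)
    x1 = np.asarray(sibling_counts, dtype=float)
    X0 = sm.add_constant(pd.DataFrame({"sib": x1}))
    X1 = sm.add_constant(pd.DataFrame({"sib": x1, "log_rate": np.log(rate)}))
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    df_resid = len(y) - 3
    ss_gain = max(fit0.ssr - fit1.ssr, 0.0)  # 0 when the covariate is collinear
    if fit1.ssr <= 0 or df_resid <= 0:
        return 0.0, 1.0
    f = (ss_gain / 1.0) / (fit1.ssr / df_resid)
    return float(f), float(stats.f.sf(f, 1, df_resid))


def homogeneity_test(tables: list[CountTable2x2]):
    """Breslow-Day test for homogeneity of odds ratios across strata.

    Expected cell counts under the Mantel-Haenszel common OR solve a
    quadratic (linear when the common OR is exactly 1 - the degenerate case
    some library implementations mishandle). Returns (chi2, p, df).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 strata")
    arrs = [t.as_array().astype(float) for t in tables]
    num = sum(a[0, 0] * a[1, 1] / a.sum() for a in arrs)
    den = sum(a[0, 1] * a[1, 0] / a.sum() for a in arrs)
    or_mh = num / den if den > 0 else np.inf
    chi2 = 0.0
    for a in arrs:
        r1, r2 = a[0].sum(), a[1].sum()
        c1 = a[:, 0].sum()
        # expected a11 under common OR: solve psi*(x)(n22)=...(quadratic)
        if np.isinf(or_mh):
            e11 = min(r1, c1)
        elif abs(or_mh - 1.0) < 1e-12:
            e11 = r1 * c1 / a.sum()
        else:
            # solve or_mh = x(N - r1 - c1 + x) / ((r1 - x)(c1 - x)) for x = e11
            A = or_mh - 1.0
            B = -((r1 + c1) * or_mh + (a.sum() - r1 - c1))
            C = or_mh * r1 * c1
            disc = B * B - 4 * A * C
            x1 = (-B - np.sqrt(disc)) / (2 * A)
            x2 = (-B + np.sqrt(disc)) / (2 * A)
            e11 = x1 if 0 <= x1 <= min(r1, c1) else x2
        e12, e21 = r1 - e11, c1 - e11
        e22 = r2 - e21
        with np.errstate(divide="ignore"):
            var = 1.0 / (1.0 / e11 + 1.0 / e12 + 1.0 / e21 + 1.0 / e22)
        if var > 0:
            chi2 += (a[0, 0] - e11) ** 2 / var
    df = len(arrs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), p, df


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))
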