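"""Genotype-call filtering, transmission labeling and sample QC.

Calls are tabular (one row per sample-site) with the quality fields the hard
filters act on: read depth DP, alternate-allele balance AB (alt reads over
total depth), and genotype quality GQ. Role-specific thresholds follow the
trio convention for X: mothers are diploid het carriers, male children are
haploid (an alternate call should be essentially pure), female children are
diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AF_STRATA_EDGES = (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
AF_STRATA_LABELS = ("<=0.01%", "0.01-0.1%", "0.1-1%", "1-10%")


@dataclass(frozen=True)
class RoleThresholds:
    dp_min: float
    ab_min: float
    ab_max: float
    gq_min: float

    def __post_init__(self):
        if min(self.dp_min, self.gq_min) < 0 or not (0 <= self.ab_min <= self.ab_max <= 1):
            raise ValueError("thresholds must be non-negative with ordered AB bounds")


@dataclass
class FilterConfig:
    """Per-role hard thresholds. All comparisons are inclusive (>= / <=)."""

    roles: dict = field(default_factory=dict)
    af_max: float = 0.001

    @classmethod
    def trio_default(cls) -> "FilterConfig":
        return cls(
            roles={
                "mother": RoleThresholds(20, 0.3, 0.7, 20),
                "male_child": RoleThresholds(10, 0.95, 1.0, 90),
                "female_child": RoleThresholds(20, 0.3, 0.7, 90),
                "father": RoleThresholds(10, 0.0, 1.0, 20),
            }
        )

    @classmethod
    def case_control(cls) -> "FilterConfig":
        """Single-sample hemizygous calling mode."""
        return cls(roles={"single_male": RoleThresholds(10, 0.95, 1.0, 90)})

    @classmethod
    def spark(cls) -> "FilterConfig":
        """Joint-called dialect: uniform DP >= 20 and GQ >= 20, VQSR pass upstream."""
        return cls(
            roles={
                "mother": RoleThresholds(20, 0.3, 0.7, 20),
                "male_child": RoleThresholds(20, 0.95, 1.0, 20),
            }
        )


def normalize_gt(gt: pd.Series) -> pd.Series:
    """Normalize GT dialects: haploid male '1' and diploid '1/1' both mean alt."""
    s = gt.astype(str).str.replace("|", "/", regex=False)
    mapping = {"1": "1", "1/1": "1", "0": "0", "0/0": "0", "0/1": "0/1", "1/0": "0/1",
               ".": ".", "./.": "."}
    bad = ~s.isin(mapping)
    if bad.any():
        raise ValueError(f"conflicting GT encodings: {sorted(s[bad].unique())}")
    return s.map(mapping)


def apply_filters(calls: pd.DataFrame, config: FilterConfig, roles: pd.Series | dict):
    """Keep calls whose role-specific DP/AB/GQ thresholds all hold.

    Returns (passing calls, tally) where the tally counts removals per
    criterion (a call failing several criteria counts toward each).
    """
    roles = pd.Series(roles)
    calls = calls.copy()
    role_of = calls["sample_id"].map(roles)
    unknown = role_of.isna() | ~role_of.isin(config.roles)
    if unknown.any():
        missing = sorted(calls.loc[unknown, "sample_id"].unique())
        raise ValueError(f"unknown role for sample(s): {missing}")
    dp_min = role_of.map({r: t.dp_min for r, t in config.roles.items()})
    ab_min = role_of.map({r: t.ab_min for r, t in config.roles.items()})
    ab_max = role_of.map({r: t.ab_max for r, t in config.roles.items()})
    gq_min = role_of.map({r: t.gq_min for r, t in config.roles.items()})
    fail_dp = calls["DP"] < dp_min
    fail_ab = (calls["AB"] < ab_min) | (calls["AB"] > ab_max)
    fail_gq = calls["GQ"] < gq_min
    tally = {
        "input": len(calls),
        "fail_DP": int(fail_dp.sum()),
        "fail_AB": int(fail_ab.sum()),
        "fail_GQ": int(fail_gq.sum()),
    }
    ok = ~(fail_dp | fail_ab | fail_gq)
    tally["passing"] = int(ok.sum())
    return calls[ok].reset_index(drop=True), tally


_SITE = ["chrom", "pos", "ref", "alt"]


def label_transmission(
    mother_calls: pd.DataFrame,
    child_calls: pd.DataFrame,
    child_sex: str,
    father_calls: pd.DataFrame | None = None,
    child_passing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label each filter-passing maternal het site for one child.

    Sons: alt-hemizygous -> transmitted, ref-hemizygous -> untransmitted.
    Daughters additionally require a ref-hemizygous father (paternal
    transmissions are excluded); het -> transmitted, ref -> untransmitted.
    Sites where the child call fails filters are labeled ``n/a``.

    ``mother_calls`` must already be het and filter-passing;
    ``child_passing`` (default: ``child_calls``) defines which child calls
    survived filtering.
    """
    mom = mother_calls[normalize_gt(mother_calls["GT"]) == "0/1"]
    child = child_calls.copy()
    child["GT"] = normalize_gt(child["GT"])
    if child_passing is None:
        child_passing = child_calls
    pass_key = set(map(tuple, child_passing[_SITE].itertuples(index=False)))
    merged = mom[_SITE].merge(child[_SITE + ["GT"]], on=_SITE, how="left")
    labels = []
    for row in merged.itertuples(index=False):
        site = tuple(row[:4])
        gt = row.GT
        if pd.isna(gt) or site not in pass_key:
            labels.append("n/a")
            continue
        if child_sex == "M":
            labels.append("transmitted" if gt == "1" else
                          "untransmitted" if gt == "0" else "n/a")
        else:
            labels.append("transmitted" if gt == "0/1" else
                          "untransmitted" if gt == "0" else "n/a")
    merged["transmission"] = labels
    if child_sex == "F":
        if father_calls is None:
            raise ValueError("daughter transmission labeling requires father calls")
        dad = father_calls.copy()
        dad["GT"] = normalize_gt(dad["GT"])
        dad_alt = set(map(tuple, dad.loc[dad["GT"] != "0", _SITE].itertuples(index=False)))
        drop = merged[_SITE].apply(tuple, axis=1).isin(dad_alt)
        merged = merged[~drop]  # paternal transmission excluded
    return merged.reset_index(drop=True)


def af_filter(records: pd.DataFrame, af_max: float = 0.001, strata: bool = False) -> pd.DataFrame:
    """Keep records rare in both the cohort and the reference panel (AND, inclusive).

    With ``strata=True`` no rows are removed; an ``af_stratum`` column bins
    ``panel_af`` into (<=0.01%, 0.01-0.1%, 0.1-1%, 1-10%].
    """
    for col in ("cohort_af", "panel_af"):
        if col not in records or records[col].isna().any():
            raise ValueError(f"missing allele-frequency field: {col}")
    if strata:
        out = records.copy()
        out["af_stratum"] = pd.cut(
            out["panel_af"], bins=AF_STRATA_EDGES, labels=AF_STRATA_LABELS,
            include_lowest=True,
        )
        return out
    keep = (records["cohort_af"] <= af_max) & (records["panel_af"] <= af_max)
    return records[keep].reset_index(drop=True)


def exclude_outlier_samples(
    counts: pd.Series, strata: pd.Series | dict | None = None
) -> tuple[list, list]:
    """Drop samples outside mean +/- 3 sample SDs of their stratum (one pass).

    Returns (kept sample ids, excluded sample ids). Strata with fewer than 3
    samples are passed through with a warning.
    """
    import warnings

    if strata is None:
        strata = pd.Series("all", index=counts.index)
    strata = pd.Series(strata)
    kept, excluded = [], []
    for _, idx in counts.groupby(strata.reindex(counts.index)).groups.items():
        vals = counts.loc[idx]
        if len(vals) < 3:
            warnings.warn("stratum with fewer than 3 samples: no outlier exclusion")
            kept.extend(idx)
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        ok = (vals >= mu - 3 * sd) & (vals <= mu + 3 * sd)
        kept.extend(vals.index[ok])
        excluded.extend(vals.index[~ok])
    return kept, excluded


def call_concordance(single_sample_calls: set, trio_calls: set):
    """Recall and precision of single-sample hemizygous calls against trio truth.

    Elements are matched exactly (e.g. (sample, pos, ref, alt) tuples).
    Recall is None when the trio set is empty.
    """
    inter = len(single_sample_calls & trio_calls)
    recall = inter / len(trio_calls) if trio_calls else None
    precision = inter / len(single_sample_calls) if single_sample_calls else None
    return recall, precision


def confirmation_rate(n_confirmed: int, n_assessed: int) -> float:
    """Fraction of assessed calls that verified, as a percentage."""
    if n_assessed <= 0:
        raise ValueError("need at least one assessed call")
    return 100.0 * n_confirmed / n_assessed
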