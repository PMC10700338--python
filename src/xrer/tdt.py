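"""Gene discovery with a control-calibrated transmission disequilibrium test.

Systematic undercalling of rare maternally inherited hemizygous calls pushes
the observed transmission fraction below the Mendelian 1/2 (to d/(1+d) for a
per-call detection rate d), so a naive binomial TDT against 0.5 is
conservative and loses power. The corrected test estimates the *null*
transmission probability locally from control children: the non-PAR is tiled
into 3-Mb windows, each window's null is the control transmitted fraction of
damaging variants, and each gene is tested against the null of the window(s)
it overlaps (taking the higher probability when a gene straddles two
windows - the conservative choice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval

logger = logging.getLogger(__name__)

DAMAGING = ("LGD", "Mis3")
UNIVERSES = {"rer": 149, "chrx": 808, "exome": 19_251}


@dataclass
class WindowNull:
    window: Interval
    t_ctrl: int
    u_ctrl: int
    n_het_mothers: int
    usable: bool

    @property
    def p_null(self) -> float:
        tot = self.t_ctrl + self.u_ctrl
        return self.t_ctrl / tot if tot else float("nan")


def estimate_window_nulls(
    control_records: pd.DataFrame,
    span: Interval,
    window_size: int = 3_000_000,
    min_het_mothers: int = 10,
) -> list[WindowNull]:
    """Tile the non-PAR and estimate each window's null transmission probability.

    The null is the transmitted fraction of *damaging* control records; a
    window is usable only if it holds at least ``min_het_mothers`` distinct
    rare maternal het sites (any class, distinct (family, variant) pairs or
    sites when no variant key is present), has at least one damaging record
    and a nonzero transmitted count (a zero null would make any case
    transmission trivially significant).
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if len(control_records) == 0:
        raise ValueError("control record set is empty")
    edges = np.arange(span[0], span[1], window_size, dtype=np.int64)
    edges = np.append(edges, span[1])  # final partial window retained
    dam = control_records[control_records["vclass"].isin(DAMAGING)]
    key_cols = ["family", "variant_id"] if "variant_id" in control_records else ["family", "pos"]
    out = []
    pos_all = control_records["pos"].to_numpy(float)
    pos_dam = dam["pos"].to_numpy(float)
    t_dam = (dam["transmission"] == "transmitted").to_numpy()
    for i in range(len(edges) - 1):
        lo, hi = int(edges[i]), int(edges[i + 1])
        in_w = (pos_all >= lo) & (pos_all < hi)
        n_het = int(control_records.loc[in_w, key_cols].drop_duplicates().shape[0])
        in_d = (pos_dam >= lo) & (pos_dam < hi)
        t = int(t_dam[in_d].sum())
        u = int(in_d.sum() - t)
        usable = n_het >= min_het_mothers and (t + u) > 0 and t > 0
        out.append(WindowNull((lo, hi), t, u, n_het, usable))
    return out


class GeneExcluded(ValueError):
    """Gene overlaps no usable window."""


def gene_null_prob(gene_interval: Interval, windows: list[WindowNull],
                   pooled_fallback: float | None = None) -> float:
    """Null transmission probability for a gene: the *higher* p_null among the
    usable windows it overlaps (conservative for an upper-tail test)."""
    ps = [
        w.p_null
        for w in windows
        if w.usable and gene_interval[0] < w.window[1] and gene_interval[1] > w.window[0]
    ]
    if not ps:
        if pooled_fallback is not None:
            return pooled_fallback
        raise GeneExcluded(f"gene {gene_interval} overlaps only unusable windows")
    return max(ps)


def gene_binomial_test(t: int, u: int, p_null: float) -> float:
    """One-sided upper-tail exact binomial p, inclusive of the observed count."""
    if not (0 < p_null < 1):
        raise ValueError("p_null must lie strictly inside (0, 1)")
    if t + u < 1:
        raise ValueError("need at least one transmitted or untransmitted count")
    return float(stats.binomtest(t, t + u, p_null, alternative="greater").pvalue)


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit universe size m.

    m defaults to the number of observed p-values; a larger m treats the
    unobserved members of the universe as p = 1 (their adjusted values are
    capped anyway, so only the rank multipliers change).
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def correct_multiplicity(results: pd.DataFrame, universes: dict | None = None) -> pd.DataFrame:
    """Attach Bonferroni and BH-FDR columns at each stated gene universe."""
    if universes is None:
        universes = UNIVERSES
    out = results.copy()
    for name, m in universes.items():
        out[f"bonferroni_{name}"] = np.minimum(out["raw_p"] * m, 1.0)
        out[f"bh_fdr_{name}"] = bh_adjust(out["raw_p"].to_numpy(), m)
        out.attrs[f"alpha_{name}"] = 0.05 / m
    return out


def gene_counts(records: pd.DataFrame, classes=DAMAGING) -> pd.DataFrame:
    """Transmitted/untransmitted damaging counts per gene."""
    dam = records[records["vclass"].isin(classes)]
    g = dam.groupby("gene_id")["transmission"]
    t = g.apply(lambda s: int((s == "transmitted").sum()))
    u = g.apply(lambda s: int((s == "untransmitted").sum()))
    return pd.DataFrame({"T": t, "U": u}).reset_index()


def qq_data(raw_p: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p with a 95% order-statistic band."""
    p = np.sort(np.asarray(raw_p, dtype=float))
    n = len(p)
    k = np.arange(1, n + 1)
    expected = k / (n + 1)
    lo = stats.beta.ppf(0.025, k, n - k + 1)
    hi = stats.beta.ppf(0.975, k, n - k + 1)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.maximum(p, 1e-300)),
            "band_low_neglog10": -np.log10(hi),
            "band_high_neglog10": -np.log10(lo),
        }
    )


def discover_genes(
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    genes: pd.DataFrame,
    span: Interval,
    gene_set: str | None = None,
    window_size: int = 3_000_000,
    universes: dict | None = None,
    fixed_null: float | None = None,
    pooled_fallback: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full gene-discovery pipeline: window nulls -> per-gene tests -> corrections.

    ``gene_set`` restricts to 'RER' or 'NER' genes (per the ``region_class``
    column); ``fixed_null`` bypasses the window estimate (the naive test).
    Returns (ranked per-gene results, QQ-plot table).
    """
    sel = genes if gene_set is None else genes[genes["region_class"] == gene_set]
    if len(sel) == 0:
        raise ValueError(f"empty gene set {gene_set!r}")
    windows = None
    pooled = None
    if fixed_null is None:
        windows = estimate_window_nulls(control_records, span, window_size)
        if pooled_fallback:
            dam = control_records[control_records["vclass"].isin(DAMAGING)]
            tr = (dam["transmission"] == "transmitted").mean()
            pooled = float(tr)
    counts = gene_counts(case_records).set_index("gene_id")
    rows = []
    n_excluded = 0
    for row in sel.itertuples(index=False):
        if row.gene_id not in counts.index:
            continue
        t, u = int(counts.loc[row.gene_id, "T"]), int(counts.loc[row.gene_id, "U"])
        if t + u < 1:
            continue
        if fixed_null is not None:
            p0 = fixed_null
        else:
            try:
                p0 = gene_null_prob((row.start, row.end), windows, pooled)
            except GeneExcluded:
                n_excluded += 1
                logger.info("gene %s excluded: only unusable windows", row.gene_id)
                continue
        rows.append({"gene_id": row.gene_id, "T": t, "U": u, "p_null": p0,
                     "raw_p": gene_binomial_test(t, u, p0)})
    if n_excluded:
        logger.info("%d genes excluded for lacking a usable window null", n_excluded)
    res = pd.DataFrame(rows)
    if len(res) == 0:
        return res, pd.DataFrame()
    res = correct_multiplicity(res, universes).sort_values("raw_p").reset_index(drop=True)
    return res, qq_data(res["raw_p"].to_numpy())
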