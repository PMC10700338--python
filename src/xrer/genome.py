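"""Coordinate frame for the analysis: chromosome-X non-PAR, genes, recombination map.

The genome model is synthetic but mirrors the dimensions of the human Chr X
non-pseudoautosomal region: a ~152-Mb non-PAR holding 808 protein-coding
genes, of which 149 fall inside four designated risk intervals (the regions
a segregation analysis should rediscover) and 659 outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval, clip_intervals, overlaps_any, subtract_intervals

# GRCh37-like Chr X landmarks (0-based half-open).
NONPAR: Interval = (2_699_520, 154_931_044)
CENTROMERE: Interval = (58_100_000, 61_100_000)

#: Four implanted risk intervals, each 9 Mb (a peak extended +/- 4.5 Mb).
DEFAULT_RISK_INTERVALS: list[Interval] = [
    (15_000_000, 24_000_000),
    (40_000_000, 49_000_000),
    (95_000_000, 104_000_000),
    (130_000_000, 139_000_000),
]

N_GENES = 808
N_RER_GENES = 149


class ConfigurationError(ValueError):
    """Raised for inconsistent genome/simulation configuration."""


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rate over the non-PAR.

    Segments ``[starts[i], ends[i])`` carry ``rates[i]`` in cM/Mb. The map
    doubles as the crossover-position sampling distribution: positions are
    drawn with probability proportional to local genetic length.
    """

    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray  # cM/Mb

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ConfigurationError("recombination rates must be >= 0")
        # cumulative genetic length (Morgans) at segment boundaries
        seg_m = self.rates * (self.ends - self.starts) / 1e6 / 100.0
        self._cum = np.concatenate([[0.0], np.cumsum(seg_m)])

    @property
    def total_morgans(self) -> float:
        return float(self._cum[-1])

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n crossover positions with density proportional to local rate."""
        if n == 0:
            return np.empty(0)
        u = rng.uniform(0.0, self.total_morgans, size=n)
        return self.positions_at(u)

    def positions_at(self, genetic: np.ndarray) -> np.ndarray:
        """Map cumulative genetic coordinates (Morgans) to basepair positions."""
        idx = np.clip(np.searchsorted(self._cum, genetic, side="right") - 1, 0, len(self.rates) - 1)
        seg_len_m = self._cum[idx + 1] - self._cum[idx]
        frac = np.where(seg_len_m > 0, (genetic - self._cum[idx]) / np.where(seg_len_m > 0, seg_len_m, 1.0), 0.0)
        return self.starts[idx] + frac * (self.ends[idx] - self.starts[idx])

    def mean_rate(self, bin_edges: np.ndarray) -> np.ndarray:
        """Average cM/Mb within each bin of a binning of the map span."""
        out = np.zeros(len(bin_edges) - 1)
        for i in range(len(bin_edges) - 1):
            lo, hi = bin_edges[i], bin_edges[i + 1]
            ov = np.clip(np.minimum(self.ends, hi) - np.maximum(self.starts, lo), 0, None)
            w = ov.sum()
            out[i] = float((self.rates * ov).sum() / w) if w > 0 else 0.0
        return out

    @classmethod
    def uniform(cls, span: Interval, rate: float) -> "RecombinationMap":
        return cls(np.array([span[0]]), np.array([span[1]]), np.array([rate]))

    @classmethod
    def default(
        cls,
        span: Interval = NONPAR,
        centromere: Interval = CENTROMERE,
        hotspots: list[Interval] | None = None,
        baseline: float = 1.0,
        hotspot_rate: float = 3.0,
        centromere_rate: float = 0.02,
    ) -> "RecombinationMap":
        """Baseline 1 cM/Mb, suppressed centromere, a few elevated hotspots.

        Total genetic length lands near 1.8-2.0 Morgans, matching the female
        Chr X map (~180 cM).
        """
        if hotspots is None:
            # four hotspots coincide with the default risk intervals (risk
            # regions and recombination hotspots are correlated in this
            # setting), three equally sized ones do not
            hotspots = [
                (17_500_000, 21_500_000),
                (42_500_000, 46_500_000),
                (70_000_000, 74_000_000),
                (97_500_000, 101_500_000),
                (110_000_000, 114_000_000),
                (132_500_000, 136_500_000),
                (145_000_000, 149_000_000),
            ]
        cut = {span[0], span[1], centromere[0], centromere[1]}
        for s, e in hotspots:
            cut.update((s, e))
        edges = np.array(sorted(p for p in cut if span[0] <= p <= span[1]))
        starts, ends = edges[:-1], edges[1:]
        mids = (starts + ends) / 2
        rates = np.full(len(mids), baseline)
        for s, e in hotspots:
            rates[(mids >= s) & (mids < e)] = hotspot_rate
        rates[(mids >= centromere[0]) & (mids < centromere[1])] = centromere_rate
        return cls(starts, ends, rates)


@dataclass
class GenomeModel:
    """Genes, risk intervals and recombination map on the Chr X non-PAR."""

    nonpar: Interval
    centromere: Interval
    genes: pd.DataFrame  # gene_id, start, end, region_class, expression_rank
    recomb_map: RecombinationMap
    risk_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        g = self.genes
        if len(g) and (g["start"].min() < self.nonpar[0] or g["end"].max() > self.nonpar[1]):
            raise ConfigurationError("gene intervals must lie within the non-PAR")
        if len(g) and not g["start"].is_monotonic_increasing:
            raise ConfigurationError("genes must be sorted by start")

    @property
    def n_rer_genes(self) -> int:
        return int((self.genes["region_class"] == "RER").sum())

    def gene_interval(self, gene_id: str) -> Interval:
        row = self.genes.set_index("gene_id").loc[gene_id]
        return (int(row["start"]), int(row["end"]))


def _place_genes(regions: list[Interval], n: int, rng: np.random.Generator,
                 min_len: int, max_len: int) -> list[Interval]:
    """Place n non-overlapping genes across regions, proportionally to length.

    Each region is divided into equal slots; one gene lands at a random
    offset inside each slot, so genes are sorted and disjoint by construction.
    """
    lens = np.array([e - s for s, e in regions], dtype=float)
    alloc = np.floor(lens / lens.sum() * n).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(lens / (alloc + 1)))] += 1
    out: list[Interval] = []
    for (s, e), k in zip(regions, alloc):
        if k == 0:
            continue
        slot = (e - s) / k
        for j in range(k):
            glen = int(rng.integers(min_len, max_len + 1))
            glen = min(glen, int(slot) - 1)
            lo = s + j * slot
            start = int(lo + rng.uniform(0, slot - glen))
            out.append((start, start + glen))
    return sorted(out)


def simulate_genome(
    seed: int = 0,
    n_genes: int = N_GENES,
    n_rer_genes: int = N_RER_GENES,
    nonpar: Interval = NONPAR,
    centromere: Interval = CENTROMERE,
    risk_intervals: list[Interval] | None = None,
    recomb_map: RecombinationMap | None = None,
    gene_length: Interval = (15_000, 80_000),
) -> GenomeModel:
    """Build a synthetic genome model with the configured gene universe.

    By default 808 genes are placed on the non-PAR, exactly ``n_rer_genes``
    of them inside the risk intervals; the remainder are distributed over
    the complement (excluding the centromere).
    """
    if nonpar[1] <= nonpar[0]:
        raise ConfigurationError("non-PAR interval has zero or negative length")
    if n_genes < 1:
        raise ConfigurationError("need at least one gene")
    if risk_intervals is None:
        risk_intervals = list(DEFAULT_RISK_INTERVALS)
    risk_intervals = clip_intervals(risk_intervals, *nonpar)
    if not risk_intervals:
        n_rer_genes = 0
    rng = np.random.default_rng(seed)
    ner_space = subtract_intervals(nonpar, risk_intervals + [centromere])
    ivs = []
    if n_rer_genes:
        ivs += _place_genes(risk_intervals, n_rer_genes, rng, *gene_length)
    ivs += _place_genes(ner_space, n_genes - n_rer_genes, rng, *gene_length)
    ivs = sorted(ivs)
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    in_rer = overlaps_any(starts, ends, risk_intervals)
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(len(ivs))],
            "start": starts,
            "end": ends,
            "region_class": np.where(in_rer, "RER", "NER"),
            "expression_rank": rng.uniform(0, 1, len(ivs)).round(6),
        }
    )
    if recomb_map is None:
        recomb_map = RecombinationMap.default(nonpar, centromere)
    if recomb_map.total_morgans == 0:
        warnings.warn("recombination map has zero total genetic length; no crossovers will occur")
    return GenomeModel(nonpar, centromere, genes, recomb_map, risk_intervals)
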