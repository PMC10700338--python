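"""Risk-enriched-region discovery from maternal haplotype segregation.

Families with one male proband and at least two unaffected male brothers are
screened for genomic segments that the proband inherited from a different
maternal X haplotype than *every* unaffected brother ("proband-unique"
segments). Stacking those segments across informative families produces a
coverage density whose peaks, extended by a fixed padding, define the
risk-enriched regions (RERs); the remainder of the non-PAR is non-enriched
(NER).

Maternal phase is never observed directly. Sons are haploid, so each
informative SNP (mother heterozygous) reveals which maternal allele a son
received; the two maternal alleles are linked from SNP to SNP by parsimony
across the sibship (the orientation that flips the fewest children's origins
between adjacent SNPs), which is correct whenever fewer than half the
children recombine inside one SNP gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, clip_intervals, merge_intervals, overlaps_any

ORIGIN_LABELS = ("M1", "M2")


@dataclass
class OriginTrack:
    """Mosaic of maternal haplotype origins along one child's X.

    Segments tile ``span`` exactly: breakpoints are sorted interior
    positions, and origins alternate starting from ``start_origin``
    (0 -> M1, 1 -> M2). Labels are consistent *within* a family but their
    global polarity is arbitrary (maternal phase is only relatively known).
    """

    sample_id: str
    span: Interval
    start_origin: int
    breakpoints: np.ndarray

    def __post_init__(self):
        self.breakpoints = np.asarray(sorted(self.breakpoints), dtype=float)

    def origin_at(self, positions) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(positions, dtype=float))
        cnt = np.searchsorted(self.breakpoints, pos, side="right")
        return self.start_origin ^ (cnt & 1)

    def segments(self) -> list[tuple[int, int, int]]:
        """(start, end, origin) triples tiling the span."""
        edges = [self.span[0], *self.breakpoints.astype(int), self.span[1]]
        return [
            (edges[i], edges[i + 1], self.start_origin ^ (i & 1))
            for i in range(len(edges) - 1)
        ]

    def majority_origin(self, interval: Interval | None = None) -> int:
        """Length-weighted majority origin over ``interval`` (default: whole span)."""
        lo, hi = interval if interval is not None else self.span
        w = [0.0, 0.0]
        for s, e, o in self.segments():
            ov = min(e, hi) - max(s, lo)
            if ov > 0:
                w[o] += ov
        return int(w[1] > w[0])


class UninformativeFlankError(ValueError):
    """A centromere flank has no informative SNP; the family must be dropped."""


def _parsimony_phase(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP origins for all children of one sibship.

    genotypes: (n_children, n_snps) haploid alleles at maternal-het SNPs.
    Returns an equally shaped 0/1 origin matrix under the relative phase that
    minimizes origin flips between adjacent SNPs (ties keep the previous
    orientation).
    """
    n_child, n_snp = genotypes.shape
    origins = genotypes.copy().astype(int)
    orient = 0
    for i in range(1, n_snp):
        flips_keep = int((origins[:, i - 1] != (genotypes[:, i] ^ orient)).sum())
        flips_swap = int((origins[:, i - 1] != (genotypes[:, i] ^ orient ^ 1)).sum())
        if flips_swap < flips_keep:
            orient ^= 1
        origins[:, i] = genotypes[:, i] ^ orient
    return origins


def _track_from_snp_origins(sample_id, positions, origins, span) -> OriginTrack:
    """Breakpoints at midpoints between adjacent SNPs with different origins."""
    change = np.flatnonzero(np.diff(origins) != 0)
    bp = (positions[change] + positions[change + 1]) / 2.0
    return OriginTrack(sample_id, span, int(origins[0]), bp)


def infer_family_origins(
    positions: np.ndarray,
    child_genotypes: pd.DataFrame,
    mother_genotypes: np.ndarray | None,
    centromere: Interval,
    span: Interval,
) -> dict[str, OriginTrack]:
    """Infer per-child origin tracks jointly for one sibship of male children.

    ``child_genotypes``: rows = children (index = sample id), columns align
    with ``positions`` (haploid 0/1 alleles). ``mother_genotypes`` selects
    informative sites (heterozygous, coded 1); pass None if all sites are
    known informative.

    Raises :class:`UninformativeFlankError` if either centromere flank holds
    no informative SNP, in which case the caller should drop the family.
    """
    positions = np.asarray(positions, dtype=float)
    keep = np.ones(len(positions), dtype=bool)
    if mother_genotypes is not None:
        keep = np.asarray(mother_genotypes) == 1
    pos = positions[keep]
    if (pos < centromere[0]).sum() == 0 or (pos > centromere[1]).sum() == 0:
        raise UninformativeFlankError(
            "no informative SNP on one centromere flank; origin unknown"
        )
    gt = child_genotypes.to_numpy()[:, keep].astype(int)
    origins = _parsimony_phase(gt)
    return {
        sid: _track_from_snp_origins(sid, pos, origins[i], span)
        for i, sid in enumerate(child_genotypes.index)
    }


def infer_origin(
    child_gt: np.ndarray,
    mother_gt: np.ndarray,
    sibling_gts: pd.DataFrame,
    positions: np.ndarray,
    centromere: Interval,
    span: Interval,
    sample_id: str = "child",
) -> OriginTrack:
    """Origin track for one child, phased against its sibship."""
    sibs = sibling_gts.copy()
    sibs.loc[sample_id] = np.asarray(child_gt)
    tracks = infer_family_origins(positions, sibs, mother_gt, centromere, span)
    return tracks[sample_id]


def select_informative_families(
    family_tracks: dict, proband_of: dict, unaffected_sibs_of: dict
) -> tuple[list, dict]:
    """Families where the proband shares its chromosome-level maternal origin
    with at least one unaffected male sibling.

    Returns the kept family ids and a count summary.
    """
    kept = []
    for fam, tracks in family_tracks.items():
        pro = tracks[proband_of[fam]]
        sibs = [tracks[s] for s in unaffected_sibs_of[fam] if s in tracks]
        if not sibs:
            continue
        p0 = pro.majority_origin()
        if any(s.majority_origin() == p0 for s in sibs):
            kept.append(fam)
    return kept, {"n_families": len(family_tracks), "n_informative": len(kept)}


def proband_unique_segments(
    proband: OriginTrack, siblings: list[OriginTrack]
) -> list[Interval]:
    """Maximal intervals where the proband's local origin differs from every sibling's."""
    if not siblings:
        return []
    edges = np.unique(
        np.concatenate(
            [
                np.array(proband.span, dtype=float),
                proband.breakpoints,
                *[s.breakpoints for s in siblings],
            ]
        )
    )
    mids = (edges[:-1] + edges[1:]) / 2.0
    pro = proband.origin_at(mids)
    unique = np.ones(len(mids), dtype=bool)
    for s in siblings:
        unique &= s.origin_at(mids) != pro
    out = [
        (int(edges[i]), int(edges[i + 1]))
        for i in np.flatnonzero(unique)
    ]
    return merge_intervals(out)


@dataclass
class DensityCurve:
    """Per-bin family counts of proband-unique-segment evidence.

    ``statistic`` records what was counted: ``"coverage"`` (families whose
    proband-unique segments cover the bin) or ``"events"`` (families with an
    informative recombination - a unique-segment boundary - in the bin).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_families: int
    statistic: str = "coverage"

    @property
    def density(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "count": self.counts,
                "density": self.density,
            }
        )


@dataclass
class RegionSet:
    """RER intervals plus the induced exhaustive RER/NER gene partition."""

    rer_intervals: list[Interval]
    gene_partition: dict = field(default_factory=dict)

    def assign_genes(self, genes: pd.DataFrame) -> "RegionSet":
        hit = overlaps_any(genes["start"], genes["end"], self.rer_intervals)
        self.gene_partition = dict(
            zip(genes["gene_id"], np.where(hit, "RER", "NER"))
        )
        return self

    def gene_sets(self) -> tuple[set, set]:
        rer = {g for g, c in self.gene_partition.items() if c == "RER"}
        ner = {g for g, c in self.gene_partition.items() if c == "NER"}
        return rer, ner


def coverage_curve(
    segments_by_family: dict, span: Interval, bin_width: int = 100_000,
    bounded_only: bool = False,
) -> DensityCurve:
    """Per-bin count of families with a proband-unique segment covering the bin.

    With ``bounded_only`` a segment contributes only if both of its ends are
    observed recombinations, i.e. it does not run into a span boundary: a
    segment reaching the telomere is not delimited by an informative
    recombination on that side and carries no localizing evidence there.
    """
    edges = np.arange(span[0], span[1] + bin_width, bin_width, dtype=float)
    edges[-1] = span[1]
    counts = np.zeros(len(edges) - 1, dtype=int)
    for segs in segments_by_family.values():
        covered = np.zeros(len(counts), dtype=bool)
        for s, e in segs:
            if bounded_only and (s <= span[0] or e >= span[1]):
                continue
            i0 = np.searchsorted(edges, s, side="right") - 1
            i1 = np.searchsorted(edges, e, side="left")
            covered[max(i0, 0): i1] = True
        counts += covered
    return DensityCurve(edges, counts, len(segments_by_family), "coverage")


def event_curve(
    segments_by_family: dict, span: Interval, bin_width: int = 1_000_000
) -> DensityCurve:
    """Per-bin count of families with an informative recombination in the bin.

    An informative recombination is a proband-unique-segment boundary that is
    an observed crossover (boundaries at the span edges are not delimited by
    recombination and do not count). Each family contributes at most once per
    bin.
    """
    edges = np.arange(span[0], span[1] + bin_width, bin_width, dtype=float)
    edges[-1] = span[1]
    counts = np.zeros(len(edges) - 1, dtype=int)
    for segs in segments_by_family.values():
        hit = np.zeros(len(counts), dtype=bool)
        for s, e in segs:
            for b in (s, e):
                if span[0] < b < span[1]:
                    i = min(int(np.searchsorted(edges, b, side="right") - 1), len(counts) - 1)
                    hit[i] = True
        counts += hit
    return DensityCurve(edges, counts, len(segments_by_family), "events")


def call_rers(
    segments_by_family: dict,
    span: Interval,
    bin_width: int = 1_000_000,
    peak_threshold: float | None = None,
    padding: int = 4_500_000,
    statistic: str = "events",
) -> tuple[RegionSet, DensityCurve]:
    """Call RERs from proband-unique segments pooled across families.

    The per-bin statistic is the informative-recombination density (families
    with a unique-segment boundary in the bin; ``statistic="coverage"``
    switches to segment coverage). Peaks are maximal runs of bins reaching
    the threshold (default: max(2, 90th percentile of nonzero bin counts));
    each peak's count-weighted midpoint is extended by ``padding`` on both
    sides, overlapping extensions are merged, and the result is clipped to
    the span.
    """
    if not segments_by_family:
        raise ValueError("need at least one informative family")
    if statistic == "events":
        curve = event_curve(segments_by_family, span, bin_width)
    else:
        curve = coverage_curve(segments_by_family, span, bin_width)
    counts = curve.counts
    nz = counts[counts > 0]
    if peak_threshold is None:
        peak_threshold = max(2.0, float(np.percentile(nz, 90))) if len(nz) else 2.0
    above = counts >= peak_threshold
    if not above.any():
        warnings.warn("no bin reaches the peak threshold; empty region set")
        return RegionSet([]), curve
    centers = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2.0
    intervals: list[Interval] = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        w = counts[i: j + 1].astype(float)
        anchor = float(np.average(centers[i: j + 1], weights=w))
        if padding > 0:
            intervals.append((int(anchor - padding), int(anchor + padding)))
        else:
            intervals.append((int(curve.bin_edges[i]), int(curve.bin_edges[j + 1])))
        i = j + 1
    intervals = clip_intervals(merge_intervals(intervals), *span)
    return RegionSet(intervals), curve


def density_vs_recomb_map(curve: DensityCurve, recomb_map, span: Interval,
                          bin_width: int = 1_000_000):
    """Paired location test of the segregation density against the map density.

    Both curves are rebinned at ``bin_width``, normalized to sum to one, and
    compared with a Wilcoxon signed-rank test on per-bin differences.
    Returns (statistic, p_value, per-bin table).
    """
    edges = np.arange(span[0], span[1] + bin_width, bin_width, dtype=float)
    edges[-1] = span[1]
    seg = np.zeros(len(edges) - 1)
    src_centers = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2.0
    idx = np.clip(np.searchsorted(edges, src_centers, side="right") - 1, 0, len(seg) - 1)
    np.add.at(seg, idx, curve.counts.astype(float))
    rate = recomb_map.mean_rate(edges)
    if len(seg) != len(rate):
        raise ValueError("bin-count mismatch between density and map")
    a = seg / seg.sum() if seg.sum() else seg
    b = rate / rate.sum() if rate.sum() else rate
    diff = a - b
    if np.allclose(diff, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(a, b, zero_method="wilcox")
    table = pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "segregation_density": a,
            "map_density": b,
        }
    )
    return float(stat), float(p), table
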