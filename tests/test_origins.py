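import numpy as np
import pandas as pd
import pytest

from xrer import RecombinationMap, call_rers, density_vs_recomb_map, proband_unique_segments
from xrer.intervals import jaccard
from xrer.origins import (
    OriginTrack,
    UninformativeFlankError,
    coverage_curve,
    infer_family_origins,
    select_informative_families,
)

SPAN = (0, 100_000_000)
CEN = (48_000_000, 52_000_000)


def _family_gt(positions, origin_rows, m1):
    """Genotypes from per-child origin vectors and a maternal phase vector."""
    gt = np.array([m1 ^ o for o in origin_rows])
    return pd.DataFrame(gt, index=[f"c{i}" for i in range(len(origin_rows))],
                        columns=positions)


class TestInferOrigins:
    def test_constant_origin_gives_single_segment(self):
        pos = np.arange(5e6, 100e6, 5e6)
        rng = np.random.default_rng(0)
        m1 = rng.integers(0, 2, len(pos))
        gt = _family_gt(pos, [np.zeros(len(pos), int), np.ones(len(pos), int)], m1)
        tracks = infer_family_origins(pos, gt, None, CEN, SPAN)
        assert len(tracks["c0"].breakpoints) == 0
        assert len(tracks["c1"].breakpoints) == 0
        assert tracks["c0"].majority_origin() != tracks["c1"].majority_origin()

    def test_breakpoint_at_midpoint_between_discordant_snps(self):
        # child switches origin between SNPs at 49.5 and 50.5 Mb -> 50.0 Mb
        pos = np.array([10e6, 30e6, 49.5e6, 50.5e6, 70e6, 90e6])
        o_child = np.array([0, 0, 0, 1, 1, 1])
        o_sib = np.zeros(6, int)
        m1 = np.array([1, 0, 1, 1, 0, 1])
        gt = _family_gt(pos, [o_child, o_sib], m1)
        tracks = infer_family_origins(pos, gt, None, CEN, SPAN)
        assert tracks["c0"].breakpoints == pytest.approx([50.0e6])
        assert len(tracks["c1"].breakpoints) == 0

    def test_flank_without_informative_snp_raises(self):
        pos = np.array([10e6, 20e6, 30e6])  # all left of the centromere
        gt = _family_gt(pos, [np.zeros(3, int)], np.ones(3, int))
        with pytest.raises(UninformativeFlankError):
            infer_family_origins(pos, gt, None, CEN, SPAN)

    def test_mother_homozygous_sites_ignored(self):
        pos = np.array([10e6, 30e6, 60e6, 90e6])
        mother = np.array([1, 0, 1, 1])  # site 2 uninformative
        o = np.array([0, 0, 0])
        m1 = np.array([1, 0, 1])
        gt = _family_gt(pos[mother == 1], [o], m1)
        gt_full = pd.DataFrame(np.array([[1, 9, 0, 1]]), index=["c0"], columns=pos)
        gt_full.loc["c0", pos[mother == 1]] = gt.loc["c0"].to_numpy()
        tracks = infer_family_origins(pos, gt_full, mother, CEN, SPAN)
        assert len(tracks["c0"].breakpoints) == 0

    def test_breakpoints_recovered_from_simulated_meioses(self, rer_scenario, genome):
        """>= 95% of true crossovers recovered within one SNP spacing."""
        cohort = rer_scenario["cohort"]
        spacing = 500_000
        positions, gt = cohort.snp_matrix(spacing)
        hits = tot = 0
        kids = cohort.samples[cohort.samples["role"].isin(["proband", "sibling"])]
        for fam, grp in kids.groupby("family"):
            ids = grp.loc[grp["sex"] == "M", "sample_id"].tolist()
            if len(ids) < 3:
                continue
            tracks = infer_family_origins(positions, gt.loc[ids], None,
                                          genome.centromere, genome.nonpar)
            for sid in ids:
                r = cohort.child_index.get_loc(sid)
                tb = cohort.child_bp[r]
                tb = tb[np.isfinite(tb)]
                tb = tb[(tb > genome.nonpar[0]) & (tb < genome.nonpar[1])]
                ib = tracks[sid].breakpoints
                for b in tb:
                    tot += 1
                    if len(ib) and np.min(np.abs(ib - b)) <= spacing:
                        hits += 1
        assert tot > 200
        assert hits / tot >= 0.95


def _track(start_origin, breakpoints, sid="x", span=SPAN):
    return OriginTrack(sid, span, start_origin, np.array(breakpoints, float))


class TestInformativeFamilies:
    def test_proband_sharing_no_sib_excluded(self):
        tracks = {"p": _track(0, []), "s1": _track(1, []), "s2": _track(1, [])}
        kept, summary = select_informative_families(
            {0: tracks}, {0: "p"}, {0: ["s1", "s2"]}
        )
        assert kept == [] and summary["n_informative"] == 0

    def test_proband_sharing_one_sib_included(self):
        tracks = {"p": _track(0, []), "s1": _track(0, []), "s2": _track(1, [])}
        kept, _ = select_informative_families({0: tracks}, {0: "p"}, {0: ["s1", "s2"]})
        assert kept == [0]

    def test_identical_tracks_included_but_contribute_nothing(self):
        tracks = {"p": _track(0, [30e6]), "s1": _track(0, [30e6]), "s2": _track(0, [30e6])}
        kept, _ = select_informative_families({0: tracks}, {0: "p"}, {0: ["s1", "s2"]})
        assert kept == [0]
        assert proband_unique_segments(tracks["p"], [tracks["s1"], tracks["s2"]]) == []


class TestProbandUniqueSegments:
    def test_set_difference_example(self):
        # proband M1 on [40,60] Mb, both sibs M2 there, everyone M1 elsewhere
        pro = _track(0, [40e6, 60e6])
        pro = OriginTrack("p", SPAN, 0, np.array([40e6, 60e6]))
        sib = OriginTrack("s", SPAN, 1, np.array([40e6, 60e6]))
        # pro: M1 [0,40) M2 [40,60) M1 [60,100); sib: the complement
        segs = proband_unique_segments(pro, [sib, sib])
        assert segs == [(0, 100_000_000)]
        # both sibs follow the proband except on [40,60)
        sib2 = OriginTrack("s2", SPAN, 0, np.array([40e6, 60e6]))
        segs = proband_unique_segments(pro, [sib2, sib2])
        assert segs == []
        sib3 = OriginTrack("s3", SPAN, 1, np.array([]))  # M2 everywhere
        segs = proband_unique_segments(pro, [sib3, sib3])
        assert segs == [(0, 40_000_000), (60_000_000, 100_000_000)]

    def test_matches_positionwise_oracle_on_random_tracks(self):
        rng = np.random.default_rng(12)
        span = (0, 10_000_000)
        for _ in range(25):
            def rand_track(sid):
                nb = rng.integers(0, 5)
                bp = np.sort(rng.integers(span[0] + 1, span[1], nb)).astype(float)
                return OriginTrack(sid, span, int(rng.integers(0, 2)), bp)

            pro = rand_track("p")
            sibs = [rand_track(f"s{i}") for i in range(int(rng.integers(1, 4)))]
            segs = proband_unique_segments(pro, sibs)
            grid = np.arange(span[0] + 500, span[1], 1000).astype(float)
            po = pro.origin_at(grid)
            unique = np.ones(len(grid), bool)
            for s in sibs:
                unique &= s.origin_at(grid) != po
            in_seg = np.zeros(len(grid), bool)
            for a, b in segs:
                in_seg |= (grid >= a) & (grid < b)
            assert (unique == in_seg).all()


class TestCallRers:
    def test_coverage_peak_midpoint_and_padding(self):
        # three families covering [10,12] Mb, threshold 2: anchor at 11 Mb
        segs = {i: [(10_000_000, 12_000_000)] for i in range(3)}
        rs, curve = call_rers(segs, SPAN, bin_width=1_000_000, peak_threshold=2,
                              padding=4_500_000, statistic="coverage")
        assert rs.rer_intervals == [(6_500_000, 15_500_000)]

    def test_zero_padding_returns_peak_run(self):
        segs = {i: [(10_000_000, 12_000_000)] for i in range(3)}
        rs, _ = call_rers(segs, SPAN, bin_width=1_000_000, peak_threshold=2,
                          padding=0, statistic="coverage")
        assert rs.rer_intervals == [(10_000_000, 12_000_000)]

    def test_no_peak_warns_and_returns_empty(self):
        segs = {0: [(10_000_000, 11_000_000)]}
        with pytest.warns(UserWarning, match="no bin reaches"):
            rs, _ = call_rers(segs, SPAN, peak_threshold=5)
        assert rs.rer_intervals == []

    def test_intervals_stay_inside_span_and_merge_idempotent(self, rer_scenario, genome):
        rs, _ = call_rers(rer_scenario["segments"], genome.nonpar)
        for s, e in rs.rer_intervals:
            assert genome.nonpar[0] <= s < e <= genome.nonpar[1]
        from xrer.intervals import merge_intervals

        assert merge_intervals(rs.rer_intervals) == rs.rer_intervals

    def test_gene_partition_exhaustive(self, rer_scenario, genome):
        rs, _ = call_rers(rer_scenario["segments"], genome.nonpar)
        rs.assign_genes(genome.genes)
        rer, ner = rs.gene_sets()
        assert len(rer) + len(ner) == len(genome.genes)
        assert not (rer & ner)

    def test_padding_robustness_jaccard(self, rer_scenario, genome):
        """Region sets called at 3.5/4.5/5.5-Mb padding stay similar."""
        sets = []
        for pad in (3_500_000, 4_500_000, 5_500_000):
            rs, _ = call_rers(rer_scenario["segments"], genome.nonpar, padding=pad)
            sets.append(rs.rer_intervals)
        for a in sets:
            for b in sets:
                assert jaccard(a, b) >= 0.6


class TestDensityVsMap:
    def test_identical_curves_give_p_one(self, genome):
        segs = {0: [(10_000_000, 12_000_000)]}
        curve = coverage_curve(segs, genome.nonpar, 1_000_000)
        rm = RecombinationMap(
            curve.bin_edges[:-1], curve.bin_edges[1:], curve.counts.astype(float)
        )
        stat, p, table = density_vs_recomb_map(curve, rm, genome.nonpar)
        assert p == 1.0
        assert table["segregation_density"].sum() == pytest.approx(1.0)

    def test_concentrated_density_vs_uniform_map_gives_small_p(self, genome):
        # all segregation mass in one bin against a flat map: many small
        # negative paired differences against one large positive one, the
        # maximal discordance a signed-rank test can register
        lo, hi = genome.nonpar
        segs = {i: [(lo + 5_000_000, lo + 5_800_000)] for i in range(30)}
        curve = coverage_curve(segs, genome.nonpar, 1_000_000)
        rm = RecombinationMap(np.array([lo], float), np.array([hi], float),
                              np.array([1.0]))
        _, p, _ = density_vs_recomb_map(curve, rm, genome.nonpar)
        assert p < 0.05

    def test_shuffled_curve_p_values_not_overdispersed(self, genome):
        rng = np.random.default_rng(3)
        lo, hi = genome.nonpar
        segs = {
            i: [(int(s), int(s) + 2_000_000)]
            for i, s in enumerate(rng.uniform(lo, hi - 2e6, 40))
        }
        curve = coverage_curve(segs, genome.nonpar, 1_000_000)
        edges = np.arange(lo, hi + 1e6, 1e6)
        edges[-1] = hi
        ps = []
        for _ in range(60):
            rates = rng.permutation(np.maximum(curve.counts, 0) + 0.0)
            rm = RecombinationMap(edges[:-1], edges[1:], rates)
            _, p, _ = density_vs_recomb_map(curve, rm, genome.nonpar)
            ps.append(p)
        # under exchangeability the test should not reject grossly in excess
        assert np.mean(np.array(ps) < 0.05) <= 0.25
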