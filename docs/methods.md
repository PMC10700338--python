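# Methods

## The setting

Males are hemizygous for the X non-PAR, so a rare damaging variant that an
unaffected heterozygous mother carries is fully exposed in a son but
buffered in a daughter. In a simplex family (one affected child, everyone
else unaffected) every maternal het site gives an internal case/control
contrast: the allele was either transmitted to the child or it was not.
The package implements region discovery from segregation, burden and
transmission statistics, a locally calibrated gene-level TDT, and
attributable-fraction estimators — plus a generator that produces cohorts
with exactly the structure these methods assume.

## Synthetic cohort model

**Genome.** A 152.2-Mb non-PAR (2,699,520–154,931,044, GRCh37-like), a 3-Mb
centromere, 808 non-overlapping genes of 15–80 kb; 149 genes fall inside
four 9-Mb implanted risk intervals, 659 outside. The recombination map is
piecewise constant: 1 cM/Mb baseline, 0.02 in the centromere, and seven
4-Mb hotspots at 3 cM/Mb — four coinciding with the risk intervals and three
decoys that do not. Risk regions correlating with hotspots mirrors the
empirical situation this style of screen faces; the equally sized decoys
exist precisely so that region recovery cannot be explained by map structure
alone. Total map length ≈ 1.9–2.0 Morgans, matching the female X map.

**Mothers and meiosis.** Each mother receives Poisson numbers of rare het
variants per gene and class (defaults per gene per mother: LGD 3×10⁻⁴,
Mis3 1×10⁻³, synonymous 1.3×10⁻³, i.e. ≈2.1 coding variants per mother
chromosome-wide — chosen so that ≈8.5% of unaffected sons carry ≥1 rare
damaging risk-interval variant, the order reported for sibling controls).
Population allele frequencies are log-uniform on [10⁻⁵, 5×10⁻³] so the
0.1% filter bites on both sides. Each child's maternal X is a crossover
mosaic: crossover count ~ Poisson(map length in Morgans), positions sampled
proportional to local cM/Mb.

**Liability and ascertainment.** A damaging variant in a risk-eligible gene
carries risk with probability *f* (default 0.2). A son's affection
probability is min(1, baseline · r^k) with k his carried risk-variant count
(baseline 0.02, relative risk r = 5 by default); daughters use a small flat
baseline (0.005) — the female-protective regime, with heterozygous
transmission kept only as a pass-through. Families are rejection-sampled
until the quota of simplex families (exactly one affected male child, all
other children unaffected) is met, with an attempt cap of 1000× the quota.
No generative process is published for cohort-level odds ratios in the
1.3–2.6 range; the multiplicative liability is our choice, as the simplest
mechanism producing odds-ratio-like enrichment with carrier mothers.

**Undercalling.** Each maternal het site is dropped with probability
1 − d_m (default d_m = 0.95); each truly transmitted child call is *missed*
with probability 1 − d (default d = 0.8). A missed alternate call yields no
usable genotype — it fails the downstream hard filters — so the record is
absent rather than flipped to untransmitted. Under the Mendelian null the
observed transmitted fraction is therefore 0.5d/(0.5d + 0.5) = d/(1+d)
(0.4444 at d = 0.8). This is the bias the modified TDT corrects.

**What the generator does not emulate.** No read-level error model (DP/AD/GQ
are drawn from simple parametric distributions only so filters have
something to act on), no linkage disequilibrium between SNPs beyond the
haplotype mosaic, no population structure or batch effects, no de novo
variants, and no female-specific risk. Passing tests therefore demonstrate
the statistical machinery under the stated model, not robustness to every
artifact of real callsets.

All randomness flows through `numpy` Generators sub-seeded from
`SimParams.seed` with fixed labels (cohort, detection-noise, snp-matrix,
vcf-quality), so identical parameters give byte-identical outputs.

## Region discovery

Sons' haplotype origins are inferred from maternal-het SNPs: each SNP
partitions the sibship by inherited allele, and adjacent SNPs are linked by
parsimony (the phase orientation flipping the fewest children), which is
correct unless half or more of the sibship recombines inside one SNP gap.
Breakpoints are placed at midpoints between discordant adjacent SNPs. The
practical consequence: with the default 1 informative SNP/Mb, two siblings
recombining inside the same (hotspot) gap occasionally swallow a breakpoint;
at 2 SNPs/Mb recovery exceeds 95% of true crossovers within one spacing.

Informative families are those where the proband's chromosome-level
(length-weighted majority) origin matches ≥1 unaffected brother's;
proband-unique segments are the maximal intervals where the proband's local
origin differs from *every* unaffected brother's.

Peak calling uses the per-bin count of families with an *informative
recombination event* — a proband-unique-segment boundary that is an observed
crossover — in 1-Mb bins. Segment *coverage* was evaluated first and
rejected: unique segments span tens of Mb, telomere-running segments (which
no recombination delimits) inflate the chromosome ends, and peaks
mislocalize. The event statistic is also the one whose chromosome-wide curve
tracks the recombination map, as observed for this family design. Peaks are
maximal runs of bins with count ≥ max(2, 90th percentile of nonzero bins);
each peak's count-weighted midpoint is extended ±4.5 Mb (the extension
anchor is a choice; the source design is silent on point versus edge),
overlaps merged, clipped to the non-PAR. A gene is RER iff it overlaps a
called region. The segregation-vs-map density comparison uses 1-Mb bins,
both curves normalized to sum 1, and a Wilcoxon signed-rank test on paired
per-bin differences (the signed-rank reading is followed where the source
is internally inconsistent about signed-rank vs rank-sum). Two
delta-function curves are *not* distinguishable by this test (only two
nonzero paired differences); the maximal registrable discordance is
concentrated-versus-flat, which the tests exercise.

## Statistics

* **Exact 2×2 tests** report the conditional-MLE odds ratio with the exact
  (noncentral hypergeometric) 95% CI and a one-sided upper-tail p inclusive
  of the observed table — the `fisher.test` convention, which is why a
  sample OR of 1.50 prints as 1.49.
* **Poisson rate test**: conditional on the total count, the case count is
  binomial; p and CI are exact binomial mapped to the rate-ratio scale.
* **Poisson regression** uses a log link with the synonymous count entering
  as log-offset; samples with zero synonymous counts get offset log(0.5).
  (A raw-count offset in a log-link model would be unconventional; the
  log-transform is our documented reading.) Phenotype groups under 100
  samples are dropped and reported.
* **Breslow–Day homogeneity** is computed directly (expected cell counts
  under the Mantel–Haenszel common OR solve a quadratic; the common-OR = 1
  branch is linear — the degenerate case some library implementations return
  NaN for) and cross-checked against statsmodels on non-degenerate strata.
* **Modified TDT**: 3-Mb windows tiled from the non-PAR start (final partial
  window retained); a window's null is the control transmitted fraction of
  damaging variants, usable only with ≥10 distinct rare maternal het sites
  (all classes — the class scope of that rule is ambiguous in the source;
  we count all), a nonzero damaging total, and a nonzero transmitted count
  (a zero null would make any case transmission trivially significant).
  Genes overlapping two windows take the higher null (conservative for an
  upper-tail test); genes with only unusable windows are excluded (a pooled
  chromosome-wide fallback exists behind a flag). Bonferroni and BH-FDR are
  computed at explicit universe sizes m ∈ {149, 808, 19251}; BH uses the
  step-up rule with rank multipliers m/rank.
* **Attributable fractions**: carrier-percentage difference with a
  per-group percentile bootstrap (10,000 replicates), lower bound floored at
  0; variants-carrying-risk is fixed to the relative rate excess
  100·(mean_case − mean_ctrl)/mean_case with the Welch mean-difference CI
  propagated — the estimator behind the published column is not fully
  specified, so this is a documented choice.

## Calibration and power checks (problem sizes used)

* Null TDT calibration: 3,000 quartet families of male children, f = 0,
  d = 0.8, with elevated variant rates (0.015 damaging and synonymous per
  gene per mother) so each gene carries ≈40 informative transmissions —
  enough that the discrete exact test has attainable rejection levels near
  0.05 and calibration is measurable. At realistic per-gene counts (2–5)
  the exact test is so discrete that almost no gene can reject at 0.05 and
  a rejection-rate comparison would be vacuous.
* Region recovery: 150 quintet all-male families (≈90 informative), four
  fully penetrant risk loci (one high-rate gene near each risk-interval
  center, baseline 0.01, r = 200 so penetrance saturates at 1) — the
  monogenic-like regime the segregation screen is designed for.
* Power: 50 replicates of 10,000 ascertained families (85% trios / 15%
  quartets), one implanted risk gene at 3× the default mutation rate with
  r = 20 at baseline 0.03.

## Known limitations

* Origin inference assumes male sibships; daughters are excluded from the
  segregation screen (their diploid genotypes are less informative and the
  screen's premise is male-specific risk).
* The parsimony phasing has no recombination-map prior; co-localized sibling
  crossovers within one SNP gap can be mis-phased (quantified above).
* Region recovery is entangled with recombination density by construction —
  exactly as in the real design; the decoy hotspots in the default map let
  the tests verify the selection signal exceeds the map signal, but with
  ~90 informative families decoy hotspots are sometimes also called
  (precision is not the tested claim; truth-region recall is).
* The Breslow–Day statistic is computed without the Tarone correction.
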