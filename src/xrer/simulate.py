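"""Simplex-family cohort simulator for X-linked maternally inherited variants.

The generator emulates the statistical structure the downstream analyses
assume:

* unaffected carrier mothers accumulate rare heterozygous variants on the
  non-PAR (Poisson per gene and class: LGD, Mis3, synonymous);
* sons inherit one maternal haplotype, a mosaic produced by map-driven
  crossovers (count ~ Poisson(map length in Morgans), positions proportional
  to local cM/Mb);
* damaging variants inside designated risk intervals may be flagged as
  risk-carrying; each carried risk variant multiplies a son's affection
  probability by a relative risk r (females follow a small baseline and are
  insensitive to hemizygous risk - the female-protective regime);
* families are ascertained as simplex: exactly one affected male child,
  all other children unaffected;
* genotype-detection noise removes maternal sites entirely (probability
  1 - d_m) and relabels truly transmitted child calls as untransmitted
  (probability 1 - d), which drives the observed null transmission fraction
  to d/(1+d) < 1/2.

All randomness flows through one seeded generator; child streams are derived
by documented sub-seeding (spawn keys named in ``_subrng``).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeModel, RecombinationMap, simulate_genome

VARIANT_CLASSES = ("LGD", "Mis3", "synonymous")
DAMAGING_CLASSES = ("LGD", "Mis3")

# padded crossover storage; P(Poisson(2) > 16) ~ 1e-12
_MAXB = 16

#: children implied by each family structure (parents + children)
_STRUCTURE_CHILDREN = {"trio": 1, "quartet": 2, "quintet": 3}


@dataclass
class SimParams:
    """Study conditions for a synthetic cohort.

    Defaults are calibrated to the cohorts the analyses target: ~8.5% of
    unaffected male siblings carry >=1 rare damaging variant inside the risk
    intervals, mothers carry ~2 rare coding non-PAR variants in total, ~20%
    of damaging risk-interval variants carry risk, and detection of a
    transmitted hemizygous call succeeds 80% of the time (observed null
    transmission 4/9).
    """

    n_families: int = 500
    family_structure: dict = field(
        default_factory=lambda: {"trio": 0.25, "quartet": 0.65, "quintet": 0.10}
    )
    variant_rates: dict = field(
        default_factory=lambda: {"LGD": 3.0e-4, "Mis3": 1.0e-3, "synonymous": 1.3e-3}
    )
    risk_fraction: float = 0.2
    relative_risk: float = 5.0
    baseline_affection: float = 0.02
    female_affection: float = 0.005
    detection_rate: float = 0.8
    maternal_detection: float = 0.95
    maf_range: tuple = (1e-5, 5e-3)
    male_child_fraction: float = 0.5
    risk_gene_ids: tuple | None = None  # restrict risk flags to these genes (f applies there)
    gene_rate_multipliers: dict | None = None  # gene_id -> multiplier on all class rates
    seed: int = 0
    max_attempt_factor: int = 1000

    def __post_init__(self):
        for name in ("risk_fraction", "baseline_affection", "female_affection",
                     "detection_rate", "maternal_detection", "male_child_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.relative_risk < 1.0:
            raise ConfigurationError("relative_risk must be >= 1")
        if any(r < 0 for r in self.variant_rates.values()):
            raise ConfigurationError("variant rates must be >= 0")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth retained for every emitted artifact."""

    risk_intervals: list
    n_attempted: int
    n_accepted: int


def _subrng(seed: int, label: str) -> np.random.Generator:
    # stable across processes (Python's hash() is salted)
    return np.random.default_rng([seed, zlib.crc32(label.encode()) % (2**31)])


def simulate_meiosis(recomb_map: RecombinationMap, seed=None, rng=None):
    """Draw one maternal meiosis: (starting origin in {0, 1}, crossover positions).

    Crossover count ~ Poisson(total map length in Morgans); positions are
    sampled proportional to local cM/Mb and returned sorted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = recomb_map.total_morgans
    if total == 0:
        warnings.warn("recombination map has zero genetic length: no crossovers")
        return int(rng.integers(0, 2)), np.empty(0)
    n = int(rng.poisson(total))
    pos = np.sort(recomb_map.sample_positions(n, rng))
    return int(rng.integers(0, 2)), pos


def _meiosis_batch(n: int, rmap: RecombinationMap, rng: np.random.Generator):
    """n meioses as (start origins, padded sorted breakpoint matrix)."""
    total = rmap.total_morgans
    start = rng.integers(0, 2, n)
    bp = np.full((n, _MAXB), np.inf)
    if total > 0:
        counts = np.minimum(rng.poisson(total, n), _MAXB)
        u = rng.uniform(0.0, total, size=(n, _MAXB))
        pos = rmap.positions_at(u.ravel()).reshape(n, _MAXB)
        mask = np.arange(_MAXB)[None, :] < counts[:, None]
        bp[mask] = pos[mask]
        bp.sort(axis=1)
    return start, bp


def _origin_at(start, bp_rows, positions):
    """Haplotype origin (0/1) of each (child-row, position) pair."""
    cnt = (bp_rows < positions[:, None]).sum(axis=1)
    return start ^ (cnt & 1)


def apply_detection_noise(variants: pd.DataFrame, transmissions: pd.DataFrame,
                          d: float, d_m: float, seed=None, rng=None):
    """Degrade perfect calls with the undercalling model.

    Each maternal het site is dropped entirely with probability ``1 - d_m``.
    Each truly transmitted child call is missed with probability ``1 - d``: a
    missed alternate call yields no usable genotype (it fails downstream
    quality filters), so the record vanishes rather than flipping to
    untransmitted. Truly untransmitted calls are always clean reference
    calls. Hence the observed transmitted fraction under the Mendelian null
    is 0.5 d / (0.5 d + 0.5) = d / (1 + d) < 1/2.
    """
    if not (0 < d <= 1) or not (0 <= d_m <= 1):
        raise ConfigurationError("detection rates must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    variants = variants.copy()
    transmissions = transmissions.copy()
    variants["site_observed"] = rng.uniform(size=len(variants)) < d_m
    detected = rng.uniform(size=len(transmissions)) < d
    truth = transmissions["transmitted"].to_numpy()
    transmissions["call_observed"] = ~truth | detected
    transmissions["observed_transmitted"] = truth & detected
    return variants, transmissions


@dataclass
class Cohort:
    """In-memory simplex-family cohort plus ground truth."""

    genome: GenomeModel
    params: SimParams
    samples: pd.DataFrame        # family, sample_id, role, sex, affected
    variants: pd.DataFrame       # family, variant_id, gene_id, vclass, pos, hap, risk, af, site_observed
    transmissions: pd.DataFrame  # variant_id, family, sample_id, transmitted, observed_transmitted
    child_start: np.ndarray      # per-child meiosis state, row-aligned with child_index
    child_bp: np.ndarray
    child_index: pd.Index        # sample_id of each track row
    truth: TruthRecord

    @property
    def n_families(self) -> int:
        return int(self.samples["family"].nunique())

    def child_origin_at(self, sample_id: str, positions: np.ndarray) -> np.ndarray:
        row = self.child_index.get_loc(sample_id)
        return _origin_at(self.child_start[row], self.child_bp[row][None, :].repeat(len(positions), 0), np.asarray(positions, float))

    def variant_records(self, observed: bool = True, male_children_only: bool = True) -> pd.DataFrame:
        """Analysis-ready long table: one row per (maternal site, child).

        ``observed=True`` applies the detection-noise view (dropped maternal
        sites removed, transmission labels as called); ``observed=False``
        exposes the ground truth.
        """
        v = self.variants
        if observed:
            v = v[v["site_observed"]]
        t = self.transmissions.merge(
            v[["variant_id", "gene_id", "vclass", "pos", "af", "risk"]],
            on="variant_id", how="inner",
        )
        kids = self.samples[self.samples["role"].isin(["proband", "sibling"])]
        t = t.merge(kids[["sample_id", "sex", "affected", "role"]], on="sample_id", how="left")
        if male_children_only:
            t = t[t["sex"] == "M"]
        if observed:
            t = t[t["call_observed"]]  # missed transmitted calls yield no record
        col = "observed_transmitted" if observed else "transmitted"
        out = pd.DataFrame(
            {
                "chrom": "X",
                "pos": t["pos"].astype(int) + 1,  # 1-based at the record boundary
                "ref": "A",
                "alt": "G",
                "gene_id": t["gene_id"],
                "vclass": t["vclass"],
                "cohort_af": t["af"],
                "panel_af": t["af"],
                "family": t["family"],
                "variant_id": t["variant_id"],
                "sample_id": t["sample_id"],
                "group": np.where(t["affected"], "case", "control"),
                "risk": t["risk"],
                "transmission": np.where(t[col], "transmitted", "untransmitted"),
            }
        )
        return out.reset_index(drop=True)

    def snp_matrix(self, spacing: int = 1_000_000):
        """Dense biallelic SNP genotypes for haplotype-origin inference.

        One informative SNP per ``spacing`` bp: the mother is heterozygous at
        every site (genotype coded 1); each male child carries the allele of
        the maternal haplotype he inherited locally (0/1). The maternal phase
        is internal to the generator and not exported.
        """
        lo, hi = self.genome.nonpar
        positions = np.arange(lo + spacing // 2, hi, spacing)
        rng = _subrng(self.params.seed, "snp-matrix")
        fams = self.samples.loc[self.samples["role"] == "mother", "family"].to_numpy()
        m1 = {f: rng.integers(0, 2, len(positions)) for f in fams}
        kids = self.samples[(self.samples["role"].isin(["proband", "sibling"])) & (self.samples["sex"] == "M")]
        rows, idx = [], []
        fam_of = kids.set_index("sample_id")["family"]
        for sid in kids["sample_id"]:
            r = self.child_index.get_loc(sid)
            origin = _origin_at(self.child_start[r], np.broadcast_to(self.child_bp[r], (len(positions), _MAXB)), positions.astype(float))
            rows.append(m1[fam_of[sid]] ^ origin)
            idx.append(sid)
        for f in fams:
            rows.append(np.ones(len(positions), dtype=int))  # mothers: het at every site
            idx.append(f"F{f:05d}_M")
        gt = pd.DataFrame(np.vstack(rows), index=pd.Index(idx, name="sample_id"), columns=positions)
        return positions, gt


def _gene_rate_matrix(genome: GenomeModel, params: SimParams) -> np.ndarray:
    G = len(genome.genes)
    R = np.zeros((G, len(VARIANT_CLASSES)))
    for j, c in enumerate(VARIANT_CLASSES):
        R[:, j] = params.variant_rates.get(c, 0.0)
    if params.gene_rate_multipliers:
        mult = genome.genes["gene_id"].map(params.gene_rate_multipliers).fillna(1.0).to_numpy()
        R *= mult[:, None]
    return R


def _risk_prob_per_gene(genome: GenomeModel, params: SimParams) -> np.ndarray:
    g = genome.genes
    if params.risk_gene_ids is not None:
        eligible = g["gene_id"].isin(params.risk_gene_ids).to_numpy()
    else:
        eligible = (g["region_class"] == "RER").to_numpy()
    return np.where(eligible, params.risk_fraction, 0.0)


def simulate_cohort(params: SimParams, genome: GenomeModel | None = None) -> Cohort:
    """Rejection-sample simplex families until the quota is met.

    Raises
    ------
    ConfigurationError
        If fewer than ``n_families`` families are accepted within
        ``max_attempt_factor * n_families`` attempts.
    """
    if genome is None:
        genome = simulate_genome(seed=params.seed)
    rng = _subrng(params.seed, "cohort")
    R = _gene_rate_matrix(genome, params)
    lam = R.sum()
    pflat = (R / lam).ravel() if lam > 0 else None
    riskp = _risk_prob_per_gene(genome, params)
    gstart = genome.genes["start"].to_numpy(float)
    gend = genome.genes["end"].to_numpy(float)
    gid = genome.genes["gene_id"].to_numpy()
    nC = len(VARIANT_CLASSES)

    structures = list(params.family_structure)
    sprobs = np.array([params.family_structure[s] for s in structures], float)
    sprobs = sprobs / sprobs.sum()
    skids = np.array([_STRUCTURE_CHILDREN[s] for s in structures])

    quota = params.n_families
    cap = params.max_attempt_factor * quota
    batch = int(min(max(5000, 8 * quota), 200_000))
    attempted = accepted = 0
    acc: dict[str, list] = {k: [] for k in
                            ("fam_kid_sex", "fam_kid_aff", "fam_kid_start", "fam_kid_bp", "fam_kid_fam", "fam_kid_ord",
                             "var_fam", "var_gene", "var_cls", "var_pos", "var_hap", "var_risk", "var_af",
                             "pair_var", "pair_kid")}
    fam_offset = 0
    var_offset = 0

    while accepted < quota and attempted < cap:
        m = min(batch, cap - attempted)
        attempted += m
        nkids_f = skids[rng.choice(len(structures), size=m, p=sprobs)]
        ntot = int(nkids_f.sum())
        kid_fam = np.repeat(np.arange(m), nkids_f)
        kid_ord = np.arange(ntot) - np.repeat(np.concatenate([[0], np.cumsum(nkids_f)[:-1]]), nkids_f)
        kid_male = rng.uniform(size=ntot) < params.male_child_fraction
        kid_start, kid_bp = _meiosis_batch(ntot, genome.recomb_map, rng)

        if lam > 0:
            K = rng.poisson(lam, m)
        else:
            K = np.zeros(m, dtype=int)
        nvar = int(K.sum())
        var_fam = np.repeat(np.arange(m), K)
        if nvar:
            flat = rng.choice(len(pflat), size=nvar, p=pflat)
            vg = flat // nC
            vc = flat % nC
            vpos = rng.uniform(gstart[vg], gend[vg])
            vhap = rng.integers(0, 2, nvar)
            vdam = vc < 2
            vrisk = vdam & (rng.uniform(size=nvar) < riskp[vg])
            vaf = np.exp(rng.uniform(np.log(params.maf_range[0]), np.log(params.maf_range[1]), nvar))
        else:
            vg = vc = vhap = np.empty(0, int)
            vpos = vaf = np.empty(0)
            vrisk = np.empty(0, bool)

        # cross-join variants x children of the same family
        child_start_of_fam = np.concatenate([[0], np.cumsum(nkids_f)])[:-1]
        reps = nkids_f[var_fam]
        pair_var = np.repeat(np.arange(nvar), reps)
        tot_pairs = int(reps.sum())
        within = np.arange(tot_pairs) - np.repeat(np.concatenate([[0], np.cumsum(reps)[:-1]]), reps)
        pair_kid = child_start_of_fam[var_fam[pair_var]] + within
        carried = _origin_at(kid_start[pair_kid], kid_bp[pair_kid], vpos[pair_var]) == vhap[pair_var]

        risk_count = np.bincount(pair_kid, weights=(carried & vrisk[pair_var]).astype(float), minlength=ntot)
        p_aff = np.where(
            kid_male,
            np.minimum(1.0, params.baseline_affection * params.relative_risk ** risk_count),
            params.female_affection,
        )
        kid_aff = rng.uniform(size=ntot) < p_aff
        aff_male = np.bincount(kid_fam, weights=(kid_aff & kid_male).astype(float), minlength=m)
        aff_all = np.bincount(kid_fam, weights=kid_aff.astype(float), minlength=m)
        accept = (aff_male == 1) & (aff_all == 1)
        take = np.flatnonzero(accept)
        if accepted + len(take) > quota:
            take = take[: quota - accepted]
        if len(take) == 0:
            continue
        sel = np.zeros(m, dtype=bool)
        sel[take] = True
        new_fam = np.full(m, -1)
        new_fam[take] = fam_offset + np.arange(len(take))

        kmask = sel[kid_fam]
        acc["fam_kid_fam"].append(new_fam[kid_fam[kmask]])
        acc["fam_kid_ord"].append(kid_ord[kmask])
        acc["fam_kid_sex"].append(kid_male[kmask])
        acc["fam_kid_aff"].append(kid_aff[kmask])
        acc["fam_kid_start"].append(kid_start[kmask])
        acc["fam_kid_bp"].append(kid_bp[kmask])

        vmask = sel[var_fam]
        new_var = np.full(nvar, -1)
        new_var[vmask] = var_offset + np.arange(int(vmask.sum()))
        acc["var_fam"].append(new_fam[var_fam[vmask]])
        acc["var_gene"].append(vg[vmask])
        acc["var_cls"].append(vc[vmask])
        acc["var_pos"].append(vpos[vmask])
        acc["var_hap"].append(vhap[vmask])
        acc["var_risk"].append(vrisk[vmask])
        acc["var_af"].append(vaf[vmask])

        pmask = vmask[pair_var]
        acc["pair_var"].append(new_var[pair_var[pmask]])
        pk = pair_kid[pmask]
        acc["pair_kid"].append(np.column_stack([new_fam[kid_fam[pk]], kid_ord[pk], carried[pmask]]))

        var_offset += int(vmask.sum())
        fam_offset += len(take)
        accepted += len(take)

    if accepted < quota:
        raise ConfigurationError(
            f"ascertainment yielded {accepted}/{quota} families within the "
            f"attempt cap ({cap} = {params.max_attempt_factor} x quota); "
            "raise max_attempt_factor or baseline_affection"
        )

    kid_fam = np.concatenate(acc["fam_kid_fam"]).astype(int)
    kid_ord = np.concatenate(acc["fam_kid_ord"]).astype(int)
    kid_male = np.concatenate(acc["fam_kid_sex"])
    kid_aff = np.concatenate(acc["fam_kid_aff"])
    child_start = np.concatenate(acc["fam_kid_start"]).astype(int)
    child_bp = np.vstack(acc["fam_kid_bp"])
    kid_sid = np.array([f"F{f:05d}_C{o}" for f, o in zip(kid_fam, kid_ord)])

    fams = np.arange(accepted)
    parents = pd.DataFrame(
        {
            "family": np.repeat(fams, 2),
            "sample_id": np.array([[f"F{f:05d}_M", f"F{f:05d}_F"] for f in fams]).ravel(),
            "role": ["mother", "father"] * accepted,
            "sex": ["F", "M"] * accepted,
            "affected": False,
        }
    )
    children = pd.DataFrame(
        {
            "family": kid_fam,
            "sample_id": kid_sid,
            "role": np.where(kid_aff, "proband", "sibling"),
            "sex": np.where(kid_male, "M", "F"),
            "affected": kid_aff,
        }
    )
    samples = pd.concat([parents, children], ignore_index=True).sort_values(
        ["family", "role"], kind="stable"
    ).reset_index(drop=True)

    var_fam = np.concatenate(acc["var_fam"]).astype(int) if var_offset else np.empty(0, int)
    variants = pd.DataFrame(
        {
            "variant_id": np.arange(var_offset),
            "family": var_fam,
            "gene_id": gid[np.concatenate(acc["var_gene"]).astype(int)] if var_offset else [],
            "vclass": np.array(VARIANT_CLASSES)[np.concatenate(acc["var_cls"]).astype(int)] if var_offset else [],
            "pos": np.concatenate(acc["var_pos"]) if var_offset else [],
            "hap": np.concatenate(acc["var_hap"]).astype(int) if var_offset else [],
            "risk": np.concatenate(acc["var_risk"]) if var_offset else [],
            "af": np.concatenate(acc["var_af"]) if var_offset else [],
        }
    )
    pair_var = np.concatenate(acc["pair_var"]).astype(int) if var_offset else np.empty(0, int)
    pk = np.vstack(acc["pair_kid"]) if var_offset else np.empty((0, 3))
    transmissions = pd.DataFrame(
        {
            "variant_id": pair_var,
            "family": pk[:, 0].astype(int),
            "sample_id": [f"F{int(f):05d}_C{int(o)}" for f, o in pk[:, :2]],
            "transmitted": pk[:, 2].astype(bool),
        }
    )
    noise_rng = _subrng(params.seed, "detection-noise")
    variants, transmissions = apply_detection_noise(
        variants, transmissions, params.detection_rate, params.maternal_detection, rng=noise_rng
    )
    truth = TruthRecord(list(genome.risk_intervals), attempted, accepted)
    order = np.lexsort((kid_ord, kid_fam))
    return Cohort(
        genome=genome,
        params=params,
        samples=samples,
        variants=variants,
        transmissions=transmissions,
        child_start=child_start[order],
        child_bp=child_bp[order],
        child_index=pd.Index(kid_sid[order]),
        truth=truth,
    )


def null_transmission_fraction(records: pd.DataFrame) -> float:
    """Observed transmitted fraction among emitted maternal-het records."""
    if len(records) == 0:
        return float("nan")
    return float((records["transmission"] == "transmitted").mean())
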