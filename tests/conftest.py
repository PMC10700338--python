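"""Shared synthetic scenarios.

Session-scoped fixtures build the expensive cohorts once; tests that probe
different aspects of the same study condition share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from xrer import SimParams, simulate_cohort, simulate_genome
from xrer.origins import (
    infer_family_origins,
    proband_unique_segments,
    select_informative_families,
)


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(seed=1)


@pytest.fixture(scope="session")
def small_cohort(genome):
    """Default study conditions at modest size."""
    return simulate_cohort(SimParams(n_families=400, seed=3), genome)


@pytest.fixture(scope="session")
def null_cohort(genome):
    """No risk effect, detection rate 0.8: the undercalled Mendelian null.

    Quartet families of male children give every proband a male sibling
    control; variant rates are elevated (~0.015 damaging and synonymous per
    gene per mother) so per-gene and per-window counts are informative at
    this cohort size.
    """
    params = SimParams(
        n_families=3000,
        seed=11,
        family_structure={"quartet": 1.0},
        male_child_fraction=1.0,
        baseline_affection=0.02,
        risk_fraction=0.0,
        detection_rate=0.8,
        variant_rates={"LGD": 0.003, "Mis3": 0.012, "synonymous": 0.015},
    )
    return simulate_cohort(params, genome)


def _risk_gene_ids(genome, centers):
    rer = genome.genes[genome.genes["region_class"] == "RER"]
    return tuple(
        rer.iloc[(rer["start"] - c).abs().argmin()]["gene_id"] for c in centers
    )


def run_rer_pipeline(cohort, genome, snp_spacing=500_000):
    """Origin inference -> informative selection -> proband-unique segments."""
    positions, gt = cohort.snp_matrix(snp_spacing)
    kids = cohort.samples[cohort.samples["role"].isin(["proband", "sibling"])]
    tracks, proband_of, sibs_of = {}, {}, {}
    for fam, grp in kids.groupby("family"):
        males = grp[grp["sex"] == "M"]
        if (males["role"] == "sibling").sum() < 2 or (males["role"] == "proband").sum() != 1:
            continue
        ids = males["sample_id"].tolist()
        tracks[fam] = infer_family_origins(positions, gt.loc[ids], None,
                                           genome.centromere, genome.nonpar)
        proband_of[fam] = males.loc[males["role"] == "proband", "sample_id"].iloc[0]
        sibs_of[fam] = males.loc[males["role"] == "sibling", "sample_id"].tolist()
    kept, summary = select_informative_families(tracks, proband_of, sibs_of)
    segments = {
        f: proband_unique_segments(tracks[f][proband_of[f]],
                                   [tracks[f][s] for s in sibs_of[f]])
        for f in kept
    }
    return segments, summary


@pytest.fixture(scope="session")
def rer_scenario(genome):
    """Quintet cohort with four strongly penetrant risk loci, one per region.

    Emulates the monogenic-like regime the segregation screen targets:
    risk variants fully penetrant in males (baseline x relative risk >= 1),
    concentrated in one high-rate gene near each implanted region's center.
    """
    risk_genes = _risk_gene_ids(genome, [19.5e6, 44.5e6, 99.5e6, 134.5e6])
    params = SimParams(
        n_families=150,
        seed=7,
        family_structure={"quintet": 1.0},
        male_child_fraction=1.0,
        baseline_affection=0.01,
        relative_risk=200.0,
        risk_fraction=1.0,
        risk_gene_ids=risk_genes,
        gene_rate_multipliers={g: 38.0 for g in risk_genes},
    )
    cohort = simulate_cohort(params, genome)
    segments, summary = run_rer_pipeline(cohort, genome)
    return {"cohort": cohort, "segments": segments, "summary": summary,
            "risk_genes": risk_genes}
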