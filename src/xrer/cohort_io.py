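"""Readers and writers for the cohort's on-disk formats.

VCF 4.2 with FORMAT GT:DP:AD:GQ (haploid GT for male X calls) via pysam;
6-column PED; TSV SNP genotype matrix (samples x positions); BED (0-based
half-open) truth risk regions; TSV gene map; YAML run-parameters echo.

The DP/AD/GQ quality fields are drawn from simple parametric distributions
at write time (seeded from the cohort), solely so the hard filters have
something to act on; there is no read-level simulation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .simulate import Cohort, _subrng

CHROM = "X"
CHROM_LEN = 155_270_560


def _vcf_header(sample_ids) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={CHROM},length={CHROM_LEN}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    h.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    h.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    h.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">')
    h.add_line('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">')
    h.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel allele frequency">')
    for s in sample_ids:
        h.add_sample(s)
    return h


def _quality_fields(rng, het: bool, depth_mean: int):
    dp = max(int(rng.poisson(depth_mean)), 1)
    if het:
        alt = int(np.clip(rng.binomial(dp, 0.5), 0, dp))
    else:
        alt = dp
    gq = 99 if rng.uniform() < 0.97 else int(rng.integers(10, 99))
    return dp, alt, gq


def write_vcf(cohort: Cohort, path: str | Path) -> Path:
    """One multi-sample VCF per cohort: mothers 0/1, male children haploid 0 or 1.

    Only observed sites/calls are emitted (the detection-noise view): dropped
    maternal sites are absent, and a missed transmitted call appears as a
    reference call, exactly how undercalling manifests in real callsets.
    """
    path = Path(path)
    rng = _subrng(cohort.params.seed, "vcf-quality")
    v = cohort.variants[cohort.variants["site_observed"]].copy()
    v["pos1"] = v["pos"].astype(int) + 1
    v = v.sort_values(["pos1", "variant_id"])
    trans = cohort.transmissions.set_index(["variant_id", "sample_id"])[
        ["observed_transmitted", "call_observed"]]
    kids = cohort.samples[cohort.samples["role"].isin(["proband", "sibling"])]
    kids_by_fam = kids.groupby("family")["sample_id"].apply(list)
    sex_of = cohort.samples.set_index("sample_id")["sex"]
    header = _vcf_header(cohort.samples["sample_id"].tolist())
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in v.itertuples(index=False):
            rec = out.new_record(contig=CHROM, start=int(row.pos1) - 1,
                                 stop=int(row.pos1), alleles=("A", "G"))
            rec.info["GENE"] = row.gene_id
            rec.info["VCLASS"] = row.vclass
            rec.info["AF"] = (float(row.af),)
            mother = f"F{row.family:05d}_M"
            dp, alt, gq = _quality_fields(rng, het=True, depth_mean=35)
            rec.samples[mother]["GT"] = (0, 1)
            rec.samples[mother]["DP"] = dp
            rec.samples[mother]["AD"] = (dp - alt, alt)
            rec.samples[mother]["GQ"] = gq
            for kid in kids_by_fam.get(row.family, []):
                try:
                    tr = trans.loc[(row.variant_id, kid)]
                    carried = bool(tr["observed_transmitted"])
                    observed = bool(tr["call_observed"])
                except KeyError:
                    carried, observed = False, True
                dp, alt, gq = _quality_fields(rng, het=False, depth_mean=30)
                if not observed:
                    # missed transmitted call: no usable genotype at this site
                    rec.samples[kid]["GT"] = (None,) if sex_of[kid] == "M" else (None, None)
                    rec.samples[kid]["DP"] = 0
                    continue
                if sex_of[kid] == "M":
                    rec.samples[kid]["GT"] = (1,) if carried else (0,)
                    rec.samples[kid]["AD"] = (0, alt) if carried else (dp, 0)
                else:
                    rec.samples[kid]["GT"] = (0, 1) if carried else (0, 0)
                    alt_f = int(np.clip(rng.binomial(dp, 0.5), 0, dp)) if carried else 0
                    rec.samples[kid]["AD"] = (dp - alt_f, alt_f)
                rec.samples[kid]["DP"] = dp
                rec.samples[kid]["GQ"] = gq
            out.write(rec)
    return path


def read_vcf_calls(path: str | Path) -> pd.DataFrame:
    """Flatten a VCF into one row per sample-site with GT/DP/AB/GQ fields."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for sid, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(g is None for g in gt):
                    continue
                dp = call.get("DP") or 0
                ad = call.get("AD")
                alt = ad[1] if ad is not None and len(ad) > 1 and ad[1] is not None else 0
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": rec.alts[0] if rec.alts else ".",
                        "GT": "/".join(str(g) for g in gt if g is not None),
                        "DP": int(dp),
                        "AB": (alt / dp) if dp else 0.0,
                        "GQ": int(call.get("GQ") or 0),
                        "gene_id": rec.info.get("GENE"),
                        "vclass": rec.info.get("VCLASS"),
                        "panel_af": float(np.atleast_1d(rec.info.get("AF", 0.0))[0]),
                    }
                )
    return pd.DataFrame(rows)


def write_ped(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for row in cohort.samples.itertuples(index=False):
        fam = f"F{row.family:05d}"
        father = f"{fam}_F" if row.role in ("proband", "sibling") else "0"
        mother = f"{fam}_M" if row.role in ("proband", "sibling") else "0"
        rows.append(
            (fam, row.sample_id, father, mother,
             1 if row.sex == "M" else 2, 2 if row.affected else 1)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


def read_ped(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["family", "sample_id", "father", "mother", "sex", "phenotype"])
    df["sex"] = df["sex"].map({1: "M", 2: "F"})
    df["affected"] = df["phenotype"] == 2
    return df


def write_snp_matrix(cohort: Cohort, path: str | Path, spacing: int = 1_000_000) -> Path:
    _, gt = cohort.snp_matrix(spacing)
    gt.to_csv(path, sep="\t")
    return Path(path)


def read_snp_matrix(path: str | Path):
    gt = pd.read_csv(path, sep="\t", index_col=0)
    gt.columns = gt.columns.astype(int)
    return gt.columns.to_numpy(), gt


def write_bed(intervals, path: str | Path, name: str = "region") -> Path:
    pd.DataFrame(
        [(CHROM, int(s), int(e), f"{name}{i + 1}") for i, (s, e) in enumerate(intervals)]
    ).to_csv(path, sep="\t", header=False, index=False)
    return Path(path)


def read_bed(path: str | Path):
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return list(zip(df["start"].astype(int), df["end"].astype(int)))


def write_gene_map(genes: pd.DataFrame, path: str | Path) -> Path:
    genes.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_records(records: pd.DataFrame, path: str | Path) -> Path:
    records.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Emit the full cohort artifact set into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": write_vcf(cohort, outdir / "cohort.vcf"),
        "ped": write_ped(cohort, outdir / "cohort.ped"),
        "snps": write_snp_matrix(cohort, outdir / "snp_matrix.tsv"),
        "truth_bed": write_bed(cohort.truth.risk_intervals, outdir / "truth_risk_regions.bed"),
        "genes": write_gene_map(cohort.genome.genes, outdir / "gene_map.tsv"),
    }
    params = dataclasses.asdict(cohort.params)
    params["maf_range"] = list(params["maf_range"])
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh)
    paths["params"] = outdir / "params.yaml"
    return paths
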