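"""Genotype I/O and quality-control filtering.

The central container is :class:`GenotypeMatrix`: an individuals x sites
matrix of alternate-allele dosages (0, 1, 2) with ``-1`` marking missing
calls, plus per-site and per-individual metadata tables.  All downstream
statistics operate on this container and treat missing entries as
locus-wise / pairwise-complete observations.

Conventions
-----------
* Positions are 1-based (VCF convention) everywhere.
* Sites are biallelic SNPs; half-calls and non-diploid genotypes are
  read as missing.
* Per-site mean depth is taken from the per-sample FORMAT/DP mean when
  present, otherwise from INFO/DP divided by the number of samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

_META_COLUMNS = ["id", "region", "subregion", "lat", "lon"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with site and individual metadata.

    Attributes
    ----------
    dosages
        ``(n_individuals, n_sites)`` int8 array with values in
        ``{0, 1, 2, MISSING}``.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, qual, mean_depth``.
    individuals
        DataFrame with columns ``id, region, subregion, lat, lon``.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")
        if self.dosages.shape[0] != len(self.individuals):
            raise ValueError("individuals table does not match dosage rows")
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError("sites table does not match dosage columns")
        ids = self.individuals["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id: {dup!r}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"site positions not strictly increasing on {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_ids(self) -> np.ndarray:
        """``chrom:pos`` labels, the site identifier used in all outputs."""
        return (
            self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)
        ).to_numpy()

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def site_missing_frac(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=0)

    def individual_missing_frac(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=1)

    def individual_mean_depth(self) -> np.ndarray:
        """Mean of per-site mean depths over the individual's called sites."""
        called = self.called_mask()
        depth = self.sites["mean_depth"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            num = called @ depth
            den = called.sum(axis=1)
        out = np.full(self.n_individuals, np.nan)
        np.divide(num, den, out=out, where=den > 0)
        return out

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[idx],
            self.sites.reset_index(drop=True),
            self.individuals.iloc[idx].reset_index(drop=True),
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.sites.iloc[idx].reset_index(drop=True),
            self.individuals.reset_index(drop=True),
        )


@dataclass
class SiteFilterConfig:
    """Per-site filter thresholds.

    Defaults follow the low-coverage resequencing protocol: mean depth in
    [5, 12] (maximum twice the mean coverage), quality >= 50, at most 10%
    missing genotypes, biallelic SNPs only.  ``maf_min`` defaults to 0
    (no frequency filter); analyses that need common variants pass 0.05.
    """

    min_mean_depth: float = 5.0
    max_mean_depth: float = 12.0
    min_qual: float = 50.0
    max_missing_frac: float = 0.10
    maf_min: float = 0.0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_mean_depth > self.max_mean_depth:
            raise ValueError("min_mean_depth must be <= max_mean_depth")
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass
class FilterReport:
    """Counts of records removed by each rule during filtering."""

    n_individuals_in: int = 0
    n_individuals_out: int = 0
    n_sites_in: int = 0
    n_sites_out: int = 0
    individual_rules: dict = field(default_factory=dict)
    site_rules: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-delimited individual metadata table."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in ("id", "region") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    for col in _META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    return meta[_META_COLUMNS]


def read_vcf(path: str | Path, metadata: Optional[str | Path | pd.DataFrame] = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles in the GT field.  Half-calls
    and non-diploid genotypes become missing.  Multi-allelic records are
    kept (flagged ``biallelic=False``) so that the biallelic filter can
    count them; their dosages refer to the first alternate allele.

    Parameters
    ----------
    metadata
        Optional path to (or DataFrame of) the tab-delimited individual
        table with columns ``id region subregion lat lon``; joined on id.
        Every metadata id must be present in the VCF.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate individual id in VCF header")

    dosage_rows: list[np.ndarray] = []
    records: list[tuple] = []
    n = len(samples)
    for var in vcf:
        gts = var.genotype.array()  # (n, ploidy+1); last col = phasing
        alleles = gts[:, :-1]
        diploid = alleles.shape[1] == 2
        if diploid:
            called = np.all(alleles >= 0, axis=1)
            dos = np.where(called, alleles.sum(axis=1), MISSING)
            # >1 alt allele index still counts as carrying alt (first alt
            # dosage is what downstream biallelic analyses use)
            dos = np.where(called, np.minimum(dos, 2), dos)
        else:
            dos = np.full(n, MISSING)
        dosage_rows.append(dos.astype(np.int8))

        fmt_dp = None
        try:
            fmt_dp = var.format("DP")
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None:
            dp = np.asarray(fmt_dp, float).ravel()
            dp = dp[np.isfinite(dp) & (dp >= 0)]
            mean_depth = float(dp.mean()) if dp.size else np.nan
        else:
            info_dp = var.INFO.get("DP")
            mean_depth = float(info_dp) / n if info_dp is not None else np.nan

        alt = var.ALT
        biallelic = len(alt) == 1 and len(var.REF) == 1 and all(len(a) == 1 for a in alt)
        records.append(
            (
                var.CHROM,
                var.POS,
                var.REF,
                alt[0] if alt else ".",
                var.QUAL if var.QUAL is not None else np.nan,
                mean_depth,
                biallelic,
            )
        )
    vcf.close()

    sites = pd.DataFrame(
        records,
        columns=["chrom", "pos", "ref", "alt", "qual", "mean_depth", "biallelic"],
    )
    dosages = (
        np.stack(dosage_rows, axis=1) if dosage_rows else np.empty((n, 0), np.int8)
    )

    individuals = pd.DataFrame({"id": samples})
    for col in _META_COLUMNS[1:]:
        individuals[col] = np.nan
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
        absent = set(meta["id"]) - set(samples)
        if absent:
            raise ValueError(f"metadata id not in VCF: {sorted(absent)[0]!r}")
        individuals = individuals[["id"]].merge(meta, on="id", how="left")

    return GenotypeMatrix(dosages, sites, individuals)


def write_vcf(gm: GenotypeMatrix, path: str | Path, depth_matrix: Optional[np.ndarray] = None) -> None:
    """Write a minimal VCF v4.2 with GT (and DP when provided).

    Without an explicit per-sample depth matrix, the site mean depth is
    written as an integer INFO/DP total so that read_vcf recovers it.
    """
    sites = gm.sites
    ids = gm.individuals["id"].tolist()
    n = gm.n_individuals
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth_matrix is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in sites["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            if depth_matrix is None:
                md = row["mean_depth"]
                info = "." if pd.isna(md) else f"DP={int(round(md * n))}"
                fmt = "GT"
                calls = [gt_codes[int(d)] for d in gm.dosages[:, j]]
            else:
                info = "."
                fmt = "GT:DP"
                calls = [
                    f"{gt_codes[int(gm.dosages[i, j])]}:{int(depth_matrix[i, j])}"
                    for i in range(n)
                ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t{info}\t{fmt}\t" + "\t".join(calls) + "\n"
            )


def minor_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency, ``min(p, 1-p)``.

    ``p`` is the alternate-allele frequency over called genotypes; sites
    with no called genotype get NaN.
    """
    called = gm.called_mask()
    dos = np.where(called, gm.dosages, 0).astype(float)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_called)
    p = np.where(n_called > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def filter_dataset(
    gm: GenotypeMatrix,
    cfg: SiteFilterConfig | None = None,
    ind_min_depth: float = 3.0,
    ind_max_missing: float = 0.20,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply individual-level then site-level quality filters.

    Individuals with mean depth below ``ind_min_depth`` (a depth in x,
    not a percentage) or missing fraction above ``ind_max_missing`` are
    removed first; site statistics (missingness, MAF) are then
    recomputed on the survivors before the site rules run.
    """
    if gm.n_sites == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    cfg = cfg or SiteFilterConfig()
    report = FilterReport(
        n_individuals_in=gm.n_individuals, n_sites_in=gm.n_sites
    )

    ind_depth = gm.individual_mean_depth()
    ind_miss = gm.individual_missing_frac()
    # NaN depth (no depth information anywhere) is not held against an
    # individual
    fail_depth = np.where(np.isnan(ind_depth), False, ind_depth < ind_min_depth)
    fail_miss = ind_miss > ind_max_missing
    report.individual_rules = {
        "low_mean_depth": int(fail_depth.sum()),
        "high_missingness": int(fail_miss.sum()),
    }
    keep_ind = ~(fail_depth | fail_miss)
    if not keep_ind.any():
        raise ValueError("all individuals removed by filters")
    gm2 = gm.take_individuals(np.flatnonzero(keep_ind))

    depth = gm2.sites["mean_depth"].to_numpy(float)
    qual = gm2.sites["qual"].to_numpy(float)
    miss = gm2.site_missing_frac()
    maf = minor_allele_freq(gm2)

    with np.errstate(invalid="ignore"):
        fail = {
            "low_depth": np.where(np.isnan(depth), False, depth < cfg.min_mean_depth),
            "high_depth": np.where(np.isnan(depth), False, depth > cfg.max_mean_depth),
            "low_qual": np.where(np.isnan(qual), False, qual < cfg.min_qual),
            "high_missing": miss > cfg.max_missing_frac,
            "low_maf": np.where(np.isnan(maf), True, maf < cfg.maf_min),
        }
    if cfg.maf_min == 0:
        # keep NaN-MAF handling consistent: a site with zero called
        # genotypes always fails missingness anyway
        fail["low_maf"] = np.where(np.isnan(maf), False, maf < cfg.maf_min)
    if cfg.biallelic_only and "biallelic" in gm2.sites.columns:
        fail["not_biallelic"] = ~gm2.sites["biallelic"].to_numpy(bool)

    report.site_rules = {k: int(v.sum()) for k, v in fail.items()}
    keep_site = ~np.logical_or.reduce(list(fail.values()))
    out = gm2.take_sites(np.flatnonzero(keep_site))
    report.n_individuals_out = out.n_individuals
    report.n_sites_out = out.n_sites
    return out, report
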