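"""Synthetic genotype-environment datasets with known truth.

Populations drift from a common ancestral allele-frequency pool under the
Balding-Nichols model: at each locus the frequency of population *i* is
drawn from Beta(p(1-F_i)/F_i, (1-p)(1-F_i)/F_i), so that E[freq] = p and
the expected fixation index of population *i* is F_i.  On top of that the
generator can plant

* partial selfing (heterozygote deficit 2p(1-p)(1-F_IS) with the
  equilibrium F_IS = s/(2-s) for selfing rate s),
* admixed individuals with Dirichlet ancestry proportions,
* pedigree dyads (parent-offspring, full sibs, half sibs) by explicit
  gene dropping from population founders,
* adaptive loci whose individual-level allele frequency follows an
  environmental gradient on the logit scale, and
* missing genotypes and per-site depth/quality metadata.

Every random draw comes from a single integer seed, so the same
configuration reproduces byte-identical output.  The returned
:class:`TruthTable` records drift, ancestry, pedigree kinship and
adaptive-locus assignments for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import MISSING, GenotypeMatrix

PEDIGREE_KINSHIP = {"parent-offspring": 0.25, "full-sib": 0.25, "half-sib": 0.125}


@dataclass
class SimConfig:
    """Generator settings.

    Defaults emulate a fragmented, range-wide tree survey: five regional
    populations of ~54 individuals drifted to F_ST 0.15, partial selfing,
    a block of admixed individuals, pedigree relatives inside sites, and
    a handful of loci tracking a north-south environmental gradient.
    """

    seed: int = 0
    n_pops: int = 5
    n_per_pop: Sequence[int] | int = 54
    fst_per_pop: Sequence[float] | float = 0.15
    n_loci: int = 5000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    selfing_rate: float = 0.0
    n_admixed: int = 0
    dirichlet_alpha: float = 0.5
    pedigree_blocks: Sequence[tuple[str, int]] = ()
    n_env_vars: int = 3
    env_correlation: float = 0.7
    n_adaptive: int = 0
    effect_size: float = 1.0
    missing_rate: float = 0.0
    depth_mean: float = 6.0
    n_chroms: int = 5
    chrom_length_bp: int = 20_000_000

    def pop_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_per_pop):
            return np.full(self.n_pops, int(self.n_per_pop))
        sizes = np.asarray(self.n_per_pop, int)
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes

    def pop_fst(self) -> np.ndarray:
        if np.isscalar(self.fst_per_pop):
            return np.full(self.n_pops, float(self.fst_per_pop))
        f = np.asarray(self.fst_per_pop, float)
        if len(f) != self.n_pops:
            raise ValueError("fst_per_pop length must equal n_pops")
        return f

    def __post_init__(self) -> None:
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive must be <= n_loci")
        if np.any(self.pop_fst() >= 1) or np.any(self.pop_fst() <= 0):
            raise ValueError("fst_per_pop must lie in (0, 1)")
        if not 0 <= self.selfing_rate < 1:
            raise ValueError("selfing_rate must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests."""

    pop_F: dict[str, float]
    Q: pd.DataFrame  # individuals x populations, rows sum to 1
    pedigree_kinship: list[tuple[str, str, float]]
    adaptive: pd.DataFrame  # site_index, site_id, env_var, effect
    env: pd.DataFrame  # individuals x env variables
    fis_expected: float

    def adaptive_site_ids(self) -> set[str]:
        return set(self.adaptive["site_id"])

    def to_json(self, path) -> None:
        import json

        payload = {
            "pop_F": self.pop_F,
            "Q": {i: row.tolist() for i, row in zip(self.Q.index, self.Q.values)},
            "pedigree_kinship": self.pedigree_kinship,
            "adaptive": self.adaptive.to_dict("records"),
            "env": {i: row.tolist() for i, row in zip(self.env.index, self.env.values)},
            "fis_expected": self.fis_expected,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _sample_genotypes(rng, freqs, f_is):
    """Genotypes with heterozygote deficit F_IS at frequencies ``freqs``.

    P(het) = 2p(1-p)(1-F), P(hom alt) = p^2 + p(1-p)F.
    """
    p = np.asarray(freqs, float)
    u = rng.random(p.shape)
    p_hom_alt = p * p + p * (1 - p) * f_is
    p_het = 2 * p * (1 - p) * (1 - f_is)
    return (u < p_hom_alt).astype(np.int8) * 2 + (
        (u >= p_hom_alt) & (u < p_hom_alt + p_het)
    ).astype(np.int8)


def _drop_child(rng, pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """One gamete from each parent's haplotype pair (L x 2 arrays)."""
    L = pa.shape[0]
    ga = pa[np.arange(L), rng.integers(0, 2, L)]
    gb = pb[np.arange(L), rng.integers(0, 2, L)]
    return np.stack([ga, gb], axis=1)


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, TruthTable]:
    """Generate genotypes, an environmental table and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.pop_sizes()
    Fs = cfg.pop_fst()
    L = cfg.n_loci
    pop_names = [f"pop{i + 1}" for i in range(cfg.n_pops)]

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, L)
    # Balding-Nichols drift per population
    pop_freq = np.empty((cfg.n_pops, L))
    for i, F in enumerate(Fs):
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pop_freq[i] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)

    f_is = cfg.selfing_rate / (2 - cfg.selfing_rate)

    ids: list[str] = []
    regions: list[str] = []
    sub: list[str] = []
    rows: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []

    for i, npop in enumerate(sizes):
        g = _sample_genotypes(rng, np.tile(pop_freq[i], (npop, 1)), f_is)
        rows.append(g)
        start = len(ids)
        ids += [f"{pop_names[i]}_{k + 1:03d}" for k in range(npop)]
        regions += [pop_names[i]] * npop
        sub += [f"{pop_names[i]}_siteA"] * npop
        q = np.zeros((npop, cfg.n_pops))
        q[:, i] = 1.0
        q_rows.append(q)

    # admixed individuals: Dirichlet ancestry over all populations
    if cfg.n_admixed:
        qa = rng.dirichlet(np.full(cfg.n_pops, cfg.dirichlet_alpha), cfg.n_admixed)
        freqs = qa @ pop_freq
        rows.append(_sample_genotypes(rng, freqs, f_is))
        ids += [f"adm_{k + 1:03d}" for k in range(cfg.n_admixed)]
        regions += ["admixed"] * cfg.n_admixed
        sub += ["admixed_siteA"] * cfg.n_admixed
        q_rows.append(qa)

    # pedigree dyads by gene dropping from fresh founders, cycling over pops
    ped: list[tuple[str, str, float]] = []
    ped_rows: list[np.ndarray] = []
    block_pop = 0
    for rel, count in cfg.pedigree_blocks:
        if rel not in PEDIGREE_KINSHIP:
            raise ValueError(f"unknown relationship {rel!r}")
        for c in range(count):
            pf = pop_freq[block_pop]
            founder = lambda: np.stack(
                [rng.random(L) < pf, rng.random(L) < pf], axis=1
            ).astype(np.int8)
            if rel == "parent-offspring":
                pa, pb = founder(), founder()
                child = _drop_child(rng, pa, pb)
                pair = [pa.sum(axis=1), child.sum(axis=1)]
            elif rel == "full-sib":
                pa, pb = founder(), founder()
                pair = [
                    _drop_child(rng, pa, pb).sum(axis=1),
                    _drop_child(rng, pa, pb).sum(axis=1),
                ]
            else:  # half-sib: shared parent pa
                pa, pb, pc = founder(), founder(), founder()
                pair = [
                    _drop_child(rng, pa, pb).sum(axis=1),
                    _drop_child(rng, pa, pc).sum(axis=1),
                ]
            name = f"{rel.replace('-', '')}{len(ped) + 1:03d}"
            ida, idb = f"ped_{name}_a", f"ped_{name}_b"
            ped.append((ida, idb, PEDIGREE_KINSHIP[rel]))
            ped_rows.append(np.stack(pair).astype(np.int8))
            ids += [ida, idb]
            regions += [pop_names[block_pop]] * 2
            sub += [f"{pop_names[block_pop]}_siteB"] * 2
            q = np.zeros((2, cfg.n_pops))
            q[:, block_pop] = 1.0
            q_rows.append(q)
            block_pop = (block_pop + 1) % cfg.n_pops
    rows += ped_rows

    dosages = np.concatenate(rows, axis=0)
    Q = np.concatenate(q_rows, axis=0)
    n = dosages.shape[0]

    # environmental gradient: population-level north-south score + local noise
    pop_score = np.linspace(-1.0, 1.0, cfg.n_pops)
    grad = Q @ pop_score + 0.3 * rng.standard_normal(n)
    grad = (grad - grad.mean()) / grad.std()
    c = cfg.env_correlation
    env = np.empty((n, cfg.n_env_vars))
    for v in range(cfg.n_env_vars):
        env[:, v] = c * grad + np.sqrt(max(1 - c * c, 0.0)) * rng.standard_normal(n)
    env_names = [f"env{v + 1}" for v in range(cfg.n_env_vars)]
    env_df = pd.DataFrame(env, columns=env_names)
    env_df.insert(0, "id", ids)

    # adaptive loci: logit-shift individual frequencies along the assigned
    # environmental variable, then redraw genotypes at those loci
    adaptive_records = []
    if cfg.n_adaptive:
        adaptive_idx = rng.choice(L, cfg.n_adaptive, replace=False)
        ind_pop_freq = Q @ pop_freq  # per-individual baseline frequency
        for t, j in enumerate(adaptive_idx):
            v = t % cfg.n_env_vars
            z = env[:, v]
            z = (z - z.mean()) / z.std()
            pj = expit(logit(np.clip(ind_pop_freq[:, j], 1e-6, 1 - 1e-6)) + cfg.effect_size * z)
            dosages[:, j] = rng.binomial(2, pj).astype(np.int8)
            adaptive_records.append((int(j), env_names[v], cfg.effect_size))

    # site coordinates across chromosomes, strictly increasing positions
    chrom_of = np.sort(rng.integers(0, cfg.n_chroms, L))
    pos = np.empty(L, int)
    for ch in range(cfg.n_chroms):
        m = chrom_of == ch
        k = int(m.sum())
        pos[m] = np.sort(rng.choice(cfg.chrom_length_bp, k, replace=False)) + 1
    chroms = np.array([f"chr{ch + 1}" for ch in chrom_of])

    # depth / quality metadata and missingness
    depth = np.clip(rng.normal(cfg.depth_mean, 1.0, L), 0.5, None)
    qual = rng.uniform(60, 900, L)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "qual": qual,
            "mean_depth": depth,
            "biallelic": True,
        }
    )
    lats = 35.0 + 10.0 * (Q @ np.linspace(0.0, 1.0, cfg.n_pops))
    individuals = pd.DataFrame(
        {
            "id": ids,
            "region": regions,
            "subregion": sub,
            "lat": -lats,
            "lon": 174.0 + 0.5 * rng.standard_normal(n),
        }
    )
    gm = GenotypeMatrix(dosages, sites, individuals)

    site_ids = gm.site_ids
    adaptive_df = pd.DataFrame(
        [(j, site_ids[j], v, e) for j, v, e in adaptive_records],
        columns=["site_index", "site_id", "env_var", "effect"],
    )
    truth = TruthTable(
        pop_F=dict(zip(pop_names, Fs)),
        Q=pd.DataFrame(Q, index=ids, columns=pop_names),
        pedigree_kinship=ped,
        adaptive=adaptive_df,
        env=env_df.set_index("id"),
        fis_expected=f_is,
    )
    return gm, env_df, truth


def paperlike_config(seed: int = 0) -> SimConfig:
    """Preset emulating the shape of a national-scale tree survey: five
    regional populations (269 individuals in total with the admixed
    block), drift F_ST 0.15, partial selfing, pedigree dyads within
    sites, and environment-tracking loci.  A shape for integration
    tests, not a claim of equivalence to any real collection."""
    return SimConfig(
        seed=seed,
        n_pops=5,
        n_per_pop=(42, 42, 42, 42, 41),
        fst_per_pop=0.15,
        n_loci=5000,
        selfing_rate=0.2,
        n_admixed=20,
        pedigree_blocks=[("full-sib", 10), ("half-sib", 10)],
        n_env_vars=4,
        env_correlation=0.8,
        n_adaptive=50,
        effect_size=2.0,
        missing_rate=0.008,
    )


def plant_differential_loci(
    gm: GenotypeMatrix,
    pops,
    n_planted: int,
    differential: float = 0.4,
    seed: int = 0,
    base_maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Overwrite ``n_planted`` random loci with a fixed allele-frequency
    differential between the two halves of a 2-population sample.

    Used to evaluate selection-scan power: the planted loci have
    frequency p0 ~ U(base_maf_range) in the first population and
    p0 + differential in the second.  Returns the modified matrix and
    the planted site ids.
    """
    pops = np.asarray(pops)
    labels = np.unique(pops)
    if len(labels) != 2:
        raise ValueError("differential planting needs exactly 2 populations")
    rng = np.random.default_rng(seed)
    dos = gm.dosages.copy()
    idx = rng.choice(gm.n_sites, n_planted, replace=False)
    rows0 = pops == labels[0]
    rows1 = pops == labels[1]
    for j in idx:
        p0 = rng.uniform(*base_maf_range)
        p1 = min(p0 + differential, 0.99)
        dos[rows0, j] = rng.binomial(2, p0, rows0.sum()).astype(np.int8)
        dos[rows1, j] = rng.binomial(2, p1, rows1.sum()).astype(np.int8)
    out = GenotypeMatrix(dos, gm.sites, gm.individuals)
    return out, out.site_ids[np.sort(idx)]


def simulate_linked_chromosome(
    n_individuals: int,
    n_snps: int,
    seed: int = 0,
    chrom: str = "chr1",
    span_bp: int = 500_000,
    decay_bp: float = 50_000.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> GenotypeMatrix:
    """A single chromosome with distance-decaying linkage disequilibrium.

    Haplotypes follow a latent Gaussian AR(1) process along the
    chromosome: adjacent latent values correlate as exp(-d/decay_bp) for
    spacing d, and the allele is the latent value thresholded at the
    site's frequency quantile.  This produces r2 that decays roughly
    exponentially with distance, which is all the pruning and decay
    profiling machinery needs.
    """
    rng = np.random.default_rng(seed)
    from scipy.stats import norm

    pos = np.sort(rng.choice(np.arange(1, span_bp), n_snps, replace=False))
    p = rng.uniform(*maf_range, n_snps)
    thresh = norm.ppf(p)
    n_hap = 2 * n_individuals
    z = np.empty((n_hap, n_snps))
    z[:, 0] = rng.standard_normal(n_hap)
    for j in range(1, n_snps):
        r = np.exp(-(pos[j] - pos[j - 1]) / decay_bp)
        z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r * r) * rng.standard_normal(n_hap)
    hap = (z < thresh).astype(np.int8)
    dosages = hap[0::2] + hap[1::2]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "qual": 100.0,
            "mean_depth": 8.0,
            "biallelic": True,
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"ind_{k + 1:03d}" for k in range(n_individuals)],
            "region": "pop1",
            "subregion": "pop1_siteA",
            "lat": np.nan,
            "lon": np.nan,
        }
    )
    return GenotypeMatrix(dosages, sites, individuals)
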