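"""Diversity and differentiation statistics.

Implements the three classical estimator families for biallelic dosage
data grouped into populations:

* Nei/Nei-Chesser gene diversities (Ho, Hs, Ht with small-sample
  corrections based on the harmonic mean sample size) and the derived
  F_ST = 1 - Hs/Ht and F_IS = 1 - Ho/Hs, aggregated across loci as
  ratios of locus averages;
* Weir & Cockerham (1984) variance components a/b/c with theta and f as
  ratios of sums across loci;
* Weir & Goudet population-specific beta-F_ST from allele-matching
  proportions, referenced to the mean between-population matching, with
  percentile bootstrap confidence intervals over loci.

Also provides pairwise theta matrices, Nei's standard (1972) and
unbiased (1978) genetic distances, and neighbour-joining trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# shared per-locus population summaries


def _pop_counts(gm: GenotypeMatrix, pops: np.ndarray):
    """Per population x locus: sample size n, alt frequency p, observed het.

    Only called genotypes count; loci with no data in a population get
    n = 0 and NaN frequency.
    """
    labels = np.unique(pops)
    dos = gm.dosages
    called = dos != MISSING
    n = np.zeros((len(labels), gm.n_sites))
    p = np.full((len(labels), gm.n_sites), np.nan)
    ho = np.full((len(labels), gm.n_sites), np.nan)
    for i, lab in enumerate(labels):
        rows = pops == lab
        c = called[rows]
        d = np.where(c, dos[rows], 0).astype(float)
        ni = c.sum(axis=0)
        n[i] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(ni > 0, d.sum(axis=0) / (2 * ni), np.nan)
            ho[i] = np.where(ni > 0, (dos[rows] == 1).sum(axis=0) / ni, np.nan)
    return labels, n, p, ho


@dataclass
class PopStats:
    """Nei per-locus and global diversity statistics."""

    labels: np.ndarray
    per_locus: pd.DataFrame  # Ho, Hs, Ht per locus
    Ho: float
    Hs: float
    Ht: float
    Fst: float
    Fis: float


def nei_basic_stats(gm: GenotypeMatrix, pops) -> PopStats:
    """Nei-Chesser corrected Ho/Hs/Ht and the derived F-statistics.

    Per locus, over the r populations with data:

    * Ho = mean observed heterozygosity,
    * Hs = n~/(n~-1) * (mean_i 2 p_i q_i - Ho / (2 n~)),
    * Ht = 2 p~ q~ + Hs/(r n~) - Ho/(2 r n~),

    with n~ the harmonic mean of the per-population sample sizes and
    p~ the unweighted mean frequency.  Global values are locus means;
    Fst = 1 - Hs/Ht and Fis = 1 - Ho/Hs on those means.
    """
    pops = np.asarray(pops)
    labels, n, p, ho = _pop_counts(gm, pops)
    if (n.sum(axis=1) == 0).any():
        bad = labels[n.sum(axis=1) == 0][0]
        raise ValueError(f"population {bad!r} has no called data")

    use = n >= 1
    r = use.sum(axis=0).astype(float)
    ok = r >= 2  # loci informative in at least two populations
    with np.errstate(invalid="ignore", divide="ignore"):
        n_h = r / np.where(use, 1.0 / np.where(n == 0, np.nan, n), np.nan).sum(
            axis=0, where=use
        )
        Ho_l = np.nanmean(np.where(use, ho, np.nan), axis=0)
        het_exp = 2 * p * (1 - p)
        Hs_raw = np.nanmean(np.where(use, het_exp, np.nan), axis=0)
        Hs_l = n_h / (n_h - 1) * (Hs_raw - Ho_l / (2 * n_h))
        p_bar = np.nanmean(np.where(use, p, np.nan), axis=0)
        Ht_raw = 2 * p_bar * (1 - p_bar)
        Ht_l = Ht_raw + Hs_l / (r * n_h) - Ho_l / (2 * r * n_h)

    per_locus = pd.DataFrame(
        {"Ho": Ho_l, "Hs": Hs_l, "Ht": Ht_l, "informative": ok}
    )
    Ho = float(np.nanmean(Ho_l[ok]))
    Hs = float(np.nanmean(Hs_l[ok]))
    Ht = float(np.nanmean(Ht_l[ok]))
    return PopStats(
        labels=labels,
        per_locus=per_locus,
        Ho=Ho,
        Hs=Hs,
        Ht=Ht,
        Fst=1 - Hs / Ht if Ht > 0 else np.nan,
        Fis=1 - Ho / Hs if Hs > 0 else np.nan,
    )


def wc_components(gm: GenotypeMatrix, pops) -> pd.DataFrame:
    """Weir-Cockerham (1984) per-locus variance components a, b, c."""
    pops = np.asarray(pops)
    labels, n, p, ho = _pop_counts(gm, pops)
    use = n >= 1
    r = use.sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - (n * n).sum(axis=0) / n_sum) / (r - 1)
        pbar = np.nansum(np.where(use, n * p, 0), axis=0) / n_sum
        s2 = np.nansum(np.where(use, n * (p - pbar) ** 2, 0), axis=0) / (
            (r - 1) * nbar
        )
        hbar = np.nansum(np.where(use, n * ho, 0), axis=0) / n_sum

        a = (nbar / nc) * (
            s2
            - 1.0
            / (nbar - 1)
            * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    valid = (r >= 2) & (nbar > 1) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return pd.DataFrame({"a": a, "b": b, "c": c, "valid": valid})


def wc_stats(gm: GenotypeMatrix, pops) -> tuple[float, float, pd.DataFrame]:
    """Weir-Cockerham theta and f as ratios of summed components."""
    comp = wc_components(gm, pops)
    v = comp["valid"].to_numpy()
    a = comp.loc[v, "a"].to_numpy()
    b = comp.loc[v, "b"].to_numpy()
    c = comp.loc[v, "c"].to_numpy()
    denom = (a + b + c).sum()
    if not v.any() or denom == 0:
        raise ValueError("theta undefined: no polymorphic locus with data")
    theta = a.sum() / denom
    f = 1.0 - c.sum() / (b + c).sum()
    return float(theta), float(f), comp


@dataclass
class BetaStats:
    """Population-specific beta-F_ST with bootstrap CIs."""

    labels: np.ndarray
    beta: np.ndarray  # per population
    overall: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    overall_ci: tuple[float, float]
    fis: np.ndarray
    n_boot: int


def _matching_per_locus(gm: GenotypeMatrix, pops: np.ndarray):
    """Per-locus within-population matching M_i and between mean M_B.

    Within-population matching is the allele-matching proportion between
    distinct individuals: with allele frequency estimated from 2n allele
    copies, the unbiased pair-matching is
        M_i = (2n (p^2 + q^2) - 1 + Ho/ ... )
    computed here directly from dosage cross-products for exactness.
    """
    labels = np.unique(pops)
    dos = gm.dosages
    called = dos != MISSING
    L = gm.n_sites
    Mw = np.full((len(labels), L), np.nan)
    pmat = np.full((len(labels), L), np.nan)
    for i, lab in enumerate(labels):
        rows = np.flatnonzero(pops == lab)
        c = called[rows]
        x = np.where(c, dos[rows], 0).astype(float)
        y = np.where(c, 2 - dos[rows], 0).astype(float)
        ni = c.sum(axis=0).astype(float)
        sx = x.sum(axis=0)
        sy = y.sum(axis=0)
        # sum over ordered distinct pairs of (x_a x_b + y_a y_b)/4
        num = (sx * sx - (x * x).sum(axis=0)) + (sy * sy - (y * y).sum(axis=0))
        pairs = ni * (ni - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Mw[i] = np.where(pairs > 0, num / (4 * pairs), np.nan)
            pmat[i] = np.where(ni > 0, sx / (2 * ni), np.nan)
    # between-population matching: mean over unordered population pairs of
    # p_i p_j + q_i q_j
    npop = len(labels)
    Mb_sum = np.zeros(L)
    Mb_n = np.zeros(L)
    for i in range(npop):
        for j in range(i + 1, npop):
            m = pmat[i] * pmat[j] + (1 - pmat[i]) * (1 - pmat[j])
            okm = np.isfinite(m)
            Mb_sum[okm] += m[okm]
            Mb_n[okm] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        Mb = np.where(Mb_n > 0, Mb_sum / Mb_n, np.nan)
    return labels, Mw, Mb


def beta_fst(gm: GenotypeMatrix, pops, n_boot: int = 1000, seed: int = 0) -> BetaStats:
    """Weir-Goudet population-specific beta-F_ST.

    beta_i = (M_i - M_B) / (1 - M_B) with M_i the mean (over loci) within-
    population allele matching between distinct individuals and M_B the
    mean between-population matching.  CIs are percentile bootstraps over
    loci (2.5/97.5%).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    pops = np.asarray(pops)
    labels, Mw, Mb = _matching_per_locus(gm, pops)
    ok = np.isfinite(Mb) & np.all(np.isfinite(Mw), axis=0)
    Mw, Mb = Mw[:, ok], Mb[ok]

    def est(idx):
        mi = Mw[:, idx].mean(axis=1)
        mb = Mb[idx].mean()
        return (mi - mb) / (1 - mb)

    L = Mb.size
    beta = est(np.arange(L))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(labels)))
    for b in range(n_boot):
        boots[b] = est(rng.integers(0, L, L))
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    ov = boots.mean(axis=1)

    # per-population F_IS from uncorrected frequencies
    _, n, p, ho = _pop_counts(gm, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = 2 * p * (1 - p)
        fis = 1 - np.nanmean(ho, axis=1) / np.nanmean(hs, axis=1)

    return BetaStats(
        labels=labels,
        beta=beta,
        overall=float(beta.mean()),
        ci_low=ci_low,
        ci_high=ci_high,
        overall_ci=(float(np.percentile(ov, 2.5)), float(np.percentile(ov, 97.5))),
        fis=fis,
        n_boot=n_boot,
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_fst(
    gm: GenotypeMatrix, pops, n_boot: int = 1000, seed: int = 0
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """Pairwise Weir-Cockerham theta with bootstrap CI matrices."""
    pops = np.asarray(pops)
    labels = list(np.unique(pops))
    k = len(labels)
    fst = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.isin(pops, [labels[i], labels[j]])
            sub = gm.take_individuals(np.flatnonzero(rows))
            comp = wc_components(sub, pops[rows])
            v = comp["valid"].to_numpy()
            a = comp.loc[v, "a"].to_numpy()
            abc = (
                comp.loc[v, ["a", "b", "c"]].to_numpy().sum(axis=1)
            )
            theta = a.sum() / abc.sum()
            L = a.size
            bt = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, L, L)
                bt[b] = a[idx].sum() / abc[idx].sum()
            fst[i, j] = fst[j, i] = theta
            lo[i, j] = lo[j, i] = np.percentile(bt, 2.5)
            hi[i, j] = hi[j, i] = np.percentile(bt, 97.5)
    return (
        DistanceMatrix(labels, fst),
        DistanceMatrix(labels, lo),
        DistanceMatrix(labels, hi),
    )


def _group_freqs(gm: GenotypeMatrix, groups: np.ndarray):
    labels = np.unique(groups)
    called = gm.dosages != MISSING
    freqs = np.full((len(labels), gm.n_sites), np.nan)
    ns = np.zeros((len(labels), gm.n_sites))
    for i, lab in enumerate(labels):
        rows = groups == lab
        c = called[rows]
        d = np.where(c, gm.dosages[rows], 0).astype(float)
        ni = c.sum(axis=0)
        if c.sum() == 0:
            raise ValueError(f"group {lab!r} has no called data")
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(ni > 0, d.sum(axis=0) / (2 * ni), np.nan)
        ns[i] = ni
    return labels, freqs, ns


def nei_D(gm: GenotypeMatrix, groups, variant: str = "1972") -> DistanceMatrix:
    """Nei's genetic distance between group allele-frequency profiles.

    ``variant="1972"`` (default) is the standard distance
    D = -ln( sum_l J_xy / sqrt(sum_l J_x * sum_l J_y) ) with per-locus
    identities J_xy = p_x p_y + q_x q_y, J_x = p_x^2 + q_x^2.
    ``variant="1978"`` applies the unbiased small-sample correction to
    the within-group identities, (2n J_x - 1) / (2n - 1).
    """
    groups = np.asarray(groups)
    labels, freqs, ns = _group_freqs(gm, groups)
    k = len(labels)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = freqs[i], freqs[j]
            ok = np.isfinite(pi) & np.isfinite(pj)
            pi, pj = pi[ok], pj[ok]
            jxy = (pi * pj + (1 - pi) * (1 - pj)).sum()
            jx = (pi**2 + (1 - pi) ** 2)
            jy = (pj**2 + (1 - pj) ** 2)
            if variant == "1978":
                ni = ns[i][ok]
                nj = ns[j][ok]
                jx = (2 * ni * jx - 1) / (2 * ni - 1)
                jy = (2 * nj * jy - 1) / (2 * nj - 1)
            val = -np.log(jxy / np.sqrt(jx.sum() * jy.sum()))
            D[i, j] = D[j, i] = max(val, 0.0) if variant == "1978" else val
    return DistanceMatrix(list(labels), D)


def nei_D_individual(gm: GenotypeMatrix, variant: str = "1972") -> DistanceMatrix:
    """Nei's D between individuals, each treated as a population of one
    with allele frequencies from its two allele copies (0, 0.5, 1)."""
    return nei_D(gm, gm.individuals["id"].to_numpy(), variant=variant)


def nj_tree(D: DistanceMatrix) -> str:
    """Neighbour-joining (Saitou-Nei, Studier-Keppler Q-criterion) newick.

    Negative branch lengths are clamped to zero and the deficit moved to
    the sister edge, preserving pairwise path lengths where possible.
    """
    labels = list(D.labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    d = D.values.astype(float).copy()
    nodes = [f"{lab}" for lab in labels]

    while len(nodes) > 3:
        n = len(nodes)
        tot = d.sum(axis=1)
        q = (n - 2) * d - tot[:, None] - tot[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (tot[i] - tot[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li  # transfer to sister edge
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dk[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final 3-node star with the three-point formulas
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"
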