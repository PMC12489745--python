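"""Linkage disequilibrium: pairwise r², decay profiling, windowed pruning.

r² is the squared Pearson correlation of genotype dosage vectors over
individuals called at both sites — the genotype (composite) LD measure
appropriate for unphased data.  Pruning removes, for every within-window
pair exceeding the r² threshold, the member with the higher missingness
(ties broken toward the larger position), which guarantees that the
surviving set contains no offending pair and that stricter thresholds
remove supersets of looser ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


@dataclass
class LDPair:
    site_a: int
    site_b: int
    distance_bp: int
    r2: float


@dataclass
class PruneResult:
    kept: list[str]
    removed: list[str]
    params: dict = field(default_factory=dict)


def _pair_r2(dos: np.ndarray, a: int, b: int) -> float:
    """r² over individuals non-missing at both sites; NaN if degenerate."""
    x, y = dos[:, a].astype(float), dos[:, b].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2(
    gm: GenotypeMatrix, window_snps: int = 100, max_dist_kb: float = 1000.0
) -> list[LDPair]:
    """All same-chromosome pairs within ``window_snps`` consecutive SNPs
    and ``max_dist_kb`` physical distance.

    Pairs where either site has zero variance among the shared calls are
    skipped (their count is not recorded on the pair list itself).
    """
    pos = gm.sites["pos"].to_numpy()
    chrom = gm.sites["chrom"].to_numpy()
    max_bp = max_dist_kb * 1000.0
    out: list[LDPair] = []
    for a in range(gm.n_sites):
        hi = min(gm.n_sites, a + window_snps + 1)
        for b in range(a + 1, hi):
            if chrom[b] != chrom[a]:
                break
            d = int(pos[b] - pos[a])
            if d > max_bp:
                break
            r2 = _pair_r2(gm.dosages, a, b)
            if np.isnan(r2):
                continue
            out.append(LDPair(a, b, d, r2))
    return out


def ld_decay(pairs: list[LDPair], bin_width_kb: float) -> pd.DataFrame:
    """Mean r² per physical-distance bin.

    Bins are half-open ``[k*w, (k+1)*w)`` kb covering ``[0, max distance]``;
    empty bins are emitted with ``n_pairs = 0``.
    """
    if bin_width_kb <= 0:
        raise ValueError("bin width must be positive")
    if not pairs:
        raise ValueError("empty pair list")
    w = bin_width_kb * 1000.0
    d = np.array([p.distance_bp for p in pairs], float)
    r2 = np.array([p.r2 for p in pairs])
    idx = np.floor(d / w).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)
    return pd.DataFrame(
        {
            "bin_start_kb": np.arange(n_bins) * bin_width_kb,
            "bin_end_kb": (np.arange(n_bins) + 1) * bin_width_kb,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )


def ld_prune(
    gm: GenotypeMatrix,
    window_kb: float = 50.0,
    step_kb: float = 10.0,
    r2_threshold: float = 0.2,
) -> PruneResult:
    """Windowed LD pruning of a sorted genotype matrix.

    Windows are half-open ``[start, start + window_kb)`` intervals strided
    by ``step_kb``; two sites share a window if both fall in any common
    window, which for window w and step s means they are within w kb and
    some stride boundary does not separate them.  For every such pair
    with r² strictly above the threshold, the site with the higher
    missingness is removed (ties: the larger position).  The survivors
    therefore contain no within-window pair above the threshold, and
    pruning at a stricter (smaller) threshold removes a superset.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    pos = gm.sites["pos"].to_numpy()
    chrom = gm.sites["chrom"].to_numpy()
    miss = gm.site_missing_frac()
    w_bp = window_kb * 1000.0
    s_bp = step_kb * 1000.0

    removed = np.zeros(gm.n_sites, bool)
    for a in range(gm.n_sites):
        b = a + 1
        while b < gm.n_sites and chrom[b] == chrom[a] and pos[b] - pos[a] < w_bp:
            if _share_window(pos[a], pos[b], w_bp, s_bp):
                r2 = _pair_r2(gm.dosages, a, b)
                if not np.isnan(r2) and r2 > r2_threshold:
                    # drop the worse site of the offending pair
                    if (miss[a], pos[a]) > (miss[b], pos[b]):
                        removed[a] = True
                    else:
                        removed[b] = True
            b += 1
    ids = gm.site_ids
    return PruneResult(
        kept=list(ids[~removed]),
        removed=list(ids[removed]),
        params={
            "window_kb": window_kb,
            "step_kb": step_kb,
            "r2_threshold": r2_threshold,
        },
    )


def _share_window(pa: float, pb: float, w_bp: float, s_bp: float) -> bool:
    """Whether two positions fall together in any window [k*s, k*s + w)."""
    if pb - pa >= w_bp:
        return False
    # windows starting at k*s with k*s <= pa and k*s + w > pb
    k_max = int(pa // s_bp)
    return k_max * s_bp + w_bp > pb


def apply_prune(gm: GenotypeMatrix, result: PruneResult) -> GenotypeMatrix:
    """Subset a matrix to the kept sites of a prune result."""
    keep = set(result.kept)
    idx = np.flatnonzero(np.isin(gm.site_ids, list(keep)))
    return gm.take_sites(idx)


def write_site_list(sites: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(sites) + ("\n" if sites else ""))
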