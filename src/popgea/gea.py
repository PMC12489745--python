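"""Genotype-environment association.

Detects loci whose allele frequencies covary with environmental
gradients, while controlling for neutral population structure, by three
complementary routes whose intersection forms the final candidate set:

1. partial redundancy analysis (pRDA) of the individual allele-frequency
   matrix on the retained environmental predictors, conditioned on
   structure covariates, with SNPs flagged by extreme loadings on the
   retained canonical axes;
2. latent factor mixed models (ridge LFMM) run per environmental
   variable, with genomic-inflation-corrected p-values and Storey
   q-values;
3. the PCA-Mahalanobis selection scan (:mod:`popgea.scan`).

Requiring all three pieces of evidence trades recall for a low false
discovery rate, the appropriate trade-off when candidates feed
conservation decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.stats import chi2

from .genio import MISSING, GenotypeMatrix
from .qvalue import qvalues
from .structure import impute_site_means


# ---------------------------------------------------------------------------
# environmental predictor pruning


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column given the others."""
    n, p = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    out = np.empty(p)
    for j in range(p):
        others = np.delete(Xs, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, Xs[:, j], rcond=None)
        resid = Xs[:, j] - A @ coef
        r2 = 1.0 - resid @ resid / (Xs[:, j] @ Xs[:, j])
        out[j] = 1.0 / max(1.0 - r2, 1e-12)
    return out


def prep_env(
    env: pd.DataFrame,
    r_max: float = 0.7,
    vif_max: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two-stage collinearity pruning of environmental predictors.

    Stage 1 drops, from every pair with |Pearson r| > ``r_max``, the
    later-listed variable (the first in column order is kept; both are
    logged).  Stage 2 repeatedly removes the variable with the highest
    VIF until all VIFs are at most ``vif_max``.  Variables removed at the
    VIF stage are returned separately: they are not independent signals
    but still belong in the model as conditioning covariates.

    ``env`` must contain an ``id`` column or use ids as index; variables
    must be complete (no missing values).
    """
    if "id" in env.columns:
        env = env.set_index("id")
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"environmental variables with missing data: {bad}")
    cols = list(env.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 environmental variables")
    log: list[str] = []

    corr = env.corr().to_numpy()
    dropped_corr = set()
    for i in range(len(cols)):
        if cols[i] in dropped_corr:
            continue
        for j in range(i + 1, len(cols)):
            if cols[j] in dropped_corr:
                continue
            if abs(corr[i, j]) > r_max:
                dropped_corr.add(cols[j])
                log.append(
                    f"corr-stage: dropped {cols[j]} (|r|={abs(corr[i, j]):.3f} "
                    f"with kept {cols[i]})"
                )
    kept = [c for c in cols if c not in dropped_corr]

    vif_removed: list[str] = []
    while len(kept) > 1:
        v = _vif(env[kept].to_numpy(float))
        worst = int(np.argmax(v))
        if v[worst] <= vif_max:
            break
        vif_removed.append(kept[worst])
        log.append(f"vif-stage: removed {kept[worst]} (VIF={v[worst]:.2f})")
        kept = [c for k, c in enumerate(kept) if k != worst]
    if not kept:
        raise ValueError("no environmental variable survives pruning")
    return env[kept], env[vif_removed], log


# ---------------------------------------------------------------------------
# response matrix


def individual_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Individual-level alternate-allele frequencies (dosage / 2), with
    missing entries imputed to the site mean frequency."""
    X, _ = impute_site_means(gm)
    return X / 2.0


# ---------------------------------------------------------------------------
# partial RDA


@dataclass
class PRDAResult:
    eigenvalues: np.ndarray  # canonical eigenvalues, descending
    axis_scores: np.ndarray  # n x n_axes site (individual) scores
    loadings: np.ndarray  # L x n_axes SNP loadings
    r2_adj_full: float
    r2_adj_climate: float
    r2_adj_structure: float
    axis_pvalues: np.ndarray
    retained_axes: int
    total_variance: float


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of M on [1, Z] (column-wise least squares)."""
    n = M.shape[0]
    A = np.ones((n, 1)) if Z is None or Z.size == 0 else np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(A, M, rcond=None)
    return M - A @ coef


def _adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel small-sample correction 1 - (1-R^2)(n-1)/(n-p-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _rda_fit(Y: np.ndarray, X: np.ndarray):
    """Least-squares fit + PCA of fitted values; returns eigendecomp."""
    fit_coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(Y)), X]), Y, rcond=None)
    fitted = np.column_stack([np.ones(len(Y)), X]) @ fit_coef
    fitted -= fitted.mean(axis=0)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (len(Y) - 1)
    return U, s, Vt, eig, fitted


def prda(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 199,
    seed: int = 0,
    n_axes: int | None = None,
) -> PRDAResult:
    """Partial redundancy analysis of Y on X conditioned on Z.

    Y (n x L) and X are residualized on [1, Z]; the canonical axes are
    the principal components of the fitted values of the residual
    regression.  Adjusted R-squared uses the Ezekiel correction; the
    variance partition reports climate given structure (the pRDA
    itself), structure given climate, and the full joint model.  Per-axis
    p-values come from permuting the rows of the residualized response.
    """
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xv = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    n, L = Y.shape
    p = Xv.shape[1]
    qz = 0 if Z is None or Z.size == 0 else np.atleast_2d(Z).shape[1]
    if n <= p + qz + 1:
        raise ValueError("too few individuals for the requested model")

    Yc = Y - Y.mean(axis=0)
    Yr = _residualize(Yc, Z)
    Xr = _residualize(Xv, Z)
    total = (Yr**2).sum()

    U, s, Vt, eig, fitted = _rda_fit(Yr, Xr)
    n_can = min(p, L, n - 1)
    eig = eig[:n_can]

    # variance partition by adjusted-R2 differencing: the unique climate
    # (resp. structure) fraction is the joint model's adjusted R2 minus
    # the other block's marginal adjusted R2
    tot_c = (Yc**2).sum()

    def _marginal_adj(M):
        _, _, _, _, f = _rda_fit(Yc, M)
        return _adj_r2((f**2).sum() / tot_c, n, M.shape[1])

    if qz:
        Zv = np.atleast_2d(Z)
        r2_full = _marginal_adj(np.column_stack([Xv, Zv]))
        r2_climate = r2_full - _marginal_adj(Zv)
        r2_structure = r2_full - _marginal_adj(Xv)
    else:
        r2_full = r2_climate = _marginal_adj(Xv)
        r2_structure = 0.0

    rng = np.random.default_rng(seed)
    perm_eig = np.empty((n_perm, n_can))
    for b in range(n_perm):
        Yp = Yr[rng.permutation(n)]
        _, _, _, pe, _ = _rda_fit(Yp, Xr)
        perm_eig[b] = pe[:n_can]
    axis_p = ((perm_eig >= eig[None, :]).sum(axis=0) + 1.0) / (n_perm + 1.0)

    keep = n_axes if n_axes is not None else n_can
    return PRDAResult(
        eigenvalues=eig,
        axis_scores=(U * s)[:, :keep],
        loadings=Vt.T[:, :keep],
        r2_adj_full=float(r2_full),
        r2_adj_climate=float(r2_climate),
        r2_adj_structure=float(r2_structure),
        axis_pvalues=axis_p,
        retained_axes=int(keep),
        total_variance=float(total),
    )


@dataclass
class CandidateSet:
    """SNP candidates with their assigned environmental variable and the
    evidence routes supporting them."""

    table: pd.DataFrame  # site, env_var, evidence flags
    thresholds: dict = field(default_factory=dict)

    @property
    def site_ids(self) -> set[str]:
        return set(self.table["site"])

    def __len__(self) -> int:
        return len(self.table)


def rda_candidates(
    res: PRDAResult,
    site_ids: np.ndarray,
    Y: np.ndarray,
    env: pd.DataFrame,
    retained_axes: int = 3,
    sd_mult: float = 3.0,
) -> CandidateSet:
    """Flag SNPs with extreme loadings on the retained canonical axes.

    A SNP is a candidate when, on any retained axis, its loading is more
    than ``sd_mult`` standard deviations from the axis mean loading.
    Each candidate is assigned the environmental variable with the
    largest absolute Pearson correlation to its frequency column.
    """
    if sd_mult <= 0:
        raise ValueError("sd_mult must be positive")
    if retained_axes > res.loadings.shape[1]:
        raise ValueError("retained_axes exceeds available axes")
    flagged = np.zeros(len(site_ids), bool)
    for ax in range(retained_axes):
        lo = res.loadings[:, ax]
        flagged |= np.abs(lo - lo.mean()) > sd_mult * lo.std()
    idx = np.flatnonzero(flagged)

    ev = env.to_numpy(float)
    ev = (ev - ev.mean(axis=0)) / ev.std(axis=0)
    names = list(env.columns)
    rows = []
    for j in idx:
        y = Y[:, j] - Y[:, j].mean()
        sd = y.std()
        if sd == 0:
            continue
        cors = np.abs(ev.T @ y) / (len(y) * sd)
        rows.append((site_ids[j], names[int(np.argmax(cors))]))
    table = pd.DataFrame(rows, columns=["site", "env_var"])
    return CandidateSet(table=table, thresholds={"sd_mult": sd_mult, "retained_axes": retained_axes})


# ---------------------------------------------------------------------------
# LFMM ridge


@dataclass
class LFMMResult:
    env_names: list[str]
    effects: np.ndarray  # L x n_env
    z: np.ndarray
    pvalues_raw: np.ndarray
    gif: np.ndarray  # per env variable
    pvalues_adj: np.ndarray
    qvalues: np.ndarray
    fdr: float
    site_ids: np.ndarray

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """Significant (site, env_var) pairs at the given FDR; a site
        associated with several variables is assigned its smallest-q one."""
        fdr = self.fdr if fdr is None else fdr
        hits = []
        for v, name in enumerate(self.env_names):
            sel = np.where(np.isnan(self.qvalues[:, v]), False, self.qvalues[:, v] <= fdr)
            for j in np.flatnonzero(sel):
                hits.append((self.site_ids[j], name, self.qvalues[j, v]))
        df = pd.DataFrame(hits, columns=["site", "env_var", "q"])
        if len(df):
            df = df.sort_values("q").drop_duplicates("site").reset_index(drop=True)
        return df


def _lfmm_ridge_single(Y, x, K, lam, max_iter=100, tol=1e-7):
    """Alternating minimization of ||Y - x b' - U V'||^2 + lam ||b||^2.

    The rank-K factor step needs only the top-K left singular subspace of
    the residual, obtained from the n x n Gram matrix; the latent term is
    then the projection of the residual onto that subspace, so V is never
    materialized.
    """
    n, L = Y.shape
    xc = (x - x.mean()) / x.std()
    xtx = float(xc @ xc)
    b = np.zeros(L)
    U = np.zeros((n, max(K, 1)))[:, :K]
    for _ in range(max_iter):
        if K:
            R = Y - np.outer(xc, b)
            Rc = R - R.mean(axis=0)
            gram = Rc @ Rc.T
            vals, vecs = np.linalg.eigh(gram)
            W = vecs[:, -K:]  # top-K left singular vectors
            U = W * np.sqrt(np.maximum(vals[-K:], 0.0))
            latent = W @ (W.T @ Rc)
        else:
            latent = 0.0
        b_new = (xc @ (Y - latent)) / (xtx + lam)
        delta = np.max(np.abs(b_new - b))
        b = b_new
        if delta < tol:
            break
    return b, U


def lfmm_scan(
    Y: np.ndarray,
    X: pd.DataFrame,
    K: int = 5,
    lam: float = 1e-5,
    fdr: float = 0.1,
    site_ids: np.ndarray | None = None,
    max_iter: int = 100,
) -> LFMMResult:
    """Latent factor ridge associations, one model per environmental
    variable (multiple testing is controlled per variable, not pooled).

    After fitting, per-SNP z-scores come from the OLS regression of Y on
    the variable with the K latent factors as covariates; the genomic
    inflation factor lambda_GIF = median(z^2)/median(chi2_1) recalibrates
    the p-values before Storey q-values are computed.
    """
    n, L = Y.shape
    if K >= n:
        raise ValueError("K must be < n individuals")
    names = list(X.columns)
    nv = len(names)
    effects = np.empty((L, nv))
    zmat = np.empty((L, nv))
    praw = np.empty((L, nv))
    padj = np.empty((L, nv))
    qmat = np.empty((L, nv))
    gifs = np.empty(nv)
    Yc = Y - Y.mean(axis=0)
    for v, name in enumerate(names):
        x = X[name].to_numpy(float)
        b, U = _lfmm_ridge_single(Yc, x, K, lam, max_iter=max_iter)
        effects[:, v] = b
        xc = (x - x.mean()) / x.std()
        design = xc[:, None] if not K else np.column_stack([xc, U])
        A = np.column_stack([np.ones(n), design])
        coef, *_ = np.linalg.lstsq(A, Yc, rcond=None)
        resid = Yc - A @ coef
        dof = n - A.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        XtXinv = np.linalg.inv(A.T @ A)
        se = np.sqrt(np.maximum(XtXinv[1, 1] * sigma2, 1e-300))
        var_ok = Yc.std(axis=0) > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = coef[1] / se
        z[~var_ok] = np.nan
        zmat[:, v] = z
        z2 = z[np.isfinite(z)] ** 2
        gifs[v] = np.median(z2) / chi2.median(1)
        praw[:, v] = chi2.sf(z**2, 1)
        padj[:, v] = chi2.sf(z**2 / gifs[v], 1)
        qmat[:, v] = qvalues(padj[:, v])
    return LFMMResult(
        env_names=names,
        effects=effects,
        z=zmat,
        pvalues_raw=praw,
        gif=gifs,
        pvalues_adj=padj,
        qvalues=qmat,
        fdr=fdr,
        site_ids=site_ids if site_ids is not None else np.arange(L).astype(str),
    )


# ---------------------------------------------------------------------------
# intersection


def intersect_candidates(
    rda: CandidateSet,
    lfmm: LFMMResult,
    scan_outliers,
    fdr: float | None = None,
) -> CandidateSet:
    """Final candidates: SNPs supported by RDA, LFMM and the outlier scan.

    The assigned environmental variable is the RDA assignment (max
    correlation); the summary table also carries the LFMM variable and
    its q-value.  All inputs must share one site universe.
    """
    scan_set = set(scan_outliers)
    universe = set(lfmm.site_ids)
    if not rda.site_ids <= universe or not scan_set <= universe:
        raise ValueError("candidate inputs use different site universes")
    sig = lfmm.significant(fdr)
    lf = dict(zip(sig["site"], zip(sig["env_var"], sig["q"])))
    rows = []
    for _, rec in rda.table.iterrows():
        s = rec["site"]
        if s in lf and s in scan_set:
            rows.append((s, rec["env_var"], lf[s][0], lf[s][1]))
    table = pd.DataFrame(rows, columns=["site", "env_var", "lfmm_env_var", "lfmm_q"])
    thr = dict(rda.thresholds)
    thr["fdr"] = lfmm.fdr if fdr is None else fdr
    return CandidateSet(table=table, thresholds=thr)


def candidate_summary(cands: CandidateSet) -> pd.DataFrame:
    """Per-environmental-variable candidate counts."""
    if len(cands) == 0:
        return pd.DataFrame(columns=["env_var", "n"])
    return (
        cands.table.groupby("env_var").size().rename("n").reset_index()
        .sort_values("n", ascending=False).reset_index(drop=True)
    )
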