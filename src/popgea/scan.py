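"""Selection-outlier scan from principal components.

SNPs that contribute exceptionally to population structure are candidate
targets of divergent selection.  Each standardized SNP is regressed on
the first K principal-component score vectors; the vector of K
regression z-scores is summarized by its Mahalanobis distance D^2 under
a robust covariance estimate across SNPs.  D^2 is recalibrated by the
genomic inflation factor lambda = median(D^2) / median(chi^2_K), upper
chi^2_K tail probabilities give p-values, and Storey q-values control
the FDR (candidates at q <= alpha).

K is a required argument: it should be chosen from the scree of the
genotype PCA (an assistive report is provided by
:func:`popgea.structure.scree_report`), mirroring the usual elbow-rule
practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

from .genio import MISSING, GenotypeMatrix
from .qvalue import qvalues
from .structure import impute_site_means


@dataclass
class OutlierScan:
    K: int
    z: np.ndarray  # L x K
    mahalanobis: np.ndarray
    gif: float
    pvalues: np.ndarray
    qvalues: np.ndarray
    alpha: float
    outliers: np.ndarray  # site ids at q <= alpha
    site_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_ids,
                "D2": self.mahalanobis,
                "p": self.pvalues,
                "q": self.qvalues,
            }
        )


def _snp_zscores(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """z-statistics of each SNP column regressed on the score matrix.

    Scores are orthogonalized internally, so the coefficient covariance
    is diagonal and the z computation vectorizes over SNPs.
    """
    n, K = scores.shape
    Qmat, _ = np.linalg.qr(scores - scores.mean(axis=0))
    coef = Qmat.T @ X  # K x L, orthonormal design
    resid = X - Qmat @ coef
    dof = n - K - 1  # intercept absorbed by centering
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        z = coef / np.sqrt(sigma2)[None, :]
    return z.T  # L x K


def outlier_scan(
    gm: GenotypeMatrix,
    K: int,
    alpha: float = 0.1,
    robust: bool = True,
    seed: int = 0,
) -> OutlierScan:
    """PCA-Mahalanobis outlier scan of all sites.

    Zero-variance SNPs get missing statistics.  The covariance of the
    z-score rows is estimated by minimum covariance determinant when
    there are at least 10*K SNPs (and ``robust`` is set), otherwise by
    the sample covariance.
    """
    if K >= gm.n_individuals:
        raise ValueError("K must be < n_individuals")
    X, _ = impute_site_means(gm)
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = (U * s)[:, :K]
    z = _snp_zscores(Xs, scores)

    L = z.shape[0]
    if robust and L >= 10 * K:
        mcd = MinCovDet(random_state=seed).fit(z)
        center, cov = mcd.location_, mcd.covariance_
    else:
        center, cov = z.mean(axis=0), np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    zc = z - center
    d2 = np.einsum("ij,jk,ik->i", zc, np.linalg.inv(cov), zc)

    gif = float(np.median(d2) / chi2.median(K))
    p = chi2.sf(d2 / gif, K)
    q = qvalues(p)

    pvals = np.full(gm.n_sites, np.nan)
    qvals = np.full(gm.n_sites, np.nan)
    d2full = np.full(gm.n_sites, np.nan)
    zfull = np.full((gm.n_sites, K), np.nan)
    pvals[ok], qvals[ok], d2full[ok], zfull[ok] = p, q, d2, z

    ids = gm.site_ids
    out = ids[np.where(np.isnan(qvals), False, qvals <= alpha)]
    return OutlierScan(
        K=K,
        z=zfull,
        mahalanobis=d2full,
        gif=gif,
        pvalues=pvals,
        qvalues=qvals,
        alpha=alpha,
        outliers=out,
        site_ids=ids,
    )


def drop_outliers(gm: GenotypeMatrix, scan: OutlierScan) -> GenotypeMatrix:
    """Matrix restricted to sites not flagged by the scan."""
    keep = ~np.isin(gm.site_ids, scan.outliers)
    return gm.take_sites(np.flatnonzero(keep))
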