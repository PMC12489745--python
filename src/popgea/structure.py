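"""Population structure: PCA, k-means/BIC cluster scan, DAPC, admixture.

PCA mean-imputes missing dosages and centers (but does not
variance-scale) each site before the eigendecomposition, which keeps
common variants weighted by their variance.  Cluster number is scanned
with k-means on the PC scores and scored by BIC; DAPC fits linear
discriminants on retained PCs with an a-score permutation criterion for
how many PCs to keep.  Admixture proportions are estimated under the
binomial likelihood g_ij ~ Bin(2, sum_k q_ik f_kj) with EM block
updates, plus masked-entry cross-validation for choosing K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genio import MISSING, GenotypeMatrix

_EPS_F = 1e-6


@dataclass
class PCAModel:
    scores: np.ndarray  # n x n_axes
    loadings: np.ndarray  # L x n_axes
    eigenvalues: np.ndarray
    site_means: np.ndarray
    explained_frac: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Centered imputed matrix from all retained axes."""
        return self.scores @ self.loadings.T


def impute_site_means(gm: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix as float with missing entries set to the site mean."""
    dos = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    if not called.any(axis=0).all():
        raise ValueError("site with no called genotypes; filter first")
    means = np.where(called, dos, 0).sum(axis=0) / called.sum(axis=0)
    return np.where(called, dos, means[None, :]), means


def pca_impute(gm: GenotypeMatrix, n_axes: int) -> PCAModel:
    """PCA of the mean-imputed, column-centered dosage matrix."""
    if n_axes > min(gm.n_individuals, gm.n_sites):
        raise ValueError("n_axes exceeds matrix rank bound")
    X, means = impute_site_means(gm)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (gm.n_individuals - 1)
    total = eig.sum()
    return PCAModel(
        scores=(U * s)[:, :n_axes],
        loadings=Vt.T[:, :n_axes],
        eigenvalues=eig[:n_axes],
        site_means=means,
        explained_frac=eig[:n_axes] / total,
    )


def scree_report(eigenvalues: np.ndarray) -> dict:
    """Assistive scree summary for choosing K by Cattell's elbow rule.

    Reports, for each axis, the eigenvalue drop to the next axis and the
    axis after which drops flatten (largest second difference).  The
    choice of K remains with the caller.
    """
    ev = np.asarray(eigenvalues, float)
    drops = -np.diff(ev)
    second = np.diff(drops)
    elbow = int(np.argmax(second) + 1) if second.size else 1
    return {"eigenvalues": ev, "drops": drops, "suggested_elbow": elbow}


@dataclass
class ClusterScan:
    k_values: np.ndarray
    bic: np.ndarray
    assignments: np.ndarray  # labels 1..chosen_k at chosen_k
    chosen_k: int
    all_assignments: dict = field(default_factory=dict)


def kmeans_bic(
    scores: np.ndarray,
    k_max: int = 20,
    n_starts: int = 10,
    seed: int = 0,
    chosen_k: int | None = None,
) -> ClusterScan:
    """k-means over k = 1..k_max scored by BIC = n ln(WSS/n) + k ln(n).

    The automatic choice is the first local BIC minimum — the first k
    whose BIC is lower than the next k's (the elbow before an increase).
    Pass ``chosen_k`` to override.
    """
    n = scores.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        raise ValueError("k_max must be < n_individuals")
    ks = np.arange(1, k_max + 1)
    bic = np.empty(len(ks))
    assignments = {}
    eps = 1e-12
    for i, k in enumerate(ks):
        km = KMeans(n_clusters=int(k), n_init=n_starts, random_state=seed)
        lab = km.fit_predict(scores)
        wss = max(km.inertia_, eps)
        bic[i] = n * np.log(wss / n) + k * np.log(n)
        assignments[int(k)] = lab + 1
    if chosen_k is None:
        chosen_k = int(ks[-1])
        for i in range(len(ks) - 1):
            if bic[i] < bic[i + 1]:
                chosen_k = int(ks[i])
                break
        else:
            chosen_k = int(ks[np.argmin(bic)])
    return ClusterScan(
        k_values=ks,
        bic=bic,
        assignments=assignments[int(chosen_k)],
        chosen_k=int(chosen_k),
        all_assignments=assignments,
    )


@dataclass
class DAPCModel:
    n_pc_retained: int
    discriminant_axes: np.ndarray
    group_centroids: np.ndarray
    scores: np.ndarray  # individuals on discriminant functions
    explained_frac: np.ndarray
    a_score: dict  # candidate n_pc -> a-score
    best_n_pc: int
    reassignment_rate: float


def _reassignment_rate(lda: LinearDiscriminantAnalysis, X, y) -> float:
    return float((lda.predict(X) == y).mean())


def dapc_fit(
    scores: np.ndarray,
    groups: np.ndarray,
    n_pc_grid: np.ndarray | None = None,
    n_perm: int = 50,
    seed: int = 0,
) -> DAPCModel:
    """Discriminant analysis of principal components with a-score tuning.

    For each candidate number of retained PCs, the a-score is the mean
    over groups of (observed correct-reassignment rate minus the mean
    rate under ``n_perm`` random permutations of the group labels) — a
    penalty for discrimination that is an artifact of dimensionality.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    n, max_pc = scores.shape
    if n_pc_grid is None:
        hi = min(max_pc, n - len(labels) - 1)
        n_pc_grid = np.unique(np.linspace(1, max(hi, 1), 10).astype(int))
    rng = np.random.default_rng(seed)

    def per_group_rate(pred, truth):
        return np.array([ (pred[truth == g] == g).mean() for g in labels ])

    a_scores = {}
    for npc in n_pc_grid:
        X = scores[:, : int(npc)]
        lda = LinearDiscriminantAnalysis().fit(X, groups)
        obs = per_group_rate(lda.predict(X), groups)
        perm = np.zeros(len(labels))
        for _ in range(n_perm):
            gp = rng.permutation(groups)
            lp = LinearDiscriminantAnalysis().fit(X, gp)
            perm += per_group_rate(lp.predict(X), gp)
        a_scores[int(npc)] = float((obs - perm / n_perm).mean())

    best = max(a_scores, key=a_scores.get)
    X = scores[:, :best]
    lda = LinearDiscriminantAnalysis().fit(X, groups)
    ev = lda.explained_variance_ratio_
    return DAPCModel(
        n_pc_retained=best,
        discriminant_axes=lda.scalings_[:, : len(labels) - 1],
        group_centroids=lda.means_,
        scores=lda.transform(X),
        explained_frac=ev,
        a_score=a_scores,
        best_n_pc=best,
        reassignment_rate=_reassignment_rate(lda, X, groups),
    )


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # n x K
    F: np.ndarray  # K x L ancestral allele frequencies
    loglik_trace: np.ndarray
    cv_error: float | None
    converged: bool


def _admix_loglik(G, called, Q, F):
    H = np.clip(Q @ F, _EPS_F, 1 - _EPS_F)
    ll = np.where(called, G * np.log(H) + (2 - G) * np.log(1 - H), 0.0)
    return float(ll.sum())


def _admix_em(G, called, Q, F, tol, max_iter):
    """EM block updates for the binomial admixture likelihood.

    The complete-data formulation assigns each of the two allele copies
    an ancestral population; the E-step computes expected copy counts
    per (individual, population) and (population, locus), the M-step
    renormalizes.  The observed-data log-likelihood is non-decreasing.
    """
    trace = [_admix_loglik(G, called, Q, F)]
    Gm = np.where(called, G, 0.0)
    G2 = np.where(called, 2.0 - G, 0.0)
    converged = False
    for _ in range(max_iter):
        H = np.clip(Q @ F, _EPS_F, 1 - _EPS_F)
        A = Gm / H  # n x L
        B = G2 / (1 - H)
        # expected alt / ref copy counts from population k
        alt = Q * (A @ F.T)  # n x K
        ref = Q * (B @ (1 - F).T)
        ncall = 2.0 * called.sum(axis=1, keepdims=True)
        Q = (alt + ref) / ncall
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        H = np.clip(Q @ F, _EPS_F, 1 - _EPS_F)
        A = Gm / H
        B = G2 / (1 - H)
        alt_f = F * (Q.T @ A)  # K x L
        ref_f = (1 - F) * (Q.T @ B)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = alt_f / (alt_f + ref_f)
        F = np.clip(np.nan_to_num(F, nan=0.5), _EPS_F, 1 - _EPS_F)

        trace.append(_admix_loglik(G, called, Q, F))
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return Q, F, np.array(trace), converged


def admixture_fit(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
    cv_folds: int = 0,
) -> AdmixtureFit:
    """Fit admixture proportions Q and ancestral frequencies F at fixed K.

    ``cv_folds > 0`` additionally estimates a cross-validation error by
    masking a random 1/cv_folds of the called genotype entries per fold,
    refitting, and scoring the mean squared prediction error
    (g - 2*h)^2 over the masked entries.  Intended input: MAF-filtered,
    LD-pruned genotypes from unrelated individuals.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    G = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    n, L = G.shape

    def init(rng_):
        Q0 = rng_.dirichlet(np.ones(K), n)
        p_obs = np.where(called, G, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1
        )
        F0 = np.clip(
            p_obs[None, :] + 0.1 * rng_.standard_normal((K, L)), _EPS_F, 1 - _EPS_F
        )
        return Q0, F0

    if K == 1:
        p_obs = np.where(called, G, 0).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1
        )
        Q = np.ones((n, 1))
        F = np.clip(p_obs[None, :], _EPS_F, 1 - _EPS_F)
        trace = np.array([_admix_loglik(G, called, Q, F)])
        converged = True
    else:
        Q0, F0 = init(rng)
        Q, F, trace, converged = _admix_em(G, called, Q0, F0, tol, max_iter)

    cv = None
    if cv_folds > 0:
        idx = np.argwhere(called)
        rng.shuffle(idx)
        folds = np.array_split(idx, cv_folds)
        errs = []
        for fold in folds:
            mask = called.copy()
            mask[fold[:, 0], fold[:, 1]] = False
            if K == 1:
                p_f = np.where(mask, G, 0).sum(axis=0) / np.maximum(
                    2 * mask.sum(axis=0), 1
                )
                Hf = np.tile(np.clip(p_f, _EPS_F, 1 - _EPS_F), (n, 1))
            else:
                Qf0, Ff0 = init(rng)
                Qf, Ff, _, _ = _admix_em(G, mask, Qf0, Ff0, tol, max_iter)
                Hf = np.clip(Qf @ Ff, _EPS_F, 1 - _EPS_F)
            g_true = G[fold[:, 0], fold[:, 1]]
            g_hat = 2.0 * Hf[fold[:, 0], fold[:, 1]]
            errs.append(np.mean((g_true - g_hat) ** 2))
        cv = float(np.mean(errs))

    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik_trace=trace, cv_error=cv, converged=converged
    )


def align_Q(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match a reference (greedy by
    correlation); returns the permuted copy."""
    K = Q.shape[1]
    remaining = list(range(K))
    order = []
    for k in range(Q_true.shape[1]):
        best = max(remaining, key=lambda c: np.dot(Q[:, c], Q_true[:, k]))
        order.append(best)
        remaining.remove(best)
    order += remaining
    return Q[:, order]


def write_Q(Q: np.ndarray, path) -> None:
    np.savetxt(path, Q, fmt="%.6f", delimiter=" ")
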