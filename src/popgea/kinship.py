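"""Allele-sharing kinship, inbreeding, and relative pruning.

Two estimators are provided:

* :func:`beta_kinship` — the allele-matching (beta) kinship of Weir &
  Goudet: pairwise matching proportions referenced to the mean
  between-individual matching, so beta averages zero over pairs by
  construction.  It does not assume independent samples or
  Hardy-Weinberg equilibrium, which suits collections with many close
  relatives and inbred individuals.  Rare alleles carry most of the
  information, so it should be run on a dataset NOT filtered by MAF.
* :func:`robust_kinship` — the robust between-family estimator (KING
  style) built from heterozygote concordance and opposing homozygotes;
  used for relatedness screening before analyses that assume
  independent samples.

Relative pruning removes, greedily, the individual involved in the most
pairs at or above the kinship threshold until none remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

MIN_CALLED_LOCI = 100


@dataclass
class KinshipMatrix:
    """Pairwise kinship with inbreeding coefficients on the diagonal."""

    labels: list[str]
    values: np.ndarray  # symmetric; diagonal = inbreeding (beta) or self-phi
    mean_matching: float | None = None  # M_B reference for beta-kinship
    low_call_flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def off_diagonal(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, 1)
        return self.values[iu]

    def scaled_to_min(self) -> np.ndarray:
        """Affine presentation scaling used for heatmaps: values shifted and
        scaled so the matrix minimum maps to 0 and the maximum to 1.
        Rank order is preserved; statistics must use the raw values."""
        v = self.values
        lo, hi = v.min(), v.max()
        return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def _matching_matrices(gm: GenotypeMatrix):
    dos = gm.dosages
    called = dos != MISSING
    x = np.where(called, dos, 0).astype(float)
    y = np.where(called, 2.0 - dos, 0.0)
    y[~called] = 0.0
    counts = called.astype(float) @ called.T.astype(float)
    num = (x @ x.T + y @ y.T) / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(counts > 0, num / counts, np.nan)
    # self-matching uses the within-individual formula 1 - x(2-x)/2
    self_m = np.where(called, 1.0 - dos * (2.0 - dos) / 2.0, 0.0)
    ncall = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.fill_diagonal(M, np.where(ncall > 0, self_m.sum(axis=1) / ncall, np.nan))
    return M, ncall


def beta_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Allele-matching beta-kinship with inbreeding on the diagonal.

    Per pair, matching averages (x_i x_j + (2-x_i)(2-x_j))/4 over
    pairwise-complete loci; per individual, self-matching averages
    1 - x(2-x)/2.  With M_B the mean off-diagonal matching,
    beta_ij = (M_ij - M_B)/(1 - M_B), and the diagonal reports the
    inbreeding coefficient 2*beta_ii - 1.
    """
    M, ncall = _matching_matrices(gm)
    n = gm.n_individuals
    iu = np.triu_indices(n, 1)
    mb = float(np.nanmean(M[iu]))
    beta = (M - mb) / (1.0 - mb)
    np.fill_diagonal(beta, 2.0 * np.diag(beta) - 1.0)
    return KinshipMatrix(
        labels=gm.individuals["id"].tolist(),
        values=beta,
        mean_matching=mb,
        low_call_flags=ncall < MIN_CALLED_LOCI,
    )


def robust_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Robust pairwise kinship from heterozygote/homozygote counts.

    phi_ij = (N_het,het - 2 N_opposing_hom) / (N_het(i) + N_het(j)),
    counting over loci called in both individuals.  Negative values are
    meaningful (less related than random) and are not clamped.  The
    diagonal holds the self-comparison value 0.5 for reference.
    """
    dos = gm.dosages
    called = (dos != MISSING).astype(float)
    het = (dos == 1).astype(float)
    hom_ref = (dos == 0).astype(float)
    hom_alt = (dos == 2).astype(float)
    n_hh = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    het_i = het @ called.T  # het of i over loci called in j
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    return KinshipMatrix(labels=gm.individuals["id"].tolist(), values=phi)


def prune_relatives(
    K: KinshipMatrix,
    threshold: float = 0.125,
    call_rates: np.ndarray | None = None,
) -> list[str]:
    """Greedy removal of relatives until no pair has kinship >= threshold.

    Repeatedly removes the individual participating in the most pairs at
    or above the threshold; ties go to the lower call rate, then to the
    lexicographically larger id.  Returns the removed ids in order.
    """
    n = len(K.labels)
    v = K.values.copy()
    np.fill_diagonal(v, -np.inf)
    adj = np.where(np.isnan(v), False, v >= threshold)
    active = np.ones(n, bool)
    cr = np.zeros(n) if call_rates is None else np.asarray(call_rates, float)
    removed: list[str] = []
    while True:
        deg = (adj & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        cand = np.flatnonzero(deg == deg.max())
        # lower call rate first, then lexicographically larger id
        order = sorted(cand, key=lambda i: (cr[i], _neg_str(K.labels[i])))
        pick = order[0]
        active[pick] = False
        removed.append(K.labels[pick])
    return removed


class _neg_str(str):
    """Reverses lexicographic comparison so 'larger id' sorts first."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)
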