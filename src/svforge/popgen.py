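"""Population-genetic summaries: Weir-Cockerham F_ST, top-quantile
breed-stratified loci, GRM-based PCA, and an allele-sharing neighbor-joining
tree.

The F_ST estimator follows Weir & Cockerham (1984): for each biallelic locus
with r = 2 populations of sizes n_i, alternate-allele frequencies p_i and
observed heterozygote frequencies h_i,

    n_bar = mean(n_i)
    n_c   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
    p_bar = sum(n_i p_i) / (r n_bar)
    s2    = sum(n_i (p_i - p_bar)^2) / ((r-1) n_bar)
    h_bar = sum(n_i h_i) / (r n_bar)

    a = n_bar/n_c * (s2 - (p_bar(1-p_bar) - (r-1)/r s2 - h_bar/4)/(n_bar-1))
    b = n_bar/(n_bar-1) * (p_bar(1-p_bar) - (r-1)/r s2
                           - (2 n_bar - 1)/(4 n_bar) h_bar)
    c = h_bar / 2

and theta = a / (a + b + c).  Negative estimates are retained; monomorphic
loci (a + b + c = 0) are undefined and excluded from ranking.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FstComponents:
    """Per-locus WC84 intermediates and variance components (vectorized)."""

    locus_ids: list[str]
    n: np.ndarray          # (2, L) per-population non-missing sample sizes
    p: np.ndarray          # (2, L) per-population alt-allele frequencies
    h: np.ndarray          # (2, L) per-population observed het frequencies
    n_bar: np.ndarray
    n_c: np.ndarray
    p_bar: np.ndarray
    s2: np.ndarray
    h_bar: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray      # NaN where undefined
    reason: list[str | None]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.theta)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.locus_ids, "a": self.a, "b": self.b, "c": self.c,
            "theta": self.theta,
        })


def weir_cockerham_fst(gm: GenotypeMatrix, group_labels) -> FstComponents:
    """Per-locus Weir-Cockerham F_ST between exactly two groups.

    ``group_labels`` assigns each sample to one of two populations; missing
    genotypes are excluded per locus per group.  A locus with fewer than two
    non-missing genotypes in either group, or monomorphic overall, gets
    theta = NaN with a reason.
    """
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    X = gm.dosages
    L = gm.n_loci
    r = 2

    n = np.zeros((2, L))
    p = np.zeros((2, L))
    h = np.zeros((2, L))
    for k, g in enumerate(groups):
        sub = X[:, labels == g]
        miss = np.isnan(sub)
        n[k] = (~miss).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p[k] = np.nansum(sub, axis=1) / (2 * np.maximum(n[k], 1))
            h[k] = np.nansum(sub == 1, axis=1) / np.maximum(n[k], 1)

    small = (n < 2).any(axis=0)
    n_bar = n.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)

        inner = (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        a = n_bar / n_c * (s2 - inner)
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1), np.nan)
    theta = np.where(small, np.nan, theta)

    reason: list[str | None] = []
    for i in range(L):
        if small[i]:
            reason.append("group-too-small")
        elif denom[i] == 0:
            reason.append("monomorphic")
        else:
            reason.append(None)
    return FstComponents(gm.locus_ids, n, p, h, n_bar, n_c, p_bar, s2, h_bar,
                         a, b, c, theta, reason)


def top_quantile_loci(fst: FstComponents, q: float = 0.05):
    """Indices of loci in the top ``q`` quantile of theta, ties included.

    The threshold is the k-th largest defined theta with k = ceil(q * m);
    with fewer than 1/q defined loci, all defined loci are returned with a
    warning.
    """
    defined = np.where(fst.defined)[0]
    m = len(defined)
    if m == 0:
        return np.array([], dtype=int), np.nan
    if m < 1.0 / q:
        log.warning("only %d defined loci for q=%g: returning all", m, q)
        return defined, float(np.nanmin(fst.theta[defined]))
    k = math.ceil(q * m)
    thetas = fst.theta[defined]
    threshold = float(np.sort(thetas)[-k])
    sel = defined[thetas >= threshold]
    return sel, threshold


@dataclass
class Grm:
    """Genomic relationship matrix with its eigendecomposition."""

    values: np.ndarray       # n x n
    eigenvalues: np.ndarray  # non-increasing
    axes: np.ndarray         # n x k sample coordinates (PC scores)
    n_loci_used: int


def grm_pca(gm: GenotypeMatrix, k_axes: int = 10) -> Grm:
    """PCA of the standardized-dosage relationship matrix.

    Missing dosages are mean-imputed; each locus is centered by 2*p_hat and
    scaled by sqrt(2*p_hat*(1-p_hat)); monomorphic loci are skipped.  Sample
    coordinates on axis j are eigvec_j * sqrt(lambda_j).
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = gm.imputed()
    p = X.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no informative loci")
    Xp = X[poly]
    pp = p[poly][:, None]
    Z = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    G = Z.T @ Z / Z.shape[0]
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(k_axes, len(w))
    axes = v[:, :k] * np.sqrt(np.clip(w[:k], 0, None))
    return Grm(G, w, axes, int(poly.sum()))


def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """1 - mean allele-sharing proportion over pairwise non-missing loci."""
    X = gm.dosages
    n = gm.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if not both.any():
                raise ValueError(
                    f"samples {gm.sample_ids[i]} and {gm.sample_ids[j]} share "
                    "no non-missing loci")
            share = 1.0 - np.abs(X[both, i] - X[both, j]) / 2.0
            D[i, j] = D[j, i] = 1.0 - share.mean()
    return D


def nj_tree(gm: GenotypeMatrix) -> str:
    """Classical neighbor-joining tree on allele-sharing distances (Newick)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if gm.n_samples < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    D = allele_sharing_distance(gm)
    dm = DistanceMatrix(D, ids=gm.sample_ids)
    tree = nj(dm)
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
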