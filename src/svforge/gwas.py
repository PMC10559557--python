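"""EMMAX-style mixed-linear-model association testing.

Model: y = X beta + u + e with u ~ N(0, sigma2_g K) and e ~ N(0, sigma2_e I).
Variance components are estimated once on the null model (no marker) by
restricted maximum likelihood over delta = sigma2_e / sigma2_g, using the
spectral decomposition K = U S U'.  Each marker is then tested by
generalized least squares with the covariance fixed at sigma2_g K +
sigma2_e I, with a Wald t-test on the marker coefficient.  Genome-wide
significance is the Bonferroni threshold alpha / n_markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    method: str


def kinship(gm: GenotypeMatrix, method: str = "IBS",
            ridge: float = 1e-6) -> KinshipMatrix:
    """Pairwise kinship from the dosage matrix.

    IBS: mean over loci of (1 - |d_i - d_j| / 2), the allele-sharing
    fraction.  GRM: VanRaden standardization Z Z' / (2 sum p(1-p)).  Missing
    dosages are mean-imputed for kinship only; a small ridge stabilizes the
    diagonal.
    """
    if gm.n_samples < 3:
        raise ValueError("kinship needs at least 3 samples")
    X = gm.imputed()                       # loci x samples
    n = gm.n_samples
    if method == "IBS":
        K = np.empty((n, n))
        for j in range(n):
            K[j] = 1.0 - np.abs(X - X[:, [j]]).mean(axis=0) / 2.0
        K = (K + K.T) / 2.0
    elif method == "GRM":
        p = X.mean(axis=1) / 2.0
        Z = X - 2 * p[:, None]
        denom = 2.0 * np.sum(p * (1 - p))
        if denom == 0:
            raise ValueError("all loci monomorphic")
        K = Z.T @ Z / denom
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = K + ridge * np.eye(n)
    return KinshipMatrix(K, method)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float                  # sigma2_e / sigma2_g
    loglik: float                 # restricted log-likelihood at the optimum
    boundary: bool = False
    eigenvalues: np.ndarray = field(default=None, repr=False)
    eigenvectors: np.ndarray = field(default=None, repr=False)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _check_full_rank(X: np.ndarray) -> None:
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    bad = piv[diag <= tol] if diag.size else []
    if len(bad):
        raise ValueError(f"design matrix is singular; collinear columns: "
                         f"{sorted(int(b) for b in bad)}")


def _reml_loglik(log_delta: float, S: np.ndarray, ystar: np.ndarray,
                 Xstar: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma2_g, as a function of
    log(delta)."""
    delta = np.exp(log_delta)
    n, p = Xstar.shape
    w = 1.0 / (S + delta)
    XtWX = Xstar.T @ (w[:, None] * Xstar)
    XtWy = Xstar.T @ (w * ystar)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ystar - Xstar @ beta
    rss = float(r @ (w * r))
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Xstar.T @ Xstar)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1)
                 + np.sum(np.log(S + delta))
                 + logdet_XtWX - logdet_XtX)
    return ll


def fit_null_reml(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                  log_delta_range: tuple[float, float] = (-10.0, 10.0),
                  grid_points: int = 101) -> VarianceComponents:
    """REML variance components of the null model via a 1-D search on
    log(delta) over a fixed grid with local refinement (deterministic)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    _check_full_rank(X)
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    grid = np.linspace(*log_delta_range, grid_points)
    lls = np.array([_reml_loglik(g, S, ystar, Xstar) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, S, ystar, Xstar),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))

    p = X.shape[1]
    w = 1.0 / (S + delta)
    XtWX = Xstar.T @ (w[:, None] * Xstar)
    beta = np.linalg.solve(XtWX, Xstar.T @ (w * ystar))
    r = ystar - Xstar @ beta
    sigma2_g = float(r @ (w * r)) / (n - p)
    sigma2_e = sigma2_g * delta
    boundary = best in (0, grid_points - 1)
    return VarianceComponents(sigma2_g, sigma2_e, delta,
                              float(-res.fun), boundary, S, U)


def mlm_association(gm: GenotypeMatrix, y: np.ndarray, X: np.ndarray,
                    vc: VarianceComponents, alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker generalized least squares with covariance fixed from the
    null fit (the EMMAX approximation).

    Each marker's dosages are mean-imputed; monomorphic markers get a NaN
    p-value with a reason.  Returns a table with beta, se, p_value and a
    Bonferroni significance flag over the tested markers.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    S, U = vc.eigenvalues, vc.eigenvectors
    w = 1.0 / np.sqrt(vc.sigma2_g * S + vc.sigma2_e)
    Ty = w * (U.T @ y)
    TX = w[:, None] * (U.T @ X)
    p_fixed = X.shape[1]
    locus_ids = gm.locus_ids

    rows = []
    for li in range(gm.n_loci):
        d = gm.dosages[li].astype(float)
        miss = np.isnan(d)
        n_used = int((~miss).sum())
        if miss.any():
            d = np.where(miss, d[~miss].mean() if n_used else 0.0, d)
        if np.allclose(d, d[0]):
            rows.append((locus_ids[li], np.nan, np.nan, np.nan, n_used,
                         "monomorphic"))
            continue
        Td = w * (U.T @ d)
        A = np.column_stack([TX, Td])
        coef, _, _, _ = np.linalg.lstsq(A, Ty, rcond=None)
        resid = Ty - A @ coef
        dof = n - p_fixed - 1
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
        t = beta / se
        pval = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((locus_ids[li], beta, se, pval, n_used, None))

    df = pd.DataFrame(rows, columns=["locus_id", "beta", "se", "p_value",
                                     "n_used", "reason"])
    tested = df["p_value"].notna().sum()
    if tested:
        thr = bonferroni_threshold(alpha, int(tested))
        df["significant"] = df["p_value"] < thr
    else:
        df["significant"] = False
    return df


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    if n_markers == 0:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median chi-square inflation factor of a p-value set."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
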