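"""Covariate-adjusted additive association with permutation adjustment.

Per-SNP ordinary least squares of a phenotype on allele dosage plus
covariates, Freedman-Lane residual permutation for adjusted p-values
(family-wise max-|t| and per-SNP), and per-SNP variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FitResult:
    beta: float  # effect per alt-allele copy, phenotype units
    se: float
    t: float
    p: float
    df: int
    n: int


def _design(covariates) -> np.ndarray:
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([np.ones(len(Z)), Z])


def fit_additive(y, g, covariates) -> FitResult:
    """OLS of y on (1, g, covariates); t-test on the dosage coefficient.

    ``g`` is the 0/1/2 alt-dosage vector; a collinear design or a
    monomorphic g raises with the offending columns named.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    Z = _design(covariates)
    if np.std(g) == 0:
        raise ValueError("collinear design: column 'g' is constant")
    X = np.column_stack([Z[:, :1], g, Z[:, 1:]])
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} samples, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name offending columns via QR pivoting on correlations
        names = ["intercept", "g"] + [f"covar{i}" for i in range(Z.shape[1] - 1)]
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(p) if abs(R[i, i]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"collinear design: columns {bad or names}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    t = float(beta[1] / se)
    pval = float(2 * stats.t.sf(abs(t), df))
    return FitResult(beta=float(beta[1]), se=se, t=t, p=pval, df=df, n=n)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Project out the column space of Z (Frisch-Waugh)."""
    coef, _, _, _ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def permutation_adjust(
    y,
    G,
    covariates,
    B: int = 100_000,
    seed: int | None = None,
    chunk: int = 2_000,
) -> pd.DataFrame:
    """Freedman-Lane residual permutation over a SNP set.

    y is regressed on the covariates; the covariate-model residuals are
    permuted B times, each time refitting every SNP. Per SNP j the
    family-wise adjusted p is (1 + #{b: max_j' |t*_{b,j'}| >= |t_j|})/(B+1)
    (max-|t|), and a per-SNP (non-family) permutation p is also reported.

    Returns a DataFrame with beta, se, t, p_nominal, p_perm_snp, p_adjusted
    per SNP (row order = column order of G).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, k = G.shape
    Z = _design(covariates)
    q = Z.shape[1]
    df = n - (q + 1)
    if df < 1:
        raise ValueError("not enough samples for the design")

    Gt = _residualize(G, Z)  # residualized dosages
    norms = (Gt * Gt).sum(axis=0)
    if (norms <= 0).any():
        bad = list(np.nonzero(norms <= 0)[0])
        raise ValueError(f"SNP columns collinear with covariates: {bad}")

    def t_stats(res_y: np.ndarray) -> np.ndarray:
        """t statistics for every SNP given residualized y columns (n, B)."""
        num = Gt.T @ res_y  # (k, B)
        betas = num / norms[:, None]
        rss = (res_y * res_y).sum(axis=0)[None, :] - betas * num
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / norms[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = betas / se
        return t, betas, se

    # observed statistics (must agree with fit_additive; covered by tests)
    yt = _residualize(y[:, None], Z)
    t_obs, beta_obs, se_obs = t_stats(yt)
    t_obs = t_obs[:, 0]
    beta_obs = beta_obs[:, 0]
    se_obs = se_obs[:, 0]
    p_nominal = 2 * stats.t.sf(np.abs(t_obs), df)

    # Freedman-Lane: permute covariate-model residuals
    resid = yt[:, 0]  # M_Z y
    rng = np.random.default_rng(seed)
    count_max = np.zeros(k, dtype=np.int64)
    count_snp = np.zeros(k, dtype=np.int64)
    done = 0
    abs_obs = np.abs(t_obs)
    while done < B:
        b = min(chunk, B - done)
        idx = np.argsort(rng.random((n, b)), axis=0)
        R = resid[idx]  # (n, b) permuted residuals
        Rt = _residualize(R, Z)
        t_star, _, _ = t_stats(Rt)
        abs_t = np.abs(t_star)
        max_t = abs_t.max(axis=0)  # (b,)
        count_max += (max_t[None, :] >= abs_obs[:, None]).sum(axis=1)
        count_snp += (abs_t >= abs_obs[:, None]).sum(axis=1)
        done += b

    return pd.DataFrame(
        {
            "beta": beta_obs,
            "se": se_obs,
            "t": t_obs,
            "p_nominal": p_nominal,
            "p_perm_snp": (1 + count_snp) / (B + 1),
            "p_adjusted": (1 + count_max) / (B + 1),
        }
    )


def variance_explained(beta: float, g, y) -> float:
    """Fraction of phenotypic variance explained: beta^2 Var(g)/Var(y),
    clipped to [0, 1]. NaN when Var(y) = 0."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    vy = float(y.var())
    if vy == 0:
        return float("nan")
    ve = float(beta) ** 2 * float(g.var()) / vy
    return float(np.clip(ve, 0.0, 1.0))
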