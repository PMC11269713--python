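"""Blood-phenotype QC and analysis.

Single-pass mean +/- k*SD outlier filtering, Welch t-tests with
Benjamini-Hochberg correction across phenotypes, pairwise Pearson
correlations, altitude-response blunting (population x altitude interaction
in a joint linear model), and mean +/- k*SD reference ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default blood indices (g/L, 1e12/L, fractions etc.; names user-extendable)
DEFAULT_INDICES = ["HGB", "RBC", "HCT", "RDW", "MCV", "MCH", "MCHC", "WBC", "PLT"]


def outlier_filter(values, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier removal outside mean +/- k*SD.

    Mean and SD (ddof=1) come from all points; applied once (re-application
    may remove more, but a single pass is the contract). Returns
    (retained values, indices of removed points). SD = 0 removes nothing.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("outlier_filter requires at least 3 values")
    mu = float(np.nanmean(v))
    sd = float(np.nanstd(v, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        return v.copy(), np.array([], dtype=int)
    bad = (v > mu + k * sd) | (v < mu - k * sd)
    bad &= np.isfinite(v)
    return v[~bad], np.nonzero(bad)[0]


def group_diff(
    pheno: pd.DataFrame,
    group_col: str,
    groups: tuple[str, str],
    phenotypes: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per phenotype between two populations, with
    Benjamini-Hochberg correction across the tested phenotypes.

    Returns one row per phenotype: group means/SDs, t, p, q and a
    significance flag (q < ``fdr``). Degenerate phenotypes (under 2 values
    in a group) get NA. Two groups with zero variance and equal means give
    t = 0, p = 1.
    """
    phenotypes = phenotypes or [c for c in DEFAULT_INDICES if c in pheno.columns]
    g1 = pheno[pheno[group_col] == groups[0]]
    g2 = pheno[pheno[group_col] == groups[1]]
    rows = []
    for ph in phenotypes:
        x = g1[ph].dropna().to_numpy(dtype=float)
        y = g2[ph].dropna().to_numpy(dtype=float)
        row = {
            "phenotype": ph,
            f"mean_{groups[0]}": x.mean() if len(x) else np.nan,
            f"sd_{groups[0]}": x.std(ddof=1) if len(x) > 1 else np.nan,
            f"mean_{groups[1]}": y.mean() if len(y) else np.nan,
            f"sd_{groups[1]}": y.std(ddof=1) if len(y) > 1 else np.nan,
        }
        if len(x) < 2 or len(y) < 2:
            row.update(t=np.nan, p=np.nan)
        elif x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            same = x.mean() == y.mean()
            row.update(t=0.0 if same else np.inf, p=1.0 if same else 0.0)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            row.update(t=float(t), p=float(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy(dtype=float))
    out["significant"] = out["q"] < fdr
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def correlations(
    pheno: pd.DataFrame,
    phenotypes: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with BH correction across pairs.

    Pairwise-complete observations; zero-variance columns give NaN for
    their pairs.
    """
    phenotypes = phenotypes or [c for c in DEFAULT_INDICES if c in pheno.columns]
    rows = []
    for i, a in enumerate(phenotypes):
        for b in phenotypes[i + 1:]:
            sub = pheno[[a, b]].dropna()
            x = sub[a].to_numpy(dtype=float)
            y = sub[b].to_numpy(dtype=float)
            if len(x) < 3 or x.std() == 0 or y.std() == 0:
                rows.append({"a": a, "b": b, "n": len(x), "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"a": a, "b": b, "n": len(x), "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy(dtype=float))
    out["significant"] = out["q"] < fdr
    return out


@dataclass
class BluntingResult:
    """Per-population altitude slopes and the interaction test."""

    slopes: dict  # population -> (slope, se) ; NaN when a single altitude
    interaction_coef: float
    interaction_se: float
    interaction_p: float
    populations: tuple[str, str]


def altitude_blunting(
    pheno: pd.DataFrame,
    group_col: str,
    altitude_col: str,
    phenotype: str,
    groups: tuple[str, str],
) -> BluntingResult:
    """Altitude-response blunting test for one phenotype.

    Fits per-population least-squares slopes of phenotype on altitude, and a
    joint model y ~ altitude * population over the two groups; blunting is
    read off the population x altitude interaction coefficient and its
    p-value. The interaction is the second group's slope minus the first's.
    """
    slopes = {}
    frames = []
    for g in groups:
        sub = pheno[pheno[group_col] == g][[altitude_col, phenotype]].dropna()
        frames.append(sub.assign(_group=g))
        alt = sub[altitude_col].to_numpy(dtype=float)
        y = sub[phenotype].to_numpy(dtype=float)
        if len(np.unique(alt)) < 2:
            slopes[g] = (np.nan, np.nan)
            continue
        res = stats.linregress(alt, y)
        slopes[g] = (float(res.slope), float(res.stderr))

    joint = pd.concat(frames, ignore_index=True)
    alt = joint[altitude_col].to_numpy(dtype=float)
    ind = (joint["_group"] == groups[1]).to_numpy(dtype=float)
    y = joint[phenotype].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(alt), alt, ind, alt * ind])
    if np.linalg.matrix_rank(X) < X.shape[1] or len(y) <= X.shape[1]:
        return BluntingResult(slopes, np.nan, np.nan, np.nan, groups)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[3, 3]))
    t = float(beta[3] / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return BluntingResult(slopes, float(beta[3]), se, p, groups)


def reference_range(values, k: float = 1.0) -> tuple[float, float]:
    """(mean, k*SD) reference interval for a phenotype.

    The SD multiple is configurable; k = 1 reproduces the common
    ``mean +/- SD`` convention for wide field samples.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("reference_range requires at least 3 values")
    return float(v.mean()), float(k * v.std(ddof=1))
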