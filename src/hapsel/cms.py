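"""Composite-of-signals scoring.

Combines the five standardized per-SNP selection statistics into one
composite score via log-likelihood ratios of calibrated score densities
(selected vs neutral class), and derives the genome-wide top-quantile
significance threshold.

The composite for a SNP with k defined components (k >= ``min_components``)
is (S/k) * sum(LLR_i) over the defined components, S being the number of
configured statistics, so scores stay comparable when some components are
undefined. The absolute scale depends on the calibration and is recorded in
the distribution metadata; significance is always by genome-wide quantile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hapsel.popgen import ALL_STATS

DEFAULT_N_BINS = 64
DEFAULT_MIN_VALUES = 500

#: tail direction in which each statistic moves under a (derived) sweep
SWEEP_TAIL = {"fst": "high", "ihs": "low", "xpehh": "high", "dihh": "high", "nsl": "low"}


@dataclass
class StatDensity:
    """Binned densities of one statistic under selection and neutrality."""

    edges: np.ndarray  # len n_bins + 1
    f_sel: np.ndarray  # len n_bins, integrates to 1
    f_neu: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.f_sel = np.asarray(self.f_sel, dtype=float)
        self.f_neu = np.asarray(self.f_neu, dtype=float)
        widths = np.diff(self.edges)
        for name, f in (("f_sel", self.f_sel), ("f_neu", self.f_neu)):
            if (f <= 0).any():
                raise ValueError(f"{name} must be strictly positive (floored)")
            if abs(float((f * widths).sum()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must integrate to 1")

    def llr(self, values) -> np.ndarray:
        """ln(f_sel / f_neu) at each value; out-of-range values use the edge
        bin; NaN propagates."""
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, np.nan)
        ok = np.isfinite(v)
        idx = np.searchsorted(self.edges, v[ok], side="right") - 1
        idx = np.clip(idx, 0, len(self.f_sel) - 1)
        out[ok] = np.log(self.f_sel[idx] / self.f_neu[idx])
        return out


@dataclass
class ScoreDistributions:
    """Per-statistic calibrated densities plus calibration metadata."""

    stats: dict  # name -> StatDensity
    meta: dict = field(default_factory=dict)

    @property
    def n_stats(self) -> int:
        return len(self.stats)

    def to_json(self, path) -> None:
        payload = {
            "meta": self.meta,
            "stats": {
                name: {
                    "edges": d.edges.tolist(),
                    "f_sel": d.f_sel.tolist(),
                    "f_neu": d.f_neu.tolist(),
                }
                for name, d in self.stats.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ScoreDistributions":
        with open(path) as fh:
            payload = json.load(fh)
        stats = {
            name: StatDensity(
                edges=np.asarray(d["edges"]),
                f_sel=np.asarray(d["f_sel"]),
                f_neu=np.asarray(d["f_neu"]),
            )
            for name, d in payload["stats"].items()
        }
        return cls(stats=stats, meta=payload.get("meta", {}))


def _fit_density(values: np.ndarray, edges: np.ndarray, eps: float) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    widths = np.diff(edges)
    dens = counts / (counts.sum() * widths)
    dens = np.maximum(dens, eps)
    dens /= float((dens * widths).sum())
    return dens


def calibrate_from_values(
    sel_values: dict,
    neu_values: dict,
    n_bins: int = DEFAULT_N_BINS,
    min_values: int = DEFAULT_MIN_VALUES,
    meta: dict | None = None,
) -> ScoreDistributions:
    """Fit per-statistic histogram densities for the selected and neutral
    classes over their pooled range, with an empty-bin floor of 1/(10 n)."""
    stats = {}
    for name in sel_values:
        sel = np.asarray(sel_values[name], dtype=float)
        neu = np.asarray(neu_values[name], dtype=float)
        sel = sel[np.isfinite(sel)]
        neu = neu[np.isfinite(neu)]
        if len(sel) < min_values or len(neu) < min_values:
            raise ValueError(
                f"insufficient calibration values for {name!r}: "
                f"{len(sel)} selected / {len(neu)} neutral (need {min_values})"
            )
        lo = min(sel.min(), neu.min())
        hi = max(sel.max(), neu.max())
        if hi == lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
        stats[name] = StatDensity(
            edges=edges,
            f_sel=_fit_density(sel, edges, eps=1.0 / (10.0 * len(sel))),
            f_neu=_fit_density(neu, edges, eps=1.0 / (10.0 * len(neu))),
        )
    full_meta = {"source": "values", "n_bins": n_bins}
    full_meta.update(meta or {})
    full_meta["n_values"] = {
        name: {"sel": int(np.isfinite(np.asarray(sel_values[name], float)).sum()),
               "neu": int(np.isfinite(np.asarray(neu_values[name], float)).sum())}
        for name in sel_values
    }
    return ScoreDistributions(stats=stats, meta=full_meta)


def calibrate(
    neutral_scores: list,
    sweep_scores: list,
    stats: tuple = ALL_STATS,
    flank_bp: int = 50_000,
    n_bins: int = DEFAULT_N_BINS,
    min_values: int = DEFAULT_MIN_VALUES,
    meta: dict | None = None,
) -> ScoreDistributions:
    """Calibrate score densities from labeled score tables.

    ``neutral_scores`` is a list of SiteScores DataFrames from neutral
    simulations; ``sweep_scores`` a list of ``(scores_df, sweep_pos)`` pairs
    from sweep simulations. Selected-class values are taken at the sweep
    site and its ``flank_bp`` flank; neutral-class values at all defined
    neutral sites.
    """
    sel_values = {name: [] for name in stats}
    neu_values = {name: [] for name in stats}
    for df in neutral_scores:
        for name in stats:
            if name in df.columns:
                neu_values[name].append(df[name].to_numpy(dtype=float))
    for df, sweep_pos in sweep_scores:
        near = (df["pos"] - sweep_pos).abs() <= flank_bp
        sub = df.loc[near]
        for name in stats:
            if name in sub.columns:
                sel_values[name].append(sub[name].to_numpy(dtype=float))
    sel = {n: np.concatenate(v) if v else np.array([]) for n, v in sel_values.items()}
    neu = {n: np.concatenate(v) if v else np.array([]) for n, v in neu_values.items()}
    full_meta = {"source": "simulation", "flank_bp": flank_bp}
    full_meta.update(meta or {})
    return calibrate_from_values(sel, neu, n_bins=n_bins, min_values=min_values, meta=full_meta)


def empirical_tail_calibration(
    scores: pd.DataFrame,
    stats: tuple = ALL_STATS,
    tail: float = 0.01,
    n_bins: int = DEFAULT_N_BINS,
    min_values: int = 10,
) -> ScoreDistributions:
    """Fallback calibration without simulations: the selected class is
    approximated by the observed sweep-direction top ``tail`` fraction of
    each statistic, the neutral class by all observed values. Documented as
    an approximation."""
    sel = {}
    neu = {}
    for name in stats:
        v = scores[name].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if SWEEP_TAIL[name] == "high":
            thr = np.quantile(v, 1 - tail)
            sel[name] = v[v >= thr]
        else:
            thr = np.quantile(v, tail)
            sel[name] = v[v <= thr]
        neu[name] = v
    return calibrate_from_values(
        sel, neu, n_bins=n_bins, min_values=min_values,
        meta={"source": "empirical-tail", "tail": tail},
    )


def cms_score(
    site_scores: pd.DataFrame,
    dists: ScoreDistributions,
    min_components: int = 3,
    llr_cap: float | None = None,
) -> pd.DataFrame:
    """Per-SNP composite score from component log-likelihood ratios.

    Adds ``llr_<stat>`` columns, ``k`` (defined components) and ``cms``
    (= (S/k) * sum LLR, S the number of calibrated statistics; NaN where
    k < ``min_components``). ``llr_cap`` clips each component LLR to
    [-cap, cap]: with few calibration values the density tails are
    undersampled and sit on the epsilon floor, so uncapped ratios there
    reflect sample size, not evidence.
    """
    out = site_scores.copy()
    llrs = []
    for name, dens in dists.stats.items():
        if name not in out.columns:
            out[f"llr_{name}"] = np.nan
        else:
            llr = dens.llr(out[name].to_numpy(dtype=float))
            if llr_cap is not None:
                llr = np.clip(llr, -llr_cap, llr_cap)
            out[f"llr_{name}"] = llr
        llrs.append(out[f"llr_{name}"].to_numpy(dtype=float))
    L = np.vstack(llrs)  # (S, n)
    k = np.isfinite(L).sum(axis=0)
    total = np.nansum(np.where(np.isfinite(L), L, 0.0), axis=0)
    S = dists.n_stats
    with np.errstate(divide="ignore", invalid="ignore"):
        cms = np.where(k >= min_components, (S / np.maximum(k, 1)) * total, np.nan)
    out["k"] = k
    out["cms"] = cms
    return out


def genome_threshold(cms_values, q: float = 0.001) -> tuple[float, np.ndarray]:
    """Empirical (1-q) quantile of the defined composite scores (type-7
    interpolation) and the >= flags for every input value (NaN -> False)."""
    v = np.asarray(cms_values, dtype=float)
    defined = v[np.isfinite(v)]
    if len(defined) == 0:
        raise ValueError("no defined composite scores")
    if q <= 0 or q > 1:
        raise ValueError("q must be in (0, 1]")
    if len(defined) < 1.0 / q:
        warnings.warn(
            f"only {len(defined)} defined scores for q={q}; threshold is noisy",
            stacklevel=2,
        )
    threshold = float(np.quantile(defined, 1.0 - q))
    with np.errstate(invalid="ignore"):
        flags = np.where(np.isfinite(v), v >= threshold, False)
    return threshold, flags.astype(bool)


@dataclass
class CMSResult:
    """Composite-score table with its genome-wide threshold."""

    table: pd.DataFrame  # includes llr_*, k, cms, is_significant
    threshold: float
    q: float

    @classmethod
    def from_scores(
        cls,
        site_scores: pd.DataFrame,
        dists: ScoreDistributions,
        q: float = 0.001,
        min_components: int = 3,
        llr_cap: float | None = None,
    ) -> "CMSResult":
        table = cms_score(site_scores, dists, min_components=min_components,
                          llr_cap=llr_cap)
        threshold, flags = genome_threshold(table["cms"].to_numpy(), q=q)
        table["is_significant"] = flags
        return cls(table=table, threshold=threshold, q=q)

    @property
    def n_undefined(self) -> int:
        return int((~np.isfinite(self.table["cms"].to_numpy(dtype=float))).sum())
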