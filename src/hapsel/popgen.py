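"""Per-SNP selection statistics on phased haplotype panels.

Implements allele frequencies, two FST estimators, EHH curves and their
integrals (iHH), and the haplotype scan statistics iHS, XPEHH, dIHH and nSL,
with derived-allele-frequency-bin standardization.

Distances for iHH integration are physical (bp). EHH walks stop at
chromosome ends and at inter-site gaps larger than ``max_gap_bp`` (default
200 kb); integration stops where EHH drops below a cutoff (default 0.05),
interpolating the crossing point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from hapsel.io_qc import HaplotypePanel

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000
DEFAULT_MIN_MAF = 0.05

#: statistics computed by :func:`compute_scores`
ALL_STATS = ("fst", "ihs", "xpehh", "dihh", "nsl")


@dataclass
class AlleleFreq:
    p: float  # derived (or alt) allele frequency
    n: int  # number of sampled alleles

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {self.p}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def allele_freq(panel: HaplotypePanel, site_index: int) -> AlleleFreq:
    """Derived-allele (or alt-allele) frequency at one site."""
    col = panel.haplotypes[:, site_index]
    return AlleleFreq(p=float(col.mean()), n=panel.n_hap)


def fst_pair(
    p1: AlleleFreq,
    p2: AlleleFreq,
    estimator: str = "hudson",
    clip: bool = False,
) -> float:
    """Per-site FST between two populations from allele frequencies.

    Hudson's estimator by default; ``weir_cockerham`` gives the
    two-population single-locus theta-hat from allele-count variance
    components. Negative estimates are reported as computed unless ``clip``.
    Returns NaN when the estimator is undefined (both populations fixed for
    the same allele).
    """
    a1, n1 = p1.p, p1.n
    a2, n2 = p2.p, p2.n
    if estimator == "hudson":
        num = (a1 - a2) ** 2 - a1 * (1 - a1) / (n1 - 1) - a2 * (1 - a2) / (n2 - 1)
        den = a1 * (1 - a2) + a2 * (1 - a1)
        if den == 0:
            return math.nan
        val = num / den
    elif estimator == "weir_cockerham":
        r = 2
        n_tot = n1 + n2
        n_bar = n_tot / r
        n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1)
        p_bar = (n1 * a1 + n2 * a2) / n_tot
        s2 = (n1 * (a1 - p_bar) ** 2 + n2 * (a2 - p_bar) ** 2) / ((r - 1) * n_bar)
        inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * inner
        if a + b == 0:
            return math.nan
        val = a / (a + b)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return max(0.0, val) if clip else val


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------


@dataclass
class EHHCurve:
    """One side of an EHH decay curve around a core site."""

    core_index: int
    side: str  # 'left' | 'right'
    distances: np.ndarray  # bp offsets from core, starting at 0, increasing
    ehh: np.ndarray  # values in [0,1]; ehh[0] == 1
    truncated: bool = False  # ended at chromosome end / max gap while EHH > 0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.ehh = np.asarray(self.ehh, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.distances) != len(self.ehh):
            raise ValueError("distances/ehh length mismatch")


_WALK_BLOCK = 64


@lru_cache(maxsize=64)
def _pair_indices(c: int) -> tuple:
    pi, pj = np.triu_indices(c, 1)
    pi.setflags(write=False)
    pj.setflags(write=False)
    return pi, pj


def _walk_pairs(
    sub: np.ndarray,
    core: int,
    step: int,
    stop_count: float,
    positions: np.ndarray | None = None,
    max_gap_bp: int | None = None,
    pair_masks: list | None = None,
):
    """Outward walk tracking which haplotype pairs stay identical.

    ``sub`` holds the walked haplotypes (rows); pairs that differ at any
    visited site die. Sites are processed in blocks; the walk records, per
    visited site, the number of still-identical pairs (for each mask in
    ``pair_masks``, or over all pairs when None) and stops after recording a
    total count < ``stop_count`` (use 0.5 to stop only at zero), at the
    chromosome end, or before a gap larger than ``max_gap_bp``.

    Returns (site_indices, counts, truncated): counts has one row per mask
    (or a single row); truncated means the walk ended at an end/gap while
    pairs were still alive above the stopping threshold.
    """
    c, m = sub.shape
    pi, pj = _pair_indices(c)
    if pair_masks is None:
        masks = [np.ones(len(pi), dtype=bool)]
    else:
        masks = pair_masks
    alive = np.arange(len(pi))
    out_sites: list[int] = []
    out_counts: list[list[float]] = [[] for _ in masks]
    prev_pos = positions[core] if positions is not None else None
    j = core + step
    while 0 <= j < m:
        # adaptive block: long walks survive on few pairs, so grow the block
        # to amortize per-block overhead while keeping work ~ alive x block
        block = int(np.clip(8 * _WALK_BLOCK * _WALK_BLOCK // max(len(alive), 1),
                            _WALK_BLOCK, 4096))
        if step > 0:
            cols = np.arange(j, min(j + block, m))
        else:
            cols = np.arange(j, max(j - block, -1), -1)
        if positions is not None and max_gap_bp is not None:
            gaps = np.abs(np.diff(np.concatenate([[prev_pos], positions[cols]])))
            bad = np.nonzero(gaps > max_gap_bp)[0]
            if len(bad):
                cols = cols[: bad[0]]
                if len(cols) == 0:
                    return out_sites, np.asarray(out_counts, dtype=float), True
        blk = sub[:, cols]
        E = blk[pi[alive]] == blk[pj[alive]]
        C = np.logical_and.accumulate(E, axis=1)
        total = C.sum(axis=0)
        below = np.nonzero(total < stop_count)[0]
        upto = below[0] + 1 if len(below) else len(cols)
        for mask, acc in zip(masks, out_counts):
            if pair_masks is None:
                acc.extend(total[:upto].tolist())
            else:
                acc.extend(C[mask[alive]].sum(axis=0)[:upto].tolist())
        out_sites.extend(cols[:upto].tolist())
        if len(below):
            return out_sites, np.asarray(out_counts, dtype=float), False
        alive = alive[C[:, -1]]
        if positions is not None:
            prev_pos = positions[cols[-1]]
        j = int(cols[-1]) + step
    return out_sites, np.asarray(out_counts, dtype=float), True


def ehh(
    panel: HaplotypePanel,
    core_index: int,
    core_allele: int,
    direction: str,
    stop_below: float | None = None,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> EHHCurve:
    """Extended haplotype homozygosity around a core allele, one direction.

    At offset x, EHH(x) is the fraction of carrier haplotype pairs identical
    over every site from the core through x. The curve always starts at
    (0, 1). Walking stops at the chromosome end, at a gap between adjacent
    sites larger than ``max_gap_bp`` (curve marked truncated), when EHH
    reaches 0, or (if ``stop_below`` is set) once EHH < ``stop_below``.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    H = panel.haplotypes
    positions = panel.positions
    carriers = H[:, core_index] == core_allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError(
            f"fewer than 2 haplotypes carry allele {core_allele} at site {core_index}"
        )
    sub = H[carriers]
    denom = n * (n - 1) // 2
    step = -1 if direction == "left" else 1
    # 0.5 stops only once EHH reaches exactly 0
    stop_count = 0.5 if stop_below is None else max(stop_below * denom, 0.5)
    sites, counts, truncated = _walk_pairs(
        sub, core_index, step, stop_count, positions, max_gap_bp
    )
    core_pos = int(positions[core_index])
    distances = np.concatenate(
        [[0.0], np.abs(positions[np.asarray(sites, dtype=int)] - core_pos)]
    ) if sites else np.asarray([0.0])
    values = np.concatenate([[1.0], counts[0] / denom]) if sites else np.asarray([1.0])
    return EHHCurve(
        core_index=core_index,
        side=direction,
        distances=np.asarray(distances),
        ehh=np.asarray(values),
        truncated=truncated,
    )


def _integrate_side(curve: EHHCurve, cutoff: float) -> tuple[float, bool]:
    """Trapezoidal integral of one EHH side out to the cutoff crossing.

    Returns (area, truncated): truncated is True when the curve never drops
    below ``cutoff`` before its end.
    """
    d, e = curve.distances, curve.ehh
    if len(d) < 2:
        return 0.0, True
    below = np.nonzero(e[1:] < cutoff)[0]
    if not len(below):
        return float(np.trapezoid(e, d)), True
    i = int(below[0]) + 1  # first point below the cutoff
    area = float(np.trapezoid(e[:i], d[:i]))
    # interpolate the crossing point where EHH == cutoff
    f = (e[i - 1] - cutoff) / (e[i - 1] - e[i])
    x_star = d[i - 1] + f * (d[i] - d[i - 1])
    area += 0.5 * (e[i - 1] + cutoff) * (x_star - d[i - 1])
    return area, False


def ihh(
    curve_left: EHHCurve,
    curve_right: EHHCurve,
    cutoff: float = DEFAULT_CUTOFF,
    on_truncated: str = "keep",
) -> float:
    """Integrated EHH: trapezoidal area under both sides of the curve.

    Each side is integrated from the core outward until EHH first drops
    below ``cutoff`` (interpolating the crossing), then the two sides are
    summed. If a side never drops below the cutoff before its end the iHH is
    flagged truncated and either kept (default) or returned as NaN
    (``on_truncated='drop'``).
    """
    if curve_left.core_index != curve_right.core_index:
        raise ValueError("curves must share a core site")
    if on_truncated not in ("keep", "drop"):
        raise ValueError("on_truncated must be 'keep' or 'drop'")
    left, trunc_l = _integrate_side(curve_left, cutoff)
    right, trunc_r = _integrate_side(curve_right, cutoff)
    truncated = trunc_l or trunc_r
    if truncated and on_truncated == "drop":
        return math.nan
    return left + right


def _ihh_at(
    panel: HaplotypePanel,
    site_index: int,
    core_allele: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> float:
    """iHH for one core allele, walking only as far as the cutoff needs."""
    left = ehh(panel, site_index, core_allele, "left", stop_below=cutoff, max_gap_bp=max_gap_bp)
    right = ehh(panel, site_index, core_allele, "right", stop_below=cutoff, max_gap_bp=max_gap_bp)
    return ihh(left, right, cutoff=cutoff)


# ---------------------------------------------------------------------------
# standardization bins
# ---------------------------------------------------------------------------


@dataclass
class StandardizationBins:
    """DAF bins with per-bin mean/SD of an unstandardized statistic."""

    edges: np.ndarray  # merged bin edges, len = n_bins + 1, spanning [0, 1]
    means: np.ndarray
    sds: np.ndarray  # population SD (ddof=0)
    counts: np.ndarray

    def bin_of(self, daf) -> np.ndarray:
        idx = np.searchsorted(self.edges, daf, side="right") - 1
        return np.clip(idx, 0, len(self.means) - 1)

    def standardize(self, values, dafs) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        idx = self.bin_of(np.asarray(dafs, dtype=float))
        mu = self.means[idx]
        sd = self.sds[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (values - mu) / sd
        out[~np.isfinite(out)] = np.nan
        return out


def build_bins(
    values,
    dafs,
    bin_width: float = 0.02,
    min_count: int = 20,
) -> StandardizationBins:
    """Equal-width DAF bins, merged left-to-right until each holds
    ``min_count`` defined values; per-bin mean and SD stored."""
    values = np.asarray(values, dtype=float)
    dafs = np.asarray(dafs, dtype=float)
    ok = np.isfinite(values) & np.isfinite(dafs)
    values, dafs = values[ok], dafs[ok]
    if len(values) == 0:
        raise ValueError("no defined values to bin")
    if len(values) < min_count:
        min_count = len(values)

    n_raw = int(round(1.0 / bin_width))
    raw_edges = np.linspace(0.0, 1.0, n_raw + 1)
    raw_idx = np.clip(np.searchsorted(raw_edges, dafs, side="right") - 1, 0, n_raw - 1)
    raw_counts = np.bincount(raw_idx, minlength=n_raw)

    # greedy left-to-right merge
    merged_edges = [0.0]
    acc = 0
    for b in range(n_raw):
        acc += raw_counts[b]
        if acc >= min_count:
            merged_edges.append(raw_edges[b + 1])
            acc = 0
    if merged_edges[-1] < 1.0:
        if len(merged_edges) > 1 and acc < min_count:
            merged_edges[-1] = 1.0  # fold the small tail into the last bin
        else:
            merged_edges.append(1.0)
    edges = np.asarray(merged_edges)

    idx = np.clip(np.searchsorted(edges, dafs, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(values[sel].mean())
            sds[b] = float(values[sel].std(ddof=0))
    return StandardizationBins(edges=edges, means=means, sds=sds, counts=counts)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def _check_site_usable(panel: HaplotypePanel, site_index: int, min_maf: float) -> None:
    if panel.sites[site_index].ancestral == "unknown":
        raise ValueError(f"ancestral allele unknown at site {site_index}")
    p = panel.derived_freq(site_index)
    if min(p, 1 - p) < min_maf:
        raise ValueError(f"MAF below {min_maf} at site {site_index}")


def ihs_unstandardized(
    panel: HaplotypePanel,
    site_index: int,
    min_maf: float = DEFAULT_MIN_MAF,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> float:
    """u = ln(iHH_ancestral / iHH_derived); NaN when either iHH is 0/undefined."""
    _check_site_usable(panel, site_index, min_maf)
    try:
        ihh_a = _ihh_at(panel, site_index, 0, cutoff, max_gap_bp)
        ihh_d = _ihh_at(panel, site_index, 1, cutoff, max_gap_bp)
    except ValueError:
        return math.nan
    if not (ihh_a > 0 and ihh_d > 0):
        return math.nan
    return math.log(ihh_a / ihh_d)


def ihs(panel: HaplotypePanel, site_index: int, bins: StandardizationBins, **kw) -> float:
    u = ihs_unstandardized(panel, site_index, **kw)
    daf = panel.derived_freq(site_index)
    return float(bins.standardize([u], [daf])[0])


def dihh_unstandardized(
    panel: HaplotypePanel,
    site_index: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> float:
    """Delta = iHH_derived - iHH_ancestral (positive under a derived sweep)."""
    if panel.sites[site_index].ancestral == "unknown":
        raise ValueError(f"ancestral allele unknown at site {site_index}")
    try:
        ihh_a = _ihh_at(panel, site_index, 0, cutoff, max_gap_bp)
        ihh_d = _ihh_at(panel, site_index, 1, cutoff, max_gap_bp)
    except ValueError:
        return math.nan
    return ihh_d - ihh_a


def dihh(panel: HaplotypePanel, site_index: int, bins: StandardizationBins, **kw) -> float:
    u = dihh_unstandardized(panel, site_index, **kw)
    daf = panel.derived_freq(site_index)
    return float(bins.standardize([u], [daf])[0])


def sl_mean(panel: HaplotypePanel, site_index: int, core_allele: int) -> float:
    """Mean, over carrier pairs, of the number of consecutive sites
    (counting the core, extended both directions) over which the pair is
    identical. Capped at chromosome ends."""
    H = panel.haplotypes
    carriers = H[:, site_index] == core_allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError(f"fewer than 2 carriers of allele {core_allele}")
    sub = H[carriers]
    denom = n * (n - 1) // 2
    total = float(denom)  # the core site counts once for every pair
    for step in (-1, 1):
        _, counts, _ = _walk_pairs(sub, site_index, step, stop_count=0.5)
        total += float(counts[0].sum())
    return total / denom


def nsl_unstandardized(
    panel: HaplotypePanel,
    site_index: int,
    min_maf: float = DEFAULT_MIN_MAF,
) -> float:
    """u = ln(SL_ancestral / SL_derived); NaN when a class has < 2 carriers."""
    _check_site_usable(panel, site_index, min_maf)
    try:
        sl_a = sl_mean(panel, site_index, 0)
        sl_d = sl_mean(panel, site_index, 1)
    except ValueError:
        return math.nan
    if not (sl_a > 0 and sl_d > 0):
        return math.nan
    return math.log(sl_a / sl_d)


def nsl(panel: HaplotypePanel, site_index: int, bins: StandardizationBins, **kw) -> float:
    u = nsl_unstandardized(panel, site_index, **kw)
    daf = panel.derived_freq(site_index)
    return float(bins.standardize([u], [daf])[0])


def _xpehh_side(
    H_t: np.ndarray,
    H_r: np.ndarray,
    positions: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
    max_gap_bp: int,
) -> tuple[float, float]:
    """One-sided iHH for target and reference, truncated where the pooled
    (both populations together) EHH first drops below ``cutoff``; the common
    stopping point is interpolated and applied to both populations."""
    n_t, n_r = H_t.shape[0], H_r.shape[0]
    den_t = n_t * (n_t - 1) / 2
    den_r = n_r * (n_r - 1) / 2
    n_p = n_t + n_r
    den_p = n_p * (n_p - 1) / 2
    core_pos = int(positions[core])

    if n_p * (n_p - 1) // 2 <= 6000:
        # block pair-walk (vectorized) — fastest for modest panel sizes
        pooled = np.vstack([H_t, H_r])
        pi, pj = _pair_indices(n_p)
        mask_t = (pi < n_t) & (pj < n_t)
        mask_r = (pi >= n_t) & (pj >= n_t)
        sites, counts, _ = _walk_pairs(
            pooled, core, step,
            stop_count=max(cutoff * den_p, 0.5),
            positions=positions,
            max_gap_bp=max_gap_bp,
            pair_masks=[mask_t, mask_r, np.ones(len(pi), dtype=bool)],
        )

        def values(idx):
            return (
                counts[0, idx] / den_t,
                counts[1, idx] / den_r,
                counts[2, idx] / den_p,
            )

        steps = [(int(positions[j]), *values(i)) for i, j in enumerate(sites)]
    else:
        # shared group partition, O(n) per step — scales to large pools
        pooled = np.vstack([H_t, H_r])
        gid = np.zeros(n_p, dtype=np.int64)
        steps = []
        prev_pos = core_pos
        m = len(positions)
        j = core + step
        while 0 <= j < m:
            pos = int(positions[j])
            if abs(pos - prev_pos) > max_gap_bp:
                break
            gid = np.unique(gid * 2 + pooled[:, j], return_inverse=True)[1]
            n_groups = int(gid.max()) + 1
            ct = np.bincount(gid[:n_t], minlength=n_groups)
            cr = np.bincount(gid[n_t:], minlength=n_groups)
            cp = ct + cr
            e_t = float((ct * (ct - 1)).sum()) / 2.0 / den_t
            e_r = float((cr * (cr - 1)).sum()) / 2.0 / den_r
            e_p = float((cp * (cp - 1)).sum()) / 2.0 / den_p
            steps.append((pos, e_t, e_r, e_p))
            if e_p < cutoff or e_p == 0.0:
                break
            prev_pos = pos
            j += step

    area_t = area_r = 0.0
    prev_d, prev_t, prev_r, prev_p = 0.0, 1.0, 1.0, 1.0
    for pos, e_t, e_r, e_p in steps:
        d = abs(pos - core_pos)
        if e_p < cutoff:
            f = (prev_p - cutoff) / (prev_p - e_p)
            x_star = prev_d + f * (d - prev_d)
            t_star = prev_t + f * (e_t - prev_t)
            r_star = prev_r + f * (e_r - prev_r)
            area_t += 0.5 * (prev_t + t_star) * (x_star - prev_d)
            area_r += 0.5 * (prev_r + r_star) * (x_star - prev_d)
            return area_t, area_r
        area_t += 0.5 * (prev_t + e_t) * (d - prev_d)
        area_r += 0.5 * (prev_r + e_r) * (d - prev_d)
        if e_p == 0.0:
            return area_t, area_r
        prev_d, prev_t, prev_r, prev_p = d, e_t, e_r, e_p
    return area_t, area_r


def xpehh_unstandardized(
    panel_target: HaplotypePanel,
    panel_ref: HaplotypePanel,
    site_index: int,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> float:
    """u = ln(iHH_target / iHH_ref) from all haplotypes of each panel around
    the site, with a common pooled-EHH stopping point for both populations.
    Panels must cover the same sites."""
    if panel_target.n_sites != panel_ref.n_sites:
        raise ValueError("panels must cover the same sites")
    positions = panel_target.positions
    if not np.array_equal(positions, panel_ref.positions):
        raise ValueError("panel site positions differ")
    H_t = panel_target.haplotypes
    H_r = panel_ref.haplotypes
    lt, lr = _xpehh_side(H_t, H_r, positions, site_index, -1, cutoff, max_gap_bp)
    rt, rr = _xpehh_side(H_t, H_r, positions, site_index, 1, cutoff, max_gap_bp)
    ihh_t = lt + rt
    ihh_r = lr + rr
    if not (ihh_t > 0 and ihh_r > 0):
        return math.nan
    return math.log(ihh_t / ihh_r)


# spec-facing aliases: the per-site ops return the unstandardized statistic;
# genome-wide standardization happens in compute_scores
xpehh = xpehh_unstandardized


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


@dataclass
class ScoreConfig:
    stats: tuple = ALL_STATS
    min_maf: float = DEFAULT_MIN_MAF
    cutoff: float = DEFAULT_CUTOFF
    max_gap_bp: int = DEFAULT_MAX_GAP_BP
    bin_width: float = 0.02
    min_bin_count: int = 20
    fst_estimator: str = "hudson"
    ref_as_ancestral: bool = False  # override: treat ref allele as ancestral

    def to_dict(self) -> dict:
        return {
            "stats": list(self.stats),
            "min_maf": self.min_maf,
            "cutoff": self.cutoff,
            "max_gap_bp": self.max_gap_bp,
            "bin_width": self.bin_width,
            "min_bin_count": self.min_bin_count,
            "fst_estimator": self.fst_estimator,
            "ref_as_ancestral": self.ref_as_ancestral,
        }


def compute_scores(
    panel_target: HaplotypePanel,
    panel_ref: HaplotypePanel,
    panel_ref2: HaplotypePanel | None = None,
    config: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-SNP SiteScores table for the target population.

    Columns: chrom, pos, id, daf, fst (vs ``panel_ref``; plus fst_ref2 when a
    second reference is given), ihs, xpehh, dihh, nsl (standardized;
    ``*_unstd`` columns carry the raw values). Undefined entries are NaN.
    iHS/nSL/dIHH require a known ancestral allele; iHS/nSL additionally
    require MAF >= ``config.min_maf``. XPEHH is computed at every site
    segregating in either population and standardized genome-wide.
    """
    cfg = config or ScoreConfig()
    m = panel_target.n_sites
    sites = panel_target.sites

    if cfg.ref_as_ancestral:
        from dataclasses import replace as _replace

        new_sites = [
            _replace(s, ancestral="ref") if s.ancestral == "unknown" else s
            for s in sites
        ]
        panel_target = HaplotypePanel.from_alt_coded(
            panel_target.alt_coded(), new_sites,
            panel_target.sample_of_haplotype, panel_target.population,
        )
        sites = new_sites

    out = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "id": [s.id for s in sites],
        }
    )
    daf = panel_target.haplotypes.mean(axis=0)
    out["daf"] = daf

    anc_known = np.asarray([s.ancestral != "unknown" for s in sites])
    maf = np.minimum(daf, 1 - daf)

    if "fst" in cfg.stats:
        fst = np.full(m, np.nan)
        fst2 = np.full(m, np.nan)
        p_ref = panel_ref.haplotypes.mean(axis=0)
        p_ref2 = panel_ref2.haplotypes.mean(axis=0) if panel_ref2 is not None else None
        # fst is computed on a common allele (alt/derived coding is shared
        # across panels because sites are shared)
        for j in range(m):
            fst[j] = fst_pair(
                AlleleFreq(float(daf[j]), panel_target.n_hap),
                AlleleFreq(float(p_ref[j]), panel_ref.n_hap),
                estimator=cfg.fst_estimator,
            )
            if p_ref2 is not None:
                fst2[j] = fst_pair(
                    AlleleFreq(float(daf[j]), panel_target.n_hap),
                    AlleleFreq(float(p_ref2[j]), panel_ref2.n_hap),
                    estimator=cfg.fst_estimator,
                )
        out["fst"] = fst
        if panel_ref2 is not None:
            out["fst_ref2"] = fst2

    if "ihs" in cfg.stats or "dihh" in cfg.stats:
        ihh_a = np.full(m, np.nan)
        ihh_d = np.full(m, np.nan)
        for j in range(m):
            if not anc_known[j] or maf[j] == 0:
                continue
            try:
                ihh_a[j] = _ihh_at(panel_target, j, 0, cfg.cutoff, cfg.max_gap_bp)
                ihh_d[j] = _ihh_at(panel_target, j, 1, cfg.cutoff, cfg.max_gap_bp)
            except ValueError:
                continue
        out["ihh_A"] = ihh_a
        out["ihh_D"] = ihh_d

    if "ihs" in cfg.stats:
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(
                (out["ihh_A"] > 0) & (out["ihh_D"] > 0) & (maf >= cfg.min_maf),
                np.log(out["ihh_A"] / out["ihh_D"]),
                np.nan,
            )
        out["ihs_unstd"] = u
        out["ihs"] = _bin_standardize(u, daf, cfg)

    if "dihh" in cfg.stats:
        u = np.where(
            np.isfinite(out["ihh_A"]) & np.isfinite(out["ihh_D"]),
            out["ihh_D"] - out["ihh_A"],
            np.nan,
        )
        out["dihh_unstd"] = u
        out["dihh"] = _bin_standardize(u, daf, cfg)

    if "nsl" in cfg.stats:
        u = np.full(m, np.nan)
        for j in range(m):
            if not anc_known[j] or maf[j] < cfg.min_maf:
                continue
            try:
                u[j] = nsl_unstandardized(panel_target, j, min_maf=cfg.min_maf)
            except ValueError:
                continue
        out["nsl_unstd"] = u
        out["nsl"] = _bin_standardize(u, daf, cfg)

    if "xpehh" in cfg.stats:
        p_ref = panel_ref.haplotypes.mean(axis=0)
        u = np.full(m, np.nan)
        for j in range(m):
            seg_t = 0 < daf[j] < 1
            seg_r = 0 < p_ref[j] < 1
            if not (seg_t or seg_r):
                continue
            u[j] = xpehh_unstandardized(
                panel_target, panel_ref, j, cfg.cutoff, cfg.max_gap_bp
            )
        out["xpehh_unstd"] = u
        ok = np.isfinite(u)
        if ok.sum() >= 2 and np.nanstd(u) > 0:
            out["xpehh"] = (u - np.nanmean(u)) / np.nanstd(u)
        else:
            out["xpehh"] = np.nan

    return out


def _bin_standardize(u: np.ndarray, daf: np.ndarray, cfg: ScoreConfig) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if not np.isfinite(u).any():
        return np.full_like(u, np.nan)
    bins = build_bins(u, daf, bin_width=cfg.bin_width, min_count=cfg.min_bin_count)
    return bins.standardize(u, daf)
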