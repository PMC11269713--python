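import math

import numpy as np
import pytest

from hapsel import popgen
from hapsel.popgen import (
    AlleleFreq,
    EHHCurve,
    ScoreConfig,
    allele_freq,
    build_bins,
    compute_scores,
    dihh_unstandardized,
    ehh,
    fst_pair,
    ihh,
    ihs_unstandardized,
    nsl_unstandardized,
    sl_mean,
    xpehh_unstandardized,
)

from conftest import make_panel, random_panel


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the walk implementation)
# ---------------------------------------------------------------------------


def ehh_oracle(haps, positions, core, allele, direction):
    """EHH by explicit enumeration of all carrier pairs and span checks."""
    haps = np.asarray(haps)
    carriers = np.nonzero(haps[:, core] == allele)[0]
    c = len(carriers)
    denom = c * (c - 1) / 2
    if direction == "right":
        span = range(core + 1, haps.shape[1])
    else:
        span = range(core - 1, -1, -1)
    dists, vals = [0.0], [1.0]
    for x in span:
        lo, hi = (core, x) if x > core else (x, core)
        ident = 0
        for a in range(c):
            for b in range(a + 1, c):
                if np.array_equal(haps[carriers[a], lo:hi + 1], haps[carriers[b], lo:hi + 1]):
                    ident += 1
        dists.append(abs(positions[x] - positions[core]))
        vals.append(ident / denom)
        if vals[-1] == 0:
            break
    return np.asarray(dists, dtype=float), np.asarray(vals)


def sl_oracle(haps, core, allele):
    """Mean pairwise identical-run length counting the core, per pair."""
    haps = np.asarray(haps)
    carriers = np.nonzero(haps[:, core] == allele)[0]
    m = haps.shape[1]
    total, pairs = 0, 0
    for a in range(len(carriers)):
        for b in range(a + 1, len(carriers)):
            ha, hb = haps[carriers[a]], haps[carriers[b]]
            length = 1  # the core
            j = core - 1
            while j >= 0 and ha[j] == hb[j]:
                length += 1
                j -= 1
            j = core + 1
            while j < m and ha[j] == hb[j]:
                length += 1
                j += 1
            total += length
            pairs += 1
    return total / pairs


# ---------------------------------------------------------------------------
# allele frequency / FST
# ---------------------------------------------------------------------------


def test_allele_freq_fixed_column():
    panel = make_panel(np.ones((10, 1), dtype=np.uint8))
    af = allele_freq(panel, 0)
    assert af.p == 1.0 and af.n == 10


def test_allele_freq_half():
    panel = make_panel(np.array([[1], [0], [1], [0]]))
    assert allele_freq(panel, 0).p == 0.5


def test_allele_freq_diploid_panel_frequency():
    # 60 diploids (120 haplotypes) near frequency 0.83 (closest count: 100)
    col = np.zeros((120, 1), dtype=np.uint8)
    col[: round(0.83 * 120)] = 1
    panel = make_panel(col)
    assert allele_freq(panel, 0).p == pytest.approx(0.83, abs=0.005)
    assert allele_freq(panel, 0).n == 120


def test_fst_equal_freqs_zero():
    # Hudson's estimator subtracts within-population sampling variance, so
    # equal sample frequencies give ~0 only as n grows (slightly negative
    # at finite n)
    small_n = fst_pair(AlleleFreq(0.5, 100), AlleleFreq(0.5, 60))
    assert small_n == pytest.approx(0.0, abs=0.02) and small_n <= 0
    big_n = fst_pair(AlleleFreq(0.5, 100_000), AlleleFreq(0.5, 60_000))
    assert big_n == pytest.approx(0.0, abs=1e-4)


def test_fst_fixed_difference():
    v = fst_pair(AlleleFreq(1.0, 2000), AlleleFreq(0.0, 2000))
    assert v == pytest.approx(1.0, abs=1e-3)


def test_fst_hudson_formula_oracle():
    p1, n1, p2, n2 = 0.97, 120, 0.27, 50
    # independently coded Hudson arithmetic
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    assert fst_pair(AlleleFreq(p1, n1), AlleleFreq(p2, n2)) == pytest.approx(
        num / den, abs=1e-12
    )


def test_fst_undefined_both_fixed_same():
    assert math.isnan(fst_pair(AlleleFreq(0.0, 10), AlleleFreq(0.0, 10)))


def test_fst_negative_reported_unless_clipped():
    a, b = AlleleFreq(0.5, 10), AlleleFreq(0.5, 10)
    assert fst_pair(a, b) < 0
    assert fst_pair(a, b, clip=True) == 0.0


def test_fst_weir_cockerham_drift_free():
    # equal frequencies -> no between-population variance component
    v = fst_pair(AlleleFreq(0.4, 100), AlleleFreq(0.4, 100), estimator="weir_cockerham")
    assert v < 0.01


def test_fst_weir_cockerham_differs_but_close_to_hudson_when_large_n():
    h = fst_pair(AlleleFreq(0.9, 10_000), AlleleFreq(0.2, 10_000))
    w = fst_pair(AlleleFreq(0.9, 10_000), AlleleFreq(0.2, 10_000), estimator="weir_cockerham")
    assert abs(h - w) < 0.05


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------


def test_ehh_identical_carriers_is_one():
    haps = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (4, 1))
    panel = make_panel(haps)
    curve = ehh(panel, 2, 1, "right")
    assert np.all(curve.ehh == 1.0)
    assert curve.truncated  # reached the chromosome end with EHH still 1


def test_ehh_all_distinct_at_first_flank():
    # 4 carriers all distinct at the first flanking site -> EHH = 0 beyond it
    haps = np.array([
        [1, 0, 0],
        [1, 0, 1],
        [1, 1, 0],
        [1, 1, 1],
    ], dtype=np.uint8)
    # make first flank fully distinguishing via two flanking sites is enough:
    curve = ehh(make_panel(haps), 0, 1, "right")
    # after site 1: groups {0,1} vs {2,3}: EHH=2/6; after site 2: all distinct
    assert curve.ehh[1] == pytest.approx(2 / 6)
    assert curve.ehh[2] == 0.0


def test_ehh_worked_fixture_matches_pair_enumeration():
    haps = np.array([
        [0, 1, 1, 0, 1],
        [1, 1, 1, 0, 0],
        [0, 0, 1, 1, 1],
        [1, 0, 1, 1, 0],
        [0, 1, 1, 0, 1],
        [1, 1, 1, 1, 1],
    ], dtype=np.uint8)
    positions = np.array([100, 250, 400, 700, 1200])
    panel = make_panel(haps, positions=positions)
    for direction in ("left", "right"):
        got = ehh(panel, 2, 1, direction)
        d, v = ehh_oracle(haps, positions, 2, 1, direction)
        np.testing.assert_allclose(got.distances[: len(d)], d)
        np.testing.assert_allclose(got.ehh[: len(v)], v, atol=1e-12)


def test_ehh_randomized_exhaustive_oracle(rng):
    """Randomized suite: panels up to 12 haplotypes x 10 sites."""
    for _ in range(40):
        n_hap = int(rng.integers(4, 13)) // 2 * 2
        n_sites = int(rng.integers(3, 11))
        panel = random_panel(rng, n_hap=n_hap, n_sites=n_sites)
        core = int(rng.integers(0, n_sites))
        allele = int(rng.integers(0, 2))
        if (panel.haplotypes[:, core] == allele).sum() < 2:
            continue
        direction = "right" if rng.random() < 0.5 else "left"
        # gap rule disabled: the oracle enumerates across any spacing
        got = ehh(panel, core, allele, direction, max_gap_bp=10**9)
        d, v = ehh_oracle(panel.haplotypes, panel.positions, core, allele, direction)
        np.testing.assert_allclose(got.distances[: len(d)], d)
        np.testing.assert_allclose(got.ehh[: len(v)], v, atol=1e-12)
        assert np.all(np.diff(got.ehh) <= 1e-12)  # non-increasing


def test_ehh_requires_two_carriers():
    haps = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
    with pytest.raises(ValueError, match="fewer than 2"):
        ehh(make_panel(haps), 0, 1, "right")


def test_ehh_max_gap_truncates():
    haps = np.tile(np.array([1, 1, 1], dtype=np.uint8), (4, 1))
    panel = make_panel(haps, positions=[1000, 2000, 300_000])
    curve = ehh(panel, 0, 1, "right", max_gap_bp=200_000)
    assert len(curve.ehh) == 2  # site at 300 kb excluded by the gap rule
    assert curve.truncated


def test_ihh_rectangle():
    left = EHHCurve(0, "left", [0, 500], [1.0, 1.0])
    right = EHHCurve(0, "right", [0, 500], [1.0, 1.0])
    assert ihh(left, right, cutoff=0.0) == pytest.approx(1000.0)


def test_ihh_triangle_drop_to_zero():
    left = EHHCurve(0, "left", [0, 200], [1.0, 0.0])
    right = EHHCurve(0, "right", [0, 200], [1.0, 0.0])
    # cutoff 0: full trapezoids, area 100 each side
    assert ihh(left, right, cutoff=0.0) == pytest.approx(200.0)


def test_ihh_piecewise_linear_hand_integral():
    # hand-integrated: side = [0,100] 1->0.5 (75) + [100,300] 0.5->0.2 (70)
    # cutoff 0.25 crossing between 0.5 and 0.2 at x = 100 + 200*(0.25/0.3)->
    # f=(0.5-0.25)/(0.5-0.2)=5/6; x*=100+200*5/6=266.667; area2=(0.5+0.25)/2*166.667=62.5
    curve = EHHCurve(0, "left", [0, 100, 300], [1.0, 0.5, 0.2])
    flat = EHHCurve(0, "right", [0], [1.0])
    got = ihh(curve, flat, cutoff=0.25)
    assert got == pytest.approx(75.0 + 62.5)


def test_ihh_cutoff_interpolation_matches_fine_grid():
    # trapezoid vs dense numerical integration of the same polyline
    d = np.array([0, 50, 120, 400, 900], dtype=float)
    e = np.array([1.0, 0.8, 0.55, 0.3, 0.01])
    curve = EHHCurve(0, "right", d, e)
    flat = EHHCurve(0, "left", [0], [1.0])
    xs = np.linspace(0, 900, 200_001)
    ys = np.interp(xs, d, e)
    mask = ys >= 0.05
    # numerical area up to the crossing
    num = np.trapezoid(np.where(mask, ys, 0), xs)
    assert ihh(flat, curve, cutoff=0.05) == pytest.approx(num, rel=1e-3)


def test_ihh_requires_shared_core():
    a = EHHCurve(0, "left", [0], [1.0])
    b = EHHCurve(1, "right", [0], [1.0])
    with pytest.raises(ValueError):
        ihh(a, b)


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------


def test_sl_two_identical_haplotypes_full_length():
    m = 7
    haps = np.vstack([np.ones(m), np.ones(m)]).astype(np.uint8)
    assert sl_mean(make_panel(haps), 3, 1) == pytest.approx(m)


def test_sl_four_haplotype_pair_enumeration():
    haps = np.array([
        [1, 1, 0, 1],
        [0, 1, 0, 1],
        [1, 1, 1, 0],
        [0, 1, 1, 1],
    ], dtype=np.uint8)
    got = sl_mean(make_panel(haps), 1, 1)
    assert got == pytest.approx(sl_oracle(haps, 1, 1), abs=1e-12)


def test_sl_randomized_oracle(rng):
    for _ in range(30):
        panel = random_panel(rng, n_hap=int(rng.integers(4, 13)) // 2 * 2,
                             n_sites=int(rng.integers(3, 11)))
        core = int(rng.integers(0, panel.n_sites))
        for allele in (0, 1):
            if (panel.haplotypes[:, core] == allele).sum() < 2:
                continue
            assert sl_mean(panel, core, allele) == pytest.approx(
                sl_oracle(panel.haplotypes, core, allele), abs=1e-12
            )


def test_nsl_symmetric_structure_is_zero():
    # ancestral and derived classes with mirrored haplotype structure
    # derived pair (rows 0,1) and ancestral pair (rows 2,3) see identical
    # flanking structure around the core at index 2
    block = np.array([
        [1, 0, 1, 0, 1],
        [1, 1, 1, 0, 0],
        [1, 0, 0, 0, 1],
        [1, 1, 0, 0, 0],
    ], dtype=np.uint8)
    panel = make_panel(block)
    assert nsl_unstandardized(panel, 2, min_maf=0.0) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# iHS / dIHH symmetric cases
# ---------------------------------------------------------------------------


def test_ihs_symmetric_zero():
    block = np.array([
        [1, 0, 1, 0, 1],
        [1, 1, 1, 0, 0],
        [1, 0, 0, 0, 1],
        [1, 1, 0, 0, 0],
    ], dtype=np.uint8)
    panel = make_panel(block)
    assert ihs_unstandardized(panel, 2, min_maf=0.0) == pytest.approx(0.0, abs=1e-12)
    assert dihh_unstandardized(panel, 2) == pytest.approx(0.0, abs=1e-9)


def test_ihs_requires_known_ancestral():
    panel = make_panel(np.array([[1, 0], [1, 1], [0, 0], [0, 1]]), ancestral="unknown")
    with pytest.raises(ValueError, match="ancestral"):
        ihs_unstandardized(panel, 0)


def test_ihs_respects_min_maf():
    haps = np.zeros((20, 3), dtype=np.uint8)
    haps[0, 1] = 1  # MAF 0.05 at site 1
    panel = make_panel(haps)
    with pytest.raises(ValueError, match="MAF"):
        ihs_unstandardized(panel, 1, min_maf=0.10)


# ---------------------------------------------------------------------------
# XPEHH
# ---------------------------------------------------------------------------


def test_xpehh_identical_panels_zero(rng):
    panel = random_panel(rng, n_hap=10, n_sites=12)
    other = make_panel(panel.haplotypes.copy(), positions=panel.positions, population="REF")
    for j in range(3, 9):
        u = xpehh_unstandardized(panel, other, j)
        if not math.isnan(u):
            assert u == pytest.approx(0.0, abs=1e-12)


def test_xpehh_requires_matching_sites(rng):
    a = random_panel(rng, n_hap=6, n_sites=5)
    b = random_panel(rng, n_hap=6, n_sites=6)
    with pytest.raises(ValueError):
        xpehh_unstandardized(a, b, 2)


def test_xpehh_longer_target_haplotypes_positive():
    # target: all identical around the core; ref: diverse
    m = 9
    target = np.tile(np.array([0, 1, 1, 0, 1, 0, 1, 1, 0], dtype=np.uint8), (8, 1))
    rng = np.random.default_rng(3)
    ref = rng.integers(0, 2, size=(8, m)).astype(np.uint8)
    ref[:, 4] = [1, 1, 1, 1, 0, 0, 0, 0]
    pos = 1000 * (1 + np.arange(m))
    pt = make_panel(target, positions=pos)
    pr = make_panel(ref, positions=pos, population="REF")
    assert xpehh_unstandardized(pt, pr, 4) > 0


# ---------------------------------------------------------------------------
# standardization bins
# ---------------------------------------------------------------------------


def test_build_bins_uniform_no_merging(rng):
    dafs = rng.uniform(0.001, 0.999, size=5000)
    values = rng.normal(size=5000)
    bins = build_bins(values, dafs, bin_width=0.02, min_count=20)
    assert len(bins.means) == 50
    np.testing.assert_allclose(bins.edges, np.linspace(0, 1, 51), atol=1e-12)


def test_build_bins_single_bin_when_concentrated(rng):
    dafs = np.full(100, 0.515)
    values = rng.normal(size=100)
    bins = build_bins(values, dafs, bin_width=0.02, min_count=20)
    # every value in one raw bin; all other bins merge around it
    idx = bins.bin_of(np.asarray([0.515]))[0]
    assert bins.counts[idx] == 100


def test_build_bins_merged_stats_match_recomputation(rng):
    dafs = rng.beta(0.4, 0.4, size=800)
    values = rng.normal(size=800) * (1 + dafs)
    bins = build_bins(values, dafs, bin_width=0.02, min_count=50)
    assert (bins.counts[bins.counts > 0] >= 50).all()
    idx = bins.bin_of(dafs)
    for b in range(len(bins.means)):
        sel = idx == b
        if sel.sum():
            assert bins.means[b] == pytest.approx(values[sel].mean())
            assert bins.sds[b] == pytest.approx(values[sel].std(ddof=0))


def test_standardized_bins_mean_zero_sd_one(rng):
    dafs = rng.uniform(0.01, 0.99, size=2000)
    values = rng.normal(2.0, 3.0, size=2000) + dafs
    bins = build_bins(values, dafs, min_count=200)
    z = bins.standardize(values, dafs)
    idx = bins.bin_of(dafs)
    for b in np.unique(idx):
        sel = idx == b
        assert np.nanmean(z[sel]) == pytest.approx(0.0, abs=1e-10)
        assert np.nanstd(z[sel]) == pytest.approx(1.0, abs=1e-10)


def test_build_bins_errors_on_all_nan():
    with pytest.raises(ValueError):
        build_bins([np.nan, np.nan], [0.5, 0.6])


# ---------------------------------------------------------------------------
# compute_scores integration
# ---------------------------------------------------------------------------


def test_compute_scores_columns_and_nan_policy(rng):
    target = random_panel(rng, n_hap=20, n_sites=40)
    ref = make_panel(
        rng.integers(0, 2, size=(16, 40)).astype(np.uint8),
        positions=target.positions, population="REF",
    )
    df = compute_scores(target, ref)
    for col in ("chrom", "pos", "id", "daf", "fst", "ihs", "xpehh", "dihh", "nsl"):
        assert col in df.columns
    # iHS defined only at MAF >= 0.05 with known ancestral
    maf = np.minimum(df["daf"], 1 - df["daf"])
    assert df.loc[maf < 0.05, "ihs"].isna().all()


def test_compute_scores_xpehh_standardized_genomewide(rng):
    target = random_panel(rng, n_hap=30, n_sites=120)
    ref = make_panel(
        rng.integers(0, 2, size=(24, 120)).astype(np.uint8),
        positions=target.positions, population="REF",
    )
    df = compute_scores(target, ref, config=ScoreConfig(stats=("xpehh",)))
    z = df["xpehh"].to_numpy(dtype=float)
    assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
    assert np.nanstd(z) == pytest.approx(1.0, abs=1e-9)


def test_compute_scores_ref_as_ancestral_override(rng):
    target = random_panel(rng, n_hap=16, n_sites=30, ancestral="unknown")
    ref = make_panel(
        rng.integers(0, 2, size=(12, 30)).astype(np.uint8),
        positions=target.positions, ancestral="unknown", population="REF",
    )
    base = compute_scores(target, ref, config=ScoreConfig(stats=("ihs",)))
    assert base["ihs"].isna().all()  # unknown ancestral: excluded
    forced = compute_scores(
        target, ref, config=ScoreConfig(stats=("ihs",), ref_as_ancestral=True)
    )
    assert forced["ihs"].notna().any()


# ---------------------------------------------------------------------------
# sign conventions on planted sweeps
# ---------------------------------------------------------------------------


def test_sweep_sign_concordance():
    """Planted hard sweep on the derived allele: negative unstandardized iHS
    and nSL, positive dIHH at the swept site (>= 90% concordance over 20
    seeded replicates)."""
    from hapsel.simulate import SimulationConfig, simulate_populations

    votes = {"ihs": 0, "nsl": 0, "dihh": 0}
    n_used = 0
    for seed in range(20):
        cfg = SimulationConfig(
            seed=seed + 300, n_diploid=100, generations=150, split_gen=70,
            ref_split_gen=50, mu=2.0e-7, rho=5e-8, length=400_000,
            s=0.15, sweep_start_gen=40,
            sample_sizes={"TBP": 50, "YKX": 10, "DUROC": 15},
            sweep_min_freq=0.5, sweep_max_freq=0.85, max_sweep_retries=20,
        )
        panels, truth = simulate_populations(cfg)
        panel = panels["TBP"]
        pos = panel.positions
        j = int(np.argmin(np.abs(pos - truth["sweep_position"])))
        daf = panel.derived_freq(j)
        if not 0.2 <= daf <= 0.9:
            continue
        n_used += 1
        u_ihs = ihs_unstandardized(panel, j, min_maf=0.05)
        u_nsl = nsl_unstandardized(panel, j, min_maf=0.05)
        u_dihh = dihh_unstandardized(panel, j)
        votes["ihs"] += bool(np.isfinite(u_ihs) and u_ihs < 0)
        votes["nsl"] += bool(np.isfinite(u_nsl) and u_nsl < 0)
        votes["dihh"] += bool(np.isfinite(u_dihh) and u_dihh > 0)
    assert n_used >= 15
    for stat, ok in votes.items():
        assert ok / n_used >= 0.9, (stat, votes, n_used)
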