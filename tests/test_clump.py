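import numpy as np
import pandas as pd
import pytest

from hapsel.clump import (
    CandidateGene,
    ClumpRegion,
    GeneAnnotation,
    annotate_snps,
    audit_regions,
    call_candidate_regions,
    clump,
    ld_r2,
    peak_gene,
    regions_to_frame,
    tbp_enriched_allele,
)
from hapsel.popgen import AlleleFreq

from conftest import make_panel


# ---------------------------------------------------------------------------
# LD r2
# ---------------------------------------------------------------------------


def r2_oracle(a, b):
    """2x2 haplotype-count arithmetic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = len(a)
    pAB = ((a == 1) & (b == 1)).sum() / n
    pA = a.mean()
    pB = b.mean()
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def test_ld_perfect_coinheritance():
    haps = np.array([[1, 1], [1, 1], [0, 0], [0, 0], [1, 1], [0, 0]], dtype=np.uint8)
    assert ld_r2(make_panel(haps), 0, 1) == pytest.approx(1.0)


def test_ld_self_is_one():
    haps = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=np.uint8)
    assert ld_r2(make_panel(haps), 0, 0) == pytest.approx(1.0)


def test_ld_monomorphic_nan():
    haps = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.uint8)
    assert np.isnan(ld_r2(make_panel(haps), 0, 1))


def test_ld_shuffled_columns_near_zero(rng):
    n = 500
    a = rng.integers(0, 2, size=n)
    b = rng.permutation(a)
    haps = np.column_stack([a, b]).astype(np.uint8)
    assert ld_r2(make_panel(haps), 0, 1) < 0.05


def test_ld_eight_haplotype_count_oracle(rng):
    for _ in range(25):
        haps = rng.integers(0, 2, size=(8, 2)).astype(np.uint8)
        if haps[:, 0].std() == 0 or haps[:, 1].std() == 0:
            continue
        got = ld_r2(make_panel(haps), 0, 1)
        assert got == pytest.approx(r2_oracle(haps[:, 0], haps[:, 1]), abs=1e-12)


def test_ld_symmetric(rng):
    haps = rng.integers(0, 2, size=(20, 5)).astype(np.uint8)
    panel = make_panel(haps)
    assert ld_r2(panel, 1, 3) == pytest.approx(ld_r2(panel, 3, 1))


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


def clump_oracle(cms, pos, chrom, H, idx_thr, sp2_thr, r2_min, radius):
    """Independent greedy re-implementation (plain loops over dicts)."""
    order = sorted(
        [j for j in range(len(cms)) if np.isfinite(cms[j]) and cms[j] >= idx_thr],
        key=lambda j: (-cms[j], pos[j]),
    )
    claimed = set()
    regions = []
    for j in order:
        if j in claimed:
            continue
        claimed.add(j)
        members = []
        for w in range(len(cms)):
            if w == j or w in claimed or not np.isfinite(cms[w]):
                continue
            if chrom[w] != chrom[j] or abs(pos[w] - pos[j]) > radius:
                continue
            if cms[w] < sp2_thr:
                continue
            r2 = r2_oracle(H[:, j], H[:, w])
            if np.isfinite(r2) and r2 >= r2_min:
                members.append(w)
        claimed.update(members)
        regions.append((j, sorted(members)))
    return regions


def _cms_frame(pos, cms, chrom="1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{i}" for i in range(len(pos))],
            "cms": cms,
        }
    )


def test_clump_empty_when_nothing_significant(rng):
    haps = rng.integers(0, 2, size=(10, 6)).astype(np.uint8)
    panel = make_panel(haps)
    df = _cms_frame(panel.positions, np.full(6, np.nan))
    assert clump(df, panel) == []


def test_clump_isolated_index_no_partners(rng):
    # one clearly top SNP, all others far away
    pos = np.array([1_000, 2_000_000, 2_001_000, 2_002_000])
    haps = rng.integers(0, 2, size=(12, 4)).astype(np.uint8)
    haps[:, 0] = [1, 0] * 6
    panel = make_panel(haps, positions=pos)
    cms = np.array([10.0, 1.0, 1.1, 0.9])
    regions = clump(_cms_frame(pos, cms), panel, index_q=0.25, sp2_q=0.5, radius_kb=500)
    top = regions[0]
    assert top.index_snp == "snp0" and top.n_members == 0


def test_clump_two_block_fixture_matches_oracle(rng):
    # 12 SNPs in two LD blocks with known scores
    n_hap = 40
    block1 = rng.integers(0, 2, size=n_hap)
    block2 = rng.integers(0, 2, size=n_hap)
    cols = []
    for k in range(6):
        noise = rng.random(n_hap) < 0.08
        cols.append(np.where(noise, 1 - block1, block1))
    for k in range(6):
        noise = rng.random(n_hap) < 0.08
        cols.append(np.where(noise, 1 - block2, block2))
    haps = np.column_stack(cols).astype(np.uint8)
    pos = np.concatenate([10_000 + 5_000 * np.arange(6), 400_000 + 5_000 * np.arange(6)])
    panel = make_panel(haps, positions=pos)
    cms = np.array([5, 8, 6, 4, 3, 2, 9, 7, 5, 4, 2, 1], dtype=float)
    df = _cms_frame(pos, cms)

    idx_thr = float(np.quantile(cms, 1 - 0.25))
    sp2_thr = float(np.quantile(cms, 1 - 0.9))
    got = clump(df, panel, index_q=0.25, sp2_q=0.9, r2_min=0.2, radius_kb=100)
    want = clump_oracle(cms, pos, ["1"] * 12, haps, idx_thr, sp2_thr, 0.2, 100_000)
    assert len(got) == len(want)
    for region, (j, members) in zip(got, want):
        assert region.index_snp == f"snp{j}"
        assert set(region.members) == {f"snp{w}" for w in members}


def test_clump_property_random_fixtures(rng):
    """Greedy clumping equals the independent re-implementation on random
    fixtures up to 50 SNPs (100 seeds), and the audit passes."""
    for trial in range(100):
        n_hap = 30
        m = int(rng.integers(5, 51))
        base = rng.integers(0, 2, size=(n_hap, max(1, m // 8)))
        cols = []
        for k in range(m):
            src = base[:, int(rng.integers(0, base.shape[1]))]
            noise = rng.random(n_hap) < 0.15
            cols.append(np.where(noise, 1 - src, src))
        haps = np.column_stack(cols).astype(np.uint8)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
        panel = make_panel(haps, positions=pos)
        cms = rng.normal(size=m)
        cms[rng.random(m) < 0.1] = np.nan
        if not np.isfinite(cms).any():
            continue
        df = _cms_frame(pos, cms)
        index_q, sp2_q = 0.2, 0.6
        defined = cms[np.isfinite(cms)]
        idx_thr = float(np.quantile(defined, 1 - index_q))
        sp2_thr = float(np.quantile(defined, 1 - sp2_q))
        got = clump(df, panel, index_q=index_q, sp2_q=sp2_q, r2_min=0.2, radius_kb=300)
        audit_regions(got, radius_kb=300)
        want = clump_oracle(cms, pos, ["1"] * m, haps, idx_thr, sp2_thr, 0.2, 300_000)
        assert [(r.index_snp, set(r.members)) for r in got] == [
            (f"snp{j}", {f"snp{w}" for w in ws}) for j, ws in want
        ]


def test_clump_tie_break_smaller_position_first(rng):
    pos = np.array([1_000, 2_000])
    haps = np.array([[1, 0], [0, 1], [1, 0], [0, 1], [1, 1], [0, 0]], dtype=np.uint8)
    panel = make_panel(haps, positions=pos)
    df = _cms_frame(pos, np.array([5.0, 5.0]))
    regions = clump(df, panel, index_q=1.0, sp2_q=1.0, r2_min=0.99)
    assert regions[0].index_snp == "snp0"


def test_call_candidate_regions_strictly_greater():
    def region(n):
        return ClumpRegion("1", "x", 100, 9.0,
                           members=[f"m{i}" for i in range(n)],
                           member_positions=list(range(200, 200 + n)))

    assert call_candidate_regions([region(5)], min_sp2=5) == []
    kept = call_candidate_regions([region(6)], min_sp2=5)
    assert len(kept) == 1
    mixed = [region(n) for n in (0, 3, 5, 6, 9)]
    assert [r.n_members for r in call_candidate_regions(mixed)] == [6, 9]


# ---------------------------------------------------------------------------
# annotation / peak genes
# ---------------------------------------------------------------------------


def _annotation():
    rows = [
        ("1", 1_000, 2_000, "GENE_A", "CDS", "+"),
        ("1", 2_000, 3_000, "GENE_A", "intron", "+"),
        ("1", 5_000, 7_000, "GENE_B", "CDS", "+"),
        ("1", 6_500, 8_000, "GENE_C", "UTR3", "-"),  # overlaps GENE_B
        ("1", 9_000, 9_500, "RE1", "regulatory", "+"),
    ]
    return GeneAnnotation(pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS))


def _region(pos, cms=9.0, members=6):
    return ClumpRegion("1", f"idx{pos}", pos, cms,
                       members=[f"m{pos}_{i}" for i in range(members)],
                       member_positions=[pos + i + 1 for i in range(members)])


def test_peak_gene_inside_one_gene():
    calls = peak_gene([_region(1_500)], _annotation())
    assert [c.gene for c in calls] == ["GENE_A"]
    assert not calls[0].ambiguous


def test_peak_gene_intergenic_reported_na():
    calls = peak_gene([_region(4_000)], _annotation())
    assert len(calls) == 1 and calls[0].gene is None


def test_peak_gene_overlapping_genes_flagged_ambiguous():
    calls = peak_gene([_region(6_800)], _annotation())
    genes = sorted(c.gene for c in calls)
    assert genes == ["GENE_B", "GENE_C"]
    assert all(c.ambiguous for c in calls)


def test_peak_gene_dedup_keeps_max_cms():
    calls = peak_gene([_region(1_500, cms=5.0), _region(2_500, cms=8.0)], _annotation())
    gene_a = [c for c in calls if c.gene == "GENE_A"]
    assert len(gene_a) == 1 and gene_a[0].peak_cms == 8.0


def test_annotate_snps_priority_and_summary():
    ann = _annotation()
    snps = pd.DataFrame({"chrom": ["1"] * 3, "pos": [1_500, 6_800, 50_000]})
    classes, summary = annotate_snps(snps, ann)
    assert list(classes) == ["CDS", "CDS", "intergenic"]
    assert summary["coding"] == 2
    assert summary["coding_percent"] + summary["noncoding_percent"] == pytest.approx(100.0)
    assert sum(summary["counts"].values()) == 3


def test_annotate_snps_cds_beats_regulatory():
    rows = [
        ("1", 100, 200, "G", "regulatory", "+"),
        ("1", 100, 200, "G", "CDS", "+"),
    ]
    ann = GeneAnnotation(pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS))
    classes, _ = annotate_snps(pd.DataFrame({"chrom": ["1"], "pos": [150]}), ann)
    assert list(classes) == ["CDS"]


def test_annotate_snps_empty_annotation_all_intergenic():
    ann = GeneAnnotation(pd.DataFrame(columns=GeneAnnotation.COLUMNS))
    snps = pd.DataFrame({"chrom": ["1", "2"], "pos": [10, 20]})
    classes, summary = annotate_snps(snps, ann)
    assert (classes == "intergenic").all()
    assert summary["noncoding_percent"] == 100.0


def test_annotation_summary_arithmetic_413_of_4598():
    """413 coding of 4,598 -> 9% coding / 91% noncoding (rounded)."""
    n, n_coding = 4598, 413
    rows = [("1", 0, n_coding * 10, "G1", "CDS", "+")]
    ann = GeneAnnotation(pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS))
    pos = np.arange(1, 10 * n, 10)[:n]  # first 413 land inside the CDS
    snps = pd.DataFrame({"chrom": "1", "pos": pos})
    _, summary = annotate_snps(snps, ann)
    assert summary["n_snps"] == 4598
    assert summary["coding"] == 413
    assert round(summary["coding_percent"]) == 9
    assert round(summary["noncoding_percent"]) == 91


def test_annotation_bed_round_trip(tmp_path):
    ann = _annotation()
    path = tmp_path / "genes.bed"
    ann.to_bed(path)
    back = GeneAnnotation.read_bed(path)
    pd.testing.assert_frame_equal(back.table, ann.table)


# ---------------------------------------------------------------------------
# enriched-allele calls
# ---------------------------------------------------------------------------


def test_enriched_allele_alt_clearly_enriched():
    call = tbp_enriched_allele(
        AlleleFreq(0.83, 120), [AlleleFreq(0.35, 50), AlleleFreq(0.43, 32)]
    )
    assert call.allele == "alt" and not call.ambiguous
    assert call.freq_target == pytest.approx(0.83)
    assert call.margin == pytest.approx(0.83 - 0.43)


def test_enriched_allele_tie_is_ambiguous():
    call = tbp_enriched_allele(
        AlleleFreq(0.5, 10), [AlleleFreq(0.5, 10), AlleleFreq(0.5, 10)]
    )
    assert call.ambiguous and call.margin == pytest.approx(0.0)


def test_enriched_allele_low_but_enriched():
    call = tbp_enriched_allele(
        AlleleFreq(0.18, 120), [AlleleFreq(0.01, 50), AlleleFreq(0.01, 32)]
    )
    assert call.allele == "alt" and not call.ambiguous
    assert call.freq_target == pytest.approx(0.18)


def test_enriched_allele_ref_side():
    call = tbp_enriched_allele(AlleleFreq(0.1, 100), [AlleleFreq(0.9, 100)])
    assert call.allele == "ref" and not call.ambiguous
    assert call.freq_target == pytest.approx(0.9)


def test_regions_to_frame_columns():
    df = regions_to_frame([_region(100)])
    assert list(df["index_pos"]) == [100]
    assert df["n_members"].iloc[0] == 6
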