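"""LD clumping of composite-significant SNPs into candidate regions.

Provides haplotype LD r2, greedy clumping (index SNPs claim SP2 members by
score quantiles, r2 and radius), region filtering, peak-SNP gene calling,
interval-class SNP annotation, and target-enriched allele calls.

Intervals are 0-based half-open (BED); SNP positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hapsel.io_qc import HaplotypePanel
from hapsel.popgen import AlleleFreq

#: annotation feature classes, highest priority first
FEATURE_CLASSES = ("CDS", "UTR5", "UTR3", "regulatory", "intron", "intergenic")
#: priority used when one SNP overlaps several classes
CLASS_PRIORITY = {"CDS": 0, "UTR5": 1, "UTR3": 1, "regulatory": 2, "intron": 3, "intergenic": 4}


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def ld_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared haplotype correlation between sites i and j.

    r2 = D^2 / (pA qA pB qB) with D = pAB - pA pB, from the phased
    haplotypes. NaN for a monomorphic site. Symmetric; r2(i, i) = 1 for a
    polymorphic site. Invariant to allele coding.
    """
    a = panel.haplotypes[:, i].astype(float)
    b = panel.haplotypes[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    if va == 0 or vb == 0:
        return math.nan
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (va * vb))


def _r2_vector(H: np.ndarray, idx: int, others: np.ndarray) -> np.ndarray:
    """Vectorized r2 between column ``idx`` and each column in ``others``."""
    a = H[:, idx].astype(float)
    B = H[:, others].astype(float)
    pa = a.mean()
    pb = B.mean(axis=0)
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    pab = (a[:, None] * B).mean(axis=0)
    d = pab - pa * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = d * d / (va * vb)
    r2[~np.isfinite(r2)] = np.nan
    return r2


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


@dataclass
class ClumpRegion:
    """An index SNP with its claimed SP2 members."""

    chrom: str
    index_snp: str
    index_pos: int
    index_cms: float
    members: list = field(default_factory=list)  # SP2 snp ids
    member_positions: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def start(self) -> int:
        return min([self.index_pos] + list(self.member_positions))

    @property
    def end(self) -> int:
        return max([self.index_pos] + list(self.member_positions))


def clump(
    cms_table: pd.DataFrame,
    panel: HaplotypePanel,
    index_q: float = 0.001,
    sp2_q: float = 0.01,
    r2_min: float = 0.2,
    radius_kb: float = 500.0,
) -> list[ClumpRegion]:
    """Greedy LD clumping on composite scores.

    SNPs scoring in the genome-wide top ``index_q`` are candidate indices,
    processed by descending score (ties: smaller position first). Each
    unclaimed index claims, as SP2 members, every unclaimed same-chromosome
    SNP within ``radius_kb`` whose score is in the top ``sp2_q`` and whose
    r2 with the index is >= ``r2_min``. Claimed SNPs cannot seed or join
    later clumps. The ``cms_table`` must align row-for-row with the panel's
    sites.
    """
    if len(cms_table) != panel.n_sites:
        raise ValueError("cms table and panel must cover the same sites")
    cms = cms_table["cms"].to_numpy(dtype=float)
    pos = cms_table["pos"].to_numpy(dtype=np.int64)
    chrom = cms_table["chrom"].to_numpy()
    ids = cms_table["id"].to_numpy()
    defined = np.isfinite(cms)
    if not defined.any():
        return []
    idx_thr = float(np.quantile(cms[defined], 1 - index_q))
    sp2_thr = float(np.quantile(cms[defined], 1 - sp2_q))
    radius = int(radius_kb * 1000)

    with np.errstate(invalid="ignore"):
        is_index_candidate = defined & (cms >= idx_thr)
        is_sp2_candidate = defined & (cms >= sp2_thr)
    order = sorted(np.nonzero(is_index_candidate)[0], key=lambda j: (-cms[j], pos[j]))

    H = panel.haplotypes
    claimed = np.zeros(len(cms), dtype=bool)
    regions: list[ClumpRegion] = []
    for j in order:
        if claimed[j]:
            continue
        claimed[j] = True
        window = np.nonzero(
            is_sp2_candidate
            & ~claimed
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= radius)
        )[0]
        members: list[int] = []
        if len(window):
            r2 = _r2_vector(H, j, window)
            members = [int(w) for w, r in zip(window, r2) if np.isfinite(r) and r >= r2_min]
        for w in members:
            claimed[w] = True
        regions.append(
            ClumpRegion(
                chrom=str(chrom[j]),
                index_snp=str(ids[j]),
                index_pos=int(pos[j]),
                index_cms=float(cms[j]),
                members=[str(ids[w]) for w in members],
                member_positions=[int(pos[w]) for w in members],
            )
        )
    return regions


def audit_regions(regions: list[ClumpRegion], radius_kb: float = 500.0) -> None:
    """Post-hoc invariant check: disjoint membership, members within radius."""
    seen: set = set()
    radius = int(radius_kb * 1000)
    for r in regions:
        ids = [r.index_snp] + list(r.members)
        for sid in ids:
            if sid in seen:
                raise AssertionError(f"SNP {sid} appears in more than one clump")
            seen.add(sid)
        for p in r.member_positions:
            if abs(p - r.index_pos) > radius:
                raise AssertionError(f"member at {p} outside radius of {r.index_pos}")


def call_candidate_regions(
    regions: list[ClumpRegion], min_sp2: int = 5
) -> list[ClumpRegion]:
    """Keep regions with strictly more than ``min_sp2`` SP2 members."""
    return [r for r in regions if r.n_members > min_sp2]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene/feature intervals: chrom, start, end (0-based half-open),
    gene name, feature class, strand."""

    table: pd.DataFrame  # columns: chrom, start, end, gene, feature_class, strand

    COLUMNS = ["chrom", "start", "end", "gene", "feature_class", "strand"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].astype(str)
        t["gene"] = t["gene"].astype(str)
        if (t["start"] >= t["end"]).any():
            raise ValueError("annotation intervals must satisfy start < end")
        bad = set(t["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_bed(cls, path) -> "GeneAnnotation":
        t = pd.read_csv(path, sep="\t", header=None, names=cls.COLUMNS, comment="#")
        return cls(t)

    def to_bed(self, path) -> None:
        self.table[self.COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    def overlapping(self, chrom: str, pos: int) -> pd.DataFrame:
        """Intervals containing the 1-based SNP position ``pos``."""
        p0 = pos - 1
        t = self.table
        return t[(t["chrom"] == chrom) & (t["start"] <= p0) & (p0 < t["end"])]

    def gene_bounds(self) -> dict:
        """gene -> (chrom, start, end) spanning all its non-intergenic intervals."""
        t = self.table[self.table["feature_class"] != "intergenic"]
        out = {}
        for gene, grp in t.groupby("gene", sort=False):
            out[str(gene)] = (
                str(grp["chrom"].iloc[0]),
                int(grp["start"].min()),
                int(grp["end"].max()),
            )
        return out


@dataclass
class CandidateGene:
    """Peak-SNP gene call for one surviving clump region."""

    gene: str | None  # None = peak SNP in no gene (reported, not dropped)
    peak_snp: str
    peak_cms: float
    region: ClumpRegion
    ambiguous: bool = False  # peak SNP inside overlapping genes
    enriched_allele: "EnrichedAllele | None" = None


def peak_gene(
    regions: list[ClumpRegion], annotation: GeneAnnotation
) -> list[CandidateGene]:
    """Call the gene containing each region's peak (index) SNP.

    Peak SNPs inside overlapping genes yield one call per gene, flagged
    ambiguous. Peak-in-no-gene regions are reported with ``gene=None``.
    Duplicate genes across regions are deduplicated keeping the call with
    the highest composite score.
    """
    calls: list[CandidateGene] = []
    for r in regions:
        hits = annotation.overlapping(r.chrom, r.index_pos)
        genes = sorted(set(hits.loc[hits["feature_class"] != "intergenic", "gene"]))
        if not genes:
            calls.append(CandidateGene(None, r.index_snp, r.index_cms, r))
        else:
            ambiguous = len(genes) > 1
            for g in genes:
                calls.append(CandidateGene(str(g), r.index_snp, r.index_cms, r, ambiguous))
    best: dict[str, CandidateGene] = {}
    out: list[CandidateGene] = []
    for c in calls:
        if c.gene is None:
            out.append(c)
        elif c.gene not in best or c.peak_cms > best[c.gene].peak_cms:
            best[c.gene] = c
    out.extend(best.values())
    out.sort(key=lambda c: -c.peak_cms)
    return out


def annotate_snps(
    snps: pd.DataFrame, annotation: GeneAnnotation
) -> tuple[pd.Series, dict]:
    """Assign each SNP its highest-priority overlapping feature class.

    ``snps`` needs ``chrom`` and ``pos`` (1-based) columns. Positions not
    covered by any interval are intergenic. Returns the per-SNP class series
    and a summary with per-class counts/percentages plus coding (= CDS) and
    noncoding totals.
    """
    t = annotation.table
    per_snp = pd.Series("intergenic", index=snps.index, dtype=object)
    for chrom, grp in snps.groupby("chrom", sort=False):
        sub = t[t["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cls_codes = sub["feature_class"].map(CLASS_PRIORITY).to_numpy(dtype=float)
        cls_names = sub["feature_class"].to_numpy()
        for ix, pos in zip(grp.index, grp["pos"].to_numpy()):
            p0 = pos - 1
            mask = (starts <= p0) & (p0 < ends)
            if mask.any():
                best = int(np.argmin(np.where(mask, cls_codes, np.inf)))
                per_snp[ix] = cls_names[best]

    n = len(per_snp)
    counts = {c: int((per_snp == c).sum()) for c in FEATURE_CLASSES}
    pct = {c: 100.0 * counts[c] / n if n else 0.0 for c in FEATURE_CLASSES}
    coding = counts["CDS"]
    summary = {
        "n_snps": n,
        "counts": counts,
        "percent": pct,
        "coding": coding,
        "noncoding": n - coding,
        "coding_percent": 100.0 * coding / n if n else 0.0,
        "noncoding_percent": 100.0 * (n - coding) / n if n else 0.0,
    }
    return per_snp, summary


# ---------------------------------------------------------------------------
# enriched-allele calls
# ---------------------------------------------------------------------------


@dataclass
class EnrichedAllele:
    """The allele enriched in the target population relative to references."""

    allele: str  # 'alt' | 'ref'
    freq_target: float  # frequency of that allele in the target
    freq_refs: list  # its frequency in each reference
    margin: float  # target freq minus the highest reference freq
    ambiguous: bool = False  # neither allele exceeds all references


def tbp_enriched_allele(
    freq_target: AlleleFreq, freq_refs: list[AlleleFreq]
) -> EnrichedAllele:
    """Call the target-enriched allele at one site.

    Frequencies are alt-allele frequencies. The enriched allele is the one
    whose target frequency strictly exceeds its frequency in every
    reference; when neither qualifies, the allele maximizing
    (target - max reference) is returned with ``ambiguous=True``.
    """
    if not freq_refs:
        raise ValueError("need at least one reference population")
    pt = freq_target.p
    refs_alt = [f.p for f in freq_refs]
    margin_alt = pt - max(refs_alt)
    margin_ref = (1 - pt) - max(1 - p for p in refs_alt)
    alt_wins = all(pt > p for p in refs_alt)
    ref_wins = all((1 - pt) > (1 - p) for p in refs_alt)
    if alt_wins:
        return EnrichedAllele("alt", pt, refs_alt, margin_alt, ambiguous=False)
    if ref_wins:
        return EnrichedAllele(
            "ref", 1 - pt, [1 - p for p in refs_alt], margin_ref, ambiguous=False
        )
    if margin_alt >= margin_ref:
        return EnrichedAllele("alt", pt, refs_alt, margin_alt, ambiguous=True)
    return EnrichedAllele(
        "ref", 1 - pt, [1 - p for p in refs_alt], margin_ref, ambiguous=True
    )


# ---------------------------------------------------------------------------
# tabular output helpers
# ---------------------------------------------------------------------------


def regions_to_frame(regions: list[ClumpRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "index_snp": r.index_snp,
                "index_pos": r.index_pos,
                "index_cms": r.index_cms,
                "n_members": r.n_members,
                "members": ",".join(r.members),
            }
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "index_snp", "index_pos",
            "index_cms", "n_members", "members",
        ],
    )


def genes_to_frame(calls: list[CandidateGene]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "gene": c.gene if c.gene is not None else "NA",
            "peak_snp": c.peak_snp,
            "peak_cms": c.peak_cms,
            "chrom": c.region.chrom,
            "region_start": c.region.start,
            "region_end": c.region.end,
            "n_members": c.region.n_members,
            "ambiguous": c.ambiguous,
        }
        if c.enriched_allele is not None:
            row["enriched_allele"] = c.enriched_allele.allele
            row["enriched_freq_target"] = c.enriched_allele.freq_target
            row["enriched_margin"] = c.enriched_allele.margin
        rows.append(row)
    columns = ["gene", "peak_snp", "peak_cms", "chrom", "region_start",
               "region_end", "n_members", "ambiguous"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)
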