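"""Standard-format IO and data QC.

Reads/writes biallelic-SNV VCFs (via pysam), sample manifests and QC
reports, applies GATK-style hard filtering, Hardy-Weinberg / missingness /
MAF variant QC, missingness / heterozygosity sample QC, and iterative
PCA-based admixture-outlier flagging.

Coordinate conventions: variant positions are 1-based (VCF); all interval
files elsewhere in the package are 0-based half-open (BED).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING = -1

ANCESTRAL_STATES = ("ref", "alt", "unknown")

#: GATK-style hard-filter clauses: (INFO key, operator, threshold).
#: A clause fires only when its key is present; all inequalities strict.
HARD_FILTER_CLAUSES = (
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("SOR", ">", 3.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantSite:
    """A biallelic SNV with optional ancestral-allele and INFO annotations."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    ancestral: str = "unknown"  # 'ref' | 'alt' | 'unknown'
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ancestral not in ANCESTRAL_STATES:
            raise ValueError(f"ancestral must be one of {ANCESTRAL_STATES}")


def _check_sorted(sites: Sequence[VariantSite]) -> None:
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            raise ValueError(
                f"sites not strictly increasing within {s.chrom} at pos {s.pos}"
            )
        last[s.chrom] = s.pos


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages, samples x sites; -1 encodes missing."""

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray  # (n_samples, n_sites) int8 in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        _check_sorted(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_rate_per_sample(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def missing_rate_per_site(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.calls == MISSING).mean(axis=0)

    def heterozygosity_per_sample(self) -> np.ndarray:
        """Observed heterozygosity: fraction of non-missing calls equal to 1."""
        obs = self.calls != MISSING
        het = self.calls == 1
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), np.nan)

    def alt_freq_per_site(self) -> np.ndarray:
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        site_idx = (
            np.arange(self.n_sites) if site_idx is None
            else np.asarray(site_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            sites=[self.sites[j] for j in site_idx],
            calls=self.calls[np.ix_(sample_idx, site_idx)],
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, 2n x m, with no missing entries.

    Column coding: 1 = derived allele where the site's ancestral allele is
    known, otherwise 1 = alt allele.
    """

    haplotypes: np.ndarray  # (2n, m) uint8
    sites: list[VariantSite]
    sample_of_haplotype: list[str]  # length 2n
    population: str = "unknown"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("column count must equal site count")
        if self.haplotypes.shape[0] != len(self.sample_of_haplotype):
            raise ValueError("row count must equal sample_of_haplotype length")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotypes must be binary")
        _check_sorted(self.sites)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        # cached: sites are fixed after construction and scans hit this hard
        cached = getattr(self, "_positions", None)
        if cached is None or len(cached) != len(self.sites):
            cached = np.asarray([s.pos for s in self.sites], dtype=np.int64)
            self._positions = cached
        return cached

    @property
    def samples(self) -> list[str]:
        return self.sample_of_haplotype[::2]

    def derived_freq(self, j: int) -> float:
        return float(self.haplotypes[:, j].mean())

    def alt_coded(self) -> np.ndarray:
        """Matrix recoded so that 1 = alt allele at every column."""
        out = self.haplotypes.copy()
        for j, s in enumerate(self.sites):
            if s.ancestral == "alt":
                out[:, j] = 1 - out[:, j]
        return out

    @classmethod
    def from_alt_coded(
        cls,
        alt_haps: np.ndarray,
        sites: list[VariantSite],
        sample_of_haplotype: list[str],
        population: str = "unknown",
    ) -> "HaplotypePanel":
        haps = np.asarray(alt_haps, dtype=np.uint8).copy()
        for j, s in enumerate(sites):
            if s.ancestral == "alt":
                haps[:, j] = 1 - haps[:, j]
        return cls(haps, sites, sample_of_haplotype, population)

    def subset_sites(self, site_idx) -> "HaplotypePanel":
        site_idx = np.asarray(site_idx, dtype=np.intp)
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, site_idx],
            sites=[self.sites[j] for j in site_idx],
            sample_of_haplotype=list(self.sample_of_haplotype),
            population=self.population,
        )

    def dosage(self) -> GenotypeMatrix:
        """Collapse to a diploid alt-dosage matrix (consecutive row pairs)."""
        alt = self.alt_coded()
        calls = (alt[0::2] + alt[1::2]).astype(np.int8)
        return GenotypeMatrix(samples=self.samples, sites=list(self.sites), calls=calls)


@dataclass
class SampleManifest:
    """Per-sample metadata: id, population, altitude (m), sex, age."""

    table: pd.DataFrame  # columns: sample, population, altitude, sex, age

    COLUMNS = ["sample", "population", "altitude", "sex", "age"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.table = self.table[self.COLUMNS].reset_index(drop=True)

    def validate(self) -> dict:
        """Check invariants and return summary counts."""
        ids = self.table["sample"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if (self.table["altitude"] < 0).any():
            raise ValueError("negative altitude in manifest")
        return {
            "n_total": int(len(self.table)),
            "per_population": self.table["population"].value_counts().to_dict(),
        }

    @property
    def n_total(self) -> int:
        return len(self.table)

    def populations(self) -> dict[str, list[str]]:
        return {
            pop: grp["sample"].tolist()
            for pop, grp in self.table.groupby("population", sort=False)
        }

    def altitude_of(self) -> dict[str, float]:
        return dict(zip(self.table["sample"], self.table["altitude"].astype(float)))

    @classmethod
    def read_tsv(cls, path) -> "SampleManifest":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def study_summary(manifests: Iterable[SampleManifest]) -> dict:
    """Combined counts over several dataset manifests (e.g. WGS + chip)."""
    counts = [m.n_total for m in manifests]
    return {"n_datasets": int(sum(counts)), "per_manifest": counts}


@dataclass
class QCReport:
    """Record of removed samples/sites with reasons, plus before/after counts."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_sites: list[tuple[str, str]] = field(default_factory=list)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_sites_before: int = 0
    n_sites_after: int = 0

    SAMPLE_REASONS = ("missingness", "heterozygosity", "pca_outlier")
    SITE_REASONS = ("hard_filter", "hwe", "mgr", "maf")

    def add_sample(self, sample_id: str, reason: str) -> None:
        if reason not in self.SAMPLE_REASONS:
            raise ValueError(f"unknown sample-removal reason {reason!r}")
        self.removed_samples.append((sample_id, reason))

    def add_site(self, site_id: str, reason: str) -> None:
        if reason not in self.SITE_REASONS:
            raise ValueError(f"unknown site-removal reason {reason!r}")
        self.removed_sites.append((site_id, reason))

    def n_removed_samples(self, reason: str | None = None) -> int:
        return sum(1 for _, r in self.removed_samples if reason is None or r == reason)

    def n_removed_sites(self, reason: str | None = None) -> int:
        return sum(1 for _, r in self.removed_sites if reason is None or r == reason)

    def check(self) -> None:
        if self.n_samples_before - self.n_removed_samples() != self.n_samples_after:
            raise ValueError("sample counts inconsistent")
        if self.n_sites_before - self.n_removed_sites() != self.n_sites_after:
            raise ValueError("site counts inconsistent")

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            removed_samples=self.removed_samples + other.removed_samples,
            removed_sites=self.removed_sites + other.removed_sites,
            n_samples_before=self.n_samples_before,
            n_samples_after=other.n_samples_after,
            n_sites_before=self.n_sites_before,
            n_sites_after=other.n_sites_after,
        )

    def summary(self) -> dict:
        by_sample_reason = {
            r: self.n_removed_samples(r) for r in self.SAMPLE_REASONS
        }
        by_site_reason = {r: self.n_removed_sites(r) for r in self.SITE_REASONS}
        return {
            "samples_before": self.n_samples_before,
            "samples_after": self.n_samples_after,
            "sites_before": self.n_sites_before,
            "sites_after": self.n_sites_after,
            "removed_samples_by_reason": by_sample_reason,
            "removed_sites_by_reason": by_site_reason,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def to_tsv(self, path) -> None:
        rows = [("sample", sid, reason) for sid, reason in self.removed_samples]
        rows += [("site", sid, reason) for sid, reason in self.removed_sites]
        pd.DataFrame(rows, columns=["level", "id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

_INFO_FLOAT_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


def _build_header(sites: Sequence[VariantSite], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for s in sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    for c in contigs:
        header.contigs.add(c)
    header.info.add("AA", 1, "String", "Ancestral allele")
    for key in _INFO_FLOAT_KEYS:
        header.info.add(key, 1, "Float", f"{key} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(obj: GenotypeMatrix | HaplotypePanel, path) -> None:
    """Write a GenotypeMatrix or HaplotypePanel as an uncompressed VCF 4.x.

    ``read_vcf(write_vcf(x))`` is the identity on calls, positions, alleles
    and ancestral flags. Panels are written phased; matrices unphased, with
    missing calls as ``./.``.
    """
    if isinstance(obj, HaplotypePanel):
        samples = obj.samples
        alt = obj.alt_coded()
        phased = True
    elif isinstance(obj, GenotypeMatrix):
        samples = obj.samples
        phased = False
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as VCF")

    header = _build_header(obj.sites, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(obj.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.ref, site.alt),
                id=site.id,
            )
            if site.ancestral == "ref":
                rec.info["AA"] = site.ref
            elif site.ancestral == "alt":
                rec.info["AA"] = site.alt
            for key in _INFO_FLOAT_KEYS:
                if key in site.info:
                    rec.info[key] = float(site.info[key])
            if phased:
                col = alt[:, j]
                for i, sample in enumerate(samples):
                    rec.samples[sample]["GT"] = (int(col[2 * i]), int(col[2 * i + 1]))
                    rec.samples[sample].phased = True
            else:
                col = obj.calls[:, j]
                for i, sample in enumerate(samples):
                    c = int(col[i])
                    if c == MISSING:
                        rec.samples[sample]["GT"] = (None, None)
                    else:
                        rec.samples[sample]["GT"] = ((0, 0), (0, 1), (1, 1))[c]
            out.write(rec)


def read_vcf(path, require_phased: bool = False, population: str = "unknown"):
    """Read a biallelic-SNV VCF.

    Returns a :class:`HaplotypePanel` when ``require_phased`` is true (any
    unphased or missing genotype is an error naming the record), otherwise a
    :class:`GenotypeMatrix`. Non-biallelic or non-SNV records are skipped
    with a logged count. Ancestral alleles are taken from the AA INFO key.
    """
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
            ):
                n_skipped += 1
                continue
            aa = rec.info.get("AA")
            if aa == rec.ref:
                ancestral = "ref"
            elif aa == rec.alts[0]:
                ancestral = "alt"
            else:
                ancestral = "unknown"
            info = {
                k: float(rec.info[k]) for k in _INFO_FLOAT_KEYS if k in rec.info
            }
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                id=rec.id or f"{rec.chrom}:{rec.pos}",
                ref=rec.ref,
                alt=rec.alts[0],
                ancestral=ancestral,
                info=info,
            )
            if require_phased:
                col = np.empty(2 * len(samples), dtype=np.uint8)
                for i, sample in enumerate(samples):
                    call = rec.samples[sample]
                    gt = call["GT"]
                    if gt is None or None in gt:
                        raise ValueError(
                            f"missing genotype at {rec.chrom}:{rec.pos} sample {sample}"
                        )
                    if len(gt) != 2 or not call.phased:
                        raise ValueError(
                            f"unphased genotype at {rec.chrom}:{rec.pos} sample {sample}"
                        )
                    col[2 * i], col[2 * i + 1] = gt
            else:
                col = np.empty(len(samples), dtype=np.int8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample]["GT"]
                    if gt is None or None in gt:
                        col[i] = MISSING
                    else:
                        col[i] = sum(gt)
            sites.append(site)
            columns.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNV records", n_skipped)

    if require_phased:
        haps_alt = (
            np.column_stack(columns)
            if columns
            else np.zeros((2 * len(samples), 0), dtype=np.uint8)
        )
        sample_of_hap = [s for s in samples for _ in range(2)]
        return HaplotypePanel.from_alt_coded(haps_alt, sites, sample_of_hap, population)
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


# ---------------------------------------------------------------------------
# variant-level QC
# ---------------------------------------------------------------------------


def gatk_style_hard_filter(site: VariantSite) -> tuple[bool, list[str]]:
    """Apply the GATK-style SNV hard filter to one site's INFO annotations.

    Returns ``(passed, reasons)``. A clause only fires when its key is
    present; ``reasons`` lists the key of every violated clause.
    """
    reasons = []
    for key, op, thr in HARD_FILTER_CLAUSES:
        if key not in site.info:
            continue
        v = float(site.info[key])
        if (op == "<" and v < thr) or (op == ">" and v > thr):
            reasons.append(key)
    return (len(reasons) == 0, reasons)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the probability
    of the observed heterozygote count (Wigginton-style recurrence).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # possible heterozygote counts share the parity of the rare-allele count
    het_min = rare % 2
    hets = list(range(het_min, rare + 1, 2))
    # unnormalized probabilities via the recurrence
    # P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2)), upward analogue below
    probs = {}
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != het_min:
        mid += 1 if mid < rare else -1
    probs[mid] = 1.0
    for h in range(mid, het_min, -2):
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * ((rare - h) / 2 + 1) * ((2 * n - rare - h) / 2 + 1)
        )
    for h in range(mid, rare - 1, 2):
        n_hom_rare = (rare - h) / 2
        n_hom_common = (2 * n - rare - h) / 2
        probs[h + 2] = probs[h] * 4.0 * n_hom_rare * n_hom_common / (
            (h + 2) * (h + 1)
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def variant_qc(
    matrix: GenotypeMatrix,
    hwe_p: float = 1e-6,
    mgr: float = 0.05,
    maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Locus-level QC: remove sites by missing rate, HWE deviation, and MAF.

    A site is removed when its missing rate exceeds ``mgr``, else when its
    HWE exact p-value is below ``hwe_p``, else when its minor-allele
    frequency (from non-missing calls) is below ``maf``. Order preserved.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample")
    report = QCReport(
        n_samples_before=matrix.n_samples,
        n_samples_after=matrix.n_samples,
        n_sites_before=matrix.n_sites,
    )
    keep = []
    miss = matrix.missing_rate_per_site()
    for j, site in enumerate(matrix.sites):
        if miss[j] > mgr:
            report.add_site(site.id, "mgr")
            continue
        col = matrix.calls[:, j]
        obs = col[col != MISSING]
        n_AA = int((obs == 0).sum())
        n_Aa = int((obs == 1).sum())
        n_aa = int((obs == 2).sum())
        if len(obs) >= 1 and hwe_exact_test(n_AA, n_Aa, n_aa) < hwe_p:
            report.add_site(site.id, "hwe")
            continue
        p = (2 * n_aa + n_Aa) / (2 * len(obs)) if len(obs) else np.nan
        if np.isnan(p) or min(p, 1 - p) < maf:
            report.add_site(site.id, "maf")
            continue
        keep.append(j)
    out = matrix.subset(site_idx=keep)
    report.n_sites_after = out.n_sites
    report.check()
    return out, report


def hard_filter_sites(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Drop sites failing the GATK-style hard filter on INFO annotations."""
    report = QCReport(
        n_samples_before=matrix.n_samples,
        n_samples_after=matrix.n_samples,
        n_sites_before=matrix.n_sites,
    )
    keep = []
    for j, site in enumerate(matrix.sites):
        passed, _ = gatk_style_hard_filter(site)
        if passed:
            keep.append(j)
        else:
            report.add_site(site.id, "hard_filter")
    out = matrix.subset(site_idx=keep)
    report.n_sites_after = out.n_sites
    report.check()
    return out, report


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------


def sample_qc(
    matrix: GenotypeMatrix,
    miss: float = 0.05,
    het_sd: float = 3.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Individual-level QC: missingness, then heterozygosity outliers.

    Samples with missing rate > ``miss`` are removed first; then samples
    whose observed heterozygosity lies outside mean +/- ``het_sd`` * SD of
    the remaining samples are removed in a single pass. With SD = 0 the
    heterozygosity rule is vacuous and removes nobody.
    """
    if matrix.n_samples < 3:
        raise ValueError("sample_qc requires at least 3 samples")
    report = QCReport(
        n_samples_before=matrix.n_samples,
        n_sites_before=matrix.n_sites,
        n_sites_after=matrix.n_sites,
    )
    miss_rate = matrix.missing_rate_per_sample()
    keep1 = []
    for i, sample in enumerate(matrix.samples):
        if miss_rate[i] > miss:
            report.add_sample(sample, "missingness")
        else:
            keep1.append(i)

    stage1 = matrix.subset(sample_idx=keep1)
    het = stage1.heterozygosity_per_sample()
    valid = ~np.isnan(het)
    keep2 = []
    if valid.sum() >= 2:
        mu = float(np.mean(het[valid]))
        sd = float(np.std(het[valid], ddof=1))
    else:
        mu, sd = 0.0, 0.0
    for i, sample in enumerate(stage1.samples):
        h = het[i]
        if sd > 0 and not np.isnan(h) and (h > mu + het_sd * sd or h < mu - het_sd * sd):
            report.add_sample(sample, "heterozygosity")
        else:
            keep2.append(i)
    out = stage1.subset(sample_idx=keep2)
    report.n_samples_after = out.n_samples
    report.check()
    return out, report


def _pca_coords(calls: np.ndarray, k: int) -> np.ndarray:
    """Patterson-style PCA coordinates of a dosage matrix (missing = -1)."""
    G = calls.astype(float)
    G[G == MISSING] = np.nan
    colmean = np.nanmean(G, axis=0)
    p = colmean / 2.0
    usable = (p > 0) & (p < 1) & ~np.isnan(p)
    if not usable.any():
        raise ValueError("degenerate genotype matrix: no polymorphic sites")
    G = G[:, usable]
    colmean = colmean[usable]
    p = p[usable]
    G = np.where(np.isnan(G), colmean, G)
    X = (G - colmean) / np.sqrt(p * (1 - p))
    # row-centered SVD
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(k, len(S))
    return U[:, :k] * S[:k]


def pca_outliers(
    matrix: GenotypeMatrix,
    populations: Sequence[str] | None = None,
    k: int = 2,
    sd: float = 6.0,
    max_iter: int = 20,
) -> tuple[pd.DataFrame, list[str]]:
    """Iterative PCA admixture-outlier flagging.

    PCs are computed from the frequency-centered, sqrt(p(1-p))-scaled dosage
    matrix. A sample is flagged when its PC1 or PC2 coordinate falls outside
    mean +/- ``sd`` * SD within its declared population; flagged samples are
    removed and the PCA re-run until no sample is flagged.

    Returns the first-pass PC coordinates for all input samples and the
    flagged sample ids (in flagging order).
    """
    if matrix.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    if populations is None:
        populations = ["all"] * matrix.n_samples
    populations = list(populations)
    if len(populations) != matrix.n_samples:
        raise ValueError("populations length must match samples")

    first_coords = _pca_coords(matrix.calls, k)
    coords_df = pd.DataFrame(
        first_coords,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(first_coords.shape[1])],
    )
    coords_df["population"] = populations

    keep = np.arange(matrix.n_samples)
    flagged: list[str] = []
    coords = first_coords
    for _ in range(max_iter):
        pops_kept = np.asarray([populations[i] for i in keep])
        bad = np.zeros(len(keep), dtype=bool)
        for pop in np.unique(pops_kept):
            rows = pops_kept == pop
            if rows.sum() < 3:
                continue
            sub = coords[rows]
            mu = sub.mean(axis=0)
            sig = sub.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore"):
                out = np.abs(sub - mu) > sd * np.where(sig > 0, sig, np.inf)
            bad[rows] |= out.any(axis=1)
        if not bad.any():
            break
        flagged.extend(matrix.samples[i] for i in keep[bad])
        keep = keep[~bad]
        if len(keep) < k + 1:
            break
        coords = _pca_coords(matrix.calls[keep], k)
    return coords_df, flagged
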