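"""Organ/system enrichment of candidate genes via eQTL interval overlap.

A gene belongs to an organ when its genomic interval overlaps any of the
organ's intervals by at least 1 bp (0-based half-open arithmetic).
Enrichment of the candidate set against a background set is a one-sided
(greater) Fisher exact test per organ, BH-corrected across organs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from hapsel.phenotypes import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class OrganEQTLMap:
    """organ/system label -> list of (chrom, start, end) intervals."""

    intervals: dict

    def __post_init__(self) -> None:
        for organ, ivs in self.intervals.items():
            for chrom, start, end in ivs:
                if start >= end:
                    raise ValueError(f"bad interval {chrom}:{start}-{end} for {organ}")

    @classmethod
    def read_bed(cls, path) -> "OrganEQTLMap":
        t = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "organ"], comment="#",
        )
        out: dict = {}
        for row in t.itertuples(index=False):
            out.setdefault(str(row.organ), []).append(
                (str(row.chrom), int(row.start), int(row.end))
            )
        return cls(out)

    def to_bed(self, path) -> None:
        rows = [
            (chrom, start, end, organ)
            for organ, ivs in self.intervals.items()
            for chrom, start, end in ivs
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _overlaps(a: tuple, b: tuple) -> bool:
    """>= 1 bp overlap of half-open intervals on the same chromosome."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def map_genes_to_organs(
    gene_intervals: dict,
    eqtl: OrganEQTLMap,
) -> dict:
    """organ -> set of genes whose interval overlaps >= 1 bp of the organ's
    intervals. ``gene_intervals`` maps gene -> (chrom, start, end); genes
    without an interval must already be excluded (callers warn)."""
    out: dict = {organ: set() for organ in eqtl.intervals}
    for gene, giv in gene_intervals.items():
        for organ, ivs in eqtl.intervals.items():
            if any(_overlaps(giv, iv) for iv in ivs):
                out[organ].add(gene)
    return out


def fisher_enrichment(
    candidates: set,
    background: set,
    organ_sets: dict,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact enrichment per organ.

    The 2x2 table per organ is [[a, b], [c, d]]: candidates in/out of the
    organ against non-candidate background genes in/out. p is the
    hypergeometric upper tail; BH correction across organs.
    """
    candidates = set(candidates)
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    rest = background - candidates
    rows = []
    for organ, genes in organ_sets.items():
        genes = set(genes) & background
        a = len(candidates & genes)
        b = len(candidates) - a
        c = len(rest & genes)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {"organ": organ, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": float(odds), "p": float(p)}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy(dtype=float))
    out["significant"] = out["q"] < fdr
    return out


def enrich_candidate_genes(
    candidate_genes: list,
    annotation_bounds: dict,
    eqtl: OrganEQTLMap,
) -> pd.DataFrame:
    """Convenience: map all annotated genes to organs and test the candidate
    set against the full annotation background. Genes without an interval in
    the annotation are excluded with a warning."""
    known = {g: iv for g, iv in annotation_bounds.items()}
    missing = [g for g in candidate_genes if g not in known]
    if missing:
        logger.warning("genes without intervals excluded: %s", missing)
    organ_sets = map_genes_to_organs(known, eqtl)
    background = set(known)
    candidates = {g for g in candidate_genes if g in known}
    return fisher_enrichment(candidates, background, organ_sets)
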