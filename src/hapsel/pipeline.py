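"""End-to-end glue: simulator-backed calibration and the scan driver."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hapsel import clump as clump_mod
from hapsel import cms as cms_mod
from hapsel import popgen
from hapsel.io_qc import HaplotypePanel
from hapsel.simulate import SimulationConfig, simulate_populations


def filter_panels_maf(
    panels: dict[str, HaplotypePanel], min_maf: float = 0.05
) -> dict[str, HaplotypePanel]:
    """Restrict every panel to sites with pooled MAF >= ``min_maf``.

    Mirrors locus-level QC running before the selection statistics: rare
    variants carry no usable haplotype/LD information and would otherwise
    dominate the scan with noise.
    """
    mats = list(panels.values())
    total = sum(p.n_hap for p in mats)
    counts = sum(p.haplotypes.sum(axis=0, dtype=np.int64) for p in mats)
    p = counts / total
    keep = np.nonzero(np.minimum(p, 1 - p) >= min_maf)[0]
    return {label: panel.subset_sites(keep) for label, panel in panels.items()}


def scores_for_study(
    panels: dict[str, HaplotypePanel],
    target: str,
    ref: str,
    ref2: str | None = None,
    config: popgen.ScoreConfig | None = None,
    panel_min_maf: float = 0.05,
) -> pd.DataFrame:
    if panel_min_maf > 0:
        panels = filter_panels_maf(panels, panel_min_maf)
    return popgen.compute_scores(
        panels[target],
        panels[ref],
        panels[ref2] if ref2 else None,
        config=config,
    )


def simulate_calibration(
    base_config: SimulationConfig,
    n_neutral: int = 3,
    n_sweep: int = 3,
    sweep_s: float = 0.05,
    sweep_start_gen: int | None = None,
    sweep_min_freq: float = 0.6,
    sweep_max_freq: float = 0.95,
    target: str = "TBP",
    ref: str = "DUROC",
    flank_bp: int = 50_000,
    min_values: int = 500,
    score_config: popgen.ScoreConfig | None = None,
) -> cms_mod.ScoreDistributions:
    """Calibrate the composite score from bundled-simulator replicates.

    Runs ``n_neutral`` neutral and ``n_sweep`` swept replicates derived from
    ``base_config`` (seeds offset deterministically), scores each, and fits
    the class densities: the selected class from the sweep site +/-
    ``flank_bp``, the neutral class from all neutral sites.

    Calibration sweeps default to roughly half the base selection duration
    (``sweep_start_gen``) so they end at intermediate frequency, keeping the
    ancestral-conditioned statistics (iHS/nSL/dIHH) defined in the selected
    class; complete sweeps leave them undefined at the swept sites.
    """
    neutral_scores = []
    sweep_scores = []
    for i in range(n_neutral):
        cfg = replace(base_config, s=0.0, seed=base_config.seed + 1000 + i)
        panels, _ = simulate_populations(cfg)
        panels = filter_panels_maf(panels)
        neutral_scores.append(
            popgen.compute_scores(panels[target], panels[ref], config=score_config)
        )
    if sweep_start_gen is None:
        sweep_start_gen = max(1, base_config.sweep_start_gen // 2)
    for i in range(n_sweep):
        cfg = replace(
            base_config,
            s=sweep_s,
            seed=base_config.seed + 2000 + i,
            sweep_start_gen=sweep_start_gen,
            sweep_min_freq=sweep_min_freq,
            sweep_max_freq=sweep_max_freq,
        )
        panels, truth = simulate_populations(cfg)
        panels = filter_panels_maf(panels)
        df = popgen.compute_scores(panels[target], panels[ref], config=score_config)
        sweep_scores.append((df, truth["sweep_position"]))
    return cms_mod.calibrate(
        neutral_scores,
        sweep_scores,
        flank_bp=flank_bp,
        min_values=min_values,
        meta={"n_neutral": n_neutral, "n_sweep": n_sweep, "sweep_s": sweep_s,
              "seed": base_config.seed},
    )


@dataclass
class ScanResult:
    scores: pd.DataFrame
    cms: cms_mod.CMSResult
    regions: list
    candidate_regions: list
    genes: list


def run_selection_scan(
    panels: dict[str, HaplotypePanel],
    calib: cms_mod.ScoreDistributions,
    target: str = "TBP",
    ref: str = "DUROC",
    ref2: str | None = "YKX",
    annotation=None,
    q: float = 0.001,
    sp2_q: float = 0.01,
    r2_min: float = 0.2,
    radius_kb: float = 500.0,
    min_sp2: int = 5,
    min_components: int = 3,
    llr_cap: float | None = 4.0,
    score_config: popgen.ScoreConfig | None = None,
    panel_min_maf: float = 0.05,
) -> ScanResult:
    """Scores -> composite -> clumping -> candidate regions -> peak genes.

    Panels are first restricted to sites with pooled MAF >=
    ``panel_min_maf`` (locus QC precedes the scan). LD for clumping is
    computed in the target population's panel. When an annotation is given,
    peak genes are called and annotated with the target-enriched allele at
    the peak SNP.
    """
    ref2 = ref2 if ref2 in panels else None
    if panel_min_maf > 0:
        panels = filter_panels_maf(panels, panel_min_maf)
    scores = scores_for_study(panels, target, ref, ref2, config=score_config,
                              panel_min_maf=0.0)
    cms_res = cms_mod.CMSResult.from_scores(
        scores, calib, q=q, min_components=min_components, llr_cap=llr_cap
    )
    regions = clump_mod.clump(
        cms_res.table, panels[target],
        index_q=q, sp2_q=sp2_q, r2_min=r2_min, radius_kb=radius_kb,
    )
    clump_mod.audit_regions(regions, radius_kb=radius_kb)
    candidates = clump_mod.call_candidate_regions(regions, min_sp2=min_sp2)
    genes: list = []
    if annotation is not None:
        genes = clump_mod.peak_gene(candidates, annotation)
        pos_of_id = dict(zip(cms_res.table["id"], range(len(cms_res.table))))
        refs = [panels[ref]] + ([panels[ref2]] if ref2 else [])
        for call in genes:
            j = pos_of_id[call.peak_snp]
            # enriched allele compared on a common (alt) coding
            t_alt = float(panels[target].alt_coded()[:, j].mean())
            r_alts = [float(rp.alt_coded()[:, j].mean()) for rp in refs]
            call.enriched_allele = clump_mod.tbp_enriched_allele(
                popgen.AlleleFreq(t_alt, panels[target].n_hap),
                [popgen.AlleleFreq(p, rp.n_hap) for p, rp in zip(r_alts, refs)],
            )
    return ScanResult(
        scores=scores,
        cms=cms_res,
        regions=regions,
        candidate_regions=candidates,
        genes=genes,
    )
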