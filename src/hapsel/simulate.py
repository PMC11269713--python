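"""Synthetic-study generator with known ground truth.

A discrete-generation forward Wright-Fisher simulator (recombination +
infinite-sites mutation on an L-bp chromosome) produces three populations —
one target that may carry a hard sweep, two lowland references — as phased
panels with exactly known ancestral alleles. On top of the panels it builds
a sample manifest (target sampled high, references across 1000-4000 m),
blood phenotypes with a causal-SNP effect and a blunted altitude response in
the target, tiled gene/regulatory annotations, and an organ eQTL map.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from hapsel.clump import GeneAnnotation
from hapsel.enrichment import OrganEQTLMap
from hapsel.io_qc import HaplotypePanel, SampleManifest, VariantSite, write_vcf

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Demography, genetics and sweep parameters. ``seed`` is mandatory."""

    seed: int
    n_diploid: int = 200  # per-population diploid size N
    generations: int = 400  # ancestral burn-in generations
    split_gen: int = 150  # generations ago: target vs lowland split
    ref_split_gen: int = 100  # generations ago: the two references split
    mu: float = 2.5e-7  # per-site per-generation mutation rate (rescaled)
    rho: float = 2.5e-7  # per-bp per-generation recombination rate (rescaled)
    length: int = 2_000_000  # chromosome length L, bp
    s: float = 0.0  # selection coefficient; 0 = neutral
    sweep_pos: int | None = None  # target bp of the sweep (nearest variant used)
    sweep_pop: str = "TBP"
    sweep_start_gen: int = 140  # generations ago selection switches on
    pop_labels: tuple = ("TBP", "YKX", "DUROC")
    sample_sizes: dict = field(default_factory=lambda: {"TBP": 60, "YKX": 16, "DUROC": 25})
    init_theta_sites: int | None = None  # standing variants at burn-in start
    sweep_min_freq: float = 0.6  # required final sweep frequency in sweep_pop
    sweep_max_freq: float = 1.0  # retry above this too (1.0 = fixation allowed)
    max_sweep_retries: int = 10
    on_sweep_loss: str = "retry"  # 'retry' | 'keep'
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("mu", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.sweep_pos is not None and not (0 <= self.sweep_pos < self.length):
            raise ValueError("sweep_pos must lie in [0, L)")
        if self.ref_split_gen > self.split_gen:
            raise ValueError("ref_split_gen cannot precede split_gen")
        if self.s > 0:
            if self.sweep_start_gen > self.split_gen:
                raise ValueError("sweep must start at or after the target split")
            if self.sweep_pop not in self.pop_labels:
                raise ValueError(f"sweep_pop must be one of {self.pop_labels}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pop_labels"] = list(self.pop_labels)
        return d


# ---------------------------------------------------------------------------
# Wright-Fisher engine
# ---------------------------------------------------------------------------


class _SiteTable:
    """Growable registry of segregating-site positions (infinite sites)."""

    def __init__(self, rng: np.random.Generator):
        self._buf = np.zeros(1024, dtype=np.int64)
        self.m = 0
        self.used: set = set()
        self.rng = rng

    @property
    def positions(self) -> np.ndarray:
        return self._buf[: self.m]

    def new_positions(self, k: int, length: int) -> np.ndarray:
        out = []
        while len(out) < k:
            cand = int(self.rng.integers(1, length + 1))
            if cand not in self.used:
                self.used.add(cand)
                out.append(cand)
        while self.m + k > len(self._buf):
            self._buf = np.concatenate([self._buf, np.zeros_like(self._buf)])
        self._buf[self.m : self.m + k] = out
        self.m += k
        return np.asarray(out, dtype=np.int64)

    def drop(self, keep_mask: np.ndarray) -> None:
        dropped = self.positions[~keep_mask]
        self.used.difference_update(int(p) for p in dropped)
        kept = self.positions[keep_mask]
        self.m = len(kept)
        self._buf[: self.m] = kept


def _reproduce(
    H: np.ndarray,
    positions: np.ndarray,
    length: int,
    rho: float,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    """One Wright-Fisher generation: returns the child haplotype matrix.

    Columns need not be position-sorted; crossover segment assignment uses
    the position of each column directly.
    """
    n2 = H.shape[0]
    n = n2 // 2
    if fitness is None:
        parents = rng.integers(0, n, size=2 * n)
    else:
        w = fitness / fitness.sum()
        parents = rng.choice(n, size=2 * n, p=w)
    start = rng.integers(0, 2, size=2 * n)
    child = H[2 * parents + start].copy()
    n_x = rng.poisson(rho * length, size=2 * n)
    other_rows = 2 * parents + (1 - start)
    # batch meioses by crossover count: 1 and 2 cover nearly all of them
    for k in (1, 2):
        gs = np.nonzero(n_x == k)[0]
        if not len(gs):
            continue
        bps = np.sort(rng.uniform(0, length, size=(len(gs), k)), axis=1)
        take_other = positions[None, :] >= bps[:, :1]
        for i in range(1, k):
            take_other ^= positions[None, :] >= bps[:, i : i + 1]
        child[gs] = np.where(take_other, H[other_rows[gs]], child[gs])
    for g in np.nonzero(n_x > 2)[0]:
        bps = np.sort(rng.uniform(0, length, size=n_x[g]))
        take_other = (np.searchsorted(bps, positions) % 2) == 1
        if take_other.any():
            other = H[other_rows[g]]
            child[g, take_other] = other[take_other]
    return child


class _Simulator:
    """Forward simulation of the three-population demography.

    Population matrices are stored in growable buffers (rows = haplotypes,
    columns = registered sites, shared registry across populations); only
    the first ``sites.m`` columns are live.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.sites = _SiteTable(rng)
        self._bufs: dict[str, np.ndarray] = {}
        self.sweep_col: int | None = None
        self.sweep_position: int | None = None

    @property
    def pops(self) -> dict[str, np.ndarray]:
        return {label: buf[:, : self.sites.m] for label, buf in self._bufs.items()}

    def _set_pop(self, label: str, H: np.ndarray) -> None:
        cap = max(1024, 2 * H.shape[1])
        buf = np.zeros((H.shape[0], cap), dtype=np.uint8)
        buf[:, : H.shape[1]] = H
        self._bufs[label] = buf

    def _ensure_capacity(self, n_cols: int) -> None:
        for label, buf in self._bufs.items():
            if buf.shape[1] < n_cols:
                grown = np.zeros((buf.shape[0], max(n_cols, 2 * buf.shape[1])), dtype=np.uint8)
                grown[:, : buf.shape[1]] = buf
                self._bufs[label] = grown

    # -- site bookkeeping ---------------------------------------------------

    def _add_mutations(self, label: str) -> None:
        cfg = self.cfg
        n_hap = self._bufs[label].shape[0]
        n_new = self.rng.poisson(n_hap * cfg.mu * cfg.length)
        if n_new == 0:
            return
        m0 = self.sites.m
        self.sites.new_positions(n_new, cfg.length)
        self._ensure_capacity(self.sites.m)
        for buf in self._bufs.values():
            buf[:, m0 : self.sites.m] = 0
        rows = self.rng.integers(0, n_hap, size=n_new)
        self._bufs[label][rows, np.arange(m0, self.sites.m)] = 1

    def _prune(self) -> None:
        """Drop columns lost everywhere or fixed everywhere; the sweep
        column, once chosen, is always retained so its fate stays visible."""
        m = self.sites.m
        if m == 0:
            return
        total = sum(buf.shape[0] for buf in self._bufs.values())
        colsum = sum(
            buf[:, :m].sum(axis=0, dtype=np.int64) for buf in self._bufs.values()
        )
        keep = (colsum > 0) & (colsum < total)
        if self.sweep_col is not None:
            keep[self.sweep_col] = True
            self.sweep_col = int(keep[: self.sweep_col].sum())
        if keep.all():
            return
        for label, buf in self._bufs.items():
            kept = buf[:, :m][:, keep]
            buf[:, : kept.shape[1]] = kept
        self.sites.drop(keep)

    # -- generations ---------------------------------------------------------

    def _step(self, label: str, sweep_active: bool) -> None:
        cfg = self.cfg
        m = self.sites.m
        H = self._bufs[label][:, :m]
        fitness = None
        if sweep_active and self.sweep_col is not None:
            dosage = H[0::2, self.sweep_col].astype(float) + H[1::2, self.sweep_col]
            fitness = (1.0 + cfg.s) ** dosage
        child = _reproduce(H, self.sites.positions, cfg.length, cfg.rho, self.rng, fitness)
        self._bufs[label][:, :m] = child
        self._add_mutations(label)

    def _init_standing_variation(self) -> None:
        """Seed the burn-in with SFS-distributed standing variants (linkage
        equilibrium start; the burn-in builds haplotype structure)."""
        cfg = self.cfg
        n2 = 2 * cfg.n_diploid
        k = cfg.init_theta_sites
        if k is None:
            theta = 4 * cfg.n_diploid * cfg.mu * cfg.length
            k = int(theta * np.log(max(n2, 2)))
        if k <= 0:
            self._set_pop("anc", np.zeros((n2, 0), dtype=np.uint8))
            return
        weights = 1.0 / np.arange(1, n2)
        counts = self.rng.choice(np.arange(1, n2), size=k, p=weights / weights.sum())
        H = np.zeros((n2, k), dtype=np.uint8)
        for j, c in enumerate(counts):
            rows = self.rng.choice(n2, size=int(c), replace=False)
            H[rows, j] = 1
        self.sites.new_positions(k, cfg.length)
        self._set_pop("anc", H)

    def _carrier_background_identity(self, col: int, flank_bp: int = 25_000) -> float:
        """Fraction of carrier haplotype pairs identical over the site's
        flanking window — 1.0 means a single haplotype background."""
        cfg = self.cfg
        m = self.sites.m
        H = self._bufs[cfg.sweep_pop][:, :m]
        positions = self.sites.positions
        window = np.nonzero(np.abs(positions - positions[col]) <= flank_bp)[0]
        carriers = np.nonzero(H[:, col] == 1)[0]
        if len(carriers) < 2:
            return 1.0
        sub = H[np.ix_(carriers, window)]
        _, counts = np.unique(sub, axis=0, return_counts=True)
        pairs = float((counts * (counts - 1) // 2).sum())
        denom = len(carriers) * (len(carriers) - 1) / 2
        return pairs / denom

    def _pick_sweep_site(self) -> None:
        """Choose the selected variant: a rare standing variant whose carriers
        share a single haplotype background (a hard sweep by construction),
        closest to the requested position; falls back to commoner or
        mixed-background variants and finally to an injected new mutation."""
        cfg = self.cfg
        m = self.sites.m
        H = self._bufs[cfg.sweep_pop][:, :m]
        n2 = H.shape[0]
        freqs = H.mean(axis=0)
        target_bp = cfg.sweep_pos if cfg.sweep_pos is not None else cfg.length // 2
        for lo, hi, min_ident in (
            (max(0.008, 1.9 / n2), 0.035, 0.9),
            (max(0.008, 1.9 / n2), 0.035, 0.0),
            (1.9 / n2, 0.1, 0.0),
            (0.0, 0.25, 0.0),
        ):
            cand = np.nonzero((freqs > lo) & (freqs <= hi))[0]
            if min_ident > 0 and len(cand):
                cand = cand[: 4000]  # bound the background checks
                cand = np.asarray(
                    [j for j in cand
                     if self._carrier_background_identity(int(j)) >= min_ident],
                    dtype=int,
                )
            if len(cand):
                j = cand[np.argmin(np.abs(self.sites.positions[cand] - target_bp))]
                self.sweep_col = int(j)
                self.sweep_position = int(self.sites.positions[j])
                return
        # no usable standing variant: inject a new mutation near the target bp
        pos = self.sites.new_positions(1, cfg.length)
        self._ensure_capacity(self.sites.m)
        for buf in self._bufs.values():
            buf[:, self.sites.m - 1] = 0
        self._bufs[cfg.sweep_pop][int(self.rng.integers(0, H.shape[0])), self.sites.m - 1] = 1
        self.sweep_col = self.sites.m - 1
        self.sweep_position = int(pos[0])

    def run_burn_in(self) -> None:
        cfg = self.cfg
        self._init_standing_variation()
        for g in range(cfg.generations):
            self._step("anc", sweep_active=False)
            if g % 25 == 24:
                self._prune()

    def snapshot(self) -> dict:
        return {
            "bufs": {k: v.copy() for k, v in self._bufs.items()},
            "site_buf": self.sites._buf.copy(),
            "m": self.sites.m,
            "used": set(self.sites.used),
        }

    def restore(self, snap: dict, rng: np.random.Generator) -> None:
        self._bufs = {k: v.copy() for k, v in snap["bufs"].items()}
        self.sites._buf = snap["site_buf"].copy()
        self.sites.m = snap["m"]
        self.sites.used = set(snap["used"])
        self.rng = rng
        self.sites.rng = rng
        self.sweep_col = None
        self.sweep_position = None

    def run_splits(self, abort_on_loss: bool = True) -> None:
        cfg = self.cfg
        t_lbl, r1_lbl, r2_lbl = cfg.pop_labels
        self._bufs[t_lbl] = self._bufs.pop("anc")
        self._bufs[r1_lbl] = self._bufs[t_lbl].copy()
        sweep_on = cfg.s > 0

        for gens_left in range(cfg.split_gen, 0, -1):
            if gens_left == cfg.ref_split_gen:
                self._bufs[r2_lbl] = self._bufs[r1_lbl].copy()
            if sweep_on and self.sweep_col is None and gens_left == cfg.sweep_start_gen:
                self._pick_sweep_site()
            sweeping = sweep_on and self.sweep_col is not None
            for label in list(self._bufs):
                active = sweeping and label == cfg.sweep_pop and gens_left <= cfg.sweep_start_gen
                self._step(label, sweep_active=active)
            if abort_on_loss and sweeping and self.sweep_freq() == 0.0:
                if r2_lbl not in self._bufs:
                    self._bufs[r2_lbl] = self._bufs[r1_lbl].copy()
                return  # sweep allele lost: abort the attempt early
            if gens_left % 25 == 0:
                self._prune()
        self._prune()

    def sweep_freq(self) -> float:
        if self.sweep_col is None:
            return float("nan")
        return float(self._bufs[self.cfg.sweep_pop][:, self.sweep_col].mean())


def _sample_panels(
    sim: _Simulator, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, HaplotypePanel]:
    order = np.argsort(sim.sites.positions)
    positions = sim.sites.positions[order]

    # keep sites segregating in at least one sampled panel
    sampled: dict[str, np.ndarray] = {}
    for label in config.pop_labels:
        H = sim.pops[label]
        n = H.shape[0] // 2
        take = rng.choice(n, size=min(config.sample_sizes[label], n), replace=False)
        rows = np.stack([2 * take, 2 * take + 1], axis=1).reshape(-1)
        sampled[label] = H[rows][:, order]
    total = sum(M.shape[0] for M in sampled.values())
    colsum = sum(M.sum(axis=0, dtype=np.int64) for M in sampled.values())
    keep = (colsum > 0) & (colsum < total)
    positions = positions[keep]

    ref_bases = _BASES[rng.integers(0, 4, size=len(positions))]
    alt_shift = rng.integers(1, 4, size=len(positions))
    alt_bases = _BASES[
        (np.searchsorted(_BASES, ref_bases) + alt_shift) % 4
    ]
    sites = [
        VariantSite(
            chrom=config.chrom,
            pos=int(p),
            id=f"snp{idx}",
            ref=str(r),
            alt=str(a),
            ancestral="ref",  # derived alleles arise as alt by construction
        )
        for idx, (p, r, a) in enumerate(zip(positions, ref_bases, alt_bases))
    ]
    panels = {}
    for label in config.pop_labels:
        M = sampled[label][:, keep]
        n = M.shape[0] // 2
        ids = [f"{label}_{i:03d}" for i in range(n)]
        panels[label] = HaplotypePanel(
            haplotypes=M,
            sites=[VariantSite(**{**s.__dict__}) for s in sites],
            sample_of_haplotype=[sid for sid in ids for _ in range(2)],
            population=label,
        )
    return panels


def simulate_populations(
    config: SimulationConfig,
) -> tuple[dict[str, HaplotypePanel], dict]:
    """Run the forward simulation and sample phased panels per population.

    Returns (panels, truth). With ``s > 0`` the run is retried (new RNG
    substream, bounded by ``max_sweep_retries``) until the sweep allele
    reaches ``sweep_min_freq`` in the sweep population, unless
    ``on_sweep_loss='keep'``. Deterministic given ``config.seed``.
    """
    sim = _Simulator(config, np.random.default_rng([config.seed, 0]))
    sim.run_burn_in()
    snap = sim.snapshot()  # burn-in is shared across sweep retries
    attempts = 0
    while True:
        sim.restore(snap, np.random.default_rng([config.seed, 1 + attempts]))
        sim.run_splits()
        freq = sim.sweep_freq()
        if (
            config.s == 0
            or config.on_sweep_loss == "keep"
            or (
                np.isfinite(freq)
                and config.sweep_min_freq <= freq <= config.sweep_max_freq
            )
        ):
            break
        attempts += 1
        if attempts > config.max_sweep_retries:
            logger.warning("no in-window sweep in %d attempts; keeping last run", attempts)
            # complete demography for the kept run (no early abort)
            sim.restore(snap, np.random.default_rng([config.seed, attempts]))
            sim.run_splits(abort_on_loss=False)
            break
        logger.info("sweep at freq %.3f outside window; retry %d", freq, attempts)

    panels = _sample_panels(sim, config, np.random.default_rng([config.seed, attempts, 1]))
    truth = {
        "config": config.to_dict(),
        "attempts": attempts,
        "sweep_position": sim.sweep_position,
        "sweep_final_freq": sim.sweep_freq(),
        "sweep_pop": config.sweep_pop if config.s > 0 else None,
        "n_sites": panels[config.pop_labels[0]].n_sites,
    }
    return panels, truth


# ---------------------------------------------------------------------------
# manifest + phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeConfig:
    """Effect sizes for the synthetic blood phenotypes."""

    causal_pos: int | None = None  # nearest usable variant is chosen
    beta_hgb: float = -8.0  # g/L per derived-allele copy
    slope_ref: float = 0.02  # g/L per metre in the references
    slope_target: float = 0.0  # blunted response
    intercept_hgb: float = 120.0
    sigma_hgb: float = 10.0
    latent_sd: float = 1.0  # shared factor linking HGB / RBC / HCT
    sigma_other: float = 1.0
    min_causal_maf: float = 0.1
    altitude_target: tuple = (3000.0, 4300.0)
    altitude_refs: tuple = (1000.0, 4000.0)


def make_manifest(
    panels: dict[str, HaplotypePanel],
    config: SimulationConfig,
    pheno_cfg: PhenotypeConfig,
    rng: np.random.Generator,
) -> SampleManifest:
    rows = []
    target = config.pop_labels[0]
    for label, panel in panels.items():
        lo, hi = (
            pheno_cfg.altitude_target if label == target else pheno_cfg.altitude_refs
        )
        for sid in panel.samples:
            rows.append(
                {
                    "sample": sid,
                    "population": label,
                    "altitude": float(np.round(rng.uniform(lo, hi), 1)),
                    "sex": int(rng.integers(0, 2)),
                    "age": int(rng.integers(1, 6)),
                }
            )
    return SampleManifest(pd.DataFrame(rows))


def _pick_causal_site(panel: HaplotypePanel, cfg: PhenotypeConfig) -> int:
    freqs = panel.haplotypes.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    target_bp = cfg.causal_pos if cfg.causal_pos is not None else int(np.median(panel.positions))
    cand = np.nonzero(maf >= cfg.min_causal_maf)[0]
    if not len(cand):
        raise ValueError("no segregating site with sufficient MAF for the causal SNP")
    return int(cand[np.argmin(np.abs(panel.positions[cand] - target_bp))])


def simulate_phenotypes(
    panels: dict[str, HaplotypePanel],
    manifest: SampleManifest,
    config: SimulationConfig,
    pheno_cfg: PhenotypeConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Blood-index table with a causal-SNP effect on HGB, population-specific
    altitude slopes (blunted in the target), and a latent factor shared by
    HGB/RBC/HCT. Returns (table, truth)."""
    target = config.pop_labels[0]
    causal_j = _pick_causal_site(panels[target], pheno_cfg)
    causal_site = panels[target].sites[causal_j]

    dosages = {}
    for label, panel in panels.items():
        H = panel.haplotypes
        d = H[0::2, causal_j].astype(float) + H[1::2, causal_j]
        dosages.update(dict(zip(panel.samples, d)))

    rows = []
    for rec in manifest.table.itertuples(index=False):
        dose = dosages.get(rec.sample, 0.0)
        slope = pheno_cfg.slope_target if rec.population == target else pheno_cfg.slope_ref
        latent = rng.normal(0.0, pheno_cfg.latent_sd)
        hgb = (
            pheno_cfg.intercept_hgb
            + slope * rec.altitude
            + pheno_cfg.beta_hgb * dose
            + 6.0 * latent
            + rng.normal(0.0, pheno_cfg.sigma_hgb)
        )
        rbc = 6.0 + 0.35 * latent + rng.normal(0.0, 0.35)
        hct = 0.40 + 0.03 * latent + rng.normal(0.0, 0.03)
        row = {
            "sample": rec.sample,
            "population": rec.population,
            "altitude": rec.altitude,
            "sex": rec.sex,
            "age": rec.age,
            "HGB": hgb,
            "RBC": rbc,
            "HCT": hct,
            "RDW": 14.0 + rng.normal(0.0, pheno_cfg.sigma_other),
            "MCV": 60.0 + rng.normal(0.0, 3 * pheno_cfg.sigma_other),
            "MCH": 18.0 + rng.normal(0.0, pheno_cfg.sigma_other),
            "MCHC": 320.0 + rng.normal(0.0, 8 * pheno_cfg.sigma_other),
            "WBC": 12.0 + rng.normal(0.0, 2 * pheno_cfg.sigma_other),
            "PLT": 300.0 + rng.normal(0.0, 40 * pheno_cfg.sigma_other),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if all(dosages.get(s, 0.0) == next(iter(dosages.values())) for s in dosages):
        raise ValueError("causal SNP is monomorphic across samples")
    truth = {
        "causal_snp": causal_site.id,
        "causal_pos": causal_site.pos,
        "beta_hgb": pheno_cfg.beta_hgb,
        "slope_target": pheno_cfg.slope_target,
        "slope_ref": pheno_cfg.slope_ref,
        "sigma_hgb": pheno_cfg.sigma_hgb,
        "latent_pairs": ["HGB", "RBC", "HCT"],
    }
    return table, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def make_fixture_annotations(
    config: SimulationConfig,
    sweep_pos: int | None,
    causal_pos: int | None,
    rng: np.random.Generator,
    gene_span: int = 30_000,
    gap: int = 10_000,
    organs: tuple = ("blood", "heart", "brain", "muscle", "liver", "digestion"),
) -> tuple[GeneAnnotation, OrganEQTLMap]:
    """Tile non-overlapping genes (UTR5/CDS/intron/CDS/UTR3) plus regulatory
    intervals over [0, L), phased so the sweep position falls inside a gene
    body, and assign organs to gene intervals with 'blood' guaranteed to
    cover the causal SNP's gene."""
    L = config.length
    period = gene_span + gap
    anchor = sweep_pos if sweep_pos is not None else L // 2
    offset = (anchor - gene_span // 2) % period

    rows = []
    gene_bounds = []
    k = 0
    start = offset - period
    while start < L:
        g0 = start
        g1 = start + gene_span
        if g0 >= 0 and g1 <= L:
            name = f"G{k:04d}"
            # UTR5 | CDS | intron | CDS | UTR3, proportional to the span
            u5 = u3 = max(gene_span // 15, 1)
            c1 = c2 = max(gene_span // 5, 1)
            intr = gene_span - u5 - u3 - c1 - c2
            b = g0
            for span, cls in ((u5, "UTR5"), (c1, "CDS"), (intr, "intron"),
                              (c2, "CDS"), (u3, "UTR3")):
                rows.append((config.chrom, b, b + span, name, cls, "+"))
                b += span
            gene_bounds.append((name, g0, g1))
            # a regulatory element in every other inter-genic gap
            if k % 2 == 0 and g1 + 2_000 + gap // 2 <= L:
                rows.append(
                    (config.chrom, g1 + gap // 2, g1 + gap // 2 + 2_000,
                     f"RE{k:04d}", "regulatory", "+")
                )
            k += 1
        start += period
    annotation = GeneAnnotation(
        pd.DataFrame(rows, columns=GeneAnnotation.COLUMNS)
    )

    causal_anchor = causal_pos if causal_pos is not None else anchor
    causal_gene = None
    for name, g0, g1 in gene_bounds:
        if g0 <= causal_anchor - 1 < g1:
            causal_gene = (name, g0, g1)
            break

    organ_map: dict = {o: [] for o in organs}
    if causal_gene is not None:
        organ_map["blood"].append((config.chrom, causal_gene[1], causal_gene[2]))
    for name, g0, g1 in gene_bounds:
        for o in organs:
            if rng.random() < 0.25:
                organ_map[o].append((config.chrom, g0, g1))
    for o in organs:  # no empty organs
        if not organ_map[o]:
            name, g0, g1 = gene_bounds[int(rng.integers(0, len(gene_bounds)))]
            organ_map[o].append((config.chrom, g0, g1))
    return annotation, OrganEQTLMap(organ_map)


# ---------------------------------------------------------------------------
# bundled study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """Everything one pipeline run needs, with ground truth."""

    panels: dict  # population -> HaplotypePanel
    manifest: SampleManifest
    phenotypes: pd.DataFrame
    annotation: GeneAnnotation
    organ_map: OrganEQTLMap
    truth: dict

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for label, panel in self.panels.items():
            write_vcf(panel, os.path.join(outdir, f"{label}.vcf"))
        self.manifest.to_tsv(os.path.join(outdir, "manifest.tsv"))
        self.phenotypes.to_csv(os.path.join(outdir, "phenotypes.tsv"), sep="\t", index=False)
        self.annotation.to_bed(os.path.join(outdir, "genes.bed"))
        self.organ_map.to_bed(os.path.join(outdir, "organs.bed"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def simulate_study(
    config: SimulationConfig,
    pheno_cfg: PhenotypeConfig | None = None,
) -> SimulatedStudy:
    """Generate a full synthetic study, deterministic given ``config.seed``."""
    pheno_cfg = pheno_cfg or PhenotypeConfig()
    panels, truth = simulate_populations(config)
    rng = np.random.default_rng([config.seed, 7])
    manifest = make_manifest(panels, config, pheno_cfg, rng)
    if pheno_cfg.causal_pos is None and truth["sweep_position"] is not None:
        pheno_cfg = PhenotypeConfig(**{**asdict(pheno_cfg), "causal_pos": truth["sweep_position"]})
    pheno, pheno_truth = simulate_phenotypes(panels, manifest, config, pheno_cfg, rng)
    annotation, organ_map = make_fixture_annotations(
        config,
        truth["sweep_position"],
        pheno_truth["causal_pos"],
        np.random.default_rng([config.seed, 11]),
    )
    truth = {**truth, **pheno_truth}
    return SimulatedStudy(
        panels=panels,
        manifest=manifest,
        phenotypes=pheno,
        annotation=annotation,
        organ_map=organ_map,
        truth=truth,
    )
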