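"""End-to-end orchestration: simulate -> GL -> SFS -> theta -> scan -> trees.

`run_replicate` executes the whole analysis once on a synthetic genome;
`run_replication` repeats it, tabulating sweep-window CLDGR recall, topology
class frequencies at the sweep locus versus genome-wide, and the flank-size
and concatenation dilution curves.

Per-subpopulation theta estimation collapses sites with identical
(order-insensitive) read-count configurations before the SAF/EM stage: the
SAF vector and filters depend only on that multiset, so the collapsed,
weighted computation is exactly equivalent and much faster at genome scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import genolik, safsfs, sweepscan, thetawin, treetopo
from .simpop import (
    DOM_SUBPOPS,
    DemographyConfig,
    ReadPile,
    apply_sweep_introgression,
    simulate_haplotypes,
    simulate_reads,
)

logger = logging.getLogger("domsweep")

WILD_REFERENCE = "OrII"
DEFAULT_WINDOW_SIZES = (20_000,)


@dataclass
class RunConfig:
    """Configuration of a full replication experiment."""

    demography: DemographyConfig = field(default_factory=DemographyConfig)
    mean_depth: float = 2.0
    error_rate: float = 0.001
    window_sizes: Tuple[int, ...] = DEFAULT_WINDOW_SIZES
    percentile: float = 97.5
    flank_sizes: Tuple[int, ...] = (20_000, 500_000)
    gene_interval: Optional[Tuple[int, int]] = None
    n_replicates: int = 20
    seed: int = 1
    sweep: bool = True
    n_concat_neutral: int = 50
    min_snps: int = 20
    min_pair_overlap: int = 20
    min_finite_ratios: int = 40
    em_tol: float = 1e-8
    em_max_iter: int = 500
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if self.gene_interval is None:
            s0, s1 = self.demography.sweep_interval
            mid = (s0 + s1) // 2
            self.gene_interval = (mid - 2_000, mid + 2_000)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        demo = raw.pop("demography", {})
        cfg = cls(demography=DemographyConfig.from_dict(demo), **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()
        })
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["demography"] = self.demography.to_dict()
        d["window_sizes"] = list(self.window_sizes)
        d["flank_sizes"] = list(self.flank_sizes)
        d["gene_interval"] = list(self.gene_interval)
        return d


# ---------------------------------------------------------------------------
# per-subpopulation theta estimation


def _unique_rows(codes: np.ndarray):
    """Row-deduplicate a non-negative integer matrix.

    Packs rows into uint64 chunks and lexsorts, which is much faster than
    ``np.unique(axis=0)`` at genome scale. Returns (representative row
    indices, inverse, counts).
    """
    c = np.ascontiguousarray(codes, dtype=np.uint64)
    S, n = c.shape
    bits = max(1, int(np.uint64(c.max() if S else 0)).bit_length())
    per = max(1, 64 // bits)
    k = -(-n // per)
    packed = np.zeros((S, k), dtype=np.uint64)
    for i in range(n):
        col = i // per
        packed[:, col] = (packed[:, col] << np.uint64(bits)) | c[:, i]
    order = np.lexsort(packed.T[::-1])
    sp = packed[order]
    boundary = np.ones(S, dtype=bool)
    if S > 1:
        boundary[1:] = np.any(sp[1:] != sp[:-1], axis=1)
    group = np.cumsum(boundary) - 1
    inverse = np.empty(S, dtype=np.int64)
    inverse[order] = group
    counts = np.bincount(group)
    return order[boundary], inverse, counts


def _collapse_counts(ref: np.ndarray, alt: np.ndarray):
    """Collapse sites sharing the same multiset of per-individual counts.

    Returns (uref, ualt, inverse, multiplicity): unique count configurations
    (U, n) each, plus the per-site index into them. Sorting within each site
    makes the key order-insensitive, which is safe because the SAF is
    exchangeable over individuals.
    """
    code = ref.astype(np.int32) * 4096 + alt.astype(np.int32)
    code = np.sort(code, axis=1)
    rep, inverse, counts = _unique_rows(code)
    uniq = code[rep]
    uref = (uniq // 4096).astype(np.int16)
    ualt = (uniq % 4096).astype(np.int16)
    return uref, ualt, inverse, counts


@dataclass
class ThetaResult:
    positions: np.ndarray  # sites with data (filter-passing)
    theta_pi: np.ndarray
    theta_w: np.ndarray
    sfs: np.ndarray
    windows: Dict[int, pd.DataFrame]


def theta_pipeline(
    pile: ReadPile,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    filters: genolik.SiteFilterConfig | None = None,
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
    chrom: str = "chr1",
) -> ThetaResult:
    """GL -> SAF -> SFS -> per-site theta -> window tables for one subpopulation."""
    n = pile.n_individuals
    if filters is None:
        filters = genolik.SiteFilterConfig.for_sample_size(n)
    site_pass = genolik.apply_site_filters(pile, filters)
    positions = np.flatnonzero(site_pass).astype(np.int64)
    ref = pile.ref[site_pass]
    alt = pile.alt[site_pass]
    uref, ualt, inverse, mult = _collapse_counts(ref, alt)
    gl = genolik.site_genotype_likelihood(uref, ualt, pile.error_rate)
    saf_log = safsfs.saf(gl)
    sfs = safsfs.estimate_sfs(
        saf_log, weights=mult.astype(float), tol=em_tol, max_iter=em_max_iter
    )
    post = safsfs.posterior_freq(saf_log, sfs)
    tpi_u, tw_u = thetawin.per_site_theta(post, 2 * n)
    theta_pi = tpi_u[inverse]
    theta_w = tw_u[inverse]
    windows = {
        w: thetawin.window_scan(positions, theta_pi, pile.L, w, chrom=chrom)
        for w in window_sizes
    }
    return ThetaResult(positions, theta_pi, theta_w, sfs, windows)


# ---------------------------------------------------------------------------
# SNP / distance stage over all samples


@dataclass
class SnpPosteriors:
    positions: np.ndarray  # (S,) SNP coordinates
    post: np.ndarray  # (n, S, 3) genotype posteriors
    covered: np.ndarray  # (n, S) bool
    ids: List[str]


def snp_stage(
    pile: ReadPile,
    ids: Sequence[str],
    filters: genolik.SiteFilterConfig | None = None,
    snp_pval: float = 1e-3,
    prior: str = "hwe",
) -> SnpPosteriors:
    """Call SNPs from pooled GLs and compute per-individual posteriors.

    Sites need at least two reads of each allele pooled across samples to be
    evaluated (anything rarer cannot approach the likelihood-ratio
    threshold), then the 1-df LRT at ``snp_pval`` decides SNP status.
    """
    n = pile.n_individuals
    if filters is None:
        filters = genolik.SiteFilterConfig.for_sample_size(n)
    site_pass = genolik.apply_site_filters(pile, filters)
    total_alt = pile.alt.sum(axis=1, dtype=np.int64)
    total_ref = pile.ref.sum(axis=1, dtype=np.int64)
    candidates = site_pass & (total_alt >= 2) & (total_ref >= 2)
    cand_idx = np.flatnonzero(candidates)
    if cand_idx.size == 0:
        return SnpPosteriors(
            cand_idx, np.zeros((n, 0, 3)), np.zeros((n, 0), dtype=bool), list(ids)
        )
    gl = genolik.site_genotype_likelihood(
        pile.ref[cand_idx], pile.alt[cand_idx], pile.error_rate
    )
    gl_lin = np.exp(gl - gl.max(axis=-1, keepdims=True))
    is_snp, _, freq = genolik.snp_call(gl, p_threshold=snp_pval)
    keep = np.flatnonzero(is_snp)
    post = genolik.genotype_posterior(gl_lin[keep], freq[keep], prior=prior)
    return SnpPosteriors(
        cand_idx[keep],
        np.ascontiguousarray(post.transpose(1, 0, 2)),
        (pile.depth[cand_idx[keep]] > 0).T.copy(),
        list(ids),
    )


# ---------------------------------------------------------------------------
# one replicate


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    truth_pi: Dict[str, np.ndarray]
    theta: Dict[str, ThetaResult]
    ratios: Dict[str, pd.DataFrame]
    threshold: Optional[float]
    cldgr: Optional[pd.DataFrame]
    n_passing_windows: int
    sweep_called: Optional[bool]
    genomewide_class: Optional[str]
    sweep_class: Optional[str]
    flank_classes: Dict[int, str]
    concat_classes: List[str]
    concat_flip_k: Optional[int]

    def slim(self) -> "ReplicateResult":
        """Drop the large per-site arrays, keeping scalars and tables."""
        return dataclasses.replace(self, truth_pi={}, theta={})


def _analysis_subpops() -> List[str]:
    return [WILD_REFERENCE] + list(DOM_SUBPOPS)


def run_replicate(
    cfg: RunConfig, replicate: int = 0, with_trees: bool = True
) -> ReplicateResult:
    """Run the full pipeline once; deterministic in (cfg, replicate)."""
    t0 = time.time()
    rep_seed = int(
        np.random.SeedSequence([cfg.seed, 7_777, replicate]).generate_state(1)[0]
        % (2**31 - 1)
    ) + 1
    demo = cfg.demography.replace(seed=rep_seed)
    haps = simulate_haplotypes(demo)
    if cfg.sweep:
        haps = apply_sweep_introgression(haps, demo)
    pile = simulate_reads(haps, cfg.mean_depth, cfg.error_rate, seed=rep_seed)
    ids = haps.individual_ids()
    window = cfg.window_sizes[0]

    truth_pi = {sp: haps.window_pi(sp, window) for sp in _analysis_subpops()}

    theta: Dict[str, ThetaResult] = {}
    for sp in _analysis_subpops():
        sub = pile.subset(haps.individuals_of(sp))
        theta[sp] = theta_pipeline(
            sub,
            cfg.window_sizes,
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            chrom=demo.chrom,
        )
        logger.debug("replicate %d: theta(%s) done", replicate, sp)

    ratios = {
        d: sweepscan.pi_ratio(theta[WILD_REFERENCE].windows[window], theta[d].windows[window])
        for d in DOM_SUBPOPS
    }
    n_passing = int(min(len(r) for r in ratios.values()))
    threshold = None
    cldgr = None
    sweep_called = None
    try:
        threshold = sweepscan.common_threshold(
            ratios, cfg.percentile, cfg.min_finite_ratios
        )
        cldgr = sweepscan.find_cldgr(ratios, threshold)
    except ValueError as exc:
        logger.warning("replicate %d: scan stage skipped (%s)", replicate, exc)
    if cldgr is not None and cfg.sweep:
        s0, s1 = demo.sweep_interval
        hit = (cldgr["start"] < s1) & (cldgr["end"] > s0)
        sweep_called = bool(hit.any())

    genomewide_class = sweep_class = None
    flank_classes: Dict[int, str] = {}
    concat_classes: List[str] = []
    concat_flip_k = None
    if with_trees:
        snp = snp_stage(pile, ids)
        tree_kwargs = dict(
            min_snps=cfg.min_snps, min_overlap=cfg.min_pair_overlap,
            progenitors=demo.progenitors,
        )
        _, genomewide_class, _ = treetopo.region_tree(
            snp.post, snp.covered, snp.positions, ids, (0, demo.L), **tree_kwargs
        )
        if cfg.sweep:
            _, sweep_class, _ = treetopo.region_tree(
                snp.post, snp.covered, snp.positions, ids, demo.sweep_interval,
                **tree_kwargs,
            )
            g0, g1 = cfg.gene_interval
            for flank in cfg.flank_sizes:
                iv = (max(0, g0 - flank), min(demo.L, g1 + flank))
                _, cls, _ = treetopo.region_tree(
                    snp.post, snp.covered, snp.positions, ids, iv, **tree_kwargs
                )
                flank_classes[flank] = cls
            concat_classes, concat_flip_k = _concatenation(
                cfg, demo, snp, ids, window
            )
    logger.info(
        "replicate %d finished in %.1fs (sweep_called=%s gw=%s sweep=%s)",
        replicate, time.time() - t0, sweep_called, genomewide_class, sweep_class,
    )
    return ReplicateResult(
        replicate=replicate,
        seed=rep_seed,
        truth_pi=truth_pi,
        theta=theta,
        ratios=ratios,
        threshold=threshold,
        cldgr=cldgr,
        n_passing_windows=n_passing,
        sweep_called=sweep_called,
        genomewide_class=genomewide_class,
        sweep_class=sweep_class,
        flank_classes=flank_classes,
        concat_classes=concat_classes,
        concat_flip_k=concat_flip_k,
    )


def _concatenation(cfg: RunConfig, demo: DemographyConfig, snp: SnpPosteriors, ids, window):
    """Pair statistics for the sweep window plus k neutral windows."""
    s0, s1 = demo.sweep_interval
    stats = [treetopo.pair_diff_stats(
        snp.post, snp.covered, (snp.positions >= s0) & (snp.positions < s1)
    )]
    n_added = 0
    start = 0
    while n_added < cfg.n_concat_neutral and start + window <= demo.L:
        end = start + window
        if end <= s0 or start >= s1:  # disjoint from the sweep
            mask = (snp.positions >= start) & (snp.positions < end)
            if mask.sum() >= cfg.min_snps:
                stats.append(treetopo.pair_diff_stats(snp.post, snp.covered, mask))
                n_added += 1
        start = end
    return treetopo.concatenation_experiment(
        stats, ids, min_overlap=cfg.min_pair_overlap, progenitors=demo.progenitors
    )


# ---------------------------------------------------------------------------
# replication experiment


def summarize(results: Sequence[ReplicateResult], cfg: RunConfig) -> dict:
    n = len(results)
    report: dict = {"n_replicates": n, "sweep": cfg.sweep}
    called = [r.sweep_called for r in results if r.sweep_called is not None]
    if called:
        report["cldgr_sweep_recall"] = float(np.mean(called))
    total_cldgr = sum(len(r.cldgr) for r in results if r.cldgr is not None)
    total_windows = sum(r.n_passing_windows for r in results)
    report["cldgr_fraction"] = (
        float(total_cldgr) / total_windows if total_windows else float("nan")
    )
    def _freq(values):
        vals = [v for v in values if v is not None]
        if not vals:
            return {}
        labels, counts = np.unique(vals, return_counts=True)
        return {str(l): float(c) / len(vals) for l, c in zip(labels, counts)}

    report["genomewide_class_freq"] = _freq([r.genomewide_class for r in results])
    report["sweep_class_freq"] = _freq([r.sweep_class for r in results])
    report["flank_class_freq"] = {
        str(f): _freq([r.flank_classes.get(f) for r in results])
        for f in cfg.flank_sizes
    }
    flips = [r.concat_flip_k for r in results if r.concat_classes]
    report["concat_flip_fraction"] = (
        float(np.mean([f is not None for f in flips])) if flips else None
    )
    report["concat_flip_k"] = [f if f is not None else -1 for f in flips]
    return report


def run_replication(cfg: RunConfig, with_trees: bool = True) -> dict:
    """Run ``cfg.n_replicates`` full-pipeline replicates and summarize.

    When ``cfg.outdir`` is set, per-replicate window tables, CLDGR calls,
    and the aggregate report are written beneath it.
    """
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        dumped = cfg.to_dict()
        dumped.pop("outdir", None)  # run-local, not part of the experiment
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(dumped, fh)
    results = []
    for rep in range(cfg.n_replicates):
        res = run_replicate(cfg, rep, with_trees=with_trees)
        results.append(res.slim())
        if outdir:
            rep_dir = outdir / f"rep{rep:03d}"
            rep_dir.mkdir(exist_ok=True)
            for sp, tr in res.theta.items():
                for w, table in tr.windows.items():
                    thetawin.write_windows(rep_dir / f"windows_{sp}_{w}.tsv", table)
            if res.cldgr is not None:
                res.cldgr.to_csv(rep_dir / "cldgr.tsv", sep="\t", index=False)
    report = summarize(results, cfg)
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
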