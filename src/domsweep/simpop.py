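"""Synthetic population data: structured coalescent haplotypes and low-coverage reads.

Emulates a six-subpopulation history — three wild groups (OrI, OrII, OrIII)
and three domesticated groups (aus, indica, japonica), each domesticate
descending from a designated wild progenitor with a bottleneck — plus a
single hard-sweep haplotype that originates on the japonica lineage and is
transplanted into all domesticated samples over a fixed interval
(introgression of the domestication haplotype).

Genealogies are simulated per non-recombining block with msprime (no
recombination within a block, independent blocks), which gives sliding
windows quasi-independent histories without a full ancestral recombination
graph. Reads are then drawn per site and individual at a configurable mean
depth with a symmetric base-miscall error, producing the kind of 1-2x
evidence the downstream genotype-likelihood machinery is built for.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import msprime
import numpy as np
from scipy import stats

WILD_SUBPOPS: Tuple[str, ...] = ("OrI", "OrII", "OrIII")
DOM_SUBPOPS: Tuple[str, ...] = ("aus", "indica", "japonica")
SUBPOPS: Tuple[str, ...] = WILD_SUBPOPS + DOM_SUBPOPS

#: Wild progenitor of each domesticated subpopulation. aus and indica derive
#: from two internal OrI lineages (OrI-a / OrI-b), japonica from OrIII.
DEFAULT_PROGENITORS: Dict[str, str] = {
    "aus": "OrI",
    "indica": "OrI",
    "japonica": "OrIII",
}

# RNG stream tags, so every stage draws from an independent child stream of
# the master seed (counter-based: SeedSequence([seed, tag, ...])).
_STREAM_ANCESTRY = 1
_STREAM_MUTATION = 2
_STREAM_SWEEP = 3
_STREAM_READS = 4


def _default_split_depths() -> Dict[str, float]:
    # Generations; chosen to give a deep japonica/indica genome-wide
    # divergence relative to the recent domestication splits.
    return {
        "aus": 2000.0,
        "indica": 2000.0,
        "japonica": 2000.0,
        "OrI_internal": 9000.0,
        "OrIII_OrI": 15000.0,
        "OrII": 25000.0,
    }


@dataclass
class DemographyConfig:
    """Parameters of the six-subpopulation demography and sweep.

    ``theta_neutral`` is the scaled diversity 4*Ne*mu per site of the wild
    populations; the wild effective size is derived from it and ``mu``.
    ``split_depths`` holds divergence times in generations for the keys
    ``aus``, ``indica``, ``japonica`` (each domesticate vs. its progenitor),
    ``OrI_internal`` (the OrI-a/OrI-b substructure), ``OrIII_OrI`` and
    ``OrII`` (deepest).
    """

    n_per_subpop: int = 8
    L: int = 1_100_000
    mu: float = 1.25e-7
    theta_neutral: float = 0.005
    split_depths: Dict[str, float] = field(default_factory=_default_split_depths)
    bottleneck_factor: float = 0.1
    sweep_interval: Tuple[int, int] = (480_000, 520_000)
    post_sweep_time: float = 100.0
    block_length: int = 5_000
    chrom: str = "chr1"
    seed: int = 1
    progenitors: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROGENITORS)
    )

    def __post_init__(self) -> None:
        if self.n_per_subpop < 1:
            raise ValueError("n_per_subpop must be >= 1")
        if self.L < 1:
            raise ValueError("L must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0.0 < self.bottleneck_factor <= 1.0):
            raise ValueError("bottleneck_factor must be in (0, 1]")
        for d in DOM_SUBPOPS:
            if d not in self.progenitors:
                raise ValueError(f"domesticated subpopulation {d!r} lacks a progenitor")
            if self.progenitors[d] not in ("OrI", "OrIII"):
                raise ValueError(f"unsupported progenitor {self.progenitors[d]!r}")
        sd = self.split_depths
        required = {"aus", "indica", "japonica", "OrI_internal", "OrIII_OrI", "OrII"}
        missing = required - set(sd)
        if missing:
            raise ValueError(f"split_depths missing keys: {sorted(missing)}")
        for key in ("OrI_internal", "OrIII_OrI", "OrII"):
            if sd[key] <= 0:
                raise ValueError(f"split depth {key} must be positive")
        for d in DOM_SUBPOPS:
            if sd[d] < 0:
                raise ValueError(f"split depth {d} must be >= 0")
        # domesticate splits are the most recent events; progenitor-level
        # splits must nest above them.
        dom_max = max(sd[d] for d in DOM_SUBPOPS)
        if not (dom_max <= sd["OrI_internal"] <= sd["OrIII_OrI"] <= sd["OrII"]):
            raise ValueError("split depths must be nested: dom <= OrI_internal <= OrIII_OrI <= OrII")
        s0, s1 = self.sweep_interval
        if not (0 <= s0 < s1 <= self.L):
            raise ValueError("sweep_interval must be a non-empty interval within [0, L)")
        if self.mu > 0 and self.theta_neutral <= 0:
            raise ValueError("theta_neutral must be positive when mu > 0")
        if self.block_length < 1:
            raise ValueError("block_length must be positive")

    @property
    def Ne_wild(self) -> float:
        if self.mu == 0:
            return 10_000.0  # arbitrary; no mutations will be placed
        return self.theta_neutral / (4.0 * self.mu)

    def replace(self, **kwargs) -> "DemographyConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_interval"] = list(self.sweep_interval)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyConfig":
        d = dict(d)
        if "sweep_interval" in d:
            d["sweep_interval"] = tuple(d["sweep_interval"])
        return cls(**d)


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes at segregating sites, with sample labels.

    ``haplotypes`` has one row per haploid genome (two consecutive rows per
    diploid individual) and one column per site; ``positions`` are 0-based bp
    coordinates, strictly increasing. Allele 0 is ancestral everywhere (the
    simulator plays the role of the reference/outgroup used to polarize).
    """

    haplotypes: np.ndarray  # (2*n_ind, S) int8
    positions: np.ndarray  # (S,) int64
    subpop: np.ndarray  # (n_ind,) of str labels
    L: int
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("haplotypes/positions shape mismatch")
        if self.positions.size and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 0
            or self.positions[-1] >= self.L
        ):
            raise ValueError("positions must be strictly increasing within [0, L)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def status(self) -> np.ndarray:
        return np.where(np.isin(self.subpop, DOM_SUBPOPS), "domesticated", "wild")

    def individual_ids(self) -> list:
        counters: Dict[str, int] = {}
        ids = []
        for sp in self.subpop:
            k = counters.get(sp, 0)
            ids.append(f"{sp}_{k}")
            counters[sp] = k + 1
        return ids

    def individuals_of(self, subpop: str) -> np.ndarray:
        return np.flatnonzero(self.subpop == subpop)

    def hap_rows_of(self, subpop: str) -> np.ndarray:
        ind = self.individuals_of(subpop)
        return np.stack([2 * ind, 2 * ind + 1], axis=1).ravel()

    def genotypes(self, individuals: np.ndarray | None = None) -> np.ndarray:
        """Diploid derived-allele dosage matrix, (S, n_ind) int8."""
        if individuals is None:
            individuals = np.arange(self.n_individuals)
        g = (
            self.haplotypes[2 * np.asarray(individuals)]
            + self.haplotypes[2 * np.asarray(individuals) + 1]
        )
        return g.T.astype(np.int8)

    def site_pi(self, subpop: str) -> np.ndarray:
        """Per-site average pairwise difference within ``subpop`` (sample pi)."""
        rows = self.hap_rows_of(subpop)
        m = rows.size
        j = self.haplotypes[rows].sum(axis=0).astype(float)
        return j * (m - j) / (m * (m - 1) / 2.0)

    def window_pi(self, subpop: str, window_size: int) -> "np.ndarray":
        """True per-site pi of ``subpop`` in non-overlapping windows.

        Returns an array of length ceil(L / window_size); the last partial
        window is normalized by its own span.
        """
        pi = self.site_pi(subpop)
        n_win = -(-self.L // window_size)
        idx = self.positions // window_size
        sums = np.bincount(idx, weights=pi, minlength=n_win)
        starts = np.arange(n_win) * window_size
        spans = np.minimum(starts + window_size, self.L) - starts
        return sums / spans

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(
            self.haplotypes.copy(),
            self.positions.copy(),
            self.subpop.copy(),
            self.L,
            self.chrom,
        )


@dataclass
class ReadPile:
    """Per-site, per-individual read evidence over the whole sequence.

    ``depth[s, i]`` is the read count at site ``s`` for individual ``i``;
    ``alt[s, i]`` of those support allele 1 (so allele-0 support is
    ``depth - alt``). ``error_rate`` is the symmetric per-base miscall
    probability used to generate the reads (and assumed by the GL model).
    """

    depth: np.ndarray  # (L, n_ind) int16
    alt: np.ndarray  # (L, n_ind) int16
    error_rate: float
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.depth.shape != self.alt.shape:
            raise ValueError("depth/alt shape mismatch")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if np.any(self.alt > self.depth) or np.any(self.alt < 0) or np.any(self.depth < 0):
            raise ValueError("base counts must satisfy 0 <= alt <= depth")

    @property
    def L(self) -> int:
        return self.depth.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.depth.shape[1]

    @property
    def ref(self) -> np.ndarray:
        return self.depth - self.alt

    def subset(self, individuals: Sequence[int]) -> "ReadPile":
        idx = np.asarray(individuals)
        return ReadPile(self.depth[:, idx], self.alt[:, idx], self.error_rate, self.chrom)


def _build_demography(cfg: DemographyConfig) -> msprime.Demography:
    Ne = cfg.Ne_wild
    Ned = Ne * cfg.bottleneck_factor
    d = msprime.Demography()
    d.add_population(name="OrI_a", initial_size=Ne)
    d.add_population(name="OrI_b", initial_size=Ne)
    d.add_population(name="OrII", initial_size=Ne)
    d.add_population(name="OrIII", initial_size=Ne)
    d.add_population(name="aus", initial_size=Ned)
    d.add_population(name="indica", initial_size=Ned)
    d.add_population(name="japonica", initial_size=Ned)
    sd = cfg.split_depths
    # Backward-in-time lineage moves (ms-style) rather than population-split
    # events, so that every population is active and sampleable at time 0.
    dom_anc = {"aus": "OrI_a", "indica": "OrI_b", "japonica": "OrIII"}
    for dom in DOM_SUBPOPS:
        anc = dom_anc[dom] if cfg.progenitors[dom] == DEFAULT_PROGENITORS[dom] else (
            "OrI_a" if cfg.progenitors[dom] == "OrI" else "OrIII"
        )
        d.add_mass_migration(time=max(sd[dom], 1e-9), source=dom, dest=anc, proportion=1.0)
    d.add_mass_migration(time=sd["OrI_internal"], source="OrI_b", dest="OrI_a", proportion=1.0)
    d.add_mass_migration(time=sd["OrIII_OrI"], source="OrIII", dest="OrI_a", proportion=1.0)
    d.add_mass_migration(time=sd["OrII"], source="OrII", dest="OrI_a", proportion=1.0)
    d.sort_events()
    return d


def _sample_sets(cfg: DemographyConfig):
    n = cfg.n_per_subpop
    n_a = (n + 1) // 2
    # time=0 everywhere: progenitor populations are ancestral in split events
    # and would otherwise default to being sampled at the split time
    samples = [
        msprime.SampleSet(n_a, population="OrI_a", ploidy=2, time=0),
        msprime.SampleSet(n - n_a, population="OrI_b", ploidy=2, time=0),
        msprime.SampleSet(n, population="OrII", ploidy=2, time=0),
        msprime.SampleSet(n, population="OrIII", ploidy=2, time=0),
        msprime.SampleSet(n, population="aus", ploidy=2, time=0),
        msprime.SampleSet(n, population="indica", ploidy=2, time=0),
        msprime.SampleSet(n, population="japonica", ploidy=2, time=0),
    ]
    labels = np.array(
        ["OrI"] * n + ["OrII"] * n + ["OrIII"] * n + ["aus"] * n + ["indica"] * n + ["japonica"] * n
    )
    return samples, labels


def _child_seeds(seed: int, stream: int, count: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed), int(stream)])
    # msprime seeds must be in [1, 2^32 - 2]
    return ss.generate_state(count, dtype=np.uint64) % (2**32 - 2) + 1


def simulate_haplotypes(cfg: DemographyConfig) -> HaplotypeSet:
    """Simulate haplotypes under the structured six-subpopulation history.

    Each non-recombining block of ``cfg.block_length`` bp gets an independent
    coalescent genealogy; mutations are Poisson on branches at rate
    ``cfg.mu`` per site per generation under a binary 0/1 model. Output is
    deterministic given ``cfg.seed``.
    """
    demography = _build_demography(cfg)
    samples, labels = _sample_sets(cfg)
    n_blocks = -(-cfg.L // cfg.block_length)
    anc_seeds = _child_seeds(cfg.seed, _STREAM_ANCESTRY, n_blocks)
    mut_seeds = _child_seeds(cfg.seed, _STREAM_MUTATION, n_blocks)

    hap_blocks = []
    pos_blocks = []
    for b in range(n_blocks):
        start = b * cfg.block_length
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=cfg.block_length,
            recombination_rate=0.0,
            random_seed=int(anc_seeds[b]),
        )
        if cfg.mu > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=cfg.mu,
                random_seed=int(mut_seeds[b]),
                model=msprime.BinaryMutationModel(),
            )
        if ts.num_sites == 0:
            continue
        g = ts.genotype_matrix()  # (sites, 2n)
        pos = ts.tables.sites.position.astype(np.int64) + start
        keep = (pos < cfg.L)
        counts = g.sum(axis=1)
        keep &= (counts > 0) & (counts < g.shape[1])
        if not np.any(keep):
            continue
        hap_blocks.append(g[keep].T.astype(np.int8))
        pos_blocks.append(pos[keep])

    n_hap = 2 * labels.size
    if hap_blocks:
        haplotypes = np.concatenate(hap_blocks, axis=1)
        positions = np.concatenate(pos_blocks)
    else:
        haplotypes = np.zeros((n_hap, 0), dtype=np.int8)
        positions = np.zeros(0, dtype=np.int64)
    return HaplotypeSet(haplotypes, positions, labels, cfg.L, cfg.chrom)


def apply_sweep_introgression(h: HaplotypeSet, cfg: DemographyConfig) -> HaplotypeSet:
    """Transplant one japonica haplotype across the sweep interval.

    The first japonica haplotype over ``cfg.sweep_interval`` is copied onto
    every domesticated haplotype (aus, indica and japonica alike), modelling
    a hard sweep of a single japonica-origin domestication haplotype spread
    by introgression. Each copy then accrues independent mutations at rate
    ``cfg.mu`` for ``cfg.post_sweep_time`` generations. Sites outside the
    interval are untouched; columns rendered monomorphic by the transplant
    are dropped.
    """
    s0, s1 = cfg.sweep_interval
    if not (0 <= s0 < s1 <= h.L):
        raise ValueError("sweep_interval outside [0, L)")
    out = h.copy()
    in_interval = (out.positions >= s0) & (out.positions < s1)
    dom_rows = np.concatenate([out.hap_rows_of(d) for d in DOM_SUBPOPS])
    donor_row = out.hap_rows_of("japonica")[0]
    donor = out.haplotypes[donor_row, in_interval].copy()
    out.haplotypes[np.ix_(dom_rows, np.flatnonzero(in_interval))] = donor

    # Post-sweep private mutations on each transplanted copy.
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), _STREAM_SWEEP]))
    lam = cfg.mu * cfg.post_sweep_time * (s1 - s0)
    new_cols: dict = {}
    n_hap = out.haplotypes.shape[0]
    pos_index = {int(p): k for k, p in enumerate(out.positions)}
    flips = []
    for row in dom_rows:
        k = rng.poisson(lam)
        for p in rng.integers(s0, s1, size=k):
            p = int(p)
            if p in pos_index:
                flips.append((row, pos_index[p]))
            else:
                new_cols.setdefault(p, []).append(row)
    for row, col in flips:
        out.haplotypes[row, col] ^= 1
    if new_cols:
        extra_pos = np.array(sorted(new_cols), dtype=np.int64)
        extra = np.zeros((n_hap, extra_pos.size), dtype=np.int8)
        for k, p in enumerate(extra_pos):
            for row in new_cols[int(p)]:
                extra[row, k] ^= 1
        all_pos = np.concatenate([out.positions, extra_pos])
        order = np.argsort(all_pos, kind="stable")
        out = HaplotypeSet(
            np.concatenate([out.haplotypes, extra], axis=1)[:, order],
            all_pos[order],
            out.subpop,
            out.L,
            out.chrom,
        )
    counts = out.haplotypes.sum(axis=0)
    seg = (counts > 0) & (counts < n_hap)
    return HaplotypeSet(out.haplotypes[:, seg], out.positions[seg], out.subpop, out.L, out.chrom)


def _fast_poisson(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Poisson draws by inverse-CDF lookup (fast for the small means used
    for read depths); falls back to the generator for large means."""
    if lam <= 0:
        return np.zeros(size, dtype=np.int16)
    if lam > 50:
        return rng.poisson(lam, size=size).astype(np.int16)
    kmax = int(lam + 12 * math.sqrt(lam) + 20)
    pmf = stats.poisson.pmf(np.arange(kmax + 1), lam)
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return np.searchsorted(cdf, u).astype(np.int16)


def simulate_reads(
    h: HaplotypeSet, mean_depth: float, e: float, seed: int
) -> ReadPile:
    """Draw low-coverage reads: depth ~ Poisson(mean_depth) per site and
    individual, each read sampled from the individual's two alleles with
    equal probability and miscalled with probability ``e``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0.0 <= e < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_READS]))
    n = h.n_individuals
    # Poisson thinning: drawing ancestral and miscalled reads independently
    # is jointly equivalent to Poisson(mean_depth) total depth with each
    # read flipped at probability e.
    ref = _fast_poisson(rng, mean_depth * (1.0 - e), (h.L, n))
    alt = _fast_poisson(rng, mean_depth * e, (h.L, n))
    depth = ref + alt
    if h.positions.size:
        g = h.genotypes()  # (S, n) dosage
        p_alt = (g / 2.0) * (1.0 - 2.0 * e) + e
        d_var = depth[h.positions]
        alt[h.positions] = rng.binomial(d_var.astype(np.int64), p_alt).astype(np.int16)
    return ReadPile(depth, alt, e, h.chrom)
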