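"""Diploid genotype likelihoods from read counts, site filters, and SNP calling.

The likelihood model is the standard biallelic per-read product with a single
symmetric miscall probability ``e``: a read drawn from a homozygous
ancestral genotype shows allele 1 with probability ``e``, a heterozygote
shows either allele with probability 1/2 regardless of ``e`` (miscalls
cancel), and the homozygous derived case mirrors the ancestral one.
Likelihoods are kept unnormalized in log space; an uncovered individual
(no reads) carries the non-informative triple (1, 1, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "site_genotype_likelihood",
    "SiteFilterConfig",
    "apply_site_filters",
    "GenotypeLikelihoodMatrix",
    "ml_allele_freq",
    "snp_call",
    "genotype_posterior",
    "write_gl",
    "read_gl",
]

_LOG_HALF = math.log(0.5)


def _xlogy(k: np.ndarray, p: float) -> np.ndarray:
    """k * log(p) with the convention 0 * log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(p)
    return np.where(k == 0, 0.0, out)


def site_genotype_likelihood(k0, k1, e: float) -> np.ndarray:
    """Log-likelihoods of genotypes g in {0, 1, 2} copies of allele 1.

    ``k0``/``k1`` are read counts supporting allele 0 / allele 1 (scalars or
    arrays of identical shape). Returns an array with a trailing axis of
    length 3 holding log L(0), log L(1), log L(2), unnormalized. A site with
    no reads yields (0, 0, 0), i.e. all genotypes equally likely.
    """
    if not (0.0 <= e < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    k0 = np.asarray(k0, dtype=np.float64)
    k1 = np.asarray(k1, dtype=np.float64)
    if np.any(k0 < 0) or np.any(k1 < 0):
        raise ValueError("read counts must be non-negative")
    l0 = _xlogy(k0, 1.0 - e) + _xlogy(k1, e)
    l1 = (k0 + k1) * _LOG_HALF
    l2 = _xlogy(k0, e) + _xlogy(k1, 1.0 - e)
    return np.stack([l0, l1, l2], axis=-1)


@dataclass
class SiteFilterConfig:
    """ANGSD-style per-site coverage filters.

    Defaults follow the "one-third of the number of individuals" rule for the
    minimum-individual and minimum-total-depth cutoffs, and five times the
    number of individuals for the maximum total depth.
    """

    minInd: int
    setMinDepth: int
    setMaxDepth: int

    def __post_init__(self) -> None:
        if self.minInd < 1:
            raise ValueError("minInd must be >= 1")
        if self.setMinDepth > self.setMaxDepth:
            raise ValueError("setMinDepth must be <= setMaxDepth")

    @classmethod
    def for_sample_size(cls, n: int) -> "SiteFilterConfig":
        third = max(1, math.ceil(n / 3))
        return cls(minInd=third, setMinDepth=third, setMaxDepth=5 * n)


def apply_site_filters(pile, f: SiteFilterConfig) -> np.ndarray:
    """Boolean per-site pass flags for a :class:`~domsweep.simpop.ReadPile`.

    A site passes iff at least ``minInd`` individuals have reads and the
    total depth lies within [setMinDepth, setMaxDepth].
    """
    depth = pile.depth if hasattr(pile, "depth") else np.asarray(pile)
    n_cov = (depth > 0).sum(axis=1)
    total = depth.sum(axis=1, dtype=np.int64)
    return (n_cov >= f.minInd) & (total >= f.setMinDepth) & (total <= f.setMaxDepth)


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-site, per-individual log genotype likelihoods plus coverage flags."""

    gl: np.ndarray  # (S, n, 3) float64, log space
    covered: np.ndarray  # (S, n) bool
    site_pass: np.ndarray  # (S,) bool
    positions: np.ndarray  # (S,) int64
    error_rate: float = 0.0

    @classmethod
    def from_readpile(
        cls, pile, filters: SiteFilterConfig | None = None
    ) -> "GenotypeLikelihoodMatrix":
        if filters is None:
            filters = SiteFilterConfig.for_sample_size(pile.n_individuals)
        gl = site_genotype_likelihood(pile.ref, pile.alt, pile.error_rate)
        covered = pile.depth > 0
        site_pass = apply_site_filters(pile, filters)
        positions = np.arange(pile.L, dtype=np.int64)
        return cls(gl, covered, site_pass, positions, pile.error_rate)

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def linear(self, normalize: bool = True) -> np.ndarray:
        """Linear-space likelihoods, optionally normalized to max 1 per entry."""
        g = self.gl
        if normalize:
            g = g - g.max(axis=-1, keepdims=True)
        return np.exp(g)


_INV_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


def _hwe_loglik(gl_lin: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood of allele-1 frequency ``f`` under HWE.

    ``gl_lin``: (S, n, 3) linear-space likelihoods; ``f``: (S,).
    """
    f = np.asarray(f, dtype=gl_lin.dtype)[:, None]
    per_ind = (
        gl_lin[..., 0] * (1 - f) ** 2
        + gl_lin[..., 1] * (2 * f * (1 - f))
        + gl_lin[..., 2] * f**2
    )
    with np.errstate(divide="ignore"):
        return np.log(per_ind).sum(axis=-1, dtype=np.float64)


def ml_allele_freq(
    gl_lin: np.ndarray, lo: float = 0.0, hi: float = 1.0, tol: float = 1e-6
) -> np.ndarray:
    """Vectorized golden-section maximization of the HWE allele-frequency
    likelihood on [lo, hi] for every site at once. Returns (S,) frequencies.
    """
    S = gl_lin.shape[0]
    a = np.full(S, float(lo))
    b = np.full(S, float(hi))
    n_iter = int(math.ceil(math.log(tol / (hi - lo)) / math.log(_INV_GOLD))) + 1
    for _ in range(n_iter):
        c = b - _INV_GOLD * (b - a)
        d = a + _INV_GOLD * (b - a)
        left = _hwe_loglik(gl_lin, c) >= _hwe_loglik(gl_lin, d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return (a + b) / 2.0


def snp_call(gl, p_threshold: float = 1e-3):
    """Likelihood-ratio SNP test per site.

    The null fixes the minor-allele frequency at zero (site monomorphic for
    the pooled-ML major allele); the alternative frequency is found by
    golden-section search over [0, 0.5] for the minor allele. The statistic
    2*(l1 - l0) is referred to a 1-df chi-square. Returns
    ``(is_snp, pvalues, ml_freq)`` with ``ml_freq`` the allele-1 frequency.

    ``gl`` may be a GenotypeLikelihoodMatrix or a (S, n, 3) array of log GLs.
    """
    if isinstance(gl, GenotypeLikelihoodMatrix):
        gl_lin = gl.linear()
    else:
        g = np.asarray(gl, dtype=float)
        if g.ndim == 2:
            g = g[None]
        gl_lin = np.exp(g - g.max(axis=-1, keepdims=True))
    gl_lin = gl_lin.astype(np.float32)
    S = gl_lin.shape[0]
    l_mono0 = _hwe_loglik(gl_lin, np.zeros(S))
    l_mono1 = _hwe_loglik(gl_lin, np.ones(S))
    major_is_0 = l_mono0 >= l_mono1
    l0 = np.where(major_is_0, l_mono0, l_mono1)
    # search the minor-allele frequency on [0, 0.5]; when the major allele is
    # allele 1 this means searching allele-1 frequency on [0.5, 1]
    f_hat = np.empty(S)
    if np.any(major_is_0):
        f_hat[major_is_0] = ml_allele_freq(gl_lin[major_is_0], 0.0, 0.5)
    if not np.all(major_is_0):
        f_hat[~major_is_0] = ml_allele_freq(gl_lin[~major_is_0], 0.5, 1.0)
    l1 = _hwe_loglik(gl_lin, f_hat)
    lrt = np.maximum(2.0 * (l1 - l0), 0.0)
    pvalues = stats.chi2.sf(lrt, df=1)
    return pvalues < p_threshold, pvalues, f_hat


def genotype_posterior(
    gl_lin: np.ndarray, freq: np.ndarray | None = None, prior: str = "hwe"
) -> np.ndarray:
    """Per-individual genotype posteriors from linear GLs.

    ``prior='hwe'`` uses Hardy-Weinberg proportions at the per-site allele
    frequency ``freq`` (the -doPost 1 analogue); ``prior='uniform'`` just
    normalizes the likelihoods.
    """
    if prior == "hwe":
        if freq is None:
            raise ValueError("freq required for the HWE prior")
        f = np.asarray(freq)[:, None, None]
        w = np.concatenate([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
        post = gl_lin * w
    elif prior == "uniform":
        post = gl_lin.copy()
    else:
        raise ValueError(f"unknown prior {prior!r}")
    total = post.sum(axis=-1, keepdims=True)
    return post / total


def write_gl(path, glm: GenotypeLikelihoodMatrix, ids=None) -> None:
    """Write log GLs as TSV: pos, pass, then three columns per individual."""
    n = glm.n_individuals
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    header = ["pos", "pass"] + [f"{s}_{g}" for s in ids for g in ("AA", "Aa", "aa")]
    with open(path, "w") as fh:
        fh.write("#error_rate=%g\n" % glm.error_rate)
        fh.write("\t".join(header) + "\n")
        flat = glm.gl.reshape(glm.n_sites, 3 * n)
        for s in range(glm.n_sites):
            row = [str(int(glm.positions[s])), "1" if glm.site_pass[s] else "0"]
            row += ["%.6g" % v for v in flat[s]]
            fh.write("\t".join(row) + "\n")


def read_gl(path) -> GenotypeLikelihoodMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        error_rate = float(first.split("=", 1)[1]) if first.startswith("#") else 0.0
        if not first.startswith("#"):
            fh.seek(0)
        header = fh.readline().rstrip("\n").split("\t")
        n = (len(header) - 2) // 3
        positions, passes, vals = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            positions.append(int(parts[0]))
            passes.append(parts[1] == "1")
            vals.append([float(v) for v in parts[2:]])
    gl = np.array(vals).reshape(-1, n, 3)
    covered = ~np.all(gl == 0.0, axis=-1)
    return GenotypeLikelihoodMatrix(
        gl,
        covered,
        np.array(passes, dtype=bool),
        np.array(positions, dtype=np.int64),
        error_rate,
    )
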