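"""Sample allele frequency likelihoods, SFS EM estimation, and posteriors.

The per-site SAF vector L(j) is the likelihood of a site's read data given j
derived alleles among the m = 2n sampled chromosomes, obtained by a dynamic
program over individuals with hypergeometric assignment weights. An EM pass
over all covered sites then yields the population site frequency spectrum,
which serves as an empirical prior for per-site allele-frequency posteriors
(the SFS-as-prior construction).
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

__all__ = [
    "saf",
    "saf_bruteforce",
    "estimate_sfs",
    "posterior_freq",
    "write_saf",
    "read_saf",
    "write_sfs",
    "read_sfs",
]


def saf(gl_log: np.ndarray) -> np.ndarray:
    """Site allele frequency log-likelihood vectors.

    ``gl_log``: (S, n, 3) or (n, 3) per-individual log genotype likelihoods.
    Returns (S, 2n+1) log-space SAF vectors, each normalized so its maximum
    entry is 0. The DP combines individuals one at a time:

        h_k(j) = sum_g h_{k-1}(j - g) * GL_k(g) * C(2,g) * C(2k-2, j-g) / C(2k, j)

    computed in linear space with per-step renormalization to avoid
    underflow.
    """
    g = np.asarray(gl_log, dtype=np.float64)
    squeeze = g.ndim == 2
    if squeeze:
        g = g[None]
    S, n, _ = g.shape
    gl_lin = np.exp(g - g.max(axis=-1, keepdims=True))
    m = 2 * n
    h = np.zeros((S, m + 1))
    h[:, 0] = 1.0
    logscale = np.zeros(S)
    for k in range(1, n + 1):
        prev_m = 2 * (k - 1)
        new = np.zeros((S, m + 1))
        j = np.arange(2 * k + 1, dtype=np.float64)
        denom = comb(2 * k, j)
        for gt in range(3):
            # weight for placing gt derived alleles in individual k when the
            # previous k-1 individuals carry j - gt of them
            jprev = np.arange(prev_m + 1, dtype=np.float64)
            w = comb(2, gt) * comb(prev_m, jprev) / denom[jprev.astype(int) + gt]
            new[:, gt : gt + prev_m + 1] += (
                h[:, : prev_m + 1] * w[None, :] * gl_lin[:, k - 1, gt : gt + 1]
            )
        h = new
        peak = h.max(axis=1)
        peak = np.where(peak > 0, peak, 1.0)
        h /= peak[:, None]
        logscale += np.log(peak)
    with np.errstate(divide="ignore"):
        out = np.log(h)
    out -= out.max(axis=1, keepdims=True)
    return out[0] if squeeze else out


def saf_bruteforce(gl_log: np.ndarray) -> np.ndarray:
    """Brute-force SAF by enumerating all 3^n genotype configurations.

    Independent oracle for :func:`saf`; only sensible for small n. Returns a
    log-space vector normalized to max 0.
    """
    g = np.asarray(gl_log, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("expected a single site: (n, 3) array")
    n = g.shape[0]
    gl_lin = np.exp(g - g.max(axis=-1, keepdims=True))
    m = 2 * n
    acc = np.zeros(m + 1)
    for config in np.ndindex(*([3] * n)):
        j = sum(config)
        w = 1.0
        for i, gt in enumerate(config):
            w *= gl_lin[i, gt] * comb(2, gt)
        acc[j] += w
    acc /= comb(m, np.arange(m + 1))
    with np.errstate(divide="ignore"):
        out = np.log(acc)
    return out - out.max()


def estimate_sfs(
    saf_log: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_history: bool = False,
):
    """EM estimate of the site frequency spectrum from per-site SAF vectors.

    ``saf_log``: (S, m+1) log-space SAF (any per-site normalization).
    ``weights`` optionally gives a multiplicity per row (identical sites can
    be collapsed upstream; the result is exactly the expanded-input EM).
    Starts from the uniform spectrum and iterates

        p_j <- (1/S) * sum_s w_s * p_j L_s(j) / sum_k p_k L_s(k)

    until max_j |delta p_j| < tol or ``max_iter`` sweeps. The per-iteration
    log-likelihood is non-decreasing; with ``return_history=True`` the
    sequence is returned for verification.
    """
    Ls = np.asarray(saf_log, dtype=np.float64)
    if Ls.ndim != 2 or Ls.shape[0] < 1:
        raise ValueError("need at least one site")
    finite = np.isfinite(Ls).any(axis=1)
    if not np.all(finite):
        raise ValueError("SAF rows with no finite entry (uncovered sites)")
    L = np.exp(Ls - Ls.max(axis=1, keepdims=True))
    S, K = L.shape
    if weights is None:
        w = np.ones(S)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (S,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per site")
    total_w = w.sum()
    p = np.full(K, 1.0 / K)
    history = []
    for _ in range(max_iter):
        mix = L @ p  # (S,)
        if return_history:
            history.append(float(np.dot(w, np.log(mix))))
        p_new = p * (L.T @ (w / mix)) / total_w
        p_new /= p_new.sum()
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break
    if return_history:
        history.append(float(np.dot(w, np.log(L @ p))))
        return p, history
    return p


def posterior_freq(saf_log: np.ndarray, sfs: np.ndarray) -> np.ndarray:
    """Per-site posterior P(j | data) over derived-allele counts.

    Proportional to ``sfs[j] * exp(saf_log[s, j])``, normalized to sum 1.
    """
    Ls = np.asarray(saf_log, dtype=np.float64)
    squeeze = Ls.ndim == 1
    if squeeze:
        Ls = Ls[None]
    sfs = np.asarray(sfs, dtype=np.float64)
    if Ls.shape[1] != sfs.shape[0]:
        raise ValueError("SAF and SFS dimension mismatch")
    post = np.exp(Ls - Ls.max(axis=1, keepdims=True)) * sfs[None, :]
    total = post.sum(axis=1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("zero posterior mass at some site")
    post /= total
    return post[0] if squeeze else post


def write_saf(path, positions: np.ndarray, saf_log: np.ndarray) -> None:
    saf_log = np.atleast_2d(saf_log)
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(f"L{j}" for j in range(saf_log.shape[1])) + "\n")
        for p, row in zip(positions, saf_log):
            fh.write(str(int(p)) + "\t" + "\t".join("%.6g" % v for v in row) + "\n")


def read_saf(path):
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    return data[:, 0].astype(np.int64), data[:, 1:]


def write_sfs(path, sfs: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join("%.10g" % v for v in sfs) + "\n")


def read_sfs(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)
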