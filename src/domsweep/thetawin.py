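"""Per-site diversity estimators and nonoverlapping window aggregation.

From each site's allele-frequency posterior P(j | data) over j derived
copies among m chromosomes:

    theta_pi = sum_j P(j) * j * (m - j) / C(m, 2)
    theta_w  = [sum_{0 < j < m} P(j)] / a_m,   a_m = sum_{i=1}^{m-1} 1/i

Windows tile the chromosome (0-based half-open); the per-site window value
divides the summed theta_pi by the number of sites with data, and windows
with less than 25% of their span covered by data are flagged as failing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["per_site_theta", "window_scan", "WINDOW_COLUMNS"]

WINDOW_COLUMNS = ["chrom", "start", "end", "sum_tP", "n_sites", "tP_per_site", "pass"]


def harmonic(m: int) -> float:
    """a_m = sum_{i=1}^{m-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m)))


def per_site_theta(posterior: np.ndarray, m: int | None = None):
    """Tajima's and Watterson's per-site theta from frequency posteriors.

    ``posterior``: (S, m+1) rows summing to 1 (or a single vector).
    Returns ``(theta_pi, theta_w)`` arrays of shape (S,).
    """
    P = np.atleast_2d(np.asarray(posterior, dtype=np.float64))
    if m is None:
        m = P.shape[1] - 1
    if P.shape[1] != m + 1:
        raise ValueError("posterior length must be m + 1")
    j = np.arange(m + 1, dtype=np.float64)
    pair_weight = j * (m - j) / (m * (m - 1) / 2.0)
    theta_pi = P @ pair_weight
    a_m = harmonic(m)
    theta_w = P[:, 1:m].sum(axis=1) / a_m
    return theta_pi, theta_w


def window_scan(
    positions: np.ndarray,
    theta_pi: np.ndarray,
    L: int,
    window_size: int,
    chrom: str = "chr1",
    min_data_frac: float = 0.25,
) -> pd.DataFrame:
    """Aggregate per-site theta_pi of data-bearing sites into tiled windows.

    ``positions`` must be sorted, strictly increasing coordinates of the
    sites with data (filter-passing sites); ``theta_pi`` their per-site
    values. The last partial window is kept and judged against its own span.
    """
    positions = np.asarray(positions)
    theta_pi = np.asarray(theta_pi, dtype=np.float64)
    if positions.shape != theta_pi.shape:
        raise ValueError("positions/theta shape mismatch")
    if positions.size and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be sorted and strictly increasing")
    if positions.size and (positions[0] < 0 or positions[-1] >= L):
        raise ValueError("positions outside [0, L)")
    n_win = -(-L // window_size)
    idx = positions // window_size
    sums = np.bincount(idx, weights=theta_pi, minlength=n_win)
    counts = np.bincount(idx, minlength=n_win)
    starts = np.arange(n_win, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, L)
    spans = ends - starts
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    passes = counts / spans >= min_data_frac
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "sum_tP": sums,
            "n_sites": counts,
            "tP_per_site": per_site,
            "pass": passes,
        }
    )


def write_windows(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pass"] = df["pass"].astype(bool)
    return df
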