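"""The pi_w/pi_d sweep scan: ratio tables, the common empirical threshold,
colocated low-diversity genomic region (CLDGR) calling, and gene overlap
annotation.

A window's ratio is wild diversity (the OrII reference population) over a
domesticated population's diversity. Per domesticated subpopulation the
97.5th percentile of finite ratios defines a candidate threshold; the
smallest of the three is the common significance threshold, and windows
exceeding it in aus AND indica AND japonica simultaneously are CLDGRs.
Zero-diversity domesticate windows yield infinite ratios: excluded from the
percentile computation but always counted as exceedances.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "pi_ratio",
    "common_threshold",
    "find_cldgr",
    "merge_windows",
    "annotate_genes",
    "read_genes_bed",
]

_KEY = ["chrom", "start", "end"]


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        a[_KEY].reset_index(drop=True).equals(b[_KEY].reset_index(drop=True))
    ):
        raise ValueError("window tables are not on the same grid")


def pi_ratio(wild: pd.DataFrame, dom: pd.DataFrame) -> pd.DataFrame:
    """Per-window pi_w/pi_d from two window tables on an identical grid.

    Windows failing the data-fraction filter in either population are
    dropped. ``ratio`` is +inf (with ``finite`` False) where pi_d is zero.
    """
    _check_same_grid(wild, dom)
    keep = wild["pass"].to_numpy() & dom["pass"].to_numpy()
    out = wild.loc[keep, _KEY].reset_index(drop=True).copy()
    pi_w = wild.loc[keep, "tP_per_site"].to_numpy(dtype=float)
    pi_d = dom.loc[keep, "tP_per_site"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(pi_d > 0, pi_w / np.where(pi_d > 0, pi_d, 1.0), np.inf)
    ratio = np.where((pi_d == 0) & (pi_w == 0), np.nan, ratio)
    out["pi_w"] = pi_w
    out["pi_d"] = pi_d
    out["ratio"] = ratio
    out["finite"] = np.isfinite(ratio)
    return out.dropna(subset=["ratio"]).reset_index(drop=True)


def percentile_linear(values: np.ndarray, q: float) -> float:
    """Linear-interpolation ('type 7') percentile of ``values`` (0-100)."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def common_threshold(
    ratios: Mapping[str, pd.DataFrame],
    percentile: float = 97.5,
    min_finite: int = 40,
) -> float:
    """The common significance threshold: the minimum over subpopulations of
    each one's ``percentile`` of finite ratios.
    """
    per_subpop = {}
    for name, table in ratios.items():
        finite = table.loc[table["finite"], "ratio"].to_numpy(dtype=float)
        if finite.size < min_finite:
            raise ValueError(
                f"{name}: only {finite.size} finite ratio windows (< {min_finite})"
            )
        per_subpop[name] = percentile_linear(finite, percentile)
    return min(per_subpop.values())


def find_cldgr(ratios: Mapping[str, pd.DataFrame], threshold: float) -> pd.DataFrame:
    """Windows whose ratio exceeds ``threshold`` in every subpopulation.

    Infinite ratios count as exceedances. Only windows present (i.e. passing
    filters) in all tables can qualify. Returns a window table with one
    ratio column per subpopulation.
    """
    names = list(ratios)
    merged = None
    for name in names:
        t = ratios[name][_KEY + ["ratio"]].rename(columns={"ratio": f"ratio_{name}"})
        merged = t if merged is None else merged.merge(t, on=_KEY, how="inner")
    mask = np.ones(len(merged), dtype=bool)
    for name in names:
        mask &= merged[f"ratio_{name}"].to_numpy() > threshold
    out = merged.loc[mask].reset_index(drop=True)
    out.insert(3, "threshold", threshold)
    return out


def merge_windows(cldgr: pd.DataFrame) -> pd.DataFrame:
    """Collapse book-ended CLDGR windows into maximal runs (merged BED)."""
    if len(cldgr) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_windows"])
    rows = []
    for chrom, grp in cldgr.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_start = cur_end = None
        count = 0
        for _, r in grp.iterrows():
            if cur_end is not None and r["start"] <= cur_end:
                cur_end = max(cur_end, r["end"])
                count += 1
            else:
                if cur_end is not None:
                    rows.append((chrom, cur_start, cur_end, count))
                cur_start, cur_end, count = r["start"], r["end"], 1
        rows.append((chrom, cur_start, cur_end, count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


def read_genes_bed(path) -> pd.DataFrame:
    """Read a BED3+name file of gene intervals (half-open coordinates)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
    )
    if df[["start", "end"]].isna().any().any() or (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED: need end > start on every row")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def annotate_genes(cldgr: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping gene names to each CLDGR window.

    Intervals are half-open; an overlap requires at least one shared base,
    so a gene abutting a window boundary does not count.
    """
    out = cldgr.copy()
    annotations = []
    for _, w in out.iterrows():
        hits = genes[
            (genes["chrom"] == w["chrom"])
            & (genes["start"] < w["end"])
            & (genes["end"] > w["start"])
        ]
        annotations.append(",".join(hits["name"].astype(str)) if len(hits) else "")
    out["genes"] = annotations
    return out
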