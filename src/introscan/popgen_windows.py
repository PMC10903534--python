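"""Windowed population-genetic statistics (pi, dxy, Hudson FST),
recombination-rate binning, and rank correlations between window tracks.

pi and dxy are reported per analyzed variant site (per-SNP averages); pass a
set of accessible sites to the caller-side weighting if per-bp values are
needed.  FST is the Hudson-type ratio of averages 1 - mean(Hw)/mean(Hb).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import FrequencyTable, RecombinationMap, contig_windows

logger = logging.getLogger("introscan")


# ---------------------------------------------------------------------------
# Per-site building blocks
# ---------------------------------------------------------------------------


def pi_sites(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity n/(n-1) * 2 p (1-p).

    NaN where fewer than 2 chromosomes were called.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = n / (n - 1) * 2.0 * p * (1.0 - p)
    return np.where(n >= 2, h, np.nan)


def dxy_sites(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-site absolute divergence p1(1-p2) + p2(1-p1)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1 * (1 - p2) + p2 * (1 - p1)


# ---------------------------------------------------------------------------
# Window values
# ---------------------------------------------------------------------------


def pi_window(p: np.ndarray, n: np.ndarray) -> float:
    """Mean per-site pi over the window's analyzed sites (NaN if none)."""
    h = pi_sites(p, n)
    ok = ~np.isnan(h)
    return float(np.mean(h[ok])) if ok.any() else np.nan


def dxy_window(p1: np.ndarray, p2: np.ndarray) -> float:
    """Mean per-site dxy over the window's analyzed sites."""
    d = dxy_sites(p1, p2)
    ok = ~np.isnan(d)
    return float(np.mean(d[ok])) if ok.any() else np.nan


def fst_window(p1, n1, p2, n2) -> float:
    """Hudson-type FST: 1 - mean(Hw)/mean(Hb), raw (not clamped).

    Hw is the mean of the two within-population unbiased heterozygosities,
    Hb the per-site dxy; undefined (NaN) when mean(Hb) = 0.
    """
    h1 = pi_sites(p1, n1)
    h2 = pi_sites(p2, n2)
    hb = dxy_sites(p1, p2)
    ok = ~(np.isnan(h1) | np.isnan(h2) | np.isnan(hb))
    if not ok.any():
        return np.nan
    hw_mean = float(np.mean((h1[ok] + h2[ok]) / 2.0))
    hb_mean = float(np.mean(hb[ok]))
    if hb_mean == 0:
        return np.nan
    return 1.0 - hw_mean / hb_mean


def windowed_popgen(
    ft: FrequencyTable,
    pop1: str,
    pop2: str | None = None,
    window: int = 100_000,
    step: int | None = None,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Windowed pi (both populations), dxy and FST between two populations.

    With ``pop2=None`` only pi of ``pop1`` is emitted.  Per window the raw
    mean within/between heterozygosities (``hw``, ``hb``) are included so the
    identity FST = 1 - hw/hb can be checked downstream.
    """
    grid = contig_windows(ft.chrom, ft.pos, window, step, contig_lengths)
    p1_all, n1_all = ft.freq_of(pop1), ft.n_of(pop1)
    if pop2 is not None:
        p2_all, n2_all = ft.freq_of(pop2), ft.n_of(pop2)
    pos0 = ft.pos - 1
    rows = []
    for c, sub in grid.groupby("chrom", sort=False):
        on_c = ft.chrom == c
        cp = pos0[on_c]
        order = np.argsort(cp, kind="stable")
        cp = cp[order]
        q1, m1 = p1_all[on_c][order], n1_all[on_c][order]
        if pop2 is not None:
            q2, m2 = p2_all[on_c][order], n2_all[on_c][order]
        for w in sub.itertuples(index=False):
            lo = np.searchsorted(cp, w.start, side="left")
            hi = np.searchsorted(cp, w.end, side="left")
            s1, c1 = q1[lo:hi], m1[lo:hi]
            row = {
                "chrom": c, "start": w.start, "end": w.end, "partial": w.partial,
                "n_sites": hi - lo, f"pi_{pop1}": pi_window(s1, c1),
            }
            if pop2 is not None:
                s2, c2 = q2[lo:hi], m2[lo:hi]
                h1 = pi_sites(s1, c1)
                h2 = pi_sites(s2, c2)
                hb = dxy_sites(s1, s2)
                ok = ~(np.isnan(h1) | np.isnan(h2) | np.isnan(hb))
                hw_mean = float(np.mean((h1[ok] + h2[ok]) / 2)) if ok.any() else np.nan
                hb_mean = float(np.mean(hb[ok])) if ok.any() else np.nan
                row[f"pi_{pop2}"] = pi_window(s2, c2)
                row["dxy"] = dxy_window(s1, s2)
                row["hw"] = hw_mean
                row["hb"] = hb_mean
                row["fst"] = (
                    1.0 - hw_mean / hb_mean
                    if ok.any() and hb_mean not in (0,) and np.isfinite(hb_mean)
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recombination binning and correlations
# ---------------------------------------------------------------------------


def bin_recombination(
    rmap: RecombinationMap,
    window: int = 100_000,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Length-weighted mean recombination rate per nonoverlapping window.

    Windows with no map coverage get NaN (missing, not zero).
    """
    t = rmap.table
    rows = []
    for c, grp in t.groupby("chrom", sort=False):
        L = (
            int(contig_lengths[str(c)])
            if contig_lengths is not None and str(c) in contig_lengths
            else int(grp["end"].max())
        )
        starts = np.asarray(grp["start"], dtype=np.int64)
        ends = np.asarray(grp["end"], dtype=np.int64)
        rates = np.asarray(grp["rate"], dtype=float)
        for ws in range(0, L, window):
            we = min(ws + window, L)
            ov = np.minimum(ends, we) - np.maximum(starts, ws)
            ov = np.clip(ov, 0, None)
            cov = ov.sum()
            rate = float(np.sum(ov * rates) / cov) if cov > 0 else np.nan
            rows.append((c, ws, we, rate))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])


def spearman(x, y):
    """Spearman rank correlation (average ranks for ties) with asymptotic P.

    NaN pairs are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined pairs")
    rho, p = spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def correlate_windows(
    a: pd.DataFrame, b: pd.DataFrame, col_a: str, col_b: str
):
    """Join two window tables on (chrom, start, end) and correlate columns."""
    merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    ca = col_a if col_a in merged.columns else f"{col_a}_a"
    cb = col_b if col_b in merged.columns else f"{col_b}_b"
    rho, p = spearman(merged[ca], merged[cb])
    logger.info("spearman(%s, %s): rho=%.4f p=%.3g over %d windows", col_a, col_b, rho, p, len(merged))
    return rho, p, merged
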