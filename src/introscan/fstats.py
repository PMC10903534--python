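"""ABBA-BABA D, windowed fd introgression scans, and f4 / f4-ratio ancestry
estimation with weighted block-jackknife uncertainty.

All statistics operate on population allele frequencies.  The fd statistic
follows the frequency formulation with a dynamic donor: at each site the
denominator replaces both P2 and P3 by the larger of the two frequencies, so
fd equals 1 under complete introgression from P3 into P2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_io import FrequencyTable, PopulationMap, contig_windows

logger = logging.getLogger("introscan")


@dataclass
class AncestryEstimate:
    """An admixture proportion (alpha) with block-jackknife uncertainty."""

    population: str
    category: str  # feature category, or "genome"
    alpha: float
    se: float
    n_blocks: int
    n_sites: int
    reliable: bool = True


# ---------------------------------------------------------------------------
# Site patterns and fd
# ---------------------------------------------------------------------------


def site_patterns(p1, p2, p3, p4):
    """ABBA/BABA pattern weights from allele frequencies (vectorized).

    abba = (1-p1) p2 p3 (1-p4);  baba = p1 (1-p2) p3 (1-p4)
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _fd_terms(p1, p2, p3, p4):
    """Per-site numerator and dynamic-donor denominator terms of fd."""
    abba, baba = site_patterns(p1, p2, p3, p4)
    pd_ = np.maximum(p2, p3)
    abba_d, baba_d = site_patterns(p1, pd_, pd_, p4)
    return abba, baba, abba_d - baba_d


def fd_window(p1, p2, p3, p4) -> dict:
    """D and fd over one window of per-site frequencies.

    Sites with any undefined frequency are skipped.  fd is undefined (NaN)
    when the window's D or fd is negative, or the denominator is zero.
    n_informative counts sites with abba + baba > 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
    p1, p2, p3, p4 = p1[ok], p2[ok], p3[ok], p4[ok]
    abba, baba, den_d = _fd_terms(p1, p2, p3, p4)
    num = float(np.sum(abba - baba))
    tot = float(np.sum(abba + baba))
    den = float(np.sum(den_d))
    n_informative = int(np.sum(abba + baba > 0))
    D = num / tot if tot > 0 else np.nan
    fd_raw = num / den if den > 0 else np.nan
    if den <= 0 or np.isnan(D) or D < 0 or fd_raw < 0:
        fd = np.nan
    else:
        fd = fd_raw
    return {"D": D, "fd": fd, "fd_raw": fd_raw, "n_informative": n_informative}


def scan_fd(
    ft: FrequencyTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    window: int = 100_000,
    step: int = 20_000,
    min_sites: int = 100,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window fd scan: P1 = sister reference, P2 = focal admixed,
    P3 = donor, O = outgroup.

    All windows are emitted; ``eligible`` marks windows that qualify for
    outlier calling (D > 0, fd defined and > 0, n_informative >= min_sites).
    """
    if ft.n_sites == 0:
        raise ValueError("empty frequency table")
    grid = contig_windows(ft.chrom, ft.pos, window, step, contig_lengths)
    f1, f2, f3, f4_ = (ft.freq_of(p) for p in (p1, p2, p3, outgroup))
    pos0 = ft.pos - 1
    rows = []
    for c, sub in grid.groupby("chrom", sort=False):
        on_c = ft.chrom == c
        cp = pos0[on_c]
        q1, q2, q3, q4 = f1[on_c], f2[on_c], f3[on_c], f4_[on_c]
        order = np.argsort(cp, kind="stable")
        cp, q1, q2, q3, q4 = cp[order], q1[order], q2[order], q3[order], q4[order]
        for w in sub.itertuples(index=False):
            lo = np.searchsorted(cp, w.start, side="left")
            hi = np.searchsorted(cp, w.end, side="left")
            res = fd_window(q1[lo:hi], q2[lo:hi], q3[lo:hi], q4[lo:hi])
            rows.append((c, w.start, w.end, w.partial, res["D"], res["fd"],
                         res["fd_raw"], res["n_informative"]))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "partial", "D", "fd", "fd_raw",
                 "n_informative"],
    )
    out["stat"] = "fd"
    out["eligible"] = (
        np.isfinite(out["fd"]) & (out["fd"] > 0) & (out["D"] > 0)
        & (out["n_informative"] >= min_sites)
    )
    return out


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a vector of P-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def z_fdr_outliers(
    stats: pd.DataFrame, alpha: float = 0.05, min_sites: int = 100
) -> pd.DataFrame:
    """Z-standardize fd, convert to one-sided upper-tail P-values, apply
    Benjamini-Hochberg, and flag outliers at q <= alpha.

    The standardization uses the genome-wide distribution of the raw
    (untruncated) window ratio over all windows meeting the informative-site
    minimum: standardizing against only the retained (D > 0) half of the
    distribution is anti-conservative, since that half is a positive
    truncation of a distribution symmetric around 0 under the
    no-introgression null.  Outliers additionally require window D > 0,
    fd > 0 and the informative-site minimum (the ``eligible`` flag).
    """
    out = stats.copy()
    elig = out["eligible"].to_numpy(dtype=bool)
    if elig.sum() < 2:
        raise ValueError("need at least 2 eligible windows")
    raw = out["fd_raw"].to_numpy(dtype=float)
    use = np.isfinite(raw) & (out["n_informative"].to_numpy() >= min_sites)
    fd = raw[use]
    sd = fd.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(fd).max())):
        raise ValueError("zero variance among eligible fd values")
    z = (fd - fd.mean()) / sd
    p = 1 - norm.cdf(z)
    q = bh_qvalues(p)
    out["z"] = np.nan
    out["p"] = np.nan
    out["q"] = np.nan
    out.loc[use, "z"] = z
    out.loc[use, "p"] = p
    out.loc[use, "q"] = q
    out["outlier"] = elig & (out["q"] <= alpha)
    logger.info(
        "fd outlier scan: %d/%d eligible windows, %d outliers at FDR <= %g",
        elig.sum(), len(out), int(out["outlier"].sum()), alpha,
    )
    return out


# ---------------------------------------------------------------------------
# f4 and the f4-ratio
# ---------------------------------------------------------------------------


def f4(pA, pB, pC, pD) -> float:
    """f4(A,B;C,D) = mean over sites of (pA - pB)(pC - pD).

    Sites with any undefined frequency are dropped.
    """
    pA, pB, pC, pD = (np.asarray(p, dtype=float) for p in (pA, pB, pC, pD))
    ok = ~(np.isnan(pA) | np.isnan(pB) | np.isnan(pC) | np.isnan(pD))
    if not ok.any():
        raise ValueError("no shared sites with defined frequencies")
    return float(np.mean((pA[ok] - pB[ok]) * (pC[ok] - pD[ok])))


def weighted_block_jackknife(theta_full: float, loo: np.ndarray, weights: np.ndarray):
    """Weighted delete-one block jackknife (Busing et al. 1999).

    ``loo`` are the delete-one-block estimates and ``weights`` the block
    sizes (site counts).  Returns ``(estimate, se)`` where the estimate is
    the bias-corrected jackknife mean.
    """
    loo = np.asarray(loo, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = len(loo)
    if g < 2:
        raise ValueError("need at least 2 blocks")
    W = w.sum()
    h = W / w
    theta_j = g * theta_full - np.sum((1 - w / W) * loo)
    tau = h * theta_full - (h - 1) * loo  # pseudo-values
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    return theta_j, float(np.sqrt(var))


def _block_ids(chrom: np.ndarray, pos: np.ndarray, block_size: int) -> np.ndarray:
    """Contiguous genomic block labels (per-chrom, block_size bp)."""
    labels = np.empty(len(pos), dtype=object)
    for c in dict.fromkeys(np.asarray(chrom)):
        sel = chrom == c
        labels[sel] = [f"{c}:{b}" for b in (pos[sel] - 1) // block_size]
    return labels


def f4_ratio(
    ft: FrequencyTable,
    pm: PopulationMap,
    test_pop: str,
    block_size: int = 5_000_000,
    category: str = "genome",
    den_tol: float = 1e-12,
) -> AncestryEstimate:
    """Ancestry proportion alpha of the donor (WL) lineage in ``test_pop``.

    alpha = f4(ref, out; test, EL) / f4(ref, out; WL, EL), computed as a
    ratio of genome-wide sums, with SE from the weighted delete-one block
    jackknife over contiguous ``block_size`` blocks.
    """
    ref = pm.pop_with_role("wl_reference")
    out = pm.pop_with_role("outgroup")
    wl = pm.pop_with_role("wl_source")
    el = pm.pop_with_role("el_source")

    pR, pO, pW, pE, pT = (ft.freq_of(p) for p in (ref, out, wl, el, test_pop))
    ok = ~(np.isnan(pR) | np.isnan(pO) | np.isnan(pW) | np.isnan(pE) | np.isnan(pT))
    if ok.sum() == 0:
        raise ValueError("no sites with all five populations defined")
    base = (pR - pO)[ok]
    num_site = base * (pT - pE)[ok]
    den_site = base * (pW - pE)[ok]

    blocks = _block_ids(ft.chrom[ok], ft.pos[ok], block_size)
    uniq, inv = np.unique(blocks, return_inverse=True)
    num_b = np.bincount(inv, weights=num_site)
    den_b = np.bincount(inv, weights=den_site)
    w_b = np.bincount(inv).astype(float)

    num, den = num_b.sum(), den_b.sum()
    if abs(den) < den_tol:
        raise ValueError("f4 denominator is (numerically) zero")
    alpha = num / den

    reliable = True
    if len(uniq) < 2:
        logger.warning("f4_ratio for %s/%s: fewer than 2 jackknife blocks", test_pop, category)
        return AncestryEstimate(test_pop, category, float(alpha), np.nan,
                                int(len(uniq)), int(ok.sum()), reliable=False)
    loo = (num - num_b) / (den - den_b)
    _, se = weighted_block_jackknife(alpha, loo, w_b)
    return AncestryEstimate(
        population=test_pop,
        category=category,
        alpha=float(alpha),
        se=se,
        n_blocks=int(len(uniq)),
        n_sites=int(ok.sum()),
        reliable=reliable,
    )
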