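"""Adaptive-introgression scanning: windowed U and Q95 statistics, top-
percentile outliers, intersection with fd outliers, and region merging.

U(w, x, y) counts sites that are rare (< w) in the non-introgressed
reference panel, common (>= x) in the focal panel and (nearly) fixed (>= y)
in the donor panel; Q95 is the 95% quantile of the focal-panel frequency
over the sites passing the reference and donor conditions.  Both are
evaluated on sliding windows after discarding sites with too much missing
data in any panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FrequencyTable, contig_windows
from .popgen_windows import dxy_sites, pi_sites

logger = logging.getLogger("introscan")


@dataclass
class RegionSet:
    """Merged candidate intervals with provenance (which tests fired)."""

    regions: pd.DataFrame  # chrom, start, end, provenance (";"-joined), n_windows
    members: list = field(default_factory=list)  # per-region member windows

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.provenance}\n")


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------


def u_stat(
    ref_freq, focal_freq, donor_freq, w: float = 0.01, x: float = 0.20, y: float = 1.0
) -> int:
    """Count of sites with ref < w, focal >= x and donor >= y.

    The donor condition is evaluated on non-missing calls, so y = 1.0 means
    every called donor chromosome carries the allele.  Sites with undefined
    frequencies in any panel are skipped.
    """
    r, f, d = (np.asarray(a, dtype=float) for a in (ref_freq, focal_freq, donor_freq))
    ok = ~(np.isnan(r) | np.isnan(f) | np.isnan(d))
    return int(np.sum((r[ok] < w) & (f[ok] >= x) & (d[ok] >= y)))


def q95_stat(
    ref_freq, focal_freq, donor_freq, w: float = 0.01, y: float = 1.0, q: float = 0.95
) -> float:
    """Quantile (linear interpolation) of focal frequency over the
    conditioning set {ref < w and donor >= y}; NaN when the set is empty."""
    r, f, d = (np.asarray(a, dtype=float) for a in (ref_freq, focal_freq, donor_freq))
    ok = ~(np.isnan(r) | np.isnan(f) | np.isnan(d))
    cond = f[ok][(r[ok] < w) & (d[ok] >= y)]
    if len(cond) == 0:
        return np.nan
    return float(np.quantile(cond, q, method="linear"))


def scan_uq95(
    ft: FrequencyTable,
    ref_pop: str,
    focal_pop: str,
    donor_pop: str,
    window: int = 100_000,
    step: int = 20_000,
    w: float = 0.01,
    x: float = 0.20,
    y: float = 1.0,
    max_missing: float = 0.25,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window U and Q95 scan.

    Sites with a missing-genotype fraction above ``max_missing`` in any of
    the three panels are discarded before windowing.
    """
    keep = (
        (ft.miss_of(ref_pop) <= max_missing)
        & (ft.miss_of(focal_pop) <= max_missing)
        & (ft.miss_of(donor_pop) <= max_missing)
    )
    sub = ft.subset(keep)
    grid = contig_windows(ft.chrom, ft.pos, window, step, contig_lengths)
    r_all, f_all, d_all = (sub.freq_of(p) for p in (ref_pop, focal_pop, donor_pop))
    pos0 = sub.pos - 1
    rows = []
    for c, gsub in grid.groupby("chrom", sort=False):
        on_c = sub.chrom == c
        cp = pos0[on_c]
        order = np.argsort(cp, kind="stable")
        cp = cp[order]
        r, f, d = r_all[on_c][order], f_all[on_c][order], d_all[on_c][order]
        for win in gsub.itertuples(index=False):
            lo = np.searchsorted(cp, win.start, side="left")
            hi = np.searchsorted(cp, win.end, side="left")
            rows.append((
                c, win.start, win.end, win.partial,
                u_stat(r[lo:hi], f[lo:hi], d[lo:hi], w, x, y),
                q95_stat(r[lo:hi], f[lo:hi], d[lo:hi], w, y),
                hi - lo,
            ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial", "U", "Q95", "n_sites"])


def top_percentile(stats: pd.DataFrame, col: str, q: float = 0.01) -> pd.DataFrame:
    """Windows with ``col`` at or above the (1-q) empirical quantile of the
    defined values; ties at the threshold are all included."""
    vals = stats[col].to_numpy(dtype=float)
    defined = np.isfinite(vals)
    if defined.sum() == 0:
        return stats.iloc[0:0].copy()
    dv = vals[defined]
    if np.all(dv == dv[0]):
        logger.warning("top_percentile(%s): all values equal; returning all defined windows", col)
        return stats.loc[defined].copy()
    thr = np.quantile(dv, 1 - q)
    return stats.loc[defined & (vals >= thr)].copy()


# ---------------------------------------------------------------------------
# Region intersection / merging
# ---------------------------------------------------------------------------


def merge_windows(windows: pd.DataFrame, flags: dict | None = None) -> RegionSet:
    """Merge overlapping or book-ended window intervals into maximal regions.

    ``flags`` maps window index -> iterable of provenance labels; merged
    regions carry the union of their members' labels.
    """
    if len(windows) == 0:
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end", "provenance", "n_windows"]))
    df = windows.sort_values(["chrom", "start", "end"]).reset_index()
    rows, members = [], []
    cur = None
    for r in df.itertuples(index=False):
        labels = set(flags.get(r.index, ())) if flags is not None else set()
        if cur is not None and r.chrom == cur["chrom"] and r.start <= cur["end"]:
            cur["end"] = max(cur["end"], r.end)
            cur["labels"] |= labels
            cur["members"].append(r.index)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": r.chrom, "start": r.start, "end": r.end,
                   "labels": labels, "members": [r.index]}
    rows.append(cur)
    out = pd.DataFrame(
        [(r["chrom"], r["start"], r["end"], ";".join(sorted(r["labels"])), len(r["members"]))
         for r in rows],
        columns=["chrom", "start", "end", "provenance", "n_windows"],
    )
    return RegionSet(out, [r["members"] for r in rows])


def _overlaps_any(chrom, start, end, other: pd.DataFrame) -> bool:
    sel = other["chrom"] == chrom
    return bool(np.any((other.loc[sel, "start"] < end) & (other.loc[sel, "end"] > start)))


def intersect_and_merge(
    fd_outliers: pd.DataFrame, u_top: pd.DataFrame, q_top: pd.DataFrame
) -> RegionSet:
    """Putative adaptive-introgression regions.

    Candidate windows are those present in both the top U and top Q95 sets
    (same window key) whose span overlaps at least one fd outlier window
    (>= 1 bp).  Overlapping/book-ended candidates are merged; provenance
    records the three tests.
    """
    key = ["chrom", "start", "end"]
    uq = u_top[key].merge(q_top[key], on=key)
    if len(uq) == 0:
        return RegionSet(pd.DataFrame(columns=key + ["provenance", "n_windows"]))
    hits = [
        _overlaps_any(r.chrom, r.start, r.end, fd_outliers)
        for r in uq.itertuples(index=False)
    ]
    cand = uq.loc[hits]
    if len(cand) == 0:
        return RegionSet(pd.DataFrame(columns=key + ["provenance", "n_windows"]))
    flags = {i: ("fd", "U", "Q95") for i in cand.index}
    merged = merge_windows(cand, flags)
    logger.info("AI candidates: %d windows merged into %d regions", len(cand), len(merged))
    return merged


# ---------------------------------------------------------------------------
# Per-region evidence bundle
# ---------------------------------------------------------------------------


def candidate_report(
    region,
    ft: FrequencyTable,
    wl_pop: str,
    focal_pop: str,
    el_pop: str,
    fine_window: int = 10_000,
    fine_step: int = 5_000,
    maf: float = 0.05,
    flank: int = 100_000,
) -> dict:
    """Fine-scale evidence for one candidate region (plus flanks).

    Returns ``tracks`` (10 kb / 5 kb FST and dxy of the focal population
    against both parents, and pi) and ``vaf`` (per-site frequencies in the
    three panels, minor-allele frequency filtered on the pooled panels).
    """
    chrom, start, end = region if isinstance(region, tuple) else (
        region["chrom"], region["start"], region["end"])
    lo, hi = max(0, start - flank), end + flank
    sel = (ft.chrom == chrom) & (ft.pos - 1 >= lo) & (ft.pos - 1 < hi)
    sub = ft.subset(sel)

    pw, pf, pe = (sub.freq_of(p) for p in (wl_pop, focal_pop, el_pop))
    nw, nf, ne = (sub.n_of(p) for p in (wl_pop, focal_pop, el_pop))
    pos0 = sub.pos - 1

    rows = []
    for ws in range(lo, hi, fine_step):
        we = ws + fine_window
        m = (pos0 >= ws) & (pos0 < we)
        if not m.any():
            rows.append((chrom, ws, we, 0, *(np.nan,) * 5))
            continue
        hf = pi_sites(pf[m], nf[m])

        def _fst(pp, nn):
            hp = pi_sites(pp[m], nn[m])
            hb = dxy_sites(pf[m], pp[m])
            ok = ~(np.isnan(hf) | np.isnan(hp) | np.isnan(hb))
            if not ok.any() or np.mean(hb[ok]) == 0:
                return np.nan, np.nan
            return 1 - np.mean((hf[ok] + hp[ok]) / 2) / np.mean(hb[ok]), float(np.mean(hb[ok]))

        fst_wl, dxy_wl = _fst(pw, nw)
        fst_el, dxy_el = _fst(pe, ne)
        okf = ~np.isnan(hf)
        pi_f = float(np.mean(hf[okf])) if okf.any() else np.nan
        rows.append((chrom, ws, we, int(m.sum()), fst_wl, fst_el, dxy_wl, dxy_el, pi_f))
    tracks = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites",
                 "fst_vs_wl", "fst_vs_el", "dxy_vs_wl", "dxy_vs_el", "pi_focal"],
    )

    # pooled minor-allele frequency over the three panels (n-weighted)
    tot_n = nw + nf + ne
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(tot_n > 0, (pw * nw + pf * nf + pe * ne) / tot_n, np.nan)
    pooled_maf = np.minimum(pooled, 1 - pooled)
    in_region = (pos0 >= start) & (pos0 < end)
    vmask = in_region & (pooled_maf >= maf)
    vaf = pd.DataFrame({
        "chrom": sub.chrom[vmask], "pos": sub.pos[vmask],
        f"freq_{wl_pop}": pw[vmask], f"freq_{focal_pop}": pf[vmask],
        f"freq_{el_pop}": pe[vmask],
    })
    return {"tracks": tracks, "vaf": vaf}
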