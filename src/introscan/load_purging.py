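"""Introgressed-load analysis: WL-origin classification, variant-impact
stratification, and the r_xy purging statistic with a leave-one-linkage-
group-out jackknife.

r_xy compares the abundance of a category of alleles between two
populations, normalized by an equally sized random draw of intergenic
(putatively neutral) variants:

    L_x!y = sum_i f_x(1 - f_y),   L_y!x = sum_i f_y(1 - f_x)
    r_xy  = [L_x!y(cat) / L_y!x(cat)] / [L_x!y(neu) / L_y!x(neu)]

r_xy = 1 when frequency changes in the category track the neutral
background; r_xy < 1 indicates a deficit of the focal alleles in population
x relative to y.  When profiling population pairs along the contact-zone
gradient, the population farther from the introgression entry is placed at
x, so purging there yields r_xy < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import FrequencyTable
from .fstats import weighted_block_jackknife

logger = logging.getLogger("introscan")

IMPACT_CLASSES = ("LOW", "MODERATE", "HIGH")

#: SnpEff effect term -> impact class; other coding terms are excluded.
EFFECT_TO_IMPACT = {
    "synonymous_variant": "LOW",
    "missense_variant": "MODERATE",
    "stop_gained": "HIGH",
}

_SEVERITY = {"NONCODING": 0, "LOW": 1, "MODERATE": 2, "HIGH": 3}


# ---------------------------------------------------------------------------
# WL-origin classification
# ---------------------------------------------------------------------------


def classify_wl_origin(
    ft: FrequencyTable,
    el_ref: str,
    wl_ref: str,
    el_max: float = 0.05,
    wl_min: float = 0.95,
):
    """Flag sites of donor (WL) origin: freq <= el_max in the EL reference
    AND freq >= wl_min in the WL reference (bounds inclusive).

    Sites with an undefined reference frequency are skipped (flag False) and
    counted; returns ``(flags, n_skipped)``.
    """
    fe = ft.freq_of(el_ref)
    fw = ft.freq_of(wl_ref)
    defined = ~(np.isnan(fe) | np.isnan(fw))
    flags = np.zeros(ft.n_sites, dtype=bool)
    flags[defined] = (fe[defined] <= el_max) & (fw[defined] >= wl_min)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("classify_wl_origin: %d sites skipped (undefined reference frequency)", n_skipped)
    return flags, n_skipped


# ---------------------------------------------------------------------------
# Impact annotation
# ---------------------------------------------------------------------------


def parse_impacts(source) -> pd.DataFrame:
    """Build a (chrom, pos, impact) table from SnpEff-style annotations.

    ``source`` may be a DataFrame or TSV path with columns chrom/pos/impact
    (or chrom/pos/effect, mapped through the SnpEff effect terms), or a VCF
    path whose INFO contains an ``ANN`` field.  Multi-annotation sites take
    the maximum-severity impact; coding terms outside the mapping are
    excluded and counted in ``df.attrs['n_excluded']``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = str(source)
        if path.endswith((".vcf", ".vcf.gz")):
            return _impacts_from_vcf(path)
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
    n_excluded = 0
    if "impact" not in df.columns:
        if "effect" not in df.columns:
            raise ValueError("impact table needs an 'impact' or 'effect' column")
        mapped = df["effect"].map(EFFECT_TO_IMPACT)
        n_excluded = int(mapped.isna().sum())
        df = df.assign(impact=mapped).dropna(subset=["impact"])
    bad = set(df["impact"]) - set(IMPACT_CLASSES) - {"NONCODING"}
    if bad:
        raise ValueError(f"unknown impact classes: {sorted(bad)}")
    out = _max_severity(df[["chrom", "pos", "impact"]])
    out.attrs["n_excluded"] = n_excluded
    return out


def _impacts_from_vcf(path: str) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows, n_excluded, n_malformed = [], 0, 0
    for v in VCF(path):
        ann = v.INFO.get("ANN")
        if ann is None:
            continue
        best = None
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 2:
                n_malformed += 1
                continue
            for effect in fields[1].split("&"):
                impact = EFFECT_TO_IMPACT.get(effect)
                if impact is None:
                    n_excluded += 1
                    continue
                if best is None or _SEVERITY[impact] > _SEVERITY[best]:
                    best = impact
        if best is not None:
            rows.append((v.CHROM, v.POS, best))
    if n_malformed:
        logger.warning("parse_impacts: %d malformed ANN entries skipped", n_malformed)
    out = _max_severity(pd.DataFrame(rows, columns=["chrom", "pos", "impact"]))
    out.attrs["n_excluded"] = n_excluded
    return out


def _max_severity(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        return df.reset_index(drop=True)
    df = df.assign(_sev=df["impact"].map(_SEVERITY))
    df = df.sort_values("_sev").drop_duplicates(["chrom", "pos"], keep="last")
    return df.drop(columns="_sev").sort_values(["chrom", "pos"]).reset_index(drop=True)


def impacts_for_sites(ft: FrequencyTable, impacts: pd.DataFrame) -> np.ndarray:
    """Per-site impact labels aligned to ``ft``; NONCODING where absent."""
    key = pd.MultiIndex.from_arrays([ft.chrom, ft.pos])
    table = impacts.set_index(["chrom", "pos"])["impact"]
    return table.reindex(key).fillna("NONCODING").to_numpy()


# ---------------------------------------------------------------------------
# r_xy
# ---------------------------------------------------------------------------


@dataclass
class RxyEstimate:
    category: str
    subset: str  # "all" | "WL_origin"
    pop_x: str
    pop_y: str
    value: float
    se: float
    ci_lo: float
    ci_hi: float
    n_sites: int
    n_neutral: int


def _l_sums(fx, fy):
    return np.sum(fx * (1 - fy)), np.sum(fy * (1 - fx))


def rxy(
    ft: FrequencyTable,
    pop_x: str,
    pop_y: str,
    category_sites: np.ndarray,
    neutral_sites: np.ndarray,
    category: str = "category",
    subset: str = "all",
) -> RxyEstimate:
    """r_xy for a category site set against a neutral site set, with SE and
    95% CI (+- 1.96 SE) from the delete-one jackknife across linkage groups
    (chromosomes of ``ft``).

    ``category_sites`` / ``neutral_sites`` are boolean masks or index arrays
    over the table's sites.  Sites with an undefined frequency in either
    population are dropped.  A zero L sum raises ``ValueError`` naming it.
    """
    cat_mask = _as_mask(category_sites, ft.n_sites)
    neu_mask = _as_mask(neutral_sites, ft.n_sites)
    if cat_mask.sum() == 0 or neu_mask.sum() == 0:
        raise ValueError("category and neutral site sets must be non-empty")
    fx_all, fy_all = ft.freq_of(pop_x), ft.freq_of(pop_y)
    defined = ~(np.isnan(fx_all) | np.isnan(fy_all))
    cat_mask = cat_mask & defined
    neu_mask = neu_mask & defined

    def _sums_for(mask):
        return _l_sums(fx_all[mask], fy_all[mask])

    names = ("L_x_not_y(category)", "L_y_not_x(category)",
             "L_x_not_y(neutral)", "L_y_not_x(neutral)")
    cxy, cyx = _sums_for(cat_mask)
    nxy, nyx = _sums_for(neu_mask)
    for name, val in zip(names, (cxy, cyx, nxy, nyx)):
        if val == 0:
            raise ValueError(f"{name} is zero; r_xy undefined")
    value = (cxy / cyx) / (nxy / nyx)

    # leave-one-LG-out jackknife
    lgs = list(dict.fromkeys(np.asarray(ft.chrom)))
    loo, weights = [], []
    for lg in lgs:
        off = ft.chrom != lg
        c_m, n_m = cat_mask & off, neu_mask & off
        w = int((cat_mask & ~off).sum() + (neu_mask & ~off).sum())
        if c_m.sum() == 0 or n_m.sum() == 0:
            continue
        a, b = _sums_for(c_m)
        c, d = _sums_for(n_m)
        if min(a, b, c, d) <= 0:
            continue
        loo.append((a / b) / (c / d))
        weights.append(max(w, 1))
    if len(loo) >= 2:
        _, se = weighted_block_jackknife(value, np.asarray(loo), np.asarray(weights, float))
    else:
        logger.warning("rxy: fewer than 2 usable jackknife blocks; SE undefined")
        se = np.nan
    return RxyEstimate(
        category=category, subset=subset, pop_x=pop_x, pop_y=pop_y,
        value=float(value), se=float(se),
        ci_lo=float(value - 1.96 * se), ci_hi=float(value + 1.96 * se),
        n_sites=int(cat_mask.sum()), n_neutral=int(neu_mask.sum()),
    )


def _as_mask(sites, n: int) -> np.ndarray:
    sites = np.asarray(sites)
    if sites.dtype == bool:
        if len(sites) != n:
            raise ValueError("boolean site mask length mismatch")
        return sites.copy()
    mask = np.zeros(n, dtype=bool)
    mask[sites] = True
    return mask


def draw_neutral_sites(
    candidate_mask: np.ndarray, n_draw: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded draw of ``n_draw`` neutral (intergenic) sites.

    Sampling is without replacement when possible; falls back to with-
    replacement (with a warning) when the candidate pool is smaller.
    """
    idx = np.flatnonzero(np.asarray(candidate_mask))
    if len(idx) == 0:
        raise ValueError("no neutral candidate sites to sample from")
    if len(idx) >= n_draw:
        return rng.choice(idx, size=n_draw, replace=False)
    logger.warning(
        "neutral pool (%d) smaller than requested draw (%d); sampling with replacement",
        len(idx), n_draw,
    )
    return rng.choice(idx, size=n_draw, replace=True)


def rxy_profile(
    ft: FrequencyTable,
    pairs: list,
    impacts: np.ndarray,
    origin_flags: np.ndarray,
    intergenic_mask: np.ndarray,
    seed: int | None = None,
) -> list[RxyEstimate]:
    """The r_xy grid: every (pair x impact class x {all, WL-origin}) cell.

    ``pairs`` are (nearer, farther) population tuples ordered along the
    gradient away from the introgression entry; each cell is evaluated with
    the farther population at x, so purging there yields r_xy < 1.  The
    neutral set is an equally sized seeded draw from ``intergenic_mask``
    per cell; for WL-origin cells the draw is additionally restricted to
    WL-origin intergenic variants so the neutral proxy matches the ancestry
    composition of the category (otherwise the ancestry-proportion gradient
    itself, not selection, would drive every WL-origin cell away from 1).
    """
    impacts = np.asarray(impacts)
    origin_flags = np.asarray(origin_flags, dtype=bool)
    intergenic_mask = np.asarray(intergenic_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    out = []
    for near, far in pairs:
        for impact in IMPACT_CLASSES:
            for subset in ("all", "WL_origin"):
                mask = impacts == impact
                if subset == "WL_origin":
                    mask = mask & origin_flags
                if mask.sum() == 0:
                    logger.warning("rxy_profile: empty cell %s/%s for (%s,%s)",
                                   impact, subset, near, far)
                    continue
                pool = intergenic_mask
                if subset == "WL_origin":
                    pool = pool & origin_flags
                neutral = draw_neutral_sites(pool, int(mask.sum()), rng)
                try:
                    est = rxy(ft, far, near, mask, neutral,
                              category=impact, subset=subset)
                except ValueError as exc:
                    logger.warning("rxy_profile cell %s/%s (%s,%s) failed: %s",
                                   impact, subset, near, far, exc)
                    continue
                out.append(est)
    return out


def rxy_table(estimates: list[RxyEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.pop_x, e.pop_y, e.category, e.subset, e.value, e.se, e.ci_lo, e.ci_hi,
          e.n_sites, e.n_neutral) for e in estimates],
        columns=["pop_x", "pop_y", "impact", "subset", "rxy", "se", "ci_lo", "ci_hi",
                 "n_sites", "n_neutral"],
    )
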