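"""Feature-stratified f4-ratio ancestry with an empirical resampling test
against the intergenic background.

Each site is assigned one of the six genomic-feature categories; the donor
ancestry proportion alpha is re-estimated on each category's site subset
with its own block jackknife, and compared with the intergenic estimate by
resampling both estimates from normal distributions parameterized by their
jackknife standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CATEGORIES, FeatureTrack, FrequencyTable, PopulationMap
from .fstats import AncestryEstimate, f4_ratio

logger = logging.getLogger("introscan")


@dataclass
class ResampleResult:
    p: float
    direction: str  # "higher" | "lower"
    n: int


def alpha_by_feature(
    ft: FrequencyTable,
    pm: PopulationMap,
    track: FeatureTrack,
    test_pop: str,
    block_size: int = 5_000_000,
) -> list[AncestryEstimate]:
    """One ancestry estimate per feature category for ``test_pop``.

    Categories whose site subset yields fewer than 2 jackknife blocks are
    flagged unreliable (``reliable=False``, SE = NaN).
    """
    cats = track.assign(ft.chrom, ft.pos - 1)
    out = []
    for cat in CATEGORIES:
        mask = cats == cat
        if mask.sum() == 0:
            out.append(AncestryEstimate(test_pop, cat, np.nan, np.nan, 0, 0, reliable=False))
            continue
        sub = ft.subset(mask)
        try:
            est = f4_ratio(sub, pm, test_pop, block_size=block_size, category=cat)
        except ValueError as exc:
            logger.warning("alpha_by_feature %s/%s failed: %s", test_pop, cat, exc)
            est = AncestryEstimate(test_pop, cat, np.nan, np.nan, 0, int(mask.sum()),
                                   reliable=False)
        out.append(est)
    return out


def resample_test(
    feature_est: AncestryEstimate,
    intergenic_est: AncestryEstimate,
    n: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    resample_background: bool = True,
) -> ResampleResult:
    """Empirical significance of a feature's alpha against the intergenic one.

    Draws a_f ~ N(alpha_f, SE_f) and (by default) a_i ~ N(alpha_i, SE_i)
    independently ``n`` times; the two-sided empirical P is
    2*min(#[a_f > a_i], #[a_f < a_i])/n, floored at 1/n.  With
    ``resample_background=False`` the intergenic alpha is held fixed.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    for est in (feature_est, intergenic_est):
        if not np.isfinite(est.alpha) or not np.isfinite(est.se):
            raise ValueError("estimates must have finite alpha and SE")
    rng = np.random.default_rng(seed)
    a_f = rng.normal(feature_est.alpha, feature_est.se, size=n)
    if resample_background:
        a_i = rng.normal(intergenic_est.alpha, intergenic_est.se, size=n)
    else:
        a_i = np.full(n, intergenic_est.alpha)
    n_gt = int(np.sum(a_f > a_i))
    n_lt = int(np.sum(a_f < a_i))
    direction = "higher" if n_gt >= n_lt else "lower"
    if two_sided:
        p = 2.0 * min(n_gt, n_lt) / n
    else:
        p = (n_lt if direction == "higher" else n_gt) / n
    p = min(max(p, 1.0 / n), 1.0)
    return ResampleResult(p=p, direction=direction, n=n)


def feature_ancestry_table(
    ft: FrequencyTable,
    pm: PopulationMap,
    track: FeatureTrack,
    test_pops: list | None = None,
    n_resample: int = 10_000,
    seed: int | None = None,
    block_size: int = 5_000_000,
) -> pd.DataFrame:
    """Per-population, per-category alpha with significance vs intergenic.

    Output mirrors the usual feature-stratified ancestry plot: one row per
    (population, category) with alpha, SE, empirical P and direction;
    ``significant`` marks P < 0.05.
    """
    if test_pops is None:
        test_pops = pm.admixed_pops()
    rows = []
    for k, pop in enumerate(test_pops):
        ests = {e.category: e for e in alpha_by_feature(ft, pm, track, pop, block_size)}
        inter = ests["intergenic"]
        for cat in CATEGORIES:
            est = ests[cat]
            if cat == "intergenic" or not (est.reliable and inter.reliable):
                p, direction = np.nan, ""
            else:
                sub_seed = None if seed is None else seed + 1000 * k + CATEGORIES.index(cat)
                res = resample_test(est, inter, n=n_resample, seed=sub_seed)
                p, direction = res.p, res.direction
            rows.append((pop, cat, est.alpha, est.se, est.n_blocks, est.n_sites,
                         est.reliable, p, direction, bool(p < 0.05) if np.isfinite(p) else False))
    return pd.DataFrame(
        rows,
        columns=["population", "category", "alpha", "se", "n_blocks", "n_sites",
                 "reliable", "p_vs_intergenic", "direction", "significant"],
    )
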