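"""Synthetic secondary-contact cohort generator with ground truth.

The generator emulates, at desk scale, the statistical structure every
analysis stage of this package assumes: two parental lineages diverged by
drift (Balding-Nichols model), an outgroup, admixed populations carrying a
known genome-wide donor (WL) ancestry proportion laid down in exponentially
distributed ancestry blocks, optional window-localized adaptive-introgression
sweeps, a deterministic genomic-feature track, impact-labelled coding
variants with an optional planted purging gradient, and a recombination map.

A fraction of sites (``diag_frac``) are fixed lineage differences, as
expected between deeply diverged lineages; without them the donor-fixed /
reference-absent conditioning set of the U/Q95 statistics would be
essentially empty at desk scale.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    FeatureTrack,
    FrequencyTable,
    PopulationMap,
    RecombinationMap,
    VariantTable,
    derive_promoters,
    write_vcf,
)

logger = logging.getLogger("introscan")

WL_SOURCE = "DEN-NOR"
WL_REFERENCE = "GBR-GRO"
EL_SOURCE = "RUS-LEV"
OUTGROUP = "CAN-TEM"
PARENTAL_POPS = (WL_SOURCE, WL_REFERENCE, EL_SOURCE, OUTGROUP)

_IMPACT_EFFECT = {
    "LOW": "synonymous_variant",
    "MODERATE": "missense_variant",
    "HIGH": "stop_gained",
}


@dataclass
class PlantedAI:
    """A window-localized adaptive-introgression sweep."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    donor_freq_target: float = 0.9
    focal_pops: tuple = ("BS7",)


@dataclass
class SimConfig:
    """Scenario parameters of the synthetic secondary-contact cohort.

    Defaults mirror the real study's scale where that is feasible on a
    desktop: 20 autosomal linkage groups, a gradient of admixed populations
    with decreasing WL ancestry, lineage drift F_split = 0.2, within-lineage
    drift F_pop = 0.05 and outgroup drift F_out = 0.4.
    """

    seed: int
    n_contigs: int = 20
    contig_length: int = 2_000_000
    n_sites: int = 50_000
    f_split: float = 0.2
    f_pop: float = 0.05
    f_out: float = 0.4
    diag_frac: float = 0.08
    alphas: dict = field(
        default_factory=lambda: {"GER-RUE": 0.35, "POL-GDY": 0.22, "BS7": 0.12}
    )
    # ~1/(r*t) for a ~10 kya contact: r ~ 1e-8 /bp/gen, t ~ 4e3 generations
    block_length_mean: float = 25_000.0
    n_diploids: int = 20
    planted_ai: list = field(default_factory=list)
    purging_multipliers: dict = field(default_factory=dict)  # impact -> multiplier
    purged_pops: tuple = ()
    feature_alpha_boost: dict = field(default_factory=dict)  # category -> extra donor prob
    impact_fractions: dict = field(
        default_factory=lambda: {"LOW": 0.5, "MODERATE": 0.3, "HIGH": 0.2}
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("f_split", "f_pop", "f_out"):
            f = getattr(self, name)
            if not (0 < f < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        for pop, a in self.alphas.items():
            if not (0 <= a <= 1):
                raise ValueError(f"alpha for {pop} must be in [0, 1]")

    @property
    def contigs(self) -> list:
        return [f"LG{i + 1:02d}" for i in range(self.n_contigs)]

    @property
    def contig_lengths(self) -> dict:
        return {c: self.contig_length for c in self.contigs}


@dataclass
class TruthTable:
    """Simulator ground truth, consistent with the emitted variant table."""

    alpha_configured: dict
    alpha_realized: dict
    wl_frac: dict  # admixed pop -> per-site realized WL-ancestry fraction
    true_freqs: dict  # parental/outgroup pop -> per-site true frequency
    diagnostic: np.ndarray  # per-site fixed-lineage-difference flag
    planted_ai: list
    purged_sites: pd.DataFrame  # chrom, pos, impact, multiplier

    def to_json(self, path) -> None:
        payload = {
            "alpha_configured": self.alpha_configured,
            "alpha_realized": self.alpha_realized,
            "planted_ai": [
                {"chrom": p.chrom, "start": p.start, "end": p.end,
                 "donor_freq_target": p.donor_freq_target,
                 "focal_pops": list(p.focal_pops)}
                for p in self.planted_ai
            ],
            "n_purged_sites": int(len(self.purged_sites)),
            "purged_sites": self.purged_sites.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimResult:
    config: SimConfig
    vt: VariantTable
    popmap: PopulationMap
    track: FeatureTrack
    genes: pd.DataFrame
    categories: np.ndarray  # per-site feature category
    impacts: pd.DataFrame  # chrom, pos, effect (SnpEff-style terms)
    rmap: RecombinationMap
    truth: TruthTable

    @property
    def contig_lengths(self) -> dict:
        return self.config.contig_lengths


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------


def balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Drifted frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); fixed alleles
    (p = 0 or 1) stay fixed."""
    p = np.asarray(p, dtype=float)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]
    out[interior] = rng.beta(a[interior], b[interior])
    return out


def _site_positions(cfg: SimConfig, rng: np.random.Generator):
    """Sorted unique 1-based positions, spread evenly across contigs."""
    per = [cfg.n_sites // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_sites % cfg.n_contigs):
        per[i] += 1
    chroms, pos = [], []
    for c, k in zip(cfg.contigs, per):
        draw = np.unique(rng.integers(1, cfg.contig_length + 1, size=2 * k + 16))
        while len(draw) < k:
            draw = np.unique(
                np.concatenate([draw, rng.integers(1, cfg.contig_length + 1, size=2 * k)])
            )
        take = np.sort(rng.choice(draw, size=k, replace=False))
        chroms.append(np.full(k, c, dtype=object))
        pos.append(take.astype(np.int64))
    return np.concatenate(chroms), np.concatenate(pos)


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None):
    """True parental/outgroup allele frequencies for every site.

    Returns ``(chrom, pos, freqs, diagnostic)`` where ``freqs`` maps the four
    parental/outgroup populations to per-site true frequencies and
    ``diagnostic`` flags the fixed lineage differences.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom, pos = _site_positions(cfg, rng)
    n = len(pos)
    p0 = rng.uniform(0.05, 0.95, n)
    wl_anc = balding_nichols(rng, p0, cfg.f_split)
    el_anc = balding_nichols(rng, p0, cfg.f_split)
    diagnostic = rng.random(n) < cfg.diag_frac
    orient = rng.random(n) < 0.5  # which lineage carries the alt allele
    wl_anc = np.where(diagnostic, np.where(orient, 1.0, 0.0), wl_anc)
    el_anc = np.where(diagnostic, np.where(orient, 0.0, 1.0), el_anc)
    freqs = {
        WL_SOURCE: balding_nichols(rng, wl_anc, cfg.f_pop),
        WL_REFERENCE: balding_nichols(rng, wl_anc, cfg.f_pop),
        EL_SOURCE: balding_nichols(rng, el_anc, cfg.f_pop),
        OUTGROUP: balding_nichols(rng, p0, cfg.f_out),
    }
    return chrom, pos, freqs, diagnostic


def true_frequency_table(chrom, pos, freqs) -> FrequencyTable:
    """Package true frequencies as a FrequencyTable (infinite-panel limit)."""
    pops = list(freqs)
    freq = np.column_stack([freqs[p] for p in pops])
    n = np.full_like(freq, 10**9, dtype=np.int32)
    miss = np.zeros_like(freq)
    return FrequencyTable(np.asarray(chrom, dtype=object), np.asarray(pos), pops,
                          freq, n, miss)


# ---------------------------------------------------------------------------
# Feature track, impacts, recombination map
# ---------------------------------------------------------------------------

# deterministic 100 kb layout unit (relative coordinates): one 20 kb gene at
# [30k, 50k) with six 1 kb exons, two constrained elements inside its introns,
# and one constrained element out in the intergenic space.
_UNIT = 100_000
_GENE = (30_000, 50_000)
_EXON_OFFSETS = (0, 4_000, 8_000, 12_000, 16_000, 19_000)
_EXON_LEN = 1_000
_CE_IN = ((5_500, 6_000), (13_500, 14_000))
_CE_OUT = (70_000, 71_000)


def make_feature_track(cfg: SimConfig):
    """Deterministic feature annotation: gene-dense compact-genome layout
    (6% CDS).  Returns ``(FeatureTrack, genes)``."""
    rows, gene_rows = [], []
    for c in cfg.contigs:
        for u in range(0, cfg.contig_length, _UNIT):
            gs, ge = u + _GENE[0], u + _GENE[1]
            if ge > cfg.contig_length:
                continue
            strand = "+" if (u // _UNIT) % 2 == 0 else "-"
            gene_rows.append((c, gs, ge, strand))
            for off in _EXON_OFFSETS:
                rows.append((c, gs + off, gs + off + _EXON_LEN, "CDS"))
            rows.append((c, gs, ge, "intron"))  # CDS takes precedence inside
            for s, e in _CE_IN:
                rows.append((c, gs + s, gs + e, "CE_in_gene"))
            rows.append((c, u + _CE_OUT[0], u + _CE_OUT[1], "CE_outside_gene"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])
    promoters = derive_promoters(genes, 1_000, cfg.contig_lengths)
    intervals = pd.concat(
        [pd.DataFrame(rows, columns=["chrom", "start", "end", "category"]), promoters],
        ignore_index=True,
    )
    return FeatureTrack(intervals, cfg.contig_lengths), genes


def make_recombination_map(cfg: SimConfig, rng: np.random.Generator) -> RecombinationMap:
    """Gamma-distributed window rates (mean 3 cM/Mb) on a 100 kb grid."""
    rows = []
    for c in cfg.contigs:
        for s in range(0, cfg.contig_length, 100_000):
            e = min(s + 100_000, cfg.contig_length)
            rows.append((c, s, e, float(rng.gamma(2.0, 1.5))))
    return RecombinationMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"]))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _hap_block_ancestry(rng, length, mean_len, alpha, pos0):
    """Per-site donor-ancestry flags for one haplotype (exponential blocks)."""
    lens = rng.exponential(mean_len, size=int(length / mean_len * 1.5) + 8)
    while lens.sum() < length:
        lens = np.concatenate([lens, rng.exponential(mean_len, size=len(lens))])
    ends = np.cumsum(lens)
    anc = rng.random(len(ends)) < alpha
    return anc[np.searchsorted(ends, pos0, side="right")]


def simulate_admixed(
    cfg: SimConfig,
    chrom: np.ndarray,
    pos: np.ndarray,
    freqs: dict,
    rng_geno: np.random.Generator,
    rng_plant: np.random.Generator,
    categories: np.ndarray | None = None,
):
    """Genotypes for all populations plus realized-ancestry truth.

    Parental/outgroup genotypes are binomial draws from the true
    frequencies.  Admixed haplotypes are mosaics of exponentially
    distributed ancestry blocks (donor with probability alpha), with alleles
    sampled from the block's parental population frequency.  Planted
    adaptive-introgression sweeps and per-feature ancestry boosts are
    applied at the haplotype level here so the ancestry truth stays
    consistent.
    """
    n = len(pos)
    pops = list(PARENTAL_POPS) + list(cfg.alphas)
    sample_names, pop_of_sample = [], []
    for p in pops:
        for i in range(cfg.n_diploids):
            sample_names.append(f"{p.replace('-', '')}_{i:02d}")
            pop_of_sample.append(p)

    gt = np.empty((n, len(sample_names)), dtype=np.int8)
    col = 0
    for p in PARENTAL_POPS:
        gt[:, col:col + cfg.n_diploids] = rng_geno.binomial(
            2, freqs[p][:, None], size=(n, cfg.n_diploids)
        )
        col += cfg.n_diploids

    # one shared sweep haplotype per planted window
    sweep_haps = {}
    for k, plant in enumerate(cfg.planted_ai):
        if plant.donor_freq_target <= 0:
            continue
        m = (chrom == plant.chrom) & (pos - 1 >= plant.start) & (pos - 1 < plant.end)
        sweep_haps[k] = (m, rng_plant.random(int(m.sum())) < freqs[WL_SOURCE][m])

    boost_masks = {}
    if cfg.feature_alpha_boost and categories is not None:
        for cat, delta in cfg.feature_alpha_boost.items():
            boost_masks[cat] = np.asarray(categories) == cat

    p_wl, p_el = freqs[WL_SOURCE], freqs[EL_SOURCE]
    wl_frac = {}
    for pop, alpha in cfg.alphas.items():
        anc_sum = np.zeros(n)
        haps = np.empty((2 * cfg.n_diploids, n), dtype=np.int8)
        for c in dict.fromkeys(chrom):
            on_c = chrom == c
            cp = (pos[on_c] - 1).astype(float)
            idx = np.flatnonzero(on_c)
            for h in range(2 * cfg.n_diploids):
                anc = _hap_block_ancestry(
                    rng_geno, cfg.contig_length, cfg.block_length_mean, alpha, cp
                )
                allele = rng_geno.random(len(cp)) < np.where(anc, p_wl[on_c], p_el[on_c])
                # planted sweeps on this contig
                for k, plant in enumerate(cfg.planted_ai):
                    if plant.chrom != c or pop not in plant.focal_pops or k not in sweep_haps:
                        continue
                    m, sweep = sweep_haps[k]
                    if rng_plant.random() < plant.donor_freq_target:
                        local = m[on_c]
                        allele[local] = sweep
                        anc[local] = True
                # per-feature local ancestry boosts
                for cat, delta in cfg.feature_alpha_boost.items():
                    local = boost_masks[cat][on_c]
                    if not local.any():
                        continue
                    hit = rng_plant.random(int(local.sum())) < delta
                    li = np.flatnonzero(local)[hit]
                    allele[li] = rng_plant.random(len(li)) < p_wl[on_c][li]
                    anc[li] = True
                haps[h, idx] = allele
                anc_sum[idx] += anc
        gt[:, col:col + cfg.n_diploids] = (haps[0::2] + haps[1::2]).T
        wl_frac[pop] = anc_sum / (2 * cfg.n_diploids)
        col += cfg.n_diploids

    vt = VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "T", dtype=object),
        qual=np.full(n, 100.0),
        samples=sample_names,
        gt=gt,
    )
    popmap = PopulationMap(
        dict(zip(sample_names, pop_of_sample)),
        roles={
            WL_SOURCE: "wl_source", WL_REFERENCE: "wl_reference",
            EL_SOURCE: "el_source", OUTGROUP: "outgroup",
            **{p: "admixed" for p in cfg.alphas},
        },
    )
    return vt, popmap, wl_frac


def plant_purging(
    cfg: SimConfig,
    vt: VariantTable,
    popmap: PopulationMap,
    freqs: dict,
    categories: np.ndarray,
    rng_impact: np.random.Generator,
    rng_purge: np.random.Generator,
):
    """Label coding sites with impact classes and thin donor-origin alleles.

    Every CDS site receives an impact class (LOW/MODERATE/HIGH).  For each
    impact class with a purging multiplier m < 1, alleles at WL-origin sites
    (true WL frequency >= 0.95, true EL frequency <= 0.05) are retained with
    probability m per allele copy in the designated purged populations.
    Returns ``(impacts, purged_sites)``; the genotype matrix of ``vt`` is
    modified in place.
    """
    coding = np.asarray(categories) == "CDS"
    classes = list(cfg.impact_fractions)
    probs = np.asarray([cfg.impact_fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    impact = np.full(len(categories), "", dtype=object)
    impact[coding] = rng_impact.choice(classes, size=int(coding.sum()), p=probs)

    impacts = pd.DataFrame({
        "chrom": vt.chrom[coding],
        "pos": vt.pos[coding],
        "effect": [_IMPACT_EFFECT[i] for i in impact[coding]],
        "impact": impact[coding],
    })

    wl_origin_true = (freqs[WL_SOURCE] >= 0.95) & (freqs[EL_SOURCE] <= 0.05)
    purged_rows = []
    sample_idx = {s: j for j, s in enumerate(vt.samples)}
    for klass, mult in cfg.purging_multipliers.items():
        if mult >= 1:
            continue
        sites = coding & (impact == klass) & wl_origin_true
        if not sites.any():
            continue
        for pop in cfg.purged_pops:
            cols = [sample_idx[s] for s in popmap.samples_of(pop)]
            block = vt.gt[np.ix_(sites, cols)]
            carried = block > 0
            thinned = rng_purge.binomial(np.where(carried, block, 0), mult)
            vt.gt[np.ix_(sites, cols)] = np.where(carried, thinned, block).astype(np.int8)
        for c_, p_ in zip(vt.chrom[sites], vt.pos[sites]):
            purged_rows.append((c_, int(p_), klass, mult))
    purged = pd.DataFrame(purged_rows, columns=["chrom", "pos", "impact", "multiplier"])
    return impacts, purged


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator for one configuration (fully seeded)."""
    root = np.random.default_rng(cfg.seed)
    rng_freq, rng_geno, rng_plant, rng_impact, rng_purge, rng_rec = root.spawn(6)

    chrom, pos, freqs, diagnostic = simulate_frequencies(cfg, rng_freq)
    track, genes = make_feature_track(cfg)
    categories = track.assign(chrom, pos - 1)
    vt, popmap, wl_frac = simulate_admixed(
        cfg, chrom, pos, freqs, rng_geno, rng_plant, categories
    )
    impacts, purged = plant_purging(
        cfg, vt, popmap, freqs, categories, rng_impact, rng_purge
    )
    rmap = make_recombination_map(cfg, rng_rec)
    truth = TruthTable(
        alpha_configured=dict(cfg.alphas),
        alpha_realized={p: float(np.mean(wl_frac[p])) for p in cfg.alphas},
        wl_frac=wl_frac,
        true_freqs=freqs,
        diagnostic=diagnostic,
        planted_ai=list(cfg.planted_ai),
        purged_sites=purged,
    )
    logger.info(
        "simulated %d sites x %d samples; realized alpha: %s",
        vt.n_sites, vt.n_samples,
        {p: round(a, 4) for p, a in truth.alpha_realized.items()},
    )
    return SimResult(cfg, vt, popmap, track, genes, categories, impacts, rmap, truth)


def write_outputs(sim: SimResult, outdir) -> dict:
    """Write the cohort VCF, popmap TSV, feature BED, recombination TSV,
    impact TSV and truth JSON; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "popmap": out / "popmap.tsv",
        "features": out / "features.bed",
        "recomb": out / "recombination.tsv",
        "impacts": out / "impacts.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(sim.vt, paths["vcf"])
    sim.popmap.write_tsv(paths["popmap"])
    sim.track.to_bed(paths["features"])
    sim.rmap.write_tsv(paths["recomb"])
    sim.impacts[["chrom", "pos", "effect"]].to_csv(paths["impacts"], sep="\t", index=False)
    sim.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
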