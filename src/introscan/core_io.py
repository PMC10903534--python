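"""Variant I/O, site filtering, allele frequencies and genomic-feature assignment.

Conventions used throughout the package:

* VCF positions are 1-based; every internal interval is 0-based half-open
  (BED convention).  Conversions happen only at I/O boundaries.
* Genotypes are stored as alternate-allele dosages in {0, 1, 2} with ``-1``
  for missing calls.
* Allele frequencies are alternate-allele frequencies relative to the
  reference genome (no ancestral polarization); the downstream fd / U / Q95
  formulations are polarization-consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("introscan")

MISSING = -1

#: the six genomic-feature categories, ordered by assignment precedence
#: (highest first); "intergenic" is a pure residual.
CATEGORIES = (
    "CDS",
    "CE_in_gene",
    "promoter",
    "intron",
    "CE_outside_gene",
    "intergenic",
)

ROLES = ("wl_source", "wl_reference", "el_source", "outgroup", "admixed")
_SINGLETON_ROLES = ("wl_source", "wl_reference", "el_source", "outgroup")
_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Biallelic-SNP genotype matrix for a sample cohort.

    Attributes
    ----------
    chrom, pos : arrays of per-site chromosome id and 1-based position.
    ref, alt : per-site single-base alleles.
    qual : per-site Phred-scaled site quality (NaN when absent).
    samples : sample ids, column order of ``gt``.
    gt : ``(n_sites, n_samples)`` int8 alternate-allele dosage, -1 missing.
    depth, gq : optional per-genotype depth / genotype-quality matrices.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    samples: list
    gt: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            samples=list(self.samples),
            gt=self.gt[mask],
            depth=None if self.depth is None else self.depth[mask],
            gq=None if self.gq is None else self.gq[mask],
            meta=dict(self.meta),
        )

    def validate(self) -> None:
        """Check the structural invariants (biallelic SNPs, sorted positions)."""
        if self.gt.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape mismatch")
        bad = ~np.isin(self.gt, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        for allele in (self.ref, self.alt):
            if not all(a in _BASES for a in allele):
                raise ValueError("alleles must be single bases (biallelic SNPs only)")

    def __eq__(self, other) -> bool:  # round-trip identity checks
        if not isinstance(other, VariantTable):
            return NotImplemented
        same = (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.allclose(self.qual, other.qual, equal_nan=True)
            and self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
        )
        for a, b in ((self.depth, other.depth), (self.gq, other.gq)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return bool(same)


@dataclass
class PopulationMap:
    """sample -> population assignment plus analysis roles per population.

    Exactly one population may carry each of the roles ``wl_source``,
    ``wl_reference``, ``el_source`` and ``outgroup``; any number may be
    ``admixed``.
    """

    sample_to_pop: dict
    roles: dict = field(default_factory=dict)

    def __post_init__(self):
        for role in _SINGLETON_ROLES:
            pops = [p for p, r in self.roles.items() if r == role]
            if len(pops) > 1:
                raise ValueError(f"role {role!r} assigned to multiple populations: {pops}")
        unknown = {r for r in self.roles.values()} - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")

    @property
    def populations(self) -> list:
        seen = dict.fromkeys(self.sample_to_pop.values())
        return list(seen)

    def samples_of(self, pop: str) -> list:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def pop_with_role(self, role: str) -> str:
        pops = [p for p, r in self.roles.items() if r == role]
        if not pops:
            raise KeyError(f"no population with role {role!r}")
        return pops[0]

    def admixed_pops(self) -> list:
        return [p for p, r in self.roles.items() if r == "admixed"]

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        """Read a ``sample<TAB>population[<TAB>role]`` map."""
        s2p, roles = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed population-map line: {line!r}")
                sample, pop = parts[0], parts[1]
                if sample in s2p:
                    raise ValueError(f"sample {sample!r} listed twice")
                s2p[sample] = pop
                if len(parts) >= 3 and parts[2]:
                    roles[pop] = parts[2]
        return cls(s2p, roles)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.sample_to_pop.items():
                role = self.roles.get(pop, "")
                fh.write(f"{sample}\t{pop}\t{role}\n")


@dataclass
class FrequencyTable:
    """Per-site, per-population alternate-allele frequencies.

    ``freq`` is NaN where no chromosomes were called (n == 0); ``n`` is the
    number of called chromosomes and ``miss`` the fraction of missing diploid
    genotypes in the panel.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pops: list
    freq: np.ndarray  # (n_sites, n_pops) float
    n: np.ndarray  # (n_sites, n_pops) int
    miss: np.ndarray  # (n_sites, n_pops) float

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def _col(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None

    def freq_of(self, pop: str) -> np.ndarray:
        return self.freq[:, self._col(pop)]

    def n_of(self, pop: str) -> np.ndarray:
        return self.n[:, self._col(pop)]

    def miss_of(self, pop: str) -> np.ndarray:
        return self.miss[:, self._col(pop)]

    def subset(self, mask: np.ndarray) -> "FrequencyTable":
        return FrequencyTable(
            self.chrom[mask], self.pos[mask], list(self.pops),
            self.freq[mask], self.n[mask], self.miss[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for j, pop in enumerate(self.pops):
            df[f"freq_{pop}"] = self.freq[:, j]
            df[f"n_{pop}"] = self.n[:, j]
        return df


class FeatureTrack:
    """Genomic-feature annotation supporting precedence-based assignment.

    Intervals are 0-based half-open and are merged per category on
    construction; positions are assigned exactly one of the six categories
    via the precedence CDS > CE_in_gene > promoter > intron >
    CE_outside_gene > intergenic.
    """

    def __init__(self, intervals: pd.DataFrame, contig_lengths: dict | None = None):
        req = {"chrom", "start", "end", "category"}
        if not req.issubset(intervals.columns):
            raise ValueError(f"feature intervals need columns {sorted(req)}")
        bad = set(intervals["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")
        self.intervals = intervals.reset_index(drop=True)
        self.contig_lengths = contig_lengths
        # per (chrom, category): merged sorted (starts, ends)
        self._idx: dict = {}
        for (chrom, cat), grp in intervals.groupby(["chrom", "category"], sort=False):
            starts, ends = _merge_sorted(
                np.asarray(grp["start"], dtype=np.int64),
                np.asarray(grp["end"], dtype=np.int64),
            )
            self._idx[(chrom, cat)] = (starts, ends)

    def _member(self, chrom: str, cat: str, pos0: np.ndarray) -> np.ndarray:
        key = (chrom, cat)
        if key not in self._idx:
            return np.zeros(len(pos0), dtype=bool)
        starts, ends = self._idx[key]
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = i >= 0
        ok[ok] = pos0[ok] < ends[i[ok]]
        return ok

    def assign(self, chroms: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Assign one category per 0-based position (vectorized)."""
        chroms = np.asarray(chroms)
        pos0 = np.asarray(pos0, dtype=np.int64)
        if self.contig_lengths is not None:
            for c in np.unique(chroms):
                L = self.contig_lengths.get(str(c))
                if L is not None and np.any(pos0[chroms == c] >= L):
                    raise ValueError(f"position beyond contig length on {c}")
        out = np.full(len(pos0), "intergenic", dtype=object)
        # low-to-high precedence so later (higher) categories overwrite
        for cat in reversed(CATEGORIES[:-1]):
            for c in np.unique(chroms):
                sel = chroms == c
                hit = self._member(str(c), cat, pos0[sel])
                idx = np.flatnonzero(sel)[hit]
                out[idx] = cat
        return out

    @classmethod
    def from_bed(cls, path, contig_lengths: dict | None = None) -> "FeatureTrack":
        """Read features from BED with the category in the name column."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])
        return cls(df, contig_lengths)

    def to_bed(self, path) -> None:
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        with open(path, "w") as fh:
            for r in df.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.category}\t0\t.\n")


def _merge_sorted(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-overlapping intervals; returns sorted disjoint arrays."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


@dataclass
class RecombinationMap:
    """Windowed recombination rates in cM/Mb (0-based half-open windows)."""

    table: pd.DataFrame  # chrom, start, end, rate

    def __post_init__(self):
        t = self.table
        if (t["rate"] < 0).any():
            raise ValueError("negative recombination rates")
        for c, grp in t.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping recombination windows on {c}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "RecombinationMap":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "rate"],
            dtype={"chrom": str},
        )
        return cls(df)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path, samples: list | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF into a :class:`VariantTable`.

    Multiallelic records and indels are dropped; their counts are recorded in
    ``table.meta``.  ``samples`` optionally restricts (and orders) the cohort.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True, samples=samples)
    if samples is not None:
        missing = set(samples) - set(vcf.samples)
        if missing:
            raise KeyError(f"samples not in VCF header: {sorted(missing)}")
    kept_samples = list(vcf.samples)

    chrom, pos, ref, alt, qual = [], [], [], [], []
    gts, depths, gqs = [], [], []
    n_multi = n_indel = 0
    has_dp = has_gq = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in _BASES or v.REF not in _BASES:
            n_indel += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(np.nan if v.QUAL is None else v.QUAL)
        g = v.gt_types.astype(np.int8)  # gts012: 0,1,2 dosage; 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        try:
            d = v.format("DP")
        except KeyError:
            d = None
        if d is not None:
            has_dp = True
            d = d.reshape(-1)
        depths.append(d)
        try:
            q = v.format("GQ")
        except KeyError:
            q = None
        if q is not None:
            has_gq = True
            q = q.reshape(-1)
        gqs.append(q)

    n = len(pos)
    table = VariantTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        samples=kept_samples,
        gt=np.vstack(gts).astype(np.int8) if n else np.empty((0, len(kept_samples)), np.int8),
        depth=np.vstack(depths).astype(np.int32) if (n and has_dp) else None,
        gq=np.vstack(gqs).astype(np.float32) if (n and has_gq) else None,
        meta={"n_multiallelic_dropped": n_multi, "n_non_snp_dropped": n_indel},
    )
    logger.info(
        "read %d biallelic SNPs from %s (dropped %d multiallelic, %d non-SNP)",
        n, path, n_multi, n_indel,
    )
    return table


def write_vcf(vt: VariantTable, path) -> None:
    """Write a :class:`VariantTable` as plain-text VCF 4.2 (GT[:DP:GQ])."""
    fmt_keys = ["GT"]
    if vt.depth is not None:
        fmt_keys.append("DP")
    if vt.gq is not None:
        fmt_keys.append("GQ")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if vt.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if vt.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in dict.fromkeys(vt.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            q = "." if np.isnan(vt.qual[i]) else f"{vt.qual[i]:g}"
            cols = [
                str(vt.chrom[i]), str(vt.pos[i]), ".", vt.ref[i], vt.alt[i],
                q, "PASS", ".", ":".join(fmt_keys),
            ]
            for j in range(vt.n_samples):
                parts = [gt_str[int(vt.gt[i, j])]]
                if vt.depth is not None:
                    parts.append(str(int(vt.depth[i, j])))
                if vt.gq is not None:
                    parts.append(str(int(vt.gq[i, j])))
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------


def apply_site_filters(
    vt: VariantTable,
    min_cov: float = 5,
    max_cov: float = 25,
    min_gq: float = 20,
    min_qual: float = 30,
    max_missing: float = 0.75,
):
    """Apply the standard hard site filters; returns ``(table, report)``.

    Genotypes with GQ below ``min_gq`` are set to missing first; a site is
    then removed when its mean depth falls outside ``[min_cov, max_cov]``,
    its QUAL is below ``min_qual``, or its missing-genotype fraction strictly
    exceeds ``max_missing``.
    """
    for t in (min_cov, min_gq, min_qual, max_missing):
        if t < 0:
            raise ValueError("thresholds must be non-negative")
    gt = vt.gt.copy()
    n_gq_masked = 0
    if vt.gq is not None and min_gq > 0:
        low = (vt.gq < min_gq) & (gt != MISSING)
        n_gq_masked = int(low.sum())
        gt[low] = MISSING

    n_sites = vt.n_sites
    keep = np.ones(n_sites, dtype=bool)
    report = {"input_sites": n_sites, "genotypes_masked_low_gq": n_gq_masked}

    if vt.depth is not None:
        mean_dp = np.nanmean(np.where(vt.depth < 0, np.nan, vt.depth), axis=1)
        low_cov = mean_dp < min_cov
        high_cov = mean_dp > max_cov
    else:
        low_cov = high_cov = np.zeros(n_sites, dtype=bool)
    low_qual = np.where(np.isnan(vt.qual), False, vt.qual < min_qual)
    missing_frac = (gt == MISSING).mean(axis=1) if vt.n_samples else np.zeros(n_sites)
    too_missing = missing_frac > max_missing

    report["removed_low_coverage"] = int((keep & low_cov).sum())
    keep &= ~low_cov
    report["removed_high_coverage"] = int((keep & high_cov).sum())
    keep &= ~high_cov
    report["removed_low_qual"] = int((keep & low_qual).sum())
    keep &= ~low_qual
    report["removed_missingness"] = int((keep & too_missing).sum())
    keep &= ~too_missing
    report["surviving_sites"] = int(keep.sum())

    out = vt.subset_sites(keep)
    out.gt = gt[keep]
    logger.info("site filters: %s", report)
    return out, report


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    vt: VariantTable, pm: PopulationMap, pops: list | None = None
) -> FrequencyTable:
    """Per-population alternate-allele frequencies with call counts.

    freq = sum(dosage) / (2 * called diploids); NaN where no calls.
    """
    if pops is None:
        pops = [p for p in pm.populations]
    sample_idx = {s: j for j, s in enumerate(vt.samples)}
    n_sites = vt.n_sites
    freq = np.full((n_sites, len(pops)), np.nan)
    n = np.zeros((n_sites, len(pops)), dtype=np.int32)
    miss = np.zeros((n_sites, len(pops)))
    for k, pop in enumerate(pops):
        cols = [sample_idx[s] for s in pm.samples_of(pop) if s in sample_idx]
        if not cols:
            logger.warning("population %r has no samples in the variant table", pop)
            miss[:, k] = 1.0
            continue
        g = vt.gt[:, cols]
        called = g != MISSING
        n_called = called.sum(axis=1)
        dosage = np.where(called, g, 0).sum(axis=1)
        n[:, k] = 2 * n_called
        miss[:, k] = 1.0 - n_called / len(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, k] = np.where(n_called > 0, dosage / (2.0 * n_called), np.nan)
    return FrequencyTable(vt.chrom.copy(), vt.pos.copy(), list(pops), freq, n, miss)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def derive_promoters(
    genes: pd.DataFrame, length: int = 1000, contig_lengths: dict | None = None
) -> pd.DataFrame:
    """Promoters as ``length``-bp stretches upstream of the gene start.

    ``genes`` needs columns chrom/start/end/strand (0-based half-open).
    Promoters are truncated at contig boundaries.
    """
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            s, e = g.start - length, g.start
        elif g.strand == "-":
            s, e = g.end, g.end + length
        else:
            raise ValueError(f"unknown strand {g.strand!r} for gene at {g.chrom}:{g.start}")
        s = max(s, 0)
        if contig_lengths is not None and str(g.chrom) in contig_lengths:
            e = min(e, contig_lengths[str(g.chrom)])
        if e > s:
            rows.append((g.chrom, s, e, "promoter"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def assign_feature(chrom: str, pos0: int, track: FeatureTrack) -> str:
    """Category of a single 0-based position (convenience wrapper)."""
    return track.assign(np.asarray([chrom], dtype=object), np.asarray([pos0]))[0]


# ---------------------------------------------------------------------------
# Window grids
# ---------------------------------------------------------------------------


def window_grid(length: int, window: int, step: int | None = None) -> pd.DataFrame:
    """Sliding-window grid anchored at 0: full windows plus one flagged
    partial tail window when the contig is not covered exactly."""
    if step is None:
        step = window
    starts, partial = [], []
    s = 0
    while s + window <= length:
        starts.append(s)
        partial.append(False)
        s += step
    covered = (starts[-1] + window) if starts else 0
    if covered < length:
        starts.append(s)
        partial.append(True)
    ends = [min(s + window, length) for s in starts]
    return pd.DataFrame({"start": starts, "end": ends, "partial": partial})


def contig_windows(
    chroms: np.ndarray,
    pos: np.ndarray,
    window: int,
    step: int | None = None,
    contig_lengths: dict | None = None,
) -> pd.DataFrame:
    """Window grid across contigs.  Contig lengths default to the largest
    observed 1-based position per contig."""
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    out = []
    for c in dict.fromkeys(chroms):
        if contig_lengths is not None and str(c) in contig_lengths:
            L = int(contig_lengths[str(c)])
        else:
            L = int(pos[chroms == c].max())
        grid = window_grid(L, window, step)
        grid.insert(0, "chrom", c)
        out.append(grid)
    return pd.concat(out, ignore_index=True)
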