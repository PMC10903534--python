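# Methods

This note documents the statistical procedures implemented in `introscan`,
the model behind the synthetic-data generator, the defaults that matter,
and the design choices made where the underlying methodology leaves room.

## Setting

Two diverged lineages (donor WL, recipient EL) met in a secondary-contact
zone; admixed populations carry a gradient of donor ancestry.  Analyses
are run on a cohort VCF of biallelic SNPs with four designated panels —
donor source (WL), donor reference (a WL population ancestral to the
source), recipient source (EL) and an outgroup — plus any number of
admixed test populations.  All frequencies are alternate-allele
frequencies relative to the reference genome; no ancestral polarization is
applied (the fd, U and Q95 formulations used here are consistent under
that convention).  An optional derived-allele mode would only require
re-polarizing the frequency table and is deliberately not entangled with
the statistics.

## Site filters

Standard hard filters, applied in this order: genotypes with GQ < 20 are
set to missing (per-genotype, matching VCFtools semantics); then sites are
removed if mean depth < 5x or > 25x, QUAL < 30, or missing-genotype
fraction strictly greater than 0.75 (a site at exactly 0.75 survives — the
rule is a strict inequality).  All thresholds are parameters.

## Ancestry: f4 and the f4-ratio

`f4(A,B;C,D)` is the mean over sites of `(pA − pB)(pC − pD)`.  The donor
ancestry proportion of a test population is

```
alpha = f4(Ref, Out; Test, EL) / f4(Ref, Out; WL, EL)
```

computed as a ratio of genome-wide sums (not a mean of per-block ratios),
which is robust to site-density variation across blocks.  Uncertainty
comes from a weighted delete-one block jackknife (Busing et al. 1999) over
contiguous 5 Mb blocks, with block site counts as weights.  The block size
is a convention, exposed as a parameter; on the synthetic 2 Mb contigs
each contig forms one block, giving 20 jackknife blocks.

Feature-stratified ancestry re-runs the estimator on each feature
category's site subset.  Categories are assigned by precedence
CDS > CE-in-gene > promoter > intron > CE-outside-gene > intergenic, so
"intergenic" is a pure residual background.  Promoters are the 1 kb
upstream of the gene start (strand-aware, truncated at contig ends).
Significance against the intergenic background uses an empirical
resampling test: both alphas are re-drawn 10,000 times from
`N(alpha, SE_jackknife)` and the two-sided empirical P is
`2 * min(#[a_f > a_i], #[a_f < a_i]) / n`, floored at `1/n`.  Both sides
are resampled (a fixed-background and a one-sided mode exist as flags)
because features can be significantly enriched *or* depleted relative to
intergenic levels.

## Introgression scanning: fd

Per site, `ABBA = (1−p1) p2 p3 (1−p4)` and `BABA = p1 (1−p2) p3 (1−p4)`
with P1 = recipient-side reference, P2 = focal admixed, P3 = donor,
P4 = outgroup.  Windows (100 kb, 20 kb step, grid anchored at 0 with the
final partial window flagged) accumulate

```
D  = sum(ABBA − BABA) / sum(ABBA + BABA)
fd = sum(ABBA − BABA) / sum(ABBA_D − BABA_D)
```

where the denominator replaces both P2 and P3 by the site-wise donor
`p_D = max(p2, p3)`.  fd is reported as undefined for windows with D < 0
or fd < 0 rather than clamped.  A window is *eligible* for outlier calling
when D > 0, fd is defined and positive, and it has at least 100
informative sites (`ABBA + BABA > 0`).

Outlier calling Z-standardizes window values, converts to one-sided
upper-tail normal P-values, applies Benjamini–Hochberg and flags windows
with q ≤ 0.05.  One deliberate choice: the standardization uses the raw,
untruncated window ratio over **all** windows passing the site floor, not
just the eligible (positive) ones.  Under a no-introgression null the raw
ratio is approximately symmetric around 0 and the eligible subset is its
positive truncation; estimating the spread from that half systematically
understates it and makes the scan anti-conservative (in null simulations
the truncated version calls a handful of spurious windows per genome; the
symmetric version calls a median of zero).  Eligibility still gates which
windows can be *called* outliers.

Note on range: fd is only a well-behaved proportion at window scale.  For
adversarial single-site frequency configurations the dynamic-donor
denominator can be arbitrarily small and fd can exceed 1 even when D > 0;
on windowed admixture data the retained values stay within [0, 1] up to
sampling noise, and the test suite asserts exactly that.

## Adaptive introgression: U and Q95

`U(w, x, y)` counts sites with reference-panel frequency < w, focal
frequency ≥ x and donor frequency ≥ y; defaults (0.01, 0.20, 1.0) mean
"absent from EL, at ≥ 20% in the focal panel, fixed in WL".  The donor
condition is evaluated on non-missing calls, so missing genotypes cannot
disqualify a truly fixed site.  `Q95` is the 95% quantile (type-7 linear
interpolation, the common default; exposed as a flag) of the focal
frequency over sites passing the reference and donor conditions.  Sites
with more than 25% missing data in any of the three panels are discarded
first.  Scans use the same 100 kb / 20 kb grid.

Top-1% windows of each statistic are taken genome-wide against the
empirical quantile of defined values, with all threshold ties included
(deterministic).  Candidate adaptive-introgression regions are windows in
the U-top ∩ Q95-top set whose span overlaps (≥ 1 bp) at least one
fd-outlier window; overlapping or book-ended candidates merge into maximal
intervals carrying their provenance.  Per region, a fine-scale evidence
bundle is computed: 10 kb / 5 kb FST and dxy of the focal panel against
both parents, focal pi, and a per-site frequency matrix filtered at pooled
minor-allele frequency ≥ 0.05 — a selective sweep on introgressed
haplotypes shows lowered FST to the donor, raised FST to the recipient and
depressed focal diversity at the sweep center.

## Windowed population genetics

Per-site heterozygosity uses the unbiased form `n/(n−1) · 2p(1−p)` (n =
called chromosomes).  Windowed pi and dxy are means over analyzed variant
sites ("per variant site"); absolute per-bp values would need the callable
site count per window, which is an optional input, and the rank
correlations these tracks feed are invariant to that constant scale.  FST
is the Hudson-type ratio of averages `1 − mean(Hw)/mean(Hb)` with `Hw` the
mean of the two within-population heterozygosities and `Hb` the per-site
dxy; the raw value is stored unclamped and the identity between the three
emitted components is exact by construction.  Recombination maps are
binned to 100 kb windows by length-weighted averaging; bins without map
coverage are missing, not zero.  Correlations between any two window
tracks are Spearman rank correlations (average ranks on ties, asymptotic
P), joined on the window key, using eligible windows by default.

## Introgressed load: r_xy

Variants are WL-origin when the EL reference frequency is ≤ 0.05 **and**
the WL reference frequency is ≥ 0.95 (bounds inclusive).  Coding impact
comes from SnpEff-style annotations: synonymous → LOW, missense →
MODERATE, stop-gained → HIGH; multi-annotation sites take the
maximum-severity class; other coding terms are excluded and counted.

For a category site set and an equally sized neutral set,

```
L_x¬y = Σ f_x (1 − f_y)      L_y¬x = Σ f_y (1 − f_x)
r_xy  = [L_x¬y / L_y¬x]_category / [L_x¬y / L_y¬x]_neutral
```

`r_xy = 1` when the category's frequency changes track the neutral
background; `r_xy < 1` indicates a deficit of the focal alleles in
population x.  When profiling pairs along the contact-zone gradient the
population **farther** from the introgression entry is placed at x, so
more efficient purging away from the entry reads as r_xy < 1, matching the
conventional presentation.  The neutral set is a seeded random draw of
intergenic variants of the same size; for WL-origin cells the draw is
restricted to WL-origin intergenic variants, because the neutral proxy
must share the category's ancestry composition — with an unmatched draw
the ancestry-proportion difference between the two populations, not
selection, would push every WL-origin cell away from 1.  SEs come from the
delete-one jackknife across linkage groups (the 20 chromosomes), and the
95% CI is the normal approximation ± 1.96 SE.  Any zero L sum raises an
error naming the offending sum.

## The synthetic-data generator

The generator produces, from a single integer seed, a byte-reproducible
cohort with known truth.  Defaults: 20 linkage groups of 2 Mb, 50,000
SNPs, 20 diploids per population, lineage drift F_split = 0.2,
within-lineage drift F_pop = 0.05, outgroup drift F_out = 0.4, admixed
populations GER-RUE (alpha 0.35), POL-GDY (0.22) and BS7 (0.12) mirroring
the north–south ancestry gradient of a post-glacial contact zone.

*Frequencies.*  Ancestral `p0 ~ U(0.05, 0.95)`; lineage and population
frequencies follow the Balding–Nichols model
`Beta(p(1−F)/F, (1−p)(1−F)/F)` applied hierarchically (lineages from p0,
populations from their lineage, outgroup from p0 with F_out).  A fraction
`diag_frac = 0.08` of sites are fixed lineage differences (one lineage
carries the alternate allele at frequency 1, the other at 0, orientation
random).  Deeply diverged lineages carry many such diagnostic sites, and
the donor-fixed/reference-absent conditioning set of the U/Q95 statistics
is built from exactly these; a pure Balding–Nichols marginal at F = 0.2
produces essentially none (~1 per 10 Mb), which would be a desk-scale
artifact rather than a property of real secondary-contact data.

*Admixture.*  Each admixed haplotype is a mosaic of ancestry blocks with
exponentially distributed lengths (mean 25 kb), each donor-derived with
probability alpha; alleles are Bernoulli draws from the block's parental
population frequency.  The 25 kb default is the recombination-clock
expectation `1/(r·t)` for a contact ~4,000 generations old at ~1 cM/Mb —
block length matters, because tracts approaching the 100 kb scan-window
scale make whole windows' focal frequencies fluctuate together and
degrade the contrast of the window statistics in ways real kb-scale
tracts do not.  Realized per-site donor-ancestry fractions are recorded as
truth; parameter-recovery tests compare estimates to realized (not
configured) ancestry, removing block-sampling noise from the comparison.

*Planted signals.*  An adaptive-introgression sweep plants one shared
donor haplotype (drawn from the donor frequencies) into a target window,
carried by each focal haplotype with probability `donor_freq_target`
(default 0.9).  Purging thins alternate-allele copies at WL-origin coding
sites of a chosen impact class in designated populations, retaining each
copy with the class's multiplier.  Feature-localized ancestry boosts
(e.g. elevated donor ancestry in promoters) re-draw site alleles from the
donor with a per-category probability.  Planting, purging and the main
genotype stream use independently spawned RNG streams, so a configuration
with a zero-effect plant is bit-identical to one without it.

*Annotation sidecars.*  A deterministic feature layout (one 20 kb gene per
100 kb with six 1 kb exons, two intronic constrained elements, one
intergenic constrained element; 6% CDS overall — a compact, gene-dense
genome) plus derived promoters; a gamma-distributed recombination map
(mean 3 cM/Mb, 100 kb windows); SnpEff-style effect terms for every CDS
site with class fractions LOW 0.5 / MODERATE 0.3 / HIGH 0.2.  The HIGH
share is far above a real exome's; it is chosen so that every impact ×
origin cell of the r_xy grid contains enough sites to be estimable at the
50,000-SNP desk scale.

*What the generator does not emulate.*  Linkage disequilibrium beyond
block structure, invariant sites, genotyping error and missingness
patterns, realistic Baltic Sea demography, selection acting through time,
and sex-chromosome complications.  Passing tests therefore demonstrate
estimator correctness and pipeline wiring under the stated model, not
robustness to every property of real resequencing data.

## Problem sizes used in the checks

The test suite validates parameter recovery on 50,000-SNP genomes (20
seeds, true alpha 0.10 and 0.35, coverage within 3 jackknife SE), and the
scan stages on 150,000-SNP genomes — about 375 SNPs per 100 kb window, so
windows comfortably clear the 100-informative-site eligibility floor
(real cohorts of this kind run ~1,000 SNPs per 100 kb; at the generator's
50k default almost no window is eligible and the outlier machinery never
engages).  The r_xy null check uses 10,000 category plus 10,000 neutral
sites over 20 linkage groups.  Brute-force oracle equivalence (fd, pi,
dxy, FST, U, Q95 against independent per-site loops) runs on a 1,000-site
fixture at 1e-12 tolerance.

## Numerical notes and edge cases

* Window grids are anchored at 0 per contig; the final partial window is
  emitted and flagged, never silently dropped.
* Zero fd-scan variance (all windows identical) is an error, not a NaN.
* Degenerate top-percentile inputs (all values equal) return all defined
  windows with a warning rather than an arbitrary subset.
* Frequencies with zero called chromosomes are NaN and excluded sitewise
  from every statistic; the per-population missing fraction drives the
  U/Q95 25% missing-data filter.
* Empirical P-values are floored at 1/n; Monte-Carlo tests in the suite
  compare against closed-form normal-difference tails within binomial
  error.
* The jackknife returns the full-data ratio as the point estimate (the
  bias-corrected jackknife mean is computed internally but not reported),
  matching common practice for ratio estimators.
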