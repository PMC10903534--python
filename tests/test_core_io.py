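"""Variant I/O, site filters, allele frequencies, feature assignment."""

import numpy as np
import pandas as pd
import pytest

from introscan import (
    FeatureTrack,
    PopulationMap,
    allele_frequencies,
    apply_site_filters,
    assign_feature,
    derive_promoters,
    read_vcf,
    window_grid,
    write_vcf,
)
from introscan.core_io import CATEGORIES

from conftest import make_variant_table

VCF_MIXED = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=LG01>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1
LG01\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\t./.
LG01\t200\t.\tA\tAT\t50\tPASS\t.\tGT\t0/1\t0/0
LG01\t300\t.\tG\tA,C\t50\tPASS\t.\tGT\t1/2\t0/0
"""


class TestVcfIO:
    def test_only_biallelic_snps_retained(self, tmp_path):
        p = tmp_path / "mixed.vcf"
        p.write_text(VCF_MIXED)
        vt = read_vcf(p)
        assert vt.n_sites == 1
        assert vt.pos[0] == 100
        assert vt.meta["n_multiallelic_dropped"] == 1
        assert vt.meta["n_non_snp_dropped"] == 1

    def test_missing_genotype_becomes_missing_dosage(self, tmp_path):
        p = tmp_path / "mixed.vcf"
        p.write_text(VCF_MIXED)
        vt = read_vcf(p)
        assert vt.gt[0, 0] == 1
        assert vt.gt[0, 1] == -1

    def test_unknown_sample_raises(self, tmp_path):
        p = tmp_path / "mixed.vcf"
        p.write_text(VCF_MIXED)
        with pytest.raises(KeyError):
            read_vcf(p, samples=["nope"])

    def test_round_trip_identity(self, tmp_path):
        vt = make_variant_table(
            ["LG01", "LG01", "LG02"], [10, 25, 7],
            [[0, 1, 2], [2, -1, 0], [1, 1, 1]],
            qual=[30, 45, 60],
            depth=[[10, 12, 9], [8, 11, 20], [15, 5, 7]],
            gq=[[99, 30, 25], [40, 99, 21], [60, 50, 80]],
        )
        p = tmp_path / "rt.vcf"
        write_vcf(vt, p)
        back = read_vcf(p)
        back.meta = vt.meta
        assert back == vt


class TestSiteFilters:
    def _table(self):
        # 6 sites: clean, low-cov, high-cov, low-qual, too-missing, gq-driven
        n_samp = 4
        gt = np.zeros((6, n_samp), dtype=np.int8)
        gt[4, :3] = -1  # 3/4 missing = 0.75 -> retained (strict >)
        depth = np.full((6, n_samp), 10, dtype=np.int32)
        depth[1] = 2      # mean depth < 5
        depth[2] = 40     # mean depth > 25
        qual = np.full(6, 50.0)
        qual[3] = 10.0    # QUAL < 30
        gq = np.full((6, n_samp), 99.0, dtype=np.float32)
        gq[5, :4] = 5.0   # all genotypes masked -> missingness 1 > 0.75
        return make_variant_table(
            ["LG01"] * 6, [10, 20, 30, 40, 50, 60], gt,
            qual=qual, depth=depth, gq=gq,
        )

    def test_each_rule_removes_its_site(self):
        out, report = apply_site_filters(self._table())
        # site 5 (pos 50) has missingness exactly 0.75 and must survive
        assert list(out.pos) == [10, 50]
        assert report["removed_low_coverage"] == 1
        assert report["removed_high_coverage"] == 1
        assert report["removed_low_qual"] == 1
        assert report["removed_missingness"] == 1

    def test_report_counts_sum_to_input(self):
        _, r = apply_site_filters(self._table())
        removed = sum(v for k, v in r.items() if k.startswith("removed_"))
        assert removed + r["surviving_sites"] == r["input_sites"]

    def test_disabled_thresholds_identity(self):
        vt = self._table()
        out, _ = apply_site_filters(vt, 0, np.inf, 0, 0, 1.0)
        assert out == vt

    def test_missingness_exactly_at_threshold_retained(self):
        gt = np.array([[-1, -1, -1, 0]], dtype=np.int8)  # exactly 0.75
        vt = make_variant_table(["LG01"], [1], gt)
        out, _ = apply_site_filters(vt)
        assert out.n_sites == 1

    def test_low_gq_genotypes_masked_before_missingness(self):
        gt = np.array([[1, 1, 1, 0]], dtype=np.int8)
        gq = np.array([[5, 5, 5, 99]], dtype=np.float32)
        vt = make_variant_table(["LG01"], [1], gt, gq=gq)
        out, report = apply_site_filters(vt)
        assert report["genotypes_masked_low_gq"] == 3
        assert out.n_sites == 1  # 0.75 missing, not > 0.75
        assert list(out.gt[0]) == [-1, -1, -1, 0]


class TestAlleleFrequencies:
    def _pm(self):
        return PopulationMap({"s0": "P", "s1": "P", "s2": "P"})

    @pytest.mark.parametrize(
        "gts, freq, n",
        [
            ([[0, 1, 2]], 0.5, 6),
            ([[-1, -1, -1]], np.nan, 0),
            ([[2, 2, -1]], 1.0, 4),
        ],
    )
    def test_basic_arithmetic(self, gts, freq, n):
        vt = make_variant_table(["LG01"], [1], gts)
        ft = allele_frequencies(vt, self._pm())
        got = ft.freq_of("P")[0]
        assert ft.n_of("P")[0] == n
        if np.isnan(freq):
            assert np.isnan(got)
        else:
            assert got == freq

    def test_complement_symmetry(self):
        """f(alt) = 1 - f(ref) at every site with calls."""
        rng = np.random.default_rng(0)
        gt = rng.integers(-1, 3, size=(50, 6)).astype(np.int8)
        vt = make_variant_table(["LG01"] * 50, np.arange(1, 51), gt)
        pm = PopulationMap({f"s{j}": "P" for j in range(6)})
        f_alt = allele_frequencies(vt, pm).freq_of("P")
        flipped = gt.copy()
        called = flipped != -1
        flipped[called] = 2 - flipped[called]
        vt2 = make_variant_table(["LG01"] * 50, np.arange(1, 51), flipped)
        f_ref = allele_frequencies(vt2, pm).freq_of("P")
        ok = ~np.isnan(f_alt)
        assert np.allclose(f_alt[ok], 1 - f_ref[ok])


class TestFeatures:
    def test_promoters_by_strand_and_truncation(self):
        genes = pd.DataFrame(
            {"chrom": ["c", "c", "c"], "start": [5000, 5000, 400],
             "end": [8000, 8000, 900], "strand": ["+", "-", "+"]}
        )
        prom = derive_promoters(genes, 1000)
        assert list(prom.itertuples(index=False, name=None)) == [
            ("c", 4000, 5000, "promoter"),
            ("c", 8000, 9000, "promoter"),
            ("c", 0, 400, "promoter"),
        ]

    def test_unknown_strand_raises(self):
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [10], "end": [20], "strand": ["?"]}
        )
        with pytest.raises(ValueError):
            derive_promoters(genes)

    def _track(self):
        iv = pd.DataFrame(
            [
                ("c", 100, 200, "CDS"),
                ("c", 150, 400, "CE_in_gene"),   # overlaps the CDS
                ("c", 300, 500, "intron"),
                ("c", 450, 600, "promoter"),     # promoter overlapping an intron
                ("c", 800, 900, "CE_outside_gene"),
            ],
            columns=["chrom", "start", "end", "category"],
        )
        return FeatureTrack(iv)

    @pytest.mark.parametrize(
        "pos0, want",
        [
            (150, "CDS"),          # CDS beats the constrained element
            (250, "CE_in_gene"),
            (350, "CE_in_gene"),
            (460, "promoter"),     # promoter beats intron
            (420, "intron"),
            (850, "CE_outside_gene"),
            (700, "intergenic"),   # residual
        ],
    )
    def test_precedence(self, pos0, want):
        assert assign_feature("c", pos0, self._track()) == want

    def test_assignment_partitions_positions(self):
        track = self._track()
        pos = np.arange(0, 1000)
        cats = track.assign(np.full(1000, "c", dtype=object), pos)
        counts = pd.Series(cats).value_counts()
        assert counts.sum() == 1000
        assert set(counts.index) <= set(CATEGORIES)

    def test_bed_round_trip(self, tmp_path):
        track = self._track()
        p = tmp_path / "features.bed"
        track.to_bed(p)
        back = FeatureTrack.from_bed(p)
        pos = np.arange(0, 1000)
        chroms = np.full(1000, "c", dtype=object)
        assert np.array_equal(track.assign(chroms, pos), back.assign(chroms, pos))


class TestWindowGrid:
    def test_exact_cover_500kb(self):
        g = window_grid(500_000, 100_000, 20_000)
        assert len(g) == 21
        assert list(g["start"]) == list(range(0, 400_001, 20_000))
        assert not g["partial"].any()

    def test_partial_tail_flagged(self):
        g = window_grid(510_000, 100_000, 20_000)
        assert g.iloc[-1]["partial"]
        assert g.iloc[-1]["end"] == 510_000
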