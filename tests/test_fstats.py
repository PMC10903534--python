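"""D/fd statistics, f4 and f4-ratio estimation, jackknife machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan import (
    SimConfig,
    allele_frequencies,
    bh_qvalues,
    f4,
    f4_ratio,
    fd_window,
    scan_fd,
    simulate,
    site_patterns,
    weighted_block_jackknife,
    z_fdr_outliers,
)

from conftest import make_freq_table

freqs = st.floats(0.0, 1.0)


class TestSitePatterns:
    def test_hand_values(self):
        assert site_patterns(0, 0.5, 0.5, 0) == (0.25, 0.0)
        abba, baba = site_patterns(0.1, 0.6, 0.8, 0.0)
        assert abba == pytest.approx(0.432, abs=1e-15)
        assert baba == pytest.approx(0.032, abs=1e-15)

    @given(freqs)
    def test_equal_frequencies_give_zero_d_contribution(self, p):
        abba, baba = site_patterns(p, p, p, p)
        assert abba == pytest.approx(baba, abs=1e-12)


class TestFdWindow:
    def test_single_site_hand_value(self):
        res = fd_window([0.1], [0.6], [0.8], [0.0])
        assert res["fd"] == pytest.approx(0.4 / 0.56, abs=1e-12)
        assert res["n_informative"] == 1

    def test_complete_introgression_limit(self):
        # P2 == P3 > P1 with outgroup fixed ancestral: fd = 1
        res = fd_window([0.1, 0.2], [0.9, 0.8], [0.9, 0.8], [0.0, 0.0])
        assert res["fd"] == pytest.approx(1.0, abs=1e-12)

    def test_no_introgression_null_is_zero(self):
        p = np.array([0.3, 0.6, 0.1])
        res = fd_window(p, p, [0.9, 0.8, 0.7], [0.0, 0.0, 0.0])
        assert res["D"] == 0
        assert res["fd"] == 0

    def test_negative_d_window_undefined(self):
        res = fd_window([0.6], [0.1], [0.8], [0.0])  # baba >> abba
        assert res["D"] < 0
        assert np.isnan(res["fd"])

    @given(st.lists(st.tuples(freqs, freqs, freqs, freqs), min_size=2, max_size=30))
    @settings(deadline=None)
    def test_d_bounded_on_any_frequency_input(self, sites):
        p1, p2, p3, p4 = (np.array(c) for c in zip(*sites))
        res = fd_window(p1, p2, p3, p4)
        if not np.isnan(res["D"]):
            assert -1 - 1e-9 <= res["D"] <= 1 + 1e-9

    def test_fd_bounded_on_simulated_windows(self, small_sim, small_freqs):
        """On admixture data with many sites per window, retained fd values
        stay within [0, 1] up to sampling noise.  (Adversarial single-site
        frequency configurations can exceed 1; the bound is a property of
        windowed data, not of the ratio itself.)"""
        out = scan_fd(
            small_freqs, "RUS-LEV", "BS7", "DEN-NOR", "CAN-TEM",
            min_sites=30, contig_lengths=small_sim.contig_lengths,
        )
        vals = out.loc[out["eligible"], "fd"]
        assert len(vals) > 50
        assert (vals >= 0).all() and (vals <= 1.05).all()


class TestScan:
    def test_window_count_on_500kb_contig(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 500_001), 800, replace=False))
        f = rng.random((800, 4))
        ft = make_freq_table(["c"] * 800, pos, ["p1", "p2", "p3", "o"], f)
        out = scan_fd(ft, "p1", "p2", "p3", "o", contig_lengths={"c": 500_000})
        assert len(out) == 21
        assert list(out["start"]) == list(range(0, 400_001, 20_000))

    def test_bh_hand_example(self):
        assert np.allclose(bh_qvalues([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_zero_variance_raises(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 500_001), 600, replace=False))
        ft = make_freq_table(
            ["c"] * 600, pos, ["p1", "p2", "p3", "o"],
            np.tile([0.1, 0.6, 0.8, 0.0], (600, 1)),
        )
        out = scan_fd(ft, "p1", "p2", "p3", "o", min_sites=5,
                      contig_lengths={"c": 500_000})
        with pytest.raises(ValueError, match="variance"):
            z_fdr_outliers(out, min_sites=5)

    def test_extreme_window_gets_smallest_q(self):
        rng = np.random.default_rng(2)
        n = 2000
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), n, replace=False))
        p2 = rng.uniform(0.2, 0.4, n)
        boosted = (pos - 1 >= 1_000_000) & (pos - 1 < 1_100_000)
        p2[boosted] = 0.95
        f = np.column_stack([np.full(n, 0.1), p2, np.full(n, 0.9), np.zeros(n)])
        ft = make_freq_table(["c"] * n, pos, ["p1", "p2", "p3", "o"], f)
        out = scan_fd(ft, "p1", "p2", "p3", "o", min_sites=20,
                      contig_lengths={"c": 2_000_000})
        out = z_fdr_outliers(out, min_sites=20)
        best = out.loc[out["q"].idxmin()]
        assert best["start"] <= 1_000_000 < best["end"] or 1_000_000 <= best["start"] < 1_100_000


class TestF4:
    def test_hand_value(self):
        assert f4([1, 1], [0, 0], [1, 0], [0, 0]) == pytest.approx(0.5)

    def test_identical_cd_gives_zero(self):
        c = [0.2, 0.7, 0.4]
        assert f4([0.9, 0.1, 0.5], [0.3, 0.8, 0.2], c, c) == 0

    @given(st.lists(st.tuples(freqs, freqs, freqs, freqs), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_antisymmetry_in_ab(self, sites):
        a, b, c, d = (np.array(x) for x in zip(*sites))
        assert f4(a, b, c, d) == pytest.approx(-f4(b, a, c, d), abs=1e-12)

    def test_linearity_over_site_sets(self):
        rng = np.random.default_rng(3)
        x = rng.random((30, 4))
        y = rng.random((50, 4))
        z = np.vstack([x, y])
        combined = f4(*z.T)
        weighted = (30 * f4(*x.T) + 50 * f4(*y.T)) / 80
        assert combined == pytest.approx(weighted, abs=1e-12)


class TestJackknife:
    def test_equal_weights_match_standard_jackknife(self):
        """Busing's weighted formula reduces to the textbook delete-one
        jackknife when all blocks have equal size."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        theta = x.mean()
        loo = np.array([np.delete(x, i).mean() for i in range(40)])
        g = 40
        se_std = np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2))
        _, se = weighted_block_jackknife(theta, loo, np.ones(g))
        assert se == pytest.approx(se_std, rel=1e-10)

    def test_se_shrinks_with_block_count(self):
        """On iid blocks the jackknife SE scales ~ 1/sqrt(n_blocks)."""
        rng = np.random.default_rng(5)

        def se_for(g, reps=30):
            out = []
            for _ in range(reps):
                x = rng.normal(size=g)
                loo = (x.sum() - x) / (g - 1)
                out.append(weighted_block_jackknife(x.mean(), loo, np.ones(g))[1])
            return np.mean(out)

        ratio = se_for(25) / se_for(400)
        assert ratio == pytest.approx(4.0, rel=0.35)


class TestF4Ratio:
    def test_test_population_equal_to_sources(self, small_sim, small_freqs):
        import copy

        ft = small_freqs
        # alias the WL source as a fake test population -> alpha = 1
        ft2 = copy.copy(ft)
        ft2.pops = list(ft.pops) + ["WL_ALIAS", "EL_ALIAS"]
        ft2.freq = np.column_stack(
            [ft.freq, ft.freq_of("DEN-NOR"), ft.freq_of("RUS-LEV")]
        )
        ft2.n = np.column_stack([ft.n, ft.n_of("DEN-NOR"), ft.n_of("RUS-LEV")])
        ft2.miss = np.column_stack(
            [ft.miss, ft.miss_of("DEN-NOR"), ft.miss_of("RUS-LEV")]
        )
        assert f4_ratio(ft2, small_sim.popmap, "WL_ALIAS").alpha == pytest.approx(1.0)
        assert f4_ratio(ft2, small_sim.popmap, "EL_ALIAS").alpha == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_alpha(self):
        cfg = SimConfig(seed=11, n_sites=50_000, alphas={"MIX": 0.2})
        sim = simulate(cfg)
        ft = allele_frequencies(sim.vt, sim.popmap)
        est = f4_ratio(ft, sim.popmap, "MIX")
        truth = sim.truth.alpha_realized["MIX"]
        assert abs(est.alpha - truth) < 3 * est.se
        assert est.n_blocks == 20

    def test_denominator_zero_raises(self):
        ft = make_freq_table(
            ["c"] * 3, [1, 2, 3], ["R", "O", "W", "E", "T"],
            np.column_stack([
                [0.5, 0.5, 0.5], [0.5, 0.5, 0.5],  # ref == outgroup
                [0.9, 0.1, 0.4], [0.1, 0.9, 0.6], [0.5, 0.5, 0.5],
            ]),
        )
        from introscan import PopulationMap

        pm = PopulationMap(
            {"a": "R", "b": "O", "c": "W", "d": "E", "e": "T"},
            roles={"R": "wl_reference", "O": "outgroup", "W": "wl_source",
                   "E": "el_source", "T": "admixed"},
        )
        with pytest.raises(ValueError, match="denominator"):
            f4_ratio(ft, pm, "T")
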