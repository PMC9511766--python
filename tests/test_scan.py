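"""Window construction, diversity, Fst, the composite-likelihood sweep score,
ranking and PSG intersection — each against an independent oracle where the
spec of the statistic allows one."""

import itertools

import numpy as np
import pandas as pd
import pytest

from domestiscan.scan import (
    XpclrParams,
    akey_fst_site,
    assign_sites_to_windows,
    estimate_omega,
    intersect_psgs,
    make_windows,
    pi_ratio,
    select_top_windows,
    site_heterozygosity,
    windowize,
    windows_to_genes,
    xpclr_site_loglik,
    xpclr_window_scores,
)
from domestiscan.variantio import GeneModel, make_site_table


class TestMakeWindows:
    def test_hundred_kb_chromosome(self):
        w = make_windows({"c": 100_000})
        assert list(zip(w["start"], w["end"])) == [
            (0, 40_000), (20_000, 60_000), (40_000, 80_000),
            (60_000, 100_000), (80_000, 100_000),
        ]
        assert w["short"].tolist() == [False, False, False, False, True]

    def test_exactly_one_full_window(self):
        w = make_windows({"c": 40_000})
        full = w[~w["short"]]
        assert len(full) == 1 and (full.iloc[0]["start"], full.iloc[0]["end"]) == (0, 40_000)

    def test_chromosome_shorter_than_window(self):
        w = make_windows({"c": 15_000})
        assert len(w) == 1 and w.iloc[0]["short"]
        assert (w.iloc[0]["start"], w.iloc[0]["end"]) == (0, 15_000)

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100_000}, size=20_000, step=40_000)

    def test_interior_coverage_is_size_over_step(self):
        w = make_windows({"c": 200_000})
        bp = 100_000
        covering = ((w["start"] <= bp) & (w["end"] > bp)).sum()
        assert covering == 2


def brute_force_pi_per_bp(haplotypes: np.ndarray, length: int) -> float:
    """Mean pairwise difference count over all haplotype pairs, per bp."""
    n = haplotypes.shape[0]
    total = sum(
        (haplotypes[i] != haplotypes[j]).sum()
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / length


class TestHeterozygosityAndPi:
    def test_monomorphic_site_is_zero(self):
        h = site_heterozygosity(np.array([[6, 0]]), np.array([6]))
        assert h[0] == 0.0

    def test_half_frequency_four_alleles(self):
        h = site_heterozygosity(np.array([[2, 2]]), np.array([4]))
        assert h[0] == pytest.approx(4 / 3 * 0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_window_pi_equals_brute_force_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n_hap = rng.integers(2, 7)
        n_sites = rng.integers(1, 21)
        haps = rng.integers(0, 2, size=(n_hap, n_sites))
        length = 1_000
        counts = np.stack(
            [(haps == 0).sum(axis=0), (haps == 1).sum(axis=0)], axis=1
        )
        h = site_heterozygosity(counts, np.full(n_sites, n_hap))
        windows = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [length], "short": [False]})
        pi, _ = windowize(h, [np.arange(n_sites)], windows, "sum_per_bp")
        assert pi[0] == pytest.approx(brute_force_pi_per_bp(haps, length), abs=1e-12)

    def test_windowize_examples(self):
        windows = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 40_000], "end": [40_000, 80_000], "short": [False] * 2}
        )
        agg, n = windowize([0.6667], [np.array([0]), np.array([], dtype=int)], windows, "sum_per_bp")
        assert agg[0] == pytest.approx(1.6667e-5, rel=1e-4)
        assert agg[1] == 0.0 and n[1] == 0
        agg, n = windowize([0.5], [np.array([], dtype=int), np.array([0])], windows, "mean")
        assert np.isnan(agg[0]) and agg[1] == 0.5

    def test_window_boundaries_half_open(self):
        sites = make_site_table(["c"] * 2, [40_001, 80_001], ["A"] * 2, [("G",)] * 2)
        # 1-based 40001 -> 0-based 40000 (window start, included);
        # 1-based 80001 -> 0-based 80000 (window end, excluded)
        windows = pd.DataFrame(
            {"chrom": ["c"], "start": [40_000], "end": [80_000], "short": [False]}
        )
        idx = assign_sites_to_windows(sites, windows)
        assert idx[0].tolist() == [0]


class TestPiRatio:
    def test_equal_diversity_gives_one(self):
        assert pi_ratio([2e-4], [2e-4])[0] == 1.0

    def test_inbred_fixation_gives_inf(self):
        assert np.isposinf(pi_ratio([1e-4], [0.0])[0])

    def test_fourfold(self):
        assert pi_ratio([2e-4], [5e-5])[0] == pytest.approx(4.0)

    def test_both_zero_undefined(self):
        assert np.isnan(pi_ratio([0.0], [0.0])[0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pi_ratio([-1e-4], [1e-4])


# Oracle values computed longhand from the ANOVA estimator as exact
# fractions before wiring them to the implementation.
FST_CASES = [
    (10, 1.0, 10, 0.0, 1.0),
    (10, 0.5, 10, 0.5, -1 / 9),
    (10, 0.8, 10, 0.3, 94 / 279),
    (20, 0.9, 40, 0.1, 7343 / 9503),
    (30, 0.25, 50, 0.6, 1723 / 8773),
    (16, 0.125, 24, 0.875, 8033 / 11393),
]


class TestAkeyFst:
    @pytest.mark.parametrize("n1,p1,n2,p2,expected", FST_CASES)
    def test_matches_hand_evaluation(self, n1, p1, n2, p2, expected):
        assert akey_fst_site([n1], [p1], [n2], [p2])[0] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_in_both_is_undefined(self):
        assert np.isnan(akey_fst_site([10], [1.0], [10], [1.0])[0])

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(1)
        n1 = rng.integers(4, 40, 500)
        n2 = rng.integers(4, 40, 500)
        p1 = rng.random(500)
        p2 = rng.random(500)
        f = akey_fst_site(n1, p1, n2, p2)
        f = f[np.isfinite(f)]
        assert (f <= 1.0 + 1e-12).all()


class TestEstimateOmega:
    def test_closed_forms(self):
        assert estimate_omega(np.full(200, 0.5)) == pytest.approx(1.0)
        assert estimate_omega(np.full(200, 0.2)) == pytest.approx(0.25)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            estimate_omega(np.full(50, 0.3))

    def test_fixture_omega_in_sane_range(self, filtered_panel):
        from domestiscan.scan import biallelic_group_counts

        gm, _ = filtered_panel
        m1, n1 = biallelic_group_counts(gm, "wild")
        m2, n2 = biallelic_group_counts(gm, "classical_inbred")
        f = akey_fst_site(n1, m1 / n1, n2, m2 / n2)
        assert 0.05 <= estimate_omega(f) <= 5.0


class TestXpclrSite:
    def test_small_theta_nests_neutral(self):
        l0, l1 = xpclr_site_loglik([12], [40], [5], [40], omega=0.5, theta=1.0,
                                   distance_bp=10_000)
        assert l1[0] == pytest.approx(l0[0], abs=1e-6)

    def test_fixed_object_allele_favors_selection(self):
        l0, l1 = xpclr_site_loglik([12], [40], [40], [40], omega=0.5, theta=1e6,
                                   distance_bp=1_000)
        assert l1[0] > l0[0]

    def test_vanishing_drift_approaches_binomial(self):
        m1, n1, m2, n2 = 20, 40, 10, 20
        from scipy.stats import binom

        l0, _ = xpclr_site_loglik([m1], [n1], [m2], [n2], omega=1e-6, theta=100.0,
                                  distance_bp=5_000)
        assert l0[0] == pytest.approx(binom.logpmf(m2, n2, m1 / n1), abs=1e-3)


class TestXpclrWindow:
    def test_null_panel_scores_near_zero(self, filtered_panel, sim_config):
        from domestiscan.scan import biallelic_group_counts

        gm, sites = filtered_panel
        rng = np.random.default_rng(42)
        m1, n1 = biallelic_group_counts(gm, "wild")
        p1 = m1 / np.maximum(n1, 1)
        n2 = np.full_like(n1, 40)
        m2 = rng.binomial(40, p1)
        windows = make_windows(sim_config.chrom_lengths())
        idx = assign_sites_to_windows(sites, windows)
        params = XpclrParams(omega=0.5)
        scores = xpclr_window_scores(
            m1, n1, m2, n2, sites["pos"].to_numpy(), idx, windows, params
        )
        finite = scores[np.isfinite(scores)]
        assert np.median(finite) < np.percentile(finite, 95)
        assert np.median(finite) < 5.0

    def test_sweep_windows_exceed_null_percentile(self, bundle, scan_results):
        ws = scan_results["window_stats"]
        sweep = set(bundle["truth"].sweep_windows)
        is_sweep = ws.apply(
            lambda r: (r["chrom"], int(r["start"]), int(r["end"])) in sweep, axis=1
        )
        nonsweep = ws.loc[~is_sweep & ~ws["masked"], "xpclr"].dropna()
        assert ws.loc[is_sweep, "xpclr"].min() > np.percentile(nonsweep, 99)

    def test_sparse_window_masked(self):
        params = XpclrParams(omega=0.5, min_snps=10)
        windows = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [40_000], "short": [False]}
        )
        scores = xpclr_window_scores(
            [5], [40], [5], [40], [100], [np.array([0])], windows, params
        )
        assert np.isnan(scores[0])


def _window_frame(n, stat_name="fst", values=None, masked=None):
    return pd.DataFrame(
        {
            "chrom": ["c"] * n,
            "start": np.arange(n) * 20_000,
            "end": np.arange(n) * 20_000 + 40_000,
            stat_name: values if values is not None else np.ones(n),
            "masked": masked if masked is not None else [False] * n,
        }
    )


class TestSelectTopWindows:
    def test_ceil_counts(self):
        assert len(select_top_windows(_window_frame(200), "fst")) == 10
        assert len(select_top_windows(_window_frame(41), "fst")) == 3

    def test_all_equal_takes_coordinate_order(self):
        top = select_top_windows(_window_frame(40), "fst")
        assert top["start"].tolist() == [0, 20_000]

    def test_inf_sentinel_ranks_first(self):
        vals = np.ones(40)
        vals[17] = np.inf
        top = select_top_windows(_window_frame(40, values=vals), "fst")
        assert top.iloc[0]["start"] == 17 * 20_000

    def test_masked_windows_excluded(self):
        masked = [True] * 20 + [False] * 20
        top = select_top_windows(_window_frame(40, masked=masked), "fst")
        assert len(top) == 1 and (top["start"] >= 20 * 20_000).all()


class TestGeneMappingAndIntersection:
    GENES = [
        GeneModel("inside", "c", 45_000, 50_000),
        GeneModel("edge", "c", 19_000, 20_001),          # 1 bp into [20k, 60k)
        GeneModel("outside", "c", 100_000, 120_000),
        GeneModel("spanning", "c", 55_000, 70_000),
        GeneModel("otherchrom", "d", 45_000, 50_000),
    ]

    def test_toy_overlap_enumeration(self):
        wins = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [20_000, 40_000], "end": [60_000, 80_000]}
        )
        assert windows_to_genes(wins, self.GENES) == {"inside", "edge", "spanning"}

    def test_intersection_and_venn(self):
        psg, venn = intersect_psgs({"a", "b", "c"}, {"b", "c", "d"}, {"c", "b", "e"})
        assert psg == ["b", "c"]
        assert venn["n_all"] == 2 and venn["n_pi_fst"] == 2

    def test_disjoint_and_identical(self):
        assert intersect_psgs({"a"}, {"b"}, {"c"})[0] == []
        assert intersect_psgs({"a", "b"}, {"a", "b"}, {"a", "b"})[0] == ["a", "b"]

    def test_psgs_subset_of_each_top_set(self, scan_results):
        psg = set(scan_results["psgs"])
        for stat, genes in scan_results["gene_sets"].items():
            assert psg <= genes

    def test_fixture_recovery(self, bundle, scan_results):
        truth = set(bundle["truth"].sweep_genes)
        psg = set(scan_results["psgs"])
        assert truth <= psg
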