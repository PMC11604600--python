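"""Likelihood-weighted trait distributions: grids, binning, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nannotraits import (
    build_cl_histogram,
    build_weight_grid,
    morphogroup_trait_distribution,
    summarize_distribution,
)
from nannotraits.allometry import (
    CnHistogram,
    cell_diameter_placolith,
)
from nannotraits.carbon import (
    cellular_pic,
    coccolith_pic,
    poc_from_volume,
    sphere_volume,
)
from nannotraits.errors import ConfigurationError, InsufficientDataError
from nannotraits.params import KsEntry, RegressionParams
from nannotraits.traits import ClHistogram, bin_center

PARAMS = RegressionParams("X", 0.478, 0.151)
KS = KsEntry("X", 0.06, "distal shield length")


def _cl_hist(bins, sample_id="s", morphogroup="X", width=0.5):
    return ClHistogram(sample_id, morphogroup, bins, width)


def _random_hists(rng, n_cl=10, n_cn=10):
    w1 = rng.dirichlet(np.ones(n_cl))
    w2 = rng.dirichlet(np.ones(n_cn))
    cl = _cl_hist({2.25 + 0.5 * i: float(w) for i, w in enumerate(w1)})
    cn = CnHistogram("X", {6 + i: float(w) for i, w in enumerate(w2)})
    return cl, cn


class TestClHistogram:
    def test_from_measurements_bins_on_half_micron_lattice(self):
        h = build_cl_histogram([4.1, 4.4, 4.6, 5.2], bin_width=0.5)
        assert h.bins == {4.25: 0.5, 4.75: 0.25, 5.25: 0.25}

    def test_empty(self):
        with pytest.raises(InsufficientDataError):
            build_cl_histogram([])


class TestWeightGrid:
    def test_uniform_two_by_two(self):
        cl = _cl_hist({4.25: 0.5, 4.75: 0.5})
        cn = CnHistogram("X", {10: 0.5, 12: 0.5})
        grid = build_weight_grid(cl, cn)
        assert np.allclose(grid.weights, 0.25)

    def test_degenerate_single_bins(self):
        grid = build_weight_grid(_cl_hist({4.25: 1.0}),
                                 CnHistogram("X", {10: 1.0}))
        assert grid.weights.shape == (1, 1)
        assert grid.weights[0, 0] == 1.0

    def test_marginals_match_inputs(self, rng):
        cl, cn = _random_hists(rng)
        grid = build_weight_grid(cl, cn)
        assert np.allclose(grid.weights.sum(axis=1),
                           [cl.bins[c] for c in grid.cl_values], atol=1e-12)
        assert np.allclose(grid.weights.sum(axis=0),
                           [cn.bins[k] for k in grid.cn_values], atol=1e-12)
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestTraitDistribution:
    def test_single_node_grid(self):
        grid = build_weight_grid(_cl_hist({6.25: 1.0}),
                                 CnHistogram("X", {12: 1.0}))
        dist = morphogroup_trait_distribution(grid, PARAMS, KS)
        theta = cell_diameter_placolith(6.25, 12, PARAMS)
        poc = poc_from_volume(sphere_volume(theta))
        pic = cellular_pic(coccolith_pic(6.25, KS), 12)
        assert dist.size_bins == {bin_center(theta, 1.0): 1.0}
        assert dist.poc_bins == {bin_center(poc, 30.0): 1.0}
        assert dist.pic_bins == {bin_center(pic, 30.0): 1.0}
        assert dist.ratio_bins == {bin_center(pic / poc, 0.1): 1.0}
        assert dist.mean_size == pytest.approx(theta)
        assert dist.mean_ratio == pytest.approx(pic / poc)

    def test_conservation_on_random_grids(self, rng):
        for _ in range(20):
            cl, cn = _random_hists(rng)
            dist = morphogroup_trait_distribution(
                build_weight_grid(cl, cn), PARAMS, KS)
            for bins in (dist.size_bins, dist.poc_bins, dist.pic_bins,
                         dist.ratio_bins):
                assert abs(sum(bins.values()) - 1.0) < 1e-9

    def test_matches_exhaustive_enumeration_bitwise(self, rng):
        """20×15 grid: accumulated weights identical to an independent
        brute-force loop over all 300 nodes."""
        w1 = rng.dirichlet(np.ones(20))
        w2 = rng.dirichlet(np.ones(15))
        cl = _cl_hist({3.25 + 0.5 * i: float(w) for i, w in enumerate(w1)})
        cn = CnHistogram("X", {5 + i: float(w) for i, w in enumerate(w2)})
        grid = build_weight_grid(cl, cn)
        dist = morphogroup_trait_distribution(grid, PARAMS, KS)

        # oracle: naive scalar enumeration in the same row-major order
        size_bins, poc_bins = {}, {}
        for c, wc in sorted(cl.bins.items()):
            for k, wk in sorted(cn.bins.items()):
                w = wc * wk
                theta = cell_diameter_placolith(np.float64(c), np.float64(k),
                                                PARAMS)
                poc = poc_from_volume(sphere_volume(np.float64(theta)))
                sb = bin_center(theta, 1.0)
                pb = bin_center(poc, 30.0)
                size_bins[sb] = size_bins.get(sb, 0.0) + w
                poc_bins[pb] = poc_bins.get(pb, 0.0) + w
        assert dist.size_bins == size_bins
        assert dist.poc_bins == poc_bins

    def test_binned_mean_within_half_bin_of_exact_mean(self, rng):
        cl, cn = _random_hists(rng)
        dist = morphogroup_trait_distribution(build_weight_grid(cl, cn),
                                              PARAMS, KS)
        binned_mean = sum(c * w for c, w in dist.size_bins.items())
        assert abs(binned_mean - dist.mean_size) <= 0.5

    def test_shifted_lengths_shift_traits_upward(self, rng):
        """Stochastic dominance: moving the C_L histogram one bin up moves
        size, POC and PIC to weakly larger values (size strictly)."""
        cl, cn = _random_hists(rng)
        shifted = _cl_hist({c + 0.5: w for c, w in cl.bins.items()})
        d0 = morphogroup_trait_distribution(build_weight_grid(cl, cn),
                                            PARAMS, KS)
        d1 = morphogroup_trait_distribution(build_weight_grid(shifted, cn),
                                            PARAMS, KS)
        assert d1.mean_size > d0.mean_size
        assert d1.mean_poc > d0.mean_poc
        assert d1.mean_pic > d0.mean_pic

        def cdf_at(bins, xs):
            centers = np.array(sorted(bins))
            w = np.array([bins[c] for c in centers])
            return np.array([w[centers <= x].sum() for x in xs])

        for b0, b1 in ((d0.size_bins, d1.size_bins),
                       (d0.poc_bins, d1.poc_bins),
                       (d0.pic_bins, d1.pic_bins)):
            xs = sorted(set(b0) | set(b1))
            assert np.all(cdf_at(b1, xs) <= cdf_at(b0, xs) + 1e-12)

    def test_mean_ratio_is_not_ratio_of_means_on_skewed_fixture(self):
        # a heavy small-cell mode plus a rare large-cell mode: the weighted
        # mean of per-combination PIC:POC differs from mean PIC / mean POC
        cl = _cl_hist({3.25: 0.9, 9.75: 0.1})
        cn = CnHistogram("X", {8: 0.5, 20: 0.5})
        dist = morphogroup_trait_distribution(build_weight_grid(cl, cn),
                                              PARAMS, KS)
        ratio_of_means = dist.mean_pic / dist.mean_poc
        assert dist.mean_ratio != pytest.approx(ratio_of_means, rel=1e-3)

    def test_parameter_type_mismatch(self):
        grid = build_weight_grid(_cl_hist({4.25: 1.0}),
                                 CnHistogram("X", {10: 1.0}))
        with pytest.raises(ConfigurationError):
            morphogroup_trait_distribution(grid, object(), KS)
        with pytest.raises(ConfigurationError):
            morphogroup_trait_distribution(grid, PARAMS, None)


class TestSummarize:
    def test_single_bin(self):
        grid = build_weight_grid(_cl_hist({6.25: 1.0}),
                                 CnHistogram("X", {12: 1.0}))
        dist = morphogroup_trait_distribution(grid, PARAMS, KS)
        s = summarize_distribution(dist)
        (center,) = dist.size_bins
        assert s["size"]["p5"] == s["size"]["p95"] == center
        assert s["size"]["mean"] == pytest.approx(dist.mean_size)

    def test_uniform_median_tie_rule(self):
        from nannotraits.traits import _binned_percentile

        bins = {float(i): 0.1 for i in range(1, 11)}
        # first bin whose cumulative weight reaches 0.5
        assert _binned_percentile(bins, 50) == 5.0

    def test_percentiles_match_cumulative_scan(self, rng):
        from nannotraits.traits import _binned_percentile

        w = rng.dirichlet(np.ones(50))
        bins = {float(i): float(x) for i, x in enumerate(w)}
        for q in (5, 25, 50, 75, 95):
            cum, expected = 0.0, None
            for c in sorted(bins):
                cum += bins[c]
                if cum >= q / 100 - 1e-12:
                    expected = c
                    break
            assert _binned_percentile(bins, q) == expected

    def test_p95_bin_reaches_cumulative_095(self, rng):
        cl, cn = _random_hists(rng)
        dist = morphogroup_trait_distribution(build_weight_grid(cl, cn),
                                              PARAMS, KS)
        s = summarize_distribution(dist)
        cum = sum(w for c, w in dist.size_bins.items()
                  if c <= s["size"]["p95"])
        assert cum >= 0.95 - 1e-12


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_grid_weights_always_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    cl, cn = _random_hists(rng, n_cl=rng.integers(1, 15),
                           n_cn=rng.integers(1, 15))
    grid = build_weight_grid(cl, cn)
    assert grid.weights.sum() == pytest.approx(1.0, abs=1e-9)
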