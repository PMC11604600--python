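"""Assemblage statistics, community stacking, partitioning and scenarios."""

import math

import numpy as np
import pandas as pd
import pytest

from nannotraits import (
    coccolith_to_cell_abundance,
    ecological_index,
    implied_standing_stock,
    partition_size_classes,
    reconstruct_communities,
    relative_abundance_with_ci,
    scenario_totals,
    smooth_abundance,
    stack_community,
)
from nannotraits.community import CommunityReconstruction, abundance_series
from nannotraits.errors import ConfigurationError, DomainError
from nannotraits.io import AssemblageSample
from nannotraits.traits import DEFAULT_BINS, TraitDistribution


def _singleton_dist(mg, size_center, poc, pic):
    """Trait distribution concentrated in one size bin."""
    return TraitDistribution(
        morphogroup=mg, sample_id="s",
        size_bins={size_center: 1.0},
        poc_bins={15.0: 1.0}, pic_bins={15.0: 1.0},
        ratio_bins={round((pic / poc) // 0.1 * 0.1 + 0.05, 9): 1.0},
        poc_by_size_bin={size_center: poc},
        pic_by_size_bin={size_center: pic},
        mean_size=size_center, mean_poc=poc, mean_pic=pic,
        mean_ratio=pic / poc,
    )


class TestRelativeAbundanceCI:
    def test_wald_interval_hand_value(self):
        s = AssemblageSample("s", 10.0, {"A": 150, "B": 150})
        p, lo, hi = relative_abundance_with_ci(s)["A"]
        half = 1.959964 * math.sqrt(0.25 / 300)
        assert p == 0.5
        assert lo == pytest.approx(0.5 - half, abs=1e-6)
        assert hi == pytest.approx(0.5 + half, abs=1e-6)
        assert (lo, hi) == (pytest.approx(0.4434, abs=5e-4),
                            pytest.approx(0.5566, abs=5e-4))

    def test_zero_count_is_degenerate_point(self):
        s = AssemblageSample("s", 10.0, {"A": 300, "B": 0})
        assert relative_abundance_with_ci(s)["B"] == (0.0, 0.0, 0.0)

    def test_proportions_sum_to_one(self):
        s = AssemblageSample("s", 10.0, {"A": 120, "B": 90, "C": 90})
        cis = relative_abundance_with_ci(s)
        assert sum(p for p, _, _ in cis.values()) == pytest.approx(1.0)

    def test_wilson_is_narrower_near_extremes(self):
        s = AssemblageSample("s", 10.0, {"A": 297, "B": 3})
        _, lo_w, hi_w = relative_abundance_with_ci(s, method="wilson")["B"]
        assert lo_w > 0.0  # Wilson never collapses to zero width at p>0

    def test_series_are_depth_ordered(self):
        samples = [AssemblageSample("s2", 20.0, {"A": 100, "B": 200}),
                   AssemblageSample("s1", 10.0, {"A": 200, "B": 100})]
        series = abundance_series(samples)
        assert [p[1] for p in series["A"].points] == [10.0, 20.0]
        assert series["A"].points[0][2] == pytest.approx(2 / 3)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        df = pd.DataFrame({"A": [0.3] * 8, "B": [0.7] * 8})
        out = smooth_abundance(df)
        assert np.allclose(out.to_numpy(), df.to_numpy())

    def test_interior_impulse_spreads_one_fifth(self):
        a = np.zeros(9)
        a[4] = 1.0
        df = pd.DataFrame({"A": a, "B": 1.0 - a})
        out = smooth_abundance(df, renormalize=False)
        assert np.allclose(out["A"].to_numpy()[2:7], 0.2)
        assert out["A"].iloc[0] == 0.0

    def test_interior_values_match_windowed_mean_oracle(self, rng):
        vals = rng.random((12, 3))
        df = pd.DataFrame(vals, columns=list("ABC"))
        out = smooth_abundance(df, renormalize=False)
        for i in range(2, 10):
            assert np.allclose(out.iloc[i].to_numpy(),
                               vals[i - 2:i + 3].mean(axis=0), atol=1e-12)

    def test_ends_truncate_symmetrically(self, rng):
        vals = rng.random((7, 2))
        df = pd.DataFrame(vals, columns=list("AB"))
        out = smooth_abundance(df, renormalize=False)
        assert np.allclose(out.iloc[0].to_numpy(), vals[0])
        assert np.allclose(out.iloc[1].to_numpy(), vals[0:3].mean(axis=0))

    def test_renormalized_rows_sum_to_one(self, rng):
        vals = rng.dirichlet(np.ones(4), size=10)
        out = smooth_abundance(pd.DataFrame(vals))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)


class TestCellConversion:
    def test_shared_mean_cn_leaves_proportions_unchanged(self):
        props = {"A": 0.25, "B": 0.75}
        out = coccolith_to_cell_abundance(props, {"A": 14.0, "B": 14.0})
        assert out == pytest.approx(props)

    def test_hand_example(self):
        out = coccolith_to_cell_abundance({"A": 0.8, "B": 0.2},
                                          {"A": 16.0, "B": 4.0})
        assert out == pytest.approx({"A": 0.5, "B": 0.5})

    def test_single_morphogroup(self):
        assert coccolith_to_cell_abundance({"A": 1.0}, {"A": 9.0}) == {"A": 1.0}

    def test_missing_mean_cn(self):
        with pytest.raises(ConfigurationError):
            coccolith_to_cell_abundance({"A": 1.0}, {})


class TestStacking:
    def test_single_morphogroup_community_equals_its_distribution(self):
        d = _singleton_dist("A", 9.5, 100.0, 150.0)
        recon = stack_community({"A": d}, {"A": 1.0})
        assert recon.size_structure == d.size_bins
        assert recon.total_poc == pytest.approx(100 * d.mean_poc)
        assert recon.community_pic_poc == pytest.approx(d.mean_ratio)
        assert recon.mean_community_size == pytest.approx(9.5)

    def test_equal_poc_ratio_one_and_three_mix_to_two(self):
        a = _singleton_dist("A", 6.5, 80.0, 80.0)    # ratio 1.0
        b = _singleton_dist("B", 12.5, 80.0, 240.0)  # ratio 3.0
        recon = stack_community({"A": a, "B": b}, {"A": 0.5, "B": 0.5})
        assert recon.community_pic_poc == pytest.approx(2.0)

    def test_community_ratio_bounded_by_contributions(self, reconstruction):
        recons, dists = reconstruction
        for r in recons:
            ratios = [dists[(r.sample_id, mg)].mean_pic /
                      dists[(r.sample_id, mg)].mean_poc
                      for mg in r.cell_proportions
                      if (r.sample_id, mg) in dists]
            assert min(ratios) <= r.community_pic_poc <= max(ratios)

    def test_community_ratio_is_poc_weighted_mean_of_bin_ratios(
            self, reconstruction):
        recons, _ = reconstruction
        for r in recons:
            num = sum(r.poc_by_bin[c] * (r.pic_by_bin[c] / r.poc_by_bin[c])
                      for c in r.poc_by_bin if r.poc_by_bin[c] > 0)
            assert num / r.total_poc == pytest.approx(
                r.community_pic_poc, rel=1e-9)

    def test_missing_distribution_is_configuration_error(self):
        d = _singleton_dist("A", 9.5, 100.0, 150.0)
        with pytest.raises(ConfigurationError):
            stack_community({"A": d}, {"A": 0.5, "B": 0.5})


class TestSizeClasses:
    def test_everything_in_one_class(self):
        d = _singleton_dist("A", 9.5, 100.0, 150.0)
        part = partition_size_classes(stack_community({"A": d}, {"A": 1.0}))
        assert part.classes["8-11"]["cells_pct"] == pytest.approx(100.0)
        assert part.classes["8-11"]["poc_pct"] == pytest.approx(100.0)
        assert part.classes["8-11"]["pic_pct"] == pytest.approx(100.0)
        assert part.classes["2-5"]["pic_poc"] is None  # empty class

    def test_two_class_fixture_matches_hand_partition(self):
        a = _singleton_dist("A", 6.5, 50.0, 100.0)
        b = _singleton_dist("B", 12.5, 150.0, 150.0)
        recon = stack_community({"A": a, "B": b}, {"A": 0.4, "B": 0.6})
        part = partition_size_classes(recon)
        poc_a, poc_b = 100 * 0.4 * 50.0, 100 * 0.6 * 150.0
        assert part.classes["5-8"]["poc_pct"] == pytest.approx(
            100 * poc_a / (poc_a + poc_b))
        assert part.classes["11-15"]["pic_poc"] == pytest.approx(150.0 / 150.0)

    def test_percentages_conserve_totals(self, reconstruction):
        recons, _ = reconstruction
        for r in recons:
            part = partition_size_classes(r)
            assert sum(c["cells_pct"] for c in part.classes.values()) == \
                pytest.approx(100.0, abs=1e-6)
            assert sum(c["poc"] for c in part.classes.values()) == \
                pytest.approx(r.total_poc, abs=1e-9 * max(1.0, r.total_poc))

    def test_bad_edges(self):
        d = _singleton_dist("A", 9.5, 100.0, 150.0)
        recon = stack_community({"A": d}, {"A": 1.0})
        with pytest.raises(ConfigurationError):
            partition_size_classes(recon, edges=(5, 2))


class TestEcologicalIndex:
    def test_threshold_labels(self):
        props = {"Chiasmolithus": 0.20, "R. daviesii": 0.15,
                 "Cl. subdistichus": 0.0, "Other": 0.65}
        assert ecological_index(props) == (pytest.approx(35.0), "cooler")
        props = {"Chiasmolithus": 0.05, "R. daviesii": 0.15,
                 "Cl. subdistichus": 0.0, "Other": 0.80}
        assert ecological_index(props)[1] == "intermediate"

    def test_absent_taxa_count_zero_with_warning(self):
        with pytest.warns(UserWarning):
            index, label = ecological_index({"Other": 1.0})
        assert index == 0.0 and label == "warmer"


def _flat_recon(total_poc, total_pic, stock=100.0):
    return CommunityReconstruction(
        sample_id="s", age=30.0, cell_proportions={"A": 1.0},
        size_structure={9.5: 1.0},
        poc_by_bin={9.5: total_poc}, pic_by_bin={9.5: total_pic},
        mean_community_size=9.5, total_poc=total_poc, total_pic=total_pic,
        community_pic_poc=total_pic / total_poc, standing_stock=stock,
    )


class TestScenario:
    def test_identical_reconstructions_zero_change(self):
        r = _flat_recon(10_000.0, 15_000.0)
        report = scenario_totals(r, r, 100.0, 100.0)
        assert report.poc_change_pct == 0
        assert report.pic_change_pct == 0
        assert report.stock_change_pct == 0

    def test_printed_endpoint_arithmetic(self):
        # POC 9,261 → 14,308 pg C/mL and PIC 13,975 → 21,949 pg C/mL while
        # standing stock rises 100 → 110 cells/mL
        a = _flat_recon(9_261.0, 13_975.0)
        b = _flat_recon(14_308.0 * 100 / 110, 21_949.0 * 100 / 110)
        report = scenario_totals(a, b, 100.0, 110.0)
        assert report.poc_a == pytest.approx(9_261.0)
        assert report.poc_b == pytest.approx(14_308.0)
        assert report.poc_change_pct == 54
        assert report.pic_change_pct == 57

    def test_stock_change_110_to_235(self):
        r = _flat_recon(10_000.0, 15_000.0)
        assert scenario_totals(r, r, 110.0, 235.0).stock_change_pct == 114

    def test_implied_stock_at_fixed_budget(self):
        r = _flat_recon(4_870.0, 5_000.0)  # mean cellular POC 48.7 pg
        assert implied_standing_stock(11_450.0, r) == pytest.approx(
            11_450.0 / 48.7)

    def test_positive_stocks_required(self):
        r = _flat_recon(10_000.0, 15_000.0)
        with pytest.raises(DomainError):
            scenario_totals(r, r, 0.0, 100.0)


class TestEndToEnd:
    def test_deterministic_reconstruction(self, bundle, reconstruction):
        recons, _ = reconstruction
        again, _ = reconstruct_communities(
            bundle.coccospheres, bundle.lith_samples, bundle.assemblages,
            bundle.registry, bundle.age_model)
        for a, b in zip(recons, again):
            assert a.community_pic_poc == b.community_pic_poc
            assert a.total_poc == b.total_poc
            assert a.size_structure == b.size_structure

    def test_structure_sums_and_ages(self, reconstruction, bundle):
        recons, _ = reconstruction
        assert len(recons) == 18
        for r in recons:
            assert abs(sum(r.cell_proportions.values()) - 1.0) < 1e-9
            assert abs(sum(r.size_structure.values()) - 1.0) < 1e-9
            assert 26.5 <= r.age <= 34.7
        depths = [s.depth for s in sorted(bundle.assemblages,
                                          key=lambda s: s.depth)]
        ages = [r.age for r in recons]
        assert ages == sorted(ages)  # deeper is older
        assert len(depths) == len(ages)
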