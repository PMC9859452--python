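"""Stratified volatility summaries, curves and depth quartiles."""

import numpy as np
import pandas as pd
import pytest

from microvol.summaries import (
    AbundanceBinning,
    add_abundance_bins,
    assign_abundance_bins,
    assign_depth_quartiles,
    curve_peak_abundance,
    depth_quartile_analysis,
    qualitative_curve,
    summarize_changes,
)


def change_frame(**columns):
    n = max(len(v) for v in columns.values())
    base = {
        "subject": ["A"] * n,
        "pair_id": [f"p{i}" for i in range(n)],
        "taxon": ["t0"] * n,
        "mean_original_depth": [100.0] * n,
        "mean_abundance": [0.01] * n,
        "d_additive": [0.0] * n,
        "d_multiplicative": [0.0] * n,
        "d_clr": [0.0] * n,
        "d_qualitative": [0] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)


class TestBinning:
    def test_interior_value(self):
        assert str(assign_abundance_bins([0.005])[0]) == "(0.001, 0.01]"

    def test_right_closed_boundary(self):
        assert str(assign_abundance_bins([0.001])[0]) == "(0.0001, 0.001]"

    def test_top_bin_matches_coarse_split(self):
        assert str(assign_abundance_bins([0.5])[0]) == "(0.01, 1]"

    def test_zero_goes_to_floor_bin(self):
        assert str(assign_abundance_bins([0.0])[0]) == "[0, 1e-05]"

    def test_custom_edges_validated(self):
        with pytest.raises(ValueError):
            AbundanceBinning((0.0, 0.5, 0.4, 1.0))
        with pytest.raises(ValueError):
            AbundanceBinning((0.0, 0.5))  # top edge must be 1
        custom = AbundanceBinning((0.0, 0.001, 1.0))
        assert str(assign_abundance_bins([0.5], custom)[0]) == "(0.001, 1]"

    def test_every_taxon_maps_to_exactly_one_bin(self):
        rng = np.random.default_rng(0)
        bins = assign_abundance_bins(rng.random(100))
        assert not pd.isna(bins).any()


class TestSummarize:
    def test_sample_sd_uses_n_minus_one(self):
        changes = change_frame(d_additive=[-0.1, 0.1])
        out = summarize_changes(changes)
        assert out["sd_additive"].iloc[0] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_all_quiet_gives_zero_proportion(self):
        out = summarize_changes(change_frame(d_qualitative=[0, 0, 0]))
        assert out["prop_qualitative"].iloc[0] == 0.0

    def test_proportion_counts_both_flip_directions(self):
        out = summarize_changes(change_frame(d_qualitative=[1, -1, 0, 0]))
        assert out["prop_qualitative"].iloc[0] == 0.5

    def test_all_multiplicative_undefined(self):
        out = summarize_changes(
            change_frame(d_multiplicative=[np.nan, np.nan, np.nan])
        )
        assert np.isnan(out["sd_multiplicative"].iloc[0])
        assert out["n_defined_multiplicative"].iloc[0] == 0

    def test_single_record_stratum_has_missing_sd(self):
        out = summarize_changes(change_frame(d_additive=[0.4]))
        assert np.isnan(out["sd_additive"].iloc[0])
        assert out["n_records"].iloc[0] == 1

    def test_pooled_records_preserved_across_strata(self):
        rng = np.random.default_rng(1)
        changes = change_frame(
            d_additive=rng.normal(size=40),
            mean_abundance=rng.choice([1e-6, 1e-3, 0.5], size=40),
        )
        binned = add_abundance_bins(changes)
        out = summarize_changes(binned, ["abundance_bin"])
        assert out["n_records"].sum() == 40

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_changes(change_frame(d_additive=[]).iloc[:0])


class TestQualitativeCurve:
    def test_flat_input_gives_flat_curve(self):
        rows = []
        rng = np.random.default_rng(2)
        for j, ab in enumerate(np.logspace(-4, -1, 12)):
            flips = rng.permutation([1] * 5 + [0] * 5)  # every taxon at 0.5
            for k, q in enumerate(flips):
                rows.append(
                    {"taxon": f"t{j}", "mean_abundance": ab, "d_qualitative": q}
                )
        changes = pd.DataFrame(rows)
        curve, excluded = qualitative_curve(changes, span=0.75)
        assert excluded.empty
        assert np.allclose(curve["fitted"], 0.5, atol=1e-8)

    def test_interior_maximum_recovered(self):
        # proportions rise then fall with abundance; fitted peak is interior
        abundances = np.logspace(-5, -1, 15)
        props = np.exp(-((np.log10(abundances) + 3) ** 2))
        rows = []
        for j, (ab, p) in enumerate(zip(abundances, props)):
            n_flip = int(round(20 * p))
            for k in range(20):
                rows.append(
                    {
                        "taxon": f"t{j}",
                        "mean_abundance": ab,
                        "d_qualitative": 1 if k < n_flip else 0,
                    }
                )
        curve, _ = qualitative_curve(pd.DataFrame(rows), span=0.5)
        peak = curve_peak_abundance(curve)
        assert -4.0 < peak < -2.0

    def test_zero_abundance_taxa_reported_separately(self):
        changes = pd.concat(
            [
                change_frame(
                    taxon=[f"t{j}" for j in range(8)],
                    mean_abundance=list(np.logspace(-4, -1, 8)),
                ),
                change_frame(taxon=["zero"], mean_abundance=[0.0], d_qualitative=[1]),
            ],
            ignore_index=True,
        )
        curve, excluded = qualitative_curve(changes)
        assert list(excluded["taxon"]) == ["zero"]
        assert "zero" not in set(curve["taxon"])

    def test_deterministic(self):
        changes = change_frame(
            taxon=[f"t{j}" for j in range(10)],
            mean_abundance=list(np.logspace(-4, -1, 10)),
            d_qualitative=[0, 1] * 5,
        )
        a, _ = qualitative_curve(changes)
        b, _ = qualitative_curve(changes)
        pd.testing.assert_frame_equal(a, b)


class TestDepthQuartiles:
    def test_eight_distinct_depths_split_two_each(self):
        q = assign_depth_quartiles(np.arange(8) * 100.0)
        assert list(pd.Series(q).value_counts().sort_index()) == [2, 2, 2, 2]

    def test_all_equal_depths_fall_in_one_group(self):
        q = assign_depth_quartiles(np.full(6, 500.0))
        assert set(q) == {"Q1"}

    def test_tie_at_cutpoint_goes_to_lower_quartile(self):
        depths = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cut = np.quantile(depths, 0.25)  # type-7: 2.0
        q = assign_depth_quartiles(depths)
        assert q[list(depths).index(cut)] == "Q1"

    def test_quartile_summaries_keyed_by_quartile_and_bin(self):
        rng = np.random.default_rng(3)
        changes = change_frame(
            pair_id=[f"p{i}" for i in range(16)],
            mean_original_depth=list(rng.permutation(np.arange(16) * 50.0 + 100)),
            d_additive=list(rng.normal(size=16)),
        )
        out = depth_quartile_analysis(changes)
        assert set(out["depth_quartile"]) == {"Q1", "Q2", "Q3", "Q4"}
        assert out["n_records"].sum() == 16

    def test_null_depths_give_comparable_quartile_sds(self):
        # depth-independent changes: quartile SDs agree within sampling error
        rng = np.random.default_rng(4)
        n = 2000
        changes = change_frame(
            pair_id=[f"p{i}" for i in range(n)],
            mean_original_depth=list(rng.uniform(100, 10000, n)),
            d_additive=list(rng.normal(0, 0.1, n)),
        )
        out = depth_quartile_analysis(changes)
        sds = out.groupby("depth_quartile", observed=True)["sd_additive"].mean()
        assert sds.max() / sds.min() < 1.2
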