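"""Division classifiers: boundary semantics, invariances, co-segregation,
genotype summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tribekit import (
    classify_log2fc_pairs,
    classify_numb_pairs,
    cosegregation_table,
    score_polarity_cells,
    simulate_costained_pairs,
    simulate_daughter_pairs,
    simulate_polarity_cells,
    summarize_divisions,
)


def _pairs(i1, i2, genotype="WT", replicate=1):
    return pd.DataFrame(
        {"pair_id": [f"p{k}" for k in range(len(i1))], "genotype": genotype,
         "replicate": replicate, "marker": "NUMB", "i1": i1, "i2": i2}
    )


class TestNumbClassifier:
    def test_ratio_exactly_two_is_asymmetric(self):
        out = classify_numb_pairs(_pairs([100.0], [50.0]), high_threshold=60)
        assert out.iloc[0]["class"] == "asymmetric"

    def test_high_mean_symmetric_is_commitment(self):
        out = classify_numb_pairs(_pairs([80.0], [80.0]), high_threshold=50)
        assert out.iloc[0]["class"] == "sym_commitment"

    def test_low_mean_symmetric_is_renewal(self):
        out = classify_numb_pairs(_pairs([10.0], [12.0]), high_threshold=50)
        assert out.iloc[0]["class"] == "sym_renewal"

    def test_non_positive_intensity_rejected(self):
        with pytest.raises(ValueError, match="i2"):
            classify_numb_pairs(_pairs([10.0], [0.0]), high_threshold=50)

    def test_auto_threshold_is_per_replicate_median(self):
        df = pd.concat(
            [_pairs([10.0, 30.0, 100.0], [10.0, 30.0, 100.0], replicate=1),
             _pairs([1000.0, 3000.0, 5000.0], [1000.0, 3000.0, 5000.0], replicate=2)],
            ignore_index=True,
        )
        out = classify_numb_pairs(df)  # replicate medians: 30 and 3000
        assert list(out["class"]) == [
            "sym_renewal", "sym_commitment", "sym_commitment",
            "sym_renewal", "sym_commitment", "sym_commitment",
        ]

    @given(st.floats(min_value=0.01, max_value=1e4),
           st.floats(min_value=0.01, max_value=1e4))
    def test_swap_symmetry(self, a, b):
        thr = 100
        c1 = classify_numb_pairs(_pairs([a], [b]), high_threshold=thr).iloc[0]["class"]
        c2 = classify_numb_pairs(_pairs([b], [a]), high_threshold=thr).iloc[0]["class"]
        assert c1 == c2

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.01, max_value=50.0))
    def test_asymmetry_decision_scale_invariant(self, a, b, c):
        base = classify_numb_pairs(_pairs([a], [b]), high_threshold=1e12).iloc[0]["class"]
        scaled = classify_numb_pairs(_pairs([a * c], [b * c]), high_threshold=1e12).iloc[0]["class"]
        # with the high/low split disabled, the ratio rule alone decides
        assert (base == "asymmetric") == (scaled == "asymmetric")


class TestLog2fcClassifier:
    def test_boundary_inclusive_for_pairs(self):
        i2 = 100.0 * 2**0.6
        out = classify_log2fc_pairs(_pairs([100.0], [i2]), high_threshold=1e9)
        assert out.iloc[0]["class"] == "asymmetric"

    def test_equal_intensities_split_by_mean(self):
        high = classify_log2fc_pairs(_pairs([300.0], [300.0]), high_threshold=200)
        low = classify_log2fc_pairs(_pairs([100.0], [100.0]), high_threshold=200)
        assert high.iloc[0]["class"] == "sym_high"
        assert low.iloc[0]["class"] == "sym_low"

    def test_below_threshold_is_symmetric(self):
        out = classify_log2fc_pairs(_pairs([100.0], [140.0]), high_threshold=50)
        # log2(1.4) = 0.485 < 0.6
        assert out.iloc[0]["class"] == "sym_high"


class TestPolarity:
    def _cells(self, h1, h2):
        return pd.DataFrame({"cell_id": ["c"], "genotype": "WT", "h1": h1, "h2": h2})

    def test_equal_halves_unpolarized(self):
        assert not score_polarity_cells(self._cells([100.0], [100.0])).iloc[0]["polar"]

    def test_boundary_excluded_by_strict_inequality(self):
        out = score_polarity_cells(self._cells([100.0], [100.0 * 2**0.6]))
        assert not out.iloc[0]["polar"]

    def test_clear_difference_is_polar(self):
        out = score_polarity_cells(self._cells([100.0], [160.0]))
        assert out.iloc[0]["polar"]  # log2(1.6) = 0.678 > 0.6

    def test_non_positive_half_rejected(self):
        with pytest.raises(ValueError):
            score_polarity_cells(self._cells([100.0], [-1.0]))


class TestNoiselessRecovery:
    def test_confusion_matrix_exactly_diagonal(self):
        pairs = simulate_daughter_pairs(
            3000, mix=(0.4, 0.3, 0.3), noise_cv=0.0, seed=13
        )
        out = classify_numb_pairs(pairs, high_threshold=200.0)
        cm = pd.crosstab(out["true_class"], out["class"])
        off_diag = cm.to_numpy().sum() - np.trace(
            cm.reindex(index=cm.columns, columns=cm.columns).fillna(0).to_numpy()
        )
        assert off_diag == 0

    def test_polarity_noiseless_recovery(self):
        cells = simulate_polarity_cells(500, frac_polar=1.0, noise_sd=0.0, seed=2)
        out = score_polarity_cells(cells)
        assert out["polar"].all()
        cells0 = simulate_polarity_cells(500, frac_polar=0.0, seed=2)
        assert not score_polarity_cells(cells0)["polar"].any()


class TestCosegregation:
    def test_identical_markers_fully_concordant(self):
        df = simulate_costained_pairs(200, frac_asymmetric=1.0, coseg_prob=1.0,
                                      noise_cv=0.0, seed=1)
        df = classify_log2fc_pairs(df, high_threshold=1e9, out_col="class_m1")
        df = classify_log2fc_pairs(df, high_threshold=1e9,
                                   intensity_cols=("j1", "j2"), out_col="class_m2")
        res = cosegregation_table(df)
        assert res["concordance"] == 1.0

    def test_swapped_marker_fully_discordant(self):
        df = simulate_costained_pairs(200, frac_asymmetric=1.0, coseg_prob=0.0,
                                      noise_cv=0.0, seed=1)
        df = classify_log2fc_pairs(df, high_threshold=1e9, out_col="class_m1")
        df = classify_log2fc_pairs(df, high_threshold=1e9,
                                   intensity_cols=("j1", "j2"), out_col="class_m2")
        res = cosegregation_table(df)
        assert res["concordance"] == 0.0

    def test_generator_concordance_recovered(self):
        df = simulate_costained_pairs(500, frac_asymmetric=0.6, coseg_prob=0.8, seed=6)
        df = classify_log2fc_pairs(df, high_threshold=1e9, out_col="class_m1")
        df = classify_log2fc_pairs(df, high_threshold=1e9,
                                   intensity_cols=("j1", "j2"), out_col="class_m2")
        res = cosegregation_table(df)
        assert abs(res["concordance"] - 0.8) < 0.05
        assert res["fisher_p"] <= 1.0

    def test_no_doubly_asymmetric_pairs_reported_undefined(self):
        df = simulate_costained_pairs(50, frac_asymmetric=0.0, seed=3)
        df = classify_log2fc_pairs(df, high_threshold=1e9, out_col="class_m1")
        df = classify_log2fc_pairs(df, high_threshold=1e9,
                                   intensity_cols=("j1", "j2"), out_col="class_m2")
        res = cosegregation_table(df)
        assert np.isnan(res["concordance"])


class TestSummaries:
    def test_fractions_sum_to_one(self):
        pairs = simulate_daughter_pairs(300, seed=4, n_replicates=3)
        out = classify_numb_pairs(pairs, high_threshold=200.0)
        res = summarize_divisions(out)
        sums = res["fractions_by_replicate"].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_single_category_gives_fraction_one(self):
        pairs = simulate_daughter_pairs(100, mix=(1.0, 0.0, 0.0), noise_cv=0.0, seed=1)
        out = classify_numb_pairs(pairs, high_threshold=1e9)
        res = summarize_divisions(out)
        assert res["summary"][("sym_renewal", "mean")].iloc[0] == 1.0

    def test_single_replicate_skips_tests(self):
        pairs = pd.concat(
            [simulate_daughter_pairs(50, seed=1, genotype="WT"),
             simulate_daughter_pairs(50, seed=2, genotype="KO")],
            ignore_index=True,
        )
        out = classify_numb_pairs(pairs, high_threshold=200.0)
        res = summarize_divisions(out)
        assert res["tests"] is None and res["notice"] is not None

    def test_power_to_detect_mixture_shift(self):
        """5 replicates x 100 pairs per genotype: a 0.5 vs 0.7 shift in the
        first category is detected (p < 0.05) in >= 90% of 20 seeds."""
        detected = 0
        for seed in range(20):
            wt = classify_numb_pairs(
                simulate_daughter_pairs(500, (0.5, 0.25, 0.25), seed=seed * 2,
                                        genotype="WT", n_replicates=5),
                high_threshold=200.0,
            )
            ko = classify_numb_pairs(
                simulate_daughter_pairs(500, (0.7, 0.2, 0.1), seed=seed * 2 + 1,
                                        genotype="KO", n_replicates=5),
                high_threshold=200.0,
            )
            res = summarize_divisions(pd.concat([wt, ko], ignore_index=True))
            p = res["tests"].set_index("category").loc["sym_renewal", "p_value"]
            detected += p < 0.05
        assert detected >= 18
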