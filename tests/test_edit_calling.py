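"""Edit-caller unit and property tests: frequencies, Fisher test, thresholds,
annotation priority, gene summaries, BH behaviour."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tribekit import (
    EditSimConfig,
    annotate_sites,
    call_edits,
    compare_target_sets,
    simulate_edit_dataset,
    summarize_targets,
)
from tribekit import test_site as site_pvalue  # alias: keep pytest from collecting it
from tribekit.editcalls import apply_call_thresholds, compute_site_frequencies
from tribekit.stats import benjamini_hochberg, fisher_exact_two_sided


def _counts_frame(rows):
    """rows: (site_id, [(ref, alt) per sample S_ADAR_1, S_ADAR_2, EV_1, EV_2])"""
    recs = []
    for site_id, pairs in rows:
        rec = {"site_id": site_id, "gene": "g1", "chrom": "g1", "pos": 0, "strand": "+"}
        for (r, a), s in zip(pairs, ["S_ADAR_1", "S_ADAR_2", "EV_1", "EV_2"]):
            rec[f"ref_{s}"] = r
            rec[f"alt_{s}"] = a
        recs.append(rec)
    return pd.DataFrame(recs)


class TestFrequencies:
    def test_hand_examples(self):
        counts = _counts_frame([
            ("s1", [(10, 0), (5, 5), (7, 3), (14, 6)]),
        ])
        freqs, summary = compute_site_frequencies(counts)
        row = freqs.iloc[0]
        assert row["freq_S_ADAR_1"] == 0.0
        assert row["freq_S_ADAR_2"] == 0.5
        # unweighted mean: (3/10 + 6/20)/2 = 0.3 despite unequal depth
        assert summary.iloc[0]["f_ev"] == pytest.approx(0.3)
        assert summary.iloc[0]["f_adar"] == pytest.approx(0.25)

    def test_zero_depth_sample_excluded_from_mean(self):
        counts = _counts_frame([("s1", [(0, 0), (5, 5), (10, 0), (10, 0)])])
        _, summary = compute_site_frequencies(counts)
        assert summary.iloc[0]["f_adar"] == pytest.approx(0.5)
        assert summary.iloc[0]["n_samples_adar"] == 1

    def test_zero_depth_condition_flagged_untestable(self):
        counts = _counts_frame([("s1", [(0, 0), (0, 0), (10, 0), (10, 0)])])
        _, summary = compute_site_frequencies(counts)
        assert not summary.iloc[0]["testable"]

    def test_negative_counts_rejected(self):
        counts = _counts_frame([("s1", [(-1, 0), (5, 5), (10, 0), (10, 0)])])
        with pytest.raises(ValueError, match="non-negative"):
            compute_site_frequencies(counts)


def _oracle_fisher(a, b, c, d):
    """Independent oracle: enumerate the hypergeometric support with exact
    Fraction probabilities; two-sided p = total probability of tables no more
    probable than the observed one."""
    n1, n2, m = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, m)
    probs = {}
    for k in range(max(0, m - n2), min(m, n1) + 1):
        probs[k] = Fraction(comb(n1, k) * comb(n2, m - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_identical_pooled_counts_give_p_one(self):
        assert site_pvalue([4, 4], [6, 6], [4, 4], [6, 6]) == 1.0

    def test_example_table_matches_enumeration(self):
        p = site_pvalue([8], [2], [1], [9])
        assert p == pytest.approx(_oracle_fisher(8, 2, 1, 9), abs=1e-12)

    def test_depth_one_per_condition_is_powerless(self):
        # one read each: pooled table margins are 1/1, no table is extreme
        assert site_pvalue([1], [0], [0], [1]) >= 0.05

    def test_scipy_cross_check(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            ours = fisher_exact_two_sided(a, b, c, d)
            theirs = fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestCalling:
    def test_threshold_semantics(self):
        tested = pd.DataFrame(
            {
                "site_id": ["a", "b", "c", "d"],
                "delta_f": [0.15, 0.09, 0.15, 0.10],
                "q_value": [0.04, 0.04, 0.05, 0.04],
            }
        )
        called = apply_call_thresholds(tested, alpha=0.05, min_delta=0.1)
        # q<0.05 AND delta>0.1, both strict: only 'a' survives
        assert list(called["site_id"]) == ["a"]

    def test_empty_table_returns_empty_result(self):
        out = call_edits(pd.DataFrame())
        assert out.empty

    def test_depth_filter_excludes_shallow_sites(self):
        counts = _counts_frame([
            ("deep", [(10, 10), (10, 10), (20, 0), (20, 0)]),
            ("shallow", [(2, 2), (1, 1), (3, 0), (3, 0)]),
        ])
        tested = call_edits(counts, min_depth=10, return_all=True)
        assert list(tested["site_id"]) == ["deep"]

    def test_recovers_planted_sites(self):
        ds = simulate_edit_dataset(EditSimConfig(n_genes=300, effect_delta=0.4, seed=21))
        calls = call_edits(ds.counts)
        truth = ds.truth.set_index("site_id")["is_true_target"]
        called = set(calls["site_id"])
        true_sites = set(truth[truth].index)
        sens = len(called & true_sites) / len(true_sites)
        prec = len(called & true_sites) / max(len(called), 1)
        assert sens > 0.85 and prec > 0.9

    def test_betabinom_lrt_orders_effects(self):
        strong = site_pvalue([40, 38], [60, 62], [1, 0], [99, 100], method="betabinom_lrt")
        null = site_pvalue([2, 1], [98, 99], [1, 2], [99, 98], method="betabinom_lrt")
        assert 0 <= strong < 1e-4
        assert null > 0.05

    def test_output_sorted_by_q_then_delta(self, small_calls):
        q = small_calls["q_value"].to_numpy()
        assert (np.diff(q) >= 0).all()


class TestAnnotation:
    def _transcripts(self):
        return pd.DataFrame(
            {
                "gene": ["gA", "gA", "gA", "gB"],
                "transcript_id": ["gA.t1", "gA.t1", "gA.t2", "gB.t1"],
                "chrom": ["chr1"] * 4,
                "strand": ["+"] * 4,
                "region": ["5UTR", "CDS", "3UTR", "CDS"],
                "start": [0, 200, 150, 5000],
                "end": [200, 1100, 400, 6000],
            }
        )

    def _calls(self, pos):
        return pd.DataFrame(
            {
                "site_id": ["s1"], "gene": ["input_gene"], "chrom": ["chr1"],
                "pos": [pos], "strand": ["+"], "f_adar": [0.4], "f_ev": [0.0],
                "delta_f": [0.4], "p_value": [1e-6], "q_value": [1e-5],
            }
        )

    def test_unique_3utr_assignment(self):
        out = annotate_sites(self._calls(160), self._transcripts())
        assert out.iloc[0]["region"] == "3UTR"  # 3UTR of isoform 2 beats 5UTR of isoform 1

    def test_isoform_conflict_resolves_to_3utr(self):
        # pos 300: CDS of gA.t1 and 3UTR of gA.t2 -> 3UTR by priority
        out = annotate_sites(self._calls(300), self._transcripts())
        assert out.iloc[0]["region"] == "3UTR"

    def test_no_overlap_keeps_input_gene_with_region_other(self):
        out = annotate_sites(self._calls(4000), self._transcripts())
        assert out.iloc[0]["region"] == "other"
        assert out.iloc[0]["gene"] == "input_gene"

    def test_majority_of_true_calls_fall_in_3utr(self, small_calls):
        counts = small_calls["region"].value_counts()
        assert counts.get("3UTR", 0) > counts.get("CDS", 0)


class TestSummaries:
    def test_two_calls_one_gene(self):
        calls = pd.DataFrame(
            {
                "site_id": ["s1", "s2"], "gene": ["g", "g"],
                "q_value": [0.01, 0.002], "delta_f": [0.2, 0.3],
            }
        )
        table, hist = summarize_targets(calls)
        assert len(table) == 1
        assert table.iloc[0]["n_edit_sites"] == 2
        assert table.iloc[0]["best_q"] == 0.002
        assert table.iloc[0]["max_delta_f"] == 0.3
        assert hist.loc[2] == 1

    def test_shared_unique_partition(self):
        a = {f"g{i}" for i in range(796)}
        shared = set(list(a)[:534])
        b = shared | {f"h{i}" for i in range(71)}
        res = compare_target_sets(a, b)
        assert res == {"n_a": 796, "n_b": 605, "shared": 534, "a_only": 262, "b_only": 71}
        assert res["n_a"] == res["shared"] + res["a_only"]

    def test_sites_per_gene_mode_is_one_to_two(self, small_calls):
        _, hist = summarize_targets(small_calls)
        assert hist.idxmax() in (1, 2)


class TestBH:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_q_values_are_valid_and_monotone_in_sorted_p(self, ps):
        p = np.array(ps)
        q = benjamini_hochberg(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


def test_delta_f_invariant_to_depth_rescaling():
    """Doubling coverage leaves the mean delta_f estimate essentially unchanged."""
    means = []
    for cov in (100.0, 200.0):
        ds = simulate_edit_dataset(
            EditSimConfig(n_genes=800, coverage_mean=cov, effect_delta=0.3, seed=31)
        )
        _, summary = compute_site_frequencies(ds.counts)
        true_mask = ds.truth["is_true_target"].to_numpy()
        means.append(summary.loc[true_mask, "delta_f"].mean())
    assert abs(means[0] - means[1]) < 0.01
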