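"""Paired Wilcoxon, BH correction, and the crossover contrast machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from lipidcross import (
    Direction,
    Intervention,
    Layer,
    TrialConfig,
    Effect,
    between_contrast,
    bh_adjust,
    describe_features,
    generate_trial,
    prevalence_filter,
    class_totals,
    results_frame,
    volcano_table,
    wilcoxon_signed_rank,
    within_contrast,
)
from lipidcross.layers import species_table
from conftest import brute_force_bh, brute_force_wilcoxon_p, make_matrix


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank([(0.0, d) for d in (1, 2, 3, 4, 5)])
        assert res.exact
        assert res.p_value == pytest.approx(2 / 32, abs=0)

    def test_degenerate_all_zero_differences(self):
        res = wilcoxon_signed_rank([(1.0, 1.0)] * 6)
        assert res.degenerate and res.p_value == 1.0

    def test_no_pairs_returns_none(self):
        assert wilcoxon_signed_rank([]) is None
        assert wilcoxon_signed_rank([(float("nan"), 1.0)]) is None

    def test_zero_differences_discarded_before_ranking(self):
        with_zeros = wilcoxon_signed_rank([(1, 1), (0, 1), (0, 2), (0, 3), (0, 4), (0, 5)])
        without = wilcoxon_signed_rank([(0, 1), (0, 2), (0, 3), (0, 4), (0, 5)])
        assert with_zeros.n_used == 5
        assert with_zeros.p_value == without.p_value

    def test_matches_exhaustive_enumeration(self):
        """Exact p equals full 2^n sign-flip enumeration for n <= 12."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            d = rng.normal(size=n).round(3)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size or d.size == 0:
                continue
            res = wilcoxon_signed_rank([(0.0, x) for x in d])
            assert res.exact
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_statistic_is_min_rank_sum(self):
        # d = [+1, -2, +3]: ranks 1,2,3; W+ = 4, W- = 2 -> W = 2
        res = wilcoxon_signed_rank([(0, 1), (0, -2), (0, 3)])
        assert res.statistic == 2

    def test_ties_fall_back_to_normal_approximation(self):
        res = wilcoxon_signed_rank([(0, x) for x in (1, 1, 2, 3, 4, 5)])
        assert not res.exact
        assert 0 < res.p_value <= 1

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(0)
        res = wilcoxon_signed_rank([(0.0, x) for x in rng.normal(size=40)])
        assert not res.exact


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passes_through(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_step_up_formula_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_dominance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        # discoveries shrink as alpha shrinks
        counts = [(q < a).sum() for a in (0.2, 0.1, 0.05, 0.01)]
        assert counts == sorted(counts, reverse=True)

    def test_nan_passthrough_excluded_from_family(self):
        q = bh_adjust([0.01, float("nan"), 0.02])
        assert math.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], brute_force_bh(np.array([0.01, 0.02])))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def _crossover_matrix(values_before, values_after, n_subjects):
    """Single-species matrix with the given per-subject before/after values."""
    meta, data = [], []
    for i in range(n_subjects):
        for iv in ("eTRE", "lTRE"):
            meta.append((f"S{i}_{iv}_b", f"S{i}", iv, "before"))
            meta.append((f"S{i}_{iv}_a", f"S{i}", iv, "after"))
            data.extend([values_before[i], values_after[i]])
    return make_matrix({"PC 34:1;0": data}, meta)


class TestContrasts:
    def test_identical_before_after_is_null(self):
        mat = _crossover_matrix([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 5)
        res = within_contrast(species_table(mat), Intervention.ETRE)
        assert res[0].p_raw == 1.0
        assert res[0].fold_change == pytest.approx(1.0)
        assert res[0].degenerate

    def test_label_permutation_inverts_fold_change(self):
        before = [1.0, 2.0, 3.0, 4.0, 6.0, 8.0]
        after = [1.5, 2.2, 2.5, 5.0, 7.0, 8.5]
        fwd = within_contrast(
            species_table(_crossover_matrix(before, after, 6)), Intervention.ETRE
        )[0]
        rev = within_contrast(
            species_table(_crossover_matrix(after, before, 6)), Intervention.ETRE
        )[0]
        assert rev.fold_change == pytest.approx(1 / fwd.fold_change)
        assert rev.p_raw == fwd.p_raw
        assert rev.delta_mean == pytest.approx(-fwd.delta_mean)

    def test_underpowered_flag_and_no_crash_on_single_subject(self):
        mat = _crossover_matrix([1.0], [2.0], 1)
        res = within_contrast(species_table(mat), Intervention.ETRE)
        assert res[0].underpowered and res[0].n_pairs == 1
        assert 0 < res[0].p_raw <= 1
        between = between_contrast(species_table(mat))
        assert between[0].underpowered

    def test_within_detects_injected_class_effect(self):
        cfg = TrialConfig(
            n_subjects=30, seed=11,
            effects=[Effect(Intervention.ETRE, "Cer", 0.8)],
        )
        matrix, _ = generate_trial(cfg)
        filtered, _ = prevalence_filter(matrix)
        res = within_contrast(class_totals(filtered), Intervention.ETRE)
        cer = next(r for r in res if r.feature == "Cer")
        assert cer.q_bh < 0.05
        assert cer.fold_change < 1
        assert cer.direction is Direction.DOWN

    def test_between_null_when_same_effect_in_both_arms(self):
        cfg = TrialConfig(
            n_subjects=30, seed=5,
            effects=[
                Effect(Intervention.ETRE, "Cer", 0.8),
                Effect(Intervention.LTRE, "Cer", 0.8),
            ],
        )
        matrix, _ = generate_trial(cfg)
        filtered, _ = prevalence_filter(matrix)
        res = between_contrast(class_totals(filtered))
        assert all(r.q_bh >= 0.05 or math.isnan(r.q_bh) for r in res)

    def test_between_flags_one_arm_effect(self):
        cfg = TrialConfig(
            n_subjects=30, seed=13,
            effects=[Effect(Intervention.ETRE, "Cer", 0.7)],
        )
        matrix, _ = generate_trial(cfg)
        filtered, _ = prevalence_filter(matrix)
        res = between_contrast(class_totals(filtered))
        cer = next(r for r in res if r.feature == "Cer")
        assert cer.q_bh < 0.05
        # eTRE decreased, lTRE flat: FC_e/FC_l < 1
        assert cer.fold_change < 1

    def test_delta_ci_contains_mean(self):
        mat = _crossover_matrix([1, 2, 3, 4, 6, 8], [2, 2.5, 3.5, 5, 7, 9.5], 6)
        res = within_contrast(species_table(mat), Intervention.ETRE)[0]
        lo, hi = res.delta_ci95
        assert lo <= res.delta_mean <= hi


class TestVolcano:
    def test_columns_and_neg_log10(self):
        mat = _crossover_matrix([1, 2, 3, 4, 6], [2, 3, 4, 5, 7], 5)
        res = within_contrast(species_table(mat), Intervention.ETRE)
        vt = volcano_table(res)
        row = vt.iloc[0]
        assert row["neg_log10_p"] == pytest.approx(-math.log10(row["p_raw"]))
        p = 0.05
        assert -math.log10(p) == pytest.approx(1.30103, abs=1e-5)

    def test_threshold_absent_without_bh_significance(self):
        mat = _crossover_matrix([1, 2, 3], [1.1, 1.9, 3.2], 3)
        vt = volcano_table(within_contrast(species_table(mat), Intervention.ETRE))
        assert not vt["significant_bh"].any()
        assert vt["bh_threshold_p"].isna().all()

    def test_threshold_is_max_significant_raw_p(self):
        cfg = TrialConfig(
            n_subjects=30, seed=17, effects=[Effect(Intervention.ETRE, "Cer", 0.7)]
        )
        matrix, _ = generate_trial(cfg)
        filtered, _ = prevalence_filter(matrix)
        res = within_contrast(class_totals(filtered), Intervention.ETRE)
        vt = volcano_table(res)
        sig = vt[vt["significant_bh"]]
        assert len(sig) > 0
        assert vt["bh_threshold_p"].iloc[0] == pytest.approx(sig["p_raw"].max())

    def test_empty_results_give_header_only(self):
        vt = volcano_table([])
        assert vt.empty and "fold_change" in vt.columns


class TestDescribe:
    def test_mean_sd_median_iqr(self, four_sample_meta):
        mat = make_matrix({"PC 34:1;0": [1.0, 2.0, 3.0, 4.0]}, four_sample_meta)
        df = describe_features(species_table(mat))
        row = df.iloc[0]
        assert row["mean"] == pytest.approx(2.5)
        assert row["median"] == pytest.approx(2.5)
        assert row["sd"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert row["q25"] == pytest.approx(1.75)


class TestCoverage:
    def test_delta_ci_covers_injected_additive_effect(self):
        """95% CI on delta covers the true additive shift in >=93% of seeds."""
        hits = 0
        n_seeds = 200
        shift = 0.5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            before = np.exp(rng.normal(1.0, 0.3, size=30))
            after = before * np.exp(rng.normal(0.0, 0.1, size=30)) + shift
            mat = _crossover_matrix(before, after, 30)
            res = within_contrast(species_table(mat), Intervention.ETRE)[0]
            lo, hi = res.delta_ci95
            # true additive effect: E[after - before] = shift + E[b(e^z - 1)]
            true_delta = shift + np.mean(before * (np.exp(0.1 ** 2 / 2) - 1))
            if lo <= true_delta <= hi:
                hits += 1
        assert hits / n_seeds >= 0.93
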