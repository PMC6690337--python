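"""Production-coding reliability: filtering, accuracy, kappa, ICC."""

import numpy as np
import pandas as pd
import pytest

from tonetrain.reliability import (
    canonical_pinyin,
    cicchetti_label,
    cohen_kappa,
    derive_accuracy,
    filter_unusable,
    icc_average,
    landis_koch_label,
)


def _rating_records(n_trials, zero_trials=(), subjects=None):
    rows = []
    for rater in (1, 2):
        for i in range(n_trials):
            rows.append(
                {
                    "trial_id": f"t{i:05d}",
                    "subject_id": subjects[i] if subjects else "S001",
                    "task": "repetition",
                    "session": "pre",
                    "rater_id": rater,
                    "tone_label": 0 if (i in zero_trials and rater == 1) else 2,
                    "rating": 4,
                    "transcription": "ma",
                    "target_tone": 2,
                    "target_transcription": "ma",
                }
            )
    return pd.DataFrame(rows)


class TestFilterUnusable:
    def test_planted_zero_codes_percentage(self):
        records = _rating_records(1000, zero_trials=range(50))
        usable, stats = filter_unusable(records)
        assert stats.count == 50
        assert stats.denominator == 1000
        assert stats.percent == 5.00
        assert usable["trial_id"].nunique() == 950

    def test_no_zero_codes(self):
        _, stats = filter_unusable(_rating_records(100))
        assert stats.percent == 0.00

    def test_excluded_subject_counts_toward_removal(self):
        subjects = ["S001"] * 90 + ["S002"] * 10
        records = _rating_records(100, subjects=subjects)
        usable, stats = filter_unusable(records, excluded_subjects=("S002",))
        assert stats.count == 10
        assert "S002" not in set(usable["subject_id"])

    def test_empty_input(self):
        usable, stats = filter_unusable(pd.DataFrame())
        assert usable.empty and stats.denominator == 0

    def test_percent_recomputable_from_filtered_table(self):
        records = _rating_records(400, zero_trials=range(13))
        usable, stats = filter_unusable(records)
        removed = records["trial_id"].nunique() - usable["trial_id"].nunique()
        assert round(100 * removed / stats.denominator, 2) == stats.percent


class TestDeriveAccuracy:
    def test_tone_match(self):
        records = _rating_records(10)
        acc = derive_accuracy(records, "tone")
        assert acc["correct"].eq(1).all()  # label 2 vs target 2

    def test_pinyin_one_character_error_scores_zero(self):
        records = _rating_records(4)
        records.loc[records["rater_id"] == 2, "transcription"] = ["mao", "ma", "max", "ma"]
        acc = derive_accuracy(records, "pinyin")
        assert list(acc["correct"]) == [0, 1, 0, 1]

    def test_canonicalisation_strips_tone_marks_and_case(self):
        assert canonical_pinyin("  Mǎo3 ") == "mao"
        assert canonical_pinyin("ma") != canonical_pinyin("mao")

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="measure"):
            derive_accuracy(_rating_records(3), "prosody")


class TestCohenKappa:
    def test_identical_vectors(self):
        assert cohen_kappa([1, 2, 3, 4] * 5, [1, 2, 3, 4] * 5).value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # counts: 40 agree-A, 10 A/B, 10 B/A, 40 agree-B
        # p_o = 0.8, p_e = 0.5, kappa = 0.6
        r1 = ["A"] * 40 + ["A"] * 10 + ["B"] * 10 + ["B"] * 40
        r2 = ["A"] * 40 + ["B"] * 10 + ["A"] * 10 + ["B"] * 40
        res = cohen_kappa(r1, r2)
        assert res.value == pytest.approx(0.6, abs=1e-12)
        assert res.label == "moderate agreement"

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 5, 200)
        b = rng.integers(1, 5, 200)
        assert cohen_kappa(a, b).value == pytest.approx(cohen_kappa(b, a).value)
        perm = rng.permutation(200)
        assert cohen_kappa(a[perm], b[perm]).value == pytest.approx(cohen_kappa(a, b).value)

    def test_kappa_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 4, 300)
        b = np.where(rng.random(300) < 0.7, a, rng.integers(1, 4, 300))
        p_o = (a == b).mean()
        assert cohen_kappa(a, b).value <= p_o + 1e-12

    def test_constant_raters_undefined(self):
        with pytest.raises(ValueError, match="single category"):
            cohen_kappa([1, 1, 1], [1, 1, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            cohen_kappa([1, 2], [1, 2, 3])

    @pytest.mark.parametrize(
        "kappa,label",
        [(0.39, "fair agreement"), (0.33, "fair agreement"),
         (0.67, "substantial agreement"), (0.53, "moderate agreement"),
         (0.95, "almost perfect agreement"), (-0.1, "poor agreement")],
    )
    def test_landis_koch_bands(self, kappa, label):
        assert landis_koch_label(kappa) == label


class TestICC:
    def test_identical_columns_give_unity(self):
        mat = pd.DataFrame({"r1": [1.0, 2, 3, 5, 6], "r2": [1.0, 2, 3, 5, 6]})
        res = icc_average(mat)
        assert res.value == pytest.approx(1.0)
        assert res.label == "excellent"

    def test_matches_mean_square_hand_computation(self):
        mat = pd.DataFrame({"r1": [1.0, 2.0, 3.0, 4.0], "r2": [2.0, 4.0, 3.0, 6.0]})
        res = icc_average(mat)
        # two-way ANOVA mean squares, computed independently
        x = mat.to_numpy()
        n, k = x.shape
        grand = x.mean()
        ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
        ms_err = sse / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / ms_rows
        assert res.value == pytest.approx(expected, abs=1e-10)

    def test_noise_strictly_decreases_icc(self):
        rng = np.random.default_rng(3)
        base = rng.normal(4, 1.5, 60)
        clean = pd.DataFrame({"r1": base, "r2": base})
        noisy = pd.DataFrame({"r1": base, "r2": base + rng.normal(0, 1.0, 60)})
        assert icc_average(noisy).value < icc_average(clean).value

    def test_zero_between_item_variance_undefined(self):
        mat = pd.DataFrame({"r1": [3.0, 3.0, 3.0], "r2": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="between-item variance"):
            icc_average(mat)

    def test_listwise_deletion_requirement(self):
        mat = pd.DataFrame({"r1": [1.0, np.nan], "r2": [2.0, 3.0]})
        with pytest.raises(ValueError, match=">=2 items"):
            icc_average(mat)

    @pytest.mark.parametrize(
        "icc,label",
        [(0.22, "poor"), (0.37, "poor"), (0.45, "fair"), (0.65, "good"), (0.80, "excellent")],
    )
    def test_cicchetti_bands(self, icc, label):
        assert cicchetti_label(icc) == label
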