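import numpy as np
import pytest

from eogstage import reference_tables as ref
from eogstage.agreement import (
    ConfusionTable,
    bland_altman,
    confusion_matrix,
    icc,
    onset_difference_bin,
    per_stage_kappa,
    percent_agreement,
    reconstruct_counts,
    sensitivity_ppv,
    sleep_onset,
    sleep_summary,
)
from eogstage.io import STAGES, Hypnogram, RespiratoryEventList


def random_table(rng, low=0, high=200):
    t = rng.integers(low, high, size=(5, 5))
    if t.sum() == 0:
        t[0, 0] = 1
    return ConfusionTable(counts=t)


class TestConfusionMatrix:
    def test_identical_hypnograms_give_diagonal(self, hypnogram_factory, rng):
        stages = list(rng.choice(STAGES, size=200))
        h = hypnogram_factory(stages)
        table = confusion_matrix(h, hypnogram_factory(stages))
        assert np.all(table.counts == np.diag(np.diag(table.counts)))

    def test_single_off_diagonal_cell(self, hypnogram_factory):
        manual = hypnogram_factory(["W"] * 10)
        auto = hypnogram_factory(["N1"] * 10)
        table = confusion_matrix(manual, auto)
        assert table.counts[0, 1] == 10 and table.total == 10

    def test_epoch_conservation(self, hypnogram_factory, rng):
        m = hypnogram_factory(list(rng.choice(STAGES, size=321)))
        a = hypnogram_factory(list(rng.choice(STAGES, size=321)))
        assert confusion_matrix(m, a).total == 321

    def test_length_mismatch_rejected(self, hypnogram_factory):
        with pytest.raises(ValueError):
            confusion_matrix(hypnogram_factory(["W"] * 3), hypnogram_factory(["W"] * 4))


def kappa_2x2_oracle(counts: np.ndarray, s: int) -> float:
    """Direct binary-kappa formula, coded independently of the library."""
    n = counts.sum()
    tp = counts[s, s]
    fn = counts[s].sum() - tp
    fp = counts[:, s].sum() - tp
    tn = n - tp - fn - fp
    po = (tp + tn) / n
    p_yes = ((tp + fn) / n) * ((tp + fp) / n)
    p_no = ((fp + tn) / n) * ((fn + tn) / n)
    pe = p_yes + p_no
    return 0.0 if pe >= 1 else (po - pe) / (1 - pe)


class TestPerStageKappa:
    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(300):
            table = random_table(rng)
            for s, stage in enumerate(STAGES):
                assert per_stage_kappa(table, stage) == pytest.approx(
                    kappa_2x2_oracle(table.counts, s), abs=1e-12
                )

    def test_matches_sklearn_on_binarized_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score

        labels_m = rng.choice(STAGES, size=500)
        labels_a = rng.choice(STAGES, size=500)
        table = confusion_matrix(
            Hypnogram(stages=list(labels_m)), Hypnogram(stages=list(labels_a))
        )
        for stage in STAGES:
            expected = cohen_kappa_score(labels_m == stage, labels_a == stage)
            assert per_stage_kappa(table, stage) == pytest.approx(expected, abs=1e-12)

    def test_perfect_agreement_gives_one(self):
        table = ConfusionTable(counts=np.diag([10, 10, 10, 10, 10]))
        assert all(per_stage_kappa(table, s) == pytest.approx(1.0) for s in STAGES)

    def test_independent_margins_give_zero(self):
        row = np.array([40, 10, 30, 10, 10])
        col = np.array([20, 20, 20, 20, 20])
        product = np.outer(row, col)  # exact independence
        table = ConfusionTable(counts=product)
        for stage in STAGES:
            assert per_stage_kappa(table, stage) == pytest.approx(0.0, abs=1e-12)

    def test_constant_raters_give_zero(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 100
        assert per_stage_kappa(ConfusionTable(counts=counts), "W") == 0.0


class TestPercentAgreement:
    def test_diagonal_table_all_hundred(self):
        table = ConfusionTable(counts=np.diag([5, 5, 5, 5, 5]))
        rows, overall = percent_agreement(table)
        assert overall == 100.0
        assert all(r[i] == 100.0 for i, r in enumerate(rows.values()))

    def test_rows_normalize_to_hundred(self, rng):
        table = random_table(rng, low=1)
        rows, _ = percent_agreement(table)
        for r in rows.values():
            assert sum(r) == pytest.approx(100.0)

    def test_zero_row_reported_as_nan_not_raised(self):
        counts = np.zeros((5, 5), int)
        counts[0, 0] = 10
        rows, _ = percent_agreement(ConfusionTable(counts=counts))
        assert np.isnan(rows["N1"]).all()


class TestReconstructCounts:
    def test_wake_row_of_published_group_table(self):
        table = reconstruct_counts(ref.NORMAL_MILD_ROW_PCT, ref.NORMAL_MILD_ROW_TOTALS)
        assert table.counts[0, 0] == round(0.797 * 7342)  # 5852
        assert np.array_equal(table.row_totals(), ref.NORMAL_MILD_ROW_TOTALS)

    def test_reconstructed_auto_wake_margin_close_to_published(self):
        table = reconstruct_counts(ref.NORMAL_MILD_ROW_PCT, ref.NORMAL_MILD_ROW_TOTALS)
        assert abs(table.col_totals()[0] - ref.NORMAL_MILD_AUTO_TOTALS[0]) <= 5

    def test_exact_percentages(self):
        pct = np.zeros((5, 5))
        pct[:, 0] = 100.0
        table = reconstruct_counts(pct, np.array([10, 1, 1, 1, 1]))
        assert table.counts[0, 0] == 10 and table.counts[0, 1:].sum() == 0

    def test_bad_row_sum_rejected(self):
        pct = np.full((5, 5), 10.0)  # rows sum to 50
        with pytest.raises(ValueError):
            reconstruct_counts(pct, np.array([10] * 5))


class TestIcc:
    def test_identity_pairs_give_one(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        assert icc(x, x) == pytest.approx(1.0)

    def test_constant_offset_penalized_for_absolute_agreement(self):
        x = np.array([10.0, 20.0, 30.0])
        y = x + 100.0
        val = icc(x, y)
        assert val < 0.2  # Pearson r would be 1

    def test_hand_computed_four_pair_example(self):
        # mean squares computed by hand for this table
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 2.0, 6.0])
        data = np.column_stack([x, y])
        grand = data.mean()
        msr = 2 * ((data.mean(1) - grand) ** 2).sum() / 3
        msc = 4 * ((data.mean(0) - grand) ** 2).sum() / 1
        mse = (((data - data.mean(1, keepdims=True) - data.mean(0) + grand) ** 2).sum()) / 3
        expected = (msr - mse) / (msr + mse + 2 * (msc - mse) / 4)
        assert icc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_oracle(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(300, 40, size=12)
        y = x + rng.normal(-10, 15, size=12)
        frame = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["m", "a"], 12),
                "value": np.column_stack([x, y]).reshape(-1),
            }
        )
        res = pg.intraclass_corr(frame, targets="subject", raters="rater", ratings="value")
        expected = float(res.loc[res["Type"].str.contains("A,1"), "ICC"].iloc[0])
        assert icc(x, y) == pytest.approx(expected, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestSensitivityPpv:
    def test_perfect_agreement(self, hypnogram_factory):
        h = hypnogram_factory(["N3"] * 25 + ["W"] * 5)
        assert sensitivity_ppv(h, h, "N3") == (100.0, 100.0)

    def test_under_minimum_excluded(self, hypnogram_factory):
        manual = hypnogram_factory(["N3"] * 19 + ["W"] * 11)
        assert sensitivity_ppv(manual, manual, "N3") is None

    def test_stage_never_emitted_by_auto(self, hypnogram_factory):
        manual = hypnogram_factory(["N3"] * 25)
        auto = hypnogram_factory(["N2"] * 25)
        sens, ppv = sensitivity_ppv(manual, auto, "N3")
        assert sens == 0.0 and np.isnan(ppv)


class TestSleepOnset:
    @pytest.mark.parametrize(
        "stages,expected",
        [
            (["W", "W", "N1", "N1", "N1", "W"], 2),
            (["W"] * 6, None),
            (["N1", "W", "N1", "N1", "W", "N1"], None),
            (["N1", "N2", "N3", "W"], 0),
        ],
    )
    def test_three_consecutive_nonwake_rule(self, hypnogram_factory, stages, expected):
        assert sleep_onset(hypnogram_factory(stages)) == expected

    def test_invariant_to_appending_after_onset(self, hypnogram_factory, rng):
        stages = ["W", "W", "N1", "N2", "N2"]
        onset = sleep_onset(hypnogram_factory(stages))
        extended = stages + list(rng.choice(STAGES, size=50))
        assert sleep_onset(hypnogram_factory(extended)) == onset


class TestOnsetBins:
    @pytest.mark.parametrize(
        "manual,auto,expected",
        [
            (10, 10, "<=3"),
            (10, 16, "<=3"),      # 3.0 min difference is inclusive
            (10, 30, "4-10"),     # 10.0 min sits in the 4-10 bin
            (10, 51, ">20"),      # 20.5 min
            (10, 50, "11-20"),    # exactly 20 min
        ],
    )
    def test_boundaries(self, manual, auto, expected):
        assert onset_difference_bin(manual, auto) == expected

    def test_undefined_onset_flagged(self):
        assert onset_difference_bin(None, 5) is None


class TestSleepSummary:
    def test_tst_and_efficiency_arithmetic(self, hypnogram_factory):
        stages = ["N2"] * 600 + ["W"] * 120
        s = sleep_summary(hypnogram_factory(stages), recording_minutes=360.0)
        assert s.tst_min == 300.0
        assert s.sleep_efficiency_pct == pytest.approx(100 * 300 / 360)

    def test_rdi_arithmetic(self, hypnogram_factory):
        stages = ["N2"] * 600 + ["W"] * 120
        events = RespiratoryEventList(total_count=150)
        s = sleep_summary(hypnogram_factory(stages), 360.0, events)
        assert s.rdi == pytest.approx(30.0)

    def test_all_wake_flags_rdi(self, hypnogram_factory):
        s = sleep_summary(hypnogram_factory(["W"] * 10), events=RespiratoryEventList(total_count=5))
        assert s.tst_min == 0 and np.isnan(s.rdi)

    def test_short_recording_rejected(self, hypnogram_factory):
        with pytest.raises(ValueError):
            sleep_summary(hypnogram_factory(["W"] * 10), recording_minutes=2.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        pairs = np.array([[300.0, 300.0], [400.0, 400.0]])
        res = bland_altman(pairs)
        assert res.bias == 0 and res.lower == res.upper == 0

    def test_constant_offset(self):
        pairs = np.array([[300.0, 305.0], [400.0, 405.0], [350.0, 355.0]])
        res = bland_altman(pairs)
        assert res.bias == pytest.approx(5.0) and res.sd_diff == pytest.approx(0.0)

    def test_matches_mean_sd_oracle(self, rng):
        manual = rng.normal(310, 30, size=40)
        auto = manual + rng.normal(-8, 27.4, size=40)
        res = bland_altman(np.column_stack([manual, auto]))
        diff = auto - manual
        assert res.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert res.sd_diff == pytest.approx(diff.std(ddof=1), abs=1e-12)
        assert res.upper == pytest.approx(diff.mean() + 2 * diff.std(ddof=1), abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([[1.0, 2.0]]))
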