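"""Behavioral statistics: binning, the z-test, criteria, calls, groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from obslearn.behavior import (
    BinStats,
    GoNogoDiscrimination,
    UndefinedStatisticError,
    bin_stats,
    bin_trials,
    call_rate_stats,
    criterion_scan,
    cumulative_escape_curves,
    daily_criterion,
    group_compare,
    load_trials,
    proportion_ztest,
)


def make_trials(escapes_puffed, escapes_unpuffed, n_per_class=50, day=1, start=1):
    """One balanced bin with the given escape counts per class."""
    rows = []
    idx = start
    for cls, n, k in (
        ("puffed", n_per_class, escapes_puffed),
        ("unpuffed", n_per_class, escapes_unpuffed),
    ):
        for i in range(n):
            rows.append((idx, "S_1", cls, i < k, day))
            idx += 1
    return pd.DataFrame(
        rows, columns=["index", "stimulus_id", "class", "escape", "day"]
    )


def flags_to_binstats(flags):
    return [
        BinStats(i + 1, 50, 50, 1.0, 0.0, 1.0, 6.0, 1e-9 if f else 0.5, bool(f))
        for i, f in enumerate(flags)
    ]


class TestBinTrials:
    @pytest.mark.parametrize(
        "n,bin_size,full,partial",
        [(800, 100, 8, 0), (850, 100, 8, 1), (800, 200, 4, 0), (0, 100, 0, 0)],
    )
    def test_bin_counts(self, n, bin_size, full, partial):
        df = pd.DataFrame(
            {
                "index": range(1, n + 1),
                "stimulus_id": "S_1",
                "class": "puffed",
                "escape": False,
                "day": 1,
            }
        )
        bins = bin_trials(df, bin_size)
        assert sum(1 for _, p in bins if not p) == full
        assert sum(1 for _, p in bins if p) == partial


class TestZTest:
    def test_null_identity(self):
        z, p = proportion_ztest(20, 50, 20, 50)
        assert z == 0.0 and p == 1.0

    def test_worked_example_against_hand_transcription(self):
        """40/50 vs 10/50 escapes: dPesc = 0.6; frozen values from a direct
        hand transcription of the printed formulas (pooled p = 0.5,
        sigma = 0.1; printed continuity term vanishes for balanced bins,
        textbook term is 0.02)."""
        s = bin_stats(make_trials(40, 10))
        assert s.dPesc == pytest.approx(0.6)
        assert s.z_stat == pytest.approx(6.0)
        assert s.p_value == pytest.approx(2 * sps.norm.sf(6.0))
        assert s.significant
        z_y, _ = proportion_ztest(40, 50, 10, 50, correction="yates")
        assert z_y == pytest.approx(5.8)

    def test_degenerate_pooled_proportion(self):
        for k in (0, 50):
            s = bin_stats(make_trials(k, k))
            assert s.p_value == 1.0 and not s.significant

    def test_undefined_when_class_missing(self):
        df = make_trials(5, 0).query("`class` == 'puffed'")
        with pytest.raises(UndefinedStatisticError):
            bin_stats(df)

    def test_printed_correction_matches_formula_unbalanced(self):
        kT, nT, kF, nF = 30, 60, 10, 40
        z, _ = proportion_ztest(kT, nT, kF, nF, correction="printed")
        PT, PF = kT / nT, kF / nF
        p = (kT + kF) / (nT + nF)
        sig = np.sqrt(p * (1 - p) * (nT + nF) / (nT * nF))
        expect = (abs(PT - PF) - (nT - nF) / (2 * nT * nF)) / sig
        assert z == pytest.approx(expect)

    @given(
        kT=st.integers(0, 50),
        kF=st.integers(0, 50),
        corr=st.sampled_from(["printed", "yates", "none"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_label_swap_symmetry(self, kT, kF, corr):
        """Swapping puffed/unpuffed leaves |Z| and p unchanged (balanced)."""
        z1, p1 = proportion_ztest(kT, 50, kF, 50, correction=corr)
        z2, p2 = proportion_ztest(kF, 50, kT, 50, correction=corr)
        assert z1 == pytest.approx(z2)
        assert p1 == pytest.approx(p2)

    def test_uncorrected_matches_statsmodels(self):
        """Cross-check the uncorrected z statistic against the standard
        pooled two-proportion test."""
        from statsmodels.stats.proportion import proportions_ztest

        z, p = proportion_ztest(34, 50, 19, 50, correction="none")
        z_sm, p_sm = proportions_ztest([34, 19], [50, 50])
        assert z == pytest.approx(abs(z_sm))
        assert p == pytest.approx(p_sm)


class TestCriterionScan:
    def test_immediate_learner_takes_800_trials(self):
        report = criterion_scan(flags_to_binstats([1] * 10))
        assert report.reached and report.criterion_bin == 8
        assert report.trials_to_criterion == 800

    def test_seven_of_eight_with_gap(self):
        report = criterion_scan(flags_to_binstats([1, 1, 1, 0, 1, 1, 1, 1]))
        assert report.reached and report.criterion_bin == 8

    def test_never_significant(self):
        report = criterion_scan(flags_to_binstats([0] * 20))
        assert not report.reached and report.trials_to_criterion is None

    def test_too_few_bins(self):
        assert not criterion_scan(flags_to_binstats([1] * 7)).reached

    def test_robustness_variants(self):
        flags = [0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
        four_of_four = criterion_scan(flags_to_binstats(flags), window=4, required=4)
        assert four_of_four.trials_to_criterion == 600
        big_bins = criterion_scan(
            flags_to_binstats(flags), bin_size=200, window=4, required=4
        )
        assert big_bins.trials_to_criterion == 1200

    @given(data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotonicity_in_significance(self, data):
        """Promoting a non-significant bin to significant never delays the
        criterion."""
        flags = data.draw(st.lists(st.booleans(), min_size=8, max_size=25))
        before = criterion_scan(flags_to_binstats(flags)).trials_to_criterion
        falses = [i for i, f in enumerate(flags) if not f]
        if not falses:
            return
        i = data.draw(st.sampled_from(falses))
        flags[i] = True
        after = criterion_scan(flags_to_binstats(flags)).trials_to_criterion
        if before is not None:
            assert after is not None and after <= before

    def test_partial_bins_excluded(self):
        bins = flags_to_binstats([1] * 8)
        bins[-1] = BinStats(8, 25, 25, 1.0, 0.0, 1.0, 6.0, 1e-9, True, partial=True)
        assert not criterion_scan(bins).reached


class TestDailyCriterion:
    def _daily(self, sig_days, n_days=10):
        frames = []
        start = 1
        for d in range(1, n_days + 1):
            k = 40 if d in sig_days else 20
            df = make_trials(k, 20, day=d, start=start)
            start += len(df)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_consecutive_pair(self):
        assert daily_criterion(self._daily({3, 4})) == 4

    def test_first_consecutive_pair_wins(self):
        assert daily_criterion(self._daily({2, 5, 7, 8})) == 8

    def test_no_pair(self):
        assert daily_criterion(self._daily({2, 5, 9})) is None

    def test_requires_positive_dpesc(self):
        """Days significant in the wrong direction do not count."""
        frames = [make_trials(10, 40, day=d, start=1 + (d - 1) * 100) for d in (1, 2)]
        assert daily_criterion(pd.concat(frames, ignore_index=True)) is None


class TestEscapeCurves:
    def test_curves_end_at_escape_rates(self):
        df = make_trials(40, 10)
        rng = np.random.default_rng(0)
        df["escape_latency_s"] = np.where(df["escape"], rng.uniform(0, 6, len(df)), np.nan)
        curves = cumulative_escape_curves(df)
        assert curves["puffed"][1][-1] == pytest.approx(0.8)
        assert curves["unpuffed"][1][-1] == pytest.approx(0.2)
        for times, cum in curves.values():
            assert np.all(np.diff(cum) >= 0)
            assert np.all(np.diff(times) >= 0)

    def test_no_escapes_gives_empty_curve(self):
        df = make_trials(0, 0)
        df["escape_latency_s"] = np.nan
        curves = cumulative_escape_curves(df)
        assert len(curves["puffed"][0]) == 0

    def test_missing_latency_column_reported(self):
        with pytest.raises(ValueError):
            cumulative_escape_curves(make_trials(5, 5))


class TestCallRates:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["trial", "class", "stim_call", "delay_call"])

    def test_identical_flags_give_zero_difference(self):
        rows = [(i, "puffed", True, True) for i in range(40)]
        rows += [(i + 40, "unpuffed", False, False) for i in range(40)]
        res = call_rate_stats(self._calls(rows))
        assert np.allclose(res.per_class["difference"], 0.0)
        assert np.allclose(res.per_class["p_value"], 1.0)

    def test_programmed_half_suppression(self):
        """Delay calls on half the puffed trials, stimulus calls on all:
        the puffed difference is exactly -0.5."""
        rows = [(i, "puffed", True, i % 2 == 0) for i in range(100)]
        res = call_rate_stats(self._calls(rows))
        row = res.per_class.set_index("class").loc["puffed"]
        assert row["difference"] == pytest.approx(-0.5)
        assert row["p_value"] < 0.01

    def test_recovers_programmed_rates_with_stimulus_breakdown(self):
        from obslearn import simulate_calls

        df = simulate_calls(
            4000,
            p_stim_call={"puffed": 0.44, "unpuffed": 0.35},
            p_delay_call={"puffed": 0.27, "unpuffed": 0.36},
            seed=3,
        )
        res = call_rate_stats(df)
        per = res.per_class.set_index("class")
        assert per.loc["puffed", "difference"] == pytest.approx(-0.17, abs=0.05)
        assert per.loc["unpuffed", "difference"] == pytest.approx(0.01, abs=0.05)
        assert res.per_stimulus is not None
        assert set(res.per_stimulus["stimulus_id"]) == {f"S_{k}" for k in range(1, 11)}


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.median_difference == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.exact  # shared values are ties

    def test_extreme_separation_exact_p(self):
        """For n=3 vs 3 without ties the minimal attainable two-sided exact
        p is 2/20 = 0.1 (all 20 rank assignments enumerated by the exact
        null distribution)."""
        res = group_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.exact
        assert res.p_value == pytest.approx(0.1)
        assert res.median_difference == -9.0

    def test_one_sided_alternative(self):
        res = group_compare([10.0, 11.0, 12.0], [1.0, 2.0, 3.0], alternative="greater")
        assert res.p_value == pytest.approx(0.05)

    def test_ties_flagged_not_exact(self):
        res = group_compare([1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0])
        assert not res.exact

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestModelResults:
    def test_pipeline_on_perfect_bird(self):
        from obslearn import perfect_discriminator_log

        model = GoNogoDiscrimination(perfect_discriminator_log(1000, seed=1))
        res = model.fit()
        assert res.trials_to_criterion == 800
        assert res.bins["significant"].all()
        assert res.dpesc_at_criterion() == pytest.approx(1.0)
        assert "trials to criterion:  800" in res.summary()

    def test_unsorted_trials_rejected(self):
        df = make_trials(10, 10)
        df = df.iloc[::-1]
        with pytest.raises(ValueError):
            GoNogoDiscrimination(df)

    def test_single_class_bin_reported_not_significant(self):
        df = make_trials(10, 10, n_per_class=50)
        df.loc[:, "class"] = "puffed"
        res = GoNogoDiscrimination(df).fit()
        assert not res.bins["significant"].any()
        assert np.isnan(res.bins["dPesc"]).all()

    def test_csv_round_trip(self, tmp_path):
        from obslearn import simulate_bird, BirdProfile

        df = simulate_bird(BirdProfile(n_trials=500, seed=2))
        path = tmp_path / "trials.csv"
        df.to_csv(path, index=False)
        back = load_trials(path)
        pd.testing.assert_frame_equal(back, df)
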