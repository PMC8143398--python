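import numpy as np
import pandas as pd
import pytest

from psyfi.angles import signed_diff_deg
from psyfi.inference import (BootstrapResult, bootstrap_contrast,
                             bootstrap_statistic, combined_participant,
                             flexibility_regression, rt_summary,
                             within_block_trends)
from psyfi.io import Dataset, EmptyDatasetError
from psyfi.observer import CohortSpec, simulate_cohort

from conftest import simulate_observer_dataset


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(n_observers={"NT": 4, "ASD": 3}, trials_per_block=60,
                      rng_seed=17)
    return simulate_cohort(spec)


def stat_mean_error(ds: Dataset) -> float:
    return float(np.mean(signed_diff_deg(ds.response_deg, ds.target_deg)))


class TestCombinedParticipant:
    def test_pools_all_group_block_trials(self, small_cohort):
        pooled = combined_participant(small_cohort, "NT", "woFB")
        assert len(pooled) == 4 * 60
        assert pooled.participants() == ["combined_NT"]

    def test_empty_selection_raises(self, small_cohort):
        empty = small_cohort.select(group="NT")
        with pytest.raises(EmptyDatasetError):
            combined_participant(empty, "ASD", "woFB")

    def test_order_invariance_of_downstream_statistic(self, small_cohort):
        pooled = combined_participant(small_cohort, "NT", "woFB")
        shuffled = Dataset(pooled.frame.sample(frac=1.0, random_state=1)
                           .reset_index(drop=True))
        assert stat_mean_error(pooled) == pytest.approx(stat_mean_error(shuffled))


class TestBootstrap:
    def test_constant_statistic_zero_width(self, small_cohort):
        res = bootstrap_statistic(small_cohort, lambda ds: 3.14, n_reps=50,
                                  seed=0)
        assert res.ci95 == (pytest.approx(3.14), pytest.approx(3.14))
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility(self, small_cohort):
        r1 = bootstrap_statistic(small_cohort, stat_mean_error, 100, seed=5)
        r2 = bootstrap_statistic(small_cohort, stat_mean_error, 100, seed=5)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_p_value_floored_and_sign_invariant(self, small_cohort):
        res = bootstrap_statistic(small_cohort, lambda ds: 1.0 + 0 * len(ds),
                                  n_reps=200, seed=1)
        assert res.p_two_sided >= 1.0 / 201
        flipped = BootstrapResult(statistic_name="neg", point=-res.point,
                                  samples=-res.samples, seed=res.seed)
        assert flipped.p_two_sided == res.p_two_sided

    def test_hierarchical_unit_resamples_participants(self, small_cohort):
        res = bootstrap_statistic(small_cohort, stat_mean_error, 25, seed=2,
                                  unit="participants")
        assert len(res.samples) == 25
        assert np.std(res.samples) > 0

    def test_contrast_delta_and_detection(self, small_cohort):
        a = combined_participant(small_cohort, "NT", "woFB")
        shifted = a.frame.copy()
        shifted["response_deg"] = (shifted["response_deg"] + 8.0) % 180
        b = Dataset(shifted)
        con = bootstrap_contrast(b, a, stat_mean_error, n_reps=300, seed=3)
        assert con.delta == pytest.approx(8.0, abs=0.5)
        assert con.p_two_sided < 0.01


class TestFlexibilityRegression:
    def test_collinear_points(self):
        tab = pd.DataFrame({"lam_woFB": [10.0, 12.0, 14.0, 16.0],
                            "omega_wFB2": [0.5, 0.45, 0.4, 0.35]})
        res = flexibility_regression(tab)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.025)

    def test_degenerate_regressor(self):
        tab = pd.DataFrame({"lam_woFB": [10.0] * 4,
                            "omega_wFB2": [0.5, 0.45, 0.4, 0.35]})
        with pytest.raises(ValueError, match="zero variance"):
            flexibility_regression(tab)

    def test_too_few_points(self):
        tab = pd.DataFrame({"lam_woFB": [10.0, 11.0],
                            "omega_wFB2": [0.5, 0.4]})
        with pytest.raises(ValueError):
            flexibility_regression(tab)


class TestWithinBlockTrends:
    def test_segments_cover_all_trials(self):
        ds = simulate_observer_dataset(14.0, 0.4, 200, seed=4)
        trends = within_block_trends(ds, "NT", "woFB", segment_length=100,
                                     segment_step=25, min_trials=50)
        assert trends["segment_start"].iloc[0] == 0
        assert trends["segment_stop"].iloc[-1] >= 200
        covered = np.zeros(200, dtype=bool)
        for row in trends.itertuples():
            covered[row.segment_start:row.segment_stop] = True
        assert covered.all()

    def test_declining_omega_recovered(self):
        # first half of the block simulated sharper than the second half
        parts = []
        for pid in range(8):
            first = simulate_observer_dataset(14.7, 0.6, 100, seed=100 + pid,
                                              pid=f"p{pid}")
            second = simulate_observer_dataset(14.7, 0.2, 100, seed=200 + pid,
                                               pid=f"p{pid}")
            second.frame["trial_index"] += 100
            parts.append(first.frame)
            parts.append(second.frame)
        ds = Dataset(pd.concat(parts, ignore_index=True))
        trends = within_block_trends(ds, "NT", "woFB", segment_length=100,
                                     segment_step=50)
        assert trends["omega"].iloc[0] > trends["omega"].iloc[-1] + 0.1

    def test_small_segments_error_names_minimum(self):
        ds = simulate_observer_dataset(14.0, 0.4, 60, seed=6)
        with pytest.raises(ValueError, match="at least 50"):
            within_block_trends(ds, "NT", "woFB", segment_length=20,
                                segment_step=20, min_trials=50)


class TestRTSummary:
    def test_median_of_known_values(self):
        frame = pd.DataFrame({
            "participant_id": "p", "group": "NT", "block": "woFB",
            "trial_index": [0, 1, 2], "target_deg": [10.0, 20.0, 30.0],
            "response_deg": [10.0, 20.0, 30.0], "rt_s": [1.0, 2.0, 3.0]})
        res = rt_summary(Dataset(frame))
        assert res.median_s == pytest.approx(2.0)
        assert res.hist_counts.sum() == 3

    def test_missing_rt_gives_explicit_missing_result(self):
        ds = simulate_observer_dataset(12.0, 0.3, 50, seed=7)
        res = rt_summary(ds)
        assert not res.available
        assert np.isnan(res.median_s)
        assert res.n_missing == 50

    def test_bootstrap_recovers_configured_median_shift(self, small_cohort):
        a = combined_participant(small_cohort, "NT", "woFB")
        b = combined_participant(small_cohort, "NT", "wFB2")
        con = bootstrap_contrast(a, b, lambda ds: rt_summary(ds).median_s,
                                 n_reps=300, seed=9)
        # generator medians: NT 3.0 s (woFB) vs 2.39 s (wFB2)
        assert con.delta == pytest.approx(0.61, abs=0.35)
        assert con.p_two_sided < 0.05
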