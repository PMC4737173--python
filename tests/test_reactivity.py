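"""Reactivity estimation: stop frequencies, theta/rho, classes, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapeseq import (
    ReactivityModel,
    RhoProfile,
    TargetRNA,
    aggregate_replicates,
    classify_reactivity,
    estimate_theta,
    mask_by_base,
    read_reactivity_table,
    stop_frequencies,
    theta_to_rho,
    welch_one_sided,
    write_reactivity_table,
)

from conftest import make_counts
from oracles import grid_search_theta, welch_textbook


class TestStopFrequencies:
    def test_single_stop_site(self):
        freq, observed = stop_frequencies(make_counts([10, 0, 0], 90))
        assert freq.tolist() == [0.1, 0.0, 0.0]
        assert observed.all()

    def test_no_stops(self):
        freq, _ = stop_frequencies(make_counts([0, 0], 100))
        assert freq.tolist() == [0.0, 0.0]

    def test_arrival_denominators(self):
        # RT walks 3'->5': site 2 sees all 100 transcripts, site 1 only the
        # 91 that survived past site 2
        freq, _ = stop_frequencies(make_counts([19, 9], 72))
        assert freq == pytest.approx([19 / 91, 9 / 100])

    def test_unreached_sites_flagged(self):
        # every transcript stops at site 2, so site 1 is never reached
        with pytest.warns(RuntimeWarning):
            freq, observed = stop_frequencies(make_counts([0, 5], 0))
        assert not observed[0] and observed[1]
        assert freq[0] == 0.0

    def test_saturated_site_clamped(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            freq, _ = stop_frequencies(make_counts([10, 0], 0))
        assert freq[0] < 1.0


class TestThetaEstimation:
    def test_single_positive_site_normalises_to_one(self):
        plus = make_counts([10, 0, 0], 90, channel="plus")
        minus = make_counts([0, 0, 0], 100, channel="minus")
        res = ReactivityModel(plus, minus).fit()
        assert res.theta == pytest.approx([1.0, 0.0, 0.0])
        assert not res.degenerate

    def test_identical_channels_are_degenerate(self):
        plus = make_counts([5, 7, 3], 85, channel="plus")
        minus = make_counts([5, 7, 3], 85, channel="minus")
        res = ReactivityModel(plus, minus).fit()
        assert res.degenerate
        assert res.theta.tolist() == [0.0, 0.0, 0.0]
        assert res.rho.tolist() == [0.0, 0.0, 0.0]

    def test_closed_form_matches_drop_off_arithmetic(self):
        plus = make_counts([19, 9], 72, channel="plus")
        minus = make_counts([10, 0], 90, channel="minus")
        res = ReactivityModel(plus, minus).fit()
        raw = np.maximum(
            0.0,
            np.log1p(-np.array([10 / 100, 0 / 100]))
            - np.log1p(-np.array([19 / 91, 9 / 100])),
        )
        assert res.theta == pytest.approx(raw / raw.sum())

    def test_closed_form_equals_grid_search_likelihood_argmax(self):
        """The closed form is the MLE: dense grid search over the explicit
        stop-process likelihood lands on the same theta."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            total = int(rng.integers(20, 201))
            plus_draw = rng.multinomial(total, np.ones(n + 1) / (n + 1))
            minus_draw = rng.multinomial(total, np.ones(n + 1) / (n + 1))
            plus = make_counts(plus_draw[:n], int(plus_draw[n]), channel="plus")
            minus = make_counts(minus_draw[:n], int(minus_draw[n]), channel="minus")
            closed = ReactivityModel(plus, minus).fit().theta
            oracle = grid_search_theta(plus.X, plus.X_full, minus.X, minus.X_full)
            assert np.abs(closed - oracle).max() < 1e-3

    def test_depth_invariance(self):
        plus = make_counts([19, 9, 4], 72, channel="plus")
        minus = make_counts([10, 0, 2], 90, channel="minus")
        base = ReactivityModel(plus, minus).fit().theta
        scaled = ReactivityModel(
            make_counts([57, 27, 12], 216, channel="plus"),
            make_counts([30, 0, 6], 270, channel="minus"),
        ).fit().theta
        assert scaled == pytest.approx(base)

    def test_length_mismatch_is_a_hard_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            ReactivityModel(make_counts([1, 2], 10), make_counts([1], 10, channel="minus"))

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalisation_invariants(self, data):
        """Sum(theta) = 1 and mean(rho) = 1 on every non-degenerate profile."""
        n = data.draw(st.integers(min_value=1, max_value=30))
        X_p = data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
        X_m = data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
        full_p = data.draw(st.integers(0, 500))
        full_m = data.draw(st.integers(0, 500))
        res = estimate_theta(
            make_counts(X_p, full_p, channel="plus"),
            make_counts(X_m, full_m, channel="minus"),
        )
        assert (res.theta >= 0).all()
        if not res.degenerate:
            assert res.theta.sum() == pytest.approx(1.0, abs=1e-9)
            assert res.rho.mean() == pytest.approx(1.0, abs=1e-9)
        else:
            assert res.theta.sum() == 0.0


class TestRhoScaling:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            ([1.0, 0.0, 0.0], [3.0, 0.0, 0.0]),
            ([0.25, 0.25, 0.25, 0.25], [1.0, 1.0, 1.0, 1.0]),
            ([0.5, 0.3, 0.2], [1.5, 0.9, 0.6]),
        ],
    )
    def test_mean_one_scaling(self, theta, expected):
        assert theta_to_rho(np.array(theta)) == pytest.approx(expected)

    def test_degenerate_profile_stays_zero(self):
        assert theta_to_rho(np.array([0.0, 0.0]), degenerate=True).tolist() == [0.0, 0.0]


class TestClassification:
    @pytest.mark.parametrize(
        "rho, expected",
        [
            (1.3, "high"),
            (1.25, "moderate"),  # boundary belongs to moderate
            (0.5, "moderate"),
            (0.2, "weak"),
            (0.0, "weak"),
        ],
    )
    def test_thresholds(self, rho, expected):
        assert classify_reactivity(rho) == expected

    def test_negative_is_an_error(self):
        with pytest.raises(ValueError):
            classify_reactivity(-0.1)


class TestReplicates:
    def test_identical_profiles_have_zero_sd(self):
        p = RhoProfile("t", np.array([1.0, 2.0, 0.5]))
        agg = aggregate_replicates([p, p, p])
        assert agg.mean == pytest.approx(p.rho)
        assert agg.sd == pytest.approx([0.0, 0.0, 0.0])

    def test_sample_standard_deviation(self):
        profiles = [RhoProfile("t", np.array([v])) for v in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(profiles)
        assert agg.mean[0] == pytest.approx(2.0)
        assert agg.sd[0] == pytest.approx(1.0)  # n-1 denominator

    def test_errors(self):
        p1 = RhoProfile("t", np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            aggregate_replicates([p1])
        with pytest.raises(ValueError):
            aggregate_replicates([p1, RhoProfile("t", np.array([1.0]))])


class TestWelch:
    def test_identical_groups_with_spread(self):
        assert welch_one_sided([1.0, 1.1, 0.9], [0.9, 1.1, 1.0]) == pytest.approx(0.5)

    def test_matches_textbook_formula(self):
        a, b = [2.0, 2.1, 1.9], [1.0, 1.1, 0.9]
        for direction in ("greater", "less"):
            _, _, p_expected = welch_textbook(a, b, direction)
            assert welch_one_sided(a, b, direction) == pytest.approx(p_expected)

    def test_satterthwaite_df_below_pooled(self):
        a, b = [1.0, 1.01, 0.99], [5.0, 9.0, 1.0]  # very unequal variances
        _, df, _ = welch_textbook(a, b)
        assert df < 4.0

    def test_zero_variance_equal_groups(self):
        with pytest.warns(RuntimeWarning):
            assert welch_one_sided([1.0, 1.0], [1.0, 1.0]) == 0.5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_one_sided([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_one_sided([1.0, 2.0], [1.0, 2.0], direction="two-sided")


class TestMasking:
    def test_dms_keeps_a_and_c(self):
        t = TargetRNA("t", "GACUACGU", 4, 5, 8)
        profile = RhoProfile("t", np.ones(4))
        masked = mask_by_base(profile, t, {"A", "C"})
        assert np.isnan(masked[0]) and np.isnan(masked[3])
        assert masked[1] == 1.0 and masked[2] == 1.0

    def test_identity_mask(self):
        t = TargetRNA("t", "GACUACGU", 4, 5, 8)
        masked = mask_by_base(RhoProfile("t", np.ones(4)), t, set("ACGU"))
        assert not np.isnan(masked).any()

    def test_gu_rich_sequence_fully_masked(self):
        t = TargetRNA("t", "GUGUGUAU", 6, 7, 8)
        masked = mask_by_base(RhoProfile("t", np.ones(6)), t, {"A", "C"})
        assert np.isnan(masked).all()

    def test_empty_keep_set_is_an_error(self):
        t = TargetRNA("t", "GACU", 2, 3, 4)
        with pytest.raises(ValueError):
            mask_by_base(RhoProfile("t", np.ones(2)), t, set())


def test_rdat_export_layout(tmp_path, demo_target):
    from shapeseq.reactivity import write_rdat

    rng = np.random.default_rng(1)
    profiles = [RhoProfile("demo", rng.uniform(0, 2, 72)) for _ in range(3)]
    agg = aggregate_replicates(profiles)
    path = tmp_path / "demo.rdat"
    write_rdat(path, demo_target, agg)
    lines = path.read_text().splitlines()
    keys = [ln.split("\t")[0] for ln in lines]
    assert keys[0] == "RDAT_VERSION"
    assert "SEQUENCE" in keys
    assert keys.count("REACTIVITY:1") == 1 and "REACTIVITY:3" in keys
    reactivity_row = next(ln for ln in lines if ln.startswith("REACTIVITY:2"))
    values = [float(v) for v in reactivity_row.split("\t")[1:]]
    assert values == pytest.approx(profiles[1].rho, abs=1e-5)


class TestTableIO:
    def test_round_trip_with_missing_sentinel(self, tmp_path, demo_target):
        plus = make_counts([10, 0, 5] + [0] * 69, 500)
        minus = make_counts([0] * 72, 515, channel="minus")
        res = ReactivityModel(plus, minus, demo_target).fit()
        path = tmp_path / "reactivity.tsv"
        write_reactivity_table(res, path)
        profiles = read_reactivity_table(path)
        assert set(profiles) == {"demo"}
        back = profiles["demo"]
        assert back.rho[back.observed] == pytest.approx(res.rho[res.observed])
        assert (back.observed == res.observed).all()
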