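"""TCR core operations against independent oracles.

Pearson correlations are checked against a direct covariance
computation, the breaking point against an exhaustive perpendicular-
distance search, the surrogate correlation null against a brute-force
permutation null, and the density-intersection threshold against the
analytic crossing of two equal-variance Gaussians.
"""

import numpy as np
import pytest

import tcreject as tj
from tcreject.tcr_core import (
    BreakingPoint,
    ConditionResult,
    EpochSet,
    TcrParams,
    amplitude_range,
    compute_template,
    epoch_and_warp,
    epoch_template_correlations,
    estimate_correlation_threshold,
    find_breaking_point,
    fraction_correlated,
    generate_surrogate_events,
    select_channels_tcr,
    smooth_moving_average,
    surrogate_condition_fractions,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def pearson_oracle(epochs, template):
    """Direct per-epoch np.corrcoef, the brute-force reference."""
    n_ch, n_ep, _ = epochs.shape
    out = np.zeros((n_ep, n_ch))
    for c in range(n_ch):
        for e in range(n_ep):
            out[e, c] = np.corrcoef(epochs[c, e], template[c])[0, 1]
    return out


def knee_oracle(y):
    """Exhaustive max perpendicular distance to the first-last chord."""
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float)
    p0 = np.array([0.0, y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    best_i, best_d = None, 0.0
    for i in range(y.size):
        v = np.array([x[i], y[i]]) - p0
        d = (chord[0] * v[1] - chord[1] * v[0]) / norm  # signed; below chord < 0
        if -d > best_d:
            best_i, best_d = i, -d
    return best_i


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


class TestSmoothing:
    def test_constant_input_stays_constant(self):
        out = smooth_moving_average(np.full(1000, 3.25), 512.0)
        assert np.allclose(out.values, 3.25)

    def test_impulse_response_matches_window_enumeration(self):
        fs, pos = 512.0, 400
        x = np.zeros(2048)
        x[pos] = 1.0
        out = smooth_moving_average(x, fs)
        window, step = out.window_samples, out.step_samples
        assert window == 51  # 100 ms at 512 Hz
        expected = np.array(
            [
                1.0 / window if k * step <= pos < k * step + window else 0.0
                for k in range(out.values.size)
            ]
        )
        assert np.allclose(out.values, expected)

    def test_ramp_outputs_equal_window_centres(self):
        x = np.arange(3000, dtype=float)
        out = smooth_moving_average(x, 512.0)
        assert np.allclose(out.values, out.positions)

    @pytest.mark.parametrize("n", [137, 512, 1001])
    def test_output_length_formula(self, n):
        out = smooth_moving_average(np.zeros(n), 512.0)
        assert out.values.size == (n - 51) // 26 + 1

    def test_rejects_signal_shorter_than_window(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_moving_average(np.zeros(10), 512.0)


# ---------------------------------------------------------------------------
# epoching / warping / template
# ---------------------------------------------------------------------------


class TestEpochAndWarp:
    def test_thousand_point_segment_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        es = epoch_and_warp(x, [0, 1000, 2000])
        assert es.epochs.shape == (1, 2, 1000)
        assert np.allclose(es.epochs[0, 0], x[:1000], atol=1e-9)

    def test_ramp_upsampled_stays_linear(self):
        x = np.linspace(0.0, 1.0, 500)
        es = epoch_and_warp(x, [0, 500])
        ideal = np.linspace(0.0, 1.0, 1000)
        assert np.max(np.abs(es.epochs[0, 0] - ideal)) < 1e-9
        assert es.epochs[0, 0, 0] == 0.0 and es.epochs[0, 0, -1] == 1.0

    def test_variable_length_cycles_phase_align_after_warping(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(400, 900, size=8)
        series = np.concatenate(
            [np.sin(2 * np.pi * np.arange(n) / n) for n in lengths]
        )
        events = np.concatenate([[0], np.cumsum(lengths)])
        es = epoch_and_warp(series, events)
        corr = np.corrcoef(es.epochs[0])
        assert corr.min() > 0.999

    def test_degenerate_cycles_skipped_with_warning(self):
        x = np.arange(100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            es = epoch_and_warp(x, [0, 50, 52, 100], min_points=4)
        assert es.n_epochs == 2 and es.skipped == [1]

    def test_needs_two_events(self):
        with pytest.raises(ValueError, match="2 events"):
            epoch_and_warp(np.zeros(100), [10])

    def test_fixed_duration_drops_truncated_epochs(self):
        es = epoch_and_warp(np.arange(100.0), [0, 40, 80], duration=20)
        assert es.n_epochs == 3
        es = epoch_and_warp(np.arange(100.0), [0, 40, 80], duration=30)
        assert es.n_epochs == 2  # epoch starting at 80 would run past the end


class TestTemplate:
    def test_identical_epochs_return_the_epoch(self):
        ep = np.tile(np.sin(np.linspace(0, 7, 1000)), (1, 4, 1))
        es = EpochSet(ep, durations=np.full(4, 1000.0))
        assert np.allclose(compute_template(es), ep[0, 0])

    def test_opposite_epochs_cancel(self):
        a = np.random.default_rng(2).normal(size=(1, 1, 1000))
        es = EpochSet(np.concatenate([a, -a], axis=1), durations=np.full(2, 1000.0))
        assert np.allclose(compute_template(es), 0.0)

    def test_noise_averaging_concentrates_around_signal(self):
        """With 500 epochs of signal + unit noise, the template deviates
        from the signal by more than 4/sqrt(500) at under 1% of points."""
        rng = np.random.default_rng(3)
        s = np.sin(np.linspace(0, 12, 1000))
        ep = s + rng.normal(size=(1, 500, 1000))
        es = EpochSet(ep, durations=np.full(500, 1000.0))
        dev = np.abs(compute_template(es)[0] - s)
        assert (dev <= 4.0 / np.sqrt(500)).mean() >= 0.99


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


class TestCorrelations:
    def test_exact_affine_and_sign_relations(self):
        t = np.sin(np.linspace(0, 9, 1000))
        epochs = np.stack([t, 3 * t + 7, -t])[None]
        es = EpochSet(epochs, durations=np.full(3, 1000.0))
        r = epoch_template_correlations(es, t[None])
        assert np.allclose(r[:, 0], [1.0, 1.0, -1.0], atol=1e-12)

    def test_zero_variance_epoch_maps_to_zero(self):
        t = np.sin(np.linspace(0, 9, 1000))
        epochs = np.stack([t, np.full(1000, 5.0)])[None]
        es = EpochSet(epochs, durations=np.full(2, 1000.0))
        r = epoch_template_correlations(es, t[None])
        assert r[1, 0] == 0.0
        # zero-variance template: whole column 0
        es2 = EpochSet(np.stack([t, t])[None], durations=np.full(2, 1000.0))
        assert np.all(epoch_template_correlations(es2, np.zeros((1, 1000))) == 0.0)

    def test_shape_mismatch_rejected(self):
        es = EpochSet(np.zeros((2, 3, 1000)), durations=np.full(3, 1000.0))
        with pytest.raises(ValueError, match="template shape"):
            epoch_template_correlations(es, np.zeros((2, 999)))

    def test_matches_brute_force_pearson_to_1e12(self):
        rng = np.random.default_rng(4)
        epochs = rng.normal(size=(3, 8, 1000))
        es = EpochSet(epochs, durations=np.full(8, 1000.0))
        template = compute_template(es)
        fast = epoch_template_correlations(es, template)
        slow = pearson_oracle(epochs, template)
        assert np.max(np.abs(fast - slow)) < 1e-12

    def test_null_distribution_matches_permutation_oracle(self):
        """Epochs warped from ~24 effective smoothed values: their
        correlation with an independent template follows the same law as
        a brute-force block-permutation null (KS distance < 0.05)."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        k, n_draw = 24, 4000
        # linear-interpolation matrix 24 -> 1000
        xs = np.linspace(0, k - 1, 1000)
        i0 = np.clip(xs.astype(int), 0, k - 2)
        w = xs - i0
        warp = np.zeros((1000, k))
        warp[np.arange(1000), i0] += 1 - w
        warp[np.arange(1000), i0 + 1] += w

        template = warp @ rng.normal(size=k)
        tc = template - template.mean()

        def corrs(blocks):
            ep = blocks @ warp.T
            ep = ep - ep.mean(axis=1, keepdims=True)
            num = ep @ tc
            return num / (np.linalg.norm(ep, axis=1) * np.linalg.norm(tc))

        observed = corrs(rng.normal(size=(n_draw, k)))
        base = rng.normal(size=k)
        perms = np.array([rng.permutation(base) for _ in range(n_draw)])
        null = corrs(perms)
        assert ks_2samp(np.abs(observed), np.abs(null)).statistic < 0.05


class TestFractionCorrelated:
    def test_counts_strictly_above_threshold(self):
        table = np.array([[0.5], [0.3], [0.45], [0.41]])
        assert fraction_correlated(table, 0.4)[0] == 0.75

    def test_anticorrelation_never_counts(self):
        assert fraction_correlated(np.full((10, 2), -0.9), 0.4).tolist() == [0.0, 0.0]


# ---------------------------------------------------------------------------
# surrogates and the correlation threshold
# ---------------------------------------------------------------------------


class TestSurrogates:
    def test_sector_counts_differ_by_at_most_one(self):
        ens = generate_surrogate_events(100000, 512.0, 20, seed=1)
        assert len(ens.event_lists) == 10
        edges = np.linspace(0, 100000, 6)
        for times in ens.event_lists:
            assert times.size == 10
            counts = np.histogram(times, bins=edges)[0]
            assert counts.tolist() == [2, 2, 2, 2, 2]

    def test_large_request_arithmetic(self):
        ens = generate_surrogate_events(10_000_000, 512.0, 1000, n_sets=2, seed=0)
        for times in ens.event_lists:
            assert times.size == 500
            counts = np.histogram(times, bins=np.linspace(0, 10_000_000, 6))[0]
            assert counts.tolist() == [100] * 5

    def test_deterministic_and_in_bounds(self):
        a = generate_surrogate_events(50000, 512.0, 40, seed=9)
        b = generate_surrogate_events(50000, 512.0, 40, seed=9)
        for ta, tb in zip(a.event_lists, b.event_lists):
            assert np.array_equal(ta, tb)
            assert ta[0] >= 0 and ta[-1] < 50000
            assert np.all(np.diff(ta) > 0)

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_surrogate_events(1000, 512.0, 100, epoch_samples=600.0, seed=0)

    def test_surrogate_fraction_below_experimental(self, walking_hp):
        """Random-event epochs correlate with their template far less
        often than true gait epochs on artifact channels."""
        _, rec, events, truth, result = walking_hp
        params = TcrParams(n_surrogate_sets=3)
        fracs, _ = surrogate_condition_fractions(
            rec, events, params, seed=2, event_label="RHS"
        )
        art = truth.artifact_channel_indices
        assert fracs.mean(axis=0)[art].max() < result.fractions[art].min()


class TestThresholdEstimate:
    def test_gaussian_crossing_at_analytic_midpoint(self):
        """Equal-variance Normal(0.6) vs Normal(0.0): densities cross at
        the midpoint of the means, r = 0.30."""
        rng = np.random.default_rng(6)
        est = estimate_correlation_threshold(
            rng.normal(0.6, 0.1, 100_000), rng.normal(0.0, 0.1, 100_000)
        )
        assert est.separated
        assert abs(est.value - 0.30) < 0.02

    def test_identical_samples_give_no_separation(self):
        rng = np.random.default_rng(7)
        s = rng.normal(0.05, 0.2, 5000)
        est = estimate_correlation_threshold(s, s)
        assert not est.separated
        assert est.used == 0.4

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError, match="100"):
            estimate_correlation_threshold(np.zeros(50), np.zeros(500))

    def test_synthetic_walking_intersection_brackets_reported_range(self):
        """On walking data whose artifact correlations are broadly
        distributed (moderate amplitude), the intersection falls in the
        0.2-0.5 range around the fixed 0.4 working threshold."""
        cfg = tj.SynthConfig(
            n_channels=32, fs=256.0, n_cycles=300, seed=1, artifact_amp_uv=40.0
        )
        rec, _, events, _ = tj.generate_walking_eeg(cfg)
        rec = tj.highpass(rec)
        params = TcrParams()
        result = tj.analyze_condition(rec, events, params, event_label="RHS")
        _, sur = surrogate_condition_fractions(
            rec, events, params, seed=2, event_label="RHS"
        )
        est = estimate_correlation_threshold(result.corr_table.ravel(), sur)
        assert est.separated
        assert 0.2 <= est.value <= 0.5


# ---------------------------------------------------------------------------
# amplitude range and breaking point
# ---------------------------------------------------------------------------


class TestAmplitudeRange:
    def _single_epoch(self, values):
        return EpochSet(np.asarray(values)[None, None, :], durations=np.array([1000.0]))

    def test_constant_epochs_have_zero_range(self):
        assert amplitude_range(self._single_epoch(np.full(1000, 2.0)))[0] == 0.0

    def test_ramp_closed_form(self):
        # each 100-point window of a 0->10 ramp spans 99 steps of 10/999
        arng = amplitude_range(self._single_epoch(np.linspace(0.0, 10.0, 1000)))
        assert np.isclose(arng[0], 99 * 10.0 / 999.0, rtol=1e-12)

    def test_subwindowing_damps_single_spikes(self):
        x = np.zeros(1000)
        x[437] = 10.0
        arng = amplitude_range(self._single_epoch(x))
        assert np.isclose(arng[0], 1.0)  # one affected window out of ten
        whole = x.max() - x.min()
        assert whole == 10.0  # a whole-epoch range would be 10x larger

    def test_rejects_indivisible_window_count(self):
        es = EpochSet(np.zeros((1, 1, 999)), durations=np.array([999.0]))
        with pytest.raises(ValueError, match="divisible"):
            amplitude_range(es)


class TestBreakingPoint:
    def test_flat_then_rise_knees_at_junction(self):
        y = np.array([5.0] * 10 + [5.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        bp = find_breaking_point(y)
        assert bp.index == knee_oracle(y) == 10
        assert bp.value == 5.0

    def test_straight_line_has_no_knee(self):
        bp = find_breaking_point(np.arange(1.0, 51.0))
        assert not bp.found

    def test_quadratic_knees_at_half(self):
        x = np.linspace(0.0, 1.0, 1001)
        bp = find_breaking_point(x**2)
        assert bp.index == 500  # x = 0.5, where x - x^2 is maximal

    def test_ties_break_toward_smaller_index(self):
        y = np.array([0.0, 0.0, 2.0, 2.0, 4.0])
        assert find_breaking_point(y).index == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search_on_random_curves(self, seed):
        rng = np.random.default_rng(seed)
        y = np.sort(np.cumsum(np.abs(rng.normal(size=40)) ** 3))
        bp = find_breaking_point(y)
        assert bp.index == knee_oracle(y)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 5"):
            find_breaking_point(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="sorted"):
            find_breaking_point(np.array([3.0, 1.0, 2.0, 4.0, 5.0]))


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------


def _result(condition, fractions, arng, breaking_value):
    fractions = np.asarray(fractions, dtype=float)
    arng = np.asarray(arng, dtype=float)
    return ConditionResult(
        condition=condition,
        fractions=fractions,
        arng=arng,
        breaking=BreakingPoint(0, breaking_value),
        corr_table=np.zeros((1, fractions.size)),
        template=np.zeros((fractions.size, 1000)),
        n_epochs=1,
        labels=[f"E{i}" for i in range(fractions.size)],
        params=TcrParams(),
    )


class TestSelectChannels:
    def test_conjunction_in_both_conditions_flags(self):
        a = _result("EO", [0.8, 0.1], [20.0, 5.0], 10.0)
        b = _result("BF", [0.85, 0.2], [18.0, 4.0], 9.0)
        decision = select_channels_tcr(a, b)
        assert decision.flags.tolist() == [True, False]
        assert decision.reasons[0] == {"TCR"}

    def test_high_fraction_alone_is_not_enough(self):
        a = _result("EO", [0.9, 0.9], [5.0, 20.0], 10.0)
        b = _result("BF", [0.9, 0.1], [5.0, 4.0], 10.0)
        decision = select_channels_tcr(a, b)
        assert decision.flags.tolist() == [False, True]

    def test_union_rule_removes_from_both_conditions(self):
        # criteria met only in condition A
        a = _result("EO", [0.9, 0.1], [20.0, 5.0], 10.0)
        b = _result("BF", [0.1, 0.1], [5.0, 5.0], 10.0)
        decision = select_channels_tcr(a, b)
        assert decision.flags.tolist() == [True, False]
        assert decision.evidence["met_in"][0] == ["EO"]

    def test_single_condition_warns(self):
        a = _result("EO", [0.9], [20.0], 10.0)
        with pytest.warns(UserWarning, match="single condition"):
            decision = select_channels_tcr(a)
        assert decision.flags.tolist() == [True]

    def test_channel_set_mismatch_rejected(self):
        a = _result("EO", [0.9, 0.1], [20.0, 5.0], 10.0)
        b = _result("BF", [0.9], [20.0], 10.0)
        with pytest.raises(ValueError, match="different channel sets"):
            select_channels_tcr(a, b)


def test_common_rescaling_leaves_decisions_invariant(walking_hp):
    """Scaling every channel by the same positive constant leaves the
    correlation table and fractions unchanged, scales ARNG and the
    breaking point by that constant, and preserves the flags."""
    _, rec, events, _, result = walking_hp
    scaled = rec.copy_with(rec.data * 3.0)
    scaled.condition = rec.condition
    res2 = tj.analyze_condition(scaled, events, event_label="RHS")
    assert np.allclose(res2.corr_table, result.corr_table, atol=1e-9)
    assert np.array_equal(res2.fractions, result.fractions)
    assert np.allclose(res2.arng, 3.0 * result.arng, rtol=1e-12)
    assert np.isclose(res2.breaking.value, 3.0 * result.breaking.value, rtol=1e-9)
    assert np.array_equal(res2.above_breaking, result.above_breaking)
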