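"""Classification, RT filtering, G(t) vs brute-force oracle, pooling, modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp_st

from srtpipe import behavior_metrics as bm
from srtpipe import synth_tasks as st
from srtpipe.core_io import ParameterError, Session, Trial


def g_oracle(labeled, step=0.01):
    """Brute-force G(t): per-branch counting at every grid point."""
    use = [lt for lt in labeled if lt.label in ("premature", "correct", "late")]
    max_fp = max(lt.fp for lt in use)
    n = int(round(max_fp / step))
    g = np.full(n, np.nan)
    for k in range(n):
        t = k * step
        elig = [lt for lt in use if round(lt.fp / step) > k]
        if not elig:
            continue
        numer = sum(1 for lt in elig
                    if lt.label == "premature" and round(lt.hold / step) <= k)
        g[k] = numer / len(elig)
    return g


def make_session(specs, task="srt"):
    """specs: list of (fp, hold, cue_kind) -> valid Session."""
    trials = []
    clock = 10.0
    for i, (fp, hold, cue) in enumerate(specs):
        press = round(clock, 2)
        release = round(press + hold, 2)
        stim = round(press + fp, 2) if (cue == "stimulus" and hold >= fp) else None
        trials.append(Trial(index=i, press_time=press, fp=fp, stim_time=stim,
                            release_time=release, cue_kind=cue, task=task))
        clock = release + 5.0
    return Session(rat_id="r", session_index=0, phase="Pre", post_ordinal=0,
                   lesion_group="none", task=task, trials=trials)


class TestClassification:
    @pytest.mark.parametrize("fp,hold,expected", [
        (1.0, 1.25, "correct"),          # rt 0.25 within the 600 ms window
        (1.0, 0.80, "premature"),        # released before the stimulus
        (1.0, 1.05, "subthreshold_reactive"),  # rt 50 ms: too brief to be reactive
        (1.0, 1.70, "late"),             # rt 0.7 beyond the window
        (0.5, 1.10, "correct"),          # rt 0.6 exactly at the window edge
    ])
    def test_stimulus_trial_labels(self, fp, hold, expected):
        s = make_session([(fp, hold, "stimulus")])
        [lt] = bm.classify_trials(s)
        assert lt.label == expected

    @pytest.mark.parametrize("hold,expected", [
        (1.4, "correct"),  # within [fp, fp + 1.0]
        (0.9, "premature"),
        (2.3, "late"),
    ])
    def test_selftiming_uncued_labels(self, hold, expected):
        s = make_session([(1.0, hold, "uncued")], task="selftiming")
        [lt] = bm.classify_trials(s)
        assert lt.label == expected

    def test_probe_trials_excluded(self):
        s = make_session([(1.0, 0.4, "probe")])
        [lt] = bm.classify_trials(s)
        assert lt.label == "probe_excluded"

    def test_labels_partition_session(self, default_srt_params):
        s = st.simulate_srt_session(default_srt_params, 300, 9)
        labeled = bm.classify_trials(s)
        assert sum(bm.outcome_counts(labeled).values()) == len(s)


class TestReactionTimes:
    def test_window_excludes_fast_and_slow(self):
        s = make_session([(1.0, 1.0 + rt, "stimulus") for rt in (0.05, 0.3, 0.31, 2.5)])
        rts = bm.extract_reaction_times(bm.classify_trials(s))
        assert np.allclose(sorted(rts), [0.3, 0.31])

    def test_identical_rts_all_retained(self):
        s = make_session([(1.0, 1.3, "stimulus")] * 5)
        rts = bm.extract_reaction_times(bm.classify_trials(s))
        assert len(rts) == 5

    def test_mad_removes_gross_outlier(self):
        s = make_session([(1.0, 1.30, "stimulus")] * 9 + [(1.0, 2.90, "stimulus")])
        rts = bm.extract_reaction_times(bm.classify_trials(s))
        assert len(rts) == 9 and np.allclose(rts, 0.3)


class TestMadFilter:
    def test_hand_computed_example(self):
        # median 1.05, MAD 0.05 -> cut at 10 * 1.4826 * 0.05 = 0.741
        vals = np.array([0.9, 1.0, 1.05, 1.1, 50.0])
        kept = bm.mad_filter(vals)
        assert np.allclose(kept, [0.9, 1.0, 1.05, 1.1])

    def test_constant_list_unchanged(self):
        vals = np.full(7, 2.5)
        assert np.array_equal(bm.mad_filter(vals), vals)

    def test_empty_list(self):
        assert bm.mad_filter(np.array([])).size == 0

    def test_preserves_order(self):
        vals = np.array([1.1, 0.9, 1.0, 99.0, 1.05])
        assert np.allclose(bm.mad_filter(vals), [1.1, 0.9, 1.0, 1.05])


class TestHoldDensity:
    def test_peak_at_single_duration(self):
        curve = bm.hold_density(np.array([1.0]))
        assert abs(curve.centers[np.argmax(curve.density)] - 1.0) <= curve.bin_width

    def test_integrates_to_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1.0, 0.2, size=2_000)
        x = x[x > 0.3]
        curve = bm.hold_density(x)
        integral = np.trapezoid(curve.density, curve.centers)
        assert abs(integral - 1.0) < 0.02

    def test_two_separated_points_symmetric_peaks(self):
        curve = bm.hold_density(np.array([0.5, 2.0]))
        half = curve.density[curve.centers < 1.25]
        other = curve.density[curve.centers >= 1.25]
        assert abs(half.max() - other.max()) < 1e-9


class TestGaussianMode:
    def test_symmetric_sample_exact_center(self):
        x = np.array([0.9, 1.0, 1.1] * 7)
        assert bm.fit_gaussian_mode(x) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("mu,sigma", [(1.14, 0.15), (1.48, 0.20)])
    def test_parameter_recovery(self, mu, sigma):
        rng = np.random.default_rng(17)
        x = rng.normal(mu, sigma, size=1_000)
        assert abs(bm.fit_gaussian_mode(x) - mu) < 0.02

    def test_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            bm.fit_gaussian_mode(np.array([1.0] * 10))


class TestAnticipationFunction:
    def test_no_prematures_gives_zero(self):
        s = make_session([(1.0, 1.3, "stimulus")] * 4 + [(1.5, 1.8, "stimulus")] * 4)
        curve = bm.anticipation_function(bm.classify_trials(s))
        assert np.all(curve.g[curve.defined] == 0)

    def test_six_trial_worked_example(self):
        # Branch formula: for 0.5 <= t < 1, G = (N2 F2 + N3 F3)/(N2 + N3);
        # trials of an elapsed foreperiod leave numerator and denominator
        # together, so their premature releases stop counting past their FP.
        s = make_session([
            (0.5, 0.2, "stimulus"), (0.5, 0.8, "stimulus"),
            (1.0, 0.7, "stimulus"), (1.0, 1.3, "stimulus"),
            (1.5, 1.8, "stimulus"), (1.5, 1.9, "stimulus"),
        ])
        labeled = bm.classify_trials(s)
        curve = bm.anticipation_function(labeled)
        t = curve.t

        def g_at(x):
            return curve.g[np.argmin(np.abs(t - x))]

        assert g_at(0.19) == 0.0
        assert g_at(0.20) == pytest.approx(1 / 6)   # first branch, all six trials
        assert g_at(0.49) == pytest.approx(1 / 6)
        assert g_at(0.50) == pytest.approx(0.0)     # second branch: F2 = F3 = 0 here
        assert g_at(0.70) == pytest.approx(1 / 4)   # N2*F2(0.7) = 2 * 1/2 over 4
        assert g_at(0.99) == pytest.approx(1 / 4)
        assert g_at(1.00) == pytest.approx(0.0)     # third branch: no FP-1.5 prematures
        # and the brute-force per-branch oracle agrees everywhere
        oracle = g_oracle(labeled)
        assert np.allclose(curve.g[curve.defined], oracle[~np.isnan(oracle)])

    def test_matches_brute_force_oracle_on_random_sessions(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            specs = []
            for _i in range(n):
                fp = float(rng.choice([0.5, 1.0, 1.5]))
                hold = round(float(rng.uniform(0.05, fp + 1.2)), 2)
                specs.append((fp, max(hold, 0.01), "stimulus"))
            labeled = bm.classify_trials(make_session(specs))
            curve = bm.anticipation_function(labeled)
            oracle = g_oracle(labeled)
            assert np.array_equal(np.isnan(curve.g), np.isnan(oracle))
            assert np.allclose(curve.g[curve.defined], oracle[~np.isnan(oracle)])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(hyp_st.lists(
        hyp_st.tuples(hyp_st.sampled_from([0.5, 1.0, 1.5]),
                      hyp_st.integers(min_value=1, max_value=250)),
        min_size=2, max_size=40))
    def test_monotone_and_bounded(self, pairs):
        specs = [(fp, ticks * 0.01, "stimulus") for fp, ticks in pairs]
        labeled = bm.classify_trials(make_session(specs))
        curve = bm.anticipation_function(labeled)
        g = curve.g[curve.defined]
        assert np.all((g >= 0) & (g <= 1))
        # non-decreasing within each foreperiod branch (the eligible-trial
        # pool is constant there; across branch edges it may step down)
        fps = sorted({fp for fp, _ in pairs})
        edges = [0.0] + fps
        for lo, hi in zip(edges, edges[1:]):
            sel = curve.defined & (curve.t >= lo) & (curve.t < hi)
            assert np.all(np.diff(curve.g[sel]) >= -1e-12)

    def test_recovers_deadline_cdf(self, default_srt_params):
        import dataclasses
        params = dataclasses.replace(default_srt_params, probe_fraction=0.0)
        s = st.simulate_srt_session(params, 12_000, 3)
        curve = bm.anticipation_function(bm.classify_trials(s))
        cdf = params.deadline_dist.cdf(curve.t[curve.defined])
        sup = np.max(np.abs(curve.g[curve.defined] - cdf))
        assert sup < 0.03


class TestAnticipationIntegral:
    def test_identical_curves_zero(self):
        s = make_session([(1.5, 0.7, "stimulus")] * 3 + [(1.5, 1.8, "stimulus")] * 3)
        c = bm.anticipation_function(bm.classify_trials(s))
        assert bm.anticipation_integral_change(c, c) == 0.0

    def test_constant_offset_integrates_to_span(self):
        s = make_session([(1.5, 1.8, "stimulus")] * 4)
        pre = bm.anticipation_function(bm.classify_trials(s))
        import copy
        post = copy.deepcopy(pre)
        post.g = post.g + 0.1
        # half-open grid 0..1.49: trapezoid of a constant 0.1 spans 1.49 s
        assert bm.anticipation_integral_change(pre, post) == pytest.approx(0.149)

    def test_mismatched_grids_rejected(self):
        s1 = make_session([(1.5, 1.8, "stimulus")] * 4)
        s2 = make_session([(1.0, 1.3, "stimulus")] * 4)
        c1 = bm.anticipation_function(bm.classify_trials(s1))
        c2 = bm.anticipation_function(bm.classify_trials(s2))
        with pytest.raises(Exception):
            bm.anticipation_integral_change(c1, c2)


class TestPooling:
    def _cohort(self, sizes, phase, start_index=0):
        sessions = []
        for i, n in enumerate(sizes):
            per_fp = n // 3
            specs = []
            for fp in (0.5, 1.0, 1.5):
                specs += [(fp, fp + 0.3, "stimulus")] * per_fp
            s = make_session(specs)
            s.session_index = start_index + i
            s.phase = phase
            s.post_ordinal = 0 if phase == "Pre" else i + 1
            sessions.append(s)
        return sessions

    def test_pre_pool_accumulates_until_500_per_fp(self):
        sessions = self._cohort([300] * 10, "Pre")
        pool = bm.pool_condition(sessions, "Pre")
        # 100 per FP per session -> 6 sessions for > 500
        assert len(pool.session_indices) == 6
        assert pool.complete
        assert all(c > 500 for c in pool.counts_per_fp.values())

    def test_single_giant_session_suffices(self):
        sessions = self._cohort([9_000], "Pre")
        pool = bm.pool_condition(sessions, "Pre")
        assert pool.session_indices == [0] and pool.complete

    def test_incomplete_pool_flagged_with_counts(self):
        sessions = self._cohort([90], "Pre")
        pool = bm.pool_condition(sessions, "Pre")
        assert not pool.complete
        assert pool.counts_per_fp[1.0] == 30

    def test_post_early_walks_forward_post_late_backward(self):
        sessions = self._cohort([660] * 4, "Post")
        early = bm.pool_condition(sessions, "Post_Early")
        late = bm.pool_condition(sessions, "Post_Late")
        assert early.session_indices == [0]
        assert late.session_indices == [3]

    def test_small_sessions_merge_forward(self):
        sessions = self._cohort([30, 30, 99], "Post")
        groups = bm.merge_small_sessions(sessions, threshold=50)
        assert [len(g) for g in groups] == [3]

    def test_sessions_never_split(self):
        sessions = self._cohort([300] * 8, "Pre")
        pool = bm.pool_condition(sessions, "Pre")
        pooled_count = len(pool.trials)
        assert pooled_count == sum(
            len(s) for s in sessions if s.session_index in pool.session_indices)


class TestSpeedingClassification:
    def test_generative_recovery_of_three_groups(self):
        rng = np.random.default_rng(8)
        truth = {}
        data = {}
        fps = np.repeat([0.5, 1.0, 1.5], 167)
        for i in range(12):
            slope = [-0.08, 0.08, 0.0][i % 3]
            truth[f"r{i}"] = ["speeding", "anti_speeding", "none"][i % 3]
            rts = 0.31 + slope * fps + rng.normal(0, 0.05, size=fps.size)
            data[f"r{i}"] = (rts, fps)
        labels, crit = bm.speeding_classification(data)
        assert labels == truth
        assert 0 < crit <= 0.05

    def test_single_fp_rat_excluded(self):
        rng = np.random.default_rng(1)
        fps = np.full(100, 1.0)
        labels, _ = bm.speeding_classification(
            {"solo": (rng.normal(0.3, 0.05, 100), fps)})
        assert "solo" not in labels


class TestRetrieval:
    def test_simple_duration(self):
        tr = Trial(index=0, press_time=8.0, fp=1.0, stim_time=9.0,
                   release_time=9.3, poke_time=11.5 - 0.7)
        s = Session(rat_id="r", session_index=0, phase="Pre", post_ordinal=0,
                    lesion_group="none", task="srt", trials=[tr])
        [rec] = bm.retrieval_durations([s])
        assert rec["durations"][0] == pytest.approx(1.5)

    def test_scale_shift_recovered(self, default_srt_params):
        pre = [st.simulate_srt_session(default_srt_params, 1_000, seed,
                                       session_index=seed, phase="Pre")
               for seed in range(2)]
        lesioned = st.lesioned_params(default_srt_params, poke_scale=1.74)
        post = [st.simulate_srt_session(lesioned, 1_000, 10 + seed,
                                        session_index=10 + seed, phase="Post",
                                        post_ordinal=seed + 1)
                for seed in range(2)]
        recs = bm.normalized_retrieval(bm.retrieval_durations(pre + post))
        post_norm = np.mean([r["normalized"] for r in recs if r["phase"] == "Post"])
        assert abs(post_norm - 1.74) / 1.74 < 0.05
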