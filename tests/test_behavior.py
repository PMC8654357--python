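"""Trial scoring, abort detection, lick bouts and Go-probability curves."""

import numpy as np
import pytest

from chophot.behavior import (
    LickBout,
    TrialRecord,
    bout_size_bin,
    detect_abort,
    find_intertrial_bouts,
    go_probability_curve,
    score_trial,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately written loop-by-loop, not vectorized)


def oracle_score(onset, licks):
    in_w = [l for l in licks if onset + 0.2 <= l < onset + 3.0]
    if len(in_w) == 0:
        return "miss", None
    if len(in_w) >= 7:
        ok = True
        for a, b in zip(in_w[:6], in_w[1:7]):
            if b - a > 1.0:
                ok = False
                break
        if ok:
            return "hit", in_w[6]
    return "partial_hit", None


def oracle_bouts(licks, trial_windows):
    """O(n^2) windowed scan for inter-trial bouts."""
    licks = list(licks)
    free = [
        l for l in licks if not any(s <= l < e for s, e in trial_windows)
    ]
    bouts = []
    i = 0
    while i < len(free):
        j = i
        while j + 1 < len(free) and free[j + 1] - free[j] < 0.25:
            j += 1
        run = free[i : j + 1]
        quiet_before = all(not (run[0] - 1.0 < l < run[0]) for l in licks)
        quiet_after = all(not (run[-1] < l < run[-1] + 1.0) for l in licks)
        if quiet_before and quiet_after:
            bouts.append((run[0], run[-1], len(run)))
        i = j + 1
    return bouts


def random_train(rng, n_max=10, span=(0.0, 4.0)):
    n = rng.integers(0, n_max + 1)
    return np.sort(rng.uniform(*span, size=n))


# ---------------------------------------------------------------------------


class TestScoreTrial:
    def test_criterion_bout_is_hit(self):
        licks = 10.0 + 0.3 + 0.35 * np.arange(7)
        rec = score_trial(10.0, licks)
        assert rec.outcome == "hit" and rec.go
        assert rec.seventh_lick_s == pytest.approx(10.0 + 2.4)

    def test_no_licks_is_miss(self):
        rec = score_trial(10.0, np.array([]))
        assert rec.outcome == "miss"
        assert rec.lick_count_in_window == 0 and not rec.go

    def test_six_licks_is_partial_hit(self):
        rec = score_trial(10.0, 10.3 + 0.2 * np.arange(6))
        assert rec.outcome == "partial_hit" and not rec.go

    def test_gap_over_one_second_blocks_hit(self):
        # 7 licks in the window but one 1.15 s gap among them: not a hit
        licks = np.array([10.3, 10.4, 10.5, 10.6, 11.75, 11.85, 11.95])
        assert score_trial(10.0, licks).outcome == "partial_hit"

    def test_agrees_with_oracle_on_random_trains(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            onset = float(rng.uniform(0, 1))
            licks = onset + random_train(rng)
            rec = score_trial(onset, licks)
            outcome, seventh = oracle_score(onset, licks)
            assert rec.outcome == outcome
            assert rec.seventh_lick_s == seventh

    @pytest.mark.parametrize(
        "licks_rel, expected",
        [
            # exactly 1.0 s gaps are allowed ("could not exceed 1 s");
            # values chosen exactly representable in binary
            (0.2 + np.arange(7) * 1.0 / 2.5, "hit"),
            ([0.25, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5], "hit"),
            ([0.25, 1.3125, 1.5, 1.75, 2.0, 2.25, 2.5], "partial_hit"),
            # window is [onset+0.2, onset+3.0): boundary membership
            ([0.2, 0.9, 1.4, 1.9, 2.4, 2.9, 2.999], "hit"),
            ([0.2, 0.9, 1.4, 1.9, 2.4, 2.9, 3.0], "partial_hit"),
            ([0.19, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4], "partial_hit"),
        ],
    )
    def test_boundary_cases(self, licks_rel, expected):
        rec = score_trial(5.0, 5.0 + np.asarray(licks_rel, dtype=float))
        assert rec.outcome == expected

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            licks = random_train(rng)
            a = score_trial(1.0, 1.0 + licks)
            b = score_trial(451.0, 451.0 + licks)
            assert a.outcome == b.outcome

    def test_unsorted_licks_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            score_trial(0.0, np.array([2.0, 1.0]))


class TestDetectAbort:
    def test_phase1_withhold_two_seconds(self):
        assert detect_abort(10.0, np.array([9.0]), phase=1)

    def test_phase2_withhold_shorter(self):
        assert not detect_abort(10.0, np.array([8.2]), phase=2)
        assert detect_abort(10.0, np.array([8.6]), phase=2)

    def test_no_licks_no_abort(self):
        assert not detect_abort(10.0, np.array([]), phase=1)


class TestBouts:
    def test_three_lick_bout(self):
        bouts = find_intertrial_bouts(np.array([10.0, 10.2, 10.4]), [])
        assert len(bouts) == 1
        b = bouts[0]
        assert (b.n_licks, b.size_bin) == (3, "3-4")
        assert (b.start_s, b.end_s) == (10.0, 10.4)

    def test_gap_at_250ms_splits(self):
        # 0.3 s apart: separate runs, neither has 1 s quiescence -> no bouts
        assert find_intertrial_bouts(np.array([5.0, 5.3]), []) == []
        # strict boundary: exactly 0.25 s also splits
        assert find_intertrial_bouts(np.array([5.0, 5.25]), []) == []

    def test_quiescence_against_all_licks(self):
        # run inside trial window spoils the quiescence of a nearby bout
        licks = np.array([4.5, 10.0, 10.2])
        assert len(find_intertrial_bouts(licks, [(4.0, 5.0)])) == 1
        licks2 = np.array([9.5, 10.0, 10.2])  # 9.5 in-trial but 0.5 s before
        assert find_intertrial_bouts(licks2, [(9.0, 9.8)]) == []

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            licks = np.sort(rng.uniform(0, 30, size=rng.integers(0, 25)))
            # quantize some gaps to land exactly on the 250 ms boundary
            if licks.size > 2 and rng.random() < 0.3:
                licks[1] = licks[0] + 0.25
                licks = np.sort(licks)
            windows = [(8.0, 11.0), (20.0, 23.0)] if rng.random() < 0.5 else []
            got = find_intertrial_bouts(licks, windows)
            want = oracle_bouts(licks, windows)
            assert [(b.start_s, b.end_s, b.n_licks) for b in got] == want

    def test_bouts_disjoint_and_partition(self):
        rng = np.random.default_rng(5)
        licks = np.sort(rng.uniform(0, 100, size=200))
        bouts = find_intertrial_bouts(licks, [])
        for a, b in zip(bouts, bouts[1:]):
            assert a.end_s < b.start_s
        # each lick belongs to at most one bout
        counts = [
            sum(b.start_s <= l <= b.end_s for b in bouts) for l in licks
        ]
        assert max(counts, default=0) <= 1

    def test_size_bins(self):
        assert [bout_size_bin(n) for n in (1, 2, 3, 4, 5, 6, 7, 11)] == [
            "1-2", "1-2", "3-4", "3-4", "5-6", "5-6", "7+", "7+",
        ]


class TestGoProbability:
    @staticmethod
    def _trial(onset, tone, outcome):
        return TrialRecord(
            onset_s=onset, tone=tone, outcome=outcome, go=outcome == "hit",
            lick_count_in_window=7 if outcome == "hit" else 0,
            seventh_lick_s=None,
        )

    def test_all_go_probability_one(self):
        trials = [self._trial(float(i), "low", "hit") for i in range(25)]
        curve = go_probability_curve(trials, n_bins=5)
        assert np.allclose(curve["low"], 1.0)

    def test_alternating_half(self):
        trials = [
            self._trial(float(i), "mid", "hit" if i % 2 == 0 else "miss")
            for i in range(40)
        ]
        curve = go_probability_curve(trials, n_bins=5)
        assert np.all(np.abs(curve["mid"] - 0.5) <= 1.0 / 8 + 1e-9)

    def test_aborted_excluded_and_missing_is_nan(self):
        trials = [self._trial(float(i), "low", "aborted") for i in range(4)]
        trials += [self._trial(10.0, "high", "hit")]
        curve = go_probability_curve(trials, n_bins=1)
        assert np.isnan(curve["low"][0])
        assert curve["high"][0] == 1.0
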