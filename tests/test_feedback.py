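"""Emotion sequences, music-segment decisions, motifs, protocol schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegmusic import feedback as F


class TestEmotionSequence:
    def test_rejects_wrong_window(self):
        with pytest.raises(ValueError):
            F.EmotionSequence(labels=("active",), window_s=1.0)

    def test_rejects_unknown_state(self):
        with pytest.raises(ValueError):
            F.EmotionSequence(labels=("happy",))


class TestSegmentDecision:
    def test_unanimous_block(self):
        seq = F.EmotionSequence(labels=("active",) * 12)
        assert F.segment_decision(seq) == ["positive"]

    def test_tie_is_medium(self):
        seq = F.EmotionSequence(labels=("active",) * 6 + ("passive",) * 6)
        assert F.segment_decision(seq) == ["medium"]

    def test_matches_counting_oracle(self, rng):
        labels = tuple(rng.choice(["active", "passive", "normal"], size=7 * 12 + 5))
        seq = F.EmotionSequence(labels=labels)
        got = F.segment_decision(seq)
        assert len(got) == 7  # trailing partial block dropped
        for b, decision in enumerate(got):
            block = labels[b * 12 : (b + 1) * 12]
            counts = {s: block.count(s) for s in ("active", "passive", "normal")}
            top = max(counts.values())
            winners = [s for s, c in counts.items() if c == top]
            if len(winners) > 1:
                assert decision == "medium"
            else:
                assert decision == F.STATE_TO_VALENCE[winners[0]]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            F.segment_decision(F.EmotionSequence(labels=("normal",) * 11))


class TestMarkerCount:
    @pytest.mark.parametrize("n,expected", [(399, 4788), (1, 12), (0, 0)])
    def test_values(self, n, expected):
        assert F.marker_count(n) == expected

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            F.marker_count(10, segment_s=5.0, window_s=0.7)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_window_accounting_identity(self, n):
        assert F.marker_count(n) == 12 * n


class TestRenderMusic:
    def test_deterministic(self):
        a = F.render_music("positive", seed=3)
        b = F.render_music("positive", seed=3)
        assert a.events == b.events

    @pytest.mark.parametrize("valence", F.VALENCES)
    def test_events_fit_in_six_seconds(self, valence):
        seg = F.render_music(valence, seed=1)
        assert seg.events
        for onset, _, dur, _ in seg.events:
            assert 0.0 <= onset < 6.0
            assert onset + dur <= 6.0 + 1e-9

    def test_positive_higher_than_negative(self):
        pos = F.render_music("positive", seed=2)
        neg = F.render_music("negative", seed=2)
        assert pos.mean_pitch > neg.mean_pitch

    def test_unknown_valence(self):
        with pytest.raises(ValueError):
            F.render_music("angry")


class TestFragmentTrend:
    def test_single_trial_counts(self):
        df = F.fragment_trend([["positive", "positive", "negative"]])
        assert df.loc[1, "positive"] == 2
        assert df.loc[1, "negative"] == 1
        assert df.loc[1, "medium"] == 0

    def test_all_medium_zero_slopes(self):
        df = F.fragment_trend([["medium"] * 5] * 4)
        assert df.attrs["slopes"]["positive"] == 0.0
        assert df.attrs["slopes"]["negative"] == 0.0

    def test_improving_cohort_positive_slope(self, rng):
        """State mix shifting toward active across six trials must yield a
        positive slope for positive-music counts."""
        trials = []
        for k in range(6):
            p_active = 0.2 + 0.1 * k
            states = rng.choice(
                ["active", "passive"], size=20 * 12, p=[p_active, 1 - p_active]
            )
            seq = F.EmotionSequence(labels=tuple(states))
            trials.append(F.segment_decision(seq))
        df = F.fragment_trend(trials)
        assert df.attrs["slopes"]["positive"] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            F.fragment_trend([])


class TestProtocol:
    def test_default_schedule_totals_42(self):
        sched = F.schedule_protocol()
        assert sched.total_min == 42.0

    def test_over_cap_rejected(self):
        stages = [("feedback_1", 20.0), ("feedback_2", 20.0), ("scales", 10.0)]
        with pytest.raises(ValueError):
            F.schedule_protocol(stages)

    def test_empty_config_uses_defaults(self):
        assert F.schedule_protocol(None).stages == F.DEFAULT_STAGES


def test_mostly_passive_session_yields_mostly_negative_music(rng):
    """Closed-loop property: decoding a predominantly passive session with a
    classifier trained on matched synthetic data produces more negative than
    positive music decisions."""
    from eegmusic import boosting as B
    from eegmusic.synth import simulate_session

    train = simulate_session(duration_s=60.0, seed=31)
    labels = np.asarray(train.state_labels)
    windows = train.noisy.windows(0.5)
    sel = np.isin(labels, ("active", "passive"))
    y = (labels[sel] == "active").astype(int)
    featurize = lambda w: B.bandpower_features(w, 250.0)
    gb = B.train_gb(featurize(windows[sel]), y, M=20)

    session = simulate_session(
        duration_s=60.0, seed=32, state_probs={"passive": 0.7, "normal": 0.2, "active": 0.1}
    )
    seq = F.classify_windows(
        session.noisy, gb_model=gb, gb_featurizer=featurize, calibration={"gb": 0.3}
    )
    decisions = F.segment_decision(seq)
    assert decisions.count("negative") > decisions.count("positive")


class TestClassifyWindows:
    def test_uniform_scores_all_normal(self, rng):
        """Scores pinned at 0.5 by a zero-temperature calibration decode as
        'normal' everywhere."""
        from eegmusic import boosting as B

        y = rng.integers(0, 2, 40)
        X = rng.normal(size=(40, 3, 2))
        X[:, 1, :] += (2 * y - 1)[:, None]
        gb = B.train_gb(X, y, M=5)
        from eegmusic.synth import gen_clean_eeg

        rec = gen_clean_eeg(3, 10.0, 250.0, seed=0)
        featurizer = lambda w: rng.normal(size=(w.shape[0], 3, 2))
        seq = F.classify_windows(
            rec, gb_model=gb, gb_featurizer=featurizer, calibration={"gb": 0.0}
        )
        assert set(seq.labels) == {"normal"}
        assert len(seq) == 20

    def test_untrained_model_rejected(self):
        from eegmusic import boosting as B
        from eegmusic.synth import gen_clean_eeg

        rec = gen_clean_eeg(3, 1.0, 250.0, seed=0)
        with pytest.raises(ValueError):
            F.classify_windows(rec, gb_model=B.GBModel())

    def test_no_model_rejected(self):
        from eegmusic.synth import gen_clean_eeg

        rec = gen_clean_eeg(3, 1.0, 250.0, seed=0)
        with pytest.raises(ValueError):
            F.classify_windows(rec)

    def test_inverted_thresholds_rejected(self, rng):
        assert (F.scores_to_states(np.array([0.5])) == ["normal"]).all()
        with pytest.raises(ValueError):
            F.scores_to_states(np.array([0.5]), thresholds=(0.6, 0.4))
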