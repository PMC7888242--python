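import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igf.corpus import AnomalySpec, build_sentence
from igf.dynamics import (
    DynamicsParams,
    IntegrationError,
    WordState,
    apply_integration_failure,
    attention_window,
    confidence_step,
    quality_step,
    uptake_rate,
)


@pytest.fixture
def sent():
    return build_sentence([5] * 6, [0.0] * 6, [0.3] * 6)


class TestQuality:
    def test_decay_fixed_point_at_zero(self, sent, default_dynamics):
        st_ = WordState(Q=0.0)
        quality_step(st_, sent.tokens[0], gaze_char=40.0, fixated_word=5, dt=10.0,
                     params=default_dynamics)
        assert st_.Q == 0.0

    def test_uptake_increases_but_stays_below_one(self, sent, default_dynamics):
        st_ = WordState(Q=0.5)
        tok = sent.tokens[2]
        quality_step(st_, tok, gaze_char=tok.center, fixated_word=2, dt=500.0,
                     params=default_dynamics)
        assert 0.5 < st_.Q < 1.0

    def test_repeated_decay_steps_compose_exactly(self, sent, default_dynamics):
        # k small steps must equal one big step: the decay is an exact exponential
        a, b = WordState(Q=0.8), WordState(Q=0.8)
        tok = sent.tokens[0]
        for _ in range(50):
            quality_step(a, tok, gaze_char=40.0, fixated_word=5, dt=2.0,
                         params=default_dynamics)
        quality_step(b, tok, gaze_char=40.0, fixated_word=5, dt=100.0,
                     params=default_dynamics)
        assert abs(a.Q - b.Q) < 1e-9

    def test_parafoveal_uptake_weaker_than_foveal(self, sent, default_dynamics):
        tok = sent.tokens[3]
        foveal = uptake_rate(tok, tok.center, 3, default_dynamics)
        parafoveal = uptake_rate(tok, sent.tokens[2].center, 2, default_dynamics)
        assert parafoveal < foveal

    def test_words_beyond_right_span_receive_no_uptake(self, default_dynamics):
        sent_long = build_sentence([8] * 8, [0.0] * 8, [0.3] * 8)
        far = sent_long.tokens[6]  # > 15 characters to the right of gaze at word 0
        assert uptake_rate(far, sent_long.tokens[0].center, 0, default_dynamics) is None

    def test_rarer_and_longer_words_accrue_slower(self, default_dynamics):
        base = build_sentence([5, 5], [0.0, 0.0], [0.3, 0.3]).tokens[0]
        rare = build_sentence([5, 5], [-2.0, 0.0], [0.3, 0.3]).tokens[0]
        long_ = build_sentence([10, 5], [0.0, 0.0], [0.3, 0.3]).tokens[0]
        r0 = uptake_rate(base, base.center, 0, default_dynamics)
        assert uptake_rate(rare, rare.center, 0, default_dynamics) < r0
        assert uptake_rate(long_, long_.center, 0, default_dynamics) < r0


class TestConfidence:
    def test_frozen_outside_attention(self, sent, default_dynamics):
        st_ = WordState(C=0.4, Q=0.8)
        confidence_step(st_, sent.tokens[0], in_attention=False, dt=100.0,
                        params=default_dynamics)
        assert st_.C == 0.4

    def test_no_growth_without_quality(self, sent, default_dynamics):
        st_ = WordState(C=0.4, Q=0.0)
        confidence_step(st_, sent.tokens[0], in_attention=True, dt=100.0,
                        params=default_dynamics)
        assert st_.C == 0.4

    def test_predictable_words_cross_thresholds_earlier(self, default_dynamics):
        # numeric integration oracle: same uptake, different predictability
        def first_crossing(pred, level=0.5):
            s = build_sentence([5, 5], [0.0, 0.0], [pred, pred])
            tok = s.tokens[0]
            state = WordState()
            for step in range(1, 5001):
                quality_step(state, tok, tok.center, 0, 1.0, default_dynamics)
                confidence_step(state, tok, True, 1.0, default_dynamics)
                if state.C >= level:
                    return step
            raise AssertionError("no crossing")

        assert first_crossing(0.9) < first_crossing(0.1)

    def test_halving_dt_changes_trajectory_by_under_one_percent(self, sent):
        for dt in (1.0,):
            params = DynamicsParams(dt=dt)
            tok = sent.tokens[0]
            out = {}
            for d in (dt, dt / 2):
                state = WordState()
                steps = int(2000 / d)
                for _ in range(steps):
                    quality_step(state, tok, tok.center, 0, d, params)
                    confidence_step(state, tok, True, d, params)
                out[d] = (state.Q, state.C)
            assert abs(out[dt][0] - out[dt / 2][0]) < 0.01
            assert abs(out[dt][1] - out[dt / 2][1]) < 0.01

    def test_crossing_time_decreases_with_confidence_rate(self, sent):
        times = []
        for r_c in (0.004, 0.007, 0.012):
            params = DynamicsParams(r_c=r_c)
            tok = sent.tokens[0]
            state = WordState()
            for step in range(1, 10001):
                quality_step(state, tok, tok.center, 0, 1.0, params)
                confidence_step(state, tok, True, 1.0, params)
                if state.C >= 0.5:
                    times.append(step)
                    break
        assert times == sorted(times, reverse=True) and len(times) == 3

    @given(
        r_q=st.floats(0.002, 0.05),
        r_c=st.floats(0.002, 0.05),
        lam=st.floats(0.001, 0.05),
        pred=st.floats(0.0, 1.0),
        q0=st.floats(0.0, 0.99),
        c0=st.floats(0.0, 0.99),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_levels_stay_bounded_for_random_parameters(self, r_q, r_c, lam, pred, q0, c0):
        params = DynamicsParams(r_q=r_q, r_c=r_c, lambda_decay=lam)
        s = build_sentence([5, 5], [0.0, 0.0], [pred, pred])
        tok = s.tokens[0]
        state = WordState(Q=q0, C=min(c0, params.c_max - 1e-9))
        for i in range(300):
            fixated = 0 if i < 150 else 1
            quality_step(state, tok, s.tokens[fixated].center, fixated, 5.0, params)
            confidence_step(state, tok, True, 5.0, params)
            assert 0.0 <= state.Q < 1.0
            assert 0.0 <= state.C < params.c_max + 1e-12


class TestIntegrationFailure:
    def test_full_drop(self):
        st_ = WordState(C=0.8)
        apply_integration_failure(st_, AnomalySpec(1.0))
        assert st_.C == 0.0

    def test_zero_effect_drop_leaves_state(self):
        st_ = WordState(C=0.8)
        apply_integration_failure(st_, AnomalySpec(1e-12))
        assert st_.C == pytest.approx(0.8)

    def test_partial_drop_below_forward_threshold_raises_type_I_condition(self):
        st_ = WordState(C=0.8, passed_fwd=True)
        triggered = apply_integration_failure(st_, AnomalySpec(0.5), theta_fwd=0.6)
        assert st_.C == pytest.approx(0.4)
        assert st_.passed_fwd  # latch survives the drop
        assert triggered

    def test_drop_not_crossing_threshold_raises_nothing(self):
        st_ = WordState(C=0.9, passed_fwd=True)
        assert not apply_integration_failure(st_, AnomalySpec(0.1), theta_fwd=0.6)

    def test_double_application_is_an_error(self):
        st_ = WordState(C=0.8)
        apply_integration_failure(st_, AnomalySpec(0.3))
        with pytest.raises(IntegrationError):
            apply_integration_failure(st_, AnomalySpec(0.3))


class TestAttention:
    @pytest.mark.parametrize("word,expected", [(0, (0,)), (1, (0, 1)), (5, (4, 5))])
    def test_two_word_window_clipped_left(self, word, expected):
        assert attention_window(word) == expected

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cardinality_never_exceeds_two(self, word):
        assert 1 <= len(attention_window(word)) <= 2


class TestSpillover:
    def test_previous_word_confidence_moves_while_older_words_freeze(
        self, sent, default_dynamics, default_policy
    ):
        from igf.engine import simulate_trial

        rec = simulate_trial(sent, seed=0)
        # find the fixation on word 2 and replay: C of word 1 (attended) must
        # change during it while C of word 0 stays put.  Reconstruct from the
        # per-fixation record via a fresh manual run.
        params, policy = default_dynamics, default_policy
        states = [WordState() for _ in sent.tokens]
        # fixate word 1 long enough for C1 to rise, then move to word 2
        for word, steps in ((0, 200), (1, 200), (2, 150)):
            states[word].ever_fixated = True
            gaze = sent.tokens[word].center
            before = [s.C for s in states]
            for _ in range(steps):
                for i, tok in enumerate(sent.tokens):
                    quality_step(states[i], tok, gaze, word, 1.0, params)
                for i in attention_window(word):
                    confidence_step(states[i], sent.tokens[i], True, 1.0, params)
            if word == 2:
                assert states[1].C > before[1]  # spillover continues
                assert states[0].C == before[0]  # outside attention: frozen
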