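import pytest

from igf.control import (
    Action,
    ActionKind,
    ControlPolicy,
    PolicyStateError,
    classify_regression_type,
    evaluate_policy,
    wrapup_check,
)
from igf.corpus import ConfigError, build_sentence
from igf.dynamics import WordState


def make_states(n, **common):
    return [WordState(**common) for _ in range(n)]


@pytest.fixture
def sent():
    return build_sentence([5] * 6, [0.0] * 6, [0.3] * 6)


@pytest.fixture
def policy():
    return ControlPolicy(theta_fwd=0.5, theta_bwd=0.6, theta_reinsp=0.8)


class TestPolicyValidation:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError, match="theta_fwd <= theta_bwd"):
            ControlPolicy(theta_fwd=0.7, theta_bwd=0.6, theta_reinsp=0.8)

    def test_ordering_overridable_with_explicit_flag(self):
        pol = ControlPolicy(theta_fwd=0.7, theta_bwd=0.6, theta_reinsp=0.8,
                            allow_unordered=True)
        assert pol.theta_bwd < pol.theta_fwd

    def test_regress_I_actions_always_cancel(self):
        with pytest.raises(ConfigError):
            Action(ActionKind.REGRESS_I, cancelled_fixation=False)


class TestEvaluatePolicy:
    def test_exact_forward_threshold_crossing_moves_forward(self, sent, policy):
        # inclusive crossing: C == theta_fwd ties toward action
        states = make_states(6)
        states[2].ever_fixated = True
        states[2].C = policy.theta_fwd
        states[1].ever_fixated = True
        states[1].C = 0.9
        states[1].max_C = 0.9
        act = evaluate_policy(states, 2, policy, sent, t=100.0)
        assert act.kind is ActionKind.FORWARD and act.target == 3

    def test_below_threshold_continues(self, sent, policy):
        states = make_states(6)
        states[2].ever_fixated = True
        states[2].C = 0.3
        act = evaluate_policy(states, 2, policy, sent, t=100.0)
        assert act.kind is ActionKind.CONTINUE

    def test_confidence_drop_of_previous_word_cancels_fixation(self, sent, policy):
        # the type-I release: previous word passed the forward threshold but
        # its confidence has since fallen back under it
        states = make_states(6)
        states[2].ever_fixated = True
        states[2].C = 0.2
        states[1].ever_fixated = True
        states[1].passed_fwd = True
        states[1].C = 0.3
        act = evaluate_policy(states, 2, policy, sent, t=100.0)
        assert act.kind is ActionKind.REGRESS_I
        assert act.cancelled_fixation

    def test_missing_evidence_on_previous_word_releases_type_II(self, sent, policy):
        states = make_states(6)
        states[2].ever_fixated = True
        states[2].C = 0.55  # >= theta_fwd
        states[1].ever_fixated = True
        states[1].passed_fwd = True
        states[1].C = 0.55  # < theta_bwd = 0.6
        act = evaluate_policy(states, 2, policy, sent, t=100.0)
        assert act.kind is ActionKind.REGRESS_II and act.target == 1

    def test_backward_evaluation_happens_once(self, sent, policy):
        states = make_states(6)
        states[2].ever_fixated = True
        states[2].C = 0.55
        states[1].ever_fixated = True
        states[1].passed_fwd = True
        states[1].C = 0.55
        assert evaluate_policy(states, 2, policy, sent, 0.0).kind is ActionKind.REGRESS_II
        # second query: first pass already evaluated, no re-trigger
        assert evaluate_policy(states, 2, policy, sent, 1.0).kind is ActionKind.FORWARD

    def test_skip_when_preview_confidence_sufficient(self, sent, policy):
        states = make_states(6)
        states[1].ever_fixated = True
        states[1].C = 0.6
        states[0].ever_fixated = True
        states[0].C = 0.9
        states[0].bwd_evaluated = True
        states[2].Q = 0.95  # strong parafoveal preview of word 2
        act = evaluate_policy(states, 1, policy, sent, t=100.0)
        assert act.kind is ActionKind.SKIP and act.target == 3

    def test_unfixated_word_query_is_inconsistency_error(self, sent, policy):
        states = make_states(6)
        with pytest.raises(PolicyStateError):
            evaluate_policy(states, 2, policy, sent, t=0.0)


class TestWrapup:
    def _states(self, maxes, final_c=0.9):
        states = [WordState(max_C=m, C=m, ever_fixated=True) for m in maxes]
        states.append(WordState(max_C=final_c, C=final_c, ever_fixated=True))
        return states

    def test_sufficient_evidence_ends_trial(self, sent, policy):
        states = self._states([0.9] * 5)
        act = wrapup_check(states, sent, policy, fixated=5)
        assert act.kind is ActionKind.END

    def test_weakest_link_below_backward_threshold_regresses(self, sent, policy):
        states = self._states([0.9, 0.9, 0.4, 0.9, 0.9])
        act = wrapup_check(states, sent, policy, fixated=5)
        assert act.kind is ActionKind.REGRESS_II and act.wrapup

    def test_raising_backward_threshold_never_flips_regress_to_end(self, sent):
        # monotonicity: sweep theta_bwd upward on a fixed state
        states = self._states([0.9, 0.7, 0.65, 0.8, 0.9])
        kinds = []
        for tb in (0.5, 0.6, 0.66, 0.75):
            pol = ControlPolicy(theta_fwd=0.5, theta_bwd=tb, theta_reinsp=0.8)
            kinds.append(wrapup_check(states, sent, pol, fixated=5).kind)
        seen_regress = False
        for k in kinds:
            if k is ActionKind.REGRESS_II:
                seen_regress = True
            else:
                assert not seen_regress  # END never follows REGRESS_II in the sweep

    def test_negligible_backward_threshold_never_regresses(self, sent):
        pol = ControlPolicy(theta_fwd=0.001, theta_bwd=0.001, theta_reinsp=0.8)
        states = self._states([0.2, 0.3, 0.4, 0.2, 0.3])
        assert wrapup_check(states, sent, pol, fixated=5).kind is ActionKind.END

    def test_spent_wrapup_always_ends(self, sent, policy):
        states = self._states([0.1] * 5)
        act = wrapup_check(states, sent, policy, fixated=5, wrapup_used=True)
        assert act.kind is ActionKind.END

    def test_non_final_fixation_is_an_error(self, sent, policy):
        states = self._states([0.9] * 5)
        with pytest.raises(PolicyStateError):
            wrapup_check(states, sent, policy, fixated=2)


class TestClassification:
    def test_releases_map_to_types(self):
        assert classify_regression_type(
            Action(ActionKind.REGRESS_I, cancelled_fixation=True)) == "type_I"
        assert classify_regression_type(Action(ActionKind.REGRESS_II)) == "type_II"
        assert classify_regression_type(
            Action(ActionKind.REGRESS_II, wrapup=True)) == "type_II"

    def test_non_regression_rejected(self):
        with pytest.raises(ConfigError):
            classify_regression_type(Action(ActionKind.FORWARD, target=1))

    def test_every_simulated_regression_gets_exactly_one_label(self, small_corpus):
        from igf.engine import simulate_experiment

        trials = simulate_experiment(small_corpus, n_subjects=2, base_seed=3)
        for t in trials:
            for s in t.saccades:
                if s.kind in (ActionKind.REGRESS_I, ActionKind.REGRESS_II):
                    assert s.regression_type in ("type_I", "type_II")
                else:
                    assert s.regression_type is None
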