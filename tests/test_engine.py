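import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igf.control import ActionKind, ControlPolicy
from igf.corpus import AnomalySpec, ConfigError, build_sentence, generate_corpus
from igf.engine import (
    EngineConfig,
    FixationEvent,
    SaccadeEvent,
    fixation_report,
    oracle_trace,
    simulate_experiment,
    simulate_trial,
)
from igf.targeting import TargetingConfig


def anomalous_sentence(delta=0.9, helpful=None, pred=0.0):
    """Six neutral words; word 2 carries an anomaly detected on word 3.

    ``pred`` of the detecting word (3) controls the detection gate: 0 makes
    detection certain.
    """
    preds = [0.3] * 6
    preds[3] = pred
    return build_sentence(
        [5] * 6, [0.0] * 6, preds,
        anomalies={2: AnomalySpec(delta, helpful_target=helpful)},
    )


class TestSimulateTrial:
    def test_same_seed_reproduces_identical_event_stream(self, small_corpus):
        a = simulate_trial(small_corpus[0], seed=5)
        b = simulate_trial(small_corpus[0], seed=5)
        assert a.events == b.events

    def test_degenerate_policy_never_regresses(self):
        corpus = generate_corpus(60, anomaly_rate=0.0, seed=17)
        pol = ControlPolicy(theta_bwd=0.5)  # theta_bwd == theta_fwd
        for i, sent in enumerate(corpus):
            rec = simulate_trial(sent, policy=pol, seed=i)
            assert all(not s.kind.value.startswith("REGRESS") for s in rec.saccades)

    def test_single_large_anomaly_yields_exactly_one_cancelled_regression(self):
        # hand-traced scenario: the anomaly on word 2 is detected during the
        # fixation on word 3 (detection certain at pred=0), the drop sends
        # C(2) under the forward threshold, the fixation on 3 is cancelled
        # and one type-I regression to word 2 is launched
        sent = anomalous_sentence(delta=0.9, pred=0.0)
        tar = TargetingConfig(oculomotor_sd=0.0)
        rec = simulate_trial(sent, targeting=tar, seed=0)
        regs = [s for s in rec.saccades if s.regression_type]
        assert len(regs) == 1
        assert regs[0].kind is ActionKind.REGRESS_I
        assert regs[0].regression_type == "type_I"
        assert regs[0].target_word == 2
        launch_fix = [f for f, s in zip(rec.fixations, rec.saccades) if s is regs[0]]
        assert launch_fix[0].word == 3 and launch_fix[0].cancelled
        # the cancelled fixation is cut at the detection delay
        assert launch_fix[0].duration == pytest.approx(126.0, abs=2.0)

    def test_anomaly_detection_gated_by_predictability(self):
        # a perfectly predictable detecting word never surfaces the mismatch
        sent = anomalous_sentence(delta=0.9, pred=1.0)
        rec = simulate_trial(sent, seed=0)
        assert not any(s.regression_type for s in rec.saccades)

    def test_every_regression_carries_type_and_target_mode(self, small_corpus):
        for i, sent in enumerate(small_corpus):
            rec = simulate_trial(sent, seed=i)
            for s in rec.saccades:
                if s.kind.value.startswith("REGRESS"):
                    assert s.regression_type is not None
                    assert s.target_mode is not None

    def test_initial_fixation_configurable(self, plain_sentence):
        rec0 = simulate_trial(plain_sentence, seed=0)
        rec1 = simulate_trial(plain_sentence, engine=EngineConfig(initial_word=1), seed=0)
        assert rec0.fixations[0].word == 0
        assert rec1.fixations[0].word == 1

    def test_time_cap_flags_trial_instead_of_raising(self, plain_sentence):
        rec = simulate_trial(plain_sentence, engine=EngineConfig(max_time=100.0), seed=0)
        assert rec.capped


class TestEventStreamInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_alternation_ordering_and_position_conservation(self, seed):
        sent = generate_corpus(1, words_per_sentence=(4, 7), seed=seed)[0]
        rec = simulate_trial(sent, seed=seed)
        events = rec.events
        assert isinstance(events[0], FixationEvent)
        assert isinstance(events[-1], FixationEvent)
        last_t = -1.0
        for i, e in enumerate(events):
            expected = FixationEvent if i % 2 == 0 else SaccadeEvent
            assert isinstance(e, expected)
            assert e.onset >= last_t
            last_t = e.onset
        for i in range(1, len(events) - 1, 2):
            sac, nxt = events[i], events[i + 1]
            assert sac.landing_char == pytest.approx(nxt.landing_char)
            assert sac.amplitude == pytest.approx(sac.landing_char - sac.launch_char)
            if sac.kind.value.startswith("REGRESS"):
                assert sac.amplitude < 0
        for f in rec.fixations:
            assert f.duration > 0


class TestOracle:
    def test_engine_matches_fine_timestep_reference(self):
        corpus = generate_corpus(6, words_per_sentence=(4, 6), anomaly_rate=0.5, seed=21)
        for i, sent in enumerate(corpus):
            e = simulate_trial(sent, seed=100 + i)
            o = oracle_trace(sent, seed=100 + i, dt_fine=0.1)
            assert [s.kind for s in e.saccades] == [s.kind for s in o.saccades]
            for fe, fo in zip(e.fixations, o.fixations):
                assert abs(fe.onset - fo.onset) <= 2.0  # 2 * dt

    def test_oracle_self_consistent_across_fine_steps(self):
        sent = generate_corpus(1, words_per_sentence=(4, 5), anomaly_rate=1.0, seed=33)[0]
        a = oracle_trace(sent, seed=7, dt_fine=0.1)
        b = oracle_trace(sent, seed=7, dt_fine=0.05)
        assert [s.kind for s in a.saccades] == [s.kind for s in b.saccades]

    def test_oracle_requires_fine_step(self, plain_sentence):
        with pytest.raises(ConfigError):
            oracle_trace(plain_sentence, seed=0, dt_fine=0.5)


class TestExperiment:
    def test_conditions_share_corpora_and_seeds(self, small_corpus):
        trials = simulate_experiment(
            small_corpus[:10],
            conditions=[("a", {}), ("b", {"policy.theta_bwd": 0.64})],
            n_subjects=2,
            base_seed=11,
        )
        by_cond = {}
        for t in trials:
            by_cond.setdefault(t.condition, []).append(t)
        assert len(by_cond["a"]) == len(by_cond["b"]) == 20
        # identical overrides -> identical trials (paired design)
        trials_eq = simulate_experiment(
            small_corpus[:10], conditions=[("a", {}), ("b", {})],
            n_subjects=1, base_seed=11,
        )
        half = len(trials_eq) // 2
        for x, y in zip(trials_eq[:half], trials_eq[half:]):
            assert x.events == y.events

    def test_duplicate_condition_names_rejected(self, small_corpus):
        with pytest.raises(ConfigError, match="unique"):
            simulate_experiment(small_corpus[:2],
                                conditions=[("a", {}), ("a", {})], base_seed=0)

    def test_unknown_override_key_rejected(self, small_corpus):
        with pytest.raises(ConfigError, match="nope"):
            simulate_experiment(small_corpus[:2],
                                conditions=[("a", {"policy.nope": 1})], base_seed=0)

    def test_zero_subjects_gives_empty_dataset(self, small_corpus):
        assert simulate_experiment(small_corpus, n_subjects=0, base_seed=0) == []

    def test_streaming_output_matches_in_memory_report(self, small_corpus, tmp_path):
        out = tmp_path / "run"
        trials = simulate_experiment(small_corpus[:5], n_subjects=1, base_seed=2, out=out)
        import pandas as pd

        streamed = pd.read_csv(out / "fixations.csv")
        in_memory = fixation_report(trials)
        assert len(streamed) == len(in_memory)
        assert streamed["duration_ms"].tolist() == pytest.approx(
            in_memory["duration_ms"].tolist()
        )
        assert (out / "trials.jsonl").read_text().count("\n") == 5

    def test_standard_error_shrinks_with_subject_count(self, small_corpus):
        # sqrt(n) scaling of the mean regression count across replications
        corpus = small_corpus[:8]

        def mean_regs(base_seed, n_subjects):
            trials = simulate_experiment(corpus, n_subjects=n_subjects,
                                         base_seed=base_seed)
            return np.mean([
                sum(1 for s in t.saccades if s.regression_type) for t in trials
            ])

        reps = 25
        se1 = np.std([mean_regs(1000 + r, 1) for r in range(reps)], ddof=1)
        se4 = np.std([mean_regs(2000 + r, 4) for r in range(reps)], ddof=1)
        assert se4 < se1  # quadrupling subjects must shrink the SE
        assert se1 / se4 == pytest.approx(2.0, rel=0.6)  # Monte-Carlo tolerance
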