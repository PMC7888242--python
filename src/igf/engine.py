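"""Discrete-time event loop: dynamics, control, saccade execution, logging.

The engine advances the word-level dynamics on the controller clock ``dt``,
queries the control policy every tick, and executes the resulting saccades.
Within a fixation the gaze position is constant, so every word's uptake
regime (foveal / parafoveal / decay) and rate are frozen; quality then has
a closed-form trajectory and is evaluated analytically, while confidence —
whose rate tracks the evolving quality level — is stepped per tick with a
midpoint-quality rule.  Forward, skip and type-II decisions are followed by
a motor latency during which processing continues and a detected
integration failure may still cancel the planned fixation (type I), with
``cancel_latency`` as the minimum realizable duration.  Saccade flight time
is folded into the latencies (zero-duration saccades).

:func:`oracle_trace` is a deliberately naive reference: full per-timestep
recomputation of every word's state at a finer integration step, with
decisions quantized to the same controller clock.  It shares only the
primitive rate equations and is used in tests to bound discretization
error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .control import (
    Action,
    ActionKind,
    ControlPolicy,
    classify_regression_type,
    evaluate_policy,
)
from .corpus import ConfigError, Sentence
from .dynamics import (
    DynamicsParams,
    WordState,
    apply_integration_failure,
    attention_window,
    confidence_step,
    decay_rate,
    preview_confidence,
    quality_step,
    uptake_rate,
)
from .targeting import TargetingConfig, TargetMode, draw_strategy, landing_position, select_target

__all__ = [
    "EngineConfig",
    "FixationEvent",
    "SaccadeEvent",
    "TrialRecord",
    "simulate_trial",
    "simulate_experiment",
    "oracle_trace",
    "fixation_report",
]


@dataclass(frozen=True)
class EngineConfig:
    """Trial-level caps and the initial landing word.

    Caps guard against livelock in pathological configurations; a capped
    trial is flagged, not raised, and excluded from measures by default.
    """

    max_time: float = 60000.0
    max_regressions_per_word: int = 3
    initial_word: int = 0

    def __post_init__(self) -> None:
        if self.max_time <= 0 or self.max_regressions_per_word < 1:
            raise ConfigError("EngineConfig caps must be positive")
        if self.initial_word not in (0, 1):
            raise ConfigError("initial_word must be 0 or 1")


@dataclass
class FixationEvent:
    word: int
    landing_char: float
    onset: float
    duration: float
    cancelled: bool = False


@dataclass
class SaccadeEvent:
    kind: ActionKind
    launch_char: float
    landing_char: float
    amplitude: float
    onset: float
    target_word: Optional[int] = None
    target_mode: Optional[TargetMode] = None
    regression_type: Optional[str] = None


@dataclass
class TrialRecord:
    sentence: Sentence
    subject: int = 0
    trial: int = 0
    condition: str = "default"
    seed: object = None
    events: list = field(default_factory=list)
    final_states: list[WordState] = field(default_factory=list)
    capped: bool = False

    @property
    def fixations(self) -> list[FixationEvent]:
        return [e for e in self.events if isinstance(e, FixationEvent)]

    @property
    def saccades(self) -> list[SaccadeEvent]:
        return [e for e in self.events if isinstance(e, SaccadeEvent)]


def _q_at(q0: float, rate: Optional[float], tau: float, lam: float) -> float:
    """Closed-form quality level after ``tau`` ms under a frozen regime."""
    if rate is None:
        return q0 * math.exp(-lam * tau)
    return 1.0 - (1.0 - q0) * math.exp(-rate * tau)


def _schedule_drop(
    states: Sequence[WordState],
    sentence: Sentence,
    word: int,
    onset: float,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> tuple[Optional[int], Optional[float]]:
    """Arm a pending integration-failure drop for this fixation, if any.

    An anomaly on word k fires during the fixation on word
    ``k + trigger_offset`` and only if k is attended then.  Whether the
    mismatch is actually detected is drawn once per anomaly, gated by the
    detecting word's predictability; the drop lands ``detection_delay`` ms
    into the fixation.
    """
    for k in attention_window(word):
        tok = sentence.tokens[k]
        an = tok.anomaly
        if an is None or k + an.trigger_offset != word:
            continue
        st = states[k]
        if st.drop_applied or st.type_i_spent:
            continue
        if not st.drop_drawn:
            p = 1.0 - params.detect_pred_weight * sentence.tokens[word].predictability
            st.drop_realized = bool(rng.random() < min(max(p, 0.0), 1.0))
            st.drop_drawn = True
        if st.drop_realized:
            return k, onset + params.detection_delay
    return None, None


def _resolve_regression(
    action: Action,
    states: Sequence[WordState],
    sentence: Sentence,
    word: int,
    gaze: float,
    targeting: TargetingConfig,
    rng: np.random.Generator,
    fixed_strategy: Optional[str],
) -> tuple[int, TargetMode, str]:
    rtype = classify_regression_type(action)
    anomaly_info = None
    if action.kind is ActionKind.REGRESS_I:
        anomaly_info = sentence.tokens[word - 1].anomaly
    target, mode = select_target(
        states=states,
        tokens=sentence.tokens,
        launch_char=gaze,
        fixated=word,
        regression_type=rtype,
        anomaly_info=anomaly_info,
        span=targeting.span,
        strategy_profile=targeting.strategy,
        rng=rng,
        force_strategy=action.wrapup,
        fixed_strategy=fixed_strategy,
    )
    return target, mode, rtype


def simulate_trial(
    sentence: Sentence,
    dynamics: Optional[DynamicsParams] = None,
    policy: Optional[ControlPolicy] = None,
    targeting: Optional[TargetingConfig] = None,
    engine: Optional[EngineConfig] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    fixed_strategy: Optional[str] = None,
    subject: int = 0,
    trial: int = 0,
    condition: str = "default",
) -> TrialRecord:
    """Simulate one reading trial and return its scanpath record.

    Deterministic given the sentence, the configurations and the seed (or
    generator).  Every regressive saccade in the record carries its release
    type and its target-selection mode.
    """
    params = dynamics or DynamicsParams()
    policy = policy or ControlPolicy()
    targeting = targeting or TargetingConfig()
    cfg = engine or EngineConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = sentence.n_words
    dt = params.dt
    states = [WordState() for _ in range(n)]
    events: list = []
    capped = False
    wrapup_used = False
    regressions_to = [0] * n

    word = min(cfg.initial_word, n - 1)
    gaze = sentence.tokens[word].center
    t = 0.0

    while True:
        onset = t
        states[word].ever_fixated = True
        states[word].last_visual_uptake_time = onset
        tokens = sentence.tokens
        rates = [uptake_rate(tok, gaze, word, params) for tok in tokens]
        lams = [decay_rate(tok, params) for tok in tokens]
        q0 = [s.Q for s in states]
        attended = attention_window(word)
        att_toks = [tokens[w] for w in attended]
        drop_word, drop_time = _schedule_drop(states, sentence, word, onset, params, rng)

        committed: Optional[Action] = None
        departure = math.inf
        ending: Optional[Action] = None
        cancelled = False
        elapsed = 0.0

        while True:
            elapsed += dt
            t = onset + elapsed
            # confidence of attended words, with midpoint quality
            for w, tok in zip(attended, att_toks):
                st = states[w]
                q_mid = _q_at(q0[w], rates[w], elapsed - dt / 2.0, lams[w])
                st.Q = q_mid  # kept current for policy/preview reads
                confidence_step(st, tok, True, dt, params)
                st.update_latches(policy, t)
            # pending integration-failure drop
            if drop_time is not None and t >= drop_time:
                apply_integration_failure(
                    states[drop_word], tokens[drop_word].anomaly, policy.theta_fwd
                )
                drop_time = None
            # decisions on the controller clock
            if committed is None:
                nxt = word + 1
                if nxt < n:
                    states[nxt].Q = _q_at(q0[nxt], rates[nxt], elapsed, lams[nxt])
                action = evaluate_policy(states, word, policy, sentence, t, wrapup_used)
                if action.kind is ActionKind.REGRESS_I:
                    ending = action
                    cancelled = True
                    elapsed = max(elapsed, policy.cancel_latency)
                    break
                if action.kind is not ActionKind.CONTINUE:
                    committed = action
                    departure = elapsed + policy.saccade_latency
                    if action.kind is ActionKind.SKIP:
                        skipped = action.target - 1
                        st = states[skipped]
                        st.C = max(
                            st.C, preview_confidence(st, tokens[skipped])
                        )
                        st.skip_licensed = True
                        st.update_latches(policy, t)
            else:
                prev = word - 1
                if prev >= 0:
                    sp = states[prev]
                    if sp.passed_fwd and sp.C < policy.theta_fwd and not sp.type_i_spent:
                        ending = Action(ActionKind.REGRESS_I, cancelled_fixation=True)
                        cancelled = True
                        elapsed = max(elapsed, policy.cancel_latency)
                        break
                if elapsed >= departure:
                    ending = committed
                    break
            if t >= cfg.max_time:
                capped = True
                break

        duration = elapsed
        # settle quality levels at the fixation's end
        for i in range(n):
            states[i].Q = _q_at(q0[i], rates[i], duration, lams[i])
        events.append(FixationEvent(word, gaze, onset, duration, cancelled))
        t = onset + duration

        if capped or ending.kind is ActionKind.END:
            break

        if ending.is_regression:
            target, mode, rtype = _resolve_regression(
                ending, states, sentence, word, gaze, targeting, rng, fixed_strategy
            )
            if regressions_to[target] + 1 > cfg.max_regressions_per_word:
                capped = True
                break
            regressions_to[target] += 1
            if rtype == "type_I":
                states[word - 1].type_i_spent = True
            if ending.wrapup:
                wrapup_used = True
        else:
            target, mode, rtype = ending.target, None, None

        if ending.is_regression:
            landing = landing_position(
                tokens[target], targeting.oculomotor_sd, sentence.text_length, rng
            )
        else:
            landing = tokens[target].center
        events.append(
            SaccadeEvent(
                kind=ending.kind,
                launch_char=gaze,
                landing_char=landing,
                amplitude=landing - gaze,
                onset=t,
                target_word=target,
                target_mode=mode,
                regression_type=rtype,
            )
        )
        word = sentence.word_at(landing)
        gaze = landing

    return TrialRecord(
        sentence=sentence,
        subject=subject,
        trial=trial,
        condition=condition,
        seed=seed,
        events=events,
        final_states=states,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# Fine-timestep reference


def oracle_trace(
    sentence: Sentence,
    dynamics: Optional[DynamicsParams] = None,
    policy: Optional[ControlPolicy] = None,
    targeting: Optional[TargetingConfig] = None,
    engine: Optional[EngineConfig] = None,
    seed: int = 0,
    dt_fine: Optional[float] = None,
    fixed_strategy: Optional[str] = None,
) -> TrialRecord:
    """Naive reference trace: full per-timestep recomputation at a fine step.

    Every word's quality is re-derived from the uptake geometry at every
    fine step and confidence is stepped with the plain per-step update;
    decisions run on the coarse controller clock ``dt`` (``dt_fine`` must
    divide it and be at most ``dt/10``).  Intended for tests only.
    """
    params = dynamics or DynamicsParams()
    policy = policy or ControlPolicy()
    targeting = targeting or TargetingConfig()
    cfg = engine or EngineConfig()
    dt = params.dt
    if dt_fine is None:
        dt_fine = dt / 10.0
    if dt_fine > dt / 10.0 + 1e-12:
        raise ConfigError("oracle dt_fine must be <= dt/10")
    ticks = round(dt / dt_fine)
    if abs(ticks * dt_fine - dt) > 1e-9:
        raise ConfigError("dt_fine must divide dt")

    rng = np.random.default_rng(seed)
    n = sentence.n_words
    states = [WordState() for _ in range(n)]
    events: list = []
    capped = False
    wrapup_used = False
    regressions_to = [0] * n

    word = min(cfg.initial_word, n - 1)
    gaze = sentence.tokens[word].center
    t = 0.0

    while True:
        onset = t
        states[word].ever_fixated = True
        states[word].last_visual_uptake_time = onset
        tokens = sentence.tokens
        attended = attention_window(word)
        drop_word, drop_time = _schedule_drop(states, sentence, word, onset, params, rng)

        committed: Optional[Action] = None
        departure = math.inf
        ending: Optional[Action] = None
        cancelled = False
        i = 0

        while True:
            i += 1
            elapsed = i * dt_fine
            t = onset + elapsed
            q_before = [states[w].Q for w in attended]
            for w, tok in enumerate(tokens):
                quality_step(states[w], tok, gaze, word, dt_fine, params, t)
            for w, q0 in zip(attended, q_before):
                st = states[w]
                q_after = st.Q
                # midpoint-quality evaluation of the confidence ODE over the
                # fine step (second-order accurate)
                st.Q = 0.5 * (q0 + q_after)
                confidence_step(st, tokens[w], True, dt_fine, params)
                st.Q = q_after
                st.update_latches(policy, t)
            if drop_time is not None and t >= drop_time - 1e-9:
                apply_integration_failure(
                    states[drop_word], tokens[drop_word].anomaly, policy.theta_fwd
                )
                drop_time = None
            if i % ticks != 0:
                continue
            if committed is None:
                action = evaluate_policy(states, word, policy, sentence, t, wrapup_used)
                if action.kind is ActionKind.REGRESS_I:
                    ending = action
                    cancelled = True
                    break
                if action.kind is not ActionKind.CONTINUE:
                    committed = action
                    departure = elapsed + policy.saccade_latency
                    if action.kind is ActionKind.SKIP:
                        skipped = action.target - 1
                        st = states[skipped]
                        st.C = max(st.C, preview_confidence(st, tokens[skipped]))
                        st.skip_licensed = True
                        st.update_latches(policy, t)
            else:
                prev = word - 1
                if prev >= 0:
                    sp = states[prev]
                    if sp.passed_fwd and sp.C < policy.theta_fwd and not sp.type_i_spent:
                        ending = Action(ActionKind.REGRESS_I, cancelled_fixation=True)
                        cancelled = True
                        break
                if elapsed >= departure - 1e-9:
                    ending = committed
                    break
            if t >= cfg.max_time:
                capped = True
                break

        duration = i * dt_fine
        if cancelled and duration < policy.cancel_latency:
            # fixate out the cancellation dead time: quality continues, the
            # cancelled confidence computation does not
            while duration < policy.cancel_latency - 1e-9:
                i += 1
                duration = i * dt_fine
                for w, tok in enumerate(tokens):
                    quality_step(states[w], tok, gaze, word, dt_fine, params, onset + duration)
        events.append(FixationEvent(word, gaze, onset, duration, cancelled))
        t = onset + duration

        if capped or ending.kind is ActionKind.END:
            break

        if ending.is_regression:
            target, mode, rtype = _resolve_regression(
                ending, states, sentence, word, gaze, targeting, rng, fixed_strategy
            )
            if regressions_to[target] + 1 > cfg.max_regressions_per_word:
                capped = True
                break
            regressions_to[target] += 1
            if rtype == "type_I":
                states[word - 1].type_i_spent = True
            if ending.wrapup:
                wrapup_used = True
        else:
            target, mode, rtype = ending.target, None, None

        if ending.is_regression:
            landing = landing_position(
                tokens[target], targeting.oculomotor_sd, sentence.text_length, rng
            )
        else:
            landing = tokens[target].center
        events.append(
            SaccadeEvent(
                kind=ending.kind,
                launch_char=gaze,
                landing_char=landing,
                amplitude=landing - gaze,
                onset=t,
                target_word=target,
                target_mode=mode,
                regression_type=rtype,
            )
        )
        word = sentence.word_at(landing)
        gaze = landing

    return TrialRecord(
        sentence=sentence,
        events=events,
        final_states=states,
        capped=capped,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Experiments and reports


def _apply_overrides(
    dynamics: DynamicsParams,
    policy: ControlPolicy,
    targeting: TargetingConfig,
    overrides: dict,
) -> tuple[DynamicsParams, ControlPolicy, TargetingConfig]:
    sections = {"dynamics": dynamics, "policy": policy, "targeting": targeting}
    for key, value in overrides.items():
        section, _, name = key.partition(".")
        if section not in sections or not name:
            raise ConfigError(f"unknown override key {key!r}")
        obj = sections[section]
        if "." in name:  # e.g. targeting.span.left_width
            sub, _, leaf = name.partition(".")
            inner = replace(getattr(obj, sub), **{leaf: value})
            sections[section] = replace(obj, **{sub: inner})
        else:
            if not hasattr(obj, name):
                raise ConfigError(f"unknown override key {key!r}")
            sections[section] = replace(obj, **{name: value})
    return sections["dynamics"], sections["policy"], sections["targeting"]


def simulate_experiment(
    corpus: Sequence[Sentence],
    conditions: Optional[Sequence[tuple[str, dict]]] = None,
    n_subjects: int = 1,
    base_seed: int = 0,
    dynamics: Optional[DynamicsParams] = None,
    policy: Optional[ControlPolicy] = None,
    targeting: Optional[TargetingConfig] = None,
    engine: Optional[EngineConfig] = None,
    out: Optional[str | Path] = None,
) -> list[TrialRecord]:
    """Run a multi-subject, multi-condition experiment.

    Conditions are named configuration overrides (dotted keys such as
    ``"policy.theta_bwd"``); trial random streams are derived from
    ``base_seed`` per (subject, sentence) and shared across conditions, so
    any two conditions form a matched paired design over identical corpora
    and subjects.  With per-subject strategies enabled, each subject's
    preferred regression strategy is drawn once from the strategy profile.
    With ``out`` set, the fixation report and per-trial summaries stream to
    ``<out>/fixations.csv`` and ``<out>/trials.jsonl`` as trials complete.
    """
    dynamics = dynamics or DynamicsParams()
    policy = policy or ControlPolicy()
    targeting = targeting or TargetingConfig()
    conditions = list(conditions) if conditions else [("default", {})]
    names = [name for name, _ in conditions]
    if len(set(names)) != len(names):
        raise ConfigError(f"condition names must be unique, got {names!r}")
    resolved = [
        (name, *_apply_overrides(dynamics, policy, targeting, ovr))
        for name, ovr in conditions
    ]

    out_fix = out_trials = None
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        out_fix = (out / "fixations.csv").open("w", encoding="utf-8", newline="")
        out_trials = (out / "trials.jsonl").open("w", encoding="utf-8")
        out_fix.write(",".join(_REPORT_COLUMNS) + "\n")

    trials: list[TrialRecord] = []
    try:
        for subject in range(n_subjects):
            fixed_strategy = None
            if targeting.per_subject_strategy:
                subj_rng = np.random.default_rng(
                    np.random.SeedSequence([base_seed, subject])
                )
                fixed_strategy = draw_strategy(targeting.strategy, subj_rng)
            for name, dyn_c, pol_c, tar_c in resolved:
                for idx, sentence in enumerate(corpus):
                    rng = np.random.default_rng(
                        np.random.SeedSequence([base_seed, subject, idx])
                    )
                    rec = simulate_trial(
                        sentence,
                        dynamics=dyn_c,
                        policy=pol_c,
                        targeting=tar_c,
                        engine=engine,
                        rng=rng,
                        seed=(base_seed, subject, idx),
                        fixed_strategy=fixed_strategy,
                        subject=subject,
                        trial=idx,
                        condition=name,
                    )
                    trials.append(rec)
                    if out_fix is not None:
                        for row in _report_rows(rec):
                            out_fix.write(
                                ",".join("" if v is None else str(v) for v in row)
                                + "\n"
                            )
                        out_trials.write(
                            json.dumps(
                                {
                                    "subject": subject,
                                    "trial": idx,
                                    "condition": name,
                                    "sentence_id": sentence.sentence_id,
                                    "n_fixations": len(rec.fixations),
                                    "n_regressions": sum(
                                        1 for s in rec.saccades if s.regression_type
                                    ),
                                    "capped": rec.capped,
                                    "seed": [base_seed, subject, idx],
                                }
                            )
                            + "\n"
                        )
    finally:
        if out_fix is not None:
            out_fix.close()
            out_trials.close()
    return trials


_REPORT_COLUMNS = [
    "subject",
    "trial",
    "condition",
    "sentence_id",
    "fixation_index",
    "word_index",
    "region_id",
    "landing_char",
    "onset_ms",
    "duration_ms",
    "cancelled",
    "next_saccade_kind",
    "next_saccade_amplitude",
    "next_target_mode",
    "next_regression_type",
    "capped",
]


def _report_rows(rec: TrialRecord):
    fixs = rec.fixations
    sacs = rec.saccades
    for i, f in enumerate(fixs):
        s = sacs[i] if i < len(sacs) else None
        yield (
            rec.subject,
            rec.trial,
            rec.condition,
            rec.sentence.sentence_id,
            i,
            f.word,
            rec.sentence.tokens[f.word].region_id,
            round(f.landing_char, 4),
            round(f.onset, 4),
            round(f.duration, 4),
            int(f.cancelled),
            s.kind.value if s else "END",
            round(s.amplitude, 4) if s else None,
            s.target_mode.value if s and s.target_mode else None,
            s.regression_type if s else None,
            int(rec.capped),
        )


def fixation_report(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the tidy fixation-report table.

    One row per fixation, annotated with the saccade that terminated it
    (kind, signed amplitude in characters, target mode, latent regression
    type); the measures layer consumes exactly this table.
    """
    rows = [row for rec in trials for row in _report_rows(rec)]
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return df
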