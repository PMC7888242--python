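"""The three-threshold control policy.

Every confidence level is monitored against three thresholds:

* ``theta_fwd`` — the forward threshold: reaching it licenses a progressive
  saccade (the speed/accuracy dial of reading).
* ``theta_bwd`` — the backward threshold: the evidence level that *prevents*
  a missing-evidence regression.  If the current word licenses a forward
  move while the previous word still sits below it, a type-II regression is
  launched instead.  At the sentence boundary the same threshold gates the
  whole-sentence wrap-up evaluation.
* ``theta_reinsp`` — the re-inspection threshold: a word that never reached
  it remains a candidate for linguistically guided regression targeting.

Two regression releases follow (the four canonical per-fixation patterns):

1. *continue* — the fixated word has not yet reached the forward threshold;
2. *type I* (integration difficulty) — the previous word's confidence drops
   back under the forward threshold after first passing it; the current
   fixation is cancelled, which is why pre-regression fixations are short;
3. *type II* (missing evidence) — the fixated word crosses the forward
   threshold while the previous word has not reached the backward
   threshold; the completed fixation is followed by a regression;
4. *forward* — the normal case (with a skip of word n+1 when parafoveal
   preview already provides sufficient confidence for it).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus import ConfigError, Sentence
from .dynamics import WordState, attention_window, preview_confidence

__all__ = [
    "ControlPolicy",
    "ActionKind",
    "Action",
    "PolicyStateError",
    "evaluate_policy",
    "wrapup_check",
    "classify_regression_type",
]


class PolicyStateError(RuntimeError):
    """The per-word states are inconsistent with the control contract."""


@dataclass(frozen=True)
class ControlPolicy:
    """Thresholds and motor latencies of the eye-movement controller.

    The threshold ordering ``theta_fwd <= theta_bwd <= theta_reinsp`` is
    enforced by default (set ``allow_unordered`` to experiment outside it).
    ``saccade_latency`` is the motor delay between a forward/skip/type-II
    decision and the eyes' departure; a type-I cancellation instead replaces
    the remaining planned fixation, with ``cancel_latency`` as the minimum
    realizable fixation duration.  ``wrapup_score`` selects the
    sentence-evidence aggregate (weakest link ``"min"`` or ``"mean"``).
    """

    theta_fwd: float = 0.5
    theta_bwd: float = 0.64
    theta_reinsp: float = 0.8
    theta_skip: float = 0.5
    saccade_latency: float = 50.0
    cancel_latency: float = 40.0
    wrapup_score: str = "min"
    allow_unordered: bool = False

    def __post_init__(self) -> None:
        for name in ("theta_fwd", "theta_bwd", "theta_reinsp"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"ControlPolicy.{name} must lie in (0, 1), got {v!r}")
        if not self.allow_unordered and not (
            self.theta_fwd <= self.theta_bwd <= self.theta_reinsp
        ):
            raise ConfigError(
                "ControlPolicy requires theta_fwd <= theta_bwd <= theta_reinsp "
                f"(got {self.theta_fwd}, {self.theta_bwd}, {self.theta_reinsp}); "
                "set allow_unordered=True to override"
            )
        if self.saccade_latency < 0 or self.cancel_latency < 0:
            raise ConfigError("ControlPolicy latencies must be >= 0")
        if self.wrapup_score not in ("min", "mean"):
            raise ConfigError(
                f"ControlPolicy.wrapup_score must be 'min' or 'mean', "
                f"got {self.wrapup_score!r}"
            )


class ActionKind(str, enum.Enum):
    CONTINUE = "CONTINUE"
    FORWARD = "FORWARD"
    SKIP = "SKIP"
    REGRESS_I = "REGRESS_I"
    REGRESS_II = "REGRESS_II"
    END = "END"


@dataclass(frozen=True)
class Action:
    kind: ActionKind
    target: Optional[int] = None
    cancelled_fixation: bool = False
    wrapup: bool = False

    def __post_init__(self) -> None:
        if self.kind is ActionKind.REGRESS_I and not self.cancelled_fixation:
            raise ConfigError("REGRESS_I always cancels the ongoing fixation")

    @property
    def is_regression(self) -> bool:
        return self.kind in (ActionKind.REGRESS_I, ActionKind.REGRESS_II)


def evaluate_policy(
    states: Sequence[WordState],
    fixated: int,
    policy: ControlPolicy,
    sentence: Sentence,
    t: float,
    wrapup_used: bool = False,
) -> Action:
    """One decision of the control policy during a fixation.

    Order per timestep: (a) a detected integration failure of the attended
    previous word (``passed_fwd`` set, current confidence back under the
    forward threshold) preempts everything and cancels the fixation —
    type I; (b) once the fixated word reaches the forward threshold, the
    previous word's first pass is evaluated exactly once against the
    backward threshold (type II on failure), then the skip check on word
    n+1's preview confidence, then the normal forward move; on the final
    word the forward crossing instead routes into :func:`wrapup_check`;
    (c) otherwise continue fixating.

    Threshold crossings are inclusive (``>=``); ties resolve toward action.
    Marks the previous word's backward evaluation as consumed (by design a
    single evaluation per first pass, preventing re-triggering).
    """
    n = sentence.n_words
    if not (0 <= fixated < n):
        raise PolicyStateError(f"fixated index {fixated} out of range")
    if not states[fixated].ever_fixated:
        raise PolicyStateError(f"word {fixated} evaluated but never fixated")

    attended = attention_window(fixated)
    prev = fixated - 1 if fixated > 0 else None

    # (a) type-I release: integration failure of the attended previous word.
    if prev is not None and prev in attended:
        sp = states[prev]
        if sp.passed_fwd and sp.C < policy.theta_fwd and not sp.type_i_spent:
            return Action(ActionKind.REGRESS_I, cancelled_fixation=True)

    # (b) forward threshold reached on the fixated word.
    if states[fixated].C >= policy.theta_fwd:
        if prev is not None and not states[prev].bwd_evaluated:
            states[prev].bwd_evaluated = True
            # only a word with a first pass (fixated, or deliberately skipped
            # on preview evidence) has anything to evaluate; a word passed
            # over by oculomotor error is left to the wrap-up evaluation.
            # A word whose integration failed (confidence drop applied) is
            # the type-I mechanism's case — revoked evidence, not missing
            # evidence — and is excluded from the backward check.
            sp = states[prev]
            had_first_pass = sp.ever_fixated or sp.skip_licensed
            if had_first_pass and not sp.drop_applied and sp.C < policy.theta_bwd:
                return Action(ActionKind.REGRESS_II, target=prev)
        if sentence.tokens[fixated].is_final:
            return wrapup_check(states, sentence, policy, fixated, wrapup_used)
        nxt = fixated + 1
        if nxt + 1 < n and not sentence.tokens[nxt].is_final:
            if (
                preview_confidence(states[nxt], sentence.tokens[nxt])
                >= policy.theta_skip
            ):
                return Action(ActionKind.SKIP, target=nxt + 1)
        return Action(ActionKind.FORWARD, target=nxt)

    # (c) keep fixating.
    return Action(ActionKind.CONTINUE)


def wrapup_check(
    states: Sequence[WordState],
    sentence: Sentence,
    policy: ControlPolicy,
    fixated: Optional[int] = None,
    wrapup_used: bool = False,
) -> Action:
    """Whole-sentence evaluation at the boundary.

    Once the final word has reached the forward threshold, the sentence
    evidence score aggregates the latched maximum confidence of every word
    whose attendance lies in the past (the currently fixated word is still
    being evaluated by the forward check itself).  A score below the
    backward threshold releases a wrap-up (type II) regression, whose
    target is chosen by the experience-based strategy route; otherwise the
    trial ends.  Raising the backward threshold can only flip END into a
    regression, never the reverse.
    """
    if fixated is None:
        fixated = sentence.n_words - 1
    if not sentence.tokens[fixated].is_final:
        raise PolicyStateError(
            f"wrapup_check called on non-final word {fixated}"
        )
    history = [s.max_C for i, s in enumerate(states) if i != fixated]
    score = min(history) if policy.wrapup_score == "min" else sum(history) / len(history)
    if score < policy.theta_bwd and not wrapup_used:
        return Action(ActionKind.REGRESS_II, wrapup=True)
    return Action(ActionKind.END)


def classify_regression_type(action: Action) -> str:
    """Label a regression by its release: confidence drop vs missing evidence."""
    if action.kind is ActionKind.REGRESS_I:
        return "type_I"
    if action.kind is ActionKind.REGRESS_II:
        return "type_II"
    raise ConfigError(f"not a regression action: {action.kind}")
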