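"""Word-level confidence and lexical-quality dynamics.

Each word carries two coupled levels:

* the **lexical quality level** ``Q`` — the fraction of the word's lexical
  feature bundle retrieved so far.  It rises under visual uptake (foveally,
  or parafoveally at reduced rate within the rightward perceptual span) and
  decays exponentially once uptake stops, reflecting interference from
  subsequently read material.
* the **confidence level** ``C`` — graded belief in the word's identity,
  built by matching retrieved features against context predictions.  It can
  only be computed while the word is inside the two-word attention span and
  approaches its asymptote at a rate proportional to the current quality
  level and to the word's predictability.

Both follow saturating first-order kinetics; within a timestep the rates are
frozen and the resulting linear ODE is integrated exactly, so k small decay
steps compose to one large step to machine precision.

Word frequency acts on quality accrual (lexical retrieval), predictability
on confidence accrual (prediction matching); this separation is what lets
the two variables dissociate in regression behavior.  Confidence drops are
instantaneous multiplicative events applied when a word's integration into
the sentence structure fails — typically detected one word downstream,
because higher-order integration continues after the eyes have moved on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .corpus import AnomalySpec, ConfigError, WordToken

__all__ = [
    "DynamicsParams",
    "WordState",
    "IntegrationError",
    "uptake_rate",
    "confidence_rate",
    "advance_quality",
    "advance_confidence",
    "quality_step",
    "confidence_step",
    "preview_confidence",
    "apply_integration_failure",
    "attention_window",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Rate parameters of the level dynamics (all rates per millisecond).

    r_q : base quality accrual rate under foveal uptake.
    lambda_decay : quality decay rate once uptake stops.
    r_c : base confidence accrual rate (per unit quality).
    c_max : confidence asymptote.
    preview_factor : multiplier on parafoveal (non-fixated) uptake.
    ecc_scale : characters; hyperbolic eccentricity half-rate constant —
        uptake is weighted by ``ecc_scale / (ecc_scale + distance)``.
    right_span : characters of rightward perceptual span with visual uptake.
    freq_slope : couples standardized log frequency into the quality rate
        (``exp(freq_slope * log_freq)``); rarer words retrieve slower.
    length_slope : exponent of the ``(length_ref / length)`` factor on the
        quality rate; longer words have larger feature bundles.
    pred_slope : couples predictability into the confidence rate
        (``1 + pred_slope * pred``); predictable words need less evidence.
    detection_delay : ms into a fixation at which spillover integration of
        the previous word completes and a pending mismatch drops its
        confidence.
    detect_pred_weight : gates mismatch detection by the fixated word's
        predictability — detection probability ``1 - w * pred``; a word that
        fits its context poorly surfaces integration problems more often.
    end_interference : multiplier on the quality decay rate of
        boundary-adjacent words (the last three of a sentence): the
        parafoveally signalled sentence boundary engages whole-sentence
        integration, which interferes with consolidating the newest words'
        lexical traces.
    boundary_load : proportional slow-down of confidence accrual for
        boundary-adjacent words (effective rate ``r_c / (1 + load)``): the
        whole-sentence evaluation competes with accumulating predictive
        evidence for the newest words.  Together with ``end_interference``
        this is what makes missing-evidence races fail predominantly at the
        sentence end, and it lengthens sentence-final fixations.
    dt : controller timestep in ms.
    """

    r_q: float = 0.014
    lambda_decay: float = 0.008
    r_c: float = 0.007
    c_max: float = 1.0
    preview_factor: float = 0.6
    ecc_scale: float = 4.0
    right_span: float = 15.0
    freq_slope: float = 0.25
    length_slope: float = 0.5
    length_ref: float = 5.0
    pred_slope: float = 1.0
    detection_delay: float = 125.0
    detect_pred_weight: float = 1.0
    end_interference: float = 6.0
    boundary_load: float = 0.5
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r_q", "lambda_decay", "r_c", "dt", "ecc_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"DynamicsParams.{name} must be > 0")
        if not (0.0 < self.c_max <= 1.0):
            raise ConfigError("DynamicsParams.c_max must lie in (0, 1]")
        if not (0.0 <= self.preview_factor <= 1.0):
            raise ConfigError("DynamicsParams.preview_factor must lie in [0, 1]")
        if self.detection_delay < 0 or self.right_span < 0:
            raise ConfigError("DynamicsParams delays/spans must be >= 0")


@dataclass
class WordState:
    """Dynamic state of one word within a trial.

    Threshold latches record first-crossing history and never un-set: a word
    whose confidence later falls below the forward threshold keeps
    ``passed_fwd=True`` with current ``C`` below the threshold — exactly the
    type-I trigger condition.
    """

    C: float = 0.0
    Q: float = 0.0
    max_C: float = 0.0
    passed_fwd: bool = False
    passed_bwd: bool = False
    passed_reinsp: bool = False
    t_passed_fwd: Optional[float] = None
    t_passed_bwd: Optional[float] = None
    t_passed_reinsp: Optional[float] = None
    ever_fixated: bool = False
    last_visual_uptake_time: Optional[float] = None
    # engine bookkeeping
    drop_applied: bool = False
    drop_drawn: bool = False
    drop_realized: bool = False
    bwd_evaluated: bool = False
    type_i_spent: bool = False
    skip_licensed: bool = False

    def update_latches(self, policy, t: float) -> None:
        """Latch threshold crossings (inclusive, ties toward action)."""
        if self.C > self.max_C:
            self.max_C = self.C
        if not self.passed_fwd and self.C >= policy.theta_fwd:
            self.passed_fwd = True
            self.t_passed_fwd = t
        if not self.passed_bwd and self.C >= policy.theta_bwd:
            self.passed_bwd = True
            self.t_passed_bwd = t
        if not self.passed_reinsp and self.C >= policy.theta_reinsp:
            self.passed_reinsp = True
            self.t_passed_reinsp = t


class IntegrationError(RuntimeError):
    """Contract violation in the integration-failure machinery."""


def uptake_rate(
    token: WordToken,
    gaze_char: float,
    fixated_word: int,
    params: DynamicsParams,
) -> Optional[float]:
    """Effective quality accrual rate, or ``None`` when the word decays.

    A word receives visual uptake when it is the fixated word or when its
    center lies within ``right_span`` characters to the right of the gaze
    position (parafoveal preview, scaled by ``preview_factor``).  The rate
    is weighted hyperbolically by the eccentricity of the word center and
    modulated by frequency and length.
    """
    fixated = token.index == fixated_word
    dist = abs(token.center - gaze_char)
    if not fixated:
        if not (gaze_char < token.center <= gaze_char + params.right_span):
            return None
    rate = (
        params.r_q
        * math.exp(params.freq_slope * token.log_freq)
        * (params.length_ref / token.length) ** params.length_slope
        * params.ecc_scale
        / (params.ecc_scale + dist)
    )
    if not fixated:
        rate *= params.preview_factor
    return rate


def confidence_rate(q: float, token: WordToken, params: DynamicsParams) -> float:
    """Instantaneous confidence accrual rate coefficient at quality ``q``."""
    rate = params.r_c * (1.0 + params.pred_slope * token.predictability) * q
    if token.near_boundary:
        rate /= 1.0 + params.boundary_load
    return rate


def decay_rate(token: WordToken, params: DynamicsParams) -> float:
    """Quality decay rate, with boundary interference for sentence-final words."""
    if token.near_boundary:
        return params.lambda_decay * params.end_interference
    return params.lambda_decay


def advance_quality(
    q: float,
    rate: Optional[float],
    dt: float,
    params: DynamicsParams,
    lam: Optional[float] = None,
) -> float:
    """Advance quality by ``dt`` ms under a frozen uptake regime (exact)."""
    if rate is None:
        return q * math.exp(-(params.lambda_decay if lam is None else lam) * dt)
    return 1.0 - (1.0 - q) * math.exp(-rate * dt)


def advance_confidence(
    c: float, rho: float, dt: float, params: DynamicsParams
) -> float:
    """Advance confidence by ``dt`` ms at frozen rate coefficient ``rho``."""
    return params.c_max - (params.c_max - c) * math.exp(-rho * dt)


def quality_step(
    state: WordState,
    token: WordToken,
    gaze_char: float,
    fixated_word: int,
    dt: float,
    params: DynamicsParams,
    t: float = 0.0,
) -> WordState:
    """One quality timestep: uptake toward 1 within the visual span, decay outside.

    Mutates and returns ``state``.  ``Q`` stays strictly below 1 ("never
    reaching the full quality level") and the decay branch is an exact
    exponential, so repeated small steps equal one large step.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    rate = uptake_rate(token, gaze_char, fixated_word, params)
    state.Q = advance_quality(state.Q, rate, dt, params, lam=decay_rate(token, params))
    if rate is not None:
        state.last_visual_uptake_time = t
    return state


def confidence_step(
    state: WordState,
    token: WordToken,
    in_attention: bool,
    dt: float,
    params: DynamicsParams,
) -> WordState:
    """One confidence timestep; no-op outside the attention span.

    Confidence computation always requires attention: outside the two-word
    window ``C`` is frozen.  Inside, it approaches ``c_max`` at a rate
    proportional to the current quality level and boosted by
    predictability.  Mutates and returns ``state``.
    """
    if dt <= 0:
        raise ConfigError("dt must be > 0")
    if not in_attention or state.Q <= 0.0:
        return state
    rho = confidence_rate(state.Q, token, params)
    state.C = advance_confidence(state.C, rho, dt, params)
    return state


def preview_confidence(state: WordState, token: WordToken) -> float:
    """Parafoveal preview confidence proxy licensing a skip.

    True confidence is only computed inside the attention span, so the skip
    decision uses a preview score built from the parafoveally accrued
    quality level, weighted toward predictable words:
    ``Q * (0.5 + 0.5 * predictability)``.
    """
    return state.Q * (0.5 + 0.5 * token.predictability)


def apply_integration_failure(
    state: WordState,
    spec: AnomalySpec,
    theta_fwd: Optional[float] = None,
) -> bool:
    """Apply an integration-failure confidence drop (single-shot).

    The word's confidence falls by the fraction ``mismatch_magnitude``;
    latch flags are untouched, so a word that had passed the forward
    threshold retains that history.  Returns ``True`` when the drop leaves
    the current confidence below ``theta_fwd`` with ``passed_fwd`` set —
    the type-I regression trigger condition.
    """
    if state.drop_applied:
        raise IntegrationError("integration failure already applied to this word")
    state.C *= 1.0 - spec.mismatch_magnitude
    state.drop_applied = True
    if theta_fwd is None:
        return False
    return state.passed_fwd and state.C < theta_fwd


def attention_window(fixated_word: int) -> tuple[int, ...]:
    """The two-word attention span: the fixated word and the word before."""
    if fixated_word < 0:
        raise ConfigError(f"fixated_word must be >= 0, got {fixated_word!r}")
    if fixated_word == 0:
        return (0,)
    return (fixated_word - 1, fixated_word)
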