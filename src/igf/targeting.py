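"""Regression target selection: the linguistic route and the strategy route.

A regression target is chosen one of two ways.  If linguistic processing
indicates that information about the immediately preceding word would help
(or the failure is attributed to that word itself), word n−1 is targeted
directly — it is still inside the attention span.  Otherwise the leftward
perceptual span (about 15–20 characters from the launch position) is
scanned for words whose confidence never reached the re-inspection
threshold: a *unique* such candidate is selected linguistically.  With zero
or several candidates the backward control mechanism falls back on
experience-based strategies — re-reading ab initio, right-to-left
backtracking, or selective re-inspection of low-predictability words — and
strategy targets are *not* bounded by the perceptual span.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import AnomalySpec, ConfigError, WordToken
from .dynamics import WordState

__all__ = [
    "StrategyProfile",
    "PerceptualSpan",
    "TargetingConfig",
    "TargetMode",
    "TargetingError",
    "select_target",
    "landing_position",
    "draw_strategy",
]


class TargetingError(RuntimeError):
    """No leftward target exists for the requested regression."""


class TargetMode(str, enum.Enum):
    N_MINUS_1 = "N_MINUS_1"
    LINGUISTIC = "LINGUISTIC"
    STRATEGY_RESTART = "STRATEGY_RESTART"
    STRATEGY_BACKTRACK = "STRATEGY_BACKTRACK"
    STRATEGY_SELECTIVE = "STRATEGY_SELECTIVE"


_STRATEGIES = ("RESTART", "BACKTRACK", "SELECTIVE")


@dataclass(frozen=True)
class StrategyProfile:
    """Mixture over the three experience-based regression strategies.

    Strategy preferences mainly differ between individuals; with
    per-subject assignment each simulated reader keeps one strategy for the
    whole experiment.  ``selective_bias`` steers the SELECTIVE strategy
    toward low-predictability words (sampling weight
    ``1 + selective_bias * (1 - predictability)``; 0 means uniform).
    """

    restart: float = 0.5
    backtrack: float = 0.25
    selective: float = 0.25
    selective_bias: float = 2.0

    def __post_init__(self) -> None:
        w = (self.restart, self.backtrack, self.selective)
        if any(x < 0 for x in w):
            raise ConfigError(f"strategy weights must be >= 0, got {w!r}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ConfigError(f"strategy weights must sum to 1, got {sum(w)!r}")
        if self.selective_bias < 0:
            raise ConfigError("selective_bias must be >= 0")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.restart, self.backtrack, self.selective)


@dataclass(frozen=True)
class PerceptualSpan:
    """Asymmetric perceptual span in characters around the fixation.

    The leftward extent bounds linguistic regression targeting (valid range
    15–20 characters unless explicitly overridden); the rightward extent
    bounds parafoveal visual uptake.
    """

    left_width: float = 17.0
    right_width: float = 15.0
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if not self.allow_out_of_range and not (15.0 <= self.left_width <= 20.0):
            raise ConfigError(
                f"PerceptualSpan.left_width must lie in [15, 20] "
                f"(got {self.left_width!r}); set allow_out_of_range=True to override"
            )
        if self.right_width <= 0:
            raise ConfigError("PerceptualSpan.right_width must be > 0")


@dataclass(frozen=True)
class TargetingConfig:
    span: PerceptualSpan = field(default_factory=PerceptualSpan)
    strategy: StrategyProfile = field(default_factory=StrategyProfile)
    oculomotor_sd: float = 1.5
    per_subject_strategy: bool = False

    def __post_init__(self) -> None:
        if self.oculomotor_sd < 0:
            raise ConfigError("oculomotor_sd must be >= 0")


def draw_strategy(profile: StrategyProfile, rng: np.random.Generator) -> str:
    """Draw one strategy name from the profile's mixture weights."""
    u = rng.random()
    acc = 0.0
    for name, w in zip(_STRATEGIES, profile.weights):
        acc += w
        if u < acc:
            return name
    return _STRATEGIES[-1]


def select_target(
    states: Sequence[WordState],
    tokens: Sequence[WordToken],
    launch_char: float,
    fixated: int,
    regression_type: str,
    anomaly_info: Optional[AnomalySpec],
    span: PerceptualSpan,
    strategy_profile: StrategyProfile,
    rng: np.random.Generator,
    force_strategy: bool = False,
    fixed_strategy: Optional[str] = None,
) -> tuple[int, TargetMode]:
    """Select the landing word of a regression.

    Route order: (1) word n−1, when linguistic processing attributes the
    problem there — i.e. the anomaly names ``fixated-1`` as the helpful
    target, the anomaly names no helpful target at all (type I, the dropped
    word itself is the problem), or there is no anomaly (type II, the word
    with missing evidence *is* n−1); (2) the unique word, other than n−1,
    whose span intersects the leftward window
    ``[launch_char - left_width, launch_char)`` and whose confidence never
    reached the re-inspection threshold; (3) a strategy draw — RESTART
    targets the sentence beginning, BACKTRACK the preceding word, SELECTIVE
    samples an earlier word weighted toward low predictability.  Wrap-up
    regressions pass ``force_strategy=True``: the whole-sentence evaluation
    names no single problem word.
    """
    if fixated <= 0:
        raise TargetingError("no leftward regression target exists from word 0")

    if not force_strategy:
        # Route 1: word n-1 by direct linguistic attribution.
        if anomaly_info is None:
            return fixated - 1, TargetMode.N_MINUS_1
        if regression_type == "type_I" and (
            anomaly_info.helpful_target is None
            or anomaly_info.helpful_target == fixated - 1
        ):
            return fixated - 1, TargetMode.N_MINUS_1

        # Route 2: unique under-reinspection word in the leftward span.
        lo = launch_char - span.left_width
        candidates = [
            i
            for i, tok in enumerate(tokens)
            if i != fixated
            and i != fixated - 1
            and not states[i].passed_reinsp
            and tok.char_span[0] < launch_char
            and tok.char_span[1] > lo
        ]
        if len(candidates) == 1:
            return candidates[0], TargetMode.LINGUISTIC

    # Route 3: experience-based strategy.
    name = fixed_strategy or draw_strategy(strategy_profile, rng)
    if name == "RESTART":
        return 0, TargetMode.STRATEGY_RESTART
    if name == "BACKTRACK":
        return fixated - 1, TargetMode.STRATEGY_BACKTRACK
    if name == "SELECTIVE":
        idx = np.arange(fixated)
        w = 1.0 + strategy_profile.selective_bias * (
            1.0 - np.array([tokens[i].predictability for i in idx])
        )
        w = w / w.sum()
        u = rng.random()
        target = int(idx[np.searchsorted(np.cumsum(w), u)])
        return target, TargetMode.STRATEGY_SELECTIVE
    raise ConfigError(f"unknown strategy {name!r}")  # pragma: no cover


def landing_position(
    token: WordToken,
    oculomotor_sd: float,
    text_length: float,
    rng: np.random.Generator,
) -> float:
    """Realized landing character: Gaussian error around the word center.

    The perturbation is truncated to the sentence extent.  One normal
    variate is always consumed (even at ``sd=0``) so that the random stream
    does not depend on parameter values.
    """
    if oculomotor_sd < 0:
        raise ConfigError("oculomotor_sd must be >= 0")
    pos = token.center + rng.standard_normal() * oculomotor_sd
    return float(min(max(pos, 0.0), text_length - 1e-9))
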