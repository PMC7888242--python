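"""Sentence materials: lexical annotations, regions, and a seeded synthetic generator.

Sentences are abstract token sequences — each word carries the three lexical
variables that drive the reader model (length in characters, standardized
natural-log corpus frequency, and cloze predictability) plus its character
span within the sentence.  No orthographic strings are involved: the model
consumes annotations, not text.  Character coordinates are 0-based and
half-open; every token's span includes its single trailing space except the
final word, so spans tile ``[0, text_length)`` exactly.  Sentence-final
punctuation is represented by the ``is_final`` flag on the last token (the
model treats punctuation as a parafoveally available boundary signal, not a
fixation target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AnomalySpec",
    "WordToken",
    "Sentence",
    "ConfigError",
    "CorpusFormatError",
    "build_sentence",
    "generate_corpus",
    "assign_regions",
    "read_corpus",
    "write_corpus",
]


class ConfigError(ValueError):
    """A configuration value is out of its documented domain."""


class CorpusFormatError(ValueError):
    """A corpus file contains a malformed or invariant-violating record."""


@dataclass(frozen=True)
class AnomalySpec:
    """An integration anomaly attached to a word.

    When the carrying word's integration fails, the confidence of that word
    drops by the fraction ``mismatch_magnitude`` during the fixation on word
    ``index + trigger_offset``.  ``helpful_target`` names the earlier word
    whose re-inspection would resolve the problem (garden-path-like cases,
    where the word at which trouble surfaces is not the word that caused it);
    ``None`` attributes the failure to the anomalous word itself.
    """

    mismatch_magnitude: float
    helpful_target: Optional[int] = None
    trigger_offset: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.mismatch_magnitude <= 1.0):
            raise ConfigError(
                f"AnomalySpec.mismatch_magnitude must lie in (0, 1], "
                f"got {self.mismatch_magnitude!r}"
            )
        if self.trigger_offset < 1:
            raise ConfigError(
                f"AnomalySpec.trigger_offset must be >= 1, got {self.trigger_offset!r}"
            )


@dataclass(frozen=True)
class WordToken:
    index: int
    length: int
    log_freq: float
    predictability: float
    char_span: tuple[int, int]
    region_id: int = 0
    anomaly: Optional[AnomalySpec] = None
    is_final: bool = False
    # derived: set for the last three words of a sentence, whose quality
    # traces suffer elevated interference from the imminent whole-sentence
    # evaluation (the parafoveally visible boundary); recomputed on load
    near_boundary: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigError(f"WordToken.length must be >= 1, got {self.length!r}")
        if not (0.0 <= self.predictability <= 1.0):
            raise ConfigError(
                f"WordToken.predictability must lie in [0, 1], "
                f"got {self.predictability!r}"
            )
        start, end = self.char_span
        expected = end - start - (0 if self.is_final else 1)
        if expected != self.length:
            raise ConfigError(
                f"WordToken.char_span {self.char_span!r} inconsistent with "
                f"length {self.length} (trailing space rule)"
            )
        if self.anomaly is not None and self.anomaly.helpful_target is not None:
            if not (0 <= self.anomaly.helpful_target < self.index):
                raise ConfigError(
                    f"AnomalySpec.helpful_target must precede the anomalous word "
                    f"(word {self.index}), got {self.anomaly.helpful_target!r}"
                )

    @property
    def start(self) -> int:
        return self.char_span[0]

    @property
    def end(self) -> int:
        return self.char_span[1]

    @property
    def center(self) -> float:
        """Center of the word's letters (trailing space excluded)."""
        return self.char_span[0] + self.length / 2.0


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[WordToken, ...]
    region_scheme: dict[int, str] = field(default_factory=dict)
    sentence_id: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ConfigError("Sentence needs at least 2 tokens")
        finals = [t for t in self.tokens if t.is_final]
        if len(finals) != 1 or not self.tokens[-1].is_final:
            raise ConfigError("exactly the last token must have is_final=True")
        pos = 0
        for tok in self.tokens:
            if tok.char_span[0] != pos:
                raise ConfigError(
                    f"char_spans must tile the sentence; word {tok.index} "
                    f"starts at {tok.char_span[0]}, expected {pos}"
                )
            pos = tok.char_span[1]

    @property
    def n_words(self) -> int:
        return len(self.tokens)

    @property
    def text_length(self) -> int:
        return self.tokens[-1].char_span[1]

    def word_at(self, char: float) -> int:
        """Index of the token whose span contains character position ``char``."""
        c = min(max(char, 0.0), self.text_length - 1e-9)
        for tok in self.tokens:
            if tok.char_span[0] <= c < tok.char_span[1]:
                return tok.index
        return self.n_words - 1  # pragma: no cover - unreachable after clamping

    def region_of(self, word: int) -> int:
        return self.tokens[word].region_id


def build_sentence(
    lengths: Sequence[int],
    log_freqs: Sequence[float],
    predictabilities: Sequence[float],
    anomalies: Optional[dict[int, AnomalySpec]] = None,
    region_ids: Optional[Sequence[int]] = None,
    sentence_id: int = 0,
) -> Sentence:
    """Assemble a :class:`Sentence` from parallel attribute sequences.

    Character spans are derived from the lengths (one trailing space per
    word, none after the last); regions default to one region per word.
    """
    n = len(lengths)
    if not (len(log_freqs) == len(predictabilities) == n):
        raise ConfigError("lengths, log_freqs, predictabilities must align")
    anomalies = anomalies or {}
    if region_ids is None:
        region_ids = list(range(n))
    tokens = []
    pos = 0
    for i in range(n):
        final = i == n - 1
        end = pos + int(lengths[i]) + (0 if final else 1)
        tokens.append(
            WordToken(
                index=i,
                length=int(lengths[i]),
                log_freq=float(log_freqs[i]),
                predictability=float(predictabilities[i]),
                char_span=(pos, end),
                region_id=int(region_ids[i]),
                anomaly=anomalies.get(i),
                is_final=final,
                near_boundary=i >= n - 3,
            )
        )
        pos = end
    scheme = {int(r): f"R{int(r)}" for r in dict.fromkeys(region_ids)}
    return Sentence(tokens=tuple(tokens), region_scheme=scheme, sentence_id=sentence_id)


def _length_pmf(lo: int, hi: int, mode: int) -> np.ndarray:
    """Discrete triangular pmf over [lo, hi] peaked at ``mode``."""
    lengths = np.arange(lo, hi + 1)
    left = (lengths - lo + 1) / (mode - lo + 1)
    right = (hi - lengths + 1) / (hi - mode + 1)
    w = np.minimum(left, right).astype(float)
    return w / w.sum()


def generate_corpus(
    n_sentences: int,
    words_per_sentence: tuple[int, int] = (8, 12),
    anomaly_rate: float = 0.35,
    seed: int = 0,
    length_range: tuple[int, int] = (2, 12),
    length_mode: int = 5,
    pred_beta: tuple[float, float] = (1.2, 3.0),
    helpful_target_rate: float = 0.2,
    mismatch_range: tuple[float, float] = (0.1, 0.7),
) -> list[Sentence]:
    """Generate a seeded synthetic corpus.

    Word lengths are drawn from a discrete triangular distribution on
    ``length_range`` (mode ``length_mode``), predictability from
    ``Beta(*pred_beta)``, log-frequency from a standard normal.  With
    probability ``anomaly_rate`` one random interior (non-initial,
    non-final) word carries an :class:`AnomalySpec` whose drop magnitude is
    uniform on ``mismatch_range``; with probability ``helpful_target_rate``
    the anomaly names a random earlier word as the helpful re-inspection
    target, otherwise the failure is attributed to the anomalous word
    itself.  Identical seeds give identical corpora.
    """
    if n_sentences < 1:
        raise ConfigError(f"n_sentences must be >= 1, got {n_sentences!r}")
    lo, hi = words_per_sentence
    if not (2 <= lo <= hi):
        raise ConfigError(f"words_per_sentence range invalid: {words_per_sentence!r}")
    if not (0.0 <= anomaly_rate <= 1.0):
        raise ConfigError(f"anomaly_rate must lie in [0, 1], got {anomaly_rate!r}")
    llo, lhi = length_range
    if not (1 <= llo <= length_mode <= lhi):
        raise ConfigError(
            f"length_range/length_mode invalid: {length_range!r}, {length_mode!r}"
        )
    a, b = pred_beta
    if a <= 0 or b <= 0:
        raise ConfigError(f"pred_beta parameters must be > 0, got {pred_beta!r}")
    dlo, dhi = mismatch_range
    if not (0.0 < dlo <= dhi <= 1.0):
        raise ConfigError(f"mismatch_range must lie in (0, 1], got {mismatch_range!r}")

    rng = np.random.default_rng(seed)
    pmf = _length_pmf(llo, lhi, length_mode)
    support = np.arange(llo, lhi + 1)
    sentences = []
    for s in range(n_sentences):
        n = int(rng.integers(lo, hi + 1))
        lengths = rng.choice(support, size=n, p=pmf)
        log_freqs = rng.standard_normal(n)
        preds = rng.beta(a, b, size=n)
        anomalies: dict[int, AnomalySpec] = {}
        if n > 2 and rng.random() < anomaly_rate:
            k = int(rng.integers(1, n - 1))
            helpful = None
            if k > 1 and rng.random() < helpful_target_rate:
                helpful = int(rng.integers(0, k))
            anomalies[k] = AnomalySpec(
                mismatch_magnitude=float(rng.uniform(dlo, dhi)),
                helpful_target=helpful,
            )
        sentences.append(
            build_sentence(lengths, log_freqs, preds, anomalies, sentence_id=s)
        )
    return sentences


def assign_regions(sentence: Sentence, breakpoints: Sequence[int]) -> Sentence:
    """Re-region a sentence at word-index ``breakpoints``.

    Breakpoints are strictly increasing indices in ``[1, n_words)``; region
    ``r`` covers the words between breakpoint ``r-1`` (inclusive) and
    breakpoint ``r`` (exclusive).  Token order and spans are untouched.
    """
    n = sentence.n_words
    bps = list(breakpoints)
    if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
        raise ConfigError(f"breakpoints must be strictly increasing, got {bps!r}")
    if bps and not (1 <= bps[0] and bps[-1] < n):
        raise ConfigError(f"breakpoints must lie in [1, n_words), got {bps!r}")
    region_of_word = np.searchsorted(bps, np.arange(n), side="right")
    tokens = tuple(
        replace(tok, region_id=int(region_of_word[i]))
        for i, tok in enumerate(sentence.tokens)
    )
    scheme = {int(r): f"R{int(r)}" for r in dict.fromkeys(region_of_word.tolist())}
    return Sentence(
        tokens=tokens, region_scheme=scheme, sentence_id=sentence.sentence_id
    )


# ---------------------------------------------------------------------------
# File format: JSON-lines (one sentence object per line) or a tab-delimited
# flat form (one row per token).  Both round-trip exactly.

_TSV_COLUMNS = [
    "sentence_id",
    "index",
    "length",
    "log_freq",
    "predictability",
    "region_id",
    "is_final",
    "anomaly_magnitude",
    "anomaly_helpful_target",
    "anomaly_trigger_offset",
]


def _token_dict(tok: WordToken) -> dict:
    d = {
        "index": tok.index,
        "length": tok.length,
        "log_freq": tok.log_freq,
        "predictability": tok.predictability,
        "region_id": tok.region_id,
        "is_final": tok.is_final,
    }
    if tok.anomaly is not None:
        d["anomaly"] = {
            "mismatch_magnitude": tok.anomaly.mismatch_magnitude,
            "helpful_target": tok.anomaly.helpful_target,
            "trigger_offset": tok.anomaly.trigger_offset,
        }
    return d


def _sentence_from_token_dicts(
    sentence_id: int, rows: list[dict], lineno: int
) -> Sentence:
    try:
        rows = sorted(rows, key=lambda r: r["index"])
        anomalies = {}
        for r in rows:
            if r.get("anomaly"):
                anomalies[r["index"]] = AnomalySpec(**r["anomaly"])
        return build_sentence(
            lengths=[r["length"] for r in rows],
            log_freqs=[r["log_freq"] for r in rows],
            predictabilities=[r["predictability"] for r in rows],
            anomalies=anomalies,
            region_ids=[r.get("region_id", i) for i, r in enumerate(rows)],
            sentence_id=sentence_id,
        )
    except (ConfigError, KeyError, TypeError) as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def write_corpus(sentences: Sequence[Sentence], path: str | Path) -> None:
    """Write a corpus as JSON-lines (``.jsonl``/``.json``) or flat TSV (``.tsv``)."""
    path = Path(path)
    if path.suffix == ".tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for sent in sentences:
            for tok in sent.tokens:
                an = tok.anomaly
                lines.append(
                    "\t".join(
                        [
                            str(sent.sentence_id),
                            str(tok.index),
                            str(tok.length),
                            repr(tok.log_freq),
                            repr(tok.predictability),
                            str(tok.region_id),
                            str(int(tok.is_final)),
                            "" if an is None else repr(an.mismatch_magnitude),
                            ""
                            if an is None or an.helpful_target is None
                            else str(an.helpful_target),
                            "" if an is None else str(an.trigger_offset),
                        ]
                    )
                )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        with path.open("w", encoding="utf-8") as fh:
            for sent in sentences:
                fh.write(
                    json.dumps(
                        {
                            "sentence_id": sent.sentence_id,
                            "tokens": [_token_dict(t) for t in sent.tokens],
                        }
                    )
                    + "\n"
                )


def read_corpus(path: str | Path) -> list[Sentence]:
    """Read a corpus written by :func:`write_corpus`.

    Malformed records raise :class:`CorpusFormatError` carrying the line
    number; an empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return []
    if path.suffix == ".tsv":
        return _read_tsv(text)
    sentences = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
        if not isinstance(obj, dict) or "tokens" not in obj:
            raise CorpusFormatError(f"line {lineno}: expected a sentence object")
        sentences.append(
            _sentence_from_token_dicts(
                int(obj.get("sentence_id", lineno - 1)), obj["tokens"], lineno
            )
        )
    return sentences


def _read_tsv(text: str) -> list[Sentence]:
    lines = text.splitlines()
    header = lines[0].split("\t")
    if header != _TSV_COLUMNS:
        raise CorpusFormatError(f"line 1: unexpected header {header!r}")
    by_sentence: dict[int, list[tuple[int, dict]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_TSV_COLUMNS):
            raise CorpusFormatError(
                f"line {lineno}: expected {len(_TSV_COLUMNS)} fields, got {len(parts)}"
            )
        rec = dict(zip(_TSV_COLUMNS, parts))
        try:
            row = {
                "index": int(rec["index"]),
                "length": int(rec["length"]),
                "log_freq": float(rec["log_freq"]),
                "predictability": float(rec["predictability"]),
                "region_id": int(rec["region_id"]),
                "is_final": bool(int(rec["is_final"])),
            }
            if rec["anomaly_magnitude"]:
                row["anomaly"] = {
                    "mismatch_magnitude": float(rec["anomaly_magnitude"]),
                    "helpful_target": int(rec["anomaly_helpful_target"])
                    if rec["anomaly_helpful_target"]
                    else None,
                    "trigger_offset": int(rec["anomaly_trigger_offset"]),
                }
        except ValueError as exc:
            raise CorpusFormatError(f"line {lineno}: {exc}") from exc
        by_sentence.setdefault(int(rec["sentence_id"]), []).append((lineno, row))
    return [
        _sentence_from_token_dicts(sid, [r for _, r in rows], rows[0][0])
        for sid, rows in sorted(by_sentence.items())
    ]
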