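# Methods

## Model

The simulator implements an eye-movement control policy in which every
saccade decision is a function of per-word *confidence levels* monitored
against three thresholds.  The architecture rests on six assumptions:

1. Confidence in a word's identity is computed by matching predictions
   from prior context against the word's retrieved lexical representation.
2. The lexical representation is a feature bundle retrieved gradually; its
   retrieved fraction is the *lexical quality level* `Q`, which grows under
   visual uptake and decays afterwards through interference, never reaching
   the full level.
3. Confidence computation requires attention, and attention covers exactly
   two words: the fixated word and its left neighbour.  Confidence of word
   *n−1* therefore continues to develop during the fixation on word *n*
   (spillover), while earlier words are frozen.
4. Three thresholds on confidence shape behaviour: the *forward* threshold
   triggers progressive saccades (speed–accuracy dial), the *backward*
   threshold is the evidence level that prevents a missing-evidence
   regression, and the *re-inspection* threshold exempts a word from
   linguistically guided regression targeting.
5. Two releases produce regressions: an *integration failure* drops an
   already-accepted word's confidence back under the forward threshold
   (type I; the ongoing fixation is cancelled), and *missing evidence*
   releases a regression when the fixated word licenses a forward move
   while its predecessor never reached the backward threshold, including
   the whole-sentence wrap-up evaluation at the boundary (type II).
6. Regression targets are selected either linguistically — the unique word
   in the leftward perceptual span whose confidence never passed the
   re-inspection threshold, with word *n−1* as the direct attribution when
   the problem is located there — or by experience-based strategies
   (restart, backtrack, selective re-inspection) that are not bounded by
   the span.

### Dynamics

Within a timestep all rates are frozen, giving linear ODEs that are
integrated exactly:

- uptake: `Q ← 1 − (1 − Q)·exp(−r_eff·dt)` with
  `r_eff = r_q · e^{s_f · logfreq} · (L_ref/L)^{s_L} · ecc/(ecc + d)`
  (`d` = distance of the word centre from gaze; non-fixated words inside
  the rightward span are additionally scaled by `preview_factor`),
- decay: `Q ← Q·exp(−λ_eff·dt)` outside uptake,
- confidence: `C ← c_max − (c_max − C)·exp(−ρ·dt)` with
  `ρ = r_c · (1 + s_p · pred) · Q(t)`, evaluated at the midpoint quality of
  the step (second-order accurate), and only for attended words.

The spec of the saturating shape is qualitative; exponential saturation is
the minimal form satisfying it, and the multiplicative `Q` coupling encodes
that confidence is computed *over* the retrieved features.  Frequency and
length act on retrieval (`Q`), predictability on prediction matching
(`C`); this separation is what lets the two variables dissociate in
regression behaviour (the sign table below).

Integration failures are instantaneous multiplicative drops
`C ← C·(1 − δ)` applied once, `detection_delay` ms into the fixation on the
word following the anomalous one (higher-order integration lags the eyes by
about one word).  Whether a pending mismatch is detected at all is drawn
once per anomaly with probability `1 − w_det · pred(detecting word)`: a
word that fits its context poorly surfaces problems more often.  This gate
is what produces the predicted rise of type-I regressions under a less
predictable word *n*; with no anomalies in the material no confidence ever
falls and neither release can fire.

### Sentence-boundary processing

The parafoveally visible sentence boundary engages whole-sentence
integration.  In the model this loads the last three words of the
sentence twice over: their quality traces decay faster
(`λ·end_interference`) and their confidence accrual is slowed
(`r_c/(1+boundary_load)`).  Consequences: sentence-final fixations are
longer, and the missing-evidence race — does word *n−1* reach the backward
threshold before word *n* licenses a forward move? — fails predominantly
near the boundary.  Interior words clear the swept backward-threshold
range with margin, which is why a backward-threshold manipulation moves
final-region regressions-out while leaving early-region measures exactly
unchanged (the trajectories are identical until the boundary).

The wrap-up evaluation itself runs when the final word reaches the forward
threshold: the sentence-evidence score is the minimum (configurable: mean)
of the latched maximum confidences of all words whose attendance lies in
the past; a score below the backward threshold releases one wrap-up
regression per trial, targeted by the strategy route.  The currently
fixated final word is excluded from the score — its evaluation *is* the
forward check.  Two bookkeeping rules keep the releases well-defined: each
word's backward evaluation happens exactly once (at the first forward
crossing of its successor), and a word whose confidence was dropped by an
integration failure is the type-I mechanism's case — revoked evidence, not
missing evidence — and is excluded from the backward check.  Words passed
over by oculomotor error (a regression landing short) have no first pass
to evaluate and are likewise left to the wrap-up evaluation.

### Engine

The controller runs on a 1 ms clock.  Forward, skip and type-II decisions
are followed by a 50 ms motor latency during which processing continues and
a detected integration failure can still cancel the planned fixation
(minimum realizable duration 40 ms) — this cancellation is the entire
source of the shortened pre-regression fixation signature.  Saccade flight
time is folded into the latencies.  Forward and skip saccades land on the
target-word centre; regression landings get truncated Gaussian oculomotor
error (sd 1.5 characters), part of the targeting machinery.  Trials start
at the centre of word 0 at t = 0.  A per-word regression cap (3) and a
60 s simulated-time cap guard against livelock in pathological
configurations; capped trials are flagged and excluded from measures.

`oracle_trace` is a deliberately naive reference implementation — full
per-timestep recomputation of every word's state at a fine step
(≤ dt/10), decisions quantized to the same controller clock — used in
tests to bound discretization error (event kinds identical, onsets within
2·dt).

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `r_q` | 0.014 /ms | foveal quality accrual (τ ≈ 70 ms) |
| `lambda_decay` | 0.008 /ms | quality decay without uptake |
| `r_c` | 0.007 /ms | confidence accrual per unit quality |
| `c_max` | 1.0 | confidence asymptote |
| `preview_factor` | 0.6 | parafoveal uptake multiplier |
| `ecc_scale` | 4 chars | eccentricity half-rate constant |
| `right_span` | 15 chars | rightward uptake span |
| `freq_slope` / `length_slope` | 0.25 / 0.5 | lexical modulation of retrieval |
| `pred_slope` | 1.0 | predictability boost of confidence |
| `detection_delay` | 125 ms | integration lag behind the eyes |
| `end_interference` / `boundary_load` | 6 / 0.5 | sentence-boundary processing load |
| `theta_fwd` / `theta_bwd` / `theta_reinsp` | 0.5 / 0.64 / 0.8 | control thresholds |
| `theta_skip` | 0.5 | preview confidence licensing a skip (= `theta_fwd`) |
| `saccade_latency` / `cancel_latency` | 50 / 40 ms | motor delays |
| `left_width` / `oculomotor_sd` | 17 / 1.5 chars | regression targeting |

The ordering `theta_fwd ≤ theta_bwd ≤ theta_reinsp` is enforced (an
explicit flag overrides it).  Defaults were chosen once for surface
realism of the simulated records: mean forward-fixation durations around
170–200 ms, regressive saccades a few percent of inter-word saccades with
both release types present, skipping occasional, and most regression
amplitudes inside the leftward span.  The framework's predictions are
directional, not quantitative, so no fitting to human data is involved
(and the human dataset behind the framework's published re-analysis is not
public).

## Synthetic materials

The generator emulates sentence-reading stimulus sets: 8–12 words per
sentence; word lengths from a discrete triangular distribution on 2–12
characters (mode 5); standardized natural-log frequency from N(0,1);
cloze predictability from Beta(1.2, 3) (mean ≈ 0.29, right-skewed, as
cloze norms typically are); with probability 0.35 one interior word
carries an integration anomaly (drop fraction uniform on 0.1–0.7; with
probability 0.2 the anomaly names a random earlier word as the helpful
re-inspection target, the garden-path-like case).  What it does *not*
model: real lexical co-occurrence structure (frequency, length and
predictability are sampled independently), syntax, morphology, multi-line
layout, or within-word landing-position effects.  Passing property tests
therefore demonstrate that the *mechanisms* produce the predicted
qualitative contrasts under controlled materials — not that the simulator
reproduces any particular human dataset.

The property suites use dedicated probe materials: a fixed probe position
with per-sentence jitter of the probe words' attributes (so release races
stay graded rather than deterministic), marginal anomaly magnitudes that
straddle the type-I crossing point at the probe site (maximal sensitivity
of the paired contrast), and — for the type-II cells — an anomaly-free
corpus under a raised backward threshold placed at the middle of the probe
word's spillover-evidence distribution, where the missing-evidence race is
tight in both directions.  Type-I and type-II cells are measured on
separate designs because a type-I cancellation preempts the forward
crossing that a type-II release requires; running both in one corpus
confounds the directions.

## Numerical choices

- Threshold crossings are inclusive (`≥`), ties resolving toward action,
  avoiding Zeno behaviour at exact equality.
- Per-step integration is exact for frozen rates; k small decay steps
  equal one large step to machine precision.  Halving dt changes a
  2-second trajectory by well under 1 %.
- The engine evaluates quality analytically within a fixation (gaze, and
  hence every word's uptake regime, is constant between saccades) and
  steps only attended confidences; the oracle recomputes everything
  naively per fine step.  Both evaluate the confidence rate at midpoint
  quality, so their trajectories agree to ~1e-5 and decision flips at
  threshold knife-edges are correspondingly rare.
- All randomness flows through one `numpy` generator per trial, seeded as
  `(base_seed, subject, sentence)`; conditions share trial streams, so any
  two conditions form a matched pair and null effects are exact zeros.
  Reruns are byte-identical.
- Degenerate inputs: an empty corpus file is an empty corpus; a capped
  trial is flagged, never raised; empty measure cells are absent, not
  zero; units never fixated are `skipped`, units first entered from the
  right have no defined first pass.

## Design choices on open points

- `theta_skip` is a distinct threshold defaulting to `theta_fwd`; preview
  confidence is proxied by `Q·(0.5 + 0.5·pred)` since true confidence is
  only computed under attention.  A deliberately skipped word's confidence
  is initialized to the licensing preview level.
- A word may trigger at most one type-I regression per trial; one wrap-up
  regression per trial.
- Strategy draws are per event by default; a per-subject fixed strategy
  (readers preferring one strategy) is a configuration switch.
- The selective strategy samples earlier words with weight
  `1 + selective_bias·(1 − pred)` (a pure proportionality to
  `selective_bias·(1−pred)` would make the bias parameter vacuous).
- When an anomaly names no helpful target, the failure is attributed to
  the dropped word itself (word *n−1* at detection), which the simulator
  cannot judge better without a parser.

## Known limitations

- Regression shares under defaults (~4 % of inter-word saccades) sit at
  the low end of the empirical 5–20 % range: only two release mechanisms
  are modelled, with no oculomotor-error regressions (excluded by scope)
  and no comprehension-driven re-reading beyond one wrap-up pass.
- Within-word refixations are not generated (forward landings are exact);
  the measures layer nevertheless classifies and excludes them, so
  external fixation reports are handled.
- The boundary-load mechanism is a coarse stand-in for clause-level
  integration structure; real wrap-up effects track syntactic boundaries,
  not a fixed three-word window.
- The probe-suite operating points (race threshold, marginal anomaly
  magnitudes) are matched to the default dynamics; changing dynamics
  defaults requires re-centering them, as any stimulus design would be
  re-normed for a new population.
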