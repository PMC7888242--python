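"""Scanpath reading measures over fixation-report tables.

Operates on the tidy fixation report written by the engine (or the minimal
external dialect: ``subject, trial, word_index, landing_char, duration_ms``
plus optionally region ids).  All measures are purely observational — they
use word indices, durations and character positions, never the simulator's
latent labels — so the same functions apply to external eye-tracking
fixation reports.

Conventions: saccade classification covers inter-word saccades only
(within-word refixations are excluded and counted separately); first-pass
time is the summed duration of the first visit to a unit and is undefined
(flagged, not zero) for units first entered from the right; go-past time
runs from first (left) entry until the first fixation beyond the unit,
including all re-reading after regressions launched from it;
regressions-out counts regressive exits launched during the first pass.
Regression amplitudes are differences of launch and landing character
positions (spaces counted).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasuresError",
    "classify_saccades",
    "first_pass_time",
    "go_past_time",
    "regressions_out",
    "build_measures",
    "pre_saccade_duration_table",
    "amplitude_distribution",
    "landing_region_counts",
]

_TRIAL_KEYS = ["subject", "trial"]


class MeasuresError(ValueError):
    """The fixation report violates a measures-layer precondition."""


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "trial", "word_index", "duration_ms"}
    missing = required - set(df.columns)
    if missing:
        raise MeasuresError(f"fixation report lacks columns {sorted(missing)}")
    df = df.copy()
    if "capped" in df.columns:
        df = df[df["capped"] == 0]
    if "fixation_index" not in df.columns:
        df["fixation_index"] = df.groupby(_TRIAL_KEYS).cumcount()
    if "onset_ms" in df.columns:
        bad = (
            df.sort_values(_TRIAL_KEYS + ["fixation_index"])
            .groupby(_TRIAL_KEYS)["onset_ms"]
            .apply(lambda s: bool((s.diff().dropna() < 0).any()))
        )
        if bad.any():
            raise MeasuresError("fixation events are not time-ordered within trials")
    return df.sort_values(_TRIAL_KEYS + ["fixation_index"]).reset_index(drop=True)


def classify_saccades(df: pd.DataFrame) -> pd.DataFrame:
    """Label each saccade as progressive, regressive, or a refixation.

    A saccade is the transition between consecutive fixations of a trial.
    Regressive means the landing word index is smaller than the source word
    index; same-word transitions are refixations, excluded from both
    inter-word classes.  The returned table carries the source fixation's
    duration, region and character position and the landing equivalents, so
    downstream measures need no further joins.
    """
    df = _prepare(df)
    parts = []
    for _, g in df.groupby(_TRIAL_KEYS, sort=True):
        if len(g) < 2:
            continue
        src = g.iloc[:-1].reset_index(drop=True)
        dst = g.iloc[1:].reset_index(drop=True)
        part = pd.DataFrame(
            {
                "subject": src["subject"],
                "trial": src["trial"],
                "source_word": src["word_index"].to_numpy(),
                "target_word": dst["word_index"].to_numpy(),
                "source_duration_ms": src["duration_ms"].to_numpy(),
            }
        )
        for col, name in [
            ("region_id", "source_region"),
            ("landing_char", "launch_char"),
            ("condition", "condition"),
            ("sentence_id", "sentence_id"),
            ("next_regression_type", "regression_type"),
            ("next_target_mode", "target_mode"),
        ]:
            if col in src.columns:
                part[name] = src[col].to_numpy()
        if "region_id" in dst.columns:
            part["target_region"] = dst["region_id"].to_numpy()
        if "landing_char" in dst.columns:
            part["landing_char"] = dst["landing_char"].to_numpy()
            part["amplitude"] = (
                dst["landing_char"].to_numpy() - src["landing_char"].to_numpy()
            )
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=["subject", "trial", "source_word", "target_word", "kind"]
        )
    sac = pd.concat(parts, ignore_index=True)
    sac["kind"] = np.where(
        sac["target_word"] > sac["source_word"],
        "progressive",
        np.where(sac["target_word"] < sac["source_word"], "regressive", "refixation"),
    )
    return sac


def _unit_series(g: pd.DataFrame, unit: str) -> np.ndarray:
    if unit == "word":
        return g["word_index"].to_numpy()
    if unit == "region":
        if "region_id" not in g.columns:
            raise MeasuresError("unit='region' requires a region_id column")
        return g["region_id"].to_numpy()
    raise MeasuresError(f"unit must be 'word' or 'region', got {unit!r}")


def build_measures(
    df: pd.DataFrame,
    unit: str = "region",
    units: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per subject × trial × unit table of first-pass, go-past and regressions-out.

    Units never fixated are flagged ``skipped`` (measures are NA, not
    zero); units first entered from the right have no defined first pass
    (``fp_defined`` False).  Go-past of a unit never exited to the right
    runs to the end of the trial.  ``units`` optionally enumerates the full
    unit inventory of the materials, so that units a trial never visited
    still appear as skipped rows.
    """
    df = _prepare(df)
    rows = []
    for (subject, trial), g in df.groupby(_TRIAL_KEYS, sort=True):
        units_seq = _unit_series(g, unit)
        durs = g["duration_ms"].to_numpy(dtype=float)
        words = g["word_index"].to_numpy()
        fixated_units = np.unique(units_seq)
        if units is not None:
            for u in units:
                if u not in fixated_units:
                    rows.append(
                        {
                            "subject": subject,
                            "trial": trial,
                            "unit": u,
                            "first_pass_ms": np.nan,
                            "go_past_ms": np.nan,
                            "regressions_out": np.nan,
                            "skipped": True,
                            "fp_defined": False,
                        }
                    )
        for u in fixated_units:
            hits = np.flatnonzero(units_seq == u)
            first = hits[0]
            from_right = bool((units_seq[:first] > u).any())
            # first visit: contiguous run of fixations in u starting at `first`
            end = first
            while end + 1 < len(units_seq) and units_seq[end + 1] == u:
                end += 1
            fp = float(durs[first : end + 1].sum())
            # go-past: from first entry to the fixation before the first one
            # landing beyond the unit
            later = np.flatnonzero(units_seq[first:] > u)
            gp_end = first + later[0] if len(later) else len(units_seq)
            gp = float(durs[first:gp_end].sum())
            # regressions out: regressive exits launched during first pass
            n_out = 0
            for j in range(first, end + 1):
                if j + 1 < len(words) and units_seq[j + 1] < u and words[j + 1] < words[j]:
                    n_out += 1
            rows.append(
                {
                    "subject": subject,
                    "trial": trial,
                    "unit": u,
                    "first_pass_ms": fp if not from_right else np.nan,
                    "go_past_ms": gp if not from_right else np.nan,
                    "regressions_out": n_out if not from_right else np.nan,
                    "skipped": False,
                    "fp_defined": not from_right,
                }
            )
    return pd.DataFrame(rows)


def first_pass_time(df: pd.DataFrame, unit: str = "region") -> pd.DataFrame:
    """First-pass (gaze) duration per unit: all fixations of the first visit."""
    m = build_measures(df, unit)
    return m[["subject", "trial", "unit", "first_pass_ms", "skipped", "fp_defined"]]


def go_past_time(df: pd.DataFrame, unit: str = "region") -> pd.DataFrame:
    """Go-past time per unit (first entry until first exit to the right)."""
    m = build_measures(df, unit)
    return m[["subject", "trial", "unit", "go_past_ms", "skipped", "fp_defined"]]


def regressions_out(df: pd.DataFrame, unit: str = "region") -> pd.DataFrame:
    """Count of regressive saccades launched from the unit during first pass."""
    m = build_measures(df, unit)
    return m[["subject", "trial", "unit", "regressions_out", "skipped", "fp_defined"]]


def pre_saccade_duration_table(
    df: pd.DataFrame,
    region_merge: Optional[Mapping[int, str]] = None,
) -> pd.DataFrame:
    """Mean pre-saccade fixation durations by saccade type × region group.

    For every classified inter-word saccade the duration of the fixation it
    terminated is attributed to the launch region (mapped through
    ``region_merge``, e.g. onto ``{"early", "late"}``).  Cells report mean,
    sd, count and the mean log duration; empty cells are simply absent.
    """
    sac = classify_saccades(df)
    sac = sac[sac["kind"].isin(["progressive", "regressive"])]
    if "source_region" not in sac.columns:
        raise MeasuresError("pre-saccade table requires a region_id column")
    if region_merge is not None:
        sac = sac.assign(
            region_group=sac["source_region"].map(dict(region_merge))
        ).dropna(subset=["region_group"])
    else:
        sac = sac.assign(region_group=sac["source_region"])
    out = (
        sac.groupby(["region_group", "kind"])["source_duration_ms"]
        .agg(
            mean_ms="mean",
            sd_ms="std",
            n="count",
            mean_log=lambda s: float(np.log(s).mean()),
        )
        .reset_index()
    )
    return out


def amplitude_distribution(
    df: pd.DataFrame,
    window: float = 15.0,
    launch_region: Optional[int | Sequence[int]] = None,
) -> tuple[pd.DataFrame, float]:
    """Histogram of regression amplitudes and the proportion within a window.

    Amplitudes are absolute launch-to-landing distances in characters of
    regressive inter-word saccades, binned at 1 character.  Returns the
    histogram table and the proportion of regressions whose amplitude is at
    most ``window`` characters (the leftward perceptual-span check).
    ``launch_region`` restricts to regressions initiated there.
    """
    if window <= 0:
        raise MeasuresError("window must be > 0 characters")
    sac = classify_saccades(df)
    sac = sac[sac["kind"] == "regressive"]
    if launch_region is not None:
        if "source_region" not in sac.columns:
            raise MeasuresError("launch-region filter requires a region_id column")
        regions = (
            [launch_region] if np.isscalar(launch_region) else list(launch_region)
        )
        sac = sac[sac["source_region"].isin(regions)]
    if "amplitude" not in sac.columns:
        raise MeasuresError("amplitude requires landing_char positions")
    amps = sac["amplitude"].abs().to_numpy(dtype=float)
    if len(amps) == 0:
        return pd.DataFrame(columns=["amplitude_char", "count"]), float("nan")
    edges = np.arange(0, np.ceil(amps.max()) + 2)
    counts, _ = np.histogram(amps, bins=edges)
    hist = pd.DataFrame(
        {"amplitude_char": edges[:-1].astype(int), "count": counts}
    )
    return hist, float((amps <= window).mean())


def landing_region_counts(
    df: pd.DataFrame,
    launch_region: Optional[int | Sequence[int]] = None,
) -> pd.DataFrame:
    """Counts and proportions of regressive landings per sentence region."""
    sac = classify_saccades(df)
    sac = sac[sac["kind"] == "regressive"]
    if "target_region" not in sac.columns:
        raise MeasuresError("landing-region counts require a region_id column")
    if launch_region is not None:
        regions = (
            [launch_region] if np.isscalar(launch_region) else list(launch_region)
        )
        sac = sac[sac["source_region"].isin(regions)]
    counts = sac.groupby("target_region").size().rename("count").reset_index()
    total = counts["count"].sum()
    counts["proportion"] = counts["count"] / total if total else np.nan
    return counts.rename(columns={"target_region": "region"})
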