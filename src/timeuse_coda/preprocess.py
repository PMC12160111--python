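"""Validity filtering, EMA aggregation and between/within decomposition.

Input schemas (all plain CSV-friendly DataFrames):

* daily minutes: ``participant_id, date, sb, lpa, mvpa, sleep, nonwear``
* EMA responses: ``participant_id, timestamp, happiness, anxiousness,
  tiredness`` (optionally ``window``)
* survey: ``participant_id, life_satisfaction, age_band, gender, ethnicity,
  deprivation_decile`` — one row per participant; ``ethnicity`` is a
  semicolon-separated multi-select.

The pipeline applies two inclusion rules: a day is valid when device
non-wear is at most 120 minutes, and a participant is retained with at
least two valid days.  Daily affect is the arithmetic mean of that day's
EMA responses (up to three).  Day-level ilr coordinates are split into a
between-person part (the participant's mean coordinate vector) and a
within-person part (the day's mean-centred deviation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import coda
from .coda import PARTS, IlrBasis

log = logging.getLogger(__name__)

AFFECTS = ("happiness", "anxiousness", "tiredness")
MAX_NONWEAR_MIN = 120
MIN_VALID_DAYS = 2
MAX_EMA_PER_DAY = 3

ILR_COLS = ("ilr1", "ilr2", "ilr3")
ILR_B_COLS = ("ilr_b1", "ilr_b2", "ilr_b3")
ILR_W_COLS = ("ilr_w1", "ilr_w2", "ilr_w3")


def filter_valid_days(days: pd.DataFrame, max_nonwear: float = MAX_NONWEAR_MIN) -> pd.DataFrame:
    """Drop days whose non-wear time strictly exceeds ``max_nonwear`` minutes."""
    if (days["nonwear"] < 0).any():
        raise ValueError("negative non-wear minutes")
    keep = days["nonwear"] <= max_nonwear
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("excluded %d days with non-wear > %g min", n_dropped, max_nonwear)
    return days.loc[keep].copy()


def filter_participants(days: pd.DataFrame, min_days: int = MIN_VALID_DAYS) -> pd.DataFrame:
    """Drop participants with fewer than ``min_days`` valid days."""
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    counts = days.groupby("participant_id")["participant_id"].transform("size")
    keep = counts >= min_days
    n_dropped = days.loc[~keep, "participant_id"].nunique()
    if n_dropped:
        log.info("excluded %d participants with < %d valid days", n_dropped, min_days)
    return days.loc[keep].copy()


def aggregate_daily_affect(responses: pd.DataFrame) -> pd.DataFrame:
    """Average each affect per participant-day, keeping the response count.

    Returns one row per (participant_id, date) with mean happiness,
    anxiousness, tiredness and ``n_ema``.  More than three responses on one
    day violates the prompt protocol and raises.
    """
    df = responses.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    for a in AFFECTS:
        bad = df[a].dropna()
        if ((bad < 0) | (bad > 10)).any():
            raise ValueError(f"{a} scores must lie in [0, 10]")
    grouped = df.groupby(["participant_id", "date"], as_index=False).agg(
        **{a: (a, "mean") for a in AFFECTS}, n_ema=("timestamp", "size")
    )
    if (grouped["n_ema"] > MAX_EMA_PER_DAY).any():
        bad = grouped.loc[grouped["n_ema"] > MAX_EMA_PER_DAY]
        raise ValueError(
            f"{len(bad)} participant-days carry more than {MAX_EMA_PER_DAY} "
            "EMA responses (protocol allows at most 3 prompts/day)"
        )
    return grouped


def add_ilr_coordinates(days: pd.DataFrame, basis: IlrBasis | None = None) -> pd.DataFrame:
    """Attach day-level ilr coordinates computed from the minutes columns."""
    if basis is None:
        basis = coda.default_basis()
    out = days.copy()
    z = coda.ilr_transform(out[list(PARTS)].to_numpy(), basis)
    out[list(ILR_COLS)] = z
    return out


def decompose_between_within(days: pd.DataFrame) -> pd.DataFrame:
    """Split day ilr coordinates into person means and daily deviations.

    ``ilr_b*`` is the participant's mean coordinate vector (constant within
    a person); ``ilr_w* = ilr* - ilr_b*``, so the two parts reconstruct the
    observed coordinates exactly and the within deviations average to zero
    for every participant.
    """
    out = days.copy()
    for c, b in zip(ILR_COLS, ILR_B_COLS):
        out[b] = out.groupby("participant_id")[c].transform("mean")
    for c, b, w in zip(ILR_COLS, ILR_B_COLS, ILR_W_COLS):
        out[w] = out[c] - out[b]
    return out


def assemble_analysis_table(
    days: pd.DataFrame,
    ema: pd.DataFrame,
    survey: pd.DataFrame,
    basis: IlrBasis | None = None,
    max_nonwear: float = MAX_NONWEAR_MIN,
    min_days: int = MIN_VALID_DAYS,
) -> pd.DataFrame:
    """Full preprocessing: filters, ilr, decomposition, EMA and survey join.

    Returns one row per valid person-day.  Days without any EMA response
    keep NaN affect means and ``has_affect = False``: they still inform the
    between/within decomposition (the exposure was observed) but are
    excluded from affect-model likelihoods downstream.
    """
    valid = filter_participants(filter_valid_days(days, max_nonwear), min_days)
    valid = decompose_between_within(add_ilr_coordinates(valid, basis))

    valid["date"] = pd.to_datetime(valid["date"]).dt.normalize()
    daily_affect = aggregate_daily_affect(ema)
    table = valid.merge(daily_affect, on=["participant_id", "date"], how="left")
    table["n_ema"] = table["n_ema"].fillna(0).astype(int)
    table["has_affect"] = table["n_ema"] > 0

    missing = set(table["participant_id"]) - set(survey["participant_id"])
    if missing:
        raise ValueError(
            f"survey rows missing for participants: {sorted(missing)}"
        )
    dup = survey["participant_id"].duplicated()
    if dup.any():
        raise ValueError("survey must contain one row per participant")
    table = table.merge(survey, on="participant_id", how="left")

    # 1-based study-day index from each participant's first valid wear date
    table = table.sort_values(["participant_id", "date"]).reset_index(drop=True)
    table["day_index"] = table.groupby("participant_id").cumcount() + 1
    return table


def person_level_table(table: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: between-person ilr plus survey columns.

    This is the modelling table for the cross-sectional life-satisfaction
    analysis, where exposure is the person's average composition.
    """
    keep = ["participant_id", *ILR_B_COLS]
    survey_cols = [
        c
        for c in (
            "life_satisfaction",
            "age_band",
            "gender",
            "ethnicity",
            "deprivation_decile",
        )
        if c in table.columns
    ]
    return table[keep + survey_cols].drop_duplicates("participant_id").reset_index(drop=True)
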