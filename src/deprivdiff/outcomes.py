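"""Construction of the self-reported morbidity outcome variables.

Two census-style outcomes are carried through the pipeline: the share of an
area's adult (15-65) population reporting that their general health was
"not good", and the share reporting a Limiting Long-Term Illness (LLTI).
Each is expressed as a percentage of the area denominator and then
log-transformed (base 10) to correct the moderate right skew that area
morbidity proportions show. The percentage (not the proportion) is the
canonical pre-log scale; the choice is immaterial to standardized
regression slopes (an affine shift of log10 values) but fixes the
descriptive means. Outcomes are not age-standardised.

Zero numerators make the log transform undefined. The default policy is a
hard error naming the offending areas; an opt-in continuity correction adds
0.5 to the numerator instead.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_OUTCOME_COLUMNS",
    "compute_outcomes",
    "log10_series",
    "summarize_outcomes",
]

#: outcome name -> numerator column in the area table
DEFAULT_OUTCOME_COLUMNS: dict[str, str] = {
    "not_good_health": "notgood_count",
    "llti": "llti_count",
}

ZeroPolicy = Literal["error", "continuity"]


def compute_outcomes(
    area_table: pd.DataFrame,
    outcome_columns: Mapping[str, str] | None = None,
    zero_policy: ZeroPolicy = "error",
) -> pd.DataFrame:
    """Build the long-format outcome table from area counts.

    Parameters
    ----------
    area_table:
        One row per area with columns ``area_id``, ``denominator`` and one
        numerator column per outcome.
    outcome_columns:
        Outcome name -> numerator column (default: ``not_good_health`` /
        ``llti`` from the standard schema).
    zero_policy:
        ``"error"`` (default) rejects zero numerators, naming the areas;
        ``"continuity"`` adds 0.5 to zero numerators and logs how many.

    Returns
    -------
    DataFrame with columns ``area_id, outcome, count, denominator,
    percentage, log10_pct``.
    """
    outcome_columns = dict(outcome_columns or DEFAULT_OUTCOME_COLUMNS)
    for col in ["area_id", "denominator", *outcome_columns.values()]:
        if col not in area_table.columns:
            raise InputError(f"area table is missing column {col!r}")
    denom = area_table["denominator"].to_numpy()
    if (denom <= 0).any():
        bad = area_table.loc[denom <= 0, "area_id"].tolist()
        raise InputError(f"nonpositive denominator for areas: {bad[:5]}")

    frames = []
    for outcome, col in outcome_columns.items():
        counts = area_table[col].to_numpy(dtype=float)
        if (counts < 0).any() or (counts > denom).any():
            bad = area_table.loc[(counts < 0) | (counts > denom), "area_id"].tolist()
            raise InputError(
                f"counts outside [0, denominator] for outcome {outcome!r}, areas: {bad[:5]}"
            )
        zero = counts == 0
        if zero.any():
            if zero_policy == "error":
                bad = area_table.loc[zero, "area_id"].tolist()
                raise InputError(
                    f"zero {outcome!r} count (log10 undefined) for areas: {bad[:5]}"
                    + (" ..." if len(bad) > 5 else "")
                )
            elif zero_policy == "continuity":
                counts = np.where(zero, counts + 0.5, counts)
                logger.warning(
                    "continuity correction (+0.5) applied to %d zero %r counts",
                    int(zero.sum()), outcome,
                )
            else:
                raise InputError(f"unknown zero policy {zero_policy!r}")
        pct = 100.0 * counts / denom
        frames.append(
            pd.DataFrame(
                {
                    "area_id": area_table["area_id"].to_numpy(),
                    "outcome": outcome,
                    "count": counts,
                    "denominator": denom,
                    "percentage": pct,
                    "log10_pct": np.log10(pct),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def log10_series(outcome_table: pd.DataFrame, outcome: str) -> pd.Series:
    """Per-area log10 percentage for one outcome, indexed by area_id."""
    sub = outcome_table[outcome_table["outcome"] == outcome]
    if sub.empty:
        raise InputError(f"outcome {outcome!r} not present in outcome table")
    return pd.Series(
        sub["log10_pct"].to_numpy(), index=pd.Index(sub["area_id"], name="area_id"),
        name=f"log10_pct_{outcome}",
    )


def summarize_outcomes(outcome_table: pd.DataFrame) -> pd.DataFrame:
    """Sample mean and SD (n-1 denominator) of log10 percentage per outcome.

    With a single area the SD is undefined and reported as NaN with a
    warning, not silently zero.
    """
    if outcome_table.empty:
        raise InputError("outcome table is empty")
    rows = []
    for outcome, sub in outcome_table.groupby("outcome", sort=True):
        vals = sub["log10_pct"].to_numpy()
        mean = float(vals.mean())
        if len(vals) < 2:
            logger.warning("outcome %r has a single area; SD undefined", outcome)
            sd = float("nan")
        else:
            sd = float(vals.std(ddof=1))
        rows.append({"outcome": outcome, "n": len(vals), "mean_log10_pct": mean,
                     "sd_log10_pct": sd})
    return pd.DataFrame(rows)
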