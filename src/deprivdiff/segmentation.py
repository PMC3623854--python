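"""Stratified regression: re-estimate the deprivation model within segments.

The additive model (morbidity ~ target-area deprivation + deprivation
differential) is re-fitted within population segments — IMD tertiles or
categorical geodemographic classes — with outcome and predictors re-z-scored
*within each segment*, so the betas are comparable standardized slopes per
segment. The components themselves are computed once globally and subset;
they are not re-derived per segment.

Each segment row carries beta1 (target-area deprivation), beta2
(deprivation differential) and their ratio beta1/beta2; rows are ordered by
decreasing ratio, so segments where the area's own deprivation dominates
come first and segments where the differential matters as much as absolute
deprivation come last. A large ratio therefore reads as "absolute
deprivation dominates"; a ratio near one as "relative deprivation is just
as harmful".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import DeprivationComponents
from .errors import DegenerateInputError, InputError
from .inference import RegressionFit, standardized_ols
from .outcomes import log10_series

logger = logging.getLogger(__name__)

__all__ = [
    "TERTILE_LABELS",
    "SegmentRow",
    "SegmentReport",
    "assign_tertiles",
    "segment_regressions",
    "ratio",
]

#: most- to least-deprived third
TERTILE_LABELS = (
    "Upper third (most deprived)",
    "Medium third (middle deprived)",
    "Lower third (least deprived)",
)

#: ranks for the tertile scheme (1 = most deprived)
TERTILE_RANKS = {label: i + 1 for i, label in enumerate(TERTILE_LABELS)}

DEFAULT_MIN_SEGMENT_SIZE = 30

#: |beta2| below this is treated as a division degeneracy
_RATIO_EPS = 1e-9


def ratio(beta1: float, beta2: float) -> float:
    """beta1 / beta2, rejecting a (numerically) zero beta2."""
    if abs(beta2) <= _RATIO_EPS:
        raise DegenerateInputError(
            f"beta2 = {beta2:g} is too close to zero for a beta1/beta2 ratio"
        )
    return beta1 / beta2


def assign_tertiles(imd: pd.Series) -> pd.Series:
    """Split areas into three deprivation thirds by rank.

    The most deprived (highest IMD) third is labelled first; group sizes
    differ by at most one, with any remainder allocated from the most
    deprived end. Ties in IMD are broken by area identifier, so the split
    is deterministic.
    """
    imd = pd.Series(imd, dtype=float) if not isinstance(imd, pd.Series) else imd.astype(float)
    n = len(imd)
    if n < 3:
        raise InputError(f"need at least 3 areas for tertiles, got {n}")
    order = sorted(imd.index, key=lambda a: (-imd[a], str(a)))
    labels = pd.Series(index=imd.index, dtype=object, name="segment")
    for chunk, label in zip(np.array_split(np.asarray(order, dtype=object), 3),
                            TERTILE_LABELS):
        labels.loc[list(chunk)] = label
    return labels


@dataclass(frozen=True)
class SegmentRow:
    """Within-segment multivariate fit, one row of the ratio table."""

    segment: str
    deprivation_rank: int
    beta1: float
    beta2: float
    ratio: float  # NaN when beta2 is degenerate
    stars1: str
    stars2: str
    n_areas: int


@dataclass(frozen=True)
class SegmentReport:
    """Ratio table for one outcome, rows ordered by descending ratio."""

    outcome: str
    scheme: str
    rows: tuple[SegmentRow, ...]
    dropped: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "segment": r.segment,
                    "deprivation_rank": r.deprivation_rank,
                    "beta1": r.beta1,
                    "stars1": r.stars1,
                    "beta2": r.beta2,
                    "stars2": r.stars2,
                    "ratio": r.ratio,
                    "n_areas": r.n_areas,
                }
                for r in self.rows
            ]
        )

    def to_text(self) -> str:
        lines = [f"{self.outcome} — segmentation: {self.scheme}",
                 f"{'segment':<34}{'rank':>5}{'beta1':>9}{'beta2':>9}{'ratio':>8}{'n':>7}"]
        for r in self.rows:
            ratio_txt = f"{r.ratio:.3f}" if math.isfinite(r.ratio) else "undef"
            lines.append(
                f"{r.segment:<34}{r.deprivation_rank:>5}"
                f"{r.beta1:>7.3f}{r.stars1:<3}{r.beta2:>6.3f}{r.stars2:<3}"
                f"{ratio_txt:>8}{r.n_areas:>7}"
            )
        if self.dropped:
            lines.append(f"dropped undersized segments: {', '.join(self.dropped)}")
        return "\n".join(lines)


def _segment_fit(y: pd.Series, pc1: pd.Series, pc2: pd.Series) -> RegressionFit:
    X = pd.DataFrame({"target_deprivation": pc1, "deprivation_differential": pc2})
    return standardized_ols(y, X)


def segment_regressions(
    outcome_table: pd.DataFrame,
    components: DeprivationComponents,
    labels: pd.Series,
    ranks: Mapping[str, int] | None = None,
    scheme: str = "categorical",
    outcomes: Sequence[str] | None = None,
    min_segment_size: int = DEFAULT_MIN_SEGMENT_SIZE,
) -> dict[str, SegmentReport]:
    """Re-fit the multivariate model within each segment, per outcome.

    Parameters
    ----------
    labels:
        Segment label per area (indexed by area identifier), covering the
        component area set.
    ranks:
        Segment -> deprivation rank (1 = most deprived). When omitted,
        ranks are derived from segment mean target-area deprivation,
        descending.
    min_segment_size:
        Segments with fewer areas are dropped with a warning, not an error.

    Returns
    -------
    Mapping outcome -> :class:`SegmentReport`, each with rows sorted by
    descending ratio (undefined ratios last; ties broken by segment name).
    """
    labels = labels if isinstance(labels, pd.Series) else pd.Series(labels)
    pc1, pc2 = components.target_deprivation, components.deprivation_differential
    missing = [a for a in pc1.index if a not in labels.index or pd.isna(labels[a])]
    if missing:
        raise InputError(f"segment labels missing for areas: {missing[:5]}")
    labels = labels.reindex(pc1.index)
    if outcomes is None:
        outcomes = sorted(outcome_table["outcome"].unique())

    segs = sorted(labels.unique(), key=str)
    if ranks is None:
        means = {s: float(pc1[labels == s].mean()) for s in segs}
        ordered = sorted(segs, key=lambda s: (-means[s], str(s)))
        ranks = {s: i + 1 for i, s in enumerate(ordered)}
    else:
        unranked = [s for s in segs if s not in ranks]
        if unranked:
            raise InputError(f"no deprivation rank for segments: {unranked}")

    # a 2-predictor standardized fit needs at least p + 2 = 4 areas
    effective_min = max(int(min_segment_size), 4)

    reports: dict[str, SegmentReport] = {}
    for outcome in outcomes:
        y = log10_series(outcome_table, outcome).reindex(pc1.index)
        if y.isna().any():
            raise InputError(f"outcome {outcome!r} missing for some areas")
        rows: list[SegmentRow] = []
        dropped: list[str] = []
        for seg in segs:
            mask = labels == seg
            n_seg = int(mask.sum())
            if n_seg < effective_min:
                logger.warning(
                    "segment %r has %d areas (< %d); dropped from the %r table",
                    seg, n_seg, effective_min, outcome,
                )
                dropped.append(str(seg))
                continue
            fit = _segment_fit(y[mask], pc1[mask], pc2[mask])
            b1 = fit.slope("target_deprivation")
            b2 = fit.slope("deprivation_differential")
            try:
                r = ratio(b1, b2)
            except DegenerateInputError:
                logger.warning(
                    "segment %r: beta2 ~ 0, ratio undefined for %r", seg, outcome
                )
                r = float("nan")
            rows.append(
                SegmentRow(
                    segment=str(seg),
                    deprivation_rank=int(ranks[seg]),
                    beta1=b1,
                    beta2=b2,
                    ratio=r,
                    stars1=fit.stars[0],
                    stars2=fit.stars[1],
                    n_areas=n_seg,
                )
            )
        rows.sort(key=lambda r: (not math.isfinite(r.ratio),
                                 -r.ratio if math.isfinite(r.ratio) else 0.0,
                                 r.segment))
        reports[outcome] = SegmentReport(
            outcome=outcome, scheme=scheme, rows=tuple(rows), dropped=tuple(dropped)
        )
    return reports
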