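"""Published England-wide results used for worked examples and cross-checks.

These are the printed results of the national ecological analysis of
self-reported morbidity (2001 UK census, n = 32,482 LSOAs) against the
target-area deprivation and deprivation-differential components derived
from IMD 2007: the whole-population regression table, the segment-level
standardized slopes for IMD tertiles and the thirteen "People and Places"
geodemographic classes, and the component loadings. The package uses them
as *inputs* to worked examples — e.g. recomputing the printed beta1/beta2
ratio column from the printed slope pairs — never as values its own
estimates are tuned to.

Printed slopes carry three decimals, so a recomputed ratio can differ from
the printed one in the third decimal; rows where the printed ratio is not
the 3-decimal rounding of the printed quotient are flagged
``self_consistent = False`` (two such rows exist in the 'not good health'
table and are known inconsistencies of the published table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "england_loadings",
    "england_model_table",
    "england_segment_table",
]

#: component loadings on (IMD, ALD) as published
_LOADINGS = np.array([[0.76, 0.64], [0.64, -0.76]])

#: outcome -> (beta1, beta2, adj R2 bivariate-PC1, bivariate-PC2, multivariate)
_MODEL_TABLE = {
    "not_good_health": (0.655, 0.312, 0.429, 0.097, 0.526),
    "llti": (0.548, 0.278, 0.330, 0.076, 0.410),
}

# (scheme, segment, rank, beta1, beta2, printed ratio)
_SEGMENTS_NOT_GOOD = [
    ("imd_tertiles", "Upper third (most deprived)", 1, 0.531, 0.221, 2.202),
    ("imd_tertiles", "Medium third (middle deprived)", 2, 0.555, 0.513, 1.081),
    ("imd_tertiles", "Lower third (least deprived)", 3, 0.732, 0.748, 0.978),
    ("p2_categories", "New Starters", 6, 0.736, 0.237, 3.105),
    ("p2_categories", "Urban Challenge", 1, 0.452, 0.200, 2.260),
    ("p2_categories", "Multicultural Centres", 3, 0.604, 0.265, 2.279),
    ("p2_categories", "Qualified Metropolitan", 8, 0.542, 0.246, 2.203),
    ("p2_categories", "Weathered Communities", 4, 0.441, 0.252, 1.750),
    ("p2_categories", "Urban Producers", 5, 0.627, 0.446, 1.405),
    ("p2_categories", "Disadvantaged Households", 2, 0.701, 0.523, 1.340),
    ("p2_categories", "Senior Neighbourhoods", 9, 0.541, 0.418, 1.294),
    ("p2_categories", "Suburban Stability", 7, 0.534, 0.464, 1.150),
    ("p2_categories", "Country Orchards", 11, 0.600, 0.577, 1.039),
    ("p2_categories", "Rooted Households", 10, 0.555, 0.558, 1.008),
    ("p2_categories", "Blossoming Families", 12, 0.601, 0.633, 0.949),
    ("p2_categories", "Mature Oaks", 13, 0.638, 0.688, 0.927),
]

_SEGMENTS_LLTI = [
    ("imd_tertiles", "Upper third (most deprived)", 1, 0.409, 0.112, 3.651),
    ("imd_tertiles", "Medium third (middle deprived)", 2, 0.336, 0.298, 1.127),
    ("imd_tertiles", "Lower third (least deprived)", 3, 0.577, 0.602, 0.958),
    ("p2_categories", "Urban Challenge", 1, 0.409, 0.055, 7.436),
    ("p2_categories", "Qualified Metropolitan", 8, 0.400, 0.056, 7.142),
    ("p2_categories", "New Starters", 6, 0.659, 0.172, 3.831),
    ("p2_categories", "Multicultural Centres", 3, 0.537, 0.179, 3.000),
    ("p2_categories", "Weathered Communities", 4, 0.366, 0.158, 2.316),
    ("p2_categories", "Urban Producers", 5, 0.643, 0.397, 1.619),
    ("p2_categories", "Disadvantaged Households", 2, 0.706, 0.500, 1.412),
    ("p2_categories", "Senior Neighbourhoods", 9, 0.386, 0.302, 1.278),
    ("p2_categories", "Suburban Stability", 7, 0.426, 0.354, 1.203),
    ("p2_categories", "Rooted Households", 10, 0.436, 0.404, 1.079),
    ("p2_categories", "Country Orchards", 11, 0.567, 0.546, 1.038),
    ("p2_categories", "Blossoming Families", 12, 0.550, 0.559, 0.983),
    ("p2_categories", "Mature Oaks", 13, 0.567, 0.606, 0.935),
]


def england_loadings() -> np.ndarray:
    """Published 2x2 component loadings, rows = (PC1, PC2), cols = (IMD, ALD)."""
    return _LOADINGS.copy()


def england_model_table() -> pd.DataFrame:
    """Whole-population standardized slopes and adjusted R2 per outcome."""
    rows = [
        {
            "outcome": outcome,
            "beta1": b1,
            "beta2": b2,
            "adj_r2_pc1": r1,
            "adj_r2_pc2": r2,
            "adj_r2_multivariate": rm,
        }
        for outcome, (b1, b2, r1, r2, rm) in _MODEL_TABLE.items()
    ]
    return pd.DataFrame(rows)


def england_segment_table(outcome: str | None = None) -> pd.DataFrame:
    """Segment-level slopes and printed ratios for both outcomes.

    ``self_consistent`` marks rows whose printed ratio equals
    ``round(beta1/beta2, 3)`` to within one unit in the last decimal.
    """
    records = []
    for out, rows in (("not_good_health", _SEGMENTS_NOT_GOOD), ("llti", _SEGMENTS_LLTI)):
        if outcome is not None and out != outcome:
            continue
        for scheme, seg, rank, b1, b2, printed in rows:
            records.append(
                {
                    "outcome": out,
                    "scheme": scheme,
                    "segment": seg,
                    "deprivation_rank": rank,
                    "beta1": b1,
                    "beta2": b2,
                    "printed_ratio": printed,
                    "self_consistent": abs(round(b1 / b2, 3) - printed) <= 1e-3 + 1e-12,
                }
            )
    return pd.DataFrame(records)
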