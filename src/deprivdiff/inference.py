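"""Standardized linear regression of morbidity on the deprivation components.

All models are ordinary least squares on z-scored outcome and predictors
(sample, n-1, standard deviations), so slopes are standardized betas: for a
single predictor the slope equals the Pearson correlation, and because the
two deprivation components are uncorrelated by construction, the
multivariate slopes coincide with the bivariate ones — the structure that
lets the two effects be read off a single additive model. Two-sided t-test
p-values use n - p - 1 degrees of freedom, summarised with the conventional
star codes (*** p<0.001, ** p<0.01, * p<0.05). No spatial-error or
cluster-robust correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .decomposition import DeprivationComponents
from .errors import DegenerateInputError, InputError
from .outcomes import log10_series

__all__ = [
    "RegressionFit",
    "DecompositionTable",
    "standardized_ols",
    "fit_decomposition_table",
    "significance_stars",
]

#: condition-number ceiling for the z-scored design matrix
_COND_MAX = 1e8


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def zscore(x: np.ndarray) -> np.ndarray:
    """z-score with sample (n-1) SD; raises on constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class RegressionFit:
    """One standardized OLS fit: slopes, p-values, fit statistics."""

    predictors: tuple[str, ...]
    std_slopes: tuple[float, ...]
    p_values: tuple[float, ...]
    r2: float
    adj_r2: float
    n: int

    @property
    def stars(self) -> tuple[str, ...]:
        return tuple(significance_stars(p) for p in self.p_values)

    def slope(self, predictor: str) -> float:
        return self.std_slopes[self.predictors.index(predictor)]

    def __str__(self) -> str:
        terms = ", ".join(
            f"{name}: beta={b:+.3f}{'' if s == 'ns' else s}"
            for name, b, s in zip(self.predictors, self.std_slopes, self.stars)
        )
        return f"RegressionFit(n={self.n}, {terms}, adjR2={self.adj_r2:.3f})"


def standardized_ols(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame | Mapping[str, Sequence[float]],
    predictor_names: Sequence[str] | None = None,
) -> RegressionFit:
    """Fit OLS after z-scoring outcome and every predictor column.

    Requires n > p + 1, complete data and non-constant columns; a design
    with condition number above 1e8 after z-scoring (effectively collinear
    predictors) is rejected as degenerate.
    """
    Xdf = pd.DataFrame(X)
    if predictor_names is not None:
        Xdf.columns = list(predictor_names)
    yarr = np.asarray(y, dtype=float)
    n, p = Xdf.shape
    if len(yarr) != n:
        raise InputError(f"y has {len(yarr)} rows but X has {n}")
    if n <= p + 1:
        raise InputError(f"need n > p + 1 (n={n}, p={p})")
    if not np.isfinite(yarr).all() or not np.isfinite(Xdf.to_numpy()).all():
        raise InputError("missing or non-finite values in regression data")

    yz = zscore(yarr)
    try:
        Xz = np.column_stack([zscore(Xdf[c].to_numpy()) for c in Xdf.columns])
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"constant predictor column: {exc}") from exc
    if np.linalg.cond(Xz) > _COND_MAX:
        raise DegenerateInputError(
            f"collinear predictors (condition number > {_COND_MAX:g})"
        )
    model = sm.OLS(yz, sm.add_constant(Xz, has_constant="add"))
    res = model.fit()
    return RegressionFit(
        predictors=tuple(str(c) for c in Xdf.columns),
        std_slopes=tuple(float(b) for b in res.params[1:]),
        p_values=tuple(float(pv) for pv in res.pvalues[1:]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
    )


@dataclass(frozen=True)
class DecompositionTable:
    """Per-outcome bivariate and multivariate fits on the two components.

    Mirrors the canonical three-column presentation: a bivariate model for
    each component and the additive multivariate model, plus diagnostics
    for predictor orthogonality and the R-squared additivity identity
    (with exactly orthogonal predictors the multivariate unadjusted R2 is
    the sum of the two bivariate ones).
    """

    fits: Mapping[str, Mapping[str, RegressionFit]]  # outcome -> {"pc1","pc2","multi"}
    predictor_correlation: float

    def additivity(self, outcome: str) -> dict[str, float]:
        f = self.fits[outcome]
        return {
            "r2_sum_bivariate": f["pc1"].r2 + f["pc2"].r2,
            "r2_multivariate": f["multi"].r2,
            "adj_r2_sum_bivariate": f["pc1"].adj_r2 + f["pc2"].adj_r2,
            "adj_r2_multivariate": f["multi"].adj_r2,
        }

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format analog of the published regression table."""
        rows = []
        for outcome, f in self.fits.items():
            rows.append({
                "outcome": outcome,
                "beta1_bivariate": f["pc1"].std_slopes[0],
                "stars1_bivariate": f["pc1"].stars[0],
                "adj_r2_pc1": f["pc1"].adj_r2,
                "beta2_bivariate": f["pc2"].std_slopes[0],
                "stars2_bivariate": f["pc2"].stars[0],
                "adj_r2_pc2": f["pc2"].adj_r2,
                "beta1_multivariate": f["multi"].slope("target_deprivation"),
                "beta2_multivariate": f["multi"].slope("deprivation_differential"),
                "adj_r2_multivariate": f["multi"].adj_r2,
                "n": f["multi"].n,
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = []
        for outcome, f in self.fits.items():
            add = self.additivity(outcome)
            lines.append(f"{outcome} (n={f['multi'].n})")
            lines.append(
                "  target area deprivation     "
                f"bivariate {f['pc1'].std_slopes[0]:+.3f}{f['pc1'].stars[0]}"
                f"  multivariate {f['multi'].slope('target_deprivation'):+.3f}"
                f"{f['multi'].stars[0]}"
            )
            lines.append(
                "  deprivation differential    "
                f"bivariate {f['pc2'].std_slopes[0]:+.3f}{f['pc2'].stars[0]}"
                f"  multivariate {f['multi'].slope('deprivation_differential'):+.3f}"
                f"{f['multi'].stars[1]}"
            )
            lines.append(
                f"  adjusted R2: {f['pc1'].adj_r2:.3f} / {f['pc2'].adj_r2:.3f}"
                f" / {f['multi'].adj_r2:.3f}"
                f"  (bivariate sum {add['adj_r2_sum_bivariate']:.3f})"
            )
        return "\n".join(lines)


def fit_decomposition_table(
    outcome_table: pd.DataFrame,
    components: DeprivationComponents,
    outcomes: Sequence[str] | None = None,
) -> DecompositionTable:
    """Fit the three standard models per outcome.

    The outcome table and the components must cover the same areas (islands
    are removed upstream, before the decomposition).
    """
    if outcomes is None:
        outcomes = sorted(outcome_table["outcome"].unique())
    pc1 = components.target_deprivation
    pc2 = components.deprivation_differential
    corr = float(np.corrcoef(pc1.to_numpy(), pc2.to_numpy())[0, 1])
    fits: dict[str, dict[str, RegressionFit]] = {}
    for outcome in outcomes:
        y = log10_series(outcome_table, outcome)
        if set(y.index) != set(pc1.index):
            raise InputError(
                f"outcome {outcome!r} and components cover different area sets"
            )
        y = y.reindex(pc1.index)
        fits[outcome] = {
            "pc1": standardized_ols(y, {"target_deprivation": pc1}),
            "pc2": standardized_ols(y, {"deprivation_differential": pc2}),
            "multi": standardized_ols(
                y,
                pd.DataFrame(
                    {"target_deprivation": pc1, "deprivation_differential": pc2}
                ),
            ),
        }
    return DecompositionTable(fits=fits, predictor_correlation=corr)
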