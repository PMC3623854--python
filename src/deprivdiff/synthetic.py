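"""Synthetic study regions with the statistical structure the analysis assumes.

The generator builds a rectangular lattice of small areas (queen
contiguity), gives it a spatially autocorrelated deprivation field, and
draws self-reported morbidity counts from a latent log-linear model on the
*actual* orthogonalized deprivation components — so every downstream stage
(lag, decomposition, regression, segmentation) can be exercised and its
parameter recovery checked against closed-form targets, without any
external census or deprivation download.

Generative model
----------------
1. Deprivation: iid standard-normal innovations, then ``smoothing_rounds``
   passes of ``d <- (1 - rho) * d + rho * (neighbour mean of d)`` — a
   moving-average smoother that induces the IMD/ALD collinearity the
   orthogonalization exists to solve — finally shifted to be nonnegative
   (IMD-like scores are nonnegative; the shift is immaterial downstream).
2. Components: the *pipeline's own* contiguity and decomposition stages are
   run on the simulated field, so the generative effects are expressed on
   exactly the predictors the analysis uses.
3. Outcomes: latent log10 percentage
   ``y_i = mu + b1 * z(PC1_i) + b2 * z(PC2_i) + sigma * eps_i``, proportion
   ``p_i = 10^y_i / 100`` clipped just inside (0, 1), and counts drawn as
   Binomial(denominator_i, p_i). For z-scored orthogonal predictors the
   population standardized slope of the fitted model is
   ``b / sqrt(b1^2 + b2^2 + sigma^2)`` (ignoring binomial noise), the
   recovery target used throughout the tests.
4. Segments: deprivation-quantile bins with a seeded 10% of areas bumped to
   an adjacent bin — classes that correlate with, but are not determined
   by, deprivation, like real geodemographic segmentations.

Defaults reproduce the reference study conditions used by the test suite:
a deprivation field with rho = 0.8 and five smoothing rounds, effects
b1 = 0.6 and b2 = 0.3 with residual sigma = 0.74 on the log10-percentage
scale, baseline mu = 0.95 (~9% morbidity), adult denominators uniform on
900-2100 (areas of roughly 1,500 residents) and thirteen segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .contiguity import ContiguityGraph, queen_from_grid, row_standardized_matrix, spatial_lag
from .decomposition import DeprivationComponents, decompose
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_region",
    "simulate_outcomes",
    "simulate_segments",
    "smooth_field",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic region generator (see module docstring)."""

    grid_rows: int = 50
    grid_cols: int = 50
    autocorr_mix: float = 0.8      # rho, neighbour-mixing weight in [0, 1)
    smoothing_rounds: int = 5
    effect_target: float = 0.6     # b1, effect of z(PC1) on log10 pct
    effect_differential: float = 0.3  # b2, effect of z(PC2)
    noise_sd: float = 0.74         # sigma on the log10-percentage scale
    baseline_log10_pct: float = 0.95  # mu; 10^0.95 ~ 8.9%
    denominator_range: tuple[int, int] = (900, 2100)
    n_segments: int = 13
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid_rows and grid_cols must be positive")
        if self.grid_rows * self.grid_cols < 9:
            raise ConfigurationError("grid_rows * grid_cols must be at least 9")
        if not (0.0 <= self.autocorr_mix < 1.0):
            raise ConfigurationError("autocorr_mix must lie in [0, 1)")
        if self.smoothing_rounds < 0:
            raise ConfigurationError("smoothing_rounds must be nonnegative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        lo, hi = self.denominator_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                "denominator_range must satisfy 1 <= min <= max"
            )
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def smooth_field(
    values: np.ndarray, graph: ContiguityGraph, mix: float, rounds: int
) -> np.ndarray:
    """Apply ``rounds`` passes of ``d <- (1-mix) d + mix * W d``.

    W is the row-standardised queen weight matrix; island rows of W are
    zero, so islands decay toward 0 rather than borrowing a neighbour mean.
    With ``mix = 0`` or ``rounds = 0`` this is the identity.
    """
    if mix == 0.0 or rounds == 0:
        return np.asarray(values, dtype=float).copy()
    W, _ = row_standardized_matrix(graph)
    d = np.asarray(values, dtype=float).copy()
    for _ in range(rounds):
        d = (1.0 - mix) * d + mix * (W @ d)
    return d


def simulate_region(config: SimulationConfig) -> tuple[pd.DataFrame, ContiguityGraph]:
    """Generate one synthetic study region.

    Returns the standard area table (``area_id, imd, notgood_count,
    llti_count, denominator, segment``) and the queen-contiguity graph of
    the lattice. Identical configs give bit-identical tables.
    """
    config.validate()
    graph = queen_from_grid(config.grid_rows, config.grid_cols)
    n = graph.n
    rng = np.random.default_rng(config.seed)

    innovations = rng.standard_normal(n)
    d = smooth_field(innovations, graph, config.autocorr_mix, config.smoothing_rounds)
    d = d - d.min()  # affine shift: IMD-like scores are nonnegative
    imd = pd.Series(d, index=pd.Index(graph.nodes, name="area_id"), name="imd")

    lo, hi = config.denominator_range
    denominators = rng.integers(lo, hi + 1, size=n)

    # components from the real pipeline so effects live on the analysis scale
    lag = spatial_lag(imd, graph)
    if lag.islands:
        raise ConfigurationError(
            f"simulated lattice has {len(lag.islands)} island(s); enlarge the grid"
        )
    components = decompose(imd, lag.ald.reindex(imd.index))

    notgood = simulate_outcomes(components, config, denominators, rng)
    llti = simulate_outcomes(components, config, denominators, rng)
    segments = simulate_segments(
        imd, config.n_segments, seed=int(rng.integers(2**31))
    )

    table = pd.DataFrame(
        {
            "area_id": list(graph.nodes),
            "imd": imd.to_numpy(),
            "notgood_count": notgood,
            "llti_count": llti,
            "denominator": denominators,
            "segment": segments.reindex(imd.index).to_numpy(),
        }
    )
    return table, graph


def simulate_outcomes(
    components: DeprivationComponents,
    config: SimulationConfig,
    denominators: Sequence[int] | np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one outcome's counts from the latent log-linear model.

    The latent log10 percentage is ``mu + b1 z(PC1) + b2 z(PC2) + sigma
    eps``; the implied proportion is clipped to
    ``[1/(denom+2), 1 - 1/(denom+2)]`` so it is always strictly inside
    (0, 1), and counts are Binomial(denominator, p).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    denom = np.asarray(denominators, dtype=int)
    if (denom < 1).any():
        raise InputError("denominators must be positive integers")
    pc1 = components.target_deprivation.to_numpy()
    pc2 = components.deprivation_differential.to_numpy()
    if len(pc1) != len(denom):
        raise InputError("denominators and components cover different area counts")

    def z(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=1)

    with np.errstate(over="ignore", invalid="ignore"):
        y = (
            config.baseline_log10_pct
            + config.effect_target * z(pc1)
            + config.effect_differential * z(pc2)
            + config.noise_sd * rng.standard_normal(len(denom))
        )
    if not np.isfinite(y).all():
        raise ConfigurationError(
            "non-finite latent morbidity values; effects or noise_sd too large"
        )
    p = np.power(10.0, y) / 100.0
    p = np.clip(p, 1.0 / (denom + 2), 1.0 - 1.0 / (denom + 2))
    return rng.binomial(denom, p)


def simulate_segments(
    deprivation: pd.Series, n_segments: int, seed: int, reassign_share: float = 0.10
) -> pd.Series:
    """Deprivation-quantile segment labels with adjacent-bin noise.

    Bin 1 is the most deprived quantile (labels ``segment_01`` ...); a
    seeded random ``reassign_share`` fraction of areas (default 10%) is
    moved to an adjacent bin so that segments correlate with, but are not
    a function of, deprivation — the behaviour of geodemographic
    classifications with a deprivation rank. With ``reassign_share = 0``
    the labels are exactly the deprivation quantile bins.
    """
    deprivation = (
        pd.Series(deprivation, dtype=float)
        if not isinstance(deprivation, pd.Series)
        else deprivation.astype(float)
    )
    n = len(deprivation)
    if n_segments < 2:
        raise InputError("n_segments must be at least 2")
    if n_segments > n:
        raise InputError(f"n_segments = {n_segments} exceeds the {n} areas")
    if not (0.0 <= reassign_share <= 1.0):
        raise InputError("reassign_share must lie in [0, 1]")
    order = sorted(deprivation.index, key=lambda a: (-deprivation[a], str(a)))
    bin_of = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), n_segments)):
        for area in chunk:
            bin_of[area] = b
    bins = pd.Series([bin_of[a] for a in deprivation.index],
                     index=deprivation.index, dtype=int)
    rng = np.random.default_rng(seed)
    n_move = int(reassign_share * n)
    if n_move:
        movers = rng.choice(n, size=n_move, replace=False)
        direction = rng.choice([-1, 1], size=n_move)
        for k, s in zip(movers, direction):
            area = deprivation.index[int(k)]
            b = int(bins.loc[area]) + int(s)
            bins.loc[area] = min(max(b, 0), n_segments - 1)
    width = max(2, len(str(n_segments)))
    return bins.map(lambda b: f"segment_{b + 1:0{width}d}").rename("segment")
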