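"""Orthogonalization of (IMD, ALD) into uncorrelated deprivation components.

An area's deprivation score (IMD) and the mean deprivation of its contiguous
neighbours (ALD) are strongly collinear — deprived areas cluster — so their
separate effects on a health outcome cannot be disentangled by entering both
in a regression. A principal-components rotation of the two variables yields
two exactly uncorrelated predictors:

* **target area deprivation** (PC1): the dominant shared-deprivation axis,
  loading positively on both IMD and ALD — how deprived the area *and its
  surroundings* are;
* **deprivation differential** (PC2): the orthogonal contrast, loading
  positively on IMD and negatively on ALD — positive when an area is more
  deprived than its neighbours.

The decomposition is an eigendecomposition of the 2x2 sample covariance
matrix of the mean-centred (IMD, ALD) pair; scores are the centred data
projected onto the (sign-fixed) eigenvectors, so var(PC1) + var(PC2) equals
var(IMD) + var(ALD) and the two score vectors have exactly zero sample
correlation. Covariance (not correlation) PCA is the default: with only two
variables, correlation-matrix PCA always returns +-1/sqrt(2) loadings,
whereas unequal IMD/ALD variances produce the asymmetric loadings seen in
real national data; a correlation mode is kept for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

__all__ = ["DeprivationComponents", "decompose", "interpret_differential"]

PCAMode = Literal["covariance", "correlation"]


@dataclass(frozen=True)
class DeprivationComponents:
    """Per-area scores and loadings of the two-component decomposition.

    ``loadings`` rows are the components, columns are (IMD, ALD); rows are
    orthonormal. ``variance_explained`` holds the two eigenvalues (sample
    variances of the score vectors). ``means`` (and ``scales`` in
    correlation mode) are the centring constants, retained so scores can be
    computed for held-out areas.
    """

    target_deprivation: pd.Series
    deprivation_differential: pd.Series
    loadings: np.ndarray
    variance_explained: tuple[float, float]
    means: tuple[float, float]
    scales: tuple[float, float] = (1.0, 1.0)
    mode: PCAMode = "covariance"

    @property
    def index(self) -> pd.Index:
        return self.target_deprivation.index

    def loadings_text(self) -> str:
        """Loadings in the conventional notation PC1 = a*IMD + b*ALD."""
        (a1, b1), (a2, b2) = self.loadings
        return (
            f"PC1 = {a1:+.3f}*IMD {b1:+.3f}*ALD (var {self.variance_explained[0]:.4g}); "
            f"PC2 = {a2:+.3f}*IMD {b2:+.3f}*ALD (var {self.variance_explained[1]:.4g})"
        )

    def transform(self, imd: np.ndarray | float, ald: np.ndarray | float) -> np.ndarray:
        """Score new (imd, ald) observations with the fitted rotation."""
        x = np.column_stack([np.atleast_1d(imd), np.atleast_1d(ald)]).astype(float)
        x = (x - np.asarray(self.means)) / np.asarray(self.scales)
        return x @ self.loadings.T


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Resolve eigenvector sign ambiguity.

    PC1: both loadings positive (the variables are positively correlated in
    any spatially smooth field; when they are not, the loading of larger
    magnitude is made positive). PC2: IMD loading positive so that an area
    more deprived than its neighbours gets a positive differential; when the
    IMD loading is (numerically) zero, the ALD loading is made negative.
    """
    out = loadings.copy()
    if out[0].sum() < 0 or (out[0].sum() == 0 and out[0, np.argmax(np.abs(out[0]))] < 0):
        out[0] = -out[0]
    if out[1, 0] < 0 or (abs(out[1, 0]) < 1e-15 and out[1, 1] > 0):
        out[1] = -out[1]
    return out


def decompose(
    imd: pd.Series,
    ald: pd.Series,
    mode: PCAMode = "covariance",
) -> DeprivationComponents:
    """Rotate (imd, ald) into target-area deprivation and the differential.

    Both series must be indexed by area identifier and aligned on the same
    (non-island) area set, with at least three areas and neither vector
    constant.
    """
    imd = pd.Series(imd, dtype=float) if not isinstance(imd, pd.Series) else imd.astype(float)
    ald = pd.Series(ald, dtype=float) if not isinstance(ald, pd.Series) else ald.astype(float)
    if set(imd.index) != set(ald.index):
        raise InputError("imd and ald are not defined on the same area set")
    ald = ald.reindex(imd.index)
    n = len(imd)
    if n < 3:
        raise InputError(f"need at least 3 areas, got {n}")
    if not (np.isfinite(imd.to_numpy()).all() and np.isfinite(ald.to_numpy()).all()):
        raise InputError("non-finite deprivation values")
    X = np.column_stack([imd.to_numpy(), ald.to_numpy()])
    means = X.mean(axis=0)
    Xc = X - means
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(("imd", "ald"), sds):
        if sd == 0:
            raise DegenerateInputError(f"{name} is constant across areas")
    scales = (1.0, 1.0)
    if mode == "correlation":
        Xc = Xc / sds
        scales = (float(sds[0]), float(sds[1]))
    elif mode != "covariance":
        raise InputError(f"unknown PCA mode {mode!r}")

    C = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(C)  # ascending
    order = [1, 0]
    # exactly tied eigenvalues: PC1 is the vector with the larger IMD loading
    if evals[0] == evals[1] and abs(evecs[0, 0]) > abs(evecs[0, 1]):
        order = [0, 1]
    loadings = _fix_signs(evecs[:, order].T)
    scores = Xc @ loadings.T
    return DeprivationComponents(
        target_deprivation=pd.Series(scores[:, 0], index=imd.index, name="target_deprivation"),
        deprivation_differential=pd.Series(
            scores[:, 1], index=imd.index, name="deprivation_differential"
        ),
        loadings=loadings,
        variance_explained=(float(evals[order[0]]), float(evals[order[1]])),
        means=(float(means[0]), float(means[1])),
        scales=scales,
        mode=mode,
    )


def interpret_differential(components: DeprivationComponents) -> dict:
    """Orientation report for the fitted components.

    Confirms the sign convention — an area with IMD above its neighbours'
    mean has a positive deprivation differential, which holds exactly when
    the PC2 loading on IMD is positive and on ALD nonpositive — and reports
    the descriptive score ranges and variance shares.
    """
    (a1, b1), (a2, b2) = components.loadings
    orientation_ok = bool(a2 > 0 and b2 <= 0 and a1 >= 0 and b1 >= 0)
    ve = components.variance_explained
    total = ve[0] + ve[1]
    return {
        "orientation_ok": orientation_ok,
        "loadings_text": components.loadings_text(),
        "target_deprivation_range": (
            float(components.target_deprivation.min()),
            float(components.target_deprivation.max()),
        ),
        "deprivation_differential_range": (
            float(components.deprivation_differential.min()),
            float(components.deprivation_differential.max()),
        ),
        "variance_share": (ve[0] / total, ve[1] / total) if total > 0 else (np.nan, np.nan),
        "note": (
            "positive differential = area more deprived than its contiguous neighbours"
        ),
    }
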