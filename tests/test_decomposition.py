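"""Orthogonalization of (IMD, ALD) into uncorrelated components.

The independent oracle here is a closed-form 2x2 eigendecomposition built
from the quadratic formula on the characteristic polynomial, implemented
without numpy's eigensolver.
"""

import math

import numpy as np
import pandas as pd
import pytest

from deprivdiff import (
    DegenerateInputError,
    InputError,
    SimulationConfig,
    decompose,
    interpret_differential,
    simulate_region,
    spatial_lag,
)


def closed_form_components(imd, ald):
    """Quadratic-formula eigendecomposition of the 2x2 sample covariance.

    Independent of numpy.linalg: eigenvalues from the characteristic
    polynomial, eigenvectors from (C - lambda I) v = 0, signs fixed to the
    package's convention (PC1 loadings nonnegative, PC2 IMD-loading
    positive).
    """
    x = np.asarray(imd, dtype=float)
    y = np.asarray(ald, dtype=float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    a = float(xc @ xc) / (n - 1)
    b = float(xc @ yc) / (n - 1)
    c = float(yc @ yc) / (n - 1)
    disc = math.sqrt((a - c) ** 2 + 4 * b * b)
    lam1 = (a + c + disc) / 2
    lam2 = (a + c - disc) / 2
    vecs = []
    for lam in (lam1, lam2):
        if abs(b) > 1e-300:
            v = np.array([b, lam - a])
        elif a >= c:
            v = np.array([1.0, 0.0]) if lam == lam1 else np.array([0.0, 1.0])
        else:
            v = np.array([0.0, 1.0]) if lam == lam1 else np.array([1.0, 0.0])
        vecs.append(v / math.hypot(*v))
    v1, v2 = vecs
    if v1.sum() < 0:
        v1 = -v1
    if v2[0] < 0 or (v2[0] == 0 and v2[1] > 0):
        v2 = -v2
    scores1 = xc * v1[0] + yc * v1[1]
    scores2 = xc * v2[0] + yc * v2[1]
    return (lam1, lam2), (v1, v2), (scores1, scores2)


class TestDegenerateAndTrivialCases:
    def test_identical_inputs_have_zero_differential(self):
        ids = [f"a{i}" for i in range(12)]
        imd = pd.Series(np.linspace(1, 30, 12), index=ids)
        comp = decompose(imd, imd.copy())
        assert comp.variance_explained[1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(comp.deprivation_differential.to_numpy(), 0.0, atol=1e-10)
        assert comp.loadings[0] == pytest.approx([1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_uncorrelated_inputs_give_axis_loadings(self, rng):
        # construct a sample with exactly zero covariance, var(imd)=2, var(ald)=1
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        x = x - x.mean()
        y = y - y.mean()
        y = y - (x @ y) / (x @ x) * x  # exact sample orthogonality
        ids = [f"a{i}" for i in range(8)]
        imd = pd.Series(np.sqrt(2.0) * x / x.std(ddof=1), index=ids)
        ald = pd.Series(y / y.std(ddof=1), index=ids)
        comp = decompose(imd, ald)
        np.testing.assert_allclose(np.abs(comp.loadings[0]), [1.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(np.abs(comp.loadings[1]), [0.0, 1.0], atol=1e-9)
        assert comp.variance_explained[0] == pytest.approx(2.0, rel=1e-9)
        assert comp.variance_explained[1] == pytest.approx(1.0, rel=1e-9)

    def test_constant_input_rejected(self):
        ids = list("abcd")
        with pytest.raises(DegenerateInputError, match="constant"):
            decompose(pd.Series(1.0, index=ids), pd.Series([1, 2, 3, 4.0], index=ids))

    def test_mismatched_area_sets_rejected(self):
        with pytest.raises(InputError, match="area set"):
            decompose(
                pd.Series([1, 2, 3.0], index=list("abc")),
                pd.Series([1, 2, 3.0], index=list("abd")),
            )


class TestOracleEquivalence:
    def test_scores_match_closed_form_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n) * rng.uniform(0.5, 5)
            y = 0.6 * x + rng.normal(size=n) * rng.uniform(0.5, 5)
            ids = [f"a{i}" for i in range(n)]
            comp = decompose(pd.Series(x, index=ids), pd.Series(y, index=ids))
            (lam1, lam2), (v1, v2), (s1, s2) = closed_form_components(x, y)
            assert comp.variance_explained[0] == pytest.approx(lam1, abs=1e-8)
            assert comp.variance_explained[1] == pytest.approx(lam2, abs=1e-8)
            np.testing.assert_allclose(comp.loadings[0], v1, atol=1e-8)
            np.testing.assert_allclose(comp.loadings[1], v2, atol=1e-8)
            np.testing.assert_allclose(
                comp.target_deprivation.to_numpy(), s1, atol=1e-8
            )
            np.testing.assert_allclose(
                comp.deprivation_differential.to_numpy(), s2, atol=1e-8
            )


class TestInvariants:
    def test_orthogonality_and_variance_conservation(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.gamma(2, 10, n)
            y = 0.8 * x + rng.normal(0, 5, n)
            ids = [f"a{i}" for i in range(n)]
            comp = decompose(pd.Series(x, index=ids), pd.Series(y, index=ids))
            s1 = comp.target_deprivation.to_numpy()
            s2 = comp.deprivation_differential.to_numpy()
            # exactly uncorrelated score vectors: the point of the method
            assert abs(np.corrcoef(s1, s2)[0, 1]) < 1e-10
            total_in = np.var(x, ddof=1) + np.var(y, ddof=1)
            total_out = np.var(s1, ddof=1) + np.var(s2, ddof=1)
            assert abs(total_out - total_in) / total_in < 1e-10
            # orthonormal loading rows
            L = comp.loadings
            np.testing.assert_allclose(L @ L.T, np.eye(2), atol=1e-10)

    def test_sign_convention_stable_under_negated_eigenvectors(self, series_pair):
        imd, ald = series_pair
        comp = decompose(imd, ald)
        assert (comp.loadings[0] >= 0).all()
        assert comp.loadings[1][0] > 0 and comp.loadings[1][1] < 0

    def test_area_above_neighbour_mean_gets_positive_differential(self, series_pair):
        imd, ald = series_pair
        comp = decompose(imd, ald)
        delta = 0.5 * imd.std()
        score = comp.transform(imd.mean() + delta, ald.mean() - delta)
        assert score[0, 1] > 0


class TestInterpretDifferential:
    def test_orientation_report(self, series_pair):
        imd, ald = series_pair
        comp = decompose(imd, ald)
        report = interpret_differential(comp)
        assert report["orientation_ok"]
        lo, hi = report["deprivation_differential_range"]
        assert lo == pytest.approx(comp.deprivation_differential.min())
        assert hi == pytest.approx(comp.deprivation_differential.max())
        assert report["variance_share"][0] > report["variance_share"][1]

    def test_smooth_field_has_smaller_differential_share(self):
        shares = {}
        for rho in (0.0, 0.8):
            cfg = SimulationConfig(grid_rows=15, grid_cols=15, autocorr_mix=rho,
                                   smoothing_rounds=5, seed=3)
            table, graph = simulate_region(cfg)
            imd = pd.Series(table["imd"].to_numpy(),
                            index=pd.Index(table["area_id"]))
            ald = spatial_lag(imd, graph).ald.reindex(imd.index)
            comp = decompose(imd, ald)
            shares[rho] = interpret_differential(comp)["variance_share"][1]
        assert shares[0.8] < shares[0.0]


class TestCorrelationMode:
    def test_two_variable_correlation_pca_gives_equal_loadings(self, series_pair):
        imd, ald = series_pair
        comp = decompose(imd, ald, mode="correlation")
        np.testing.assert_allclose(
            np.abs(comp.loadings), np.full((2, 2), 1 / np.sqrt(2)), atol=1e-10
        )
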