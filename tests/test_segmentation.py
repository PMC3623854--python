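"""Tertile assignment, within-segment refits, and the beta-ratio tables."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from deprivdiff import (
    DegenerateInputError,
    InputError,
    SimulationConfig,
    assign_tertiles,
    compute_outcomes,
    decompose,
    ratio,
    segment_regressions,
    simulate_region,
    spatial_lag,
)
from deprivdiff.reference import england_segment_table
from deprivdiff.segmentation import TERTILE_LABELS


def components_for(table, graph):
    imd = pd.Series(table["imd"].to_numpy(), index=pd.Index(table["area_id"]))
    ald = spatial_lag(imd, graph).ald.reindex(imd.index)
    return decompose(imd, ald)


class TestAssignTertiles:
    def test_exact_thirds(self):
        imd = pd.Series(np.arange(1.0, 10.0), index=[f"a{i}" for i in range(9)])
        labels = assign_tertiles(imd)
        upper = set(imd[labels == TERTILE_LABELS[0]])
        assert upper == {7.0, 8.0, 9.0}
        assert set(imd[labels == TERTILE_LABELS[1]]) == {4.0, 5.0, 6.0}
        assert set(imd[labels == TERTILE_LABELS[2]]) == {1.0, 2.0, 3.0}

    def test_remainder_allocation_deterministic(self):
        imd = pd.Series(np.arange(10.0), index=[f"a{i}" for i in range(10)])
        labels = assign_tertiles(imd)
        sizes = labels.value_counts()
        assert sorted(sizes) == [3, 3, 4]
        assert labels.equals(assign_tertiles(imd))

    def test_tie_break_by_identifier(self):
        imd = pd.Series(5.0, index=[f"a{i}" for i in range(9)])
        labels = assign_tertiles(imd)
        # deterministic: identifier order decides the split
        assert list(imd[labels == TERTILE_LABELS[0]].index) == ["a0", "a1", "a2"]

    def test_sizes_differ_by_at_most_one(self, rng):
        for n in (9, 10, 11, 100, 101):
            imd = pd.Series(rng.normal(size=n), index=[f"a{i}" for i in range(n)])
            sizes = assign_tertiles(imd).value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_too_few_areas(self):
        with pytest.raises(InputError):
            assign_tertiles(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestRatio:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [
            (0.638, 0.688, 0.927),   # published 'not good health', most affluent class
            (0.409, 0.055, 7.436),   # published LLTI, most deprived class
            (0.555, 0.513, 1.081),   # published 'not good health', middle tertile
            (0.3, 0.3, 1.0),
        ],
    )
    def test_worked_examples(self, b1, b2, expected):
        assert ratio(b1, b2) == pytest.approx(expected, abs=1e-3)

    def test_zero_denominator_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ratio(0.5, 0.0)

    def test_published_self_consistent_rows(self):
        table = england_segment_table()
        consistent = table[table["self_consistent"]]
        assert len(consistent) >= 20  # most printed rows are reproducible
        for _, row in consistent.iterrows():
            assert ratio(row["beta1"], row["beta2"]) == pytest.approx(
                row["printed_ratio"], abs=1.5e-3
            )


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(grid_rows=30, grid_cols=30, seed=4)
    table, graph = simulate_region(cfg)
    comp = components_for(table, graph)
    outcome_table = compute_outcomes(table, zero_policy="continuity")
    labels = pd.Series(table["segment"].to_numpy(),
                       index=pd.Index(table["area_id"]))
    return table, comp, outcome_table, labels


class TestSegmentRegressions:
    def test_rows_ordered_by_descending_ratio(self, fitted):
        _, comp, outcome_table, labels = fitted
        reports = segment_regressions(outcome_table, comp, labels)
        for rep in reports.values():
            finite = [r.ratio for r in rep.rows if math.isfinite(r.ratio)]
            assert finite == sorted(finite, reverse=True)

    def test_ratio_column_consistent_with_betas(self, fitted):
        _, comp, outcome_table, labels = fitted
        reports = segment_regressions(outcome_table, comp, labels)
        for rep in reports.values():
            for row in rep.rows:
                if abs(row.beta2) > 1e-9:
                    assert row.ratio == pytest.approx(row.beta1 / row.beta2, abs=1e-9)

    def test_undersized_segments_dropped_with_warning(self, fitted, caplog):
        _, comp, outcome_table, labels = fitted
        tiny = labels.copy()
        tiny.iloc[:5] = "tiny_segment"
        with caplog.at_level(logging.WARNING, logger="deprivdiff.segmentation"):
            reports = segment_regressions(outcome_table, comp, tiny)
        for rep in reports.values():
            assert "tiny_segment" in rep.dropped
            assert all(r.segment != "tiny_segment" for r in rep.rows)
        assert any("tiny_segment" in rec.message for rec in caplog.records)

    def test_restandardization_within_segments(self, fitted, rng):
        # a segment whose IMD is shifted but internally identical must give
        # identical betas: global z-scores are never reused
        n = 200
        ids_a = [f"s{i}" for i in range(n)]
        ids_b = [f"t{i}" for i in range(n)]
        pc1 = rng.normal(size=n)
        pc2 = rng.normal(size=n)
        y = 0.5 * pc1 + 0.2 * pc2 + rng.normal(size=n) * 0.3

        def fake_components(pc1_vals, pc2_vals, ids):
            from deprivdiff import DeprivationComponents
            return DeprivationComponents(
                target_deprivation=pd.Series(pc1_vals, index=ids),
                deprivation_differential=pd.Series(pc2_vals, index=ids),
                loadings=np.array([[1.0, 0.0], [0.0, -1.0]]),
                variance_explained=(2.0, 1.0),
                means=(0.0, 0.0),
            )

        all_ids = ids_a + ids_b
        comp = fake_components(
            np.concatenate([pc1, pc1 + 50.0]),  # second segment shifted
            np.concatenate([pc2, pc2]),
            all_ids,
        )
        outcome_table = pd.DataFrame(
            {
                "area_id": all_ids,
                "outcome": "not_good_health",
                "count": 1,
                "denominator": 100,
                "percentage": 1.0,
                "log10_pct": np.concatenate([y, y]),
            }
        )
        labels = pd.Series(["A"] * n + ["B"] * n, index=all_ids)
        reports = segment_regressions(
            outcome_table, comp, labels, ranks={"A": 1, "B": 2}
        )
        rows = {r.segment: r for r in reports["not_good_health"].rows}
        assert rows["A"].beta1 == pytest.approx(rows["B"].beta1, abs=1e-10)
        assert rows["A"].beta2 == pytest.approx(rows["B"].beta2, abs=1e-10)

    def test_null_effects_give_small_segment_betas(self):
        # pooled null on the full study grid: tertile segments of ~833 areas
        cfg = SimulationConfig(effect_target=0.0, effect_differential=0.0, seed=9)
        table, graph = simulate_region(cfg)
        comp = components_for(table, graph)
        outcome_table = compute_outcomes(table, zero_policy="continuity")
        labels = assign_tertiles(
            pd.Series(table["imd"].to_numpy(), index=pd.Index(table["area_id"]))
        )
        reports = segment_regressions(outcome_table, comp, labels, scheme="imd_tertiles")
        for rep in reports.values():
            for row in rep.rows:
                assert row.n_areas >= 200
                assert abs(row.beta1) < 0.1
                assert abs(row.beta2) < 0.1

    def test_missing_labels_rejected(self, fitted):
        _, comp, outcome_table, labels = fitted
        with pytest.raises(InputError, match="missing"):
            segment_regressions(outcome_table, comp, labels.iloc[:-3])
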