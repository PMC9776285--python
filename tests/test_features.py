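"""VIF multicollinearity filtering and feature-variant construction."""

import numpy as np
import pandas as pd
import pytest

from renalnmp.features import (
    build_variant,
    interpolate_missing,
    marker_summary,
    standardize,
    vif,
    vif_filter,
)
from renalnmp.records import GRID_20MIN, GRID_60MIN, MARKER_ORDER
from renalnmp.screen import SignificanceMap


def sig_map_from_cells(cells, alpha=0.05):
    """SignificanceMap with the given (marker, t) cells significant (2v3)."""
    rows = [{"marker": m, "t_min": t, "pair": "2v3", "route": "anova",
             "p": 0.01, "significant": True} for m, t in cells]
    return SignificanceMap(alpha=alpha, table=pd.DataFrame(
        rows, columns=["marker", "t_min", "pair", "route", "p", "significant"]))


class TestVif:
    def test_independent_columns_near_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        assert (vif(m) < 1.1).all()

    def test_equicorrelation_closed_form(self, rng):
        # r = 0.5 equicorrelation, 3 variables: VIF = (1+r)/((1-r)(1+2r)) = 1.5
        r = 0.5
        cov = np.full((3, 3), r) + (1 - r) * np.eye(3)
        x = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        # evaluate the definition on the exact correlation matrix instead of
        # the sample: build data whose sample correlation is exact
        chol = np.linalg.cholesky(cov)
        z = rng.normal(size=(2000, 3))
        z = (z - z.mean(0)) / z.std(0)
        u, _, vt = np.linalg.svd(z, full_matrices=False)
        exact = u @ vt @ chol.T  # columns with exactly the target correlation
        got = vif(pd.DataFrame(exact, columns=list("abc")))
        assert np.allclose(got, 1.5, atol=1e-8)

    def test_duplicated_column_reported_infinite(self, rng):
        a = rng.normal(size=80)
        m = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=80)})
        v = vif(m)
        assert v["a"] > 1e6 and v["b"] > 1e6

    def test_matches_regression_definition(self, rng):
        m = pd.DataFrame(rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5)),
                         columns=list("abcde"))
        v = vif(m)
        x = (m - m.mean()) / m.std(ddof=0)
        for j, col in enumerate(m.columns):
            others = x.drop(columns=[col]).to_numpy()
            design = np.column_stack([np.ones(len(x)), others])
            beta, *_ = np.linalg.lstsq(design, x[col].to_numpy(), rcond=None)
            resid = x[col].to_numpy() - design @ beta
            r2 = 1 - resid @ resid / (x[col] @ x[col])
            assert v[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)

    def test_incomplete_input_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            vif(m)


class TestVifFilter:
    def test_uncorrelated_matrix_untouched(self, rng):
        m = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        kept, log = vif_filter(m)
        assert kept == list("abcd")
        assert log.empty

    def test_removes_constructed_collinearity(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        m = pd.DataFrame({"a": a, "b": b,
                          "c": a + b + rng.normal(0, 1e-3, 100)})
        kept, log = vif_filter(m, threshold=10.0)
        assert len(kept) == 2
        assert len(log) == 1
        assert log.iloc[0]["vif"] > 10.0
        final = vif(m[kept])
        assert (final <= 10.0).all()

    def test_row_order_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)) @ rng.normal(size=(4, 4)),
                         columns=list("abcd"))
        kept1, _ = vif_filter(m)
        kept2, _ = vif_filter(m.iloc[rng.permutation(50)])
        assert kept1 == kept2

    def test_terminates_within_variable_count(self, rng):
        base = rng.normal(size=60)
        m = pd.DataFrame({f"v{i}": base + rng.normal(0, 0.01, 60)
                          for i in range(6)})
        kept, log = vif_filter(m)
        assert len(log) <= 5
        assert len(kept) >= 1


class TestVariants:
    def test_variant_a_feature_count_arithmetic(self, clean_tables):
        # 4 markers on the 20-min grid + 2 on the 60-min grid, each
        # significant somewhere: variant A = 4*12 + 2*4 = 56 features
        markers = ["rbf", "ap", "t_kidney", "vo2", "urine_rate", "rel_urea"]
        sig = sig_map_from_cells([(m, 60) for m in markers])
        fm = build_variant(clean_tables, sig, "A", markers)
        assert fm.X.shape[1] == 56

    def test_variant_nesting_by_time_cutoff(self, clean_tables):
        cells = [("rbf", t) for t in GRID_20MIN] + [
            ("urine_rate", t) for t in GRID_60MIN]
        sig = sig_map_from_cells(cells)
        cols = {}
        for v in "BCDE":
            cols[v] = set(build_variant(clean_tables, sig, v,
                                        ["rbf", "urine_rate"]).X.columns)
        assert cols["E"] <= cols["D"] <= cols["C"] <= cols["B"]

    def test_empty_significance_is_error(self, clean_tables):
        sig = sig_map_from_cells([])
        with pytest.raises(ValueError):
            build_variant(clean_tables, sig, "B", list(MARKER_ORDER))

    def test_columns_follow_canonical_marker_order(self, clean_tables):
        cells = [("urine_rate", 60), ("rbf", 40), ("ap", 20)]
        fm = build_variant(clean_tables, sig_map_from_cells(cells), "B",
                           ["urine_rate", "rbf", "ap"])
        assert list(fm.X.columns) == ["rbf@40", "ap@20", "urine_rate@60"]


class TestStandardize:
    def test_train_moments_and_no_refit(self, rng):
        tr = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        te = pd.DataFrame(rng.normal(5, 3, size=(10, 4)), columns=list("abcd"))
        tr_z, te_z, scaler = standardize(tr, te)
        assert np.allclose(tr_z.mean(), 0, atol=1e-12)
        assert np.allclose(tr_z.std(ddof=0), 1, atol=1e-12)
        # the fitted scale comes from the training rows, so the test moments
        # do not become 0/1 (no leakage)
        assert not np.allclose(te_z.mean().abs(), 0, atol=1e-3)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        tr = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning):
            tr_z, _, _ = standardize(tr)
        assert list(tr_z.columns) == ["a"]


class TestMissingHandling:
    def test_interior_gap_interpolated_linearly(self, clean_tables):
        tab = clean_tables[0]
        frame = tab.frame.copy()
        frame.loc[120, "rbf"] = np.nan
        broken = type(tab)(tab.kidney_id, tab.function_class, tab.weight_g,
                           tab.split, frame)
        fixed = interpolate_missing([broken])[0]
        expected = (frame.loc[100, "rbf"] + frame.loc[140, "rbf"]) / 2
        assert fixed.frame.loc[120, "rbf"] == pytest.approx(expected)

    def test_edge_gap_takes_nearest(self, clean_tables):
        tab = clean_tables[0]
        frame = tab.frame.copy()
        frame.loc[20, "do2"] = np.nan
        broken = type(tab)(tab.kidney_id, tab.function_class, tab.weight_g,
                           tab.split, frame)
        fixed = interpolate_missing([broken])[0]
        assert fixed.frame.loc[20, "do2"] == pytest.approx(
            frame.loc[40, "do2"])

    def test_marker_summary_shape(self, tables):
        summ = marker_summary(tables)
        assert summ.shape == (len(tables), 11)
        assert list(summ.columns) == list(MARKER_ORDER)
        assert summ.notna().all().all()
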