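"""Efficiency, tVIF and contrast-VIF behavior, including the classic
collinearity-workaround scenarios (reparameterization, derivative
omission, event merging, regressor omission)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvifkit.design import TimeGrid, assemble_design, make_regressor
from cvifkit.diagnostics import (
    ContrastSpec,
    SingularDesignError,
    cvif,
    efficiency,
    parse_contrast,
    tvif,
    vif_report,
)

from conftest import event_table


def design_from_array(X, names, task=None, grid=None):
    grid = grid or TimeGrid(run_lengths=(X.shape[0] * 0.8,))
    from cvifkit.design import DesignMatrix

    frame = pd.DataFrame(X, columns=names)
    return DesignMatrix(frame=frame, grid=grid,
                        task_columns=task or [n for n in names if n != "intercept"])


def correlated_pair(n=50, r=0.9):
    """Two centered unit-norm regressors with exact correlation r."""
    rng = np.random.default_rng(42)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean() + a @ b * a @ np.ones(n) * 0  # center
    b -= a * (a @ b)
    b -= b.mean()
    b /= np.linalg.norm(b)
    x2 = r * a + np.sqrt(1 - r**2) * b
    return a, x2


class TestEfficiency:
    def test_identity_crossproduct_unit_contrast(self):
        X = np.eye(4)
        d = design_from_array(X, ["a", "b", "c", "d"])
        assert efficiency(d, ContrastSpec("a", np.array([1.0, 0, 0, 0]))) == pytest.approx(1.0)

    def test_identity_crossproduct_difference_contrast(self):
        X = np.eye(4)
        d = design_from_array(X, ["a", "b", "c", "d"])
        c = ContrastSpec("a-b", np.array([1.0, -1.0, 0, 0]))
        assert efficiency(d, c) == pytest.approx(0.5)

    def test_matches_matrix_inversion_oracle(self):
        x1, x2 = correlated_pair(r=0.9)
        X = np.column_stack([x1, x2])
        d = design_from_array(X, ["a", "b"])
        c = np.array([1.0, 0.0])
        oracle = 1.0 / (c @ np.linalg.inv(X.T @ X) @ c)
        assert efficiency(d, ContrastSpec("a", c)) == pytest.approx(oracle, rel=1e-12)

    def test_variance_identity(self):
        # Var(c b^) * efficiency == sigma^2 by construction of both formulas
        x1, x2 = correlated_pair(r=0.6)
        X = np.column_stack([x1, x2, np.ones(len(x1))])
        d = design_from_array(X, ["a", "b", "intercept"])
        c = ContrastSpec("diff", np.array([1.0, -1.0, 0.0]))
        sigma2 = 2.7
        var = float(c.weights @ np.linalg.inv(X.T @ X) @ c.weights) * sigma2
        assert var * efficiency(d, c) == pytest.approx(sigma2, rel=1e-10)

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ContrastSpec("null", np.zeros(3))


class TestTvif:
    def test_orthogonal_regressor_has_tvif_one(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((40, 3))
        raw -= raw.mean(axis=0)  # orthogonal to the intercept as well
        Q, _ = np.linalg.qr(raw)
        X = np.column_stack([Q[:, 0], Q[:, 1], np.ones(40)])
        d = design_from_array(X, ["a", "b", "intercept"])
        assert tvif(d, "a") == pytest.approx(1.0, abs=1e-12)

    def test_correlation_09_closed_form(self):
        x1, x2 = correlated_pair(r=0.9)
        X = np.column_stack([x1, x2, np.ones(len(x1))])
        d = design_from_array(X, ["a", "b", "intercept"])
        assert tvif(d, "a") == pytest.approx(1 / (1 - 0.81), rel=1e-9)

    def test_duplicated_column_raises_singularity(self):
        x1, _ = correlated_pair()
        X = np.column_stack([x1, x1, np.ones(len(x1))])
        d = design_from_array(X, ["a", "a_copy", "intercept"])
        with pytest.raises(SingularDesignError):
            tvif(d, "a")

    def test_requires_intercept(self):
        x1, x2 = correlated_pair()
        d = design_from_array(np.column_stack([x1, x2]), ["a", "b"])
        with pytest.raises(ValueError, match="intercept"):
            tvif(d, "a")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(20, 60))
    def test_matches_two_model_variance_ratio_oracle(self, seed, p, n):
        """tVIF equals the explicit full-vs-reduced variance ratio computed
        through an independent pseudoinverse route."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        X = np.column_stack([X, np.ones(n)])
        names = [f"c{i}" for i in range(p)] + ["intercept"]
        d = design_from_array(X, names)
        j = int(rng.integers(p))
        full_var = (np.linalg.pinv(X) @ np.linalg.pinv(X).T)[j, j]
        Xr = np.column_stack([np.ones(n), X[:, j]])
        red_var = (np.linalg.pinv(Xr) @ np.linalg.pinv(Xr).T)[1, 1]
        assert tvif(d, names[j]) == pytest.approx(full_var / red_var, abs=1e-8, rel=1e-8)


class TestCvif:
    def test_elementary_contrast_equals_tvif(self, saturated_design):
        for col in ("cue_LargeWin", "rt", "feedback_NeutralMiss"):
            w = np.zeros(len(saturated_design.column_names))
            w[saturated_design.column_names.index(col)] = 1.0
            assert cvif(saturated_design, ContrastSpec(col, w)) == pytest.approx(
                tvif(saturated_design, col), abs=1e-8
            )

    def test_reparameterization_keeps_cvif_but_zeroes_tvif(self, adjacent_pair_design):
        """Serially orthogonalizing one of two correlated condition
        regressors makes every tVIF ~1, yet the variance inflation of the
        original condition contrast is unchanged."""
        d = adjacent_pair_design
        x_a = d.frame["A"].to_numpy()
        x_b = d.frame["B"].to_numpy()
        assert np.corrcoef(x_a, x_b)[0, 1] > 0.8
        a = float(x_a @ x_b / (x_a @ x_a))
        ortho = assemble_design({"A": x_a, "B_orth": x_b - a * x_a}, d.grid)
        assert tvif(ortho, "A") == pytest.approx(1.0, abs=0.05)
        assert tvif(ortho, "B_orth") == pytest.approx(1.0, abs=0.05)
        c_cond = parse_contrast("A", d.column_names)
        c_ortho = ContrastSpec("A_orig", np.array([1.0, -a, 0.0]))
        value = cvif(ortho, c_ortho, condition_design=d)
        reference = cvif(d, c_cond)
        assert reference > 2.0  # genuinely inflated despite orthogonal columns
        assert value == pytest.approx(reference, rel=0.01)

    def test_omitting_derivatives_lowers_cvif(self, toy_grid, toy_kernel):
        """Short adjacent events whose regressors carry temporal
        derivatives: dropping the derivatives deflates the condition
        difference cVIF by much more than 3x."""
        onsets = [2.0, 12.0, 22.0, 32.0, 42.0]
        pair_a = make_regressor(event_table(onsets, 1.0, "A"), toy_grid, "boxcar",
                                toy_kernel, with_derivative=True)
        pair_b = make_regressor(event_table([o + 1 for o in onsets], 1.0, "B"),
                                toy_grid, "boxcar", toy_kernel, with_derivative=True)
        with_d = assemble_design(
            {"A": pair_a[:, 0], "A_deriv": pair_a[:, 1],
             "B": pair_b[:, 0], "B_deriv": pair_b[:, 1]}, toy_grid)
        without = assemble_design({"A": pair_a[:, 0], "B": pair_b[:, 0]}, toy_grid)
        c_with = parse_contrast("A - B", with_d.column_names)
        c_without = parse_contrast("A - B", without.column_names)
        assert cvif(with_d, c_with) > 3 * cvif(without, c_without)

    def test_merging_adjacent_events_reduces_cvif(self, adjacent_pair_design,
                                                  toy_grid, toy_kernel):
        merged_reg = make_regressor(event_table([2., 12., 22., 32., 42.], 2.0, "AB"),
                                    toy_grid, "boxcar", toy_kernel)
        merged = assemble_design({"AB": merged_reg}, toy_grid)
        c_sep = parse_contrast("A", adjacent_pair_design.column_names)
        c_merged = parse_contrast("AB", merged.column_names)
        assert cvif(merged, c_merged) < cvif(adjacent_pair_design, c_sep) / 2

    def test_zero_weight_contrast_rejected(self, adjacent_pair_design):
        with pytest.raises(ValueError):
            ContrastSpec("zero", np.zeros(3))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(25, 60))
    def test_cvif_at_least_one(self, seed, p, n):
        """Adding regressors can only inflate a contrast's variance."""
        rng = np.random.default_rng(seed)
        X = np.column_stack([rng.standard_normal((n, p)), np.ones(n)])
        names = [f"c{i}" for i in range(p)] + ["intercept"]
        d = design_from_array(X, names)
        w = np.append(rng.integers(-2, 3, size=p).astype(float), 0.0)
        if not w[:p].any():
            w[0] = 1.0
        assert cvif(d, ContrastSpec("w", w)) >= 1.0 - 1e-9


class TestParseContrast:
    def test_simple_difference(self):
        c = parse_contrast("CueLW - CueNeut", ["CueLW", "CueNeut", "intercept"])
        assert np.allclose(c.weights, [1.0, -1.0, 0.0])

    def test_weighted_feedback_contrast(self):
        cols = ["feedback_LargeWinHit", "feedback_SmallWinHit",
                "feedback_LargeWinMiss", "feedback_SmallWinMiss", "intercept"]
        c = parse_contrast(
            ".5*feedback_LargeWinHit + .5*feedback_SmallWinHit "
            "- .5*feedback_LargeWinMiss - .5*feedback_SmallWinMiss", cols)
        assert np.allclose(c.weights, [0.5, 0.5, -0.5, -0.5, 0.0])

    def test_unknown_name_lists_candidates(self):
        with pytest.raises(ValueError, match="Bar|unknown"):
            parse_contrast("Foo - Bar", ["Foo", "Baz"])


class TestVifReport:
    def test_orthogonal_design_all_flags_clear(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 3)))
        X = np.column_stack([Q - Q.mean(axis=0), np.ones(40)])
        d = design_from_array(X, ["a", "b", "c", "intercept"])
        contrasts = [parse_contrast("a - b", d.column_names)]
        report = vif_report(d, contrasts)
        assert all(flag == "" for flag in report.flags.values())
        assert not report.warnings

    def test_derivative_design_flags_excessive(self, saturated_derivs_design):
        from cvifkit.mid import contrast_library

        lib = contrast_library(saturated_derivs_design.column_names)
        report = vif_report(saturated_derivs_design, [lib["Cue:LW-Neut"]])
        assert "excessive" in report.flags["Cue:LW-Neut"]

    def test_omitted_regressor_warning(self, adjacent_pair_design):
        contrasts = [parse_contrast("A", adjacent_pair_design.column_names)]
        report = vif_report(adjacent_pair_design, contrasts,
                            candidate_columns=["A", "B", "C_probe"])
        assert any("C_probe" in w and "omitted" in w for w in report.warnings)
        assert "C_probe" not in report.tvif
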