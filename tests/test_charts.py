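"""The core engine: B-spline bases, the pinball-loss LP, chart fitting,
evaluation and rank lookup."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cfcentiles import (
    PatientRecord,
    PercentileChart,
    Registry,
    SplineSpec,
    ValidationError,
    bspline_basis,
    filter_registry,
    fit_chart,
    fit_quantile,
    pinball_loss,
    true_quantile,
)
from cfcentiles.charts import DomainError, FitError, _build_design


def _cox_de_boor(knots, degree, i, x):
    """Independent naive Cox-de Boor recursion (test oracle)."""
    if degree == 0:
        # half-open intervals, closed at the right end of the last span
        last = knots[-1]
        if knots[i] <= x < knots[i + 1]:
            return 1.0
        if x == last and knots[i] < knots[i + 1] == last:
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) * _cox_de_boor(
            knots, degree - 1, i, x
        )
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (knots[i + degree + 1] - x) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * _cox_de_boor(knots, degree - 1, i + 1, x)
    return left + right


class TestBasis:
    @given(x=st.floats(0.0, 10.0))
    def test_partition_of_unity(self, x):
        spec = SplineSpec().fit_knots(np.linspace(0, 10, 200))
        assert bspline_basis(spec, x).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_nodes", [4, 6, 9])
    def test_dimension_is_interior_plus_four(self, n_nodes):
        spec = SplineSpec(n_nodes=n_nodes).fit_knots(np.linspace(0, 1, 500))
        assert spec.dimension == (n_nodes - 2) + 4

    def test_matches_naive_cox_de_boor(self):
        """One-interior-knot cubic basis evaluated against an independent
        recursion, at several interior points."""
        spec = SplineSpec(n_nodes=3).fit_knots(np.linspace(0, 1, 101))
        for x in (0.1, 0.25, 0.4, 0.5, 0.77, 1.0):
            vals = bspline_basis(spec, x)
            oracle = [
                _cox_de_boor(spec.knots, 3, i, x) for i in range(spec.dimension)
            ]
            assert vals == pytest.approx(oracle, abs=1e-12)

    def test_nonnegative_entries(self):
        spec = SplineSpec().fit_knots(np.linspace(0, 1, 100))
        for x in np.linspace(0, 1, 23):
            assert np.all(bspline_basis(spec, x) >= 0)

    def test_outside_boundary_rejected(self):
        spec = SplineSpec().fit_knots(np.linspace(0, 1, 100))
        with pytest.raises(DomainError):
            spec.design_matrix(np.array([1.5]))


class TestPinball:
    @pytest.mark.parametrize(
        "tau, residual, expected",
        [(0.5, 2.0, 1.0), (0.25, -4.0, 3.0), (0.9, 10.0, 9.0)],
    )
    def test_values(self, tau, residual, expected):
        assert pinball_loss(tau, residual) == pytest.approx(expected)

    def test_invalid_tau(self):
        with pytest.raises(ValidationError):
            pinball_loss(1.2, 1.0)


def _total_loss(tau, y, fitted):
    return float(np.sum(pinball_loss(tau, y - fitted)))


class TestFitQuantile:
    def test_intercept_only_median(self):
        X = np.ones((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        beta = fit_quantile(X, y, 0.5)
        assert _total_loss(0.5, y, X @ beta) == pytest.approx(
            _total_loss(0.5, y, np.full(3, 2.0)), abs=1e-9
        )

    def test_matches_brute_force_grid(self, rng):
        """Intercept-only fit attains the grid minimum over a fine grid of
        constants (n=51 draws)."""
        y = rng.normal(size=51)
        X = np.ones((51, 1))
        beta = fit_quantile(X, y, 0.3)
        grid = np.linspace(y.min(), y.max(), 20001)
        grid_losses = np.sum(
            pinball_loss(0.3, y[:, None] - grid[None, :]), axis=0
        )
        assert _total_loss(0.3, y, X @ beta) <= grid_losses.min() + 1e-8

    def test_loss_equals_order_statistic_minimum(self, rng):
        """On any dataset the intercept-only optimum is attained at a data
        value; achieved loss matches that enumeration to 1e-9."""
        for trial in range(20):
            n = int(rng.integers(5, 200))
            tau = float(rng.uniform(0.05, 0.95))
            y = rng.normal(size=n) * rng.uniform(0.5, 3)
            beta = fit_quantile(np.ones((n, 1)), y, tau)
            candidates = [_total_loss(tau, y, np.full(n, c)) for c in y]
            assert _total_loss(tau, y, np.full(n, beta[0])) <= min(candidates) + 1e-9

    def test_linear_conditional_quantile_recovery(self, rng):
        """y = a + b x + heteroscedastic-free noise: the fitted tau-line
        matches the known conditional quantile at n=20,000."""
        n = 20000
        x = rng.uniform(0, 10, n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        for tau in (0.25, 0.75):
            beta = fit_quantile(X, y, tau)
            from scipy.stats import norm

            truth = np.array([1.0 + norm.ppf(tau), 2.0])
            assert beta == pytest.approx(truth, abs=0.06)

    def test_matches_statsmodels_quantreg(self, rng):
        """Independent cross-check: same achieved pinball loss as the IRLS
        implementation in statsmodels, to 1e-6 relative."""
        sm = pytest.importorskip("statsmodels.api")
        n = 800
        x = rng.uniform(0, 1, n)
        y = np.sin(3 * x) + rng.normal(size=n) * 0.3
        X = np.column_stack([np.ones(n), x, x**2])
        for tau in (0.1, 0.5, 0.9):
            ours = _total_loss(tau, y, X @ fit_quantile(X, y, tau))
            theirs_beta = sm.QuantReg(y, X).fit(q=tau).params
            theirs = _total_loss(tau, y, X @ theirs_beta)
            assert ours <= theirs * (1 + 1e-6)

    def test_equivariance_under_shift(self, rng):
        """Adding c to all y shifts every fitted curve by exactly c (the
        intercept lies in the basis span)."""
        n = 500
        x = rng.uniform(0, 1, n)
        y = x + rng.normal(size=n) * 0.2
        spec = SplineSpec(n_nodes=4).fit_knots(x)
        X = spec.design_matrix(x)
        grid = spec.design_matrix(np.linspace(0.05, 0.95, 11))
        base = grid @ fit_quantile(X, y, 0.3)
        shifted = grid @ fit_quantile(X, y + 5.0, 0.3)
        assert shifted - base == pytest.approx(np.full(11, 5.0), abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(FitError, match="rank"):
            fit_quantile(X, np.arange(50.0), 0.5)

    def test_underdetermined_rejected(self):
        with pytest.raises(FitError, match="n="):
            fit_quantile(np.eye(3, 5), np.zeros(3), 0.5)


class TestFilterRegistry:
    @staticmethod
    def _toy_registry():
        recs = [
            PatientRecord("p1", "France", 2005, "M", 10.0, 140, 32, 1.8),
            PatientRecord("p2", "France", 2005, "M", 20.0, 175, 60, 3.0,
                          transplanted=True),
            PatientRecord("p3", "France", 2005, "F", 45.0, 165, 55, 2.0),
            PatientRecord("p4", "France", 2005, "F", 6.0, 115, 20, 1.0),
            PatientRecord("p5", "France", 2005, "F", 40.0, 165, 55, 1.5),
        ]
        return Registry.from_records(recs)

    def test_toy_counts(self):
        reg = self._toy_registry()
        assert filter_registry(reg, "fev1").n_records == 3

    def test_closed_interval_boundaries(self):
        kept = filter_registry(self._toy_registry(), "fev1").frame
        assert 6.0 in kept.age_years.values
        assert 40.0 in kept.age_years.values

    def test_bmi_keeps_young_children(self):
        recs = [
            PatientRecord("p1", "France", 2005, "F", 3.0, 95, 14.5),
            PatientRecord("p2", "France", 2005, "F", 10.0, 138, 31, 1.6),
        ]
        reg = Registry.from_records(recs)
        assert filter_registry(reg, "bmi").n_records == 2
        assert filter_registry(reg, "fev1").n_records == 1

    def test_filters_recorded_in_provenance(self):
        out = filter_registry(self._toy_registry(), "fev1")
        assert any("transplant" in f for f in out.filters_applied)


class TestFitChart:
    def test_coverage_within_two_points(self, medium_oracle_setup):
        """For each fitted tau the fraction of training points strictly
        below the curve is within 2 percentage points of tau."""
        _, registry = medium_oracle_setup
        for sex in ("M", "F"):
            chart = fit_chart(
                registry, "fev1", sex, ("age",),
                taus=[0.1, 0.25, 0.5, 0.75, 0.9],
                specs={"age": SplineSpec()},
            )
            frame = registry.frame[registry.frame.sex == sex]
            vals = chart.curve_values({"age": frame.age_years.values})
            for tau, curve in zip(chart.taus, vals):
                frac = np.mean(frame.fev1_l.values < curve)
                assert abs(frac - tau) < 0.02

    def test_median_curve_recovers_truth(self, medium_oracle_setup):
        """Fitted median within a few percent of the closed-form conditional
        median over the central 80% of the age range."""
        config, registry = medium_oracle_setup
        chart = fit_chart(
            registry, "fev1", "M", ("age",), taus=[0.5],
            specs={"age": SplineSpec()},
        )
        grid = np.linspace(6 + 0.1 * 34, 40 - 0.1 * 34, 40)
        fitted = chart.curve_values({"age": grid})[0]
        truth = np.array(
            [true_quantile(config, "fev1", "M", 0.5, a) for a in grid]
        )
        y = registry.frame.query("sex == 'M'").fev1_l
        assert np.max(np.abs(fitted - truth)) < 0.03 * (y.max() - y.min())

    def test_duplication_invariance(self, fev1_registry):
        """Duplicating every record doubles the achieved pinball loss
        exactly and leaves the fitted curves essentially unchanged
        (minimizers may differ within LP degeneracy)."""
        frame = fev1_registry.frame.query("sex == 'F'")
        x, y = frame.age_years.values, frame.fev1_l.values
        spec1 = SplineSpec(n_nodes=4).fit_knots(x)
        x2, y2 = np.tile(x, 2), np.tile(y, 2)
        spec2 = SplineSpec(n_nodes=4).fit_knots(x2)
        grid = np.linspace(7, 39, 21)
        for tau in (0.25, 0.75):
            b1 = fit_quantile(spec1.design_matrix(x), y, tau)
            b2 = fit_quantile(spec2.design_matrix(x2), y2, tau)
            l1 = np.sum(pinball_loss(tau, y - spec1.design_matrix(x) @ b1))
            l2 = np.sum(pinball_loss(tau, y2 - spec2.design_matrix(x2) @ b2))
            assert l2 == pytest.approx(2 * l1, rel=1e-5)  # LP solver tolerance
            c1 = spec1.design_matrix(grid) @ b1
            c2 = spec2.design_matrix(grid) @ b2
            assert c1 == pytest.approx(c2, abs=5e-3)

    def test_metadata_records_fit(self, fev1_registry):
        chart = fit_chart(fev1_registry, "fev1", "M", ("age",), taus=[0.5],
                          specs={"age": SplineSpec()})
        assert chart.metadata["n"] == (fev1_registry.frame.sex == "M").sum()
        assert chart.metadata["filters"]

    def test_too_few_records_explains(self, fev1_registry):
        tiny = fev1_registry.with_frame(fev1_registry.frame.head(5))
        with pytest.raises(FitError, match="5"):
            fit_chart(tiny, "fev1", "M", ("age",), taus=[0.5],
                      specs={"age": SplineSpec(n_nodes=6)})


@pytest.fixture(scope="module")
def chart(medium_oracle_setup):
    """Full 99-tau male age chart on the oracle registry."""
    _, registry = medium_oracle_setup
    return fit_chart(registry, "fev1", "M", ("age",),
                     specs={"age": SplineSpec()})


class TestEvaluateAndRank:

    def test_evaluate_finite_everywhere(self, chart):
        lo, hi = chart.training_range("age")
        for tau in (0.01, 0.5, 0.99):
            for age in (lo, (lo + hi) / 2, hi):
                assert np.isfinite(chart.evaluate(tau, age=age))

    def test_extrapolation_contract(self, chart):
        with pytest.raises(DomainError, match="training range"):
            chart.evaluate(0.5, age=50.0)
        assert np.isfinite(chart.evaluate(0.5, age=50.0, extrapolate=True))

    def test_median_observation_ranks_fifty(self, chart):
        v = chart.evaluate(0.5, age=20.0)
        assert chart.percentile_rank(v, age=20.0) == pytest.approx(50.0, abs=1.0)

    def test_clamped_below_first_percentile(self, chart):
        assert chart.percentile_rank(0.01, age=20.0) == 1.0
        assert chart.percentile_rank(50.0, age=20.0) == 99.0

    def test_rank_evaluate_round_trip(self, chart):
        """rank(evaluate(tau)) = 100 tau within one percentile point, after
        rearrangement, across the tau grid."""
        for tau in (0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95):
            for age in (10.0, 18.0, 30.0):
                v = chart.evaluate(tau, age=age)
                assert chart.percentile_rank(v, age=age) == pytest.approx(
                    100 * tau, abs=1.0
                )

    def test_training_ranks_uniform(self, medium_oracle_setup, chart):
        """Probability-integral-transform: training-sample ranks are
        approximately uniform on [1, 99]."""
        _, registry = medium_oracle_setup
        ranks = chart.rank_records(registry)
        assert len(ranks) > 4000
        # compare to uniform on [1, 99] at the percent scale
        emp = np.sort(ranks.values)
        uni = np.linspace(1, 99, len(emp))
        assert np.max(np.abs(emp - uni)) < 3.0
        assert np.median(emp) == pytest.approx(50.0, abs=1.0)

    def test_monotone_in_observed_value(self, chart):
        obs = np.linspace(0.5, 6.0, 40)
        ranks = [chart.percentile_rank(v, age=18.0) for v in obs]
        assert np.all(np.diff(ranks) >= 0)


class TestSerialization:
    def test_json_round_trip(self, fev1_registry, tmp_path):
        chart = fit_chart(fev1_registry, "fev1", "M", ("age",),
                          taus=[0.25, 0.5, 0.75], specs={"age": SplineSpec()})
        path = tmp_path / "chart.json"
        chart.to_json(path)
        loaded = PercentileChart.from_json(path)
        grid = {"age": np.linspace(*chart.training_range("age"), 17)}
        assert loaded.curve_values(grid) == pytest.approx(
            chart.curve_values(grid), abs=1e-12
        )
        assert loaded.metadata["n"] == chart.metadata["n"]

    def test_curves_frame_layout(self, fev1_registry):
        chart = fit_chart(fev1_registry, "fev1", "F", ("age",), taus=[0.5],
                          specs={"age": SplineSpec()})
        grid = {"age": np.linspace(*chart.training_range("age"), 10)}
        frame = chart.curves_frame(grid)
        assert list(frame.columns) == ["sex", "outcome", "tau", "age", "value"]
        assert len(frame) == 10

    def test_additive_design_full_rank(self, fev1_registry):
        frame = fev1_registry.frame.query("sex == 'M'")
        specs = {
            "age": SplineSpec().fit_knots(frame.age_years.values),
            "height": SplineSpec().fit_knots(frame.height_cm.values),
        }
        X = _build_design(
            specs, ("age", "height"),
            {"age": frame.age_years.values, "height": frame.height_cm.values},
        )
        assert np.linalg.matrix_rank(X.toarray()) == X.shape[1]
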