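"""Directed-separation tests, Fisher's C, chi-square GOF, model comparison."""

import numpy as np
import pandas as pd
import pytest

from psem.dsep_inference import test_claim as run_claim_test
from psem.dsep_inference import test_all_claims as run_all_claim_tests
from psem.causal_graph import PathSpec, SemModelSpec, add_path, basis_set
from psem.dsep_inference import (  # noqa: F401
    GofReport,
    ModelFitError,
    chi2_gof,
    compare_models,
    evaluate_model,
    fishers_c,
    fit_all_equations,
    gof_p,
)
from psem.station_io import StationTable, scale_covariates
from psem.synthetic import Truth, generate_counts, generate_covariates, GeneratorConfig

from conftest import make_station_frame


def small_truth(extra_coef: float = 0.0) -> Truth:
    """X1, X2 exogenous; chain A -> B among species; optional omitted
    direct X2 -> B effect of strength ``extra_coef``."""
    paths = [PathSpec("X1", "A", "positive"), PathSpec("A", "B", "positive")]
    coefs = {("X1", "A"): 0.5, ("A", "B"): 0.15}
    if extra_coef:
        paths.append(PathSpec("X2", "B", "positive"))
        coefs[("X2", "B")] = extra_coef
    spec = SemModelSpec(
        endogenous=frozenset({"A", "B"}),
        exogenous=frozenset({"X1", "X2"}),
        paths=tuple(paths),
        name="small",
    )
    return Truth(spec=spec, coefficients=coefs, intercepts={"A": 0.8, "B": 0.5})


def fitted_spec(truth: Truth) -> SemModelSpec:
    """The analysis model: the truth's DAG without any X2 -> B path."""
    spec = truth.spec
    if spec.has_path("X2", "B"):
        from psem.causal_graph import remove_path

        spec = remove_path(spec, "X2", "B")
    return spec


def simulate_small(truth: Truth, n: int, seed: int) -> StationTable:
    """Station-table-shaped data for the small truth: X1, X2 ride in the
    elevation and tri columns; species A, B in lynx and wolf."""
    rng = np.random.default_rng(seed)
    frame = make_station_frame(n, rng)
    frame["elevation"] = rng.normal(1100, 200, n)
    frame["tri"] = rng.normal(250, 60, n)
    table = scale_covariates(StationTable(frame))
    x1, x2 = table.column("elevation"), table.column("tri")
    a = rng.poisson(np.exp(truth.intercepts["A"] + truth.coefficients[("X1", "A")] * x1))
    eta_b = truth.intercepts["B"] + truth.coefficients[("A", "B")] * a
    if ("X2", "B") in truth.coefficients:
        eta_b = eta_b + truth.coefficients[("X2", "B")] * x2
    b = rng.poisson(np.exp(eta_b))
    df = table.data.copy()
    df["lynx"], df["wolf"] = a.astype(np.int64), b.astype(np.int64)
    return StationTable(df, covariate_scaling=table.covariate_scaling)


def rename_small(spec: SemModelSpec) -> SemModelSpec:
    """Map the small truth's abstract names onto table columns."""
    mapping = {"X1": "elevation", "X2": "tri", "A": "lynx", "B": "wolf"}
    return SemModelSpec(
        endogenous=frozenset(mapping[v] for v in spec.endogenous),
        exogenous=frozenset(mapping[v] for v in spec.exogenous),
        paths=tuple(
            PathSpec(mapping[p.cause], mapping[p.effect], p.expected_sign)
            for p in spec.paths
        ),
        name=spec.name,
    )


class TestFishersC:
    def test_all_ones_give_zero(self):
        assert fishers_c([1.0, 1.0]) == (0.0, 4)

    def test_closed_form_halves(self):
        c, df = fishers_c([0.5, 0.5])
        assert c == pytest.approx(-4 * np.log(0.5), abs=1e-12)
        assert df == 4

    def test_underflow_is_floored(self):
        c, df = fishers_c([1e-310])
        assert np.isfinite(c)
        assert c == pytest.approx(-2 * np.log(1e-300))

    def test_empty_basis_set_is_saturated(self):
        assert fishers_c([]) == (0.0, 0)

    def test_monotone_decreasing_in_each_p(self):
        base = [0.3, 0.6, 0.9]
        c0, _ = fishers_c(base)
        for i in range(3):
            bumped = list(base)
            bumped[i] = base[i] + 0.05
            assert fishers_c(bumped)[0] < c0


class TestGofP:
    def test_zero_statistic_is_one(self):
        assert gof_p(0.0, 5) == pytest.approx(1.0)

    def test_published_combined_model_probability(self):
        # C = 27.973 on 26 df sits in the bulk of the chi-square: p = 0.36
        assert gof_p(27.973, 26) == pytest.approx(0.36, abs=0.005)

    def test_published_topdown_probability_is_negligible(self):
        assert gof_p(64.787, 28) < 0.001

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            gof_p(-1.0, 4)


class TestTestClaim:
    def test_collinear_other_vertex_raises_with_claim_identity(self):
        truth = small_truth()
        table = simulate_small(truth, 200, seed=0)
        df = table.data.copy()
        df["tri"] = df["elevation"]  # X2 a pure copy of X1
        table = StationTable(df, covariate_scaling=table.covariate_scaling)
        spec = rename_small(fitted_spec(truth))
        claims = [c for c in basis_set(spec) if c.pair == ("elevation", "wolf")]
        # claim conditions on lynx's parent elevation and adds tri -> collinear
        claim = next(c for c in basis_set(spec) if "tri" in c.pair and "lynx" in c.pair)
        with pytest.raises(ModelFitError, match="tri"):
            run_claim_test(claim, table, spec)

    def test_power_against_an_omitted_path(self):
        # a real X2 -> B path of moderate strength must be flagged
        truth = small_truth(extra_coef=0.5)
        spec = rename_small(fitted_spec(truth))
        hits = 0
        n_reps = 100
        for rep in range(n_reps):
            table = simulate_small(truth, 300, seed=1000 + rep)
            claims = run_all_claim_tests(spec, table)
            claim = next(c for c in claims if c.pair == ("tri", "wolf"))
            hits += claim.p_value < 0.05
        assert hits >= 0.9 * n_reps

    def test_type_i_error_for_a_true_absence(self):
        truth = small_truth()
        spec = rename_small(fitted_spec(truth))
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            table = simulate_small(truth, 300, seed=5000 + rep)
            claims = run_all_claim_tests(spec, table)
            claim = next(c for c in claims if c.pair == ("tri", "wolf"))
            rejections += claim.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09


class TestChi2Gof:
    def saturated_spec(self):
        return SemModelSpec(
            endogenous=frozenset({"lynx", "wolf"}),
            exogenous=frozenset({"elevation", "tri", "forest", "road_density"}),
            paths=tuple(
                PathSpec(c, e)
                for e in ("lynx", "wolf")
                for c in ("elevation", "tri", "forest", "road_density")
            )
            + (PathSpec("lynx", "wolf"),),
        )

    def test_saturated_model_has_zero_chi2(self, medium_table):
        table = scale_covariates(medium_table)
        chi2, df, p = chi2_gof(self.saturated_spec(), table)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert df == 0
        assert p == pytest.approx(1.0)

    def test_removing_one_path_gives_df_one(self, medium_table):
        from psem.causal_graph import remove_path

        table = scale_covariates(medium_table)
        spec = remove_path(self.saturated_spec(), "forest", "lynx")
        _, df, _ = chi2_gof(spec, table)
        assert df == 1

    def test_calibrated_under_the_true_model(self):
        truth = small_truth()
        spec = rename_small(truth.spec)
        ok = 0
        n_reps = 40
        for rep in range(n_reps):
            table = simulate_small(truth, 500, seed=9000 + rep)
            _, _, p = chi2_gof(spec, table)
            ok += p > 0.05
        assert ok >= 0.85 * n_reps


class TestEvaluateAndCompare:
    def test_report_df_bookkeeping(self):
        truth = small_truth()
        spec = rename_small(truth.spec)
        table = simulate_small(truth, 400, seed=77)
        report = evaluate_model(spec, table)
        assert report.c_df == 2 * len(report.per_claim)
        assert report.c_p == pytest.approx(gof_p(report.fisher_c, report.c_df))
        assert len(report.per_equation) == 2

    def test_adding_a_path_drops_c_df_by_two(self):
        truth = small_truth()
        spec = rename_small(truth.spec)
        table = simulate_small(truth, 400, seed=78)
        before = evaluate_model(spec, table)
        wider = add_path(spec, PathSpec("tri", "wolf"))
        after = evaluate_model(wider, table)
        assert before.c_df - after.c_df == 2

    def test_compare_orders_by_c_p_descending(self):
        def report(name, c_p):
            return GofReport(
                name=name, fisher_c=1.0, c_df=2, c_p=c_p,
                chi2=0.0, chi2_df=0, chi2_p=1.0,
                per_claim=(), per_equation=(),
            )

        table = compare_models([report("bad", 0.001), report("good", 0.4)])
        assert list(table["Model"]) == ["good", "bad"]
        assert bool(table.loc[0, "poor_fit"]) is False
        assert bool(table.loc[1, "poor_fit"]) is True

    def test_compare_tie_break_is_stable(self):
        def report(name):
            return GofReport(
                name=name, fisher_c=1.0, c_df=2, c_p=0.5,
                chi2=0.0, chi2_df=0, chi2_p=1.0,
                per_claim=(), per_equation=(),
            )

        table = compare_models([report("first"), report("second")])
        assert list(table["Model"]) == ["first", "second"]

    def test_single_report_is_an_error(self):
        with pytest.raises(ValueError):
            compare_models([GofReport(
                name="only", fisher_c=0, c_df=0, c_p=1,
                chi2=0, chi2_df=0, chi2_p=1, per_claim=(), per_equation=(),
            )])


def test_equation_fits_carry_standardized_estimates():
    truth = small_truth()
    spec = rename_small(truth.spec)
    table = simulate_small(truth, 400, seed=3)
    fits = fit_all_equations(spec, table)
    for fit in fits:
        assert fit.std_estimates is not None
        assert fit.std_method == "latent_linear"
        assert np.all(np.sign(fit.std_estimates) == np.sign(fit.coefficients))
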