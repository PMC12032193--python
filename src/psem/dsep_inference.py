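"""Goodness of fit for piecewise SEMs: d-separation tests, Fisher's C, chi-square.

The model's global fit is judged without a joint likelihood.  Each
independence claim in the basis set is tested by regressing the claim's
response on its conditioning set plus the other vertex, taking the Wald
p-value of that extra coefficient.  Fisher's C = -2 * sum(ln p_i) combines
the claim p-values and is referred to a chi-square with 2k degrees of
freedom; a NON-significant result means the data are consistent with the
claimed absences of paths.  A complementary chi-square statistic compares
the summed equation log-likelihoods against saturated counterparts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .causal_graph import (
    IndependenceClaim,
    SemModelSpec,
    basis_set,
    require_valid,
    topological_order,
)
from .glm_core import P_FLOOR, EquationFit, fit_poisson, standardize_coefficients
from .station_io import StationTable

logger = logging.getLogger(__name__)

ALPHA = 0.05


class ModelFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# equation fitting


def design_for(
    table: StationTable, response: str, predictors: list[str], spec: SemModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Response counts and predictor matrix for one structured equation.

    Landscape covariates enter as their (scaled) column values; species
    predictors enter as raw counts — only landscape variables are centred
    and scaled before analysis.
    """
    y = table.counts(response)
    cols = [table.column(p) for p in predictors]
    X = np.column_stack(cols) if cols else np.empty((table.n, 0))
    return y, X


def fit_equation(
    spec: SemModelSpec,
    table: StationTable,
    response: str,
    extra_predictors: list[str] | None = None,
    standardize: bool = True,
) -> EquationFit:
    """Fit one endogenous vertex's Poisson regression on its parents."""
    predictors = sorted(spec.parents(response)) + list(extra_predictors or [])
    y, X = design_for(table, response, predictors, spec)
    fit = fit_poisson(y, X, predictors, response=response)
    if standardize and predictors:
        sds = np.array(
            [np.std(table.column(p), ddof=1) for p in predictors], dtype=float
        )
        std = standardize_coefficients(fit, sds, method="latent_linear")
        fit = dc_replace(fit, std_estimates=std, std_method="latent_linear")
    return fit


def fit_all_equations(
    spec: SemModelSpec, table: StationTable, standardize: bool = True
) -> list[EquationFit]:
    require_valid(spec)
    order = topological_order(spec)
    return [
        fit_equation(spec, table, v, standardize=standardize)
        for v in order
        if v in spec.endogenous
    ]


# ---------------------------------------------------------------------------
# independence claims


def test_claim(
    claim: IndependenceClaim, table: StationTable, spec: SemModelSpec
) -> IndependenceClaim:
    """Fill in a claim's p-value.

    The response is regressed on its conditioning set plus the other
    vertex; the p-value is the Wald p of the other vertex's coefficient.
    For unordered dual-endogenous claims both directions are fitted and
    the smaller p is kept.
    """
    directions = [(claim.response, claim.other)]
    if claim.both_directions:
        directions.append((claim.other, claim.response))
    best_p, best_resp = None, claim.response
    for resp, other in directions:
        predictors = sorted(claim.conditioning_set - {other}) + [other]
        y, X = design_for(table, resp, predictors, spec)
        try:
            fit = fit_poisson(y, X, predictors, response=resp)
        except Exception as exc:
            raise ModelFitError(
                f"claim ({claim.a}, {claim.b}) | {sorted(claim.conditioning_set)}: "
                f"{exc}"
            ) from exc
        p = fit.p_for(other)
        if best_p is None or p < best_p:
            best_p, best_resp = p, resp
    return dc_replace(claim, p_value=float(best_p), response=best_resp)


def test_all_claims(
    spec: SemModelSpec, table: StationTable, conserve: bool = True
) -> list[IndependenceClaim]:
    return [test_claim(c, table, spec) for c in basis_set(spec, conserve=conserve)]


def fishers_c(p_values: list[float]) -> tuple[float, int]:
    """C = -2 * sum(ln p_i) with df = 2k; p-values floored at 1e-300."""
    if len(p_values) == 0:
        logger.info("empty basis set (saturated model): C = 0, df = 0")
        return 0.0, 0
    arr = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, 1.0)
    return float(-2.0 * np.sum(np.log(arr))), 2 * len(p_values)


def gof_p(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability of a goodness-of-fit statistic."""
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(statistic, df))


# ---------------------------------------------------------------------------
# chi-square goodness of fit


def _saturated_predecessors(spec: SemModelSpec) -> dict[str, list[str]]:
    """Every topologically permissible predecessor of each endogenous vertex:
    all exogenous vertices plus all endogenous vertices earlier in the
    deterministic causal order."""
    order = topological_order(spec)
    exo = sorted(spec.exogenous)
    preds: dict[str, list[str]] = {}
    earlier: list[str] = []
    for v in order:
        if v in spec.endogenous:
            preds[v] = exo + list(earlier)
            earlier.append(v)
    return preds


def chi2_gof(
    spec: SemModelSpec,
    table: StationTable,
    fits: list[EquationFit] | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square of the model against saturated equations.

    chi2 = -2 * (sum model log-lik - sum saturated log-lik), where each
    saturated counterpart regresses the response on ALL permissible
    predecessors; df is the difference in total parameter count.
    """
    if fits is None:
        fits = fit_all_equations(spec, table, standardize=False)
    sat_preds = _saturated_predecessors(spec)
    chi2 = 0.0
    df = 0
    for fit in fits:
        full = sat_preds[fit.response]
        y, X = design_for(table, fit.response, full, spec)
        try:
            sat = fit_poisson(y, X, full, response=fit.response)
        except Exception as exc:
            raise ModelFitError(
                f"saturated fit for {fit.response} failed: {exc}"
            ) from exc
        chi2 += -2.0 * (fit.log_lik - sat.log_lik)
        df += sat.n_params - fit.n_params
    chi2 = max(chi2, 0.0)
    return chi2, df, gof_p(chi2, df)


# ---------------------------------------------------------------------------
# reports


@dataclass(frozen=True)
class GofReport:
    """Machine twin of a model-comparison row: Fisher's C and chi-square."""

    name: str
    fisher_c: float
    c_df: int
    c_p: float
    chi2: float
    chi2_df: int
    chi2_p: float
    per_claim: tuple[IndependenceClaim, ...]
    per_equation: tuple[EquationFit, ...]
    notes: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "C": self.fisher_c,
            "C_p": self.c_p,
            "C_df": self.c_df,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "chi2_df": self.chi2_df,
            "claims": [
                {
                    "a": c.a,
                    "b": c.b,
                    "conditioning_set": sorted(c.conditioning_set),
                    "response": c.response,
                    "p_value": c.p_value,
                }
                for c in self.per_claim
            ],
            "notes": list(self.notes),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_model(
    spec: SemModelSpec,
    table: StationTable,
    conserve: bool = True,
    with_chi2: bool = True,
) -> GofReport:
    """Fit all equations, test the basis set, and assemble a GofReport."""
    fits = fit_all_equations(spec, table)
    claims = test_all_claims(spec, table, conserve=conserve)
    c_stat, c_df = fishers_c([c.p_value for c in claims])
    if with_chi2:
        x2, x2_df, x2_p = chi2_gof(spec, table, fits=fits)
    else:
        x2, x2_df, x2_p = np.nan, 0, np.nan
    return GofReport(
        name=spec.name or "model",
        fisher_c=c_stat,
        c_df=c_df,
        c_p=gof_p(c_stat, c_df),
        chi2=x2,
        chi2_df=x2_df,
        chi2_p=x2_p,
        per_claim=tuple(claims),
        per_equation=tuple(fits),
    )


def compare_models(reports: list[GofReport]) -> pd.DataFrame:
    """Model-comparison table sorted by Fisher's C p descending (best first).

    Ties keep the original order; models with C p < 0.05 are flagged as
    poor fits.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = [
        {
            "Model": r.name,
            "C": r.fisher_c,
            "C_p": r.c_p,
            "C_DF": r.c_df,
            "chi2": r.chi2,
            "chi2_p": r.chi2_p,
            "chi2_DF": r.chi2_df,
            "poor_fit": bool(r.c_p < ALPHA),
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    return df.sort_values("C_p", ascending=False, kind="stable").reset_index(drop=True)
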