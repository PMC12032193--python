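"""Stepwise model optimization and the three-model study workflow.

Starting from an a-priori model, each pass (1) tests every independence
claim, (2) walks the significant claims in ascending-p order: a claim
matching a whitelisted path is tentatively added and kept only if it
lowers Fisher's C; a significant species-species claim with no whitelist
match becomes a correlated error (an acknowledged association without a
causal path, which drops the pair from the basis set); anything else is
rejected; then (3) hypothesized paths that are both non-significant and
fitted with the wrong sign are pruned.  Passes repeat until nothing
changes.  Additions strictly lower C and the whitelist is finite, so the
loop terminates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import causal_graph as cg
from .causal_graph import PathSpec, SemModelSpec
from .dsep_inference import (
    ALPHA,
    GofReport,
    evaluate_model,
    fishers_c,
    test_all_claims,
)
from .glm_core import EquationFit, fits_to_frame
from .station_io import StationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraceStep:
    action: str  # add_path | add_correlated_error | remove_path | reject_candidate
    item: str
    p_value: float | None
    fisher_c_before: float | None
    fisher_c_after: float | None
    reason: str


@dataclass(frozen=True)
class OptimizationTrace:
    initial_spec: SemModelSpec
    final_spec: SemModelSpec
    steps: tuple[TraceStep, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "initial": cg.spec_to_dict(self.initial_spec),
            "final": cg.spec_to_dict(self.final_spec),
            "steps": [asdict(s) for s in self.steps],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def replay(self) -> SemModelSpec:
        """Re-apply the recorded actions to the initial spec."""
        spec = self.initial_spec
        for step in self.steps:
            if step.action == "add_path":
                cause, effect = step.item.split("->")
                w = next(
                    (p for p in spec.whitelist if p.cause == cause and p.effect == effect),
                    PathSpec(cause, effect, hypothesized=False),
                )
                spec = cg.add_path(
                    spec,
                    PathSpec(cause, effect, w.expected_sign, hypothesized=False, note=w.note),
                )
            elif step.action == "remove_path":
                cause, effect = step.item.split("->")
                spec = cg.remove_path(spec, cause, effect)
            elif step.action == "add_correlated_error":
                a, b = step.item.split("~~")
                spec = cg.add_correlated_error(spec, a, b)
        return spec


def _whitelist_match(spec: SemModelSpec, pair: tuple[str, str]) -> PathSpec | None:
    for w in spec.whitelist:
        if tuple(sorted((w.cause, w.effect))) == pair:
            return w
    return None


def _current_c(spec: SemModelSpec, table: StationTable, conserve: bool) -> float:
    claims = test_all_claims(spec, table, conserve=conserve)
    c, _ = fishers_c([c.p_value for c in claims])
    return c


def optimize(
    spec: SemModelSpec,
    table: StationTable,
    alpha: float = ALPHA,
    conserve: bool = True,
    max_passes: int = 20,
) -> tuple[SemModelSpec, OptimizationTrace]:
    """Run the stepwise optimization protocol.

    Returns the final spec and a full trace.  Candidate claims are
    processed in ascending p-value (lexicographic pair ties) for
    reproducibility.  Only hypothesized paths are eligible for
    sign-mismatch pruning; paths added during the run are never pruned,
    and a pruned path never re-enters.
    """
    cg.require_valid(spec)
    if not table.is_scaled:
        raise ValueError("table must be scaled before optimization")
    initial = spec
    steps: list[TraceStep] = []
    removed: set[tuple[str, str]] = set()
    rejected: set[tuple[str, str]] = set()

    for _ in range(max_passes):
        changed = False
        claims = test_all_claims(spec, table, conserve=conserve)
        c_before, _ = fishers_c([c.p_value for c in claims])
        significant = sorted(
            (c for c in claims if c.p_value < alpha),
            key=lambda c: (c.p_value, c.pair),
        )
        for claim in significant:
            if claim.pair in rejected:
                continue
            if cg_pair_resolved(spec, claim.pair):
                continue
            wl = _whitelist_match(spec, claim.pair)
            item = f"{claim.pair[0]}~~{claim.pair[1]}"
            if wl is not None:
                if (wl.cause, wl.effect) in removed:
                    continue
                candidate = cg.add_path(
                    spec,
                    PathSpec(wl.cause, wl.effect, wl.expected_sign,
                             hypothesized=False, note=wl.note),
                )
                c_after = _current_c(candidate, table, conserve)
                if c_after < c_before:
                    spec = candidate
                    steps.append(TraceStep(
                        "add_path", f"{wl.cause}->{wl.effect}", claim.p_value,
                        c_before, c_after,
                        "significant claim matching whitelist; Fisher's C lowered",
                    ))
                    c_before = c_after
                    changed = True
                else:
                    steps.append(TraceStep(
                        "reject_candidate", f"{wl.cause}->{wl.effect}",
                        claim.p_value, c_before, c_after,
                        "whitelisted but did not lower Fisher's C",
                    ))
                    rejected.add(claim.pair)
            elif claim.a in spec.endogenous and claim.b in spec.endogenous:
                spec = cg.add_correlated_error(spec, *claim.pair)
                c_after = _current_c(spec, table, conserve)
                steps.append(TraceStep(
                    "add_correlated_error", item, claim.p_value,
                    c_before, c_after,
                    "significant species-species claim outside the whitelist",
                ))
                c_before = c_after
                changed = True
            else:
                steps.append(TraceStep(
                    "reject_candidate", item, claim.p_value, c_before, None,
                    "significant claim outside the model hypothesis",
                ))
                rejected.add(claim.pair)

        # prune hypothesized paths: non-significant AND sign-mismatched
        fits = {f.response: f for f in
                _fit_cached(spec, table)}
        for path in list(spec.paths):
            if not path.hypothesized or path.expected_sign == "none":
                continue
            fit = fits[path.effect]
            p = fit.p_for(path.cause)
            b = fit.coef_for(path.cause)
            fitted_sign = "positive" if b > 0 else "negative"
            if p >= alpha and fitted_sign != path.expected_sign:
                spec = cg.remove_path(spec, path.cause, path.effect)
                removed.add((path.cause, path.effect))
                steps.append(TraceStep(
                    "remove_path", f"{path.cause}->{path.effect}", p,
                    None, None,
                    f"non-significant (p={p:.3f}) with fitted sign "
                    f"{fitted_sign} contradicting expected {path.expected_sign}",
                ))
                changed = True
                fits = {f.response: f for f in _fit_cached(spec, table)}
        if not changed:
            break

    return spec, OptimizationTrace(initial_spec=initial, final_spec=spec,
                                   steps=tuple(steps))


def _path_wald_p(spec: SemModelSpec, table: StationTable, path: PathSpec) -> float:
    """Wald p of one path's coefficient within its own model's equation."""
    from .dsep_inference import fit_equation

    fit = fit_equation(spec, table, path.effect, standardize=False)
    return fit.p_for(path.cause)


def cg_pair_resolved(spec: SemModelSpec, pair: tuple[str, str]) -> bool:
    """A pair already adjacent or under a correlated error needs no action."""
    a, b = pair
    if spec.adjacent(a, b):
        return True
    return pair in {tuple(sorted(p)) for p in spec.correlated_errors}


def _fit_cached(spec: SemModelSpec, table: StationTable) -> list[EquationFit]:
    from .dsep_inference import fit_all_equations

    return fit_all_equations(spec, table, standardize=False)


def combine(
    opt_a: SemModelSpec,
    opt_b: SemModelSpec,
    table: StationTable | None = None,
    name: str = "combined",
) -> SemModelSpec:
    """Union of two optimized models' retained paths and correlated errors.

    Both specs must cover the same vertex set; duplicate paths collapse;
    a shared path with conflicting expected signs is an error.  When the
    two models retained opposite directions over the same pair (e.g.
    predator->prey in one, prey->predator in the other) the union would be
    cyclic; with a ``table`` the direction with the smaller Wald p-value
    in its source model is kept, otherwise the conflict is an error.
    """
    if opt_a.vertices != opt_b.vertices or opt_a.endogenous != opt_b.endogenous:
        raise cg.SpecError("specs cover different vertex sets")
    paths: dict[tuple[str, str], PathSpec] = {}
    sources: dict[tuple[str, str], SemModelSpec] = {}
    for spec_src, spec_paths in ((opt_a, opt_a.paths), (opt_b, opt_b.paths)):
        for p in spec_paths:
            key = (p.cause, p.effect)
            rev = (p.effect, p.cause)
            if key in paths:
                if paths[key].expected_sign != p.expected_sign:
                    raise cg.SpecError(
                        f"sign conflict on shared path {p.cause}->{p.effect}"
                    )
                continue
            if rev in paths:
                if table is None:
                    raise cg.SpecError(
                        f"direction conflict on pair ({p.effect}, {p.cause}); "
                        "pass a table to resolve by Wald support"
                    )
                p_new = _path_wald_p(spec_src, table, p)
                p_old = _path_wald_p(sources[rev], table, paths[rev])
                if p_new < p_old:
                    del paths[rev], sources[rev]
                else:
                    continue
            paths[key] = p
            sources[key] = spec_src
    ces = sorted({tuple(sorted(p)) for p in
                  opt_a.correlated_errors + opt_b.correlated_errors})
    # drop correlated errors made adjacent by the union, and whitelist dups
    path_pairs = {tuple(sorted(k)) for k in paths}
    ces = [p for p in ces if p not in path_pairs]
    wl = {(w.cause, w.effect): w for w in opt_a.whitelist + opt_b.whitelist
          if (w.cause, w.effect) not in paths}
    spec = SemModelSpec(
        endogenous=opt_a.endogenous,
        exogenous=opt_a.exogenous,
        paths=tuple(paths.values()),
        correlated_errors=tuple(ces),
        whitelist=tuple(wl.values()),
        name=name,
    )
    cg.require_valid(spec)
    return spec


@dataclass(frozen=True)
class StudyResult:
    reports: tuple[GofReport, ...]
    traces: tuple[OptimizationTrace, ...]
    comparison: pd.DataFrame
    coefficients: pd.DataFrame  # combined-model tidy coefficient table
    combined_spec: SemModelSpec


def run_study(
    table: StationTable,
    topdown_spec: SemModelSpec,
    bottomup_spec: SemModelSpec,
    alpha: float = ALPHA,
    conserve: bool = True,
) -> StudyResult:
    """End-to-end workflow: optimize both a-priori models, combine, evaluate.

    Deterministic given the table and specs.  Returns goodness-of-fit
    reports for the optimized top-down, bottom-up and combined models, the
    optimization traces, a model-comparison table and the combined model's
    tidy coefficient table.
    """
    if table.n == 0:
        raise ValueError("empty table")
    if not table.is_scaled:
        raise ValueError("table must be scaled")
    from dataclasses import replace as dc_replace

    opt_td, trace_td = optimize(topdown_spec, table, alpha=alpha, conserve=conserve)
    opt_bu, trace_bu = optimize(bottomup_spec, table, alpha=alpha, conserve=conserve)
    opt_td = dc_replace(opt_td, name="topdown_optimized")
    opt_bu = dc_replace(opt_bu, name="bottomup_optimized")
    combined = combine(opt_td, opt_bu, table=table)
    reports = tuple(
        evaluate_model(spec, table, conserve=conserve)
        for spec in (combined, opt_td, opt_bu)
    )
    from .dsep_inference import compare_models

    comparison = compare_models(list(reports))
    coefficients = fits_to_frame(list(reports[0].per_equation))
    return StudyResult(
        reports=reports,
        traces=(trace_td, trace_bu),
        comparison=comparison,
        coefficients=coefficients,
        combined_spec=combined,
    )
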