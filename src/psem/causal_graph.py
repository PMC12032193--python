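"""Causal DAGs for piecewise SEM: paths, correlated errors, basis sets.

A model is a directed acyclic graph whose vertices are either endogenous
(species counts, each modelled by a Poisson log-link regression) or
exogenous (landscape covariates, never a response).  Its testable content
is the basis set: for every eligible non-adjacent pair the graph claims
conditional independence given the union of the two vertices' parents.
Correlated-error pairs acknowledge an association without a causal path
and are excluded from the basis set, as are exogenous-exogenous pairs
(their covariances are unconstrained by the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import yaml


class SpecError(ValueError):
    """A model specification violates its invariants."""


Sign = str  # "positive" | "negative" | "none"
_SIGNS = ("positive", "negative", "none")


@dataclass(frozen=True)
class PathSpec:
    """One directed causal path with its expected sign.

    ``hypothesized`` is True for paths in the a-priori model and False for
    paths added during optimization; ``note`` carries the biological
    rationale and has no computational role.
    """

    cause: str
    effect: str
    expected_sign: Sign = "none"
    hypothesized: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.cause == self.effect:
            raise SpecError(f"self-loop on {self.cause!r}")
        if self.expected_sign not in _SIGNS:
            raise SpecError(f"unknown sign {self.expected_sign!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.cause, self.effect)))


@dataclass(frozen=True)
class IndependenceClaim:
    """One d-separation claim: a and b independent given their parents.

    ``response`` names which endpoint is regressed; for unordered
    dual-endogenous pairs under the conserve rule both directions are
    fitted and the smaller p kept, and ``response`` records the direction
    that produced it.
    """

    a: str
    b: str
    conditioning_set: frozenset[str]
    response: str
    p_value: float | None = None
    both_directions: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.a, self.b)))

    @property
    def other(self) -> str:
        return self.b if self.response == self.a else self.a


@dataclass(frozen=True)
class SemModelSpec:
    endogenous: frozenset[str]
    exogenous: frozenset[str]
    paths: tuple[PathSpec, ...]
    correlated_errors: tuple[tuple[str, str], ...] = ()
    whitelist: tuple[PathSpec, ...] = ()
    name: str = ""

    @property
    def vertices(self) -> frozenset[str]:
        return self.endogenous | self.exogenous

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.vertices))
        g.add_edges_from((p.cause, p.effect) for p in self.paths)
        return g

    def parents(self, v: str) -> frozenset[str]:
        return frozenset(p.cause for p in self.paths if p.effect == v)

    def has_path(self, cause: str, effect: str) -> bool:
        return any(p.cause == cause and p.effect == effect for p in self.paths)

    def adjacent(self, a: str, b: str) -> bool:
        return self.has_path(a, b) or self.has_path(b, a)

    def path_between(self, cause: str, effect: str) -> PathSpec | None:
        for p in self.paths:
            if p.cause == cause and p.effect == effect:
                return p
        return None


def validate_spec(spec: SemModelSpec) -> list[str]:
    """Collect every invariant violation; empty list means the spec is ok."""
    issues: list[str] = []
    if spec.endogenous & spec.exogenous:
        issues.append(
            "vertices both endogenous and exogenous: "
            f"{sorted(spec.endogenous & spec.exogenous)}"
        )
    for p in spec.paths:
        if p.cause not in spec.vertices or p.effect not in spec.vertices:
            issues.append(f"path {p.cause}->{p.effect} uses unknown vertex")
        elif p.effect in spec.exogenous:
            issues.append(f"path {p.cause}->{p.effect}: effect is exogenous")
    seen: set[tuple[str, str]] = set()
    for p in spec.paths:
        key = (p.cause, p.effect)
        if key in seen:
            issues.append(f"duplicate path {p.cause}->{p.effect}")
        seen.add(key)
    g = spec.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        issues.append(
            "cycle: " + " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        )
    for a, b in spec.correlated_errors:
        if a not in spec.vertices or b not in spec.vertices:
            issues.append(f"correlated error ({a}, {b}) uses unknown vertex")
        elif spec.adjacent(a, b):
            issues.append(f"correlated error ({a}, {b}) on adjacent pair")
    ce_pairs = [tuple(sorted(p)) for p in spec.correlated_errors]
    if len(ce_pairs) != len(set(ce_pairs)):
        issues.append("duplicate correlated-error pair")
    for w in spec.whitelist:
        if spec.has_path(w.cause, w.effect):
            issues.append(f"whitelist entry {w.cause}->{w.effect} duplicates a path")
    return issues


def require_valid(spec: SemModelSpec) -> None:
    issues = validate_spec(spec)
    if issues:
        raise SpecError("; ".join(issues))


def topological_order(spec: SemModelSpec) -> list[str]:
    """Deterministic causal order: exogenous first, lexicographic ties."""
    require_valid(spec)
    g = spec.graph()
    # exogenous vertices sort ahead of endogenous, then by name
    key = lambda v: (v in spec.endogenous, v)
    order = list(nx.lexicographical_topological_sort(g, key=key))
    exo = [v for v in order if v in spec.exogenous]
    endo = [v for v in order if v in spec.endogenous]
    return exo + endo


def basis_set(spec: SemModelSpec, conserve: bool = True) -> list[IndependenceClaim]:
    """Enumerate the model's independence claims.

    One claim per unordered non-adjacent pair with at least one endogenous
    member, excluding exogenous-exogenous pairs and correlated-error
    pairs.  The conditioning set is the union of both vertices' parents.
    Response choice: the single endogenous member if only one is; the
    descendant if one endogenous member is an ancestor of the other; with
    ``conserve`` both directions otherwise (the test is not
    direction-symmetric for count responses, and keeping the smaller p is
    the cautious choice against accepting a wrong model).  Claims are
    sorted by pair name for byte-stable output.
    """
    require_valid(spec)
    g = spec.graph()
    ancestors = {v: nx.ancestors(g, v) for v in spec.vertices}
    excluded = {tuple(sorted(p)) for p in spec.correlated_errors}
    claims: list[IndependenceClaim] = []
    verts = sorted(spec.vertices)
    for i, a in enumerate(verts):
        for b in verts[i + 1 :]:
            if a in spec.exogenous and b in spec.exogenous:
                continue
            if spec.adjacent(a, b):
                continue
            if (a, b) in excluded:
                continue
            cond = frozenset((spec.parents(a) | spec.parents(b)) - {a, b})
            a_endo, b_endo = a in spec.endogenous, b in spec.endogenous
            if a_endo and not b_endo:
                response, both = a, False
            elif b_endo and not a_endo:
                response, both = b, False
            elif a in ancestors[b]:
                response, both = b, False
            elif b in ancestors[a]:
                response, both = a, False
            else:
                response, both = min(a, b), conserve
            claims.append(
                IndependenceClaim(
                    a=a, b=b, conditioning_set=cond, response=response,
                    both_directions=both,
                )
            )
    return claims


def add_path(spec: SemModelSpec, path: PathSpec) -> SemModelSpec:
    """Return a new spec with ``path`` added; the input is unchanged."""
    new = replace(
        spec,
        paths=spec.paths + (path,),
        whitelist=tuple(
            w for w in spec.whitelist
            if not (w.cause == path.cause and w.effect == path.effect)
        ),
    )
    require_valid(new)
    return new


def remove_path(spec: SemModelSpec, cause: str, effect: str) -> SemModelSpec:
    if not spec.has_path(cause, effect):
        raise SpecError(f"no path {cause}->{effect} to remove")
    new = replace(
        spec,
        paths=tuple(
            p for p in spec.paths if not (p.cause == cause and p.effect == effect)
        ),
    )
    require_valid(new)
    return new


def add_correlated_error(spec: SemModelSpec, a: str, b: str) -> SemModelSpec:
    pair = tuple(sorted((a, b)))
    if pair in {tuple(sorted(p)) for p in spec.correlated_errors}:
        raise SpecError(f"correlated error {pair} already present")
    new = replace(spec, correlated_errors=spec.correlated_errors + (pair,))
    require_valid(new)
    return new


# ---------------------------------------------------------------------------
# serialization


def spec_to_dict(spec: SemModelSpec) -> dict:
    def path_dict(p: PathSpec) -> dict:
        return {
            "cause": p.cause,
            "effect": p.effect,
            "sign": p.expected_sign,
            "hypothesized": p.hypothesized,
            "note": p.note,
        }

    return {
        "name": spec.name,
        "endogenous": sorted(spec.endogenous),
        "exogenous": sorted(spec.exogenous),
        "paths": [path_dict(p) for p in spec.paths],
        "correlated_errors": [list(p) for p in spec.correlated_errors],
        "whitelist": [path_dict(p) for p in spec.whitelist],
    }


def spec_from_dict(d: dict) -> SemModelSpec:
    def to_path(item: dict) -> PathSpec:
        return PathSpec(
            cause=item["cause"],
            effect=item["effect"],
            expected_sign=item.get("sign", "none"),
            hypothesized=bool(item.get("hypothesized", True)),
            note=item.get("note", ""),
        )

    spec = SemModelSpec(
        endogenous=frozenset(d["endogenous"]),
        exogenous=frozenset(d.get("exogenous", [])),
        paths=tuple(to_path(p) for p in d.get("paths", [])),
        correlated_errors=tuple(
            tuple(sorted(p)) for p in d.get("correlated_errors", [])
        ),
        whitelist=tuple(to_path(p) for p in d.get("whitelist", [])),
        name=d.get("name", ""),
    )
    require_valid(spec)
    return spec


def read_spec(path) -> SemModelSpec:
    """Load a model spec from a YAML (or JSON) file."""
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def write_spec(spec: SemModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def to_dot(spec: SemModelSpec) -> str:
    """GraphViz DOT: solid edges for positive paths, dashed for negative."""
    lines = [f'digraph "{spec.name or "model"}" {{']
    for v in sorted(spec.exogenous):
        lines.append(f'  "{v}" [shape=box];')
    for v in sorted(spec.endogenous):
        lines.append(f'  "{v}" [shape=ellipse];')
    for p in spec.paths:
        style = "dashed" if p.expected_sign == "negative" else "solid"
        lines.append(f'  "{p.cause}" -> "{p.effect}" [style={style}];')
    for a, b in spec.correlated_errors:
        lines.append(f'  "{a}" -> "{b}" [dir=both, style=dotted];')
    lines.append("}")
    return "\n".join(lines)
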