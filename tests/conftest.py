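"""Shared fixtures: tiny station tables, small DAGs, and a random-DAG
generator used by the basis-set oracle tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from psem.causal_graph import PathSpec, SemModelSpec
from psem.station_io import COVARIATES, SPECIES, StationTable


def make_station_frame(n: int, rng: np.random.Generator | None = None) -> pd.DataFrame:
    rng = rng or np.random.default_rng(0)
    data = {
        "station_id": [f"S{i}" for i in range(n)],
        "season": ["winter" if i % 2 == 0 else "autumn" for i in range(n)],
        "elevation": rng.uniform(663, 1617, n),
        "tri": rng.uniform(84, 494, n),
        "forest": rng.uniform(0.1, 1.0, n),
        "road_density": rng.uniform(0.21, 0.34, n),
    }
    for sp in SPECIES:
        data[sp] = rng.poisson(3.0, n)
    return pd.DataFrame(data)


@pytest.fixture
def toy_frame() -> pd.DataFrame:
    return make_station_frame(3)


@pytest.fixture
def toy_table(toy_frame) -> StationTable:
    return StationTable(toy_frame)


@pytest.fixture
def medium_table() -> StationTable:
    return StationTable(make_station_frame(200, np.random.default_rng(7)))


@pytest.fixture
def chain_spec() -> SemModelSpec:
    """X (exogenous) -> A -> B: one claim (X, B | A)."""
    return SemModelSpec(
        endogenous=frozenset({"A", "B"}),
        exogenous=frozenset({"X"}),
        paths=(PathSpec("X", "A", "positive"), PathSpec("A", "B", "positive")),
        name="chain",
    )


def random_dag(
    rng: np.random.Generator, max_vertices: int = 12, edge_prob: float = 0.4
) -> SemModelSpec:
    """Random spec: exogenous block first, edges only forward in a random
    order, so the result is acyclic by construction."""
    n = int(rng.integers(3, max_vertices + 1))
    n_exo = int(rng.integers(0, max(1, n // 2) + 1))
    names = [f"v{i}" for i in range(n)]
    exo, endo = names[:n_exo], names[n_exo:]
    if not endo:  # need at least one endogenous vertex
        endo, exo = names[-1:], names[:-1]
    order = exo + list(rng.permutation(endo))
    paths = []
    for i, cause in enumerate(order):
        for effect in order[i + 1 :]:
            if effect in exo:
                continue
            if rng.random() < edge_prob:
                paths.append(PathSpec(cause, effect))
    spec = SemModelSpec(
        endogenous=frozenset(endo), exogenous=frozenset(exo), paths=tuple(paths)
    )
    # sprinkle correlated errors on some non-adjacent endogenous pairs
    candidates = [
        (a, b)
        for i, a in enumerate(sorted(endo))
        for b in sorted(endo)[i + 1 :]
        if not spec.adjacent(a, b)
    ]
    if candidates and rng.random() < 0.5:
        k = int(rng.integers(1, min(3, len(candidates)) + 1))
        picks = [candidates[j] for j in rng.choice(len(candidates), k, replace=False)]
        spec = SemModelSpec(
            endogenous=spec.endogenous,
            exogenous=spec.exogenous,
            paths=spec.paths,
            correlated_errors=tuple(tuple(sorted(p)) for p in picks),
        )
    return spec


def brute_force_basis_pairs(spec: SemModelSpec) -> dict[tuple[str, str], set[str]]:
    """Independent enumeration of claim pairs and conditioning sets from the
    raw edge list: all unordered vertex pairs, drop adjacent pairs,
    exogenous-exogenous pairs and correlated-error pairs; condition on the
    union of parents."""
    edges = {(p.cause, p.effect) for p in spec.paths}
    parents = {v: {c for c, e in edges if e == v} for v in spec.vertices}
    ce = {tuple(sorted(p)) for p in spec.correlated_errors}
    out: dict[tuple[str, str], set[str]] = {}
    verts = sorted(spec.vertices)
    for i, a in enumerate(verts):
        for b in verts[i + 1 :]:
            if (a, b) in edges or (b, a) in edges:
                continue
            if a in spec.exogenous and b in spec.exogenous:
                continue
            if (a, b) in ce:
                continue
            out[(a, b)] = (parents[a] | parents[b]) - {a, b}
    return out
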