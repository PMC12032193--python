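"""Packaged model fixtures: the hypothesized top-down and bottom-up DAGs
(reconstructed from the study's narrative) and the final combined model
with its published path coefficients."""

from __future__ import annotations

from importlib import resources

from ..causal_graph import SemModelSpec, read_spec


def _load(name: str) -> SemModelSpec:
    ref = resources.files(__package__) / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return read_spec(path)


def topdown_hypothesized() -> SemModelSpec:
    return _load("topdown_hypothesized")


def bottomup_hypothesized() -> SemModelSpec:
    return _load("bottomup_hypothesized")


def combined_final() -> SemModelSpec:
    return _load("combined_final")


def table3_coefficients() -> dict[tuple[str, str], float]:
    """Published link-scale path estimates for the combined model."""
    return {
        ("tri", "lynx"): -0.174,
        ("hare", "lynx"): 0.098,
        ("forest", "lynx"): -0.035,
        ("road_density", "wolf"): -0.616,
        ("elevation", "wolf"): 0.202,
        ("tri", "wolf"): -0.145,
        ("wild_boar", "wolf"): 0.010,
        ("forest", "wolf"): 0.071,
        ("roe_deer", "wolf"): 0.009,
        ("elevation", "fox"): -0.380,
        ("wolf", "fox"): 0.056,
        ("lynx", "fox"): 0.027,
        ("forest", "fox"): 0.072,
        ("hare", "fox"): 0.022,
        ("elevation", "wildcat"): -0.467,
        ("forest", "wildcat"): 0.223,
        ("lynx", "wildcat"): 0.060,
        ("tri", "hare"): -0.533,
        ("elevation", "hare"): 0.460,
        ("forest", "hare"): -0.099,
        ("road_density", "red_deer"): -0.528,
        ("forest", "red_deer"): 0.163,
        ("tri", "red_deer"): -0.112,
        ("elevation", "red_deer"): -0.021,
        ("elevation", "roe_deer"): -0.486,
        ("tri", "roe_deer"): -0.338,
        ("forest", "roe_deer"): -0.119,
        ("tri", "wild_boar"): -0.314,
        ("road_density", "wild_boar"): -0.264,
        ("elevation", "wild_boar"): -0.251,
        ("forest", "wild_boar"): -0.159,
    }
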