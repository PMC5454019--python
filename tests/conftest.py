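"""Shared fixtures: synthetic scenes and their analyses.

Scene generation is deterministic, so session-scoped fixtures are safe
and keep the suite fast.  Scenario analyses use Otsu thresholding (see
docs/methods.md: the moments method over-thresholds foregrounds with
large within-class variance, truncating the intensity tails that the
correlation checks depend on).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import fretcoloc as fc

SCENARIO_THRESHOLD = "otsu"


def respec(spec: fc.SceneSpec, **overrides) -> fc.SceneSpec:
    d = dataclasses.asdict(spec)
    d.update(overrides)
    return fc.SceneSpec(**d)


@pytest.fixture(scope="session")
def scenarios() -> dict[str, fc.SceneSpec]:
    return fc.scenario_library()


@pytest.fixture(scope="session")
def true_factors() -> fc.BleedthroughFactors:
    # the generator's ground-truth bleed-through fractions
    return fc.BleedthroughFactors(d=0.15, a=0.05)


@pytest.fixture(scope="session")
def distinct_scene(scenarios):
    return fc.generate_scene(scenarios["distinct_localization"])


@pytest.fixture(scope="session")
def overexposed_scene(scenarios):
    return fc.generate_scene(scenarios["overexposed"])


@pytest.fixture(scope="session")
def interaction_scene(scenarios):
    return fc.generate_scene(scenarios["true_interaction"])


@pytest.fixture(scope="session")
def donor_only_scene(scenarios):
    return fc.generate_scene(scenarios["donor_only"])


@pytest.fixture(scope="session")
def acceptor_only_scene(scenarios):
    return fc.generate_scene(scenarios["acceptor_only"])


@pytest.fixture(scope="session")
def distinct_analysis(distinct_scene, true_factors):
    stack, _ = distinct_scene
    return fc.analyze_triple(stack, true_factors, threshold_method=SCENARIO_THRESHOLD)


@pytest.fixture(scope="session")
def overexposed_analysis(overexposed_scene, true_factors):
    stack, _ = overexposed_scene
    return fc.analyze_triple(stack, true_factors, threshold_method=SCENARIO_THRESHOLD)


@pytest.fixture(scope="session")
def interaction_analysis(interaction_scene, true_factors):
    stack, _ = interaction_scene
    return fc.analyze_triple(stack, true_factors, threshold_method=SCENARIO_THRESHOLD)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def small_scene(**overrides) -> tuple[fc.TripleStack, fc.GroundTruth]:
    """A quick 160x160 scene for unit tests; overrides forwarded to SceneSpec."""
    defaults = dict(shape=(160, 160), n_objects=8, radius_range=(5.0, 8.0), seed=7)
    defaults.update(overrides)
    return fc.generate_scene(fc.SceneSpec(**defaults))
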