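"""Shared synthetic fixtures. Everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from syntopo.atlas import RegionNode, RegionOntology
from syntopo.synth import (
    ClassMixture,
    IntensityModel,
    make_toy_atlas,
    random_mixtures,
    render_if_section,
)


@pytest.fixture(scope="session")
def toy_ontology() -> RegionOntology:
    """Three-level toy tree: root(1) -> {ctx(2), sub(3)}; ctx -> {l23(4), l5(5)};
    sub -> {th(6)}."""
    return RegionOntology(
        [
            RegionNode(1, "root", "whole brain", None),
            RegionNode(2, "CTX", "cortex", 1),
            RegionNode(3, "SUB", "subcortex", 1),
            RegionNode(4, "L23", "cortex layer 2/3", 2),
            RegionNode(5, "L5", "cortex layer 5", 2),
            RegionNode(6, "TH", "thalamus", 3),
        ]
    )


@pytest.fixture(scope="session")
def small_plate():
    plate, ontology = make_toy_atlas(6, (192, 192), seed=3)
    return plate, ontology


@pytest.fixture(scope="session")
def small_section(small_plate):
    plate, ontology = small_plate
    mixtures = random_mixtures(range(1, 7), seed=4)
    section, truth = render_if_section(plate, mixtures, 40, seed=5)
    return plate, ontology, mixtures, section, truth


@pytest.fixture(scope="session")
def default_model() -> IntensityModel:
    return IntensityModel()
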