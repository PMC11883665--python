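"""Shared fixtures: small hand-built models and seeded synthetic inputs."""

import numpy as np
import pytest

from slicefit.structures import Atom, Chain, PredictedModel, Residue, ScoreType
from slicefit.synthetic import (ClassifierFixtureSpec, PlantedModelSpec,
                                make_classifier_fixture, make_planted_model)


def build_model(confidences, score_type=ScoreType.PLDDT, chain_id="A",
                start=1, spacing=3.8, model_id="toy"):
    """Linear chain of residues along x, one CA + one CB atom each."""
    residues = []
    for i, conf in enumerate(confidences):
        ca = np.array([start + i * spacing, 0.0, 0.0], dtype=float)
        atoms = [Atom("CA", "C", ca, conf),
                 Atom("CB", "C", ca + np.array([0.0, 1.5, 0.0]), conf)]
        residues.append(Residue(start + i, "", "ALA", atoms, float(conf)))
    return PredictedModel(model_id, [Chain(chain_id, residues)], score_type)


@pytest.fixture
def toy_model():
    return build_model([70.0, 85.0, 90.0])


@pytest.fixture(scope="session")
def planted_two_domain():
    """Default 2x60-residue planted model with labels and block PAE."""
    return make_planted_model(PlantedModelSpec(seed=1))


@pytest.fixture(scope="session")
def planted_three_domain():
    return make_planted_model(PlantedModelSpec(
        n_domains=3, residues_per_domain=(60, 60, 60), seed=2))


@pytest.fixture(scope="session")
def classifier_fixture():
    """Default synthetic training set: 2000 rows, 20 map groups, seed 1."""
    return make_classifier_fixture(ClassifierFixtureSpec(seed=1))
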