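"""Shared fixtures: a desk-scale head model with its forward machinery.

The session-scoped model uses a 4 mm mesh (~10k tetrahedra), small enough
that every stage of the pipeline runs in seconds while keeping the full
62-contact electrode complement and the 28-pair protocol.
"""

import numpy as np
import pytest

from seegeit.forward import compute_jacobian, solve_forward
from seegeit.geometry import build_brain_mesh, default_layout, place_electrodes
from seegeit.protocol import make_injection_protocol


@pytest.fixture(scope="session")
def model4():
    model = build_brain_mesh(semi_axes=(45.0, 30.0, 25.0), edge_length=4.0)
    return place_electrodes(model, default_layout(3))


@pytest.fixture(scope="session")
def protocol28(model4):
    return make_injection_protocol(model4, n_pairs=28, seed=0)


@pytest.fixture(scope="session")
def forward_sol(model4, protocol28):
    return solve_forward(model4, protocol28)


@pytest.fixture(scope="session")
def jacobian(model4, protocol28, forward_sol):
    return compute_jacobian(model4, protocol28, forward_sol)


@pytest.fixture(scope="session")
def study4():
    """Small end-to-end study (4 mm mesh, reduced-rate signals)."""
    from seegeit.pipeline import Study, StudyDesign

    return Study(StudyDesign(edge_length=4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
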