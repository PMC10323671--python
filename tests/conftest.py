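"""Shared fixtures: small synthetic knees meshed coarsely for speed.

A pitch of 1.6 mm keeps per-knee generation + measurement under a second
while staying well inside the generator's resolution limit (pitch <=
groove_width / 4).
"""

import numpy as np
import pytest

from trochlemetry import SynthParams, generate, measure_mesh

FAST_PITCH = 1.6


@pytest.fixture(scope="session")
def knee23():
    """Canonical left knee at the control angle (23 deg), noise-free."""
    return generate(SynthParams(theta_deg=23.0, mesh_pitch_mm=FAST_PITCH,
                                seed=11))


@pytest.fixture(scope="session")
def knee23_right():
    """Exact mirror of knee23's parameters."""
    return generate(SynthParams(theta_deg=23.0, side="right",
                                mesh_pitch_mm=FAST_PITCH, seed=11))


@pytest.fixture(scope="session")
def knee50():
    """Dysplastic left knee (50 deg)."""
    return generate(SynthParams(theta_deg=50.0, mesh_pitch_mm=FAST_PITCH,
                                seed=12))


@pytest.fixture(scope="session")
def measured23(knee23):
    mesh, _ = knee23
    return measure_mesh(mesh)


@pytest.fixture(scope="session")
def measured50(knee50):
    mesh, _ = knee50
    return measure_mesh(mesh)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
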