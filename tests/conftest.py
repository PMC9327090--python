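"""Shared fixtures: a short phantom session and its level-0 trunk mesh.

The phantom defaults are the study conditions (3 min quiet breathing);
tests use a shortened quiet window purely for runtime, which leaves every
measured property unchanged (the waveform, geometry, amplitudes and noise
model are the defaults).
"""

import numpy as np
import pytest

from thoraco import (PhantomConfig, default_layout, generate_phantom,
                     mesh_from_frame)

SHORT_QUIET_S = 20.0


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def short_session():
    cfg = PhantomConfig(quiet_duration_s=SHORT_QUIET_S, seed=1)
    trajs, truth = generate_phantom(cfg)
    return cfg, trajs, truth


@pytest.fixture(scope="session")
def clean_session():
    cfg = PhantomConfig(quiet_duration_s=SHORT_QUIET_S, seed=1, jitter_sd_mm=0.0)
    trajs, truth = generate_phantom(cfg)
    return cfg, trajs, truth


@pytest.fixture(scope="session")
def trunk0(short_session, layout):
    _, trajs, _ = short_session
    return mesh_from_frame(trajs.frame(0), layout, "trunk")


@pytest.fixture(scope="session")
def clean_trunk0(clean_session, layout):
    _, trajs, _ = clean_session
    return mesh_from_frame(trajs.frame(0), layout, "trunk")


def rigid_transform(seed: int = 0):
    """A random rotation + translation for invariance tests."""
    rng = np.random.default_rng(seed)
    a, b, c = rng.uniform(0, 2 * np.pi, 3)

    def rot(axis, ang):
        c_, s_ = np.cos(ang), np.sin(ang)
        m = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][axis]
        m[i, i] = c_
        m[j, j] = c_
        m[i, j] = -s_
        m[j, i] = s_
        return m

    r = rot(0, a) @ rot(1, b) @ rot(2, c)
    t = rng.uniform(-300, 300, 3)
    return r, t
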