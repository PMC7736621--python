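import numpy as np
import pytest

from synmorph.synthetic import PitModel, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def small_scene():
    """One resting bouton with a few pits, shared across read-only tests."""
    return generate_scene(SceneSpec(seed=42, pit_rate=3.0))


@pytest.fixture(scope="session")
def reference_pit():
    """Sphere-neck pit with the closed-form D=89.4, P=46.0, I~83.0 nm."""
    return PitModel(radius_nm=44.7, pore_radius_nm=23.0, neck_length_nm=0.0)


def random_valid_mesh(rng, n_vertices=30, n_faces=50, scale=1.0):
    """Random triangle soup that passes TriangleMesh validation."""
    from synmorph.geometry import TriangleMesh

    while True:
        v = rng.normal(size=(n_vertices, 3)) * scale
        f = rng.integers(0, n_vertices, size=(n_faces, 3))
        try:
            return TriangleMesh(v, f)
        except ValueError:
            continue
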