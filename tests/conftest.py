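import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memscope import (SurfaceParams, make_capsid_shell, make_membrane_frame,
                      make_trajectory, merge_frames)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

BOX = (400.0, 400.0, 400.0)
N_PER_LEAFLET = 150


@pytest.fixture(scope="session")
def flat_surface():
    return SurfaceParams(c0=50.0)


@pytest.fixture(scope="session")
def flat_scene(flat_surface):
    """Flat bilayer patch plus the construction-truth leaflet map."""
    frame, truth = make_membrane_frame(
        flat_surface, n_per_leaflet=N_PER_LEAFLET, box=BOX, seed=11)
    leaflets = {m: ("upper" if m <= N_PER_LEAFLET else "lower")
                for m in range(1, 2 * N_PER_LEAFLET + 1)}
    return frame, truth, leaflets


@pytest.fixture(scope="session")
def dimple_surface():
    return SurfaceParams(c0=50.0, A=-30.0, x0=200.0, y0=200.0,
                         sx=80.0, sy=80.0)


@pytest.fixture(scope="session")
def capsid_scene(flat_surface):
    """Flat membrane + icosahedral shell hovering above it."""
    membrane, _ = make_membrane_frame(
        flat_surface, n_per_leaflet=N_PER_LEAFLET, box=BOX, seed=7)
    shell = make_capsid_shell(center=(200.0, 200.0, 190.0), radius=125.0,
                              beads_per_face=10, seed=7)
    return merge_frames(membrane, shell)


@pytest.fixture(scope="session")
def short_trajectory(capsid_scene, flat_surface):
    frames, truth = make_trajectory(
        capsid_scene, n_frames=20,
        rotation_schedule=np.linspace(0.0, 38.0, 20),
        rotation_axis=(0.0, 0.0, 1.0),
        dimple_schedule=[flat_surface] * 20, seed=3)
    return frames, truth
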