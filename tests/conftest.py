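import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import folliculometry as fol

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SPACING = (16.0, 4.0, 4.0)


@pytest.fixture(scope="session")
def spacing():
    return SPACING


@pytest.fixture(scope="session")
def small_scene():
    """A compact three-follicle scene with a vessel, blur and noise on."""
    spec = fol.PhantomSpec(
        volume_shape=(64, 256, 256),
        follicles=[
            fol.FolliclePhantom(
                center=(512, 512, 512),
                semi_axes=(250, 230, 220),
                orientation=fol.inplane_rotation(30),
                theca_thickness_base=60,
                theca_thickness_modulation=0.1,
                gap_width=10,
                granulosa_width=18,
                coc_diameter=80,
                coc_anchor_deg=45,
            ),
            fol.FolliclePhantom(
                center=(300, 200, 200),
                semi_axes=(60, 58, 56),
                theca_thickness_base=25,
                gap_width=8,
                granulosa_width=10,
            ),
            fol.FolliclePhantom(
                center=(750, 800, 300),
                semi_axes=(42, 41, 40),
                theca_thickness_base=45,
                gap_width=0,
                granulosa_width=0,
            ),
        ],
        vessels=[
            fol.VesselPhantom(
                polyline=[(30, 950, 100), (500, 980, 130), (990, 960, 90)], radius=16
            )
        ],
        seed=7,
    )
    stack, truth = fol.build_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_scene(small_scene):
    """The same scene rendered without blur or noise (exact intensity levels)."""
    spec, _, _ = small_scene
    import dataclasses

    clean = dataclasses.replace(spec, blur=False, noise=False, seed=3)
    stack, truth = fol.build_phantom(clean)
    return clean, stack, truth
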