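"""Shared fixtures: a desk-scale probe and a simulated clutter corpus.

The corpus emulates the clutter-phantom study conditions at desk scale:
a 64-element, 0.3 mm pitch, 5 MHz linear array (λ = 0.308 mm), 15 plane
waves spanning ±18°, fully developed speckle (40 scatterers/mm²), one
anechoic disk inclusion at 10 mm depth, and a reflecting layer at 6 mm
(r = 0.7, two orders) whose first-order ghosts of the shallow speckle land
inside the inclusion — the severe in-target reverberation regime. Everything is generated programmatically and cached for the
session.
"""

from __future__ import annotations

import pytest

from pwcoh import (
    AngleSequence,
    BeamformConfig,
    Inclusion,
    PixelGrid,
    ProbeConfig,
    ReverbLayer,
    SceneConfig,
    beamform_all,
    load_acquisition,
    make_corpus,
    maxabs_normalize,
    selection_for_acquisition,
)

CORPUS_SEED = 123


@pytest.fixture(scope="session")
def desk_probe() -> ProbeConfig:
    return ProbeConfig(n_elements=64, pitch=0.3e-3, f0=5e6, c=1540.0, fs=20e6)


@pytest.fixture(scope="session")
def reference_probe() -> ProbeConfig:
    """128-element L11-5v-class probe: W = 38.4 mm, λ = 0.308 mm."""
    return ProbeConfig(n_elements=128, pitch=0.3e-3, f0=5e6, c=1540.0, fs=20e6)


@pytest.fixture(scope="session")
def desk_angles() -> AngleSequence:
    return AngleSequence.symmetric(18.0, 15)


@pytest.fixture(scope="session")
def desk_grid(desk_probe) -> PixelGrid:
    return PixelGrid.lambda_third(desk_probe, z0=6e-3, nz=128, nx=128)


@pytest.fixture(scope="session")
def desk_scene_template() -> SceneConfig:
    return SceneConfig(
        speckle_density=40.0,
        inclusions=(Inclusion(center=(0.0, 10e-3), radius=2.5e-3, echogenicity=0.0),),
        reverb_layers=(ReverbLayer(depth=6e-3, reflection_coefficient=0.7, max_order=2),),
        noise_snr_db=40.0,
    )


DESK_EXTENT = (-8e-3, 8e-3, 2e-3, 20e-3)


@pytest.fixture(scope="session")
def clutter_corpus(tmp_path_factory, desk_probe, desk_angles, desk_scene_template):
    """Four containers (3 train + 1 held out) with ROI sidecars."""
    out = tmp_path_factory.mktemp("corpus")
    return make_corpus(
        4, desk_probe, desk_angles, desk_scene_template, DESK_EXTENT, out, seed=CORPUS_SEED
    )


@pytest.fixture(scope="session")
def clutter_frame_sets(clutter_corpus, desk_grid):
    """Beamformed, max-abs-normalized frame sets of the corpus."""
    cfg = BeamformConfig(grid=desk_grid)
    return [maxabs_normalize(beamform_all(load_acquisition(p), cfg)) for p in clutter_corpus]


@pytest.fixture(scope="session")
def desk_selection(desk_probe, desk_angles):
    return selection_for_acquisition(desk_probe, desk_angles)
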