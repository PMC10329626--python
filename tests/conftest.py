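import numpy as np
import pytest

from mtunit import (DiscriminatorSpec, GeneratorSpec, MTModuleSpec,
                    SceneSpec, ToolSpec, build_bundle, generate_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_tool_sample():
    """64x64 scene, one 6x20 tool translating at (2, 0) px/frame."""
    spec = SceneSpec(image_size=(64, 64),
                     tools=[ToolSpec(size=(6, 20), velocity=(2.0, 0.0),
                                     start_position=(10.0, 24.0))])
    return generate_scene(spec, T=10, seed=7)


@pytest.fixture(scope="session")
def tiny_scene_spec():
    """32x32 scene with a small tool, for fast training tests."""
    return SceneSpec(image_size=(32, 32),
                     tools=[ToolSpec(size=(4, 10), velocity=(1.0, 0.0),
                                     start_position=(6.0, 12.0))],
                     boundary="clamp")


@pytest.fixture(scope="session")
def tiny_bundle():
    gen = GeneratorSpec(base_width=4, n_downsample=2, n_resblocks=2,
                        n_shared_resblocks=1)
    mt = MTModuleSpec(base_width=4, unet_depth=2)
    disc = DiscriminatorSpec(n_scales=1, n_layers=2, base_width=4)
    return build_bundle(gen, mt, disc, seed=3)
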