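"""Desk-scale benchmark scenario: two synthetic domains, MT vs. ablation.

Fixed study conditions for the package's end-to-end direction check: two
style-distinct 64×64 synthetic surgical domains sharing scene structure,
200 consecutive-frame training pairs per domain (20 scenes of 11 frames),
300 optimisation steps at batch size 1 with oracle source flow, and
held-out scenes scored with the tOF metric under the classical iLK flow
estimator.  The motion-translation variant uses the full objective; the
ablation zeroes both temporal weights, reducing training to the plain
shared-latent backbone.  This checks the *direction* of the mechanism —
that motion translation yields more temporally consistent sequences — not
any full-scale magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .flow import ClassicalEstimator
from .losses import LossWeights
from .metrics import tof_distance
from .models import DiscriminatorSpec, GeneratorSpec, MTModuleSpec, \
    build_bundle
from .synthetic import BackgroundStyle, SceneSpec, ToolSpec, make_domain_pair
from .training import (TrainConfig, TrainState, pairs_from_sample,
                       train_step, translate_sequence)

IMAGE_SIZE = 64
TRAIN_SCENES = 20          # 20 scenes x 10 pairs = 200 pairs per domain
TRAIN_SEQ_LEN = 11
HELDOUT_SCENES = 3         # evaluated in both directions -> 6 sequences
EVAL_SEQ_LEN = 10
STEPS = 300

STYLE_A = BackgroundStyle(base_color=(0.55, 0.35, 0.25),
                          pupil_color=(0.08, 0.05, 0.05),
                          gradient_strength=0.5, noise_amp=0.02)
STYLE_B = BackgroundStyle(base_color=(0.25, 0.45, 0.55),
                          pupil_color=(0.02, 0.08, 0.10),
                          gradient_strength=0.3, noise_amp=0.02)


def shared_scene_spec() -> SceneSpec:
    return SceneSpec(image_size=(IMAGE_SIZE, IMAGE_SIZE),
                     tools=[ToolSpec()], boundary="clamp")


def toy_scene_pairs(seed0: int, n_scenes: int, seq_len: int):
    """Matched-structure scene pairs plus their consecutive-pair datasets."""
    pairs_a, pairs_b, scenes = [], [], []
    for i in range(n_scenes):
        sa, sb = make_domain_pair(shared_scene_spec(), STYLE_A, STYLE_B,
                                  seq_len, seed=(seed0 + i) % (2 ** 31))
        pairs_a += pairs_from_sample(sa)
        pairs_b += pairs_from_sample(sb)
        scenes.append((sa, sb))
    return pairs_a, pairs_b, scenes


def toy_specs(seed: int):
    gen = GeneratorSpec(base_width=8, n_downsample=2, n_resblocks=2,
                        n_shared_resblocks=1)
    mt = MTModuleSpec(base_width=8, unet_depth=3)
    disc = DiscriminatorSpec(n_scales=1, n_layers=3, base_width=8)
    return build_bundle(gen, mt, disc, seed=seed)


def train_toy(dataset_a, dataset_b, seed: int, temporal: bool,
              steps: int = STEPS, bundle=None):
    """Train one variant; ``temporal=False`` zeroes both temporal weights."""
    bundle = bundle or toy_specs(seed)
    cfg = TrainConfig(epochs=steps, batch_size=1, image_size=IMAGE_SIZE,
                      decay_start_epoch=steps // 2, seed=seed)
    weights = LossWeights() if temporal else LossWeights(delta_mt=0.0,
                                                         delta_ssim=0.0)
    state = TrainState.fresh(bundle, cfg)
    rng = np.random.default_rng(seed)
    order_a = rng.permutation(len(dataset_a))
    order_b = rng.permutation(len(dataset_b))
    lr = cfg.lr0
    for step in range(steps):
        if step >= cfg.decay_start_epoch:
            lr = cfg.lr0 * (steps - step) / (steps - cfg.decay_start_epoch)
        batch_a = [dataset_a[order_a[step % len(dataset_a)]]]
        batch_b = [dataset_b[order_b[step % len(dataset_b)]]]
        report, state = train_step(bundle, batch_a, batch_b, cfg, state,
                                   weights, lr=lr)
    return bundle, report


def heldout_tof(bundle, scenes, estimator=None) -> float:
    """Mean tOF of translated held-out sequences, both directions."""
    estimator = estimator or ClassicalEstimator("ilk")
    values = []
    for sa, sb in scenes:
        for src, direction in ((sa, "A->B"), (sb, "B->A")):
            trans = translate_sequence(bundle, src.frames, direction)
            values.append(tof_distance(src.frames, trans, estimator))
    return float(np.mean(values))


@dataclass
class DirectionResult:
    seed: int
    tof_mt: float
    tof_ablation: float

    @property
    def mt_better(self) -> bool:
        return self.tof_mt < self.tof_ablation


def direction_experiment(seed: int, steps: int = STEPS,
                         n_train_scenes: int = TRAIN_SCENES) -> DirectionResult:
    """Train MT vs. ablation from one seed and score held-out tOF."""
    data_seed = (1000 + 131 * seed) % (2 ** 31)
    ds_a, ds_b, _ = toy_scene_pairs(data_seed, n_train_scenes, TRAIN_SEQ_LEN)
    _, _, held = toy_scene_pairs((9000 + 977 * seed) % (2 ** 31),
                                 HELDOUT_SCENES, EVAL_SEQ_LEN)
    bundle_mt, _ = train_toy(ds_a, ds_b, seed, temporal=True, steps=steps)
    bundle_ab, _ = train_toy(ds_a, ds_b, seed, temporal=False, steps=steps)
    return DirectionResult(seed, heldout_tof(bundle_mt, held),
                           heldout_tof(bundle_ab, held))
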