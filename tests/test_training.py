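import numpy as np
import pytest
from autograd import value_and_grad

from mtunit import make_domain_pair
from mtunit.losses import (LossWeights, backbone_terms, backbone_weight_map)
from mtunit.models import (DiscriminatorSpec, GeneratorSpec, MTModuleSpec,
                           build_bundle)
from mtunit.synthetic import BackgroundStyle
from mtunit.training import (TrainConfig, TrainState, fit, load_checkpoint,
                             lr_at_epoch, pairs_from_sample,
                             pairs_from_sequence, save_checkpoint,
                             train_step)

STYLE_A = BackgroundStyle(base_color=(0.55, 0.35, 0.25))
STYLE_B = BackgroundStyle(base_color=(0.25, 0.45, 0.55))


def tiny_datasets(tiny_scene_spec, n_scenes=2, seq_len=9, seed0=50):
    ds_a, ds_b = [], []
    for i in range(n_scenes):
        sa, sb = make_domain_pair(tiny_scene_spec, STYLE_A, STYLE_B,
                                  seq_len, seed=seed0 + i)
        ds_a += pairs_from_sample(sa)
        ds_b += pairs_from_sample(sb)
    return ds_a, ds_b


def tiny_train_bundle(seed=0):
    return build_bundle(
        GeneratorSpec(base_width=4, n_downsample=2, n_resblocks=2,
                      n_shared_resblocks=1),
        MTModuleSpec(base_width=4, unet_depth=2),
        DiscriminatorSpec(n_scales=1, n_layers=2, base_width=4), seed=seed)


class TestSchedule:
    def test_closed_form_at_every_epoch(self):
        cfg = TrainConfig(seed=0)
        for epoch in range(201):
            expected = (2e-4 if epoch < 100
                        else 2e-4 * (200 - epoch) / 100)
            assert lr_at_epoch(epoch, cfg) == pytest.approx(expected,
                                                            rel=1e-12)
        assert lr_at_epoch(0, cfg) == 2e-4
        assert lr_at_epoch(150, cfg) == pytest.approx(1e-4)
        assert lr_at_epoch(200, cfg) == 0.0

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig(seed=0)
        with pytest.raises(ValueError):
            lr_at_epoch(-1, cfg)
        with pytest.raises(ValueError):
            lr_at_epoch(201, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=50, decay_start_epoch=80)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(mt_routing="sideways")


class TestTrainStep:
    def _setup(self, tiny_scene_spec, seed=0):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        bundle = tiny_train_bundle(seed)
        cfg = TrainConfig(epochs=4, batch_size=2, image_size=32,
                          decay_start_epoch=2, seed=seed)
        state = TrainState.fresh(bundle, cfg)
        return bundle, cfg, state, ds_a, ds_b

    def test_deterministic_given_state_and_inputs(self, tiny_scene_spec):
        r = []
        for _ in range(2):
            bundle, cfg, state, ds_a, ds_b = self._setup(tiny_scene_spec)
            report, _ = train_step(bundle, ds_a[:2], ds_b[:2], cfg, state)
            r.append((report, bundle))
        assert r[0][0].terms == r[1][0].terms
        for k in r[0][1].params:
            assert np.array_equal(r[0][1].params[k], r[1][1].params[k])

    def test_weight_zero_ablation_reduces_to_backbone(self, tiny_scene_spec):
        """With both temporal weights zero, the generator objective equals
        the pure backbone objective, gradient for gradient."""
        from mtunit.losses import joint_generator_terms

        bundle, cfg, state, ds_a, ds_b = self._setup(tiny_scene_spec)

        weights = LossWeights(delta_mt=0.0, delta_ssim=0.0)
        report, _ = train_step(bundle, ds_a[:2], ds_b[:2], cfg, state,
                               weights)
        assert "mt_A" not in report.terms
        assert "msssim_A" not in report.terms

        # gradient-for-gradient: the (batched) training objective vs. the
        # plain backbone objective on the same parameters and inputs
        xa = np.stack([p.frame_t for p in ds_a[:2]]).transpose(0, 3, 1, 2)
        xb = np.stack([p.frame_t for p in ds_b[:2]]).transpose(0, 3, 1, 2)
        xa = xa.astype(np.float32)
        xb = xb.astype(np.float32)
        wmap = backbone_weight_map(weights)
        frozen = dict(bundle.params)

        def weighted(terms):
            total = None
            for name, val in terms.items():
                c = wmap.get(name, 1.0) * val
                total = c if total is None else total + c
            return total

        def train_obj(gp):
            p = {**frozen, **gp}
            fa = np.zeros((2, 2, 32, 32), np.float32)
            return weighted(joint_generator_terms(
                p, bundle.gen_spec, bundle.disc_spec, bundle.mt_spec,
                xa, xa, xb, xb, fa, fa, temporal=False))

        def backbone_obj(gp):
            p = {**frozen, **gp}
            terms, _ = backbone_terms(p, bundle.gen_spec, bundle.disc_spec,
                                      xa, xb)
            return weighted(terms)

        gsub = {k: bundle.params[k] for k in bundle.generator_keys}
        v1, g1 = value_and_grad(train_obj)(gsub)
        v2, g2 = value_and_grad(backbone_obj)(gsub)
        assert float(v1) == pytest.approx(float(v2), rel=1e-6)
        # float32 batched-vs-separate reductions agree to accumulation noise
        for k in gsub:
            np.testing.assert_allclose(g1[k], g2[k], rtol=2e-3, atol=1e-4,
                                       err_msg=k)

    def test_loss_decreases_over_fifty_steps(self, tiny_scene_spec):
        """Seeded toy training lowers the weighted generator total within 50
        steps for a majority of seeds."""
        wins = 0
        for seed in (0, 1, 2):
            bundle, cfg, state, ds_a, ds_b = self._setup(tiny_scene_spec,
                                                         seed)
            first = last = None
            rng = np.random.default_rng(seed)
            for step in range(50):
                ia = rng.choice(len(ds_a), 2, replace=False)
                ib = rng.choice(len(ds_b), 2, replace=False)
                report, state = train_step(
                    bundle, [ds_a[i] for i in ia], [ds_b[i] for i in ib],
                    cfg, state, lr=2e-4)
                gen_total = sum(
                    report.weight_of.get(k, 1.0) * v
                    for k, v in report.terms.items()
                    if not k.startswith("disc"))
                if first is None:
                    first = gen_total
                last = gen_total
            wins += last < first
        assert wins >= 2

    def test_translation_moves_toward_target_palette(self):
        """After brief training on two constant-palette domains, translated
        frames shift their mean colour toward the target domain."""
        from mtunit.models import translate_frame
        from mtunit.training import PairSample

        rng = np.random.default_rng(0)
        col_a = np.array([0.8, 0.2, 0.2], np.float32)
        col_b = np.array([0.2, 0.2, 0.8], np.float32)

        def domain(color):
            pairs = []
            for _ in range(8):
                base = np.clip(color + rng.normal(0, 0.03, (32, 32, 3)),
                               0, 1).astype(np.float32)
                pairs.append(PairSample(base, base,
                                        np.zeros((32, 32, 2), np.float32)))
            return pairs

        ds_a, ds_b = domain(col_a), domain(col_b)
        bundle = tiny_train_bundle(1)
        cfg = TrainConfig(epochs=40, batch_size=2, image_size=32,
                          decay_start_epoch=39, seed=1)
        state = TrainState.fresh(bundle, cfg)
        weights = LossWeights(delta_mt=0.0, delta_ssim=0.0)
        frame = ds_a[0].frame_t
        before = translate_frame(bundle, frame, "A->B").mean(axis=(0, 1))
        for step in range(40):
            ia = state.rng.choice(8, 2, replace=False)
            ib = state.rng.choice(8, 2, replace=False)
            _, state = train_step(bundle, [ds_a[i] for i in ia],
                                  [ds_b[i] for i in ib], cfg, state,
                                  weights, lr=2e-4)
        after = translate_frame(bundle, frame, "A->B").mean(axis=(0, 1))
        dist_before = np.linalg.norm(before - col_b)
        dist_after = np.linalg.norm(after - col_b)
        assert dist_after < dist_before

    def test_mismatched_batch_shapes_rejected(self, tiny_scene_spec,
                                              one_tool_sample):
        bundle, cfg, state, ds_a, _ = self._setup(tiny_scene_spec)
        ds_big = pairs_from_sample(one_tool_sample)
        with pytest.raises(ValueError, match="share a shape"):
            train_step(bundle, ds_a[:2], ds_big[:2], cfg, state)


class TestFitAndCheckpoints:
    def _cfg(self, **kw):
        kw.setdefault("epochs", 1)
        kw.setdefault("batch_size", 4)
        kw.setdefault("image_size", 32)
        kw.setdefault("decay_start_epoch", 0)
        kw.setdefault("seed", 0)
        return TrainConfig(**kw)

    def test_single_epoch_bookkeeping(self, tiny_scene_spec, tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        cfg = self._cfg()
        ckpt = fit(cfg, ds_a, ds_b, tmp_path / "run",
                   bundle=tiny_train_bundle())
        assert ckpt.exists()
        rows = (tmp_path / "run" / "losses.csv").read_text().strip()
        assert len(rows.splitlines()) == 2  # header + one epoch

    def test_identical_seeds_give_bit_identical_checkpoints(
            self, tiny_scene_spec, tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        paths = []
        for name in ("r1", "r2"):
            cfg = self._cfg(epochs=2, decay_start_epoch=1)
            paths.append(fit(cfg, ds_a, ds_b, tmp_path / name,
                             bundle=tiny_train_bundle()))
        b1, _, _ = load_checkpoint(paths[0])
        b2, _, _ = load_checkpoint(paths[1])
        for k in b1.params:
            assert np.array_equal(b1.params[k], b2.params[k]), k

    def test_resume_reproduces_uninterrupted_run(self, tiny_scene_spec,
                                                 tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        cfg_full = self._cfg(epochs=2, decay_start_epoch=1)
        full = fit(cfg_full, ds_a, ds_b, tmp_path / "full",
                   bundle=tiny_train_bundle())

        cfg_half = self._cfg(epochs=2, decay_start_epoch=1)
        n_batches = min(len(ds_a), len(ds_b)) // cfg_half.batch_size
        fit(cfg_half, ds_a, ds_b, tmp_path / "half",
            bundle=tiny_train_bundle(), max_steps=n_batches)
        resumed = fit(cfg_half, ds_a, ds_b, tmp_path / "half",
                      resume_from=tmp_path / "half" / "checkpoint.npz")

        bf, _, _ = load_checkpoint(full)
        br, _, _ = load_checkpoint(resumed)
        for k in bf.params:
            assert np.array_equal(bf.params[k], br.params[k]), k

        csv_full = (tmp_path / "full" / "losses.csv").read_text().splitlines()
        csv_half = (tmp_path / "half" / "losses.csv").read_text().splitlines()
        assert csv_full[-1] == csv_half[-1]

    def test_checkpoint_round_trip(self, tiny_scene_spec, tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        bundle = tiny_train_bundle()
        cfg = self._cfg(epochs=3, decay_start_epoch=2)
        state = TrainState.fresh(bundle, cfg)
        train_step(bundle, ds_a[:4], ds_b[:4], cfg, state)
        path = save_checkpoint(tmp_path / "ck.npz", bundle, state, cfg)
        b2, s2, c2 = load_checkpoint(path)
        assert c2 == cfg
        assert s2.step == state.step
        assert s2.rng.bit_generator.state == state.rng.bit_generator.state
        for k in bundle.params:
            assert np.array_equal(bundle.params[k], b2.params[k])
        for k in state.opt_g.m:
            assert np.array_equal(state.opt_g.m[k], s2.opt_g.m[k])

    def test_empty_dataset_rejected(self, tiny_scene_spec, tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        with pytest.raises(ValueError, match="non-empty"):
            fit(self._cfg(), [], ds_b, tmp_path / "x")

    def test_dataset_shorter_than_batch_rejected(self, tiny_scene_spec,
                                                 tmp_path):
        ds_a, ds_b = tiny_datasets(tiny_scene_spec)
        cfg = self._cfg(batch_size=64)
        with pytest.raises(ValueError, match="shorter than one batch"):
            fit(cfg, ds_a, ds_b, tmp_path / "x")


class TestPairsFromSequence:
    def test_flows_estimated_and_cached(self, tiny_scene_spec, tmp_path):
        from mtunit.flow import ClassicalEstimator
        from mtunit.synthetic import generate_scene

        sample = generate_scene(tiny_scene_spec, T=4, seed=0)
        est = ClassicalEstimator("ilk")
        pairs = pairs_from_sequence(sample.frames, est,
                                    cache_dir=tmp_path / "cache")
        assert len(pairs) == 3
        assert (tmp_path / "cache" / "flow_000000.flo").exists()
        again = pairs_from_sequence(sample.frames, est,
                                    cache_dir=tmp_path / "cache")
        assert np.array_equal(pairs[0].flow_fwd, again[0].flow_fwd)

    def test_oracle_pairs_carry_ground_truth(self, one_tool_sample):
        pairs = pairs_from_sample(one_tool_sample)
        assert len(pairs) == len(one_tool_sample.frames) - 1
        assert np.array_equal(pairs[2].flow_fwd,
                              one_tool_sample.flows_fwd[2].values)
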