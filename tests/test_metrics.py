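import numpy as np
import pytest

from mtunit import corrupt_sequence, generate_scene
from mtunit.flow import BACKWARD, ClassicalEstimator, FlowField, \
    OracleEstimator
from mtunit.metrics import (DefaultEmbedder, MetricReport, evaluate_sequences,
                            extract_foreground, fid, get_embedder, kid,
                            lpips_diversity, temporal_consistency,
                            tlp_distance, tof_distance, warping_error)
from mtunit.seqio import FrameSequence, MaskSequence
from mtunit.synthetic import SceneSpec, ToolSpec


def _mask(*rows):
    return np.array(rows, dtype=np.uint8)


class TestExtractForeground:
    def test_oracle_returns_ground_truth(self, one_tool_sample):
        out = extract_foreground(one_tool_sample.frames, "oracle",
                                 sample=one_tool_sample)
        assert np.array_equal(out.masks, one_tool_sample.masks.masks)

    def test_oracle_without_sample_rejected(self, one_tool_sample):
        with pytest.raises(ValueError, match="synthetic"):
            extract_foreground(one_tool_sample.frames, "oracle")

    def test_static_sequence_gives_empty_masks(self, rng):
        frame = rng.random((8, 8, 3)).astype(np.float32)
        seq = FrameSequence(np.repeat(frame[None], 5, axis=0), np.arange(5))
        out = extract_foreground(seq, "temporal_median", {"threshold": 0.05})
        assert out.masks.sum() == 0

    def test_temporal_median_overlaps_ground_truth(self):
        # fast narrow tool: every pixel is background for most frames, so
        # the per-pixel temporal median recovers the background
        spec = SceneSpec(image_size=(64, 64),
                         tools=[ToolSpec(size=(6, 10), velocity=(4.0, 0.0),
                                         start_position=(4.0, 28.0))])
        sample = generate_scene(spec, T=10, seed=11)
        out = extract_foreground(sample.frames, "temporal_median",
                                 {"threshold": 0.1})
        gt = sample.masks.masks
        jacc = []
        for m, g in zip(out.masks.astype(bool), gt.astype(bool)):
            jacc.append((m & g).sum() / max((m | g).sum(), 1))
        assert np.mean(jacc) > 0.8


class TestTemporalConsistency:
    def test_identity_ideal_values(self, one_tool_sample):
        m = one_tool_sample.masks
        assert temporal_consistency(m, m, "RMSE") == 0.0
        assert temporal_consistency(m, m, "SSIM") == pytest.approx(1.0)

    def test_hand_worked_two_frame_example(self):
        src = MaskSequence(np.stack([_mask([1, 0], [0, 0]),
                                     _mask([0, 1], [0, 0])]))
        trans = MaskSequence(np.stack([_mask([1, 0], [0, 0]),
                                       _mask([1, 0], [0, 0])]))
        value = temporal_consistency(src, trans, "RMSE")
        assert value == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_symmetric_in_arguments(self, one_tool_sample):
        src = one_tool_sample.masks
        trans = MaskSequence(np.flip(src.masks, axis=0).copy())
        for d in ("RMSE", "SSIM"):
            assert temporal_consistency(src, trans, d) == pytest.approx(
                temporal_consistency(trans, src, d))

    def test_length_mismatch_rejected(self, one_tool_sample):
        short = MaskSequence(one_tool_sample.masks.masks[:3])
        with pytest.raises(ValueError):
            temporal_consistency(one_tool_sample.masks, short)

    def test_unknown_distance_rejected(self, one_tool_sample):
        with pytest.raises(ValueError):
            temporal_consistency(one_tool_sample.masks,
                                 one_tool_sample.masks, "L7")


class _ConstantFlowEstimator:
    """Returns a constant field chosen by the mean intensity of frame 1."""

    name = "stub"

    def __init__(self, mapping):
        self.mapping = mapping

    def estimate(self, f1, f2):
        for key, value in self.mapping.items():
            if abs(float(np.mean(f1)) - key) < 1e-6:
                field = np.zeros(f1.shape[:2] + (2,), np.float32)
                field[..., 0], field[..., 1] = value
                return FlowField(field, "forward")
        raise AssertionError("unexpected frame")


class TestTofDistance:
    def test_identical_sequences_give_zero(self, one_tool_sample):
        est = OracleEstimator(one_tool_sample)
        assert tof_distance(one_tool_sample.frames, one_tool_sample.frames,
                            est) == 0.0

    def test_uniform_offset_gives_half(self):
        # src flow (0,0) vs trans flow (1,0): mean |diff| over 2 channels
        src = FrameSequence(np.full((3, 8, 8, 3), 0.25), np.arange(3))
        trans = FrameSequence(np.full((3, 8, 8, 3), 0.75), np.arange(3))
        est = _ConstantFlowEstimator({0.25: (0.0, 0.0), 0.75: (1.0, 0.0)})
        assert tof_distance(src, trans, est) == pytest.approx(0.5)

    def test_static_collapse_increases_tof(self, one_tool_sample):
        est = ClassicalEstimator("ilk")
        clean = one_tool_sample.frames
        collapsed = corrupt_sequence(one_tool_sample, "static_collapse")
        assert (tof_distance(clean, collapsed, est)
                > tof_distance(clean, clean, est))


class _MeanFreeEmbedder:
    name = "mean-free"

    def embed(self, frame):
        f = np.asarray(frame, dtype=np.float64)
        return (f - f.mean()).ravel()

    def distance(self, f1, f2):
        return float(np.linalg.norm(self.embed(f1) - self.embed(f2)))


class TestTlpDistance:
    def test_identical_sequences_give_zero(self, one_tool_sample):
        emb = DefaultEmbedder()
        assert tlp_distance(one_tool_sample.frames, one_tool_sample.frames,
                            emb) == 0.0

    def test_flicker_detected_against_static(self, rng):
        frame = rng.random((16, 16, 3)).astype(np.float32)
        static = FrameSequence(np.repeat(frame[None], 4, axis=0),
                               np.arange(4))
        gains = np.array([1.0, 0.8, 1.0, 0.8])[:, None, None, None]
        flick = FrameSequence(np.clip(static.frames * gains, 0, 1),
                              np.arange(4))
        emb = DefaultEmbedder()
        assert tlp_distance(static, flick, emb) > 0.0

    def test_invariant_to_shared_constant_shift(self, rng):
        base = rng.random((4, 12, 12, 3)) * 0.5
        seq1 = FrameSequence(base, np.arange(4))
        seq2 = FrameSequence(base[::-1].copy(), np.arange(4))
        emb = _MeanFreeEmbedder()
        v0 = tlp_distance(seq1, seq2, emb)
        shifted1 = FrameSequence(base + 0.3, np.arange(4))
        shifted2 = FrameSequence(base[::-1].copy() + 0.3, np.arange(4))
        assert tlp_distance(shifted1, shifted2, emb) == pytest.approx(
            v0, abs=1e-6)


class TestWarpingError:
    def test_static_sequence_zero_flow_gives_zero(self, rng):
        frame = rng.random((8, 8, 3)).astype(np.float32)
        seq = FrameSequence(np.repeat(frame[None], 4, axis=0), np.arange(4))
        flows = [FlowField(np.zeros((8, 8, 2)), BACKWARD)] * 3
        assert warping_error(seq, flows) == 0.0

    def test_oracle_closure_gives_zero_on_valid(self, one_tool_sample):
        s = one_tool_sample
        assert warping_error(s.frames, s.flows_bwd, s.valid) == 0.0

    def test_drop_tool_increases_error(self, one_tool_sample):
        s = one_tool_sample
        dropped = corrupt_sequence(s, "drop_tool", {"frames": [4, 5]})
        assert (warping_error(dropped, s.flows_bwd, s.valid)
                > warping_error(s.frames, s.flows_bwd, s.valid))

    def test_flow_count_mismatch_rejected(self, one_tool_sample):
        with pytest.raises(ValueError, match="flow fields"):
            warping_error(one_tool_sample.frames,
                          one_tool_sample.flows_bwd[:-2])


class TestDistributionMetrics:
    def test_fid_identical_sets_is_zero(self, rng):
        x = rng.normal(0, 1, (500, 8))
        assert fid(x, x) < 1e-6

    def test_fid_matches_mean_offset_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (10_000, 8))
        mu = rng.normal(0, 1, 8)
        mu = 2.0 * mu / np.linalg.norm(mu)
        y = rng.normal(0, 1, (10_000, 8)) + mu
        assert fid(x, y) == pytest.approx(4.0, abs=0.2)

    def test_fid_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError):
            fid(rng.normal(0, 1, (1, 4)), rng.normal(0, 1, (5, 4)))

    def test_kid_identical_sets_is_zero(self, rng):
        x = rng.normal(0, 1, (500, 8))
        mean, sd = kid(x, x, subset_size=100, n_subsets=10, seed=0)
        assert abs(mean) < 1e-3

    def test_kid_symmetric_same_seed(self, rng):
        x = rng.normal(0, 1, (300, 8))
        y = rng.normal(0.5, 1, (300, 8))
        assert kid(x, y, 100, 5, 3) == pytest.approx(kid(y, x, 100, 5, 3))

    def test_kid_positive_for_offset_distributions(self, rng):
        x = rng.normal(0, 1, (400, 8))
        y = rng.normal(1.0, 1, (400, 8))
        mean, _ = kid(x, y, 100, 10, 0)
        assert mean > 0.0


class TestDiversity:
    def test_identical_frames_give_zero(self, rng):
        frame = rng.random((16, 16, 3))
        frames = [frame.copy() for _ in range(5)]
        assert lpips_diversity(frames, DefaultEmbedder(), 20, 0) == 0.0

    def test_deterministic_given_seed(self, rng):
        frames = [rng.random((16, 16, 3)) for _ in range(6)]
        emb = DefaultEmbedder()
        assert lpips_diversity(frames, emb, 30, 5) == lpips_diversity(
            frames, emb, 30, 5)

    def test_duplicate_frame_does_not_increase_expected_value(self, rng):
        frames = [rng.random((16, 16, 3)) for _ in range(6)]
        emb = DefaultEmbedder()
        base = lpips_diversity(frames, emb, 400, 7)
        dup = lpips_diversity(frames + [frames[0].copy()], emb, 400, 7)
        assert dup <= base * 1.05

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            lpips_diversity([rng.random((8, 8, 3))], DefaultEmbedder())

    def test_lpips_adapter_unavailable(self):
        from mtunit.flow import CapabilityError

        with pytest.raises(CapabilityError):
            get_embedder("lpips")


class TestEvaluateSequences:
    def test_identity_pairs_attain_ideal_values(self, one_tool_sample):
        seq = one_tool_sample.frames
        config = {"metrics": ("tc_rmse", "tc_ssim", "tof", "tlp"),
                  "estimator": OracleEstimator(one_tool_sample),
                  "embedder": DefaultEmbedder()}
        report = evaluate_sequences([(seq, seq)], config)
        assert report.values["tc_rmse"] == 0.0
        assert report.values["tc_ssim"] == pytest.approx(1.0)
        assert report.values["tof"] == 0.0
        assert report.values["tlp"] == 0.0

    def test_aggregate_equals_mean_of_per_pair(self, one_tool_sample):
        spec = SceneSpec(image_size=(64, 64),
                         tools=[ToolSpec(size=(6, 20), velocity=(0.0, 2.0),
                                         start_position=(30.0, 8.0))])
        other = generate_scene(spec, T=10, seed=3)
        config = {"metrics": ("tc_rmse", "tlp"),
                  "embedder": DefaultEmbedder()}
        pairs = [(one_tool_sample.frames, one_tool_sample.frames),
                 (other.frames, corrupt_sequence(other, "flicker",
                                                 {"amplitude": 0.2}))]
        report = evaluate_sequences(pairs, config)
        for m in config["metrics"]:
            assert report.values[m] == pytest.approx(
                np.mean(report.per_pair[m]))
        assert report.n_items == 2

    def test_failing_pair_is_named(self, one_tool_sample):
        seq = one_tool_sample.frames
        config = {"metrics": ("tof",)}  # no estimator supplied
        with pytest.raises(RuntimeError, match="pair 0"):
            evaluate_sequences([(seq, seq)], config)

    def test_length_mismatch_rejected(self, one_tool_sample):
        seq = one_tool_sample.frames
        short = FrameSequence(seq.frames[:5], np.arange(5))
        with pytest.raises(ValueError, match="lengths"):
            evaluate_sequences([(seq, short)], {"metrics": ("tc_rmse",)})

    def test_report_rejects_non_finite(self):
        with pytest.raises(ValueError):
            MetricReport({"tof": float("nan")}, {}, 1)
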