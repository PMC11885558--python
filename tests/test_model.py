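import numpy as np
import pytest

from stecg import nn
from stecg.model import (HybridECGClassifier, ModelConfig, ResNeXtSEBlock,
                         build_model, desk_config, load_checkpoint,
                         save_checkpoint)


def tiny_config(**kw):
    base = dict(stage_widths=(4, 8, 8, 8), cardinality=2, embed_dim=8,
                n_heads=2, ffn_dim=16, head_hidden=8, n_classes=4,
                input_shape=(40, 64))
    base.update(kw)
    return ModelConfig(**base)


class TestConfig:
    def test_structure_counts(self):
        m = build_model(tiny_config())
        assert len(m.stages) == 8          # 4 stages x 2 ResNeXt blocks
        assert len(m.blocks) == 4          # transformer encoder depth
        assert m.blocks[0].attn.h == 2

    def test_default_table_settings(self):
        cfg = ModelConfig()
        assert cfg.stage_widths == (64, 128, 256, 512)
        assert cfg.n_heads == 8 and cfg.ffn_dim == 2048
        assert cfg.se_reduction == 16 and cfg.stochastic_depth_p == 0.2
        assert cfg.feature_shape == (5, 32)  # 151x1000 after 5 ceil-halvings

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(tiny_config(embed_dim=9))
        with pytest.raises(ValueError, match="cardinality"):
            build_model(tiny_config(stage_widths=(6, 8, 8, 8), cardinality=4))

    def test_head_output_dimension(self):
        m = build_model(tiny_config(n_classes=5))
        x = np.zeros((1, 2, 40, 64), np.float32)
        assert m.forward(x).shape == (1, 5)


class TestResNeXtBlock:
    def test_output_shape_with_stride(self, rng):
        blk = ResNeXtSEBlock(rng, 64, 128, stride=2, cardinality=32)
        blk.train(False)
        x = nn.Tensor(rng.standard_normal((1, 64, 38, 250)).astype(np.float32))
        assert blk(x).shape == (1, 128, 19, 125)

    def test_eval_mode_deterministic(self, rng):
        blk = ResNeXtSEBlock(rng, 8, 8, 1, cardinality=2).train(False)
        x = nn.Tensor(rng.standard_normal((2, 8, 10, 10)).astype(np.float32))
        a, b = blk(x).data, blk(x).data
        assert np.array_equal(a, b)

    def test_se_gate_range_and_ablation_identity(self, rng):
        blk = ResNeXtSEBlock(rng, 8, 8, 1, cardinality=2).train(False)
        x = nn.Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        gate = blk.se.gate(blk.bn3(blk.conv3(
            blk.bn2(blk.conv2(blk.bn1(blk.conv1(x)).relu())).relu()))).data
        assert np.all(gate > 0) and np.all(gate < 1)
        # disabling the gate reduces the block to its plain form
        with_se = blk(x).data
        blk.se = None
        without_se = blk(x).data
        assert not np.allclose(with_se, without_se)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ResNeXtSEBlock(rng, 8, 6, 1, cardinality=4)


class TestEncodeSequence:
    def test_pooled_shape_for_any_feature_size(self, rng):
        m = build_model(tiny_config()).eval()
        for hp, wp in [(2, 2), (1, 2), (2, 1)]:
            f = nn.Tensor(rng.standard_normal((3, 8, hp, wp)).astype(np.float32))
            assert m.encode_sequence(f).shape == (3, 8)

    def test_zeroed_encoder_reduces_to_global_skip(self, rng):
        m = build_model(tiny_config()).eval()
        for blk in m.blocks:
            for _, p in blk.named_parameters():
                p.data = np.zeros_like(p.data)
            # zero-weight LayerNorm gains would also zero the residual path;
            # keep gains at 1 so each block computes LN(x + 0 attention).
            blk.ln1.gamma.data = np.ones_like(blk.ln1.gamma.data)
            blk.ln2.gamma.data = np.ones_like(blk.ln2.gamma.data)
        f = nn.Tensor(rng.standard_normal((2, 8, 2, 2)).astype(np.float32))
        pooled, seq = m.encode_sequence(f, return_sequence=True)
        # with zeroed attention/FFN, blocks reduce to iterated LayerNorm;
        # the global skip must still carry the positional-encoded sequence
        x = seq
        for blk in m.blocks:
            x = blk.ln2(blk.ln1(x))
        expected = (x + seq).data.mean(axis=1)
        np.testing.assert_allclose(pooled.data, expected, atol=1e-6)

    def test_wrong_channel_count_rejected(self, rng):
        m = build_model(tiny_config())
        f = nn.Tensor(np.zeros((1, 7, 2, 2), np.float32))
        with pytest.raises(ValueError):
            m.encode_sequence(f)


class TestForward:
    def test_batch_invariance_in_eval(self, rng):
        m = build_model(tiny_config(), seed=2).eval()
        x = rng.standard_normal((2, 2, 40, 64)).astype(np.float32)
        stacked = m.forward(x).data
        singles = np.vstack([m.forward(x[i:i + 1]).data for i in range(2)])
        np.testing.assert_allclose(stacked, singles, atol=1e-6)

    def test_build_determinism(self):
        a = build_model(tiny_config(), seed=7)
        b = build_model(tiny_config(), seed=7)
        assert a.n_parameters() == b.n_parameters()
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            assert np.array_equal(pa.data, pb.data)

    def test_wrong_input_channels_rejected(self):
        m = build_model(tiny_config())
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 3, 40, 64), np.float32))

    def test_single_step_reduces_sample_loss(self, rng):
        from stecg.train import focal_loss

        m = build_model(tiny_config(), seed=0)
        m.seed_rng(0)
        m.train(False)  # freeze stochastic regularizers for the smoke check
        x = nn.Tensor(rng.standard_normal((1, 2, 40, 64)).astype(np.float32))
        y = np.array([1])
        opt = nn.RAdam(m.parameters(), lr=1e-3)
        losses = []
        for _ in range(8):
            opt.zero_grad()
            loss = focal_loss(m(x), y)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0]

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = build_model(tiny_config(), seed=3).eval()
        x = rng.standard_normal((2, 2, 40, 64)).astype(np.float32)
        before = m.forward(x).data
        save_checkpoint(m, tmp_path / "ckpt.npz")
        m2 = load_checkpoint(tmp_path / "ckpt.npz").eval()
        np.testing.assert_allclose(m2.forward(x).data, before, atol=0)


class TestStochasticDepth:
    def test_droppath_identity_at_eval(self, rng):
        dp = nn.DropPath(0.5)
        dp.train(False)
        x = nn.Tensor(rng.standard_normal((4, 3)))
        assert np.array_equal(dp(x).data, x.data)

    def test_droppath_survival_scaling(self):
        dp = nn.DropPath(0.2)
        dp.rng = np.random.default_rng(0)
        x = nn.Tensor(np.ones((2000, 1)))
        out = dp(x).data
        kept = out[out != 0]
        assert np.allclose(kept, 1 / 0.8)
        assert abs((out != 0).mean() - 0.8) < 0.05
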