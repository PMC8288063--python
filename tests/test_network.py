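"""Encoder/decoder architecture, training loop, and baseline topology."""

import numpy as np
import pytest

from visfill import network as nw
from visfill import synthetic_data as sd


class TestArchitecture:
    def test_default_bottleneck_is_1024(self, default_arch):
        # shape algebra: the bottleneck flattens to 1x1x1024, the minimum
        # over all analyzed layers
        from visfill.nn import conv_out_size, tconv_out_size

        size = default_arch.input_size
        dims = {}
        for cfg in default_arch.encoder:
            size = conv_out_size(size, cfg.kernel, cfg.stride, cfg.padding)
            dims[cfg.name] = size * size * cfg.out_channels
        for cfg in default_arch.decoder[:-1]:
            size = tconv_out_size(size, cfg.kernel, cfg.stride, cfg.padding)
            dims[cfg.name] = size * size * cfg.out_channels
        assert dims["encoder_8"] == 1024
        assert min(dims.values()) == 1024
        assert min(dims, key=dims.get) == "encoder_8"

    def test_small_net_forward_shapes(self, small_net):
        x = np.zeros((2, 64, 64, 1))
        y, acts = small_net.forward(x)
        assert y.shape == (2, 64, 64, 1)
        assert acts["encoder_6"].shape == (2, 1, 1, 16)   # 1x1 bottleneck
        assert acts["decoder_6"].shape == (2, 64, 64, 1)
        assert all(np.isfinite(a).all() for a in acts.values())

    def test_skip_size_mismatch_names_both_layers(self):
        enc = (nw.ConvLayerCfg("encoder_1", "conv", 4),
               nw.ConvLayerCfg("encoder_2", "conv", 8))
        dec = (nw.ConvLayerCfg("decoder_1", "tconv", 4, skip_source=None),
               nw.ConvLayerCfg("decoder_2", "tconv", 1, activation="sigmoid",
                               norm=False, skip_source="encoder_2"))
        with pytest.raises(ValueError, match="decoder_2.*encoder_2"):
            nw.ArchitectureConfig(16, 1, enc, dec).validate()

    def test_deterministic_activations(self, small_arch):
        a = nw.EncoderDecoder(small_arch, seed=3)
        b = nw.EncoderDecoder(small_arch, seed=3)
        x = np.random.default_rng(0).random((2, 64, 64, 1))
        ya, acts_a = a.forward(x)
        yb, acts_b = b.forward(x)
        assert np.array_equal(ya, yb)
        for k in acts_a:
            assert np.array_equal(acts_a[k], acts_b[k])

    def test_weight_roundtrip(self, small_arch, tmp_path):
        a = nw.EncoderDecoder(small_arch, seed=1)
        a.save_weights(tmp_path / "w.npz")
        b = nw.EncoderDecoder(small_arch, seed=2)
        b.load_weights(tmp_path / "w.npz")
        x = np.random.default_rng(0).random((1, 64, 64, 1))
        assert np.array_equal(a.forward(x)[0], b.forward(x)[0])


class TestAnalyzedLayers:
    def test_default_has_fifteen(self, default_arch):
        layers = nw.analyzed_layers(default_arch)
        assert len(layers) == 15
        names = [n for n, _ in layers]
        assert names[:8] == [f"encoder_{i}" for i in range(1, 9)]
        assert names[8:] == [f"decoder_{i}" for i in range(1, 8)]  # output excluded

    def test_two_plus_two_config_gives_three(self):
        cfg = nw.default_architecture(4, encoder_channels=(2, 4))
        assert len(nw.analyzed_layers(cfg)) == 3

    def test_section_tags_match_rf_classification(self, default_arch):
        from visfill import rf_geometry as rfg

        spec = nw.encoder_rf_spec(default_arch)
        grids = nw.decoder_grids(default_arch)
        grids.pop("decoder_8")
        labels = rfg.classify_sections(spec, grids, 256)
        assert dict(nw.analyzed_layers(default_arch)) == labels


class TestSkipIntegrity:
    def test_zeroing_encoder_activation_changes_skip_target(self, small_arch):
        net = nw.EncoderDecoder(small_arch, seed=0)
        x = np.random.default_rng(1).random((1, 64, 64, 1))
        _, base = net.forward(x)

        class Zero:
            def forward(self, h, training=False):
                return np.zeros_like(h)

            def backward(self, dy):
                return dy

        # decoder_2's input concatenates encoder_5; silence encoder_5
        orig = net.blocks["encoder_5"]["act"]
        net.blocks["encoder_5"]["act"] = Zero()
        try:
            _, mod = net.forward(x)
        finally:
            net.blocks["encoder_5"]["act"] = orig
        assert not np.allclose(base["decoder_2"], mod["decoder_2"])


class TestTraining:
    def test_config_validation(self):
        nw.TrainingConfig(epochs=5, batch_size=5)  # the reference setting
        with pytest.raises(ValueError):
            nw.TrainingConfig(epochs=0)
        with pytest.raises(ValueError):
            nw.TrainingConfig(batch_size=0)

    def test_white_target_loss_collapses(self):
        cfg = nw.default_architecture(16, encoder_channels=(4, 8), dropout=0.0)
        net = nw.EncoderDecoder(cfg, seed=0)
        imgs = np.ones((10, 16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[8:, 8:] = True
        tc = nw.TrainingConfig(epochs=8, batch_size=5, learning_rate=0.01, seed=0)
        trace = nw.train_inpainting(net, imgs, imgs, mask, tc)
        assert trace["epoch_loss"][-1] < 0.05

    def test_loss_trace_recorded_per_epoch(self, scene_set_small):
        cfg = nw.default_architecture(64, encoder_channels=(4, 8, 8), dropout=0.2)
        net = nw.EncoderDecoder(cfg, seed=0)
        tc = nw.TrainingConfig(epochs=2, batch_size=4, dropout=0.2, seed=0)
        trace = nw.train_inpainting(net, scene_set_small.occluded_images(),
                                    scene_set_small.images,
                                    scene_set_small.occluder_mask, tc,
                                    holdout=(scene_set_small.occluded_images()[:4],
                                             scene_set_small.images[:4]))
        assert len(trace["epoch_loss"]) == 2
        assert len(trace["holdout_error"]) == 3   # before training + per epoch
        assert np.all(np.isfinite(trace["epoch_loss"]))

    def test_divergence_aborts_with_diagnostic(self, scene_set_small):
        cfg = nw.default_architecture(64, encoder_channels=(4, 8))
        net = nw.EncoderDecoder(cfg, seed=0)
        net.params()[0].value[...] = np.nan
        tc = nw.TrainingConfig(epochs=1, batch_size=4, seed=0)
        with pytest.raises(nw.TrainingDiverged, match="epoch 1"):
            nw.train_inpainting(net, scene_set_small.occluded_images(),
                                scene_set_small.images,
                                scene_set_small.occluder_mask, tc)

    def test_adversarial_head_smoke(self):
        cfg = nw.default_architecture(16, encoder_channels=(4, 8))
        net = nw.EncoderDecoder(cfg, seed=0)
        imgs = np.random.default_rng(0).random((6, 16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[8:, 8:] = True
        tc = nw.TrainingConfig(loss="l1+adversarial", epochs=1, batch_size=3, seed=0)
        trace = nw.train_inpainting(net, imgs, imgs, mask, tc)
        assert np.isfinite(trace["epoch_loss"][0])


class TestForwardCollect:
    def test_image_major_storage(self, small_net, scene_set_small):
        acts = nw.forward_collect(small_net, scene_set_small.images, batch_size=5)
        assert len(acts) == 11   # 6 encoder + 5 analyzed decoder layers
        for v in acts.values():
            assert v.shape[0] == 12

    def test_repeat_calls_bitwise_identical(self, small_net, rng):
        x = rng.random((3, 64, 64))
        a = nw.forward_collect(small_net, x, ["decoder_3"])
        b = nw.forward_collect(small_net, x, ["decoder_3"])
        assert np.array_equal(a["decoder_3"], b["decoder_3"])

    def test_unknown_layer_lists_valid_names(self, small_net):
        with pytest.raises(KeyError, match="encoder_1"):
            nw.forward_collect(small_net, np.zeros((1, 64, 64)), ["bogus"])


class TestVGGBaseline:
    def test_standard_topology_gives_five_block_final_convs(self):
        names = nw.vgg_analysis_layers(nw.vgg16_topology())
        assert names == ["conv1_2", "conv2_2", "conv3_3", "conv4_3", "conv5_3"]

    def test_single_block_topology(self):
        topo = [{"name": "conv1_1", "kind": "conv", "out_channels": 4},
                {"name": "pool1", "kind": "pool"}]
        assert nw.vgg_analysis_layers(topo) == ["conv1_1"]

    def test_matches_mechanical_block_rule(self):
        topo = nw.vgg16_topology()
        expected, block = [], []
        for e in topo:
            if e["kind"] == "conv":
                block.append(e["name"])
            else:
                expected.append(block[-1])
                block = []
        assert nw.vgg_analysis_layers(topo) == expected

    def test_topology_without_pooling_rejected(self):
        with pytest.raises(ValueError):
            nw.vgg_analysis_layers([{"name": "conv1_1", "kind": "conv", "out_channels": 4}])

    def test_forward_collect_shapes(self, rng):
        topo = nw.vgg16_topology(channel_scale=1 / 16)
        net = nw.build_vgg(topo, seed=0)
        acts = nw.vgg_forward_collect(net, rng.random((2, 64, 64)),
                                      ["conv1_2", "conv3_3"])
        assert acts["conv1_2"].shape == (2, 64, 64, 4)
        assert acts["conv3_3"].shape == (2, 16, 16, 16)
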