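import math

import numpy as np
import pytest
from scipy.special import logsumexp

from gaze3 import autograd as ag
from gaze3.data_io import Fixation, Scanpath
from gaze3.density import normalize_log_density
from gaze3.history import build_history_stack
from gaze3.readout import (ModelConfig, ScanpathModel, constant_backbone,
                           count_parameters, desk_model_config, init_params,
                           load_params, pack_histories, save_params,
                           sn_forward, spn_forward, toy_backbone)

TOY = ModelConfig(k=2, d=1, backbone_channels=4, downsample=2,
                  sn_slot_channels=8, sn_out_channels=4, fsn_hidden=(8, 4))


@pytest.fixture
def toy_model():
    return ScanpathModel(TOY, seed=1)


@pytest.fixture
def toy_image(rng):
    return rng.uniform(size=(16, 16))


@pytest.fixture
def toy_scanpath():
    return Scanpath("a", "s", [Fixation(7, 7, True), Fixation(3, 4),
                               Fixation(10, 2), Fixation(5, 12)])


log_cb_16 = np.log(np.full((16, 16), 1 / 256.0))


class TestParameterCounting:
    def test_standard_first_priority_layer_count(self):
        # 2*2048 normalization scalars + 2048*8 weights + 8 biases
        assert count_parameters(ModelConfig())["first_spn_layer"] == 20488

    def test_toy_first_layer_hand_count(self):
        cfg = ModelConfig(backbone_channels=4)
        assert count_parameters(cfg)["first_spn_layer"] == 2 * 4 + 4 * 8 + 8

    def test_scanpath_network_count_from_layer_plan(self):
        # 4 slot convs (3->128 + bias) + norm(128) + conv 128->16 + bias
        counts = count_parameters(ModelConfig())
        assert counts["modules"]["sn"] == \
            4 * (3 * 128 + 128) + 2 * 128 + (128 * 16 + 16) == 4368

    def test_ablated_configs_drop_scanpath_parameters(self):
        assert count_parameters(ModelConfig(k=0))["modules"]["sn"] == 0
        assert count_parameters(
            ModelConfig(include_scanpath=False))["modules"]["sn"] == 0

    def test_count_matches_instantiated_parameters(self):
        for cfg in (TOY, desk_model_config(), ModelConfig(include_image=False)):
            params = init_params(cfg, np.random.default_rng(0))
            n = sum(p.data.size for p in params.values())
            assert n == count_parameters(cfg)["total"]


class TestSpatialPriorityNetwork:
    def test_zero_weights_give_softplus_zero_constant(self):
        params = init_params(TOY, np.random.default_rng(0))
        for name, t in params.items():
            if name.startswith("spn") and name.endswith((".w", ".b")):
                t.data[:] = 0.0
        feats = ag.Tensor(np.random.default_rng(1).normal(size=(4, 10)))
        out = spn_forward(params, TOY, feats)
        assert np.allclose(out.data, math.log(2.0))

    def test_output_shape_has_d_channels(self):
        cfg = ModelConfig(d=3, backbone_channels=4, sn_slot_channels=8,
                          fsn_hidden=(8, 4))
        params = init_params(cfg, np.random.default_rng(0))
        out = spn_forward(params, cfg,
                          ag.Tensor(np.random.default_rng(1).normal(size=(4, 6))))
        assert out.shape == (3, 6)
        assert np.all(out.data >= 0.0)  # softplus range

    def test_invariant_to_global_affine_rescaling_of_features(self, rng):
        params = init_params(TOY, rng)
        feats = rng.normal(size=(4, 12))
        a = spn_forward(params, TOY, ag.Tensor(feats)).data
        b = spn_forward(params, TOY, ag.Tensor(2.5 * feats - 1.3)).data
        assert np.allclose(a, b, atol=1e-9)


class TestScanpathNetwork:
    def test_all_absent_slots_give_constant_map(self, toy_model):
        hs = build_history_stack(
            Scanpath("i", "s", [Fixation(1, 1)]), 1, TOY.k, (4, 4))
        hs.mask[:] = False
        hs.maps[:] = 0.0
        slots, mask = pack_histories([hs], TOY.k, 16)
        out = sn_forward(toy_model.params, TOY, slots, mask)
        assert np.allclose(out.data, out.data[:, :1])

    def test_masked_duplicate_slot_changes_nothing(self, toy_model):
        sp = Scanpath("i", "s", [Fixation(1, 1), Fixation(2, 3)])
        hs1 = build_history_stack(sp, 2, TOY.k, (4, 4))
        hs2 = build_history_stack(sp, 2, TOY.k, (4, 4))
        assert hs2.mask.tolist() == [True, True]
        hs2.mask[1] = False  # mask out the older fixation but keep its maps
        hs2.maps[1] = hs2.maps[0]
        hs1.mask[1] = False
        hs1.maps[1] = 0.0
        s1, m1 = pack_histories([hs1], TOY.k, 16)
        s2, m2 = pack_histories([hs2], TOY.k, 16)
        a = sn_forward(toy_model.params, TOY, s1, m1).data
        b = sn_forward(toy_model.params, TOY, s2, m2).data
        assert np.allclose(a, b)


class TestPredictConditional:
    def test_output_is_normalized_for_random_parameters(self, toy_image,
                                                        toy_scanpath):
        for seed in range(10):
            m = ScanpathModel(TOY, seed=seed)
            d = m.predict_conditional(toy_image, toy_scanpath, 2, log_cb_16)
            assert abs(logsumexp(d.values)) < 1e-6

    def test_order_zero_model_ignores_history(self, toy_image, rng):
        cfg = ModelConfig(k=0, backbone_channels=4, downsample=2,
                          fsn_hidden=(8, 4))
        m = ScanpathModel(cfg, seed=2)
        sp1 = Scanpath("a", "s", [Fixation(7, 7, True), Fixation(1, 1),
                                  Fixation(2, 2)])
        sp2 = Scanpath("a", "s", [Fixation(7, 7, True), Fixation(14, 14),
                                  Fixation(3, 9)])
        d1 = m.predict_conditional(toy_image, sp1, 2, log_cb_16)
        d2 = m.predict_conditional(toy_image, sp2, 2, log_cb_16)
        assert np.allclose(d1.values, d2.values)

    def test_order_k_contract_ignores_older_fixations(self, toy_image):
        m = ScanpathModel(TOY, seed=3)  # k = 2
        base = [Fixation(7, 7, True), Fixation(2, 2), Fixation(4, 9),
                Fixation(11, 5)]
        altered = [Fixation(1, 13, True), Fixation(2, 2), Fixation(4, 9),
                   Fixation(11, 5)]
        d1 = m.predict_conditional(toy_image, Scanpath("a", "s", base), 3,
                                   log_cb_16)
        d2 = m.predict_conditional(toy_image, Scanpath("a", "s", altered), 3,
                                   log_cb_16)
        assert np.allclose(d1.values, d2.values)
        # but altering a fixation within the window does change the density
        near = [Fixation(7, 7, True), Fixation(2, 2), Fixation(12, 1),
                Fixation(11, 5)]
        d3 = m.predict_conditional(toy_image, Scanpath("a", "s", near), 3,
                                   log_cb_16)
        assert not np.allclose(d1.values, d3.values)

    def test_fully_ablated_model_reduces_to_center_bias(self, rng):
        cfg = ModelConfig(k=0, include_image=False, include_scanpath=False,
                          downsample=2, fsn_hidden=(8, 4))
        m = ScanpathModel(cfg, seed=0)
        m.params["cb_weight"].data = np.array(1.0)
        log_cb = np.log(rng.dirichlet(np.ones(256)).reshape(16, 16))
        sp = Scanpath("a", "s", [Fixation(7, 7, True), Fixation(3, 3)])
        d = m.predict_conditional(rng.uniform(size=(16, 16)), sp, 1, log_cb)
        assert np.allclose(d.values, normalize_log_density(log_cb).values,
                           atol=1e-9)

    def test_initial_fixation_has_no_prediction(self, toy_model, toy_image,
                                                toy_scanpath):
        with pytest.raises(ValueError):
            toy_model.predict_conditional(toy_image, toy_scanpath, 0, log_cb_16)
        with pytest.raises(ValueError):
            toy_model.predict_conditional(toy_image, toy_scanpath, 1, None)


class TestGradientCorrectness:
    def test_objective_gradient_matches_finite_differences(self, toy_image,
                                                           toy_scanpath):
        """Central finite differences on a slice of named parameters."""
        m = ScanpathModel(TOY, seed=4)
        m.params["sigma_raw"].data = np.array(math.log(1.7))  # off kernel-radius kinks
        feats = m.backbone.apply(toy_image)
        hists = [build_history_stack(toy_scanpath, i, TOY.k, feats.shape[1:],
                                     downsample=TOY.downsample)
                 for i in (1, 2, 3)]
        targets = [4 * 16 + 3, 2 * 16 + 10, 12 * 16 + 5]

        def loss():
            out = m.log_density_batch(feats, hists, log_cb_16)
            return ag.gather_rows(out, targets).mean() * (-1.0)

        L = loss()
        L.backward()
        rng = np.random.default_rng(0)
        names = ["spn.0.conv.w", "spn.1.norm.scale", "sn.slot0.conv.w",
                 "fsn.2.conv.w", "sigma_raw"]
        for name in names:
            p = m.params[name]
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            g_an = p.grad[idx]
            eps = 1e-6
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = loss().item()
            p.data[idx] = orig - eps
            lm = loss().item()
            p.data[idx] = orig
            g_fd = (lp - lm) / (2 * eps)
            assert abs(g_an - g_fd) / max(abs(g_fd), 1e-8) < 1e-4, name


class TestToyBackbone:
    def test_deterministic_given_seed(self, toy_image):
        a = toy_backbone(5, 8, 4).apply(toy_image)
        b = toy_backbone(5, 8, 4).apply(toy_image)
        assert np.array_equal(a, b)

    def test_constant_image_gives_constant_features(self):
        feats = toy_backbone(0, 8, 4).apply(np.full((64, 64), 0.5))
        assert np.allclose(feats, feats[:, :1, :1])

    def test_shapes(self):
        feats = toy_backbone(0, 8, 4).apply(np.zeros((64, 64)))
        assert feats.shape == (8, 16, 16)
        assert constant_backbone(4).apply(np.zeros((30, 30))).shape == (1, 8, 8)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_everything(self, tmp_path, toy_model):
        save_params(toy_model.params, TOY, tmp_path / "ck.h5")
        params, cfg = load_params(tmp_path / "ck.h5")
        assert cfg == TOY
        assert set(params) == set(toy_model.params)
        for name in params:
            assert np.array_equal(params[name].data,
                                  toy_model.params[name].data)
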