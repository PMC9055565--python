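import numpy as np
import pytest
from scipy.special import logsumexp

from gaze3.baselines import (GoldStandardModel, KDEConfig,
                             UniformModel, fit_center_bias,
                             gold_standard_density, kde_accumulate)
from gaze3.data_io import Fixation, Scanpath, ScanpathSet
from gaze3.density import uniform_log_density
from gaze3.evaluation import average_loglik_bits, per_fixation_scores
from gaze3.synthetic import PlantedConfig, generate_scanpaths


def clustered_set(n_images=4, n_subjects=3, shape=(16, 16), spread=1.0,
                  seed=0):
    """Fixations concentrated near the grid center."""
    rng = np.random.default_rng(seed)
    h, w = shape
    scanpaths = []
    for i in range(n_images):
        for s in range(n_subjects):
            fx = [Fixation(w / 2, h / 2, forced=True)]
            for _ in range(4):
                x = float(np.clip(rng.normal(w / 2, spread), 0, w - 1e-6))
                y = float(np.clip(rng.normal(h / 2, spread), 0, h - 1e-6))
                fx.append(Fixation(x, y))
            scanpaths.append(Scanpath(f"im{i}", f"s{s}", fx))
    return ScanpathSet(stimuli={f"im{i}": (w, h, None) for i in range(n_images)},
                       scanpaths=scanpaths)


class TestUniformModel:
    def test_table_row_anchors(self, tiny_set):
        model = UniformModel({"img000": (32, 32)})
        scores = per_fixation_scores(model, tiny_set)
        assert np.allclose(scores["ll"], 0.0)
        assert np.allclose(scores["auc"], 0.5)
        assert np.allclose(scores["nss"], 0.0)


class TestCenterBias:
    def test_concentrated_data_peaks_at_center(self):
        sset = clustered_set(spread=0.5)
        fit = fit_center_bias(sset, bandwidths=[1.0], epsilons=[0.01])
        grid = fit.pooled_grid((16, 16))
        r, c = np.unravel_index(np.argmax(grid.values), (16, 16))
        assert (r, c) == (8, 8)

    def test_epsilon_one_is_uniform(self):
        sset = clustered_set()
        fit = fit_center_bias(sset, bandwidths=[2.0], epsilons=[1.0])
        grid = fit.pooled_grid((16, 16))
        assert np.allclose(grid.values, uniform_log_density((16, 16)).values)

    def test_mixture_floor_bounds_minimum_probability(self):
        sset = clustered_set(spread=0.5)
        eps = 0.1
        fit = fit_center_bias(sset, bandwidths=[0.8], epsilons=[eps])
        p = fit.pooled_grid((16, 16)).probabilities()
        assert p.min() >= eps / 256 * (1 - 1e-9)

    def test_single_image_rejected(self):
        sset = clustered_set(n_images=1)
        with pytest.raises(ValueError):
            fit_center_bias(sset)

    def test_leave_one_image_out_contract(self):
        """Perturbing one image's fixations never changes its own prediction."""
        base = clustered_set(n_images=4, seed=0)
        # move all of im0's free fixations into a corner
        moved = []
        for sp in base.scanpaths:
            if sp.image_id == "im0":
                fx = [sp.fixations[0]] + [Fixation(1.0, 1.0)
                                          for _ in sp.fixations[1:]]
                moved.append(Scanpath(sp.image_id, sp.subject_id, fx))
            else:
                moved.append(sp)
        perturbed = ScanpathSet(stimuli=dict(base.stimuli), scanpaths=moved)
        f1 = fit_center_bias(base, bandwidths=[1.5], epsilons=[0.05])
        f2 = fit_center_bias(perturbed, bandwidths=[1.5], epsilons=[0.05])
        assert np.allclose(f1.loo["im0"].values, f2.loo["im0"].values)
        assert not np.allclose(f1.loo["im1"].values, f2.loo["im1"].values)


class TestGoldStandard:
    def make_inputs(self):
        sset = clustered_set(n_images=3, n_subjects=4, spread=2.0, seed=3)
        cb = fit_center_bias(sset, bandwidths=[2.0], epsilons=[0.05])
        return sset, cb

    def test_zero_kde_weight_reduces_to_cb_uniform_mixture(self):
        sset, cb = self.make_inputs()
        cfg = KDEConfig(bandwidth=1.0, weights=(0.0, 0.7, 0.3))
        d = gold_standard_density("im0", sset, cb.pooled_grid((16, 16)), cfg)
        expect = 0.7 * cb.pooled_grid((16, 16)).probabilities() + 0.3 / 256
        assert np.allclose(d.probabilities(), expect / expect.sum())

    def test_pure_tiny_bandwidth_kde_peaks_at_single_fixation(self):
        sp = Scanpath("im", "s1", [Fixation(8, 8, forced=True),
                                   Fixation(3.0, 12.0)])
        others = ScanpathSet(stimuli={"im": (16, 16, None)}, scanpaths=[sp])
        cb = uniform_log_density((16, 16))
        cfg = KDEConfig(bandwidth=0.3, weights=(1.0, 0.0, 0.0))
        d = gold_standard_density("im", others, cb, cfg)
        r, c = np.unravel_index(np.argmax(d.values), (16, 16))
        assert (r, c) == (12, 3)

    def test_normalized_for_random_simplex_weights(self, rng):
        sset, cb = self.make_inputs()
        for _ in range(20):
            w = rng.dirichlet(np.ones(3))
            cfg = KDEConfig(bandwidth=1.5, weights=tuple(w))
            d = gold_standard_density("im1", sset, cb.pooled_grid((16, 16)),
                                      cfg)
            assert abs(logsumexp(d.values)) < 1e-6

    def test_no_other_subject_data_rejected(self):
        sset, cb = self.make_inputs()
        empty = ScanpathSet(stimuli=dict(sset.stimuli), scanpaths=[])
        cfg = KDEConfig(bandwidth=1.0, weights=(0.5, 0.3, 0.2))
        with pytest.raises(ValueError):
            gold_standard_density("im0", empty, cb.pooled_grid((16, 16)), cfg)

    def test_leave_one_subject_out_contract(self):
        sset, cb = self.make_inputs()
        cfg = KDEConfig(bandwidth=1.0, weights=(0.8, 0.1, 0.1))
        model = GoldStandardModel(sset, cb, cfg)
        sp0 = next(s for s in sset.scanpaths if s.subject_id == "s0"
                   and s.image_id == "im0")
        d = model.conditional(sp0, 1)
        # move s0's own fixations: the prediction for s0 must not change
        moved = []
        for sp in sset.scanpaths:
            if sp.subject_id == "s0" and sp.image_id == "im0":
                fx = [sp.fixations[0]] + [Fixation(0.5, 0.5)
                                          for _ in sp.fixations[1:]]
                moved.append(Scanpath(sp.image_id, sp.subject_id, fx))
            else:
                moved.append(sp)
        model2 = GoldStandardModel(
            ScanpathSet(stimuli=dict(sset.stimuli), scanpaths=moved), cb, cfg)
        d2 = model2.conditional(moved[0] if moved[0].subject_id == "s0"
                                else sp0, 1)
        assert np.allclose(d.values, d2.values)


def test_fit_gold_standard_selects_a_valid_config():
    from gaze3.baselines import fit_gold_standard

    sset = clustered_set(n_images=3, n_subjects=3, spread=1.5, seed=5)
    cb = fit_center_bias(sset, bandwidths=[1.5], epsilons=[0.05])
    cfg = fit_gold_standard(sset, cb, bandwidths=[1.0, 2.0],
                            weight_candidates=[(0.5, 0.3, 0.2),
                                               (0.1, 0.6, 0.3)])
    assert cfg.weights is not None
    assert sum(cfg.weights) == pytest.approx(1.0)
    assert cfg.bandwidth in (1.0, 2.0)


def test_model_hierarchy_on_planted_data():
    """Gold standard >= center bias >= uniform LL on concentrated data."""
    cfg = PlantedConfig(shape=(16, 16), n_bumps=2, seed=4)
    _, _, sset = generate_scanpaths(cfg, 8, 6, 6, seed=4)
    cb = fit_center_bias(sset, bandwidths=[1.0, 2.0, 4.0],
                         epsilons=[0.01, 0.1])
    gold_cfg = KDEConfig(bandwidth=1.5, weights=(0.6, 0.3, 0.1))
    gold = GoldStandardModel(sset, cb, gold_cfg)
    shapes = {i: sset.shape_of(i) for i in sset.image_ids()}
    ll_u = average_loglik_bits(UniformModel(shapes), sset)
    ll_cb = average_loglik_bits(cb, sset)
    ll_gold = average_loglik_bits(gold, sset)
    assert ll_u == pytest.approx(0.0)
    assert ll_cb > ll_u
    assert ll_gold > ll_cb
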