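import math

import numpy as np
import pytest

from gaze3.data_io import Fixation, Scanpath, ScanpathSet, ScreenGeometry
from gaze3.density import LogDensityGrid, normalize_log_density
from gaze3.sampling import (amplitude_autocorrelation, amplitude_histogram,
                            compute_stats, direction_histogram,
                            intersaccade_angle_histogram, matched_sample_set,
                            relative_saccade_histogram, sample_scanpath,
                            transform_pair)


class DegenerateModel:
    """All conditional mass on one cell."""

    def __init__(self, cell=(2, 3), shape=(8, 8)):
        v = np.full(shape, -np.inf)
        v[cell] = 0.0
        self.grid = LogDensityGrid(v)

    def conditional(self, sp, i):
        return self.grid


class PlantedModel:
    def __init__(self, seed=0, shape=(8, 8)):
        self.grid = normalize_log_density(
            np.random.default_rng(seed).normal(size=shape))

    def conditional(self, sp, i):
        return self.grid


def path_set(paths, shape=(32, 32), ppd=1.0):
    stimuli = {sp.image_id: (shape[1], shape[0], None) for sp in paths}
    return ScanpathSet(stimuli=stimuli, scanpaths=paths,
                       geometry=ScreenGeometry(ppd))


def make_path(coords, image_id="im", subject="s"):
    return Scanpath(image_id, subject,
                    [Fixation(float(x), float(y)) for x, y in coords])


class TestSampleScanpath:
    def test_degenerate_model_always_lands_on_its_cell(self, rng):
        model = DegenerateModel()
        sp = sample_scanpath(model, make_path([(4, 4)]), Fixation(4, 4, True),
                             5, rng)
        assert len(sp.fixations) == 6
        for f in sp.fixations[1:]:
            assert (f.x, f.y) == (3.0, 2.0)

    def test_same_seed_same_scanpath(self):
        model = PlantedModel()
        a = sample_scanpath(model, make_path([(4, 4)]), Fixation(4, 4, True),
                            6, np.random.default_rng(3))
        b = sample_scanpath(model, make_path([(4, 4)]), Fixation(4, 4, True),
                            6, np.random.default_rng(3))
        assert [(f.x, f.y) for f in a.fixations] == \
            [(f.x, f.y) for f in b.fixations]


class TestMatchedSampleSet:
    def test_preserves_image_f0_and_length(self, rng):
        paths = [make_path([(4, 4), (1, 2), (6, 7)], "imA", "s1"),
                 make_path([(3, 3), (2, 2)], "imB", "s2")]
        sset = path_set(paths, shape=(8, 8))
        out = matched_sample_set(PlantedModel(), sset, rng)
        assert len(out.scanpaths) == 2
        for orig, sampled in zip(sset.scanpaths, out.scanpaths):
            assert sampled.image_id == orig.image_id
            assert len(sampled.fixations) == len(orig.fixations)
            f0o, f0s = orig.fixations[0], sampled.fixations[0]
            assert (f0s.x, f0s.y) == (f0o.x, f0o.y)


class TestAmplitudeAutocorrelation:
    def alternating_set(self):
        # amplitudes 2,1,2,1,... along the x axis
        coords, x = [(0, 0)], 0
        for i in range(10):
            x += 2 if i % 2 == 0 else 1
            coords.append((x, 0))
        return path_set([make_path(coords, subject=f"s{j}") for j in range(3)])

    def test_alternating_amplitudes_lag1_is_minus_one(self):
        assert amplitude_autocorrelation(self.alternating_set(), 1) == \
            pytest.approx(-1.0)

    def test_alternating_amplitudes_lag2_is_plus_one(self):
        assert amplitude_autocorrelation(self.alternating_set(), 2) == \
            pytest.approx(1.0)

    def test_iid_amplitudes_are_uncorrelated(self):
        rng = np.random.default_rng(0)
        paths = []
        for j in range(500):
            coords, x = [(0.0, 0.0)], 0.0
            for _ in range(21):
                x += rng.uniform(0.5, 3.0)
                coords.append((x % 1000, 0.0))
            paths.append(make_path(coords, subject=f"s{j}"))
        sset = path_set(paths, shape=(1, 1001))
        # 500 scanpaths x 20 pairs = 10^4 lag-1 pairs
        assert abs(amplitude_autocorrelation(sset, 1)) < 0.05

    def test_too_few_pairs_rejected(self):
        sset = path_set([make_path([(0, 0), (1, 0)])])
        with pytest.raises(ValueError):
            amplitude_autocorrelation(sset, 1)


class TestRelativeSaccade:
    def test_pure_scaling(self):
        out = transform_pair(np.array([2.0, 0.0]), np.array([1.0, 0.0]))
        assert np.allclose(out, [0.5, 0.0])

    def test_retraced_saccade_maps_to_minus_one_zero(self, rng):
        for _ in range(10):
            u = rng.normal(size=2)
            out = transform_pair(u, -u)
            assert np.allclose(out, [-1.0, 0.0], atol=1e-12)

    def test_downward_previous_rotates_by_minus_ninety(self):
        # previous (0,0)->(0,2) downward on screen, next (0,2)->(1,2)
        sset = path_set([make_path([(0, 0), (0, 2), (1, 2)])])
        u = np.array([0.0, -2.0])  # y-up convention
        v = np.array([1.0, 0.0])
        assert np.allclose(transform_pair(u, v), [0.0, 0.5])

    def test_histogram_mass_and_zero_length_skip(self):
        paths = [make_path([(0, 0), (2, 0), (3, 0)]),
                 make_path([(5, 5), (5, 5), (7, 5)], subject="s2")]
        sset = path_set(paths)
        ex, ey, H = relative_saccade_histogram(sset, window=2.0, bins=9)
        assert H.sum() == pytest.approx(1.0)

    def test_invariance_to_global_rotation_and_scaling(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(5, 25, size=(6, 2))
        theta, scale = 0.7, 2.3
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        transformed = (coords - 15) @ R.T * scale + 60
        a = relative_saccade_histogram(path_set([make_path(coords)]),
                                       window=3, bins=13)
        b = relative_saccade_histogram(
            path_set([make_path(transformed)], shape=(128, 128)),
            window=3, bins=13)
        assert np.allclose(a[2], b[2])


class TestHistograms:
    def test_orthogonal_saccades_give_ninety_degrees(self):
        sset = path_set([make_path([(0, 0), (1, 0), (1, 1)])])
        h = intersaccade_angle_histogram(sset,
                                         bins=np.array([0.0, 85.0, 95.0, 180.0]))
        # all mass in the bin containing 90 degrees
        assert h.density[0] == 0.0 and h.density[2] == 0.0
        assert h.density[1] > 0.0

    def test_same_and_opposite_directions_fold_to_0_and_180(self):
        same = path_set([make_path([(0, 0), (1, 0), (2, 0)])])
        opposite = path_set([make_path([(0, 0), (2, 0), (0, 0)])])
        hs = intersaccade_angle_histogram(same, bins=np.linspace(0, 180, 10))
        ho = intersaccade_angle_histogram(opposite,
                                          bins=np.linspace(0, 180, 10))
        assert hs.density[0] > 0 and np.allclose(hs.density[1:], 0)
        assert ho.density[-1] > 0 and np.allclose(ho.density[:-1], 0)

    def test_single_345_saccade_amplitude_bin(self):
        sset = path_set([make_path([(0, 0), (3, 4)])], ppd=1.0)
        h = amplitude_histogram(sset, bins=np.linspace(0, 10, 11))
        assert np.argmax(h.density) == 5  # the [5, 6) bin
        width = h.edges[1] - h.edges[0]
        assert (h.density * width).sum() == pytest.approx(1.0)

    def test_histograms_integrate_to_one_and_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        paths = [make_path(rng.uniform(2, 30, size=(8, 2)), subject=f"s{j}")
                 for j in range(20)]
        sset = path_set(paths)
        for h in (amplitude_histogram(sset), direction_histogram(sset),
                  intersaccade_angle_histogram(sset)):
            widths = np.diff(h.edges)
            assert (h.density * widths).sum() == pytest.approx(1.0)
            inside = (h.ci_low <= h.density + 1e-12) & \
                     (h.density <= h.ci_high + 1e-12)
            assert inside.mean() > 0.9

    def test_empty_input_rejected(self):
        sset = path_set([make_path([(1, 1)])])
        with pytest.raises(ValueError):
            amplitude_histogram(sset)


def test_compute_stats_bundle_serializes(tmp_path):
    rng = np.random.default_rng(3)
    paths = [make_path(rng.uniform(2, 30, size=(6, 2)), subject=f"s{j}")
             for j in range(10)]
    bundle = compute_stats(path_set(paths))
    bundle.to_json(tmp_path / "stats.json")
    import json

    payload = json.loads((tmp_path / "stats.json").read_text())
    assert set(payload) >= {"amplitude", "direction", "intersaccade_angle",
                            "autocorrelation", "relative_saccade"}
    assert -1.0 <= payload["autocorrelation"]["1"] <= 1.0
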