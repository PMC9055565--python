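"""Probabilistic reference models: uniform, center-bias KDE, gold standard.

The center-bias model predicts fixations on an image from the fixations on
all *other* images (leave-one-image-out pooling), capturing the dataset-wide
tendency to fixate centrally without using image content.  The spatial gold
standard predicts a subject's fixations on an image from the *other
subjects'* fixations on the same image, mixed with the center bias and a
uniform floor — an empirical estimate of how predictable fixations are from
other observers.  All KDEs are evaluated as pixel-cell masses on the grid
and renormalized; kernels are truncated at 4 bandwidths.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .data_io import ScanpathSet
from .density import LogDensityGrid, uniform_log_density


@dataclass(frozen=True)
class KDEConfig:
    """Fitted smoothing parameters of the KDE baselines."""

    bandwidth: float
    epsilon: float = 0.0  # uniform mixture weight
    weights: tuple | None = None  # (w_kde, w_cb, w_unif) for the gold standard

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.weights is not None:
            w = np.asarray(self.weights)
            if w.min() < -1e-12 or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must lie on the simplex")


def kde_accumulate(shape, points, bandwidth: float) -> np.ndarray:
    """Unnormalized sum of truncated Gaussian kernels on the pixel grid."""
    h, w = shape
    out = np.zeros((h, w))
    radius = 4.0 * bandwidth
    inv = 1.0 / (2.0 * bandwidth**2)
    for x, y in points:
        r0, r1 = max(0, int(math.floor(y - radius))), min(h, int(math.ceil(y + radius)) + 1)
        c0, c1 = max(0, int(math.floor(x - radius))), min(w, int(math.ceil(x + radius)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        ys = np.arange(r0, r1, dtype=np.float64)[:, None]
        xs = np.arange(c0, c1, dtype=np.float64)[None, :]
        out[r0:r1, c0:c1] += np.exp(-((xs - x) ** 2 + (ys - y) ** 2) * inv)
    return out


def _mix_uniform(kde_sum: np.ndarray, epsilon: float) -> LogDensityGrid:
    h, w = kde_sum.shape
    total = kde_sum.sum()
    if total <= 0:
        p = np.full((h, w), 1.0 / (h * w))
    else:
        p = (1.0 - epsilon) * kde_sum / total + epsilon / (h * w)
    return LogDensityGrid(np.log(np.maximum(p, 1e-300)) - math.log(p.sum()))


# --------------------------------------------------------------------------
class UniformModel:
    """Fixations independently uniform over the image."""

    name = "uniform"

    def __init__(self, shapes: dict):
        self._grids = {img: uniform_log_density(shape)
                       for img, shape in shapes.items()}

    def conditional(self, sp, i) -> LogDensityGrid:
        return self._grids[sp.image_id]


@dataclass
class CenterBiasFit:
    """Fitted center-bias model: pooled grid plus leave-one-image-out grids."""

    config: KDEConfig
    pooled: dict  # shape -> LogDensityGrid over all training fixations
    loo: dict  # image_id -> LogDensityGrid excluding that image's fixations
    shape_of: dict  # image_id -> shape

    name = "center_bias"

    def conditional(self, sp, i) -> LogDensityGrid:
        """LOO prediction when the center bias is itself the evaluated model."""
        grid = self.loo.get(sp.image_id)
        if grid is None:
            grid = self.pooled[self.shape_of.get(sp.image_id,
                                                 next(iter(self.pooled)))]
        return grid

    def pooled_grid(self, shape) -> LogDensityGrid:
        return self.pooled[tuple(shape)]


def _free_points(sset: ScanpathSet, image_id=None):
    pts = []
    for sp in sset.scanpaths:
        if image_id is not None and sp.image_id != image_id:
            continue
        for i, f in enumerate(sp.fixations):
            if i == 0 and f.forced:
                continue
            pts.append((f.x, f.y))
    return pts


def fit_center_bias(train: ScanpathSet, bandwidths=None,
                    epsilons=None) -> CenterBiasFit:
    """Fit KDE bandwidth and uniform weight by maximum leave-one-image-out LL.

    For each candidate (bandwidth, epsilon) the prediction for image j pools
    the free fixations of every other image; the pair maximizing the
    image-averaged log-likelihood is kept.
    """
    images = train.image_ids()
    if len(images) < 2:
        raise ValueError("center-bias fit needs at least two images")
    shapes = {img: train.shape_of(img) for img in images}
    if len(set(shapes.values())) != 1:
        raise ValueError("center-bias fit expects one canonical image shape")
    shape = next(iter(set(shapes.values())))
    h, w = shape
    if bandwidths is None:
        bandwidths = np.geomspace(1.0, min(h, w) / 2.0, 6)
    if epsilons is None:
        epsilons = (0.001, 0.01, 0.05, 0.1, 0.25, 0.5)

    pts_by_image = {img: _free_points(train, img) for img in images}
    cells_by_image = {
        img: [(min(int(y), h - 1), min(int(x), w - 1))
              for x, y in pts_by_image[img]]
        for img in images
    }

    best = None
    for bw in bandwidths:
        per_img = {img: kde_accumulate(shape, pts_by_image[img], bw)
                   for img in images}
        total = sum(per_img.values())
        for eps in epsilons:
            ll_sum = 0.0
            for img in images:
                loo = total - per_img[img]
                grid = _mix_uniform(loo, eps)
                cells = cells_by_image[img]
                if not cells:
                    continue
                vals = [grid.values[r, c] for r, c in cells]
                ll_sum += (np.mean(vals) + math.log(h * w)) / math.log(2)
            ll = ll_sum / len(images)
            if best is None or ll > best[0]:
                best = (ll, bw, eps, per_img, total)

    _, bw, eps, per_img, total = best
    cfg = KDEConfig(bandwidth=float(bw), epsilon=float(eps))
    pooled = {shape: _mix_uniform(total, eps)}
    loo = {img: _mix_uniform(total - per_img[img], eps) for img in images}
    return CenterBiasFit(config=cfg, pooled=pooled, loo=loo, shape_of=shapes)


# --------------------------------------------------------------------------
def gold_standard_density(image_id: str, others: ScanpathSet,
                          cb: LogDensityGrid, cfg: KDEConfig) -> LogDensityGrid:
    """Cross-subject mixture density for one image.

    ``others`` must already be restricted to the *other* subjects'
    scanpaths; their fixations feed the KDE component, mixed with the
    center bias and a uniform floor by the simplex weights in ``cfg``.
    """
    if cfg.weights is None:
        raise ValueError("gold standard needs simplex mixture weights")
    pts = _free_points(others, image_id)
    if not pts:
        raise ValueError(f"no other-subject fixations for image {image_id!r}")
    w_kde, w_cb, w_unif = cfg.weights
    h, w = cb.shape
    kde_sum = kde_accumulate((h, w), pts, cfg.bandwidth)
    total = kde_sum.sum()
    p_kde = kde_sum / total if total > 0 else np.full((h, w), 1.0 / (h * w))
    p = w_kde * p_kde + w_cb * cb.probabilities() + w_unif / (h * w)
    return LogDensityGrid(np.log(np.maximum(p, 1e-300)) - math.log(p.sum()))


class GoldStandardModel:
    """Leave-one-subject-out cross-subject predictor."""

    name = "gold_standard"

    def __init__(self, sset: ScanpathSet, cb_fit: CenterBiasFit, cfg: KDEConfig):
        self.sset = sset
        self.cb_fit = cb_fit
        self.cfg = cfg
        self._cache = {}

    def conditional(self, sp, i) -> LogDensityGrid:
        key = (sp.image_id, sp.subject_id)
        if key not in self._cache:
            others = ScanpathSet(
                stimuli=self.sset.stimuli,
                scanpaths=[s for s in self.sset.scanpaths
                           if s.image_id == sp.image_id
                           and s.subject_id != sp.subject_id],
                geometry=self.sset.geometry,
            )
            cb = self.cb_fit.pooled_grid(self.sset.shape_of(sp.image_id))
            self._cache[key] = gold_standard_density(sp.image_id, others, cb,
                                                     self.cfg)
        return self._cache[key]


def fit_gold_standard(sset: ScanpathSet, cb_fit: CenterBiasFit,
                      bandwidths=None, weight_candidates=None) -> KDEConfig:
    """Select gold-standard bandwidth and mixture weights by LOSO likelihood."""
    shape = sset.shape_of(sset.image_ids()[0])
    h, w = shape
    if bandwidths is None:
        bandwidths = np.geomspace(1.0, min(h, w) / 4.0, 4)
    if weight_candidates is None:
        grid = (0.1, 0.3, 0.5, 0.7, 0.9)
        weight_candidates = [
            (a, b, 1.0 - a - b)
            for a, b in itertools.product(grid, grid)
            if a + b < 0.999
        ]
    best = None
    for bw in bandwidths:
        for weights in weight_candidates:
            cfg = KDEConfig(bandwidth=float(bw), weights=weights)
            model = GoldStandardModel(sset, cb_fit, cfg)
            from .evaluation import average_loglik_bits

            try:
                ll = average_loglik_bits(model, sset)
            except ValueError:
                continue
            if best is None or ll > best[0]:
                best = (ll, cfg)
    return best[1]
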