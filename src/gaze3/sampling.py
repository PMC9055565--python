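"""Scanpath sampling and saccade-statistics suite.

Sampling follows the chain rule: starting from the forced initial
fixation, each next fixation is drawn from the model's conditional density
given the history sampled so far.  The statistics suite summarizes sets of
scanpaths by saccade amplitude, direction, the angle between consecutive
saccades, amplitude autocorrelation, and the distribution of the next
saccade in the coordinate frame of the previous one (where return saccades
land at (-1, 0)).  Confidence intervals bootstrap over scanpaths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import Fixation, Scanpath, ScanpathSet, ScreenGeometry, saccade_vector
from .density import sample_fixation

logger = logging.getLogger(__name__)


def sample_scanpath(model, sp_template: Scanpath, f0: Fixation, n_fix: int,
                    rng: np.random.Generator) -> Scanpath:
    """Sample a scanpath of ``n_fix`` fixations after the given f0.

    ``model`` follows the conditional protocol (``model.conditional(sp, i)``);
    the growing sampled scanpath itself is passed as conditioning history.
    """
    if n_fix < 1:
        raise ValueError("need at least one fixation to sample")
    out = Scanpath(sp_template.image_id, sp_template.subject_id, [f0])
    for i in range(1, n_fix + 1):
        d = model.conditional(out, i)
        out.fixations.append(sample_fixation(d, rng))
    return out


def matched_sample_set(model, sset: ScanpathSet,
                       rng: np.random.Generator) -> ScanpathSet:
    """One sampled scanpath per ground-truth scanpath.

    Each partner shares the image, the initial fixation, and the length of
    its ground-truth scanpath, so statistics are compared on matched
    footing.
    """
    if not sset.scanpaths:
        raise ValueError("empty scanpath set")
    sampled = [
        sample_scanpath(model, sp, sp.fixations[0], len(sp.fixations) - 1, rng)
        for sp in sset.scanpaths
    ]
    return ScanpathSet(stimuli=dict(sset.stimuli), scanpaths=sampled,
                       geometry=sset.geometry)


# --------------------------------------------------------------------------
def _saccades(sset: ScanpathSet):
    """Per scanpath: arrays of (dx, dy, amplitude, direction) in dva/deg."""
    geo = sset.geometry or ScreenGeometry(1.0)
    out = []
    for sp in sset.scanpaths:
        rows = [saccade_vector(sp, i, geo) for i in range(1, len(sp.fixations))]
        out.append(np.asarray(rows).reshape(-1, 4))
    return out


def _bootstrap_ci(per_scanpath_stats, reduce_fn, n_boot=200, seed=0, level=0.95):
    """Bootstrap CI over scanpaths for a statistic of the pooled data."""
    rng = np.random.default_rng(seed)
    n = len(per_scanpath_stats)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        vals.append(reduce_fn([per_scanpath_stats[i] for i in idx]))
    lo, hi = np.percentile(vals, [50 * (1 - level), 100 - 50 * (1 - level)],
                           axis=0)
    return np.asarray(lo), np.asarray(hi)


@dataclass
class Histogram:
    edges: np.ndarray
    density: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def as_dict(self):
        d = {"edges": self.edges.tolist(), "density": self.density.tolist()}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low.tolist()
            d["ci_high"] = self.ci_high.tolist()
        return d


def _hist(values_per_sp, edges, n_boot=200, seed=0):
    pooled = np.concatenate([v for v in values_per_sp if len(v)])
    if pooled.size == 0:
        raise ValueError("no saccades to histogram")

    def reduce_fn(parts):
        data = np.concatenate([p for p in parts if len(p)]) if any(
            len(p) for p in parts) else np.array([0.0])
        h, _ = np.histogram(data, bins=edges, density=True)
        return h

    density, _ = np.histogram(pooled, bins=edges, density=True)
    lo, hi = _bootstrap_ci(values_per_sp, reduce_fn, n_boot=n_boot, seed=seed)
    return Histogram(np.asarray(edges, dtype=float), density, lo, hi)


def amplitude_histogram(sset: ScanpathSet, bins=None, n_boot=200,
                        seed=0) -> Histogram:
    sac = _saccades(sset)
    amps = [s[:, 2] for s in sac]
    if bins is None:
        top = max(a.max() for a in amps if len(a)) * 1.01
        bins = np.linspace(0, top, 25)
    return _hist(amps, bins, n_boot=n_boot, seed=seed)


def direction_histogram(sset: ScanpathSet, bins=None, n_boot=200,
                        seed=0) -> Histogram:
    sac = _saccades(sset)
    dirs = [s[:, 3] for s in sac]
    if bins is None:
        bins = np.linspace(0.0, 360.0, 37)
    return _hist(dirs, bins, n_boot=n_boot, seed=seed)


def intersaccade_angle_histogram(sset: ScanpathSet, bins=None, n_boot=200,
                                 seed=0) -> Histogram:
    """Absolute turning angle between consecutive saccades, in [0, 180]."""
    sac = _saccades(sset)
    angles = []
    for s in sac:
        if len(s) < 2:
            angles.append(np.array([]))
            continue
        d = np.abs(np.diff(s[:, 3]))
        angles.append(np.minimum(d % 360.0, 360.0 - d % 360.0))
    if not any(len(a) for a in angles):
        raise ValueError("need scanpaths with at least two saccades")
    if bins is None:
        bins = np.linspace(0.0, 180.0, 19)
    return _hist(angles, bins, n_boot=n_boot, seed=seed)


def amplitude_autocorrelation(sset: ScanpathSet, lag: int = 1,
                              geometry=None) -> float:
    """Pearson correlation of saccade amplitudes at a within-scanpath lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if geometry is not None:
        sset = ScanpathSet(stimuli=dict(sset.stimuli),
                           scanpaths=sset.scanpaths, geometry=geometry)
    pairs = []
    for s in _saccades(sset):
        a = s[:, 2]
        if len(a) > lag:
            pairs.append(np.stack([a[:-lag], a[lag:]], axis=1))
    if not pairs:
        raise ValueError("no amplitude pairs at this lag")
    pooled = np.concatenate(pairs)
    if len(pooled) < 3:
        raise ValueError("need at least 3 amplitude pairs")
    return float(np.corrcoef(pooled[:, 0], pooled[:, 1])[0, 1])


def relative_saccade_histogram(sset: ScanpathSet, window: float = 2.0,
                               bins: int = 41):
    """Next-saccade distribution in the frame of the previous saccade.

    Each consecutive saccade pair is transformed by the rotation+scaling
    (no reflection) that maps the previous saccade vector to (1, 0) in the
    y-up convention; the transformed next-saccade vector is histogrammed
    over [-window, window]^2.  A saccade retracing its predecessor maps to
    (-1, 0).  Returns (edges_x, edges_y, H) with H normalized to unit mass.
    """
    n_skipped = 0
    pts = []
    geo = sset.geometry or ScreenGeometry(1.0)
    for sp in sset.scanpaths:
        for i in range(2, len(sp.fixations)):
            p0, p1, p2 = sp.fixations[i - 2], sp.fixations[i - 1], sp.fixations[i]
            # y-up screen vectors
            u = np.array([p1.x - p0.x, -(p1.y - p0.y)])
            v = np.array([p2.x - p1.x, -(p2.y - p1.y)])
            nu = np.hypot(*u)
            if nu == 0:
                n_skipped += 1
                continue
            # similarity transform sending u -> (1, 0)
            c, s = u / nu
            rot = np.array([[c, s], [-s, c]]) / nu
            pts.append(rot @ v)
    if n_skipped:
        logger.info("skipped %d zero-length previous saccades", n_skipped)
    if not pts:
        raise ValueError("need scanpaths with at least two saccades")
    pts = np.asarray(pts)
    edges = np.linspace(-window, window, bins)
    H, ex, ey = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
    total = H.sum()
    if total > 0:
        H = H / total
    return ex, ey, H


def transform_pair(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map next-saccade v into the frame where previous saccade u is (1, 0)."""
    nu = np.hypot(*u)
    if nu == 0:
        raise ValueError("zero-length previous saccade")
    c, s = np.asarray(u, dtype=float) / nu
    rot = np.array([[c, s], [-s, c]]) / nu
    return rot @ np.asarray(v, dtype=float)


@dataclass
class StatsBundle:
    """All Fig-style scanpath statistics of one set, serializable to JSON."""

    amplitude: Histogram
    direction: Histogram
    intersaccade_angle: Histogram
    autocorrelation: dict  # lag -> coefficient
    relative_saccade: tuple  # (edges_x, edges_y, H)
    extras: dict = field(default_factory=dict)

    def to_json(self, path):
        ex, ey, H = self.relative_saccade
        payload = {
            "amplitude": self.amplitude.as_dict(),
            "direction": self.direction.as_dict(),
            "intersaccade_angle": self.intersaccade_angle.as_dict(),
            "autocorrelation": {str(k): v for k, v in self.autocorrelation.items()},
            "relative_saccade": {"edges_x": ex.tolist(), "edges_y": ey.tolist(),
                                 "mass": H.tolist()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def compute_stats(sset: ScanpathSet, lags=(1, 2), seed=0) -> StatsBundle:
    auto = {}
    for lag in lags:
        try:
            auto[lag] = amplitude_autocorrelation(sset, lag)
        except ValueError:
            pass
    return StatsBundle(
        amplitude=amplitude_histogram(sset, seed=seed),
        direction=direction_histogram(sset, seed=seed),
        intersaccade_angle=intersaccade_angle_histogram(sset, seed=seed),
        autocorrelation=auto,
        relative_saccade=relative_saccade_histogram(sset),
    )
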