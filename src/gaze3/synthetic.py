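"""Planted scanpath generators: exactly computable study conditions.

The generator emulates the structure free-viewing scanpath models assume:
an image-dependent priority map (Gaussian bumps rendered into the stimulus
intensity), a central fixation bias, and oculomotor dependence on the most
recent fixation (short saccade amplitudes with a horizontal preference),
optionally an order-2 return-saccade bonus toward the fixation before last.
The conditional over the next fixation is log-linear in these factors,

    p(f_i | history) = softmax( a*P + b*logG_c + c*(-|p - f_{i-1}|/lambda
                                 + m*cos 2theta) + r*logG(f_{i-2}) ),

so every conditional is exactly normalizable on the pixel grid and joint
scanpath probabilities have a closed form — the generator serves as its own
gold standard: no trained model can beat its log-likelihood on its own
samples in expectation.

Default condition (used throughout the desk-scale experiments): 32 x 32
stimuli, 3 priority bumps per image, center-bias width 0.25 * grid height,
saccade length scale lambda = 6 px, horizontal bias m = 0.5, 50 images x
16 subjects x scanpath length 10 with a forced central initial fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import Fixation, Scanpath, ScanpathSet, ScreenGeometry
from .density import LogDensityGrid, normalize_log_density, sample_fixation


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted generative model.

    With ``c = 0`` and ``r = 0`` the generator is order-0 (no history
    dependence); with ``r = 0`` it is order-1.  ``interaction=True`` swaps
    between two bump sets depending on the horizontal direction of the last
    saccade, planting a priority/history interaction that a single scalar
    priority map cannot represent.
    """

    shape: tuple = (32, 32)
    n_bumps: int = 3
    bump_sigma: tuple = (2.0, 4.0)
    bump_amplitude: float = 3.0
    center_sigma_frac: float = 0.25
    a: float = 1.0  # priority weight
    b: float = 1.0  # center-bias weight
    c: float = 1.0  # oculomotor (order-1) weight
    lam: float = 6.0  # saccade amplitude scale, px
    m: float = 0.5  # horizontal-bias strength
    r: float = 0.0  # order-2 return-saccade bonus weight
    return_sigma: float = 3.0
    seed: int = 0
    interaction: bool = False

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        for v in (self.a, self.b, self.c, self.r, self.m):
            if not math.isfinite(v):
                raise ValueError("weights must be finite")

    @property
    def order(self) -> int:
        if self.r != 0:
            return 2
        if self.c != 0 or self.interaction:
            return 1
        return 0


@dataclass
class PlantedGenerator:
    """A concrete planted model: per-image bump maps plus shared kernels."""

    cfg: PlantedConfig
    priority: dict  # image_id -> (H, W) map in [0, bump_amplitude]
    priority_alt: dict = field(default_factory=dict)  # interaction variant
    bumps: dict = field(default_factory=dict)  # image_id -> list of (cy, cx, s)

    @property
    def shape(self):
        return self.cfg.shape

    def log_center(self) -> np.ndarray:
        h, w = self.cfg.shape
        sc = self.cfg.center_sigma_frac * min(h, w)
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        return -(((xs - (w - 1) / 2) ** 2 + (ys - (h - 1) / 2) ** 2)
                 / (2.0 * sc**2))

    def conditional(self, image_id: str, history: list) -> LogDensityGrid:
        """Planted conditional over the next fixation given the history.

        ``history`` lists the fixations made so far, most recent last.
        """
        cfg = self.cfg
        h, w = cfg.shape
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        needs_last = cfg.c != 0 or cfg.interaction
        if (needs_last or cfg.r != 0) and not history:
            raise ValueError("history-dependent generator needs a history")
        pri = self.priority[image_id]
        if cfg.interaction and len(history) >= 2:
            prev, last = history[-2], history[-1]
            if last.x < prev.x:  # leftward last saccade gates the alternate map
                pri = self.priority_alt[image_id]
        raw = cfg.a * pri + cfg.b * self.log_center()
        if cfg.c != 0:
            last = history[-1]
            dx, dy = xs - last.x, ys - last.y
            dist = np.hypot(dx, dy)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos2 = np.where(dist > 0, (dx**2 - dy**2) / dist**2, 0.0)
            raw = raw + cfg.c * (-dist / cfg.lam + cfg.m * cos2)
        if cfg.r != 0 and len(history) >= 2:
            f2 = history[-2]
            raw = raw + cfg.r * (-(((xs - f2.x) ** 2 + (ys - f2.y) ** 2)
                                   / (2.0 * cfg.return_sigma**2)))
        return normalize_log_density(raw)


def _render_bumps(shape, bumps) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    m = np.zeros(shape)
    for cy, cx, s in bumps:
        m = np.maximum(m, np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * s**2)))
    return m


def make_generator(cfg: PlantedConfig, n_images: int) -> PlantedGenerator:
    """Seeded bump placement for ``n_images`` stimuli."""
    if n_images < 1:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    priority, priority_alt, bumps = {}, {}, {}
    for i in range(n_images):
        img_id = f"img{i:03d}"
        bs = [(rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w),
               rng.uniform(*cfg.bump_sigma)) for _ in range(cfg.n_bumps)]
        bumps[img_id] = bs
        priority[img_id] = cfg.bump_amplitude * _render_bumps(cfg.shape, bs)
        if cfg.interaction:
            bs2 = [(rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w),
                    rng.uniform(*cfg.bump_sigma)) for _ in range(cfg.n_bumps)]
            priority_alt[img_id] = cfg.bump_amplitude * _render_bumps(cfg.shape, bs2)
    return PlantedGenerator(cfg=cfg, priority=priority, priority_alt=priority_alt,
                            bumps=bumps)


def make_images(gen: PlantedGenerator) -> dict:
    """Stimulus images whose intensity renders the priority bumps.

    Bump centers are local intensity maxima, so any intensity-sensitive
    feature extractor can recover the planted priority structure.
    """
    images = {}
    for img_id, pri in gen.priority.items():
        img = pri / max(gen.cfg.bump_amplitude, 1e-12)
        if gen.cfg.interaction:
            # alternate map rendered at half contrast so both are visible
            img = np.maximum(img, 0.5 * gen.priority_alt[img_id]
                             / max(gen.cfg.bump_amplitude, 1e-12))
        images[img_id] = 0.1 + 0.8 * img
    return images


def generate_scanpaths(cfg: PlantedConfig, n_images: int, n_subjects: int,
                       length: int, seed: int,
                       pixels_per_dva: float = 1.0):
    """Sample a full synthetic dataset: (generator, images, ScanpathSet).

    Every scanpath starts with a forced fixation at the grid center;
    subsequent fixations are drawn from the planted conditional.
    """
    if length < 2:
        raise ValueError("scanpaths need at least one free fixation")
    gen = make_generator(cfg, n_images)
    images = make_images(gen)
    rng = np.random.default_rng(seed)
    h, w = cfg.shape
    center = Fixation(float((w - 1) // 2), float((h - 1) // 2), forced=True)
    scanpaths = []
    for img_id in sorted(gen.priority):
        for s in range(n_subjects):
            fixations = [center]
            for _ in range(length - 1):
                d = gen.conditional(img_id, fixations)
                fixations.append(sample_fixation(d, rng))
            scanpaths.append(Scanpath(img_id, f"s{s:02d}", fixations))
    stimuli = {img_id: (w, h, None) for img_id in gen.priority}
    sset = ScanpathSet(stimuli=stimuli, scanpaths=scanpaths,
                       geometry=ScreenGeometry(pixels_per_dva))
    return gen, images, sset


def generator_reference_ll(gen: PlantedGenerator, sset: ScanpathSet) -> float:
    """The generator's own chain-rule LL on a set, in bits/fixation.

    Exact evaluation of the planted conditionals; the ceiling against which
    trained models are measured.
    """
    h, w = gen.cfg.shape
    log_hw = math.log(h * w)
    total, count = 0.0, 0
    for sp in sset.scanpaths:
        if sset.shape_of(sp.image_id) != gen.cfg.shape:
            raise ValueError("scanpath set and generator shapes differ")
        for i, f in enumerate(sp.fixations):
            if i == 0 or f.forced:
                continue
            d = gen.conditional(sp.image_id, sp.fixations[:i])
            r, c = d.cell_of(f)
            total += (d.values[r, c] + log_hw) / math.log(2.0)
            count += 1
    return total / count


def scanpath_joint_logprob(gen: PlantedGenerator, sp: Scanpath) -> float:
    """Natural-log joint probability of a scanpath's free fixations.

    Computed as one product over the planted conditionals; the oracle for
    the chain-rule decomposition of whole-scanpath likelihood.
    """
    total = 0.0
    for i in range(1, len(sp.fixations)):
        d = gen.conditional(sp.image_id, sp.fixations[:i])
        r, c = d.cell_of(sp.fixations[i])
        total += d.values[r, c]
    return total
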