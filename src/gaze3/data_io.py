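"""Scanpath datasets: reading, validation, writing, folds, saccade geometry.

A scanpath is the ordered fixation sequence one subject makes on one image.
The first fixation of a trial may be an experimentally forced central
fixation; it is flagged so that downstream evaluation can condition on it
without ever scoring it.

Coordinate convention: continuous pixel coordinates, 0-based, origin at the
top-left corner, x rightward, y downward.  Likelihood lookups use the
containing pixel cell (floor).  Saccade directions are reported in the
mathematical y-up convention (0 deg = rightward, 90 deg = upward on screen).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["image_id", "subject_id", "fixation_index", "x", "y", "forced"]

# largest representable value strictly below n for in-bounds clamping
def _clamp_below(v: float, n: float) -> float:
    return min(max(v, 0.0), np.nextafter(n, 0.0))


@dataclass(frozen=True)
class Fixation:
    """A single fixation at continuous pixel coordinates (x, y)."""

    x: float
    y: float
    forced: bool = False


@dataclass
class Scanpath:
    """Ordered fixations of one subject on one image."""

    image_id: str
    subject_id: str
    fixations: list

    def __post_init__(self):
        if len(self.fixations) < 1:
            raise ValueError("a scanpath needs at least one fixation")
        if any(f.forced for f in self.fixations[1:]):
            raise ValueError("only the initial fixation may be forced")

    def __len__(self):
        return len(self.fixations)


@dataclass(frozen=True)
class ScreenGeometry:
    """Isotropic screen geometry: pixels per degree of visual angle."""

    pixels_per_dva: float

    def __post_init__(self):
        if not (math.isfinite(self.pixels_per_dva) and self.pixels_per_dva > 0):
            raise ValueError("pixels_per_dva must be finite and positive")


@dataclass
class ScanpathSet:
    """A collection of scanpaths over a set of stimuli.

    ``stimuli`` maps image_id -> (width, height, path); ``path`` may be None
    when sizes come from a sidecar index or a generator.
    """

    stimuli: dict
    scanpaths: list
    geometry: ScreenGeometry | None = None

    def __post_init__(self):
        seen = {}
        for sp in self.scanpaths:
            if sp.image_id not in self.stimuli:
                raise ValueError(f"unknown image_id {sp.image_id!r}")
            key = (sp.image_id, sp.subject_id)
            seen[key] = seen.get(key, 0) + 1

    def shape_of(self, image_id: str) -> tuple:
        w, h, _ = self.stimuli[image_id]
        return (h, w)

    def image_ids(self) -> list:
        return sorted(self.stimuli)

    def n_free_fixations(self) -> int:
        return sum(sum(1 for f in sp.fixations if not f.forced) for sp in self.scanpaths)

    def subset_images(self, image_ids) -> "ScanpathSet":
        keep = set(image_ids)
        return ScanpathSet(
            stimuli={i: s for i, s in self.stimuli.items() if i in keep},
            scanpaths=[sp for sp in self.scanpaths if sp.image_id in keep],
            geometry=self.geometry,
        )


@dataclass
class FoldAssignment:
    """Image-level cross-validation fold assignment with a role schedule.

    Evaluation fold j tests on fold j, validates on fold (j+1) mod n, and
    trains on the rest.
    """

    n_folds: int
    fold_of: dict = field(default_factory=dict)

    def images_in_fold(self, j: int) -> list:
        return sorted(i for i, f in self.fold_of.items() if f == j)

    def roles(self, j: int) -> dict:
        test = j
        val = (j + 1) % self.n_folds
        train = [f for f in range(self.n_folds) if f not in (test, val)]
        return {"test": [test], "val": [val], "train": train}

    def split_images(self, j: int) -> dict:
        r = self.roles(j)
        return {
            role: sorted(i for i, f in self.fold_of.items() if f in folds)
            for role, folds in r.items()
        }

    def fold_of_image(self, image_id: str) -> int:
        return self.fold_of[image_id]


# --------------------------------------------------------------------------
def read_scanpaths(path, stimuli_dir=None, clamp_policy="clamp",
                   geometry=None) -> ScanpathSet:
    """Read a scanpath CSV and resolve stimulus sizes.

    The CSV has columns ``image_id,subject_id,fixation_index,x,y,forced``
    with fixation_index contiguous from 0 per scanpath.  Stimulus sizes come
    from a ``stimuli.json`` sidecar in ``stimuli_dir`` (``{"img": [w, h]}``)
    or, failing that, from reading the image files themselves.

    clamp_policy: ``clamp`` moves out-of-bounds coordinates to the nearest
    in-bounds value (count logged), ``drop`` removes the offending scanpath,
    ``error`` raises naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty scanpath file")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("x", "y"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed row {row} (missing {col})")

    stimuli = _resolve_stimuli(df["image_id"].unique(), stimuli_dir)

    n_clamped = 0
    scanpaths = []
    for (img, subj), grp in df.groupby(["image_id", "subject_id"], sort=False):
        grp = grp.sort_values("fixation_index")
        if list(grp["fixation_index"]) != list(range(len(grp))):
            row = int(grp.index[0]) + 2
            raise ValueError(
                f"{path}: non-contiguous fixation_index near row {row}"
            )
        w, h, _ = stimuli[str(img)]
        fixations, dropped = [], False
        for ridx, rec in grp.iterrows():
            x, y = float(rec["x"]), float(rec["y"])
            if not (0 <= x < w and 0 <= y < h):
                if clamp_policy == "error":
                    raise ValueError(
                        f"{path}: row {ridx + 2}: fixation ({x}, {y}) outside "
                        f"{w}x{h} image {img!r}"
                    )
                if clamp_policy == "drop":
                    dropped = True
                    break
                x, y = _clamp_below(x, w), _clamp_below(y, h)
                n_clamped += 1
            fixations.append(
                Fixation(x, y, forced=bool(int(rec["forced"])))
            )
        if dropped or not fixations:
            continue
        scanpaths.append(Scanpath(str(img), str(subj), fixations))
    if n_clamped:
        logger.warning("clamped %d out-of-bounds fixations", n_clamped)
    return ScanpathSet(stimuli=stimuli, scanpaths=scanpaths, geometry=geometry)


def _resolve_stimuli(image_ids, stimuli_dir):
    stimuli = {}
    sidecar = {}
    if stimuli_dir is not None:
        sc_path = Path(stimuli_dir) / "stimuli.json"
        if sc_path.exists():
            sidecar = json.loads(sc_path.read_text())
    for img in image_ids:
        img = str(img)
        if img in sidecar:
            w, h = sidecar[img]
            p = _find_image(stimuli_dir, img)
            stimuli[img] = (int(w), int(h), p)
            continue
        p = _find_image(stimuli_dir, img)
        if p is None:
            raise ValueError(
                f"unknown image_id {img!r}: no stimulus file or sidecar entry"
            )
        import imageio.v3 as iio

        arr = iio.imread(p)
        stimuli[img] = (arr.shape[1], arr.shape[0], p)
    return stimuli


def _find_image(stimuli_dir, image_id):
    if stimuli_dir is None:
        return None
    for ext in (".png", ".jpg", ".jpeg", ""):
        p = Path(stimuli_dir) / f"{image_id}{ext}"
        if p.exists():
            return p
    return None


def write_scanpaths(sset: ScanpathSet, path) -> Path:
    """Write a ScanpathSet to CSV (+ stimuli.json sidecar next to it).

    Round-trips through :func:`read_scanpaths` with coordinates exact to
    1e-9 and flags preserved.
    """
    if not sset.scanpaths:
        raise ValueError("nothing to write: empty scanpath list")
    path = Path(path)
    rows = []
    for sp in sset.scanpaths:
        for i, f in enumerate(sp.fixations):
            rows.append(
                (sp.image_id, sp.subject_id, i, repr(f.x), repr(f.y), int(f.forced))
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)
    sidecar = {img: [w, h] for img, (w, h, _) in sset.stimuli.items()}
    (path.parent / "stimuli.json").write_text(json.dumps(sidecar, indent=1))
    return path


def assign_folds(image_ids, n_folds, seed, strata=None) -> FoldAssignment:
    """Randomly partition images into near-equal cross-validation folds.

    Deterministic given ``seed``.  With ``strata`` (image_id -> category),
    each category is split as evenly as possible across folds.
    """
    image_ids = list(image_ids)
    if n_folds < 3:
        raise ValueError("need at least 3 folds (train/val/test roles)")
    if n_folds > len(image_ids):
        raise ValueError("more folds than images")
    rng = np.random.default_rng(seed)
    fold_of = {}
    if strata is None:
        groups = [sorted(image_ids)]
    else:
        by_cat = {}
        for img in image_ids:
            by_cat.setdefault(strata[img], []).append(img)
        groups = [sorted(by_cat[c]) for c in sorted(by_cat)]
    offset = 0
    for grp in groups:
        perm = rng.permutation(len(grp))
        for pos, idx in enumerate(perm):
            fold_of[grp[idx]] = (offset + pos) % n_folds
        offset += len(grp)
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of)


def saccade_vector(sp: Scanpath, i: int, geometry: ScreenGeometry):
    """Saccade into fixation i: (dx, dy, amplitude) in dva and direction in deg.

    Direction uses the y-up convention: angle of (dx, -dy) in [0, 360).
    """
    if i < 1:
        raise ValueError("fixation 0 has no incoming saccade")
    if i >= len(sp.fixations):
        raise IndexError("fixation index out of range")
    f1, f0 = sp.fixations[i], sp.fixations[i - 1]
    s = 1.0 / geometry.pixels_per_dva
    dx, dy = (f1.x - f0.x) * s, (f1.y - f0.y) * s
    amplitude = math.hypot(dx, dy)
    direction = math.degrees(math.atan2(-dy, dx)) % 360.0
    return dx, dy, amplitude, direction
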