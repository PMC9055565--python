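"""Ablation and decomposition studies as reusable procedures.

* ``order_sweep`` trains the model over the grid {image content on/off} x
  {dependency order k = 0..k_max} with identical schedule, folds and seeds,
  and reports the log-likelihood per cell — separating what image content
  and scanpath history each contribute.
* ``priority_dim_sweep`` varies the dimensionality d of the internal
  priority map with and without the scanpath network; a static model flat
  in d while the full model rises with d indicates an interaction between
  image content and scanpath history that one scalar priority map cannot
  carry.
* ``centerbias_decomposition`` turns the fitted center-bias weights of
  four model variants (neither / scanpath-only / image-only / both) into
  explained percentages with inclusion-exclusion overlap.
* ``ll_by_fixation_index`` resolves prediction performance over the index
  of the free fixation within the scanpath.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import CenterBiasFit, fit_center_bias
from .data_io import ScanpathSet
from .evaluation import per_fixation_scores
from .readout import ModelConfig, ScanpathModel, constant_backbone, toy_backbone
from .training import FittedConditionalModel, train_model


@dataclass
class AblationGrid:
    """Per-cell trained models and scores of one ablation axis sweep."""

    cells: pd.DataFrame  # one row per cell: axis values + ll
    models: dict = field(default_factory=dict)  # cell key -> FittedConditionalModel
    per_image: dict = field(default_factory=dict)  # cell key -> Series (image -> ll)

    def ll(self, **axis) -> float:
        mask = np.ones(len(self.cells), dtype=bool)
        for k, v in axis.items():
            mask &= self.cells[k] == v
        sel = self.cells[mask]
        if len(sel) != 1:
            raise KeyError(f"no unique cell for {axis}")
        return float(sel["ll"].iloc[0])


def paired_delta_ci(grid: AblationGrid, cell_a, cell_b, n_boot: int = 2000,
                    seed: int = 0, level: float = 0.95):
    """Paired bootstrap CI (over images) of LL(cell_b) - LL(cell_a)."""
    a, b = grid.per_image[cell_a], grid.per_image[cell_b]
    diff = (b - a).dropna().to_numpy()
    rng = np.random.default_rng(seed)
    boots = [diff[rng.integers(0, len(diff), len(diff))].mean()
             for _ in range(n_boot)]
    lo, hi = np.percentile(boots, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(diff.mean()), float(lo), float(hi)


def _train_cell(config: ModelConfig, train_set, test_set, images, cb_fit,
                schedule, seed, backbone_seed):
    backbone = (toy_backbone(backbone_seed, config.backbone_channels,
                             config.downsample)
                if config.include_image else constant_backbone(config.downsample))
    model = ScanpathModel(config, backbone=backbone, seed=seed)
    train_model(model, train_set, images, cb_fit, schedule, seed=seed)
    fitted = FittedConditionalModel(model, images, cb_fit=cb_fit)
    scores = per_fixation_scores(fitted, test_set)
    per_image = scores.groupby("image_id")["ll"].mean()
    return fitted, float(per_image.mean()), per_image


def order_sweep(base_config: ModelConfig, train_set: ScanpathSet,
                test_set: ScanpathSet, images: dict, schedule: list,
                k_values=(0, 1, 2, 3, 4), seed: int = 0,
                cb_fit: CenterBiasFit | None = None,
                image_values=(True, False)) -> AblationGrid:
    """Train {image on/off} x {k} cells; all else identical across cells."""
    if cb_fit is None:
        cb_fit = fit_center_bias(train_set)
    rows, models, per_image = [], {}, {}
    for include_image in image_values:
        for k in k_values:
            config = replace(base_config, include_image=include_image, k=k)
            fitted, ll, pim = _train_cell(config, train_set, test_set, images,
                                          cb_fit, schedule, seed,
                                          backbone_seed=seed)
            rows.append({"include_image": include_image, "k": k, "ll": ll})
            models[(include_image, k)] = fitted
            per_image[(include_image, k)] = pim
    cells = pd.DataFrame(rows)
    return AblationGrid(cells=cells, models=models, per_image=per_image)


def order_sweep_deltas(grid: AblationGrid, include_image=True) -> dict:
    """Successive LL gains Delta(k -> k+1) along the order axis."""
    sub = grid.cells[grid.cells["include_image"] == include_image]
    sub = sub.sort_values("k")
    ks, lls = sub["k"].to_numpy(), sub["ll"].to_numpy()
    return {f"{ks[i]}->{ks[i+1]}": float(lls[i + 1] - lls[i])
            for i in range(len(ks) - 1)}


def priority_dim_sweep(base_config: ModelConfig, train_set: ScanpathSet,
                       test_set: ScanpathSet, images: dict, schedule: list,
                       d_values=(1, 2, 4, 8), seed: int = 0,
                       cb_fit: CenterBiasFit | None = None) -> AblationGrid:
    """Train {d} x {scanpath on/off} cells at fixed image content."""
    if cb_fit is None:
        cb_fit = fit_center_bias(train_set)
    rows, models, per_image = [], {}, {}
    for include_scanpath in (True, False):
        for d in d_values:
            config = replace(base_config, d=d,
                             include_scanpath=include_scanpath)
            fitted, ll, pim = _train_cell(config, train_set, test_set, images,
                                          cb_fit, schedule, seed,
                                          backbone_seed=seed)
            rows.append({"include_scanpath": include_scanpath, "d": d,
                         "ll": ll})
            models[(include_scanpath, d)] = fitted
            per_image[(include_scanpath, d)] = pim
    return AblationGrid(cells=pd.DataFrame(rows), models=models,
                        per_image=per_image)


# --------------------------------------------------------------------------
def centerbias_decomposition(w_cb_only: float, w_scanpath: float,
                             w_image: float, w_both: float) -> dict:
    """Explained center-bias percentages by weight ratio, with overlap.

    explained%(m) = 100 * (1 - w_m / w_cb_only); the overlap between the
    scanpath-explained and image-explained parts follows by
    inclusion-exclusion:
    overlap = explained%(scanpath) + explained%(image) - explained%(both).
    """
    if w_cb_only <= 0:
        raise ValueError("the center-bias-only weight must be positive")

    def explained(w):
        return 100.0 * (1.0 - w / w_cb_only)

    e_sp, e_im, e_both = (explained(w_scanpath), explained(w_image),
                          explained(w_both))
    return {
        "explained_scanpath": e_sp,
        "explained_image": e_im,
        "explained_both": e_both,
        "overlap": e_sp + e_im - e_both,
        "unexplained": 100.0 - e_both,
    }


def overlap_from_percentages(explained_scanpath: float, explained_image: float,
                             explained_both: float) -> float:
    """Inclusion-exclusion overlap from already-computed percentages."""
    return explained_scanpath + explained_image - explained_both


# --------------------------------------------------------------------------
def ll_by_fixation_index(model, sset: ScanpathSet, n_boot: int = 200,
                         seed: int = 0, level: float = 0.95) -> pd.DataFrame:
    """Per-free-fixation-index LL with paired bootstrap CIs.

    Index 1 is the first free fixation; the forced fixation is never
    scored.  CIs use per-image mean-centering before resampling images, so
    they reflect index structure rather than between-image difficulty.
    """
    scores = per_fixation_scores(model, sset)
    rows = []
    img_means = scores.groupby("image_id")["ll"].transform("mean")
    centered = scores.assign(ll_centered=scores["ll"] - img_means)
    images = sorted(scores["image_id"].unique())
    by_image = {img: centered[centered["image_id"] == img] for img in images}
    rng = np.random.default_rng(seed)
    boot_means = {}
    for _ in range(n_boot):
        idx = rng.integers(0, len(images), len(images))
        sample = pd.concat([by_image[images[i]] for i in idx])
        for fi, grp in sample.groupby("free_index"):
            boot_means.setdefault(fi, []).append(grp["ll_centered"].mean())
    grand = scores["ll"].mean()
    for fi, grp in scores.groupby("free_index"):
        bs = boot_means.get(fi, [])
        if bs:
            lo, hi = np.percentile(bs, [50 * (1 - level),
                                        100 - 50 * (1 - level)])
            lo, hi = grand + lo, grand + hi
        else:
            lo = hi = np.nan
        rows.append({"free_index": int(fi), "n": len(grp),
                     "ll": float(grp["ll"].mean()),
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows).sort_values("free_index").reset_index(drop=True)
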