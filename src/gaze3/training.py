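"""Maximum-likelihood training: objective, phase schedule, cross-validation.

The objective is the image-averaged log-likelihood: the per-fixation
log-likelihoods (bits, relative to uniform) are averaged first over the
fixations of an image and then over images.  Training proceeds in phases;
each phase may remove the scanpath network (turning the model into a purely
spatial predictor) or freeze named parameter groups (e.g. the first layer
of the spatial priority network).  Within a phase, ADAM takes one step per
image; the learning rate is divided by the decay factor after each listed
epoch and training stops after the last listed epoch.

Cross-validation is image-level: evaluation fold j tests on fold j,
validates on fold j+1, trains on the rest; each phase initializes every
fold from the same fold of the previous phase, so test images are never
seen at any phase.  Repeats rerun the whole schedule from fresh seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .baselines import CenterBiasFit, fit_center_bias
from .data_io import FoldAssignment, ScanpathSet
from .density import LogDensityGrid
from .history import build_history_stack
from .readout import ModelConfig, ScanpathModel, pack_histories

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PhaseSpec:
    """One row of the learning schedule.

    ``frozen`` lists parameter-name prefixes excluded from updates;
    ``scanpath_removed`` runs the model without the scanpath network (its
    parameters stay bit-identical).  ``decay_epochs`` are 1-based epochs
    after which the learning rate is divided by ``decay_factor``; training
    stops after the last listed epoch.
    """

    name: str
    lr: float
    decay_epochs: tuple
    decay_factor: float = 10.0
    scanpath_removed: bool = False
    frozen: tuple = ()
    dataset: str = "train"

    def __post_init__(self):
        de = tuple(self.decay_epochs)
        if any(b <= a for a, b in zip(de, de[1:])):
            raise ValueError("decay epochs must be strictly increasing")
        if not de:
            raise ValueError("need at least one decay epoch (the stop epoch)")

    @property
    def n_epochs(self) -> int:
        return self.decay_epochs[-1]

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during 1-based ``epoch``."""
        n_decayed = sum(1 for e in self.decay_epochs if e < epoch)
        return self.lr / self.decay_factor**n_decayed


def default_schedule(reduced: bool = True) -> list:
    """The multi-phase schedule; the reduced variant fits desk-scale runs.

    Full variant mirrors the published protocol: spatial pretraining,
    spatial training, scanpath training with the first priority layer
    fixed, then joint fine-tuning.  The reduced variant keeps the phase
    structure with shorter epoch lists for small synthetic datasets.
    """
    if reduced:
        return [
            PhaseSpec("spatial", 0.01, (12, 20), scanpath_removed=True),
            PhaseSpec("scanpath", 0.01, (12, 20), frozen=("spn.0.",)),
            PhaseSpec("finetune", 0.001, (8,)),
        ]
    return [
        PhaseSpec("pretrain_spatial", 0.001, (15, 30, 45, 60, 75),
                  scanpath_removed=True, dataset="pretrain"),
        PhaseSpec("spatial", 0.001, (3, 6, 9, 12, 15), scanpath_removed=True),
        PhaseSpec("scanpath", 0.001, (10, 20, 30, 31, 32), frozen=("spn.0.",)),
        PhaseSpec("finetune", 0.00001, (3, 6, 9)),
    ]


def sweep_schedule() -> list:
    """Shorter per-cell schedule for ablation sweeps.

    Sweeps compare cells trained under identical conditions, so a lighter
    schedule (same phase structure, fewer epochs) keeps the comparison fair
    while fitting many cells into a desk-scale run.
    """
    return [
        PhaseSpec("spatial", 0.01, (6, 10), scanpath_removed=True),
        PhaseSpec("scanpath", 0.01, (6, 10), frozen=("spn.0.",)),
        PhaseSpec("finetune", 0.001, (4,)),
    ]


# --------------------------------------------------------------------------
class Adam:
    """ADAM over a named parameter dict, honoring frozen prefixes."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999),
                 eps=1e-8, frozen=()):
        self.params = {
            n: t for n, t in params.items()
            if not any(n.startswith(p) for p in frozen)
        }
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(t.data) for n, t in self.params.items()}
        self.v = {n: np.zeros_like(t.data) for n, t in self.params.items()}

    def step(self):
        self.t += 1
        for n, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self, all_params: dict):
        for p in all_params.values():
            p.grad = None


# --------------------------------------------------------------------------
@dataclass
class ImageBatch:
    """All evaluable fixations of one image, ready for a training step."""

    image_id: str
    feats: np.ndarray  # (C, H', W')
    hists: tuple | list  # packed (slots, mask_rep) per evaluable fixation
    targets: np.ndarray  # flat cell index per evaluable fixation
    log_cb: np.ndarray  # (H, W)


def prepare_batches(model: ScanpathModel, sset: ScanpathSet, images: dict,
                    cb_fit: CenterBiasFit) -> list:
    """Build per-image training batches (features, histories, targets)."""
    cfg = model.config
    batches = []
    for img_id in sset.image_ids():
        h, w = sset.shape_of(img_id)
        feats = model.features_for(img_id, images[img_id])
        gh, gw = feats.shape[1:]
        log_cb = cb_fit.pooled_grid((h, w)).values
        hists, targets = [], []
        for sp in sset.scanpaths:
            if sp.image_id != img_id:
                continue
            for i in range(1, len(sp.fixations)):
                f = sp.fixations[i]
                if f.forced:
                    continue
                targets.append(int(f.y) * w + int(f.x))
                if cfg.uses_scanpath:
                    hists.append(build_history_stack(
                        sp, i, cfg.k, (gh, gw), downsample=cfg.downsample))
        if not targets:
            continue
        packed = (pack_histories(hists, cfg.k, gh * gw)
                  if cfg.uses_scanpath else [])
        batches.append(ImageBatch(img_id, feats, packed,
                                  np.asarray(targets, dtype=np.intp), log_cb))
    return batches


def image_loss(model: ScanpathModel, batch: ImageBatch,
               use_scanpath: bool) -> Tensor:
    """Negative mean fixation log-likelihood (bits) for one image."""
    if use_scanpath:
        out = model.log_density_batch(batch.feats, batch.hists, batch.log_cb)
        logp = ag.gather_rows(out, batch.targets)
    else:
        out = model.log_density_batch(batch.feats, [], batch.log_cb,
                                      use_scanpath=False)
        logp = ag.gather_cols(out, batch.targets)
    return logp.mean() * (-1.0 / LN2)


def image_averaged_objective(model: ScanpathModel, batches: list,
                             use_scanpath=None) -> float:
    """Image-averaged LL in bits/fixation relative to uniform (higher is better)."""
    if use_scanpath is None:
        use_scanpath = model.config.uses_scanpath
    vals = [-image_loss(model, b, use_scanpath).item()
            + math.log2(b.log_cb.size) for b in batches]
    if not vals:
        raise ValueError("no evaluable images")
    return float(np.mean(vals))


def train_phase(model: ScanpathModel, batches: list, spec: PhaseSpec,
                seed: int, val_batches=None, log: list | None = None) -> None:
    """Run one training phase in place; one ADAM step per image.

    Optimizer state is reset at phase start.  Frozen parameter groups stay
    bit-identical; with ``scanpath_removed`` the scanpath network neither
    runs nor updates.
    """
    frozen = tuple(spec.frozen)
    if spec.scanpath_removed:
        frozen = frozen + ("sn.",)
    use_scanpath = model.config.uses_scanpath and not spec.scanpath_removed
    opt = Adam(model.params, spec.lr, frozen=frozen)
    rng = np.random.default_rng(seed)
    for epoch in range(1, spec.n_epochs + 1):
        opt.lr = spec.lr_at_epoch(epoch)
        order = rng.permutation(len(batches))
        for bi in order:
            opt.zero_grad(model.params)
            loss = image_loss(model, batches[bi], use_scanpath)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss in phase {spec.name!r}, epoch {epoch}, "
                    f"image {batches[bi].image_id!r}"
                )
            loss.backward()
            opt.step()
        if log is not None:
            entry = {"phase": spec.name, "epoch": epoch, "lr": opt.lr,
                     "train_ll": image_averaged_objective(model, batches,
                                                          use_scanpath)}
            if val_batches:
                entry["val_ll"] = image_averaged_objective(
                    model, val_batches, use_scanpath)
            log.append(entry)


def train_model(model: ScanpathModel, sset: ScanpathSet, images: dict,
                cb_fit: CenterBiasFit, schedule: list, seed: int,
                val_set: ScanpathSet | None = None,
                log: list | None = None) -> ScanpathModel:
    """Run a full phase schedule on one train split."""
    batches = prepare_batches(model, sset, images, cb_fit)
    val_batches = (prepare_batches(model, val_set, images, cb_fit)
                   if val_set is not None else None)
    for pi, spec in enumerate(schedule):
        train_phase(model, batches, spec, seed + 1000 * pi,
                    val_batches=val_batches, log=log)
    return model


# --------------------------------------------------------------------------
@dataclass
class CrossValResult:
    """Per-fold, per-repeat trained parameters plus shared artifacts."""

    config: ModelConfig
    folds: FoldAssignment
    params: dict  # (fold, repeat) -> parameter dict
    cb_fits: dict  # fold -> CenterBiasFit (fitted on that fold's train images)
    logs: dict = field(default_factory=dict)
    backbone_seed: int = 0

    def model_for(self, fold: int, repeat: int = 0,
                  backbone=None) -> ScanpathModel:
        return ScanpathModel(self.config, backbone=backbone,
                             params=self.params[(fold, repeat)],
                             seed=self.backbone_seed)


def crossval_train(config: ModelConfig, sset: ScanpathSet, images: dict,
                   schedule: list, folds: FoldAssignment, seed: int = 0,
                   n_repeats: int = 1, folds_to_train=None,
                   backbone=None) -> CrossValResult:
    """Train the schedule per cross-validation fold (and repeat).

    Each fold's center bias is fitted on that fold's training images only,
    so test-fold fixations never inform any component.
    """
    if folds_to_train is None:
        folds_to_train = range(folds.n_folds)
    params, cb_fits, logs = {}, {}, {}
    for fold in folds_to_train:
        split = folds.split_images(fold)
        train_set = sset.subset_images(split["train"])
        val_set = sset.subset_images(split["val"])
        cb_fits[fold] = fit_center_bias(train_set)
        for rep in range(n_repeats):
            model = ScanpathModel(config, backbone=backbone,
                                  seed=seed + 7919 * rep)
            log = []
            train_model(model, train_set, images, cb_fits[fold], schedule,
                        seed=seed + 104729 * rep + 13 * fold,
                        val_set=val_set, log=log)
            params[(fold, rep)] = model.params
            logs[(fold, rep)] = log
    return CrossValResult(config=config, folds=folds, params=params,
                          cb_fits=cb_fits, logs=logs, backbone_seed=seed)


class FittedConditionalModel:
    """Evaluation-protocol adapter around a trained ScanpathModel.

    Routes each image to the parameters of the fold whose test split holds
    it (when a CrossValResult is given) and caches order-0 predictions.
    """

    name = "scanpath_model"

    def __init__(self, model_or_cv, images: dict, cb_fit: CenterBiasFit = None,
                 repeat: int = 0, backbone=None):
        self.images = images
        self._cache = {}
        if isinstance(model_or_cv, CrossValResult):
            self.cv = model_or_cv
            self._models = {}
            for fold in {f for (f, r) in model_or_cv.params if r == repeat}:
                self._models[fold] = model_or_cv.model_for(fold, repeat,
                                                           backbone=backbone)
            self.cb_fits = model_or_cv.cb_fits
            self.single = None
        else:
            self.cv = None
            self.single = model_or_cv
            if cb_fit is None:
                raise ValueError("a center-bias fit is required")
            self.cb_fit = cb_fit

    def _resolve(self, image_id: str):
        if self.cv is None:
            return self.single, self.cb_fit
        fold = self.cv.folds.fold_of_image(image_id)
        if fold not in self._models:
            fold = next(iter(self._models))
        return self._models[fold], self.cb_fits[fold]

    def conditional(self, sp, i) -> LogDensityGrid:
        model, cb_fit = self._resolve(sp.image_id)
        image = self.images[sp.image_id]
        shape = image.shape[:2]
        log_cb = cb_fit.pooled_grid(shape).values
        if not model.config.uses_scanpath:
            if sp.image_id not in self._cache:
                self._cache[sp.image_id] = model.predict_conditional(
                    image, sp, i, log_cb, image_id=sp.image_id)
            return self._cache[sp.image_id]
        return model.predict_conditional(image, sp, i, log_cb,
                                         image_id=sp.image_id)

    def batch_scores(self, sset: ScanpathSet):
        """Per-fixation LL/AUC/NSS, one batched forward pass per image."""
        import pandas as pd

        from .evaluation import scores_from_grid

        rows = []
        for img_id in sset.image_ids():
            model, cb_fit = self._resolve(img_id)
            cfg = model.config
            image = self.images[img_id]
            h, w = image.shape[:2]
            feats = model.features_for(img_id, image)
            gh, gw = feats.shape[1:]
            log_cb = cb_fit.pooled_grid((h, w)).values
            meta, hists = [], []
            for sp in sset.scanpaths:
                if sp.image_id != img_id:
                    continue
                free_idx = 0
                for i in range(1, len(sp.fixations)):
                    f = sp.fixations[i]
                    if f.forced:
                        continue
                    free_idx += 1
                    meta.append((sp.subject_id, free_idx,
                                 int(f.y), int(f.x)))
                    if cfg.uses_scanpath:
                        hists.append(build_history_stack(
                            sp, i, cfg.k, (gh, gw),
                            downsample=cfg.downsample))
            if not meta:
                continue
            out = model.log_density_batch(feats, hists, log_cb)
            for bi, (subj, free_idx, r, c) in enumerate(meta):
                row = 0 if not cfg.uses_scanpath else bi
                grid = out.data[row].reshape(h, w)
                ll, auc, nss = scores_from_grid(grid, r, c)
                rows.append((img_id, subj, free_idx, ll, auc, nss))
        if not rows:
            raise ValueError("no evaluable fixations in the set")
        return pd.DataFrame(rows, columns=["image_id", "subject_id",
                                           "free_index", "ll", "auc", "nss"])
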