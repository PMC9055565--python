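"""Conditional-prediction metrics for scanpath models.

Every metric scores the *conditional* density a model emits for fixation i
given the preceding history, evaluated only at the one fixation that
actually followed.  Forced initial fixations are never scored; they only
inform the conditioning history.

* LL — average log-likelihood in bits per fixation relative to the uniform
  model, averaged first over the fixations of an image, then over images
  (the same averaging order as the training objective).
* IG — LL relative to the center-bias baseline instead of uniform.
* AUC — per fixation, the fraction of grid cells whose predicted value is
  strictly below the fixated cell's plus half the ties (uniform
  non-fixation distribution, tie weight 1/2); pooled per-fixation mean.
* NSS — the z-score of the fixated cell's probability under the grid's
  mean and population standard deviation; pooled per-fixation mean; a
  zero-variance (uniform) grid scores 0.

Models plug in through a tiny protocol: ``model.conditional(sp, i)``
returns the LogDensityGrid for fixation ``i`` of scanpath ``sp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Scanpath, ScanpathSet
from .density import LogDensityGrid


def auc_conditional(d: LogDensityGrid, f) -> float:
    """Tie-aware pixel-based AUC of one conditional prediction.

    The fixated cell is ranked against every *other* grid cell (the uniform
    non-fixation distribution): strictly lower cells count 1, ties count
    1/2.  A constant grid scores exactly 0.5.
    """
    r, c = d.cell_of(f)
    v = d.values
    if v.size == 1:
        return 0.5
    target = v[r, c]
    below = np.count_nonzero(v < target)
    ties = np.count_nonzero(v == target) - 1  # exclude the fixated cell
    return (below + 0.5 * ties) / (v.size - 1)


def nss_conditional(d: LogDensityGrid, f) -> float:
    """z-score of the fixated cell's probability mass."""
    p = d.probabilities()
    r, c = d.cell_of(f)
    std = p.std()  # population std
    if std == 0.0:
        return 0.0
    return (p[r, c] - p.mean()) / std


def information_gain(model_ll: float, centerbias_ll: float) -> float:
    """IG = LL minus the center-bias LL (same averaging order)."""
    return model_ll - centerbias_ll


# --------------------------------------------------------------------------
def iter_scored_fixations(sset: ScanpathSet):
    """Yield (scanpath, index) for every evaluable (free, i >= 1) fixation."""
    for sp in sset.scanpaths:
        for i in range(1, len(sp.fixations)):
            if sp.fixations[i].forced:
                continue
            yield sp, i


def scanpath_log_likelihood(model, sp: Scanpath):
    """Chain-rule log-likelihood of one scanpath: (total bits, bits/fix)."""
    indices = [i for i in range(1, len(sp.fixations))
               if not sp.fixations[i].forced]
    if not indices:
        raise ValueError("scanpath has no free fixation to score")
    from .density import loglik_bits

    total = 0.0
    for i in indices:
        total += loglik_bits(model.conditional(sp, i), sp.fixations[i])
    return total, total / len(indices)


def scores_from_grid(values: np.ndarray, r: int, c: int):
    """(ll_bits, auc, nss) of one fixation cell under a normalized log grid."""
    target = values[r, c]
    ll = (target + math.log(values.size)) / math.log(2.0)
    below = np.count_nonzero(values < target)
    ties = np.count_nonzero(values == target) - 1
    auc = 0.5 if values.size == 1 else (below + 0.5 * ties) / (values.size - 1)
    p = np.exp(values)
    std = p.std()
    nss = 0.0 if std == 0.0 else (p[r, c] - p.mean()) / std
    return ll, auc, nss


def per_fixation_scores(model, sset: ScanpathSet) -> pd.DataFrame:
    """One row per scored fixation: image, subject, free index, ll, auc, nss.

    Models exposing ``batch_scores`` (e.g. trained readout models, which can
    evaluate all of an image's fixations in one pass) are routed through it.
    """
    if hasattr(model, "batch_scores"):
        return model.batch_scores(sset)
    from .density import loglik_bits

    rows = []
    for sp in sset.scanpaths:
        free_idx = 0
        for i in range(1, len(sp.fixations)):
            f = sp.fixations[i]
            if f.forced:
                continue
            free_idx += 1
            d = model.conditional(sp, i)
            rows.append((sp.image_id, sp.subject_id, free_idx,
                         loglik_bits(d, f), auc_conditional(d, f),
                         nss_conditional(d, f)))
    if not rows:
        raise ValueError("no evaluable fixations in the set")
    return pd.DataFrame(rows, columns=["image_id", "subject_id", "free_index",
                                       "ll", "auc", "nss"])


def image_averaged_ll(scores: pd.DataFrame) -> float:
    """Mean over images of the per-image mean fixation LL (bits/fix)."""
    return float(scores.groupby("image_id")["ll"].mean().mean())


def average_loglik_bits(model, sset: ScanpathSet) -> float:
    return image_averaged_ll(per_fixation_scores(model, sset))


@dataclass
class MetricsTable:
    """Per-model metric rows with per-image breakdowns."""

    rows: pd.DataFrame  # model, ll, ig, auc, nss
    per_image: dict = field(default_factory=dict)  # model -> DataFrame
    per_fixation: dict = field(default_factory=dict)

    def row(self, model_name: str) -> dict:
        r = self.rows[self.rows["model"] == model_name]
        if r.empty:
            raise KeyError(model_name)
        return r.iloc[0].to_dict()

    def to_csv(self, path):
        self.rows.to_csv(path, index=False)

    def to_json(self, path):
        self.rows.to_json(path, orient="records", indent=1)


def evaluate_model(model, sset: ScanpathSet, centerbias_model=None,
                   centerbias_ll: float | None = None,
                   name: str | None = None) -> MetricsTable:
    """Score one model on a set; IG requires a center-bias reference.

    The center bias may be passed as a model (scored on the same
    fixations) or as its precomputed image-averaged LL.
    """
    scores = per_fixation_scores(model, sset)
    ll = image_averaged_ll(scores)
    if centerbias_ll is None:
        if centerbias_model is None:
            raise ValueError("IG needs a center-bias model or its LL")
        centerbias_ll = average_loglik_bits(centerbias_model, sset)
    row = {
        "model": name or getattr(model, "name", type(model).__name__),
        "ll": ll,
        "ig": information_gain(ll, centerbias_ll),
        "auc": float(scores["auc"].mean()),
        "nss": float(scores["nss"].mean()),
    }
    per_image = scores.groupby("image_id")[["ll", "auc", "nss"]].mean()
    return MetricsTable(rows=pd.DataFrame([row]),
                        per_image={row["model"]: per_image},
                        per_fixation={row["model"]: scores})


def evaluate_models(models: dict, sset: ScanpathSet,
                    centerbias_model) -> MetricsTable:
    """Table-style comparison of several models against one center bias."""
    cb_ll = average_loglik_bits(centerbias_model, sset)
    tables = [evaluate_model(m, sset, centerbias_ll=cb_ll, name=name)
              for name, m in models.items()]
    rows = pd.concat([t.rows for t in tables], ignore_index=True)
    per_image = {k: v for t in tables for k, v in t.per_image.items()}
    per_fix = {k: v for t in tables for k, v in t.per_fixation.items()}
    return MetricsTable(rows=rows, per_image=per_image, per_fixation=per_fix)
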