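"""The conditional fixation model: readout networks over image features.

Architecture: a fixed, pluggable backbone turns the image into a C-channel
feature stack at a downsampled grid.  Three small readout networks of 1x1
convolutions operate on that grid:

* the **spatial priority network** (SPN) maps the C feature channels to a
  d-channel priority map (8 -> 16 -> d channels, channel normalization
  before each layer, softplus after each layer);
* the **scanpath network** (SN) maps each history slot's 3 encoding maps
  through its own 1x1 convolution to 128 channels, sums the present slots,
  and applies normalization + a 1x1 convolution to 16 channels (softplus);
* the **fixation selection network** (FSN) concatenates priority and
  scanpath channels and maps them 128 -> 8 -> 1 (normalization before each
  layer, softplus after the hidden layers, linear final layer).

The scalar FSN output map is bilinearly upsampled to image resolution,
blurred with a trainable Gaussian, combined with the weighted log center
bias, and normalized with a softmax into the conditional fixation
distribution.  The trainable scalars are all readout weights, the blur
width sigma (positively reparameterized as exp) and the center-bias
weight w.

Channel normalization is per spatial location across channels (the natural
companion of 1x1 readouts): subtract the channel mean, divide by the
channel standard deviation, then apply a per-channel scale and shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from . import autograd as ag
from .autograd import Tensor
from .data_io import Scanpath
from .density import (
    IDENTITY_SIGMA,
    LogDensityGrid,
    bilinear_upsample_operator,
    blur_operator,
)
from .history import build_history_stack

_LN_EPS = 1e-12


# --------------------------------------------------------------------------
@dataclass(frozen=True)
class BackboneContract:
    """A deterministic image -> (C, H', W') feature extractor."""

    channels: int
    downsample_factor: int
    apply: callable


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if image.max() > 1.5:  # 8-bit input
        image = image / 255.0
    return image


def _avg_pool(m: np.ndarray, d: int) -> np.ndarray:
    h, w = m.shape
    ph, pw = (-h) % d, (-w) % d
    if ph or pw:
        m = np.pad(m, ((0, ph), (0, pw)), mode="edge")
    h2, w2 = m.shape
    return m.reshape(h2 // d, d, w2 // d, d).mean(axis=(1, 3))


def toy_backbone(seed: int, channels: int = 8, downsample_factor: int = 2) -> BackboneContract:
    """Seeded random 1x1 projections of multi-scale box-filtered intensity.

    A deterministic stand-in feature extractor for desk-scale experiments:
    grayscale intensity is box-filtered at scales 1, 2, 4, 8, average-pooled
    by the downsample factor and projected to ``channels`` maps by a fixed
    random linear map.  Intensity structure in the image (and hence any
    planted priority bumps) survives into the features.
    """
    if channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    proj = rng.normal(0.0, 1.0, size=(channels, 4))
    bias = rng.normal(0.0, 0.1, size=(channels, 1, 1))

    def apply(image: np.ndarray) -> np.ndarray:
        gray = _to_gray(image)
        scales = [uniform_filter(gray, size=s, mode="nearest") for s in (1, 2, 4, 8)]
        pooled = np.stack([_avg_pool(s, downsample_factor) for s in scales])
        feats = np.einsum("cs,shw->chw", proj, pooled) + bias
        return feats

    return BackboneContract(channels=channels, downsample_factor=downsample_factor,
                            apply=apply)


def constant_backbone(downsample_factor: int = 2) -> BackboneContract:
    """Single constant feature map: the image-content-ablated backbone."""

    def apply(image: np.ndarray) -> np.ndarray:
        gray = _to_gray(image)
        h = -(-gray.shape[0] // downsample_factor)
        w = -(-gray.shape[1] // downsample_factor)
        return np.ones((1, h, w))

    return BackboneContract(channels=1, downsample_factor=downsample_factor,
                            apply=apply)


# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation switches.

    ``k`` is the scanpath dependency order (number of most recent fixations
    the conditional may use), ``d`` the number of priority-map channels.
    ``blur_sigma_init`` is in readout-grid pixels; the effective image-scale
    initialization is ``blur_sigma_init * downsample`` of the backbone.
    """

    k: int = 4
    d: int = 1
    include_image: bool = True
    include_scanpath: bool = True
    backbone_channels: int = 2048
    downsample: int = 2
    spn_hidden: tuple = (8, 16)
    sn_slot_channels: int = 128
    sn_out_channels: int = 16
    fsn_hidden: tuple = (128, 8)
    blur_sigma_init: float = 5.0
    cb_weight_init: float = 1.0

    @property
    def effective_channels(self) -> int:
        return self.backbone_channels if self.include_image else 1

    @property
    def fsn_in_channels(self) -> int:
        base = self.d
        if self.include_scanpath and self.k > 0:
            base += self.sn_out_channels
        return base

    @property
    def uses_scanpath(self) -> bool:
        return self.include_scanpath and self.k > 0


def desk_model_config(**overrides) -> ModelConfig:
    """The desk-scale configuration used for synthetic-data experiments.

    Toy backbone with 16 channels at downsample 4 over 32 x 32 stimuli and
    narrower scanpath/fixation-selection readouts (32 slot channels,
    32 -> 8 selection hidden channels); the architecture is otherwise the
    standard one.
    """
    base = dict(k=4, d=1, backbone_channels=16, downsample=4,
                sn_slot_channels=32, fsn_hidden=(32, 8))
    base.update(overrides)
    return ModelConfig(**base)


def _spn_plan(cfg: ModelConfig):
    c = cfg.effective_channels
    dims = [c, *cfg.spn_hidden, cfg.d]
    return list(zip(dims[:-1], dims[1:]))


def _fsn_plan(cfg: ModelConfig):
    dims = [cfg.fsn_in_channels, *cfg.fsn_hidden, 1]
    return list(zip(dims[:-1], dims[1:]))


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict:
    """Fresh parameter dict: name -> autograd leaf tensor."""
    params = {}

    def norm(name, c):
        params[f"{name}.scale"] = ag.parameter(np.ones((c, 1)))
        params[f"{name}.shift"] = ag.parameter(np.zeros((c, 1)))

    def conv(name, cin, cout):
        w = rng.normal(0.0, 1.0 / math.sqrt(cin), size=(cout, cin))
        params[f"{name}.w"] = ag.parameter(w)
        params[f"{name}.b"] = ag.parameter(np.zeros((cout, 1)))

    for li, (cin, cout) in enumerate(_spn_plan(cfg)):
        norm(f"spn.{li}.norm", cin)
        conv(f"spn.{li}.conv", cin, cout)
    if cfg.uses_scanpath:
        for j in range(cfg.k):
            conv(f"sn.slot{j}.conv", 3, cfg.sn_slot_channels)
        norm("sn.out.norm", cfg.sn_slot_channels)
        conv("sn.out.conv", cfg.sn_slot_channels, cfg.sn_out_channels)
    for li, (cin, cout) in enumerate(_fsn_plan(cfg)):
        norm(f"fsn.{li}.norm", cin)
        conv(f"fsn.{li}.conv", cin, cout)
    params["sigma_raw"] = ag.parameter(math.log(cfg.blur_sigma_init * cfg.downsample))
    params["cb_weight"] = ag.parameter(cfg.cb_weight_init)
    return params


def clone_params(params: dict) -> dict:
    out = {}
    for name, t in params.items():
        c = ag.parameter(t.data.copy())
        out[name] = c
    return out


def count_parameters(cfg: ModelConfig) -> dict:
    """Trainable-scalar accounting per named layer and per network.

    A "layer" comprises its preceding per-channel normalization (scale and
    shift, 2 per channel) plus the 1x1 convolution weights and biases.
    """
    layers = {}
    for li, (cin, cout) in enumerate(_spn_plan(cfg)):
        layers[f"spn.{li}"] = 2 * cin + cin * cout + cout
    if cfg.uses_scanpath:
        for j in range(cfg.k):
            layers[f"sn.slot{j}"] = 3 * cfg.sn_slot_channels + cfg.sn_slot_channels
        layers["sn.out"] = (2 * cfg.sn_slot_channels
                            + cfg.sn_slot_channels * cfg.sn_out_channels
                            + cfg.sn_out_channels)
    for li, (cin, cout) in enumerate(_fsn_plan(cfg)):
        layers[f"fsn.{li}"] = 2 * cin + cin * cout + cout
    layers["sigma"] = 1
    layers["cb_weight"] = 1
    per_module = {
        "spn": sum(v for k, v in layers.items() if k.startswith("spn")),
        "sn": sum(v for k, v in layers.items() if k.startswith("sn")),
        "fsn": sum(v for k, v in layers.items() if k.startswith("fsn")),
        "finalizer": 2,
    }
    return {
        "layers": layers,
        "modules": per_module,
        "total": sum(layers.values()),
        "first_spn_layer": layers["spn.0"],
    }


# --------------------------------------------------------------------------
# forward passes (autograd tensors; arrays are (channels, locations))
def _channel_norm(x: Tensor, scale: Tensor, shift: Tensor) -> Tensor:
    # across-channel normalization is degenerate for a single channel
    # (it would erase the signal); fall back to the per-channel affine
    if x.shape[0] == 1:
        return scale * x + shift
    return ag.layer_norm(x, scale, shift, eps=_LN_EPS)


def _conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return ag.matmul(w, x) + b


def spn_forward(params: dict, cfg: ModelConfig, feats: Tensor) -> Tensor:
    """(C, N) features -> (d, N) nonnegative priority map."""
    x = feats
    for li in range(len(_spn_plan(cfg))):
        x = _channel_norm(x, params[f"spn.{li}.norm.scale"],
                          params[f"spn.{li}.norm.shift"])
        x = _conv1x1(x, params[f"spn.{li}.conv.w"], params[f"spn.{li}.conv.b"])
        x = ag.softplus(x)
    return x


def pack_histories(hists: list, k: int, n: int):
    """Pack B HistoryStacks into slot-major arrays for the batched SN.

    Returns (slots, mask_rep): slots is (k, 3, B*n), mask_rep is (k, 1, B*n)
    with the slot presence flag repeated over its locations.
    """
    b = len(hists)
    slots = np.empty((k, 3, b * n))
    mask_rep = np.empty((k, 1, b * n))
    for bi, hs in enumerate(hists):
        slots[:, :, bi * n:(bi + 1) * n] = hs.maps.reshape(k, 3, n)
        mask_rep[:, 0, bi * n:(bi + 1) * n] = hs.mask[:, None]
    return slots, mask_rep


def sn_forward(params: dict, cfg: ModelConfig, slots: np.ndarray,
               mask_rep: np.ndarray) -> Tensor:
    """Batched scanpath features: packed (k, 3, B*N) maps -> (16, B*N).

    Present slots pass through their slot convolution and are summed;
    masked slots contribute exactly zero.
    """
    k = slots.shape[0]
    acc = None
    for j in range(k):
        out = _conv1x1(Tensor(slots[j]), params[f"sn.slot{j}.conv.w"],
                       params[f"sn.slot{j}.conv.b"])
        out = out * Tensor(mask_rep[j])
        acc = out if acc is None else acc + out
    x = _channel_norm(acc, params["sn.out.norm.scale"], params["sn.out.norm.shift"])
    x = _conv1x1(x, params["sn.out.conv.w"], params["sn.out.conv.b"])
    return ag.softplus(x)


def fsn_forward(params: dict, cfg: ModelConfig, x: Tensor) -> Tensor:
    """(d[+16], B*N) -> (1, B*N); final layer linear."""
    n_layers = len(_fsn_plan(cfg))
    for li in range(n_layers):
        x = _channel_norm(x, params[f"fsn.{li}.norm.scale"],
                          params[f"fsn.{li}.norm.shift"])
        x = _conv1x1(x, params[f"fsn.{li}.conv.w"], params[f"fsn.{li}.conv.b"])
        if li < n_layers - 1:
            x = ag.softplus(x)
    return x


def blur2d(x: Tensor, sigma: Tensor) -> Tensor:
    """Gaussian blur of (B, H, W) with a trainable width.

    Custom node: the 1-D blur operators and their elementwise d/dsigma are
    built at the current sigma, giving exact gradients for both the grid
    and the width (away from the truncation-radius jumps, which form a
    measure-zero set).
    """
    s = float(sigma.data)
    _, h, w = x.data.shape
    Bh, dBh = blur_operator(h, s, with_grad=True)
    Bw, dBw = blur_operator(w, s, with_grad=True)
    out_data = np.einsum("ih,bhw,jw->bij", Bh, x.data, Bw, optimize=True)

    def vjp(g):
        gx = np.einsum("ih,bij,jw->bhw", Bh, g, Bw, optimize=True)
        ds = (np.einsum("bij,ih,bhw,jw->", g, dBh, x.data, Bw, optimize=True)
              + np.einsum("bij,ih,bhw,jw->", g, Bh, x.data, dBw, optimize=True))
        return gx, np.array(ds)

    return Tensor(out_data, parents=(x, sigma), vjp=vjp)


# --------------------------------------------------------------------------
class ScanpathModel:
    """Conditional fixation distribution p(f_i | f_{i-k} ... f_{i-1}, image)."""

    def __init__(self, config: ModelConfig, backbone: BackboneContract | None = None,
                 params: dict | None = None, seed: int = 0):
        if backbone is None:
            backbone = (toy_backbone(seed, config.backbone_channels, config.downsample)
                        if config.include_image
                        else constant_backbone(config.downsample))
        if not config.include_image and backbone.channels != 1:
            backbone = constant_backbone(config.downsample)
        if backbone.channels != config.effective_channels:
            raise ValueError("backbone channels do not match config")
        self.config = config
        self.backbone = backbone
        self.params = params if params is not None else init_params(
            config, np.random.default_rng(seed))
        self._feature_cache = {}

    # ---- bookkeeping ----------------------------------------------------
    def features_for(self, image_id: str, image: np.ndarray) -> np.ndarray:
        if image_id not in self._feature_cache:
            self._feature_cache[image_id] = self.backbone.apply(image)
        return self._feature_cache[image_id]

    def sigma(self) -> float:
        return float(np.exp(self.params["sigma_raw"].data))

    def cb_weight(self) -> float:
        return float(self.params["cb_weight"].data)

    # ---- forward --------------------------------------------------------
    def log_density_batch(self, feats: np.ndarray, hists: list,
                          log_cb: np.ndarray, use_scanpath=None) -> Tensor:
        """Normalized (B, H*W) log-density tensor for B history conditions.

        ``feats`` is the (C, H', W') backbone stack of one image, ``hists``
        a list of B HistoryStack objects or an already packed
        (slots, mask_rep) pair (may be empty when the model does not use
        the scanpath), ``log_cb`` the (H, W) log center bias at image
        resolution.
        """
        cfg = self.config
        if use_scanpath is None:
            use_scanpath = cfg.uses_scanpath
        c, gh, gw = feats.shape
        n = gh * gw
        if isinstance(hists, tuple):
            slots, mask_rep = hists
            b = slots.shape[2] // n
        else:
            b = len(hists) if hists else 1
            slots = mask_rep = None
        h, w = log_cb.shape

        priority = spn_forward(self.params, cfg, Tensor(feats.reshape(c, n)))
        pr_tiled = ag.tile_cols(priority, b)
        if use_scanpath:
            if slots is None:
                slots, mask_rep = pack_histories(hists, cfg.k, n)
            sfeat = sn_forward(self.params, cfg, slots, mask_rep)
            fsn_in = ag.concat_rows([pr_tiled, sfeat])
        elif cfg.uses_scanpath:
            # scanpath network removed for this pass (spatial training
            # phases): the FSN sees the SN's no-history constant, i.e. the
            # model behaves as if no previous fixation existed
            slots = np.zeros((cfg.k, 3, b * n))
            mask_rep = np.zeros((cfg.k, 1, b * n))
            sfeat = sn_forward(self.params, cfg, slots, mask_rep)
            fsn_in = ag.concat_rows([pr_tiled, sfeat])
        else:
            fsn_in = pr_tiled
        readout = fsn_forward(self.params, cfg, fsn_in).reshape(b, gh, gw)

        up_r = bilinear_upsample_operator(h, gh)
        up_c = bilinear_upsample_operator(w, gw)
        readout = ag.apply_rowcol(readout, up_r, up_c)
        sigma = self.params["sigma_raw"].exp()
        blurred = blur2d(readout, sigma)
        combined = blurred + self.params["cb_weight"] * Tensor(log_cb[None, :, :])
        flat = combined.reshape(b, h * w)
        lse = ag.logsumexp_rows(flat)
        return flat - lse.reshape(b, 1)

    def predict_conditional(self, image: np.ndarray, sp: Scanpath, i: int,
                            log_cb: np.ndarray, image_id=None) -> LogDensityGrid:
        """Conditional density of fixation i given the preceding history."""
        if i < 1:
            raise ValueError("the initial fixation has no conditional prediction")
        if log_cb is None:
            raise ValueError("a log center-bias grid is required")
        cfg = self.config
        feats = (self.features_for(image_id, image) if image_id is not None
                 else self.backbone.apply(image))
        gh, gw = feats.shape[1:]
        hists = []
        if cfg.uses_scanpath:
            hists = [build_history_stack(sp, i, cfg.k, (gh, gw),
                                         downsample=cfg.downsample)]
        out = self.log_density_batch(feats, hists, np.asarray(log_cb))
        vals = out.data[0].reshape(log_cb.shape)
        return LogDensityGrid(vals)

    # ---- conditional-model protocol (used by evaluation & sampling) -----
    def conditional(self, image: np.ndarray, sp: Scanpath, i: int,
                    log_cb: np.ndarray, image_id=None) -> LogDensityGrid:
        return self.predict_conditional(image, sp, i, log_cb, image_id=image_id)


# --------------------------------------------------------------------------
def save_params(params: dict, config: ModelConfig, path) -> None:
    """Checkpoint: one HDF5 dataset per named layer, config as JSON attr."""
    import json

    import h5py

    from dataclasses import asdict

    with h5py.File(path, "w") as fh:
        for name, t in params.items():
            fh.create_dataset(name, data=t.data)
        fh.attrs["config"] = json.dumps(asdict(config))


def load_params(path):
    """Load a checkpoint; returns (params dict, ModelConfig)."""
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        cfg_dict = json.loads(fh.attrs["config"])
        for key in ("spn_hidden", "fsn_hidden"):
            cfg_dict[key] = tuple(cfg_dict[key])
        params = {name: ag.parameter(fh[name][()]) for name in fh}
    return params, ModelConfig(**cfg_dict)
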