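"""Survival architectures assembled from the neural building blocks.

Four models share a Cox regression head (tanh hidden layers, linear
prognostic-index output) and the loss compositions:

* :class:`GeneSparseAECox` — pathway-masked supervised autoencoder on
  expression; loss = Cox + gene MSE + L2.
* :class:`ImageAECox` — supervised convolutional autoencoder on tumor
  crops; loss = Cox + image MSE + L2.
* :class:`HVAECox` — hierarchical model: the two low-level latent codes
  Z1 || Z2 feed a high-level beta-VAE whose mean, concatenated with
  clinical features, feeds the Cox head; loss = L_vae + Cox + L2.
* :class:`XATVAECox` — cross-attention beta-VAE taking images and
  expression directly: each modality is reduced to a q-dimensional
  feature, self-attended, then fused by two cross-attention layers
  (image-as-query and gene-as-query); loss =
  Kvl * (image MSE + gene MSE + capacity-regularized KL)
  + Kcl * (Cox + L2).
* :class:`BaselineVAECox` — the XAT architecture with a dense
  (unmasked) gene layer and no attention.

Inference is deterministic: the latent sample is replaced by the mean
and dropout is disabled, so repeated predictions are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .datatypes import PathwayMask, RadiogenomicsDataset, SurvivalLabels
from .layers import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dense,
    MaskedDense,
    Module,
    MultiHeadAttention,
    SparsePathwayLayer,
)
from .losses import (
    CapacitySchedule,
    capacity_regularizer_t,
    cox_loss_mean_t,
    cox_loss_t,
    kl_gaussian_t,
    l2_penalty_t,
    mse_loss_t,
)


@dataclass
class ModelOutputs:
    """Forward-pass results: reconstructions, latent code, prognostic index."""

    reconstructions: dict
    latent: dict
    pi: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.pi)):
            raise ValueError("prognostic index contains non-finite values")


@dataclass
class TrainConfig:
    """Optimization settings shared by all architectures."""

    epochs: int = 100
    lr: float = 5e-3
    lr_decay: float = 0.995        # exponential decay per step
    l2_lam: float = 1e-3
    Kvl: float = 1.0
    Kcl: float = 1.0
    dropout: float = 0.2
    seed: int = 0
    capacity: CapacitySchedule = field(default_factory=CapacitySchedule)
    # anneal the KL capacity target over this run's steps rather than the
    # (much longer) schedule horizon; see the methods note
    anneal_capacity_to_run: bool = True


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        if not train or self.p <= 0 or rng is None:
            return x
        keep = rng.binomial(1, 1.0 - self.p, size=x.shape) / (1.0 - self.p)
        return x * Tensor(keep)


class CoxHead(Module):
    """tanh hidden layers and a single linear output neuron (the PI)."""

    def __init__(self, n_in: int, rng, hidden=(16,), dropout: float = 0.0):
        self.layers = []
        for h in hidden:
            self.layers.append(Dense(n_in, h, rng, activation="tanh"))
            n_in = h
        self.out = Dense(n_in, 1, rng, activation=None)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng=None, train: bool = False) -> Tensor:
        x = self.drop(x, rng, train)
        for layer in self.layers:
            x = self.drop(layer(x), rng, train)
        n = x.shape[0]
        return self.out(x).reshape(n)


def _recon_mse_t(x: np.ndarray, x_hat) -> "Tensor":
    """Reconstruction loss: per-sample sum of squared errors over
    features/pixels, averaged over the batch."""
    n_feat = float(np.prod(x.shape[1:]))
    return mse_loss_t(Tensor(x), x_hat) * n_feat


def _clean_images(images) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.min() < 0 or images.max() > 1:
        warnings.warn("image intensities outside [0, 1]; clipping",
                      stacklevel=3)
        images = np.clip(images, 0.0, 1.0)
    return images


def _run_schedule(cfg: TrainConfig) -> CapacitySchedule:
    if cfg.anneal_capacity_to_run and cfg.capacity.mode == "capacity":
        return replace(cfg.capacity, capacity_max_iter=max(1, cfg.epochs - 1))
    return cfg.capacity


def _fit(model: Module, loss_fn, cfg: TrainConfig) -> list[float]:
    """Full-batch training loop; risk sets are batch-local by design."""
    opt = Adam(model.parameters(), lr=cfg.lr, lr_decay=cfg.lr_decay,
               constraints=model.constraints())
    history = []
    for step in range(cfg.epochs):
        model.zero_grad()
        loss = loss_fn(step)
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return history


# ---------------------------------------------------------------------------
# step 1: pathway-masked gene autoencoder with Cox head
# ---------------------------------------------------------------------------

@dataclass
class GeneSparseAECoxSpec:
    latent_dim: int = 8
    cox_hidden: tuple = (8,)
    diagonal_gene_layer: bool = False


class GeneSparseAECox(Module):
    def __init__(self, mask: PathwayMask, spec: GeneSparseAECoxSpec, rng):
        m, q = mask.n_genes, mask.n_pathways
        d = spec.latent_dim
        self.mask = mask
        self.spec = spec
        self.sparse = SparsePathwayLayer(mask, rng,
                                         diagonal_gene_layer=spec.diagonal_gene_layer)
        self.to_latent = Dense(q, d, rng, activation="relu")
        self.dec_pathway = Dense(d, q, rng, activation="relu")
        self.dec_genes = MaskedDense(mask.matrix.T, rng, activation=None)
        self.dec_out = Dense(m, m, rng, activation=None)
        self.cox = CoxHead(d, rng, hidden=spec.cox_hidden)

    def encode_t(self, expr: np.ndarray) -> Tensor:
        return self.to_latent(self.sparse(Tensor(expr)))

    def forward_t(self, expr: np.ndarray, rng=None, train: bool = False):
        z = self.encode_t(expr)
        recon = self.dec_out(self.dec_genes(self.dec_pathway(z)))
        pi = self.cox(z, rng, train)
        return {"z": z, "recon": recon, "pi": pi}

    def forward(self, expr) -> ModelOutputs:
        out = self.forward_t(np.asarray(expr, dtype=float))
        return ModelOutputs({"expression": out["recon"].data},
                            {"Z1": out["z"].data}, out["pi"].data)

    def loss_t(self, out, expr, labels: SurvivalLabels, cfg: TrainConfig):
        parts = {
            "cox": cox_loss_mean_t(out["pi"], labels),
            "mse": _recon_mse_t(expr, out["recon"]),
            "l2": l2_penalty_t(self.cox.parameters(), cfg.l2_lam),
        }
        return parts["cox"] + parts["mse"] + parts["l2"], parts

    def predict_pi(self, expr) -> np.ndarray:
        return self.forward(expr).pi

    def decode_latent(self, z: np.ndarray) -> np.ndarray:
        """Numpy decoder pass (used to map latent attributions to genes)."""
        return self.dec_out(self.dec_genes(self.dec_pathway(Tensor(z)))).data

    def input_gradients(self, expr):
        """PI and its gradient w.r.t. the expression input."""
        xe = Tensor(np.asarray(expr, dtype=float), requires_grad=True)
        pi = self.cox(self.to_latent(self.sparse(xe)))
        pi.sum().backward()
        return pi.data, {"gene": xe.grad}


def fit_gene_ae(expr, labels: SurvivalLabels, mask: PathwayMask,
                spec: GeneSparseAECoxSpec | None = None,
                cfg: TrainConfig | None = None) -> GeneSparseAECox:
    spec = spec or GeneSparseAECoxSpec()
    cfg = cfg or TrainConfig()
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] != mask.n_genes:
        raise ValueError("expression gene count does not match mask")
    rng = np.random.default_rng(cfg.seed)
    model = GeneSparseAECox(mask, spec, rng)
    model.cox.drop.p = cfg.dropout
    drop_rng = np.random.default_rng([cfg.seed, 7])

    def loss_fn(step):
        out = model.forward_t(expr, drop_rng, train=True)
        total, _ = model.loss_t(out, expr, labels, cfg)
        return total

    model.history = _fit(model, loss_fn, cfg)
    return model


# ---------------------------------------------------------------------------
# step 2: supervised convolutional image autoencoder with Cox head
# ---------------------------------------------------------------------------

@dataclass
class ImageAECoxSpec:
    channels: tuple = (4, 8)
    latent_dim: int = 8
    cox_hidden: tuple = (8,)
    input_size: tuple = (64, 64)
    pool: str = "gap"   # "gap": latent from channel means; "flatten": spatial


class ImageAECox(Module):
    def __init__(self, spec: ImageAECoxSpec, rng):
        c1, c2 = spec.channels
        H, W = spec.input_size
        if H % 4 or W % 4:
            raise ValueError("input size must be divisible by 4")
        self.spec = spec
        self.h2, self.w2, self.c2 = H // 4, W // 4, c2
        self.enc1 = Conv2d(1, c1, rng, stride=2, activation="relu",
                           bias_init=0.05)
        self.enc2 = Conv2d(c1, c2, rng, stride=2, activation="relu",
                           bias_init=0.05)
        flat = c2 * self.h2 * self.w2
        enc_in = c2 if spec.pool == "gap" else flat
        self.to_latent = Dense(enc_in, spec.latent_dim, rng, activation="relu")
        self.from_latent = Dense(spec.latent_dim, flat, rng, activation="relu")
        self.dec1 = ConvTranspose2d(c2, c1, rng, activation="relu")
        self.dec2 = ConvTranspose2d(c1, 1, rng, activation="sigmoid")
        self.cox = CoxHead(spec.latent_dim, rng, hidden=spec.cox_hidden)
        self._recorded = {}

    def encode_from(self, x4: Tensor, record: bool = False) -> Tensor:
        f1 = self.enc1(x4)
        f2 = self.enc2(f1)
        if record:
            self._recorded = {"conv1": f1, "conv2": f2}
        n = f2.shape[0]
        pooled = f2.mean(axis=(2, 3)) if self.spec.pool == "gap" \
            else f2.reshape(n, -1)
        return self.to_latent(pooled)

    def encode_t(self, images: np.ndarray, record: bool = False) -> Tensor:
        x4 = Tensor(np.asarray(images, dtype=float)[:, None])
        return self.encode_from(x4, record=record)

    def forward_t(self, images: np.ndarray, rng=None, train: bool = False,
                  record: bool = False):
        z = self.encode_t(images, record=record)
        n = z.shape[0]
        h = self.from_latent(z).reshape(n, self.c2, self.h2, self.w2)
        recon = self.dec2(self.dec1(h))
        recon = recon.reshape(n, *self.spec.input_size)
        pi = self.cox(z, rng, train)
        return {"z": z, "recon": recon, "pi": pi}

    def forward(self, images) -> ModelOutputs:
        out = self.forward_t(_clean_images(images))
        return ModelOutputs({"images": out["recon"].data},
                            {"Z2": out["z"].data}, out["pi"].data)

    def loss_t(self, out, images, labels: SurvivalLabels, cfg: TrainConfig):
        parts = {
            "cox": cox_loss_mean_t(out["pi"], labels),
            "mse": _recon_mse_t(images, out["recon"]),
            "l2": l2_penalty_t(self.cox.parameters(), cfg.l2_lam),
        }
        return parts["cox"] + parts["mse"] + parts["l2"], parts

    def predict_pi(self, images) -> np.ndarray:
        return self.forward(images).pi

    def conv_layer_names(self):
        return ["conv1", "conv2"]

    def input_gradients(self, images):
        """PI and its gradient w.r.t. the input images (n, H, W)."""
        x4 = Tensor(np.asarray(images, dtype=float)[:, None],
                    requires_grad=True)
        pi = self.cox(self.encode_from(x4))
        pi.sum().backward()
        return pi.data, {"image": x4.grad[:, 0]}

    def gradcam_maps(self, images, layer: str = "conv2"):
        """Activation maps of a conv layer and the gradient of PI
        w.r.t. them; inputs (n, H, W)."""
        if layer not in self.conv_layer_names():
            raise ValueError(f"layer {layer!r} not found; available: "
                             f"{self.conv_layer_names()}")
        x4 = Tensor(np.asarray(images, dtype=float)[:, None])
        pi = self.cox(self.encode_from(x4, record=True))
        pi.sum().backward()
        f = self._recorded[layer]
        return f.data, f.grad


def fit_image_ae(images, labels: SurvivalLabels,
                 spec: ImageAECoxSpec | None = None,
                 cfg: TrainConfig | None = None) -> ImageAECox:
    images = _clean_images(images)
    spec = spec or ImageAECoxSpec(input_size=images.shape[1:])
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model = ImageAECox(spec, rng)
    model.cox.drop.p = cfg.dropout
    drop_rng = np.random.default_rng([cfg.seed, 7])

    def loss_fn(step):
        out = model.forward_t(images, drop_rng, train=True)
        total, _ = model.loss_t(out, images, labels, cfg)
        return total

    model.history = _fit(model, loss_fn, cfg)
    return model


# ---------------------------------------------------------------------------
# step 3: high-level beta-VAE over Z1 || Z2 with clinical subnetwork
# ---------------------------------------------------------------------------

@dataclass
class HVAECoxSpec:
    latent_dim: int = 16
    encoder_hidden: int = 0   # 0: linear mu/logvar heads on the input
    clinical_hidden: int = 8
    clinical_out: int = 6
    cox_hidden: tuple = ()
    detach_cox_input: bool = False


class HVAECox(Module):
    """High-level variational model over the frozen low-level codes."""

    def __init__(self, input_dim: int, n_clinical: int, spec: HVAECoxSpec,
                 rng, bypass_encoder: bool = False):
        self.spec = spec
        self.bypass = bypass_encoder
        dz = input_dim if bypass_encoder else spec.latent_dim
        self.linear_encoder = spec.encoder_hidden == 0
        if not bypass_encoder:
            if self.linear_encoder:
                self.mu_head = Dense(input_dim, dz, rng)
                self.logvar_head = Dense(input_dim, dz, rng)
                self.dec2 = Dense(dz, input_dim, rng)
            else:
                self.enc = Dense(input_dim, spec.encoder_hidden, rng,
                                 activation="relu")
                self.mu_head = Dense(spec.encoder_hidden, dz, rng)
                self.logvar_head = Dense(spec.encoder_hidden, dz, rng)
                self.dec1 = Dense(dz, spec.encoder_hidden, rng,
                                  activation="relu")
                self.dec2 = Dense(spec.encoder_hidden, input_dim, rng)
        self.clin1 = Dense(n_clinical, spec.clinical_hidden, rng,
                           activation="relu")
        self.clin2 = Dense(spec.clinical_hidden, spec.clinical_out, rng,
                           activation="relu")
        self.cox = CoxHead(dz + spec.clinical_out, rng, hidden=spec.cox_hidden)

    def forward_t(self, z12, clinical, noise: np.ndarray | None = None,
                  rng=None, train: bool = False):
        x = as_tensor(z12)
        cfeat = self.clin2(self.clin1(as_tensor(clinical)))
        if self.bypass:
            mu = x
            out = {"mu": mu, "logvar": None, "z": mu, "recon": x, "kl": None}
        else:
            h = x if self.linear_encoder else self.enc(x)
            mu, logvar = self.mu_head(h), self.logvar_head(h)
            z = mu if noise is None else mu + (logvar * 0.5).exp() * Tensor(noise)
            recon = self.dec2(z) if self.linear_encoder \
                else self.dec2(self.dec1(z))
            out = {"mu": mu, "logvar": logvar, "z": z, "recon": recon,
                   "kl": kl_gaussian_t(mu, logvar)}
        mu_in = Tensor(out["mu"].data) \
            if (self.spec.detach_cox_input and train) else out["mu"]
        out["pi"] = self.cox(concat([mu_in, cfeat], axis=1), rng, train)
        return out

    def loss_t(self, out, z12, labels, step, cfg: TrainConfig):
        parts = {
            "cox": cox_loss_mean_t(out["pi"], labels),
            "l2": l2_penalty_t(self.cox.parameters(), cfg.l2_lam),
        }
        parts["vae"] = _recon_mse_t(z12, out["recon"]) + \
            capacity_regularizer_t(out["kl"], step, _run_schedule(cfg))
        return parts["vae"] + parts["cox"] + parts["l2"], parts


class HVAECoxBundle:
    """Trained three-step hierarchy: low-level AEs plus the high-level VAE.

    Low-level encoders are frozen while the high-level model trains.
    """

    def __init__(self, gene_model: GeneSparseAECox, image_model: ImageAECox,
                 high: HVAECox, z12_stats=None):
        self.gene_model = gene_model
        self.image_model = image_model
        self.high = high
        self.z12_stats = z12_stats   # (mean, sd) from the training fold

    def _check(self, images, expr, clinical):
        for name, arr in (("images", images), ("expression", expr),
                          ("clinical", clinical)):
            if arr is None:
                raise ValueError(f"missing modality: {name}")

    def low_level_codes(self, images, expr) -> np.ndarray:
        z1 = self.gene_model.encode_t(np.asarray(expr, dtype=float)).data
        z2 = self.image_model.encode_t(_clean_images(images)).data
        z12 = np.concatenate([z1, z2], axis=1)
        if self.z12_stats is not None:
            mean, sd = self.z12_stats
            z12 = (z12 - mean) / sd
        return z12

    def predict_pi(self, images=None, expr=None, clinical=None) -> np.ndarray:
        self._check(images, expr, clinical)
        z12 = self.low_level_codes(images, expr)
        out = self.high.forward_t(z12, np.asarray(clinical, dtype=float))
        return out["pi"].data

    def forward(self, images, expr, clinical) -> ModelOutputs:
        self._check(images, expr, clinical)
        z12 = self.low_level_codes(images, expr)
        out = self.high.forward_t(z12, np.asarray(clinical, dtype=float))
        sigma = np.exp(0.5 * out["logvar"].data) if out["logvar"] is not None \
            else None
        return ModelOutputs({"z12": out["recon"].data},
                            {"mu": out["mu"].data, "sigma": sigma},
                            out["pi"].data)

    def _graph_pi(self, xi: Tensor, xe: Tensor, xc: Tensor,
                  record: bool = False) -> Tensor:
        """Differentiable PI through the frozen low-level encoders."""
        z1 = self.gene_model.to_latent(self.gene_model.sparse(xe))
        z2 = self.image_model.encode_from(xi, record=record)
        z12 = concat([z1, z2], axis=1)
        if self.z12_stats is not None:
            mean, sd = self.z12_stats
            z12 = (z12 - Tensor(mean)) * Tensor(1.0 / sd)
        return self.high.forward_t(z12, xc)["pi"]

    def input_gradients(self, images, expr, clinical):
        """PI and its gradients w.r.t. all three modality inputs."""
        self._check(images, expr, clinical)
        xi = Tensor(np.asarray(images, dtype=float)[:, None],
                    requires_grad=True)
        xe = Tensor(np.asarray(expr, dtype=float), requires_grad=True)
        xc = Tensor(np.asarray(clinical, dtype=float), requires_grad=True)
        pi = self._graph_pi(xi, xe, xc)
        pi.sum().backward()
        zeros = lambda t: t.grad if t.grad is not None \
            else np.zeros_like(t.data)
        return pi.data, {"image": zeros(xi)[:, 0], "gene": zeros(xe),
                         "clinical": zeros(xc)}

    def gradcam_maps(self, images, expr, clinical, layer: str = "conv2"):
        """Conv activations of the image autoencoder and the gradient of
        the bundle PI w.r.t. them."""
        if layer not in self.image_model.conv_layer_names():
            raise ValueError(
                f"layer {layer!r} not found; available: "
                f"{self.image_model.conv_layer_names()}")
        xi = Tensor(np.asarray(images, dtype=float)[:, None])
        xe = Tensor(np.asarray(expr, dtype=float))
        xc = Tensor(np.asarray(clinical, dtype=float))
        pi = self._graph_pi(xi, xe, xc, record=True)
        pi.sum().backward()
        f = self.image_model._recorded[layer]
        return f.data, f.grad


def fit_hvae(dataset_arrays, labels: SurvivalLabels,
             gene_model: GeneSparseAECox, image_model: ImageAECox,
             spec: HVAECoxSpec | None = None,
             cfg: TrainConfig | None = None) -> HVAECoxBundle:
    """Train the high-level beta-VAE on frozen low-level codes.

    ``dataset_arrays`` is a dict with keys images / expression / clinical.
    """
    cfg = cfg or TrainConfig()
    bundle = HVAECoxBundle(gene_model, image_model, None)
    z12 = bundle.low_level_codes(dataset_arrays["images"],
                                 dataset_arrays["expression"])
    spec = spec or HVAECoxSpec(latent_dim=z12.shape[1])
    stats = (z12.mean(axis=0), z12.std(axis=0) + 1e-8)
    bundle.z12_stats = stats
    z12 = (z12 - stats[0]) / stats[1]
    clinical = np.asarray(dataset_arrays["clinical"], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    high = HVAECox(z12.shape[1], clinical.shape[1], spec, rng)
    high.cox.drop.p = cfg.dropout
    noise_rng = np.random.default_rng([cfg.seed, 11])
    drop_rng = np.random.default_rng([cfg.seed, 7])
    dz = spec.latent_dim

    def loss_fn(step):
        noise = noise_rng.standard_normal((z12.shape[0], dz))
        out = high.forward_t(z12, clinical, noise, drop_rng, train=True)
        total, _ = high.loss_t(out, z12, labels, step, cfg)
        return total

    high.history = _fit(high, loss_fn, cfg)
    bundle.high = high
    return bundle


# ---------------------------------------------------------------------------
# XAT-VAE-Cox and baseline VAE-Cox
# ---------------------------------------------------------------------------

@dataclass
class XATVAECoxSpec:
    channels: tuple = (4, 8)
    latent_dim: int = 12          # 2q at the test-bed pathway count
    n_heads: int = 2
    cox_hidden: tuple = ()
    input_size: tuple = (64, 64)
    use_attention: bool = True
    dense_gene_layer: bool = False
    detach_cox_input: bool = False
    normalize_cox_input: bool = True
    # keep the conv bank fixed at its random init: the desk-scale
    # stand-in for the frozen pretrained backbone of the image branch
    freeze_image_conv: bool = False
    whiten_cox_input: bool = True   # ZCA-whiten the Cox input features
    diagonal_gene_layer: bool = False


@dataclass
class BaselineVAECoxSpec(XATVAECoxSpec):
    use_attention: bool = False
    dense_gene_layer: bool = True


class XATVAECox(Module):
    """Cross-attention multimodal beta-VAE with a Cox head.

    Both branches emit q-dimensional features (q = number of pathways);
    features are treated as single tokens of width q for attention.
    """

    def __init__(self, mask: PathwayMask, n_clinical: int,
                 spec: XATVAECoxSpec, rng):
        c1, c2 = spec.channels
        H, W = spec.input_size
        if H % 4 or W % 4:
            raise ValueError("input size must be divisible by 4")
        m, q = mask.n_genes, mask.n_pathways
        self.mask, self.spec = mask, spec
        self.q = q
        self.h2, self.w2, self.c2 = H // 4, W // 4, c2
        # image branch: conv stack -> GAP -> q-dim feature
        self.img_conv1 = Conv2d(1, c1, rng, stride=2, activation="relu",
                                bias_init=0.05)
        self.img_conv2 = Conv2d(c1, c2, rng, stride=2, activation="relu",
                                bias_init=0.05)
        self.img_proj = Dense(c2, q, rng)   # linear: keeps the image
        # information intact under any init (attention maps are linear too)
        if spec.freeze_image_conv:
            for layer in (self.img_conv1, self.img_conv2):
                layer.W.requires_grad = layer.b.requires_grad = False
        # gene branch: pathway-masked (or dense) layer -> q-dim feature
        if spec.dense_gene_layer:
            self.gene_dense1 = Dense(m, m, rng, activation="relu",
                                     bias_init=0.1)
            self.gene_dense2 = Dense(m, q, rng, activation="relu",
                                     bias_init=0.1)
        else:
            self.gene_sparse = SparsePathwayLayer(
                mask, rng, diagonal_gene_layer=spec.diagonal_gene_layer)
        if spec.use_attention:
            self.img_self_attn = MultiHeadAttention(q, 1, rng)
            self.gene_self_attn = MultiHeadAttention(q, spec.n_heads, rng)
            self.cross_img_q = MultiHeadAttention(q, spec.n_heads, rng)
            self.cross_gene_q = MultiHeadAttention(q, spec.n_heads, rng)
        dz = spec.latent_dim
        self.mu_head = Dense(2 * q, dz, rng)
        self.logvar_head = Dense(2 * q, dz, rng)
        # decoders
        flat = c2 * self.h2 * self.w2
        self.dec_img_fc = Dense(dz, flat, rng, activation="relu")
        self.dec_img1 = ConvTranspose2d(c2, c1, rng, activation="relu")
        self.dec_img2 = ConvTranspose2d(c1, 1, rng, activation="sigmoid")
        self.dec_gene_fc = Dense(dz, q, rng, activation="relu")
        self.dec_gene_out = Dense(q, m, rng)
        self.clin_layer = Dense(n_clinical, n_clinical, rng, activation="relu")
        self.cox = CoxHead(dz + n_clinical, rng, hidden=spec.cox_hidden)
        self._recorded = {}
        # feature scaling of the detached Cox input, frozen after training
        self._cox_stats = None

    # -- branches ------------------------------------------------------
    def _image_feature(self, images, record: bool = False) -> Tensor:
        x = images if isinstance(images, Tensor) \
            else Tensor(np.asarray(images, dtype=float)[:, None])
        f1 = self.img_conv1(x)
        f2 = self.img_conv2(f1)
        if record:
            self._recorded = {"conv1": f1, "conv2": f2}
        pooled = f2.mean(axis=(2, 3))            # global average pool
        return self.img_proj(pooled)             # (n, q)

    def _gene_feature(self, expr) -> Tensor:
        expr = as_tensor(expr)
        if self.spec.dense_gene_layer:
            return self.gene_dense2(self.gene_dense1(expr))
        return self.gene_sparse(expr)

    def encode_t(self, images, expr, record: bool = False):
        img = self._image_feature(images, record=record)
        gene = self._gene_feature(expr)
        if img.shape[-1] != self.q or gene.shape[-1] != self.q:
            raise ValueError("both branches must emit q-dim features")
        if self.spec.use_attention:
            n = img.shape[0]
            img_tok = img.reshape(n, 1, self.q)
            gene_tok = gene.reshape(n, 1, self.q)
            img_tok = self.img_self_attn(img_tok, img_tok, img_tok)
            gene_tok = self.gene_self_attn(gene_tok, gene_tok, gene_tok)
            xa_img = self.cross_img_q(img_tok, gene_tok, gene_tok)
            xa_gene = self.cross_gene_q(gene_tok, img_tok, img_tok)
            fused = concat([xa_img.reshape(n, self.q),
                            xa_gene.reshape(n, self.q)], axis=1)
        else:
            fused = concat([img, gene], axis=1)
        return self.mu_head(fused), self.logvar_head(fused)

    def forward_t(self, images, expr, clinical, noise=None, rng=None,
                  train: bool = False, record: bool = False):
        mu, logvar = self.encode_t(images, expr, record=record)
        z = mu if noise is None else mu + (logvar * 0.5).exp() * Tensor(noise)
        n = z.shape[0]
        h = self.dec_img_fc(z).reshape(n, self.c2, self.h2, self.w2)
        img_recon = self.dec_img2(self.dec_img1(h)).reshape(
            n, *self.spec.input_size)
        gene_recon = self.dec_gene_out(self.dec_gene_fc(z))
        cfeat = self.clin_layer(as_tensor(clinical))
        # the Cox gradient is blocked from the encoder only while
        # training; at inference/attribution the full graph is kept
        mu_in = Tensor(mu.data) if (self.spec.detach_cox_input and train) \
            else mu
        if self.spec.normalize_cox_input:
            if train or self._cox_stats is None:
                arr = mu.data
                mean = arr.mean(axis=0)
                if self.spec.whiten_cox_input and arr.shape[0] > arr.shape[1]:
                    cov = np.cov(arr, rowvar=False) + 1e-4 * np.eye(arr.shape[1])
                    vals, vecs = np.linalg.eigh(cov)
                    transform = vecs @ np.diag(vals ** -0.5) @ vecs.T
                else:
                    transform = np.diag(1.0 / (arr.std(axis=0) + 1e-8))
                stats = (mean, transform)
                if train:
                    self._cox_stats = stats
            else:
                stats = self._cox_stats
            mu_in = (mu_in - Tensor(stats[0])) @ Tensor(stats[1])
        pi = self.cox(concat([mu_in, cfeat], axis=1), rng, train)
        return {"mu": mu, "logvar": logvar, "z": z, "img_recon": img_recon,
                "gene_recon": gene_recon, "pi": pi,
                "kl": kl_gaussian_t(mu, logvar)}

    def forward(self, images, expr, clinical) -> ModelOutputs:
        out = self.forward_t(_clean_images(images),
                             np.asarray(expr, dtype=float),
                             np.asarray(clinical, dtype=float))
        return ModelOutputs(
            {"images": out["img_recon"].data,
             "expression": out["gene_recon"].data},
            {"mu": out["mu"].data,
             "sigma": np.exp(0.5 * out["logvar"].data)},
            out["pi"].data)

    def loss_t(self, out, images, expr, labels: SurvivalLabels, step: int,
               cfg: TrainConfig):
        parts = {
            "img_mse": _recon_mse_t(images, out["img_recon"]),
            "gene_mse": _recon_mse_t(expr, out["gene_recon"]),
            "kl_reg": capacity_regularizer_t(out["kl"], step,
                                             _run_schedule(cfg)),
            "cox": cox_loss_mean_t(out["pi"], labels),
            "l2": l2_penalty_t(self.cox.parameters(), cfg.l2_lam),
        }
        parts["xvae"] = parts["img_mse"] + parts["gene_mse"] + parts["kl_reg"]
        total = parts["xvae"] * cfg.Kvl + (parts["cox"] + parts["l2"]) * cfg.Kcl
        return total, parts

    def predict_pi(self, images=None, expr=None, clinical=None) -> np.ndarray:
        for name, arr in (("images", images), ("expression", expr),
                          ("clinical", clinical)):
            if arr is None:
                raise ValueError(f"missing modality: {name}")
        return self.forward(images, expr, clinical).pi

    def gene_branch_param_count(self, effective: bool = True) -> int:
        if self.spec.dense_gene_layer:
            return int(sum(p.data.size for p in
                           (self.gene_dense1.W, self.gene_dense1.b,
                            self.gene_dense2.W, self.gene_dense2.b)))
        s = self.gene_sparse
        w_count = int(s.A.data.sum()) if effective else s.W.data.size
        w0 = s.W0.data.size
        return w0 + s.b0.data.size + w_count + s.b.data.size

    def conv_layer_names(self):
        return ["conv1", "conv2"]

    def input_gradients(self, images, expr, clinical):
        """PI and its gradients w.r.t. all three modality inputs."""
        xi = Tensor(np.asarray(images, dtype=float)[:, None],
                    requires_grad=True)
        xe = Tensor(np.asarray(expr, dtype=float), requires_grad=True)
        xc = Tensor(np.asarray(clinical, dtype=float), requires_grad=True)
        out = self.forward_t(xi, xe, xc)
        out["pi"].sum().backward()
        zeros = lambda t, a: t.grad if t.grad is not None else np.zeros_like(a)
        return out["pi"].data, {
            "image": zeros(xi, xi.data)[:, 0],
            "gene": zeros(xe, xe.data),
            "clinical": zeros(xc, xc.data),
        }

    def gradcam_maps(self, images, expr, clinical, layer: str = "conv2"):
        if layer not in self.conv_layer_names():
            raise ValueError(f"layer {layer!r} not found; available: "
                             f"{self.conv_layer_names()}")
        out = self.forward_t(np.asarray(images, dtype=float),
                             np.asarray(expr, dtype=float),
                             np.asarray(clinical, dtype=float), record=True)
        out["pi"].sum().backward()
        f = self._recorded[layer]
        return f.data, f.grad


class BaselineVAECox(XATVAECox):
    """Ablation: dense gene layer, no attention, same loss composition."""

    def __init__(self, mask: PathwayMask, n_clinical: int,
                 spec: BaselineVAECoxSpec | None = None, rng=None):
        spec = spec or BaselineVAECoxSpec()
        if spec.use_attention or not spec.dense_gene_layer:
            raise ValueError("baseline removes attention and the mask")
        super().__init__(mask, n_clinical, spec, rng)


def fit_xat(dataset_arrays, labels: SurvivalLabels, mask: PathwayMask,
            spec: XATVAECoxSpec | None = None,
            cfg: TrainConfig | None = None,
            pretrained: tuple | None = None,
            freeze_pretrained: bool = False) -> XATVAECox:
    """Train XAT-VAE-Cox (or the baseline, given a BaselineVAECoxSpec).

    ``pretrained`` optionally supplies ``(gene_model, image_model)`` —
    trained low-level autoencoders whose conv stack and sparse pathway
    layer warm-start the corresponding XAT branches, standing in for the
    pretrained backbone of the full-scale architecture.
    """
    images = _clean_images(dataset_arrays["images"])
    expr = np.asarray(dataset_arrays["expression"], dtype=float)
    clinical = np.asarray(dataset_arrays["clinical"], dtype=float)
    spec = spec or XATVAECoxSpec(input_size=images.shape[1:])
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    cls = BaselineVAECox if isinstance(spec, BaselineVAECoxSpec) else XATVAECox
    model = cls(mask, clinical.shape[1], spec, rng)
    model.cox.drop.p = cfg.dropout
    if pretrained is not None:
        gene_model, image_model = pretrained
        if image_model is not None:
            for src, dst in ((image_model.enc1, model.img_conv1),
                             (image_model.enc2, model.img_conv2)):
                dst.W.data = src.W.data.copy()
                dst.b.data = src.b.data.copy()
                if freeze_pretrained:
                    dst.W.requires_grad = dst.b.requires_grad = False
        if gene_model is not None and not spec.dense_gene_layer:
            src, dst = gene_model.sparse, model.gene_sparse
            dst.W0.data = src.W0.data.copy()
            dst.b0.data = src.b0.data.copy()
            dst.W.data = src.W.data.copy()
            dst.b.data = src.b.data.copy()
            if freeze_pretrained:
                for t in (dst.W0, dst.b0, dst.W, dst.b):
                    t.requires_grad = False
    noise_rng = np.random.default_rng([cfg.seed, 11])
    drop_rng = np.random.default_rng([cfg.seed, 7])
    dz = spec.latent_dim

    def loss_fn(step):
        noise = noise_rng.standard_normal((len(images), dz))
        out = model.forward_t(images, expr, clinical, noise, drop_rng,
                              train=True)
        total, _ = model.loss_t(out, images, expr, labels, step, cfg)
        return total

    model.history = _fit(model, loss_fn, cfg)
    return model


def predict_pi(model, dataset: RadiogenomicsDataset) -> np.ndarray:
    """Deterministic prognostic index of a trained model on a dataset."""
    if isinstance(model, GeneSparseAECox):
        return model.predict_pi(dataset.expression.values)
    if isinstance(model, ImageAECox):
        return model.predict_pi(dataset.images.values)
    return model.predict_pi(images=dataset.images.values,
                            expr=dataset.expression.values,
                            clinical=dataset.clinical.values)
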