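"""Model families: uniform fit/predict adapters for nested CV.

Each family standardizes expression and clinical covariates with
statistics of its own training fold (images are already in [0, 1]),
maps a tuner configuration dict onto a :class:`TrainConfig`, trains the
architecture at its desk-scale recipe and predicts prognostic indices
on held-out data with the same preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import PathwayMask, RadiogenomicsDataset
from .models import (
    BaselineVAECoxSpec,
    GeneSparseAECoxSpec,
    HVAECoxSpec,
    ImageAECoxSpec,
    TrainConfig,
    XATVAECoxSpec,
    fit_gene_ae,
    fit_hvae,
    fit_image_ae,
    fit_xat,
)


@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "_Standardizer":
        return cls(values.mean(axis=0), values.std(axis=0) + 1e-8)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd


@dataclass
class FittedModel:
    model: object
    expr_std: _Standardizer | None
    clin_std: _Standardizer | None
    family: str


def _train_config(config: dict, epochs: int, seed: int,
                  base: TrainConfig) -> TrainConfig:
    known = {k: v for k, v in config.items()
             if k in ("lr", "lr_decay", "dropout", "l2_lam", "Kvl", "Kcl")}
    return replace(base, epochs=epochs, seed=seed, **known)


class _Family:
    """Shared preprocessing + config plumbing for all families."""

    name = "base"
    default_epochs = 100
    base_config = TrainConfig()

    def __init__(self, mask: PathwayMask | None = None, **spec_kwargs):
        self.mask = mask
        self.spec_kwargs = spec_kwargs

    def _arrays(self, dataset: RadiogenomicsDataset, expr_std, clin_std):
        return {
            "images": dataset.images.values,
            "expression": expr_std(dataset.expression.values)
            if expr_std else dataset.expression.values,
            "clinical": clin_std(dataset.clinical.values)
            if clin_std else dataset.clinical.values,
        }

    def fit(self, dataset: RadiogenomicsDataset, config: dict | None = None,
            epochs: int | None = None, seed: int = 0) -> FittedModel:
        config = config or {}
        epochs = epochs or self.default_epochs
        expr_std = _Standardizer.fit(dataset.expression.values)
        clin_std = _Standardizer.fit(dataset.clinical.values)
        arrays = self._arrays(dataset, expr_std, clin_std)
        cfg = _train_config(config, epochs, seed, self.base_config)
        model = self._fit(arrays, dataset, cfg, config)
        return FittedModel(model, expr_std, clin_std, self.name)

    def predict(self, fitted: FittedModel, dataset: RadiogenomicsDataset
                ) -> np.ndarray:
        arrays = self._arrays(dataset, fitted.expr_std, fitted.clin_std)
        return self._predict(fitted.model, arrays)


class GeneAEFamily(_Family):
    """Pathway-masked gene autoencoder with Cox head (expression only)."""

    name = "gene_sparse_ae_cox"
    default_epochs = 200
    base_config = TrainConfig(dropout=0.2, l2_lam=1e-3)

    def _fit(self, arrays, dataset, cfg, config):
        spec = GeneSparseAECoxSpec(
            cox_hidden=tuple(config.get("cox_hidden", (8,))),
            **self.spec_kwargs)
        return fit_gene_ae(arrays["expression"], dataset.labels, self.mask,
                           spec=spec, cfg=cfg)

    def _predict(self, model, arrays):
        return model.predict_pi(arrays["expression"])


class ImageAEFamily(_Family):
    """Supervised convolutional autoencoder with Cox head (images only)."""

    name = "image_ae_cox"
    default_epochs = 100
    base_config = TrainConfig(dropout=0.2, l2_lam=1e-3)

    def _fit(self, arrays, dataset, cfg, config):
        spec = ImageAECoxSpec(
            input_size=arrays["images"].shape[1:],
            cox_hidden=tuple(config.get("cox_hidden", (8,))),
            **self.spec_kwargs)
        return fit_image_ae(arrays["images"], dataset.labels, spec=spec,
                            cfg=cfg)

    def _predict(self, model, arrays):
        return model.predict_pi(arrays["images"])


class HVAEFamily(_Family):
    """Three-step hierarchy: low-level AEs plus high-level beta-VAE-Cox.

    The low-level autoencoders are trained within each call (frozen for
    step 3); ``epochs`` controls the high-level stage while the
    low-level stages use their family recipes.
    """

    name = "hvae_cox"
    default_epochs = 400
    base_config = TrainConfig(dropout=0.3, l2_lam=0.03)
    gene_epochs = 200
    image_epochs = 100

    def _fit(self, arrays, dataset, cfg, config):
        gene_cfg = TrainConfig(epochs=self.gene_epochs, dropout=0.2,
                               l2_lam=1e-3, seed=cfg.seed)
        image_cfg = TrainConfig(epochs=self.image_epochs, dropout=0.2,
                                l2_lam=1e-3, seed=cfg.seed)
        gene_model = fit_gene_ae(arrays["expression"], dataset.labels,
                                 self.mask, cfg=gene_cfg)
        image_model = fit_image_ae(arrays["images"], dataset.labels,
                                   cfg=image_cfg)
        spec = HVAECoxSpec(cox_hidden=tuple(config.get("cox_hidden", ())),
                           **self.spec_kwargs)
        return fit_hvae(arrays, dataset.labels, gene_model, image_model,
                        spec=spec, cfg=cfg)

    def _predict(self, bundle, arrays):
        return bundle.predict_pi(images=arrays["images"],
                                 expr=arrays["expression"],
                                 clinical=arrays["clinical"])


class XATFamily(_Family):
    """Cross-attention multimodal beta-VAE-Cox."""

    name = "xat_vae_cox"
    default_epochs = 100
    base_config = TrainConfig(dropout=0.3, l2_lam=0.03, Kcl=5.0)
    spec_cls = XATVAECoxSpec

    def _fit(self, arrays, dataset, cfg, config):
        spec = self.spec_cls(
            input_size=arrays["images"].shape[1:],
            cox_hidden=tuple(config.get("cox_hidden", ())),
            **self.spec_kwargs)
        return fit_xat(arrays, dataset.labels, self.mask, spec=spec, cfg=cfg)

    def _predict(self, model, arrays):
        return model.predict_pi(images=arrays["images"],
                                expr=arrays["expression"],
                                clinical=arrays["clinical"])


class BaselineFamily(XATFamily):
    """Ablation: dense gene layer, no attention, same protocol."""

    name = "baseline_vae_cox"
    spec_cls = BaselineVAECoxSpec


class OracleFamily(_Family):
    """Upper-bound harness: PI = true log-hazard from the ground truth.

    Used to check the evaluation protocol itself; requires the
    per-sample true log-hazard keyed by sample id.
    """

    name = "oracle"

    def __init__(self, log_hazard_by_id: dict):
        super().__init__()
        self.log_hazard_by_id = log_hazard_by_id

    def fit(self, dataset, config=None, epochs=None, seed=0):
        return FittedModel(None, None, None, self.name)

    def predict(self, fitted, dataset):
        return np.array([self.log_hazard_by_id[s] for s in dataset.sample_ids])


class ConstantFamily(_Family):
    """Degenerate reference: a constant prognostic index."""

    name = "constant"

    def fit(self, dataset, config=None, epochs=None, seed=0):
        return FittedModel(None, None, None, self.name)

    def predict(self, fitted, dataset):
        return np.zeros(dataset.n_samples)
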