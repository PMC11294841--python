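"""Core domain containers for multimodal radiogenomic survival data.

Every container validates its invariants at construction time so that
downstream model code can assume clean, aligned, finite inputs. Sample
alignment across modalities is the responsibility of
:func:`radiosurv.preprocess.align_samples`, which produces a
:class:`RadiogenomicsDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_str_list(ids) -> list[str]:
    return [str(x) for x in ids]


@dataclass
class SurvivalLabels:
    """Right-censored survival outcomes.

    Parameters
    ----------
    time
        Positive follow-up times (days).
    event
        Censoring indicator per sample: 1 if the event (death) was
        observed, 0 if the subject left observation event-free.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or self.event.ndim != 1:
            raise ValueError("time and event must be 1-D")
        if len(self.time) != len(self.event):
            raise ValueError("time and event must have equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all survival times must be finite and > 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValueError("event indicators must be 0 or 1")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalLabels":
        return SurvivalLabels(self.time[idx], self.event[idx])


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with ordered identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    allow_missing: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not self.allow_missing and not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite entries; "
                             "run imputation first or pass allow_missing=True")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx], self.gene_ids,
            [self.sample_ids[i] for i in idx], allow_missing=self.allow_missing,
        )


@dataclass
class ImageStack:
    """Per-sample 2-D grayscale images with intensities in [0, 1]."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.values.ndim != 3:
            raise ValueError("image stack must be 3-D (samples x H x W)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("images contain non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("image intensities must be normalized to [0, 1]")

    @property
    def shape(self):
        return self.values.shape[1:]

    def subset(self, idx) -> "ImageStack":
        idx = np.asarray(idx)
        return ImageStack(self.values[idx], [self.sample_ids[i] for i in idx])


@dataclass
class ClinicalTable:
    """Numeric-encoded clinical covariates (samples x c)."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = _as_str_list(self.feature_names)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("clinical table must be 2-D with >= 1 covariate")
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("clinical table shape inconsistent with id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clinical covariates must be finite")

    def subset(self, idx) -> "ClinicalTable":
        idx = np.asarray(idx)
        return ClinicalTable(self.values[idx], self.feature_names,
                             [self.sample_ids[i] for i in idx])


@dataclass
class PathwaySet:
    """Named, non-empty collections of gene identifiers."""

    sets: dict[str, list[str]]

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} is empty")
        # dedup while preserving order
        self.sets = {n: list(dict.fromkeys(g)) for n, g in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PathwayMask:
    """Binary gene x pathway membership matrix A.

    ``A[i, j] == 1`` iff gene i belongs to pathway j. Injected into the
    pathway layer of the sparse networks as an element-wise weight mask.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.pathway_names = _as_str_list(self.pathway_names)
        if self.matrix.shape != (len(self.gene_ids), len(self.pathway_names)):
            raise ValueError("mask shape inconsistent with id lists")
        if not np.all(np.isin(self.matrix, [0, 1])):
            raise ValueError("mask entries must be 0 or 1")
        if self.matrix.shape[1] and np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError("every retained pathway must contain >= 1 gene")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RadiogenomicsDataset:
    """Aligned multimodal dataset: one sample ordering across members."""

    images: ImageStack
    expression: ExpressionMatrix
    clinical: ClinicalTable
    labels: SurvivalLabels

    def __post_init__(self):
        n = len(self.labels)
        ids = self.images.sample_ids
        if not (self.expression.n_samples == n
                and self.images.values.shape[0] == n
                and self.clinical.values.shape[0] == n):
            raise ValueError("all modalities must carry the same sample count")
        if not (self.expression.sample_ids == ids == self.clinical.sample_ids):
            raise ValueError("all modalities must share one sample ordering")

    @property
    def sample_ids(self) -> list[str]:
        return self.images.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "RadiogenomicsDataset":
        return RadiogenomicsDataset(
            images=self.images.subset(idx),
            expression=self.expression.subset(idx),
            clinical=self.clinical.subset(idx),
            labels=self.labels.subset(idx),
        )
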