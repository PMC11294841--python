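"""Preprocessing rules shared by all pipeline stages.

Gene filtering and imputation operate on expression matrices that may
still contain missing values (``allow_missing=True``); alignment
produces the canonical :class:`~radiosurv.datatypes.RadiogenomicsDataset`
used everywhere downstream.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    ImageStack,
    PathwayMask,
    PathwaySet,
    RadiogenomicsDataset,
    SurvivalLabels,
)


def build_pathway_mask(sets: PathwaySet, gene_ids) -> PathwayMask:
    """Build the binary gene x pathway membership mask A.

    ``A[i, j] = 1`` iff gene i is a member of pathway j. Pathways with no
    overlap with ``gene_ids`` are dropped; genes belonging to no pathway
    keep an all-zero row so attribution indices always cover the full
    gene list.
    """
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) == 0:
        raise ValueError("gene_ids must be non-empty")
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    columns = []
    kept_names = []
    for name in sets.names:
        col = np.zeros(len(gene_ids))
        for g in sets[name]:
            i = gene_index.get(str(g))
            if i is not None:
                col[i] = 1.0
        if col.sum() > 0:
            columns.append(col)
            kept_names.append(name)
    matrix = np.column_stack(columns) if columns else np.zeros((len(gene_ids), 0))
    return PathwayMask(matrix, gene_ids, kept_names)


def filter_genes_by_missingness(raw: ExpressionMatrix,
                                max_na_fraction: float = 0.7) -> ExpressionMatrix:
    """Drop genes missing in more than ``max_na_fraction`` of samples.

    A gene is retained iff its missing fraction is <= the threshold
    (strictly greater is dropped); retained gene order is preserved.
    """
    if not 0 <= max_na_fraction <= 1:
        raise ValueError("max_na_fraction must lie in [0, 1]")
    na_frac = np.mean(np.isnan(raw.values), axis=0)
    keep = na_frac <= max_na_fraction
    if not keep.any():
        raise ValueError("missingness filter removed all genes")
    return ExpressionMatrix(
        raw.values[:, keep],
        [g for g, k in zip(raw.gene_ids, keep) if k],
        raw.sample_ids,
        allow_missing=True,
    )


def impute_missing(expr: ExpressionMatrix,
                   strategy: str = "gene_median") -> ExpressionMatrix:
    """Replace missing entries by the per-gene median of observed values.

    A deterministic, pluggable stand-in for model-based dropout
    imputation: observed entries are never modified.
    """
    if strategy != "gene_median":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = expr.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return ExpressionMatrix(values, expr.gene_ids, expr.sample_ids)
    n_obs = (~missing).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [g for g, n in zip(expr.gene_ids, n_obs) if n == 0]
        raise ValueError(f"genes with zero observed values cannot be imputed: {bad[:5]}")
    medians = np.nanmedian(values, axis=0)
    values[missing] = np.broadcast_to(medians, values.shape)[missing]
    return ExpressionMatrix(values, expr.gene_ids, expr.sample_ids)


def align_samples(images: ImageStack, expression: ExpressionMatrix,
                  clinical: ClinicalTable, labels_ids, labels: SurvivalLabels
                  ) -> RadiogenomicsDataset:
    """Intersect sample ids across modalities and re-index to sorted order.

    The canonical sample order is the lexicographic sort of the shared
    ids, so any permutation of the inputs yields an identical dataset.
    """
    labels_ids = [str(s) for s in labels_ids]
    if len(labels_ids) != len(labels):
        raise ValueError("labels_ids length must match labels")
    common = (set(images.sample_ids) & set(expression.sample_ids)
              & set(clinical.sample_ids) & set(labels_ids))
    if not common:
        raise ValueError("no samples shared by all modalities")
    order = sorted(common)

    def positions(ids):
        lookup = {s: i for i, s in enumerate(ids)}
        return np.array([lookup[s] for s in order])

    return RadiogenomicsDataset(
        images=images.subset(positions(images.sample_ids)),
        expression=expression.subset(positions(expression.sample_ids)),
        clinical=clinical.subset(positions(clinical.sample_ids)),
        labels=labels.subset(positions(labels_ids)),
    )
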